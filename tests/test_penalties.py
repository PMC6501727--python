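"""Group layout construction, penalty values and their activation gradients."""

import numpy as np
import pytest

from glsdbn.penalties import (
    GroupStructure,
    PenaltyConfig,
    build_groups,
    cauchy_value,
    group_lasso_value,
    penalty_grad_activations,
    penalty_value,
)


def _fd_grad(P, cfg, groups, eps=1e-6):
    """Central finite differences of penalty_value wrt each activation."""
    num = np.zeros_like(P)
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            Pp, Pm = P.copy(), P.copy()
            Pp[i, j] += eps
            Pm[i, j] -= eps
            num[i, j] = (
                penalty_value(Pp, cfg, groups) - penalty_value(Pm, cfg, groups)
            ) / (2 * eps)
    return num


class TestBuildGroups:
    def test_strict_overlapping_layout(self):
        gs = build_groups(13, 3, 0.2, mode="strict")
        assert gs.group_size == 5 and gs.overlap_size == 1
        assert [g.tolist() for g in gs.groups] == [
            [0, 1, 2, 3, 4],
            [4, 5, 6, 7, 8],
            [8, 9, 10, 11, 12],
        ]

    def test_zero_overlap_is_even_partition(self):
        gs = build_groups(6, 3, 0.0, mode="strict")
        assert [g.tolist() for g in gs.groups] == [[0, 1], [2, 3], [4, 5]]

    def test_single_group_covers_everything(self):
        gs = build_groups(10, 1, 0.5, mode="strict")
        assert gs.n_groups == 1 and gs.groups[0].tolist() == list(range(10))

    def test_strict_infeasible_reports_nearest_feasible(self):
        with pytest.raises(ValueError, match="nearest feasible"):
            build_groups(500, 10, 0.2, mode="strict")

    @pytest.mark.parametrize("n", range(4, 60, 3))
    @pytest.mark.parametrize("n_groups", [1, 2, 3, 5])
    @pytest.mark.parametrize("alpha", [0.0, 0.2, 0.5])
    def test_relaxed_always_covers(self, n, n_groups, alpha):
        gs = build_groups(n, n_groups, alpha, mode="relaxed")
        covered = np.zeros(n, dtype=bool)
        for g in gs.groups:
            covered[g] = True
        assert covered.all()
        assert gs.n_groups == n_groups

    def test_json_round_trip(self):
        gs = build_groups(13, 3, 0.2, mode="strict")
        gs2 = GroupStructure.from_json(gs.to_json())
        assert gs2.n_hidden == 13
        assert all((a == b).all() for a, b in zip(gs.groups, gs2.groups))


class TestPenaltyValues:
    def test_group_lasso_worked_example(self):
        gs = GroupStructure(3, (np.array([0, 1]), np.array([1, 2])))
        P = np.array([[0.3, 0.4, 0.0]])
        assert group_lasso_value(P, gs) == pytest.approx(0.9, abs=1e-12)

    def test_group_lasso_zeros_and_single_group(self):
        gs = GroupStructure(3, (np.arange(3),))
        assert group_lasso_value(np.zeros((2, 3)), gs) == 0.0
        p = np.array([[0.2, 0.3, 0.6]])
        assert group_lasso_value(p, gs) == pytest.approx(np.linalg.norm(p))

    def test_group_lasso_singletons_degenerate_to_lasso(self):
        gs = GroupStructure(4, tuple(np.array([j]) for j in range(4)))
        P = np.random.default_rng(0).uniform(0, 1, (5, 4))
        assert group_lasso_value(P, gs) == pytest.approx(
            np.abs(P).sum(axis=1).mean()
        )

    def test_cauchy_peak_and_tail_values(self):
        assert cauchy_value(np.array([[0.0]]), 1.0, 0.0) == pytest.approx(1 / np.pi)
        assert cauchy_value(np.array([[2.0]]), 2.0, 0.0) == pytest.approx(
            1 / (4 * np.pi)
        )

    def test_cauchy_additive_over_units(self):
        P = np.array([[0.1, 0.5, 0.9]])
        total = cauchy_value(P, 1.0, 0.025)
        parts = sum(cauchy_value(P[:, [j]], 1.0, 0.025) for j in range(3))
        assert total == pytest.approx(parts)

    def test_cauchy_unimodal_maximized_at_mu(self):
        mu = 0.3
        grid = np.linspace(0, 1, 101)
        vals = [cauchy_value(np.array([[p]]), 0.5, mu) for p in grid]
        peak = int(np.argmax(vals))
        assert grid[peak] == pytest.approx(mu, abs=0.01)
        left, right = vals[:peak], vals[peak:]
        assert all(np.diff(left) > 0) and all(np.diff(right) < 0)

    def test_cauchy_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            cauchy_value(np.array([[0.5]]), 0.0, 0.0)

    def test_penalty_value_reduces_to_components(self):
        gs = GroupStructure(3, (np.array([0, 1]), np.array([1, 2])))
        P = np.array([[0.3, 0.4, 0.0]])
        lasso_only = PenaltyConfig(lam=1.0, phi=0.0)
        cauchy_only = PenaltyConfig(lam=0.0, phi=1.0, cauchy_sign=1)
        both = PenaltyConfig(lam=1.0, phi=1.0, cauchy_sign=1)
        assert penalty_value(P, lasso_only, gs) == pytest.approx(0.9)
        assert penalty_value(P, cauchy_only, gs) == pytest.approx(
            cauchy_value(P, 1.0, 0.025)
        )
        assert penalty_value(P, both, gs) == pytest.approx(
            0.9 + cauchy_value(P, 1.0, 0.025)
        )


class TestPenaltyGradient:
    def test_matches_finite_differences(self, rng):
        """Permanent oracle: the analytic gradient is the exact derivative."""
        worst = 0.0
        for t in range(20):
            n = int(rng.integers(4, 12))
            m = int(rng.integers(1, 5))
            gs = build_groups(
                n, int(rng.integers(1, 4)), 0.0 if t % 3 == 0 else 0.2, "relaxed"
            )
            cfg = PenaltyConfig(
                lam=float(rng.uniform(0, 2)),
                phi=float(rng.uniform(0, 2)),
                gamma=float(rng.uniform(0.5, 2)),
                mu=0.025,
                cauchy_sign=-1 if t % 2 else 1,
            )
            P = rng.uniform(0.01, 0.99, size=(m, n))
            G = penalty_grad_activations(P, cfg, gs)
            worst = max(worst, np.abs(G - _fd_grad(P, cfg, gs)).max())
        assert worst < 1e-6

    def test_cauchy_gradient_vanishes_at_mu(self):
        gs = GroupStructure(3, (np.arange(3),))
        cfg = PenaltyConfig(lam=0.0, phi=1.0, mu=0.4)
        P = np.full((2, 3), 0.4)
        assert np.allclose(penalty_grad_activations(P, cfg, gs), 0.0)

    def test_zero_norm_group_contributes_nothing(self):
        gs = GroupStructure(4, (np.array([0, 1]), np.array([2, 3])))
        cfg = PenaltyConfig(lam=1.0, phi=0.0)
        P = np.array([[0.0, 0.0, 0.3, 0.4]])
        G = penalty_grad_activations(P, cfg, gs)
        assert np.allclose(G[0, :2], 0.0)
        assert not np.allclose(G[0, 2:], 0.0)

    def test_overlapping_unit_receives_both_groups(self, rng):
        """A shared unit's gradient is the sum of the per-group brute-force
        contributions."""
        gs = GroupStructure(3, (np.array([0, 1]), np.array([1, 2])))
        cfg = PenaltyConfig(lam=1.3, phi=0.0)
        P = rng.uniform(0.1, 0.9, size=(4, 3))
        G = penalty_grad_activations(P, cfg, gs)
        m = P.shape[0]
        brute = np.zeros_like(P)
        for g in gs.groups:
            for l in range(m):
                norm = np.linalg.norm(P[l, g])
                brute[l, g] += cfg.lam * P[l, g] / norm / m
        assert np.allclose(G, brute)

    def test_width_mismatch_rejected(self):
        gs = GroupStructure(3, (np.arange(3),))
        with pytest.raises(ValueError):
            group_lasso_value(np.zeros((1, 4)), gs)

    def test_out_of_range_group_index_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            GroupStructure(3, (np.array([0, 1, 2, 3]),))
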