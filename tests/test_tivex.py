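"""Fused-lasso and transformed-penalty solvers, region calling, selection."""

import numpy as np
import pytest

import tilescan as ts
from tilescan.tivex import (
    SolverConfig,
    call_regions,
    check_convexity,
    convex_fused_fit,
    fused_lasso_fit,
    lambda_select,
    objective_value,
    transform,
)

from conftest import fused_lasso_oracle, random_convex_config, transformed_oracle


class TestConvexityGate:
    @pytest.mark.parametrize(
        "l0,a0,l1,a1,ok",
        [
            (5.0, 0.0, 5.0, 0.0, True),   # plain fused lasso always convex
            (0.5, 2.0, 0.0, 0.0, True),   # boundary: 1 - 1 - 0 = 0
            (0.0, 0.0, 0.5, 1.0, False),  # 1 - 0 - 2 < 0
            (0.1, 0.5, 1.0, 0.23, True),
        ],
    )
    def test_printed_inequality(self, l0, a0, l1, a1, ok):
        assert check_convexity(SolverConfig(lambda0=l0, a0=a0, lambda1=l1, a1=a1)) is ok

    def test_transform_limits(self):
        t = np.array([-3.0, -0.5, 0.0, 0.5, 3.0])
        assert np.allclose(transform(t, 0.0), np.abs(t))
        assert np.allclose(transform(t, 1e-14), np.abs(t))
        # saturating: below |t|, approaching 1/a
        f = transform(t, 2.0)
        assert np.all(f <= np.abs(t) + 1e-12) and np.all(f <= 0.5 + 1e-12)

    def test_curvature_bound(self):
        """Numeric Hessian of the transformed objective is bounded below by
        the convexity margin (away from the nonsmooth set)."""
        rng = np.random.default_rng(0)
        cfg = SolverConfig(lambda0=0.3, lambda1=0.8, a0=1.0, a1=0.2)
        margin = 1 - cfg.a0 * cfg.lambda0 - 4 * cfg.a1 * cfg.lambda1
        assert margin > 0
        n = 8
        y = rng.normal(0, 1, n)
        for _ in range(20):
            x = rng.normal(0, 2, n)
            if np.min(np.abs(x)) < 0.05 or np.min(np.abs(np.diff(x))) < 0.05:
                continue
            h = 1e-5
            H = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    for si, sj, sign in ((h, h, 1), (h, -h, -1), (-h, h, -1), (-h, -h, 1)):
                        xp = x.copy()
                        xp[i] += si
                        xp[j] += sj
                        H[i, j] += sign * objective_value(y, xp, cfg)
                    H[i, j] /= 4 * h * h
            eigmin = np.linalg.eigvalsh((H + H.T) / 2).min()
            assert eigmin >= margin - 1e-3


class TestFusedLasso:
    def test_constant_signal_unchanged_without_sparsity(self):
        fit = fused_lasso_fit(np.full(7, 2.5), lambda0=0.0, lambda1=3.0)
        assert np.allclose(fit.x_hat, 2.5)
        assert fit.n_segments == 1

    def test_full_shrinkage(self):
        y = np.array([0.5, -0.4, 0.3, -0.2])
        fit = fused_lasso_fit(y, lambda0=1.0, lambda1=0.1)
        assert np.allclose(fit.x_hat, 0.0)

    def test_two_block_signal_matches_oracle(self):
        y = np.array([0.0, 0.0, -3.0, -3.0, 0.0, 0.0])
        fit = fused_lasso_fit(y, lambda0=0.1, lambda1=0.5)
        xo = fused_lasso_oracle(y, 0.1, 0.5)
        assert abs(fit.objective - objective_value(y, xo, fit.config)) < 1e-6

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(40):
            n = int(rng.integers(1, 31))
            y = rng.normal(0, 2, n)
            l0, l1 = rng.uniform(0, 1.0), rng.uniform(0, 2.0)
            fit = fused_lasso_fit(y, l0, l1)
            xo = fused_lasso_oracle(y, l0, l1)
            assert abs(fit.objective - objective_value(y, xo, fit.config)) < 1e-6

    def test_minimizer_property(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.normal(0, 1, int(rng.integers(2, 20)))
            fit = fused_lasso_fit(y, 0.3, 0.7)
            assert fit.objective <= objective_value(y, y, fit.config) + 1e-12
            assert fit.objective <= objective_value(y, np.zeros_like(y), fit.config) + 1e-12

    def test_infinite_fusion_gives_constant(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 15)
        fit = fused_lasso_fit(y, lambda0=0.0, lambda1=1e6)
        assert np.allclose(fit.x_hat, y.mean(), atol=1e-8)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN|finite"):
            fused_lasso_fit(np.array([1.0, np.nan]), 0.1, 0.1)

    def test_segments_partition_and_match_fit(self):
        rng = np.random.default_rng(13)
        y = np.repeat(rng.normal(0, 2, 4), 5) + rng.normal(0, 0.1, 20)
        fit = fused_lasso_fit(y, 0.05, 0.8)
        idx = []
        for s, e, v in fit.segments:
            idx.extend(range(s, e + 1))
            assert np.allclose(fit.x_hat[s : e + 1], v, atol=1e-8)
        assert idx == list(range(len(y)))


class TestConvexFused:
    def test_zero_signal(self):
        fit = convex_fused_fit(np.zeros(6), SolverConfig())
        assert np.allclose(fit.x_hat, 0.0) and fit.objective == pytest.approx(0.0)

    def test_reduces_to_fused_lasso_as_a_vanishes(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            y = rng.normal(0, 2, int(rng.integers(2, 25)))
            cfg = SolverConfig(lambda0=0.2, lambda1=0.6, a0=1e-8, a1=1e-8)
            fit_t = convex_fused_fit(y, cfg)
            fit_f = fused_lasso_fit(y, 0.2, 0.6)
            assert abs(fit_t.objective - fit_f.objective) < 1e-6

    def test_convexity_violation_rejected(self):
        cfg = SolverConfig(lambda0=0.1, lambda1=0.3, a0=1.0, a1=1.0)
        assert not check_convexity(cfg)
        with pytest.raises(ValueError, match="convexity"):
            convex_fused_fit(np.zeros(4), cfg)

    def test_spec_instance_matches_dense_minimization(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, 6)
        cfg = SolverConfig(lambda0=0.1, lambda1=0.3, a0=1.0, a1=0.2)
        assert check_convexity(cfg)
        fit = convex_fused_fit(y, cfg)
        xo = transformed_oracle(y, cfg)
        assert abs(fit.objective - objective_value(y, xo, cfg)) < 1e-5

    def test_random_instances_match_dense_minimization(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            n = int(rng.integers(2, 31))
            y = rng.normal(0, 2, n)
            cfg = random_convex_config(rng)
            fit = convex_fused_fit(y, cfg)
            xo = transformed_oracle(y, cfg)
            assert abs(fit.objective - objective_value(y, xo, cfg)) < 1e-5

    def test_mm_objective_monotone(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            y = rng.normal(0, 2, int(rng.integers(2, 40)))
            fit = convex_fused_fit(y, random_convex_config(rng))
            diffs = np.diff(fit.objective_trace)
            assert np.all(diffs <= 1e-10)

    def test_objective_field_consistent(self):
        rng = np.random.default_rng(23)
        y = rng.normal(0, 1, 12)
        fit = convex_fused_fit(y, SolverConfig())
        assert fit.objective == pytest.approx(objective_value(y, fit.x_hat, fit.config))


class TestCallRegions:
    def _fit(self, values, positions, gene="G"):
        values = np.asarray(values, float)
        return ts.StepFit(
            gene=gene, y=values, positions=np.asarray(positions, int),
            x_hat=values, segments=[], objective=0.0, config=SolverConfig(),
        )

    def test_flat_at_global_mean_no_regions(self):
        fit = self._fit(np.zeros(10), np.arange(10, 150, 14))
        assert call_regions({"G": fit}, baseline_stats=(0.0, 1.0), tau=1.0) == []

    def test_single_step_region(self):
        # guides every 3 nt covering aa 1..40; aa 10-30 depleted at -3
        positions = np.arange(2, 121, 3)
        aa = (positions - 1) // 3 + 1
        values = np.where((aa >= 10) & (aa <= 30), -3.0, 0.0)
        fit = self._fit(values, positions)
        regions = call_regions({"G": fit}, baseline_stats=(0.0, 1.0), tau=1.0)
        assert len(regions) == 1
        r = regions[0]
        assert (r.aa_start, r.aa_end) == (10, 30)
        assert r.score == pytest.approx(-3.0)

    def test_interrupted_runs_not_merged(self):
        values = np.array([-3.0, -3.0, 0.0, -3.0, -3.0])
        fit = self._fit(values, np.array([3, 30, 60, 90, 120]))
        regions = call_regions({"G": fit}, baseline_stats=(0.0, 1.0), tau=1.0)
        assert len(regions) == 2

    def test_min_length_filter(self):
        values = np.array([0.0, -3.0, 0.0])
        fit = self._fit(values, np.array([3, 30, 60]))
        assert call_regions({"G": fit}, baseline_stats=(0.0, 1.0), min_len_aa=5) == []

    def test_default_baseline_is_global_fit_mean(self):
        f1 = self._fit(np.full(5, -2.0), np.arange(3, 70, 14), gene="G1")
        f2 = self._fit(np.full(5, 2.0), np.arange(3, 70, 14), gene="G2")
        regions = call_regions({"G1": f1, "G2": f2}, tau=1.0)
        assert [r.gene for r in regions] == ["G1"]

    def test_empty_fits_rejected(self):
        with pytest.raises(ValueError, match="no fitted"):
            call_regions({})


class TestLambdaSelect:
    def test_single_config_grid(self):
        cfg = SolverConfig(lambda0=0.1, lambda1=0.5, a0=0.1, a1=0.1)
        assert lambda_select([np.zeros(5)], [cfg]) is cfg

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lambda_select([np.zeros(5)], [])

    def test_nonconvex_grid_entry_rejected(self):
        bad = SolverConfig(lambda0=0.1, lambda1=1.0, a0=1.0, a1=1.0)
        with pytest.raises(ValueError, match="convexity"):
            lambda_select([np.zeros(5)], [bad])

    def test_noiseless_two_step_recovers_three_segments(self):
        y = np.concatenate([np.zeros(10), np.full(10, -3.0), np.zeros(10)])
        grid = [
            SolverConfig(lambda0=0.05, lambda1=l1, a0=0.2, a1=0.1)
            for l1 in (0.2, 0.5, 1.0, 2.0)
        ]
        best = lambda_select([y], grid)
        fit = convex_fused_fit(y, best)
        assert fit.n_segments == 3

    def test_pure_noise_selects_single_segment(self):
        grid = [
            SolverConfig(lambda0=0.05, lambda1=l1, a0=0.2, a1=0.1)
            for l1 in (0.5, 1.0, 2.0)
        ]
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 0.3, 40)
            best = lambda_select([y], grid)
            if convex_fused_fit(y, best).n_segments == 1:
                hits += 1
        assert hits >= int(0.9 * n_seeds)
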