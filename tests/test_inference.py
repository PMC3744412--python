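"""Contrast curves, sup-t simultaneous bands and threshold p-values."""

import dataclasses

import numpy as np
import pytest
from scipy.special import logit

from bsamap.genome import ConfigurationError
from bsamap.inference import (
    ContrastProfile,
    InferenceConfig,
    adjusted_pvalues,
    call_qtls,
    compute_contrast,
    pvalues_from_sup,
    simultaneous_band,
)
from bsamap.smoothing import SmoothBasis, fit_pool_chromosome

POS = np.linspace(1, 500_000, 120)


def constant_fit(p, pool_id, seed=0, coverage=100):
    v = np.full(120, int(round(p * coverage)))
    return fit_pool_chromosome(
        POS, v, np.full(120, coverage), SmoothBasis(knots=8, grid_bp=5_000),
        pool_id=pool_id, chrom="chr1", chrom_length=500_000,
    )


def truncate_to_one_point(fit, i=30):
    return dataclasses.replace(
        fit,
        grid=fit.grid[i : i + 1],
        grid_design=fit.grid_design[i : i + 1],
        eta=fit.eta[i : i + 1],
        se=fit.se[i : i + 1],
    )


class TestContrast:
    def test_self_contrast_is_zero(self):
        f = constant_fit(0.5, "q")
        c, se = compute_contrast(f, f)
        assert np.allclose(c, 0.0)

    def test_constant_pools_give_log_odds_ratio(self):
        fq = constant_fit(0.6, "q")
        f0 = constant_fit(0.5, "0")
        c, _ = compute_contrast(fq, f0)
        expected = logit(0.6) - logit(0.5)  # = log(3/2) ~ 0.4055
        assert np.allclose(c, expected, atol=1e-3)

    def test_swapping_pools_negates_contrast_exactly(self):
        fq = constant_fit(0.6, "q")
        f0 = constant_fit(0.5, "0")
        c1, _ = compute_contrast(fq, f0)
        c2, _ = compute_contrast(f0, fq)
        assert np.array_equal(c1, -c2)

    def test_mismatched_grids_raise(self):
        fq = constant_fit(0.5, "q")
        other = dataclasses.replace(fq, grid=fq.grid[:-1], eta=fq.eta[:-1],
                                    se=fq.se[:-1], grid_design=fq.grid_design[:-1])
        with pytest.raises(ConfigurationError):
            compute_contrast(fq, other)


class TestSimultaneousBand:
    def test_single_point_grid_reduces_to_pointwise_normal(self):
        fq = truncate_to_one_point(constant_fit(0.5, "q"))
        f0 = truncate_to_one_point(constant_fit(0.5, "0"))
        _, _, z = simultaneous_band(fq, f0, InferenceConfig(n_sims=200_000, seed=1))
        assert z == pytest.approx(1.96, abs=0.03)

    def test_multi_point_critical_value_dominates_pointwise(self):
        fq, f0 = constant_fit(0.5, "q"), constant_fit(0.5, "0")
        _, _, z_multi = simultaneous_band(fq, f0, InferenceConfig(n_sims=20_000, seed=1))
        fq1, f01 = truncate_to_one_point(fq), truncate_to_one_point(f0)
        _, _, z_one = simultaneous_band(fq1, f01, InferenceConfig(n_sims=20_000, seed=1))
        assert z_multi >= z_one

    def test_band_is_symmetric_and_contains_estimate(self):
        fq, f0 = constant_fit(0.6, "q"), constant_fit(0.5, "0")
        cfg = InferenceConfig(n_sims=2_000, seed=2)
        lo, hi, z = simultaneous_band(fq, f0, cfg)
        c, _ = compute_contrast(fq, f0)
        assert np.all(lo <= c) and np.all(c <= hi)
        assert np.allclose(hi - c, c - lo)

    def test_same_seed_reproduces_band(self):
        fq, f0 = constant_fit(0.55, "q"), constant_fit(0.5, "0")
        cfg = InferenceConfig(n_sims=2_000, seed=3)
        assert simultaneous_band(fq, f0, cfg)[2] == simultaneous_band(fq, f0, cfg)[2]


class TestAdjustedPvalues:
    def test_contrast_inside_threshold_gives_p_one(self):
        fq, f0 = constant_fit(0.52, "q"), constant_fit(0.5, "0")
        p = adjusted_pvalues(fq, f0, InferenceConfig(n_sims=1_000, seed=4))
        assert np.all(p == 1.0)

    def test_quantile_inversion_consistency(self):
        rng = np.random.Generator(np.random.PCG64(5))
        sup = np.abs(rng.standard_normal(100_000))
        z_star = np.quantile(sup, 0.95)
        se = np.full(3, 0.1)
        delta = 0.4088
        at_zero = pvalues_from_sup(np.full(3, delta), se, sup, delta)
        at_crit = pvalues_from_sup(np.full(3, delta + z_star * 0.1 + 1e-9), se, sup, delta)
        assert np.all(at_zero == 1.0)
        assert np.allclose(at_crit, 0.05, atol=0.01)

    def test_larger_delta_never_decreases_p(self):
        fq, f0 = constant_fit(0.65, "q"), constant_fit(0.5, "0")
        p_small = adjusted_pvalues(fq, f0, InferenceConfig(delta=0.1, n_sims=2_000, seed=6))
        p_large = adjusted_pvalues(fq, f0, InferenceConfig(delta=0.5, n_sims=2_000, seed=6))
        assert np.all(p_large >= p_small)

    def test_two_sidedness_under_relabelling(self):
        rng = np.random.Generator(np.random.PCG64(7))
        v = rng.binomial(100, 0.7, 120)
        mk = lambda vv, pid: fit_pool_chromosome(
            POS, vv, np.full(120, 100), SmoothBasis(knots=8, grid_bp=5_000),
            pool_id=pid, chrom="chr1", chrom_length=500_000, lam=1.0,
        )
        f0 = constant_fit(0.5, "0")
        f0_flip = constant_fit(0.5, "0f")
        cfg = InferenceConfig(n_sims=2_000, seed=8)
        p1 = adjusted_pvalues(mk(v, "q"), f0, cfg)
        p2 = adjusted_pvalues(mk(100 - v, "qf"), f0_flip, cfg)
        assert np.allclose(p1, p2, atol=0.02)


def profile(p_adj, contrast, chrom="chr1"):
    n = len(p_adj)
    grid = np.arange(1, n + 1, dtype=float) * 1_000
    se = np.full(n, 0.1)
    return ContrastProfile(
        chrom=chrom, grid=grid, contrast=np.asarray(contrast, float), se=se,
        lo=np.asarray(contrast) - se, hi=np.asarray(contrast) + se,
        p_adj=np.asarray(p_adj, float), z_star=3.0,
    )


class TestCallQtls:
    def test_no_significant_points_gives_empty_list(self):
        calls = call_qtls([profile([0.5] * 5, [1.0] * 5)], InferenceConfig())
        assert calls == []

    def test_single_positive_run_called_superior(self):
        p = [1, 0.01, 0.01, 0.01, 1]
        c = [0.1, 1.0, 1.2, 1.0, 0.1]
        (call,) = call_qtls([profile(p, c)], InferenceConfig())
        assert call.direction == "superior"
        assert (call.start, call.end, call.peak) == (2_000, 4_000, 3_000)

    def test_opposite_signs_split_into_two_calls(self):
        p = [0.01, 0.01, 1, 0.01, 0.01]
        c = [1.0, 1.0, 0.0, -1.0, -1.0]
        calls = call_qtls([profile(p, c)], InferenceConfig())
        assert len(calls) == 2
        assert {c.direction for c in calls} == {"superior", "inferior"}

    def test_adjacent_runs_with_single_gap_merge(self):
        p = [0.01, 1, 0.01]
        c = [1.0, 1.0, 1.0]
        calls = call_qtls([profile(p, c)], InferenceConfig())
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (1_000, 3_000)

    def test_masked_interval_excluded_from_calling(self):
        p = [0.01, 0.01, 0.01]
        c = [1.0, 1.0, 1.0]
        cfg = InferenceConfig(mask=[("chr1", 1, 5_000)])
        assert call_qtls([profile(p, c)], cfg) == []

    def test_calls_sorted_by_min_p(self):
        prof1 = profile([0.03, 1, 1, 1, 1], [1, 0, 0, 0, 0], chrom="chr1")
        prof2 = profile([0.001, 1, 1, 1, 1], [-1, 0, 0, 0, 0], chrom="chr2")
        calls = call_qtls([prof1, prof2], InferenceConfig())
        assert [c.chrom for c in calls] == ["chr2", "chr1"]
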