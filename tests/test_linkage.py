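"""Exact tests, HMM smoothing, and QTL calling."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

from bsaqtl.linkage import (binom_two_sided, build_linkage_track, call_qtls,
                            site_test_vs_half, site_test_vs_random,
                            smooth_track)
from bsaqtl.poolfreq import PoolCounts


def brute_force_binom(k, n, p0):
    """Independent minlike oracle with exact rational arithmetic."""
    probs = [Fraction(math.comb(n, i)) * Fraction(p0).limit_denominator() ** i
             * (1 - Fraction(p0).limit_denominator()) ** (n - i)
             for i in range(n + 1)]
    obs = probs[k]
    return float(sum(p for p in probs if p <= obs))


def brute_force_fisher(a, b, c, d):
    """Enumerate all 2x2 tables with the observed margins (minlike)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = Fraction(math.comb(n, c1))
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x)) / denom
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


class TestExactBinomial:
    @pytest.mark.parametrize("k,n,expected", [
        (22, 24, 3.588e-5),       # prints as 3.6e-5
        (12, 24, 1.0),            # observed equals null expectation
        (19, 24, 6.611e-3),       # prints as 0.007
        (24, 24, 2 * 0.5 ** 24),  # closed form for a fixed pool
    ])
    def test_reference_values(self, k, n, expected):
        assert binom_two_sided(k, n, 0.5) == pytest.approx(expected, rel=1e-3)

    def test_symmetry_about_half(self):
        for n in (10, 24, 51):
            for k in range(n + 1):
                assert binom_two_sided(k, n, 0.5) == pytest.approx(
                    binom_two_sided(n - k, n, 0.5), rel=1e-12)

    def test_monotone_in_distance_from_expectation(self):
        n = 24
        ps = [binom_two_sided(k, n, 0.5) for k in range(12, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(1, 101))
            k = int(rng.integers(0, n + 1))
            assert binom_two_sided(k, n, 0.5) == pytest.approx(
                brute_force_binom(k, n, 0.5), abs=1e-10)

    @given(st.integers(1, 60).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n))))
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_binomtest(self, kn):
        n, k = kn
        assert binom_two_sided(k, n, 0.5) == pytest.approx(
            binomtest(k, n, 0.5).pvalue, rel=1e-9)

    def test_asymmetric_null(self):
        # minlike convention also holds away from p0 = 0.5
        assert binom_two_sided(3, 20, 0.2) == pytest.approx(
            brute_force_binom(3, 20, 0.2), abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binom_two_sided(0, 0)
        with pytest.raises(ValueError):
            binom_two_sided(5, 4)


class TestSiteTests:
    def test_vs_half_balanced(self):
        assert site_test_vs_half(PoolCounts("c", 1, 50, 50)) == 1.0

    def test_vs_half_delegates(self):
        assert site_test_vs_half(PoolCounts("c", 1, 90, 10)) == pytest.approx(
            binom_two_sided(90, 100, 0.5))

    def test_vs_half_fixed_pool(self):
        assert site_test_vs_half(PoolCounts("c", 1, 0, 20)) == pytest.approx(
            2 * 0.5 ** 20)

    def test_fisher_identical_tables(self):
        a = PoolCounts("c", 1, 30, 10)
        assert site_test_vs_random(a, a) == pytest.approx(1.0)

    def test_fisher_disjoint_closed_form(self):
        p = site_test_vs_random(PoolCounts("c", 1, 20, 0),
                                PoolCounts("c", 1, 0, 20))
        assert p == pytest.approx(2 / math.comb(40, 20), rel=1e-9)

    def test_fisher_agrees_with_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            got = site_test_vs_random(PoolCounts("c", 1, a, b),
                                      PoolCounts("c", 1, c, d))
            assert got == pytest.approx(brute_force_fisher(a, b, c, d),
                                        abs=1e-10)

    def test_fisher_zero_margin_convention(self):
        assert site_test_vs_random(PoolCounts("c", 1, 0, 0),
                                   PoolCounts("c", 1, 5, 5)) == 1.0


def _track(f_values, depth=1000, spacing=2000, chrom="chrI"):
    f = np.asarray(f_values, dtype=float)
    pos = np.arange(1, f.size + 1) * spacing
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "depth": depth,
        "count_a": np.rint(f * depth).astype(int), "f_a": f})


class TestSmoothing:
    def test_constant_half_stays_half(self):
        sm = smooth_track(_track([0.5] * 50), method="hmm")
        assert np.allclose(sm["smoothed_f"], 0.5, atol=0.01)

    def test_step_function_recovered_away_from_breakpoint(self):
        rng = np.random.default_rng(0)
        depth = 500
        latent = np.array([0.5] * 40 + [0.9] * 40)
        k = rng.binomial(depth, latent)
        track = _track(k / depth, depth=depth)
        track["count_a"] = k
        sm = smooth_track(track, method="hmm", length_scale_bp=20_000)
        away = np.r_[0:35, 45:80]
        assert np.all(np.abs(sm["smoothed_f"].to_numpy()[away] - latent[away])
                      < 0.05)

    def test_zero_persistence_limit_equals_raw(self):
        rng = np.random.default_rng(2)
        f = rng.uniform(0.2, 0.8, size=40)
        depth = 200
        k = rng.binomial(depth, f)
        track = _track(k / depth, depth=depth)
        track["count_a"] = k
        sm = smooth_track(track, method="hmm", length_scale_bp=1e-6)
        assert np.allclose(sm["smoothed_f"], k / depth, atol=0.02)

    def test_kernel_method_runs_and_bounds(self):
        sm = smooth_track(_track([0.1, 0.9] * 20), method="kernel",
                          bandwidth_bp=4000)
        assert sm["smoothed_f"].between(0, 1).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            smooth_track(_track([0.5] * 5), method="loess")


class TestQtlCalling:
    def test_no_signal_no_calls(self):
        track = _track([0.5] * 30)
        track["smoothed_f"] = 0.5
        track["smoothed_p"] = 1.0
        assert call_qtls(track) == []

    def test_run_split_by_one_site_is_merged(self):
        f = np.array([0.9] * 8 + [0.5] + [0.9] * 8)
        track = _track(f)
        track["smoothed_f"] = f
        track["smoothed_p"] = np.where(f > 0.5, 1e-6, 1.0)
        calls = call_qtls(track, merge_gap=10_000, min_sites=5)
        assert len(calls) == 1
        assert calls[0].n_sites == 16

    def test_direction_consistent_with_frequency(self, demo_cross, gmap):
        from bsaqtl.cross import sample_pool_reads
        from bsaqtl.poolfreq import filter_sites

        segs, sup, _ = demo_cross
        counts, _ = filter_sites(sample_pool_reads(sup, segs, gmap, seed=5), 20)
        track = build_linkage_track(counts)
        for call in call_qtls(track):
            sub = track[(track["chrom"] == call.chrom)
                        & track["pos"].between(call.start, call.end)]
            mean_f = sub["smoothed_f"].mean()
            assert (mean_f > 0.5) == (call.direction == "A")

    def test_min_sites_suppresses_short_runs(self):
        f = np.array([0.5] * 10 + [0.9] * 3 + [0.5] * 10)
        track = _track(f)
        track["smoothed_f"] = f
        track["smoothed_p"] = np.where(f > 0.5, 1e-6, 1.0)
        assert call_qtls(track, min_sites=5, merge_gap=1) == []

    def test_peak_tie_leftmost(self):
        f = np.array([0.9] * 6)
        track = _track(f)
        track["smoothed_f"] = f
        track["smoothed_p"] = 1e-8
        calls = call_qtls(track, min_sites=5)
        assert calls[0].peak == calls[0].start


class TestTypeIError:
    def test_null_rejection_rate_bounded(self):
        # balanced 24-member pool: true f = 0.5 at every site, so only
        # read-sampling noise drives rejections of the 0.5 reference
        from bsaqtl.cross import GenomeMap, PoolSpec, Segregant, sample_pool_reads
        from bsaqtl.poolfreq import filter_sites

        gmap = GenomeMap.regular(n_chromosomes=1, length_bp=2_400_000,
                                 snp_spacing=200)
        segs = [Segregant(i, {"chrI": np.full(gmap.snp_positions["chrI"].size,
                                              i % 2, dtype=np.uint8)})
                for i in range(24)]
        pool = PoolSpec(tuple(range(24)), "random", target_coverage=100)
        counts = sample_pool_reads(pool, segs, gmap, seed=13)
        kept, _ = filter_sites(counts, min_coverage=50)
        assert len(kept) >= 10_000
        p = np.array([site_test_vs_half(s) for s in kept])
        assert (p < 0.05).mean() <= 0.07
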