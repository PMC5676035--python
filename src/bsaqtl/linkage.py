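"""Linkage scanning of pooled allele-frequency tracks.

Two per-site tests are provided, mirroring the twin references used in
pooled-segregant mapping:

* vs the theoretical 0.5 expectation — an exact two-sided binomial test
  on the parent-A read count (under Mendelian segregation without
  linkage, half the reads at a site should carry each parent's allele);
* vs the random pool — a two-sided Fisher exact test on the 2x2 table of
  parent-A/parent-B read counts in the superior and random pools, which
  absorbs pool-composition noise the 0.5 reference cannot.

The raw frequency track is noisy at realistic depth, so a hidden-Markov
smoother pools information across neighbouring SNPs: the latent pool
frequency is discretized on a grid, emissions are binomial in the
observed counts, and the chain's stay probability decays exponentially
with inter-SNP distance.  QTLs are called as runs of significant,
direction-consistent smoothed sites.

The exact binomial uses the "minlike" two-sided convention (sum of all
outcome probabilities not exceeding that of the observed count).  At
p0 = 0.5 this equals doubling the smaller tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bsaqtl.poolfreq import PoolCounts

__all__ = [
    "binom_two_sided", "site_test_vs_half", "site_test_vs_random",
    "smooth_track", "call_qtls", "build_linkage_track", "QtlCall",
]

# Relative tolerance when comparing point probabilities in the minlike
# sum; the convention shared by R's binom.test and scipy's binomtest,
# guarding against ties broken by floating-point rounding.
_MINLIKE_RTOL = 1 + 1e-7


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial P-value (minlike convention).

    P = sum of Binomial(n, p0) point probabilities that do not exceed
    the probability of the observed count ``k``.  With a symmetric null
    (p0 = 0.5) this equals doubling the smaller tail, capped at 1.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    mask = pmf <= pmf[k] * _MINLIKE_RTOL
    if mask.all():  # observed the modal outcome: every table is as extreme
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


def site_test_vs_half(site: PoolCounts) -> float:
    """Exact binomial test of a site's counts against the 0.5 expectation."""
    return binom_two_sided(site.count_a, site.depth, 0.5)


def site_test_vs_random(superior: PoolCounts, random: PoolCounts) -> float:
    """Two-sided Fisher exact test of superior vs random pool counts.

    A degenerate table (an all-zero row or column margin) carries no
    information and returns P = 1 by convention.
    """
    table = [[superior.count_a, superior.count_b],
             [random.count_a, random.count_b]]
    if (superior.depth == 0 or random.depth == 0
            or superior.count_a + random.count_a == 0
            or superior.count_b + random.count_b == 0):
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _hmm_posterior_mean(k: np.ndarray, depth: np.ndarray, dist_bp: np.ndarray,
                        n_states: int, length_scale_bp: float) -> np.ndarray:
    """Forward-backward posterior mean of the latent frequency on one chromosome.

    States are an evenly spaced frequency grid on [0, 1]; emissions are
    Binomial(depth_t, state); the transition kernel keeps the current
    state with probability s = exp(-d/L) and otherwise redraws uniformly,
    so the effective stay probability is s + (1-s)/K.
    """
    grid = np.linspace(0.0, 1.0, n_states)
    T = k.size
    # emission matrix (T x K), scaled per-site to dodge underflow
    em = stats.binom.pmf(k[:, None], depth[:, None], grid[None, :])
    em = np.clip(em, 1e-300, None)

    alpha = np.empty((T, n_states))
    c = np.empty(T)
    prior = np.full(n_states, 1.0 / n_states)
    alpha[0] = prior * em[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    stay = np.exp(-dist_bp / length_scale_bp)
    for t in range(1, T):
        s = stay[t - 1]
        pred = s * alpha[t - 1] + (1 - s) / n_states
        alpha[t] = pred * em[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]

    beta = np.ones(n_states)
    post = np.empty((T, n_states))
    post[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        s = stay[t]
        msg = em[t + 1] * beta
        beta = (s * msg + (1 - s) * msg.mean()) / c[t + 1]
        post[t] = alpha[t] * beta
        post[t] /= post[t].sum()
    return post @ grid


def smooth_track(track: pd.DataFrame, method: str = "hmm",
                 n_states: int = 51, length_scale_bp: float = 20_000.0,
                 bandwidth_bp: float = 20_000.0) -> pd.DataFrame:
    """Smooth a frequency track and attach smoothed frequencies and P-values.

    ``track`` needs columns chrom, pos, depth, f_a (count_a optional;
    reconstructed as round(f_a * depth) when absent).  Two smoothers:

    ``hmm``
        Discrete-state forward-backward smoother (see module docstring).
        ``length_scale_bp`` (L) sets how fast state persistence decays
        with inter-SNP distance; L -> 0 reduces to the raw per-site
        maximum-likelihood frequency.
    ``kernel``
        Nadaraya-Watson regression of f_a on position with a Gaussian
        kernel of ``bandwidth_bp``, depth-weighted.

    The smoothed P-value at a site converts the posterior-mean frequency
    back to an equivalent success count k* = round(f_hat * depth) and
    applies the exact binomial test against 0.5 — an operational
    definition that anchors the smoothed track to the same reproducible
    statistic used in fine mapping.
    """
    if method not in ("hmm", "kernel"):
        raise ValueError(f"unknown smoothing method {method!r}")
    out = track.copy()
    if "count_a" not in out.columns:
        out["count_a"] = np.rint(out["f_a"] * out["depth"]).astype(int)
    smoothed = np.empty(len(out))
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        sub = out.loc[idx]
        if len(sub) < 2:
            raise ValueError(f"chromosome {chrom} has < 2 sites; cannot smooth")
        pos = sub["pos"].to_numpy(float)
        depth = sub["depth"].to_numpy(float)
        k = sub["count_a"].to_numpy(float)
        if method == "hmm":
            dist = np.diff(pos)
            fhat = _hmm_posterior_mean(k, depth, dist, n_states, length_scale_bp)
        else:
            w = np.exp(-0.5 * ((pos[:, None] - pos[None, :]) / bandwidth_bp) ** 2)
            w *= depth[None, :]
            fhat = (w @ (k / depth)) / w.sum(axis=1)
        smoothed[out.index.get_indexer(idx)] = fhat
    out["smoothed_f"] = np.clip(smoothed, 0.0, 1.0)
    out["smoothed_p"] = [
        binom_two_sided(int(round(f * d)), int(d), 0.5)
        for f, d in zip(out["smoothed_f"], out["depth"])
    ]
    return out


@dataclass(frozen=True)
class QtlCall:
    """A called linkage interval.

    ``direction`` is "A" when the interval's smoothed frequencies exceed
    0.5 (linkage with parent A) and "B" when below.
    """

    chrom: str
    start: int
    end: int
    peak: int
    direction: str
    min_p: float
    n_sites: int

    def __post_init__(self) -> None:
        if not self.start <= self.peak <= self.end:
            raise ValueError("peak must lie within [start, end]")
        if self.direction not in ("A", "B"):
            raise ValueError("direction must be 'A' or 'B'")


def call_qtls(track: pd.DataFrame, alpha: float = 0.05, min_sites: int = 5,
              merge_gap: int = 20_000, p_column: str = "smoothed_p",
              f_column: str = "smoothed_f",
              bonferroni: bool = False) -> list[QtlCall]:
    """Call QTL intervals from a smoothed linkage track.

    Maximal runs of consecutive sites with P < alpha and consistent
    direction (frequency on the same side of 0.5) are formed per
    chromosome; same-direction runs separated by less than ``merge_gap``
    bp are merged; merged runs with fewer than ``min_sites`` sites are
    discarded.  The peak is the site of minimum P (ties -> leftmost).
    ``bonferroni`` divides alpha by the number of scanned sites.
    """
    if bonferroni and len(track):
        alpha = alpha / len(track)
    calls: list[QtlCall] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        p = sub[p_column].to_numpy()
        f = sub[f_column].to_numpy()
        sig = p < alpha
        direction = np.where(f > 0.5, 1, -1)

        runs: list[tuple[int, int, int]] = []  # (start_idx, end_idx, dir)
        i = 0
        while i < len(pos):
            if not sig[i] or f[i] == 0.5:
                i += 1
                continue
            j = i
            while (j + 1 < len(pos) and sig[j + 1]
                   and direction[j + 1] == direction[i] and f[j + 1] != 0.5):
                j += 1
            runs.append((i, j, direction[i]))
            i = j + 1

        merged: list[tuple[int, int, int]] = []
        for run in runs:
            if (merged and run[2] == merged[-1][2]
                    and pos[run[0]] - pos[merged[-1][1]] < merge_gap):
                merged[-1] = (merged[-1][0], run[1], run[2])
            else:
                merged.append(run)

        for i0, i1, d in merged:
            # count significant sites only, not bridged gap sites
            n_run_sites = int(np.sum(sig[i0:i1 + 1]
                                     & (direction[i0:i1 + 1] == d)))
            if n_run_sites < min_sites:
                continue
            seg_p = p[i0:i1 + 1]
            peak_idx = i0 + int(np.argmin(seg_p))
            calls.append(QtlCall(
                chrom=chrom, start=int(pos[i0]), end=int(pos[i1]),
                peak=int(pos[peak_idx]), direction="A" if d > 0 else "B",
                min_p=float(seg_p.min()), n_sites=n_run_sites))
    return calls


def build_linkage_track(superior: list[PoolCounts],
                        random: list[PoolCounts] | None = None,
                        method: str = "hmm",
                        **smooth_kwargs) -> pd.DataFrame:
    """Full per-site linkage track from filtered pool counts.

    Columns: chrom, pos, depth, count_a, f_a (superior pool), f_random,
    p_vs_half, p_vs_random (NaN where the random pool is missing or the
    site is absent from it), smoothed_f, smoothed_p.  Sites present in
    only one pool keep their one-pool statistics, matching the policy of
    maximizing usable sites per test.
    """
    from bsaqtl.poolfreq import variant_frequency

    track = variant_frequency(superior)
    track["p_vs_half"] = [site_test_vs_half(s) for s in
                          (PoolCounts(r.chrom, r.pos, r.count_a, r.depth - r.count_a)
                           for r in track.itertuples(index=False))]
    if random is not None:
        rand_by_key = {(s.chrom, s.pos): s for s in random}
        f_rand, p_rand = [], []
        for row in track.itertuples(index=False):
            other = rand_by_key.get((row.chrom, row.pos))
            if other is None or other.depth == 0:
                f_rand.append(np.nan)
                p_rand.append(np.nan)
            else:
                f_rand.append(other.count_a / other.depth)
                sup = PoolCounts(row.chrom, row.pos, row.count_a,
                                 row.depth - row.count_a)
                p_rand.append(site_test_vs_random(sup, other))
        track["f_random"] = f_rand
        track["p_vs_random"] = p_rand
    return smooth_track(track, method=method, **smooth_kwargs)


def qtl_calls_to_bed(calls: list[QtlCall]) -> str:
    """BED6 text for called intervals (0-based half-open, name=direction)."""
    lines = []
    for c in calls:
        name = f"linked_parent_{c.direction}"
        score = int(min(1000, -10 * np.log10(max(c.min_p, 1e-300))))
        lines.append(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\t{score}\t.")
    return "\n".join(lines) + ("\n" if lines else "")
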