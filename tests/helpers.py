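"""Shared test harnesses: synthetic-cohort rendering and independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from oralcna import calling, preprocess, segment, simulate


def make_profile(values, sample_id="S1", chroms=None, spacing=1000):
    """ArrayProfile from a plain value array (single chromosome unless
    ``chroms`` gives a per-probe chromosome label)."""
    values = np.asarray(values, float)
    n = values.size
    chroms = ["chr1"] * n if chroms is None else list(chroms)
    pos = []
    counters = {}
    for c in chroms:
        counters[c] = counters.get(c, 0) + 1
        pos.append(counters[c] * spacing - spacing // 2)
    df = pd.DataFrame(
        {
            "probe_id": [f"P{i:05d}" for i in range(n)],
            "chrom": chroms,
            "pos": pos,
            "log2": values,
        }
    )
    return preprocess.ArrayProfile(sample_id, df)


def segmented_cohort(seed, n_samples=60, event_free=False, n_perm=500,
                     noise_sd=0.15, alpha=0.5):
    """Render and segment one synthetic cohort under the study conditions;
    returns (genome, cohort, segment profiles)."""
    genome, grid = simulate.generate_genome(8, 3, 10_000_000, 200_000, seed=0)
    kw = dict(n_patients=40, alpha_range=(alpha, alpha))
    if event_free:
        kw.update(event_rate_diploid=0.0, event_rate_aneuploid=0.0)
    cohort = simulate.generate_cohort(genome, simulate.CohortDesign(**kw), seed=seed)
    cohort = cohort[:n_samples]
    profs = []
    for i, s in enumerate(cohort):
        p = simulate.render_array(
            s, grid, noise_sd, 0.01, 1.0, seed=(seed * 100_003 + i) % 2**31
        )
        profs.append(segment.segment_pcf(preprocess.winsorize(p, 2.5), 40.0))
    return genome, cohort, profs


def fitted_mean_over(seg_profile, chrom, start, end):
    """Length-weighted mean of the piecewise fit over a genomic interval."""
    sp = seg_profile.segments
    sel = sp[(sp["chrom"] == chrom) & (sp["start"] < end) & (sp["end"] > start)]
    w = np.minimum(sel["end"], end) - np.maximum(sel["start"], start)
    return float((sel["mean"] * w).sum() / w.sum())


def brute_force_pcf_cost(x, gamma):
    """Exhaustive minimum of SSE + gamma * (#breakpoints) over all
    breakpoint subsets (pure python; use for n <= ~14)."""
    x = np.asarray(x, float)
    n = x.size
    best = math.inf
    for mask in range(1 << (n - 1)):
        cuts = [0] + [k + 1 for k in range(n - 1) if mask >> k & 1] + [n]
        cost = gamma * (len(cuts) - 2)
        for a, b in zip(cuts, cuts[1:]):
            seg_x = x[a:b]
            cost += float(((seg_x - seg_x.mean()) ** 2).sum())
        best = min(best, cost)
    return best


def pcf_cost(pieces, x, gamma):
    x = np.asarray(x, float)
    cost = gamma * (len(pieces) - 1)
    for a, b, _ in pieces:
        seg_x = x[a:b]
        cost += float(((seg_x - seg_x.mean()) ** 2).sum())
    return cost


# --- independent discrete-FDR oracle (combinatorics from scratch) ----------


def _hypergeom_pmf_table(a, b, c, d):
    """P(table | margins) by direct combinatorics for the 2x2 family."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    return (
        math.comb(r1, a) * math.comb(r2, c) / math.comb(n, c1)
    )


def enumerate_two_sided(a, b, c, d):
    """All attainable (two-sided p, probability) pairs with these margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {}
    for aa in range(lo, hi + 1):
        probs[aa] = _hypergeom_pmf_table(aa, r1 - aa, c1 - aa, r2 - (c1 - aa))
    pvals = {}
    for aa, pr in probs.items():
        pvals[aa] = sum(p for p in probs.values() if p <= pr * (1 + 1e-9))
    return pvals, probs


def oracle_carlson(tables):
    """Direct re-derivation of the discrete FDR estimate: thresholds are the
    observed two-sided p's; expected null discoveries summed over each
    table's attainable p distribution; q = suffix-min of FDR(t)."""
    obs = []
    dists = []
    for (a, b, c, d) in tables:
        pvals, probs = enumerate_two_sided(a, b, c, d)
        obs.append(pvals[a])
        dists.append([(pvals[aa], probs[aa]) for aa in probs])
    qs = []
    for p_i in obs:
        best = math.inf
        for t in obs:
            if t < p_i * (1 - 1e-9):
                continue
            e_null = sum(
                pr for dist in dists for (pv, pr) in dist if pv <= t * (1 + 1e-9)
            )
            n_disc = sum(1 for p in obs if p <= t * (1 + 1e-9))
            best = min(best, e_null / max(1, n_disc))
        qs.append(min(best, 1.0))
    return np.array(obs), np.array(qs)


def random_table(rng, max_n=12):
    while True:
        a, b, c, d = (int(rng.integers(0, max_n // 2 + 1)) for _ in range(4))
        if min(a + b, c + d, a + c, b + d) > 0 and a + b + c + d <= max_n:
            return a, b, c, d


_NUMBA_RUN = None


def _numba_kernel():
    global _NUMBA_RUN
    if _NUMBA_RUN is None:
        from numba import njit

        @njit(cache=False)
        def _run(cs, cs2, n, gamma):  # pragma: no cover - compiled
            best = 1e300
            for mask in range(1 << (n - 1)):
                cost = 0.0
                prev = 0
                m = mask
                for b in range(1, n):
                    if m & 1:
                        s = cs[b] - cs[prev]
                        cost += (cs2[b] - cs2[prev]) - s * s / (b - prev) + gamma
                        prev = b
                    m >>= 1
                s = cs[n] - cs[prev]
                cost += (cs2[n] - cs2[prev]) - s * s / (n - prev)
                if cost < best:
                    best = cost
            return best

        _NUMBA_RUN = _run
    return _NUMBA_RUN


def exhaustive_pcf_cost(x, gamma):
    """Exhaustive breakpoint search, numba-accelerated (n <= 20)."""
    x = np.asarray(x, float)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return float(_numba_kernel()(cs, cs2, x.size, gamma))
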