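"""Array-level preprocessing: replicate averaging, dLRs QC, MAD winsorization.

The derivative log-ratio spread (dLRs) estimates per-array noise from
consecutive-probe differences: for iid Gaussian probes with SD sigma, the
IQR of first differences is 1.349 * sigma * sqrt(2), so dividing by that
factor recovers sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ArrayProfile",
    "average_replicates",
    "dlrs",
    "qc_filter",
    "winsorize",
]

_DLRS_FACTOR = 1.349 * np.sqrt(2.0)
_MAD_SCALE = 1.4826  # consistency constant: MAD -> SD for Gaussians


class InsufficientDataError(ValueError):
    pass


class MissingDataError(ValueError):
    pass


@dataclass(frozen=True)
class ArrayProfile:
    """Per-probe log2 ratios for one biopsy sample, ordered by (chrom, pos)."""

    sample_id: str
    data: pd.DataFrame = field(repr=False)  # probe_id, chrom, pos, log2
    dlrs: float | None = None
    qc_pass: bool | None = None
    qc_override: bool = False

    def __post_init__(self) -> None:
        req = {"probe_id", "chrom", "pos", "log2"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"profile needs columns {sorted(req)}")

    def values(self) -> np.ndarray:
        return self.data["log2"].to_numpy(float)

    def with_values(self, log2: np.ndarray) -> "ArrayProfile":
        df = self.data.copy()
        df["log2"] = log2
        return replace(self, data=df)


def average_replicates(measurements: pd.DataFrame, sample_id: str) -> ArrayProfile:
    """Collapse repeated probe measurements to one mean value per probe.

    ``measurements`` is long-format with columns probe_id, chrom, pos, log2;
    a probe may appear on several rows (replicate spots).  Probes with no
    finite measurement raise ``MissingDataError``.
    """
    req = {"probe_id", "chrom", "pos", "log2"}
    if not req.issubset(measurements.columns):
        raise ValueError(f"need columns {sorted(req)}")
    n_valid = (
        measurements["log2"].notna().groupby(measurements["probe_id"]).sum()
    )
    if (n_valid == 0).any():
        bad = n_valid.index[n_valid == 0].tolist()
        raise MissingDataError(f"probes with no measurement: {bad[:10]}")
    agg = (
        measurements.groupby(["probe_id", "chrom", "pos"], as_index=False)["log2"]
        .mean()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    return ArrayProfile(sample_id, agg)


def dlrs(profile: ArrayProfile) -> float:
    """Robust noise SD from the IQR of consecutive same-chromosome differences."""
    diffs = []
    for _, grp in profile.data.groupby("chrom", sort=False):
        v = grp["log2"].to_numpy(float)
        v = v[np.isfinite(v)]
        if v.size >= 2:
            diffs.append(np.diff(v))
    if not diffs or sum(d.size for d in diffs) < 2:
        raise InsufficientDataError(
            f"{profile.sample_id}: too few probes for dLRs"
        )
    d = np.concatenate(diffs)
    q75, q25 = np.percentile(d, [75, 25])
    return float((q75 - q25) / _DLRS_FACTOR)


def qc_filter(
    profiles: list[ArrayProfile],
    max_dlrs: float = 0.35,
    allowlist: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[ArrayProfile], list[ArrayProfile]]:
    """Discard arrays whose dLRs exceeds ``max_dlrs`` (strict >).

    Samples on ``allowlist`` are kept regardless (flagged via
    ``qc_override``), mirroring manual rescue of borderline arrays after
    visual inspection.
    """
    kept, discarded = [], []
    for p in profiles:
        d = p.dlrs if p.dlrs is not None else dlrs(p)
        ok = d <= max_dlrs
        override = (not ok) and p.sample_id in allowlist
        p = replace(p, dlrs=d, qc_pass=ok or override, qc_override=override)
        (kept if p.qc_pass else discarded).append(p)
    return kept, discarded


def winsorize(profile: ArrayProfile, k: float = 2.5) -> ArrayProfile:
    """Clamp outliers to +-k scaled-MADs around each chromosome's median.

    Residuals from the per-chromosome median are clipped at
    k * 1.4826 * MAD(residuals); probes within the bound are returned
    bit-identical.  With MAD = 0 (constant chromosome) nothing is clamped
    unless a probe deviates from the median at all, in which case it is set
    to the median.
    """
    if not np.isfinite(k) or k <= 0:
        if k == np.inf:
            return profile
        raise ValueError("k must be positive")
    out = profile.values().copy()
    chroms = profile.data["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        v = out[idx]
        fin = np.isfinite(v)
        if fin.sum() < 2:
            continue
        med = np.median(v[fin])
        resid = v - med
        mad = np.median(np.abs(resid[fin]))
        bound = k * _MAD_SCALE * mad
        # touch only outliers so inliers stay bit-identical (NaN untouched)
        high = fin & (resid > bound)
        low = fin & (resid < -bound)
        out[idx[high]] = med + bound
        out[idx[low]] = med - bound
    return profile.with_values(out)
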