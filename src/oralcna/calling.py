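"""CNA calling: thresholding, focal/broad classification, recurrence testing.

The clonality dilution model relates an observed aCGH log2 ratio to the
total copy number ``q_t`` of an aberration carried by a fraction ``alpha``
of cells in a background of ploidy ``D``:

    log2 ratio = log2( (alpha*q_t + 2*(1-alpha)) / (alpha*D + 2*(1-alpha)) )

so at alpha = 0.5 in a diploid background a hemizygous deletion gives
about -0.41 and a single-copy gain about +0.32, motivating the +-0.3
calling thresholds.

Cohort-level recurrence uses a deliberately simplified frequency-and-
amplitude G score (GISTIC-style, without ziggurat deconstruction or
peel-off): per cytoband (focal) or per arm (broad) and per direction,
G = sum over samples of max(0, |amplitude| - threshold), compared against
a null built by per-sample cyclic shifts of the amplitude vector, with
Benjamini-Hochberg q-values.  A region is either broad or focal by the
half-arm rule, never both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeDef
from .segment import SegmentProfile

__all__ = [
    "expected_log2",
    "CalledRegion",
    "CNAEventCall",
    "call_segments",
    "classify_events",
    "amplitude_matrices",
    "recurrent_cnas",
    "events_frame",
]

HOMDEL_SENTINEL = float("-inf")


class ConsistencyError(ValueError):
    pass


def expected_log2(alpha: float, q_t: float, D: float = 2.0) -> float:
    """Expected log2 ratio of a clonal CNA diluted by cancer-cell fraction.

    Returns -inf (homozygous-deletion sentinel) when alpha = 1 and q_t = 0.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if q_t < 0 or D <= 0:
        raise ValueError("q_t must be >= 0 and D > 0")
    num = alpha * q_t + 2.0 * (1.0 - alpha)
    den = alpha * D + 2.0 * (1.0 - alpha)
    if num == 0.0:
        return HOMDEL_SENTINEL
    return math.log2(num / den)


@dataclass(frozen=True)
class CalledRegion:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    mean: float
    state: str  # gain | neutral | loss


@dataclass(frozen=True)
class CNAEventCall:
    sample_id: str
    direction: str  # gain | loss
    klass: str  # focal | broad
    chrom: str
    arm: str
    start: int
    end: int
    mean: float
    arm_fraction: float
    bands: tuple[str, ...]  # cytoband labels, focal only (broad: empty)

    @property
    def label(self) -> str:
        if self.klass == "broad":
            chrom_num = self.chrom[3:] if self.chrom.startswith("chr") else self.chrom
            return f"{chrom_num}{self.arm} {self.direction}"
        return f"{'|'.join(self.bands)} {self.direction}"


def call_segments(
    segments: SegmentProfile,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
) -> list[CalledRegion]:
    """Assign gain/neutral/loss per segment (inclusive thresholds) and merge
    adjacent same-state regions within a chromosome (probe-weighted mean)."""
    if not loss_thr < 0 < gain_thr:
        raise ValueError("need loss_thr < 0 < gain_thr")
    out: list[CalledRegion] = []
    for _, grp in segments.segments.groupby("chrom", sort=False):
        prev: CalledRegion | None = None
        for r in grp.itertuples():
            state = (
                "gain" if r.mean >= gain_thr else "loss" if r.mean <= loss_thr else "neutral"
            )
            if prev is not None and prev.state == state and prev.end == r.start:
                n = prev.n_probes + r.n_probes
                m = (prev.mean * prev.n_probes + r.mean * r.n_probes) / n
                prev = CalledRegion(
                    prev.sample_id, prev.chrom, prev.start, r.end, n, m, state
                )
            else:
                if prev is not None:
                    out.append(prev)
                prev = CalledRegion(
                    segments.sample_id, r.chrom, r.start, r.end, r.n_probes, r.mean, state
                )
        if prev is not None:
            out.append(prev)
    return out


def classify_events(
    called: list[CalledRegion],
    genome: GenomeDef,
    broad_arm_fraction: float = 0.5,
) -> list[CNAEventCall]:
    """Split non-neutral regions at centromeres and classify each arm piece
    as broad (piece length / arm length > ``broad_arm_fraction``) or focal
    (annotated with every overlapped cytoband)."""
    events: list[CNAEventCall] = []
    for reg in called:
        if reg.state == "neutral":
            continue
        try:
            chrom = genome.chromosome(reg.chrom)
        except KeyError as exc:
            raise ConsistencyError(f"unknown chromosome {reg.chrom}") from exc
        if reg.start < 0 or reg.end > chrom.length:
            raise ConsistencyError(
                f"{reg.sample_id}: region {reg.chrom}:{reg.start}-{reg.end} "
                f"outside chromosome (length {chrom.length})"
            )
        for arm in ("p", "q"):
            a0, a1 = chrom.arm_bounds(arm)
            s, e = max(reg.start, a0), min(reg.end, a1)
            if e <= s:
                continue
            arm_len = a1 - a0
            frac = (e - s) / arm_len if arm_len > 0 else 1.0
            if frac > broad_arm_fraction:
                events.append(
                    CNAEventCall(
                        reg.sample_id, reg.state, "broad", reg.chrom, arm,
                        s, e, reg.mean, frac, (),
                    )
                )
            else:
                bands = tuple(
                    b.label for b in genome.bands_in(reg.chrom, s, e)
                )
                events.append(
                    CNAEventCall(
                        reg.sample_id, reg.state, "focal", reg.chrom, arm,
                        s, e, reg.mean, frac, bands,
                    )
                )
    return events


def events_frame(events: list[CNAEventCall]) -> pd.DataFrame:
    rows = [
        (
            e.sample_id, e.label, e.klass, e.direction, e.chrom, e.arm,
            e.start, e.end, e.mean, e.arm_fraction, ",".join(e.bands),
        )
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "label", "class", "direction", "chrom", "arm",
            "start", "end", "mean", "arm_fraction", "bands",
        ],
    )


def amplitude_matrices(
    profiles: list[SegmentProfile],
    genome: GenomeDef,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
    broad_arm_fraction: float = 0.5,
) -> dict:
    """Per-sample marker matrices of amplitude beyond threshold, floored at
    0, split by event class so a region contributes to exactly one analysis.

    Focal matrices are samples x cytobands (amplitude of the strongest focal
    event covering the band); broad matrices are samples x arms (strongest
    broad event on the arm).  Returns a dict with keys ``focal_gain``,
    ``focal_loss``, ``broad_gain``, ``broad_loss`` and ``band_chrom`` (the
    chromosome of each cytoband column, for blockwise permutation).
    """
    band_labels = genome.band_labels()
    band_index = {lab: i for i, lab in enumerate(band_labels)}
    band_chrom = {b.label: c.name for c in genome.chromosomes for b in c.bands}
    arm_labels = [genome.arm_label(c, a) for c, a, _, _ in genome.arms()]
    arm_index = {lab: i for i, lab in enumerate(arm_labels)}
    samples = [p.sample_id for p in profiles]
    fg = np.zeros((len(profiles), len(band_labels)))
    fl = np.zeros_like(fg)
    bg = np.zeros((len(profiles), len(arm_labels)))
    bl = np.zeros_like(bg)
    for si, p in enumerate(profiles):
        called = call_segments(p, gain_thr, loss_thr)
        for ev in classify_events(called, genome, broad_arm_fraction):
            amp = ev.mean - gain_thr if ev.direction == "gain" else loss_thr - ev.mean
            amp = max(amp, 0.0)
            if ev.klass == "broad":
                j = arm_index[genome.arm_label(ev.chrom, ev.arm)]
                mat = bg if ev.direction == "gain" else bl
                mat[si, j] = max(mat[si, j], amp)
            else:
                mat = fg if ev.direction == "gain" else fl
                for lab in ev.bands:
                    j = band_index[lab]
                    mat[si, j] = max(mat[si, j], amp)
    return {
        "focal_gain": pd.DataFrame(fg, index=samples, columns=band_labels),
        "focal_loss": pd.DataFrame(fl, index=samples, columns=band_labels),
        "broad_gain": pd.DataFrame(bg, index=samples, columns=arm_labels),
        "broad_loss": pd.DataFrame(bl, index=samples, columns=arm_labels),
        "band_chrom": pd.Series(
            [band_chrom[lab] for lab in band_labels], index=band_labels
        ),
    }


def _arm_label_of(ev: CNAEventCall) -> str:
    chrom_num = ev.chrom[3:] if ev.chrom.startswith("chr") else ev.chrom
    return f"{chrom_num}{ev.arm}"


def _bh(p: np.ndarray) -> np.ndarray:
    # local BH step-up (association_stats re-exposes a public version)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    run = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        run = min(run, p[i] * m / rank)
        q[i] = run
    return q


def _perm_pvals(
    amp: np.ndarray,
    groups: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical permutation p-values for column G scores.

    ``groups`` assigns each column to a shift block (a chromosome for bands,
    one genome-wide block for arms); the null cyclically shifts each
    sample's amplitudes within each block, preserving within-block spatial
    autocorrelation.
    """
    obs = amp.sum(axis=0)
    n_samp, n_col = amp.shape
    exceed = np.zeros(n_col)
    uniq = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    for _ in range(n_perm):
        perm = np.empty_like(amp)
        for cols in uniq:
            block = amp[:, cols]
            shifts = rng.integers(0, cols.size, size=n_samp)
            idx = (np.arange(cols.size)[None, :] - shifts[:, None]) % cols.size
            perm[:, cols] = np.take_along_axis(block, idx, axis=1)
        exceed += perm.sum(axis=0) >= obs - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    return obs, p


def recurrent_cnas(
    profiles: list[SegmentProfile],
    genome: GenomeDef,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
    broad_arm_fraction: float = 0.5,
    focal_q: float = 0.25,
    broad_q: float = 0.3,
    n_perm: int = 1000,
    seed: int = 0,
    shuffle: str = "cyclic",
) -> pd.DataFrame:
    """Cohort-level recurrent CNA selection.

    Returns a table (label, class, direction, g_score, p, q, n_carriers,
    presence columns per sample) with focal rows retained at q < ``focal_q``
    and broad rows at q < ``broad_q``.  ``shuffle`` is 'cyclic' (default;
    per-sample within-block cyclic shifts) or 'independent' (per-sample
    column shuffles).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 samples")
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    rng = np.random.default_rng(seed)
    mats = amplitude_matrices(
        profiles, genome, gain_thr, loss_thr, broad_arm_fraction
    )
    events_by_sample = {
        p.sample_id: classify_events(
            call_segments(p, gain_thr, loss_thr), genome, broad_arm_fraction
        )
        for p in profiles
    }
    band_chrom = mats["band_chrom"].to_numpy()
    samples = mats["focal_gain"].index.tolist()
    rows = []
    specs = [
        ("focal", "gain", mats["focal_gain"], band_chrom, focal_q),
        ("focal", "loss", mats["focal_loss"], band_chrom, focal_q),
        ("broad", "gain", mats["broad_gain"],
         np.zeros(mats["broad_gain"].shape[1], int), broad_q),
        ("broad", "loss", mats["broad_loss"],
         np.zeros(mats["broad_loss"].shape[1], int), broad_q),
    ]
    for klass, direction, df, groups, qcut in specs:
        amp = df.to_numpy()
        if amp.sum() == 0:
            continue
        if shuffle == "independent":
            groups = np.arange(amp.shape[1]) * 0  # one block, but shuffled
            obs = amp.sum(axis=0)
            exceed = np.zeros(amp.shape[1])
            for _ in range(n_perm):
                perm = np.array([rng.permutation(row) for row in amp])
                exceed += perm.sum(axis=0) >= obs - 1e-12
            p = (1.0 + exceed) / (n_perm + 1.0)
        else:
            obs, p = _perm_pvals(amp, groups, n_perm, rng)
        # BH over the full band/arm family (zero-signal columns have p = 1)
        q = _bh(p)
        for j in np.flatnonzero(obs > 0):
            if q[j] >= qcut:
                continue
            target = str(df.columns[j])
            lab = f"{target} {direction}"
            presence = pd.Series(
                [
                    any(
                        ev.direction == direction
                        and ev.klass == klass
                        and (
                            target in ev.bands
                            if klass == "focal"
                            else _arm_label_of(ev) == target
                        )
                        for ev in events_by_sample[s]
                    )
                    for s in samples
                ],
                index=samples,
            )
            rows.append(
                {
                    "label": lab,
                    "class": klass,
                    "direction": direction,
                    "g_score": obs[j],
                    "p": p[j],
                    "q": q[j],
                    "n_carriers": int(presence.sum()),
                    "presence": presence,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["label", "class", "direction", "g_score", "p", "q",
                     "n_carriers", "presence"]
        )
    out = pd.DataFrame(rows).sort_values(
        ["class", "direction", "q", "label"], kind="stable"
    )
    return out.reset_index(drop=True)
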