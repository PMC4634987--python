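"""Synthetic aCGH cohorts with known ground truth.

Emulates the structure of an oral-medicine biopsy cohort: patients carry
lesions (OPMDs/OSCCs) at one or more oral subsites, each subsite is sampled
by one or more biopsies, and each biopsy gets a histology label, a DNA
index (DI, flow-cytometry ploidy label), a cancer-cell fraction alpha and a
list of planted copy-number events.  Probe-level log2 ratios are rendered
from the clonality dilution formula plus Gaussian noise and sparse
outliers.

Defaults mirror the study conditions at desk scale: the subsite and
histology mixes follow the published biopsy table proportions; aneuploidy
probability rises from non-dysplastic OPMD to OSCC and is elevated for
tongue lesions; aberration burden is higher in aneuploid biopsies; alpha
defaults to 0.5 and per-probe noise to 0.15 log2 units.  Recurrence is made
measurable by a designated hotspot cytoband (focal) and hotspot arm (broad)
that attract a configurable share of planted events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import expected_log2
from .genome import Cytoband, ChromosomeDef, GenomeDef, ProbeGrid
from .preprocess import ArrayProfile

__all__ = [
    "TrueEvent",
    "BiopsySample",
    "CohortDesign",
    "generate_genome",
    "generate_cohort",
    "render_array",
    "cohort_metadata",
    "event_probe_mask",
]

SUBSITES = ("BM", "TNG", "FOM", "GUM", "SP", "LIP", "HP")
HISTOLOGIES = ("ND-OPMD", "D-OPMD", "OSCC")


class ParameterError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class TrueEvent:
    direction: str  # gain | loss
    chrom: str
    start: int
    end: int
    q_t: int  # total copy number
    scope: str  # focal | broad

    def validate(self, D: float) -> None:
        if self.direction == "gain" and not self.q_t > D:
            raise ParameterError("gain requires q_t > D")
        if self.direction == "loss" and not self.q_t < D:
            raise ParameterError("loss requires q_t < D")
        if self.q_t < 0 or self.end <= self.start:
            raise ParameterError("bad event geometry or copy number")


@dataclass(frozen=True)
class BiopsySample:
    patient_id: str
    subsite: str
    biopsy_id: str
    histology: str
    di: float  # DNA index; 1.0 = diploid
    alpha: float  # cancer-cell fraction
    ploidy: float = 2.0  # background ploidy D
    events: tuple[TrueEvent, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError("alpha must be in [0, 1]")
        if self.di <= 0:
            raise ParameterError("DI must be positive")
        for ev in self.events:
            ev.validate(self.ploidy)


def generate_genome(
    n_chromosomes: int = 8,
    arm_bands: int = 3,
    band_len: int = 10_000_000,
    probe_spacing: int = 100_000,
    seed: int = 0,
) -> tuple[GenomeDef, ProbeGrid]:
    """Toy genome: every chromosome has ``arm_bands`` bands of ``band_len``
    bp per arm (centromere at the middle) and evenly spaced probes.

    Band names follow cytogenetic convention: numbered outward from the
    centromere, so coordinate order on a 2-band arm is p2, p1, q1, q2.
    Probe count is floor(total length / spacing), distributed per
    chromosome.  Deterministic for a fixed seed (the layout is actually
    seed-free; the seed names the grid design).
    """
    if min(n_chromosomes, arm_bands, band_len, probe_spacing) < 1:
        raise ParameterError("all sizes must be >= 1")
    chroms = []
    probe_rows = []
    pid = 0
    for ci in range(1, n_chromosomes + 1):
        name = f"chr{ci}"
        length = 2 * arm_bands * band_len
        cen = arm_bands * band_len
        bands = []
        for bi in range(arm_bands):  # p arm, telomere -> centromere
            start = bi * band_len
            bands.append(Cytoband(name, start, start + band_len, f"p{arm_bands - bi}"))
        for bi in range(arm_bands):  # q arm, centromere -> telomere
            start = cen + bi * band_len
            bands.append(Cytoband(name, start, start + band_len, f"q{bi + 1}"))
        chroms.append(ChromosomeDef(name, length, cen, tuple(bands)))
        n_probes = length // probe_spacing
        for k in range(n_probes):
            pos = k * probe_spacing + probe_spacing // 2
            probe_rows.append((f"P{pid:06d}", name, pos))
            pid += 1
    grid = ProbeGrid(
        pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"]),
        design=f"synthetic-{seed}",
    )
    return GenomeDef(tuple(chroms)), grid


def _table1_mixes() -> tuple[dict, dict]:
    # biopsy counts by subsite x histology in the published cohort table
    counts = {
        "BM": (183, 19, 16),
        "TNG": (67, 22, 54),
        "FOM": (21, 7, 7),
        "GUM": (49, 5, 15),
        "SP": (10, 4, 6),
        "LIP": (2, 0, 0),
        "HP": (23, 2, 10),
    }
    total = sum(sum(v) for v in counts.values())
    subsite_probs = {k: sum(v) / total for k, v in counts.items()}
    histology_probs = {
        k: {h: c / sum(v) for h, c in zip(HISTOLOGIES, v)} for k, v in counts.items()
    }
    return subsite_probs, histology_probs


_SUBSITE_PROBS, _HISTOLOGY_PROBS = _table1_mixes()


@dataclass(frozen=True)
class CohortDesign:
    """Tunable priors for cohort generation; defaults are the study-scale
    conditions described in the module docstring."""

    n_patients: int = 40
    subsite_probs: dict = field(default_factory=lambda: dict(_SUBSITE_PROBS))
    histology_probs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _HISTOLOGY_PROBS.items()
    })
    aneuploidy_prob: dict = field(default_factory=lambda: {
        "ND-OPMD": 0.2, "D-OPMD": 0.45, "OSCC": 0.65,
    })
    # histology-and-subsite specific overrides (tongue lesions run higher)
    aneuploidy_overrides: dict = field(default_factory=lambda: {
        ("ND-OPMD", "TNG"): 0.45,
    })
    second_subsite_prob: float = 0.13
    extra_biopsy_rate: float = 0.6  # biopsies per subsite = 1 + Poisson(rate)
    event_rate_diploid: float = 0.5  # Poisson mean per biopsy
    event_rate_aneuploid: float = 2.5
    focal_fraction: float = 0.5
    gain_fraction: float = 0.5
    qt_gain_probs: dict = field(default_factory=lambda: {3: 0.7, 4: 0.2, 5: 0.1})
    qt_loss_probs: dict = field(default_factory=lambda: {1: 0.9, 0: 0.1})
    alpha_range: tuple = (0.5, 0.5)
    background_ploidy: float = 2.0
    di_range: tuple = (1.1, 2.2)
    hotspot_band: tuple | None = "auto"  # (chrom, band name) or None
    hotspot_prob: float = 0.5
    hotspot_direction: str = "gain"
    hotspot_arm: tuple | None = "auto"  # (chrom, arm) or None
    hotspot_arm_prob: float = 0.5
    hotspot_arm_direction: str = "gain"
    max_focal_bands: int = 3

    def validate(self) -> None:
        def _check_dist(d, what):
            vals = list(d.values())
            if any(v < 0 or v > 1 for v in vals) or abs(sum(vals) - 1) > 1e-9:
                raise ParameterError(f"{what}: probabilities must be in [0,1] and sum to 1")

        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        _check_dist(self.subsite_probs, "subsite_probs")
        for k, v in self.histology_probs.items():
            _check_dist(v, f"histology_probs[{k}]")
        for k, v in {**self.aneuploidy_prob,
                     **self.aneuploidy_overrides}.items():
            if not 0 <= v <= 1:
                raise ParameterError(f"aneuploidy prob {k} outside [0,1]")
        for p in (self.second_subsite_prob, self.focal_fraction,
                  self.gain_fraction, self.hotspot_prob, self.hotspot_arm_prob):
            if not 0 <= p <= 1:
                raise ParameterError("probabilities must be in [0,1]")
        _check_dist(self.qt_gain_probs, "qt_gain_probs")
        _check_dist(self.qt_loss_probs, "qt_loss_probs")
        if not 0 <= self.alpha_range[0] <= self.alpha_range[1] <= 1:
            raise ParameterError("alpha_range must be within [0,1]")


def _draw(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys], float))]


def _aneuploidy_p(design: CohortDesign, histology: str, subsite: str) -> float:
    return design.aneuploidy_overrides.get(
        (histology, subsite), design.aneuploidy_prob[histology]
    )


def _resolve_hotspots(design: CohortDesign, genome: GenomeDef):
    band = design.hotspot_band
    if band == "auto":
        c = genome.chromosomes[0]
        band = (c.name, next(b for b in c.bands if b.arm == "q").name)
    arm = design.hotspot_arm
    if arm == "auto":
        c = genome.chromosomes[min(1, len(genome.chromosomes) - 1)]
        arm = (c.name, "q")
    return band, arm


def _plant_events(
    rng: np.random.Generator,
    genome: GenomeDef,
    design: CohortDesign,
    aneuploid: bool,
) -> tuple[TrueEvent, ...]:
    rate = design.event_rate_aneuploid if aneuploid else design.event_rate_diploid
    n = rng.poisson(rate)
    if n == 0:
        return ()
    hotspot_band, hotspot_arm = _resolve_hotspots(design, genome)
    lengths = np.array([c.length for c in genome.chromosomes], float)
    events: list[TrueEvent] = []
    for _ in range(n):
        focal = rng.random() < design.focal_fraction
        at_hotspot = rng.random() < (
            design.hotspot_prob if focal else design.hotspot_arm_prob
        )
        if focal and at_hotspot and hotspot_band is not None:
            direction = design.hotspot_direction
        elif not focal and at_hotspot and hotspot_arm is not None:
            direction = design.hotspot_arm_direction
        else:
            at_hotspot = False
            direction = "gain" if rng.random() < design.gain_fraction else "loss"
        qt = int(_draw(rng, design.qt_gain_probs if direction == "gain"
                       else design.qt_loss_probs))
        if focal:
            if at_hotspot:
                chrom_name, band_name = hotspot_band
                c = genome.chromosome(chrom_name)
                bands = [b for b in c.bands if b.name == band_name]
            else:
                c = genome.chromosomes[
                    rng.choice(len(genome.chromosomes), p=lengths / lengths.sum())
                ]
                arm = "p" if rng.random() < 0.5 else "q"
                arm_bands = [b for b in c.bands if b.arm == arm]
                width = int(rng.integers(1, design.max_focal_bands + 1))
                width = min(width, len(arm_bands))
                i0 = int(rng.integers(0, len(arm_bands) - width + 1))
                bands = arm_bands[i0:i0 + width]
            start, end = bands[0].start, bands[-1].end
            scope = "focal"
        else:
            if at_hotspot:
                chrom_name, arm = hotspot_arm
                c = genome.chromosome(chrom_name)
            else:
                c = genome.chromosomes[
                    rng.choice(len(genome.chromosomes), p=lengths / lengths.sum())
                ]
                arm = "p" if rng.random() < 0.5 else "q"
            a0, a1 = c.arm_bounds(arm)
            if rng.random() < 0.5:
                start, end = a0, a1  # whole arm
            else:
                frac = rng.uniform(0.55, 1.0)  # >half-arm, telomere-anchored
                span = int(frac * (a1 - a0))
                start, end = (a0, a0 + span) if arm == "p" else (a1 - span, a1)
            scope = "broad"
        ev = TrueEvent(direction, c.name, start, end, qt, scope)
        if any(e.chrom == ev.chrom and e.start < ev.end and e.end > ev.start
               for e in events):
            continue  # keep per-biopsy events disjoint
        events.append(ev)
    return tuple(events)


def generate_cohort(
    genome: GenomeDef,
    design: CohortDesign | None = None,
    seed: int = 0,
) -> list[BiopsySample]:
    """Draw a cohort of biopsies with attached ground truth.

    Every patient x subsite gets at least one biopsy; all biopsies of a
    subsite share its histology draw, while ploidy, alpha and events are
    drawn per biopsy.  DI != 1 iff the biopsy is drawn aneuploid.
    """
    design = design or CohortDesign()
    design.validate()
    rng = np.random.default_rng(seed)
    samples: list[BiopsySample] = []
    for pi in range(design.n_patients):
        patient = f"PT{pi:04d}"
        n_sub = 1 + int(rng.random() < design.second_subsite_prob)
        sub_order = [_draw(rng, design.subsite_probs) for _ in range(8)]
        subsites = list(dict.fromkeys(sub_order))[:n_sub]
        for subsite in subsites:
            histology = _draw(rng, design.histology_probs[subsite])
            n_biopsies = 1 + rng.poisson(design.extra_biopsy_rate)
            for bi in range(n_biopsies):
                aneuploid = rng.random() < _aneuploidy_p(design, histology, subsite)
                if aneuploid:
                    di = float(rng.uniform(*design.di_range))
                else:
                    di = 1.0
                alpha = float(rng.uniform(*design.alpha_range))
                events = _plant_events(rng, genome, design, aneuploid)
                samples.append(
                    BiopsySample(
                        patient_id=patient,
                        subsite=subsite,
                        biopsy_id=f"{patient}_{subsite}_B{bi}",
                        histology=histology,
                        di=di,
                        alpha=alpha,
                        ploidy=design.background_ploidy,
                        events=events,
                    )
                )
    return samples


def cohort_metadata(samples: list[BiopsySample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.patient_id, s.subsite, s.biopsy_id, s.histology, s.di, s.alpha)
            for s in samples
        ],
        columns=["patient_id", "subsite", "biopsy_id", "histology", "DI", "alpha"],
    )


def _event_means(sample: BiopsySample, grid: ProbeGrid) -> np.ndarray:
    chroms = set(grid.probes["chrom"])
    mean = np.zeros(len(grid.probes))
    pos = grid.probes["pos"].to_numpy()
    chrom_arr = grid.probes["chrom"].to_numpy()
    for ev in sample.events:
        if ev.chrom not in chroms:
            raise ConsistencyError(
                f"{sample.biopsy_id}: event on {ev.chrom} absent from grid"
            )
        mask = (chrom_arr == ev.chrom) & (pos >= ev.start) & (pos < ev.end)
        # cap the homozygous-deletion sentinel (-inf) at a deep-loss level
        mean[mask] = max(expected_log2(sample.alpha, ev.q_t, sample.ploidy), -6.0)
    return mean


def event_probe_mask(sample: BiopsySample, grid: ProbeGrid) -> np.ndarray:
    """Boolean mask of probes inside any planted event (truth bookkeeping)."""
    chrom_arr = grid.probes["chrom"].to_numpy()
    pos = grid.probes["pos"].to_numpy()
    mask = np.zeros(len(grid.probes), bool)
    for ev in sample.events:
        mask |= (chrom_arr == ev.chrom) & (pos >= ev.start) & (pos < ev.end)
    return mask


def render_array(
    sample: BiopsySample,
    grid: ProbeGrid,
    noise_sd: float = 0.15,
    outlier_rate: float = 0.01,
    outlier_sd: float = 1.0,
    seed: int = 0,
) -> ArrayProfile:
    """Render probe-level log2 ratios for one biopsy.

    Probe mean inside an event is the clonality-formula expectation
    ``expected_log2(alpha, q_t, D)``, 0 elsewhere; Gaussian noise of SD
    ``noise_sd`` is added everywhere and a fraction ``outlier_rate`` of
    probes receives extra Gaussian noise of SD ``outlier_sd``.
    """
    if noise_sd < 0 or outlier_sd < 0 or not 0 <= outlier_rate <= 1:
        raise ParameterError("bad noise parameters")
    rng = np.random.default_rng(seed)
    mean = _event_means(sample, grid)
    log2 = mean.copy()
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, size=log2.size)
    if outlier_rate > 0 and outlier_sd > 0:
        hit = rng.random(log2.size) < outlier_rate
        log2 = log2 + hit * rng.normal(0.0, outlier_sd, size=log2.size)
    df = grid.probes.copy()
    df["log2"] = log2
    return ArrayProfile(sample.biopsy_id, df.reset_index(drop=True))
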