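"""End-to-end pipeline: simulate -> preprocess -> segment -> call ->
aggregate -> associate -> report.

Every stage reads and writes plain TSV/SEG/JSON files under the configured
output directory, so stages can be re-run individually from the CLI; a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, preprocess, segment, simulate, stats, units as units_mod
from .genome import (
    GenomeDef,
    ProbeGrid,
    read_cytobands,
    read_probes,
    write_cytobands,
    write_probes,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "segment", "call", "aggregate", "associate", "report")

# the published analysis settings are the config defaults: gamma=40,
# thresholds +-0.3, dLRs cap 0.35, focal q 0.25, broad q 0.3, significance q 0.1


@dataclass
class RunConfig:
    outdir: str = "oralcna_run"
    mode: str = "synthetic"  # synthetic | real
    seed: int = 11
    # synthetic genome/cohort
    n_chromosomes: int = 8
    arm_bands: int = 3
    band_len: int = 10_000_000
    probe_spacing: int = 100_000
    design: dict = field(default_factory=dict)  # CohortDesign overrides
    noise_sd: float = 0.15
    outlier_rate: float = 0.01
    outlier_sd: float = 1.0
    # real-mode inputs
    cytoband_path: str | None = None
    probes_path: str | None = None
    profiles_path: str | None = None
    metadata_path: str | None = None
    # preprocessing / segmentation
    max_dlrs: float = 0.35
    qc_allowlist: list = field(default_factory=list)
    winsor_k: float = 2.5
    gamma: float = 40.0
    normalize: bool = True
    # calling
    gain_thr: float = 0.3
    loss_thr: float = -0.3
    broad_arm_fraction: float = 0.5
    focal_q: float = 0.25
    broad_q: float = 0.3
    n_perm: int = 500
    shuffle: str = "cyclic"
    # aggregation / association
    di_tolerance: float = 0.05
    q_threshold: float = 0.1
    alpha_cap: float = 0.05
    plan: list | None = None  # None -> stats.default_plan()

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def non_defaults(self) -> dict:
        ref = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(ref, f.name)
        }

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


@dataclass
class RunReport:
    stage_counts: dict = field(default_factory=dict)
    discarded_arrays: list = field(default_factory=list)
    decisions: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _derived_seed(base: int, k: int) -> int:
    return (base * 1_000_003 + k) % (2**31)


def _load_genome_grid(cfg: RunConfig) -> tuple[GenomeDef, ProbeGrid]:
    genome = read_cytobands(cfg.path("cytobands.tsv"))
    grid = read_probes(cfg.path("probes.tsv"))
    return genome, grid


def stage_simulate(cfg: RunConfig, report: RunReport) -> None:
    if cfg.mode == "real":
        # copy external inputs into the run directory in canonical form
        for p, what in [
            (cfg.cytoband_path, "cytoband_path"),
            (cfg.probes_path, "probes_path"),
            (cfg.profiles_path, "profiles_path"),
            (cfg.metadata_path, "metadata_path"),
        ]:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"real mode requires {what}")
        genome = read_cytobands(cfg.cytoband_path)
        grid = read_probes(cfg.probes_path)
        write_cytobands(genome, cfg.path("cytobands.tsv"))
        write_probes(grid, cfg.path("probes.tsv"))
        meta = pd.read_csv(cfg.metadata_path, sep="\t")
        meta.to_csv(cfg.path("metadata.tsv"), sep="\t", index=False)
        prof = pd.read_csv(cfg.profiles_path, sep="\t")
        prof.to_csv(cfg.path("profiles.tsv"), sep="\t", index=False, float_format="%.6g")
        report.stage_counts["simulate"] = {
            "biopsies": int(meta.shape[0]), "probes": len(grid)
        }
        return
    genome, grid = simulate.generate_genome(
        cfg.n_chromosomes, cfg.arm_bands, cfg.band_len, cfg.probe_spacing, cfg.seed
    )
    design = simulate.CohortDesign(**cfg.design)
    cohort = simulate.generate_cohort(genome, design, seed=cfg.seed)
    write_cytobands(genome, cfg.path("cytobands.tsv"))
    write_probes(grid, cfg.path("probes.tsv"))
    simulate.cohort_metadata(cohort).to_csv(
        cfg.path("metadata.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    long_rows = []
    for i, s in enumerate(cohort):
        prof = simulate.render_array(
            s, grid, cfg.noise_sd, cfg.outlier_rate, cfg.outlier_sd,
            seed=_derived_seed(cfg.seed, i + 1),
        )
        df = prof.data[["probe_id", "log2"]].copy()
        df.insert(0, "sample", s.biopsy_id)
        long_rows.append(df)
    pd.concat(long_rows).to_csv(
        cfg.path("profiles.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    truth = pd.DataFrame(
        [
            (s.biopsy_id, ev.direction, ev.chrom, ev.start, ev.end, ev.q_t, ev.scope)
            for s in cohort
            for ev in s.events
        ],
        columns=["sample", "direction", "chrom", "start", "end", "q_t", "scope"],
    )
    truth.to_csv(cfg.path("truth_events.tsv"), sep="\t", index=False)
    report.stage_counts["simulate"] = {
        "biopsies": len(cohort), "probes": len(grid),
        "true_events": int(truth.shape[0]),
    }
    report.seeds["simulate"] = cfg.seed


def _load_profiles(cfg: RunConfig, name: str) -> list[preprocess.ArrayProfile]:
    grid = read_probes(cfg.path("probes.tsv"))
    long = pd.read_csv(cfg.path(name), sep="\t")
    merged = long.merge(grid.probes, on="probe_id", how="left")
    if merged["chrom"].isna().any():
        bad = merged.loc[merged["chrom"].isna(), "probe_id"].unique()
        raise ValueError(f"profiles reference unknown probes: {bad[:5]}")
    out = []
    for sid, grp in merged.groupby("sample", sort=True):
        out.append(
            preprocess.average_replicates(
                grp[["probe_id", "chrom", "pos", "log2"]], str(sid)
            )
        )
    return out


def stage_preprocess(cfg: RunConfig, report: RunReport) -> None:
    profiles = _load_profiles(cfg, "profiles.tsv")
    kept, discarded = preprocess.qc_filter(
        profiles, max_dlrs=cfg.max_dlrs, allowlist=set(cfg.qc_allowlist)
    )
    kept = [preprocess.winsorize(p, k=cfg.winsor_k) for p in kept]
    qc = pd.DataFrame(
        [
            (p.sample_id, p.dlrs, p.qc_pass, p.qc_override)
            for p in sorted(kept + discarded, key=lambda p: p.sample_id)
        ],
        columns=["sample", "dlrs", "qc_pass", "qc_override"],
    )
    qc.to_csv(cfg.path("qc.tsv"), sep="\t", index=False, float_format="%.6g")
    rows = []
    for p in kept:
        df = p.data[["probe_id", "log2"]].copy()
        df.insert(0, "sample", p.sample_id)
        rows.append(df)
    cols = ["sample", "probe_id", "log2"]
    out = pd.concat(rows)[cols] if rows else pd.DataFrame(columns=cols)
    out.to_csv(
        cfg.path("processed_profiles.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    report.stage_counts["preprocess"] = {
        "arrays_in": len(profiles), "kept": len(kept), "discarded": len(discarded)
    }
    report.discarded_arrays = [p.sample_id for p in discarded]


def stage_segment(cfg: RunConfig, report: RunReport) -> None:
    profiles = _load_profiles(cfg, "processed_profiles.tsv")
    segs = [
        segment.segment_pcf(p, gamma=cfg.gamma, normalize=cfg.normalize)
        for p in profiles
    ]
    segment.write_seg(segs, cfg.path("segments.seg"))
    report.stage_counts["segment"] = {
        "arrays": len(segs),
        "segments": int(sum(len(s.segments) for s in segs)),
    }


def stage_call(cfg: RunConfig, report: RunReport) -> None:
    genome, _ = _load_genome_grid(cfg)
    segs = segment.read_seg(cfg.path("segments.seg"))
    all_events: list[calling.CNAEventCall] = []
    for sp in segs:
        called = calling.call_segments(sp, cfg.gain_thr, cfg.loss_thr)
        all_events.extend(
            calling.classify_events(called, genome, cfg.broad_arm_fraction)
        )
    calling.events_frame(all_events).to_csv(
        cfg.path("events.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    if len(segs) >= 2:
        rec = calling.recurrent_cnas(
            segs, genome,
            gain_thr=cfg.gain_thr, loss_thr=cfg.loss_thr,
            broad_arm_fraction=cfg.broad_arm_fraction,
            focal_q=cfg.focal_q, broad_q=cfg.broad_q,
            n_perm=cfg.n_perm, seed=_derived_seed(cfg.seed, 777),
            shuffle=cfg.shuffle,
        )
    else:
        warnings.warn("fewer than 2 arrays; recurrence stage skipped")
        rec = pd.DataFrame(
            columns=["label", "class", "direction", "g_score", "p", "q",
                     "n_carriers", "presence"]
        )
    flat = rec.drop(columns=["presence"])
    # the simplified recurrence stage assigns each region to exactly one
    # class by the half-arm rule (no GISTIC-style double assignment)
    flat.to_csv(cfg.path("recurrent.tsv"), sep="\t", index=False, float_format="%.6g")
    if len(rec):
        pres = pd.DataFrame({r.label: r.presence for r in rec.itertuples()})
        pres.index.name = "sample"
    else:
        pres = pd.DataFrame(index=pd.Index([s.sample_id for s in segs], name="sample"))
    pres.astype(int).to_csv(cfg.path("recurrent_presence.tsv"), sep="\t")
    report.stage_counts["call"] = {
        "events": len(all_events), "recurrent_cnas": int(len(rec))
    }
    report.seeds["call"] = _derived_seed(cfg.seed, 777)


def _events_from_file(path) -> list[calling.CNAEventCall]:
    df = pd.read_csv(path, sep="\t").rename(columns={"class": "klass"})
    out = []
    for r in df.itertuples():
        bands = tuple(str(r.bands).split(",")) if isinstance(r.bands, str) and r.bands else ()
        out.append(
            calling.CNAEventCall(
                str(r.sample), r.direction, r.klass, r.chrom, r.arm,
                int(r.start), int(r.end), float(r.mean),
                float(r.arm_fraction), bands,
            )
        )
    return out


def stage_aggregate(cfg: RunConfig, report: RunReport) -> None:
    meta = pd.read_csv(cfg.path("metadata.tsv"), sep="\t")
    qc = pd.read_csv(cfg.path("qc.tsv"), sep="\t")
    kept_ids = set(qc.loc[qc["qc_pass"], "sample"].astype(str))
    meta = meta[meta["biopsy_id"].astype(str).isin(kept_ids)]
    events = _events_from_file(cfg.path("events.tsv"))
    rec = pd.read_csv(cfg.path("recurrent.tsv"), sep="\t")
    labels = rec["label"].tolist() if len(rec) else []
    if meta.empty:
        units_mod.units_frame([]).to_csv(cfg.path("units.tsv"), sep="\t", index=False)
        pd.DataFrame(columns=labels).to_csv(cfg.path("presence.tsv"), sep="\t")
        report.stage_counts["aggregate"] = {"units": 0}
        return
    units = units_mod.build_units(meta, di_tolerance=cfg.di_tolerance)
    presence = units_mod.unit_cna_presence(units, events, labels)
    units_mod.attach_scores(units, events)
    udf = units_mod.units_frame(units)
    udf.to_csv(cfg.path("units.tsv"), sep="\t", index=False)
    presence.to_csv(cfg.path("presence.tsv"), sep="\t", index_label="unit")
    report.stage_counts["aggregate"] = {
        "units": len(units), "cna_labels": len(labels)
    }


def stage_associate(cfg: RunConfig, report: RunReport) -> None:
    udf = pd.read_csv(cfg.path("units.tsv"), sep="\t")
    pres = pd.read_csv(cfg.path("presence.tsv"), sep="\t", index_col=0)
    if udf.empty:
        res = pd.DataFrame(
            columns=["family", "test", "outcome", "a", "b", "c", "d",
                     "statistic", "odds_ratio", "ci_low", "ci_high", "p",
                     "q", "prevalence", "significant"]
        )
    else:
        res = stats.run_association_suite(
            udf, pres, plan=cfg.plan, q_threshold=cfg.q_threshold,
            alpha_cap=cfg.alpha_cap,
        )
    res.to_csv(cfg.path("associations.tsv"), sep="\t", index=False, float_format="%.6g")
    report.stage_counts["associate"] = {
        "tests": int(len(res)),
        "significant": int(res["significant"].fillna(False).astype(bool).sum())
        if len(res) else 0,
    }


def stage_report(cfg: RunConfig, report: RunReport) -> None:
    import oralcna

    report.versions = {
        "oralcna": getattr(oralcna, "__version__", "0"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    for key, value in sorted(cfg.non_defaults().items()):
        report.decisions.append(f"non-default parameter: {key} = {value!r}")
    report.decisions.append(
        "thresholds inclusive (>= gain_thr, <= loss_thr); broad/focal assigned "
        "exclusively by the half-arm rule"
    )
    report.to_json(cfg.path("report.json"))


_STAGE_FNS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "segment": stage_segment,
    "call": stage_call,
    "aggregate": stage_aggregate,
    "associate": stage_associate,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> RunReport:
    """Run the requested stages in order; any failure aborts with the stage
    name attached."""
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    report = RunReport()
    for st in stages:
        if st not in _STAGE_FNS:
            raise ValueError(f"unknown stage {st!r}")
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[st](cfg, report)
        except Exception as exc:
            raise RuntimeError(f"stage {st!r} failed: {exc}") from exc
        report.wall_clock_s[st] = round(time.perf_counter() - t0, 3)
    if "report" not in stages:
        report.to_json(cfg.path("report.json"))
    return report
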