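"""Genome model: chromosomes, arms, cytobands, and ordered probe grids.

All coordinates are 0-based half-open internally.  The only place 1-based
closed coordinates appear is SEG export (see :mod:`oralcna.segment`), per
that format family's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Cytoband",
    "ChromosomeDef",
    "GenomeDef",
    "ProbeGrid",
    "read_cytobands",
    "write_cytobands",
    "read_probes",
    "write_probes",
]


class GenomeFormatError(ValueError):
    """Raised when a cytoband table violates ordering/tiling rules."""


@dataclass(frozen=True)
class Cytoband:
    chrom: str
    start: int
    end: int
    name: str  # e.g. "p1", "q24.3"

    @property
    def arm(self) -> str:
        return self.name[0]

    @property
    def label(self) -> str:
        """Field-style band label, e.g. '8q24.3' for chrom 'chr8'."""
        return _chrom_number(self.chrom) + self.name


@dataclass(frozen=True)
class ChromosomeDef:
    name: str
    length: int
    centromere: int
    bands: tuple[Cytoband, ...]

    def arm_bounds(self, arm: str) -> tuple[int, int]:
        if arm == "p":
            return 0, self.centromere
        if arm == "q":
            return self.centromere, self.length
        raise ValueError(f"unknown arm {arm!r}")

    def arm_length(self, arm: str) -> int:
        s, e = self.arm_bounds(arm)
        return e - s


def _chrom_number(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosomes with cytobands tiling each one.

    Invariants (checked in ``validate``): bands tile the chromosome with no
    gaps or overlaps; no band crosses the centromere; a band is on the p arm
    iff it ends at or before the centromere.
    """

    chromosomes: tuple[ChromosomeDef, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for c in self.chromosomes:
            pos = 0
            for b in c.bands:
                if b.chrom != c.name:
                    raise GenomeFormatError(f"band {b} not on {c.name}")
                if b.start != pos:
                    raise GenomeFormatError(
                        f"{c.name}: band {b.name} starts at {b.start}, expected {pos}"
                    )
                if b.end <= b.start:
                    raise GenomeFormatError(f"{c.name}:{b.name} empty band")
                if b.start < c.centromere < b.end:
                    raise GenomeFormatError(f"{c.name}:{b.name} crosses centromere")
                expected_arm = "p" if b.end <= c.centromere else "q"
                if b.arm != expected_arm:
                    raise GenomeFormatError(
                        f"{c.name}:{b.name} named {b.arm} arm but lies on {expected_arm}"
                    )
                pos = b.end
            if pos != c.length:
                raise GenomeFormatError(f"{c.name}: bands end at {pos} != length {c.length}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> ChromosomeDef:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def arms(self) -> list[tuple[str, str, int, int]]:
        """All (chrom, arm, start, end) in genome order, p before q."""
        out = []
        for c in self.chromosomes:
            out.append((c.name, "p", 0, c.centromere))
            out.append((c.name, "q", c.centromere, c.length))
        return out

    def arm_label(self, chrom: str, arm: str) -> str:
        return _chrom_number(chrom) + arm

    def bands_in(self, chrom: str, start: int, end: int) -> list[Cytoband]:
        """Cytobands overlapping [start, end) on chrom, in order."""
        c = self.chromosome(chrom)
        return [b for b in c.bands if b.start < end and b.end > start]

    def band_at(self, chrom: str, pos: int) -> Cytoband:
        c = self.chromosome(chrom)
        for b in c.bands:
            if b.start <= pos < b.end:
                return b
        raise KeyError(f"{chrom}:{pos} outside bands")

    def band_labels(self) -> list[str]:
        return [b.label for c in self.chromosomes for b in c.bands]

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (b.chrom, b.start, b.end, b.name, "gneg")
            for c in self.chromosomes
            for b in c.bands
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])


@dataclass(frozen=True)
class ProbeGrid:
    """Ordered probes on a genome; positions strictly increase per chromosome."""

    probes: pd.DataFrame = field(repr=False)  # columns: probe_id, chrom, pos
    design: str = "synthetic"

    def __post_init__(self) -> None:
        req = {"probe_id", "chrom", "pos"}
        if not req.issubset(self.probes.columns):
            raise ValueError(f"probe table needs columns {sorted(req)}")
        for chrom, grp in self.probes.groupby("chrom", sort=False):
            d = grp["pos"].diff().dropna()
            if (d <= 0).any():
                raise ValueError(f"probe positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.probes)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.probes[self.probes["chrom"] == chrom]

    def intersect(self, other: "ProbeGrid") -> "ProbeGrid":
        """Shared-probe grid of two designs, by probe id (and position)."""
        merged = self.probes.merge(other.probes, on=["probe_id", "chrom", "pos"])
        return ProbeGrid(
            merged.reset_index(drop=True), design=f"{self.design}&{other.design}"
        )


def genome_from_frame(df: pd.DataFrame) -> GenomeDef:
    chroms = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        # the p/q transition in file order fixes the centromere
        arms = grp["band"].str[0].tolist()
        for i in range(1, len(arms)):
            if arms[i - 1] == "q" and arms[i] == "p":
                raise GenomeFormatError(
                    f"{chrom}: q band {grp['band'][i-1]!r} precedes p band "
                    f"{grp['band'][i]!r} (line order)"
                )
        if "p" in arms:
            cen = int(grp.loc[[i for i, a in enumerate(arms) if a == "p"][-1], "end"])
        else:
            cen = 0
        length = int(grp["end"].iloc[-1])
        bands = tuple(
            Cytoband(chrom, int(r.start), int(r.end), str(r.band))
            for r in grp.itertuples()
        )
        chroms.append(ChromosomeDef(chrom, length, cen, bands))
    return GenomeDef(tuple(chroms))


def read_cytobands(path) -> GenomeDef:
    """Parse a UCSC cytoBand-style TSV (chrom, start, end, band, stain).

    Accepts files with or without a header row.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise GenomeFormatError("cytoband file needs >= 4 columns")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df
    df.columns = ["chrom", "start", "end", "band", "stain"][: df.shape[1]]
    if not str(df.iloc[0]["start"]).lstrip("-").isdigit():  # header row
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    try:
        return genome_from_frame(df)
    except GenomeFormatError:
        raise
    except ValueError as exc:  # re-wrap with context
        raise GenomeFormatError(str(exc)) from exc


def write_cytobands(genome: GenomeDef, path) -> None:
    genome.to_frame().to_csv(path, sep="\t", index=False)


def read_probes(path, design: str = "file") -> ProbeGrid:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": int})
    return ProbeGrid(df[["probe_id", "chrom", "pos"]], design=design)


def write_probes(grid: ProbeGrid, path) -> None:
    grid.probes.to_csv(path, sep="\t", index=False)
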