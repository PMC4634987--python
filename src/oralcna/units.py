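"""Patient x subsite statistical units: collapsing rules and burden scores.

All biopsies from one oral subsite of one patient form a single statistical
unit.  The unit's histology is the most severe diagnosis among its biopsies
(ND-OPMD < D-OPMD < OSCC); its ploidy class is aneuploid as soon as a
single biopsy is DNA aneuploid; CNA presence follows the same any-biopsy
rule.  Burden scores count each affected location once per unit:

* TFG / TFL - number of distinct cytobands hit by >= 1 focal gain / loss,
* TBG / TBL - number of distinct (arm, direction) broad regions present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calling import CNAEventCall

__all__ = [
    "StatisticalUnit",
    "HISTOLOGY_RANK",
    "normalize_histology",
    "build_units",
    "unit_cna_presence",
    "total_scores",
    "attach_scores",
    "units_frame",
]

HISTOLOGY_RANK = {"ND-OPMD": 0, "D-OPMD": 1, "OSCC": 2}


class ValidationError(ValueError):
    pass


def normalize_histology(value: str) -> str:
    """Map recorded diagnoses onto the three analysis categories; any graded
    dysplasia collapses to D-OPMD."""
    v = str(value).strip()
    if v in HISTOLOGY_RANK:
        return v
    low = v.lower()
    if "oscc" in low or "carcinoma" in low:
        return "OSCC"
    if "dyspla" in low and not low.startswith(("nd", "non")):
        return "D-OPMD"
    if low.startswith(("nd", "non")):
        return "ND-OPMD"
    raise ValidationError(f"unrecognized histology {value!r}")


@dataclass
class StatisticalUnit:
    patient_id: str
    subsite: str
    histology: str
    ploidy: str  # diploid | aneuploid
    exclusive: bool  # patient has lesions at exactly one subsite
    biopsy_ids: tuple[str, ...]
    presence: dict = field(default_factory=dict)  # label -> bool
    tfg: int = 0
    tbg: int = 0
    tfl: int = 0
    tbl: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.subsite)


def build_units(
    metadata: pd.DataFrame,
    di_tolerance: float = 0.05,
) -> list[StatisticalUnit]:
    """Collapse biopsy metadata (patient_id, subsite, biopsy_id, histology,
    DI) into one unit per (patient, subsite).

    A biopsy is aneuploid when |DI - 1| >= ``di_tolerance``; one aneuploid
    biopsy suffices to class the unit aneuploid.
    """
    req = {"patient_id", "subsite", "biopsy_id", "histology", "DI"}
    if not req.issubset(metadata.columns):
        raise ValidationError(f"metadata needs columns {sorted(req)}")
    bad = metadata[metadata["histology"].isna() | metadata["DI"].isna()]
    if len(bad):
        raise ValidationError(
            f"missing histology/DI for biopsies: {bad['biopsy_id'].tolist()}"
        )
    units: list[StatisticalUnit] = []
    n_subsites = metadata.groupby("patient_id")["subsite"].nunique()
    for (patient, subsite), grp in metadata.groupby(
        ["patient_id", "subsite"], sort=True
    ):
        hist = max(
            (normalize_histology(h) for h in grp["histology"]),
            key=HISTOLOGY_RANK.__getitem__,
        )
        aneuploid = (grp["DI"].astype(float) - 1.0).abs().ge(di_tolerance).any()
        units.append(
            StatisticalUnit(
                patient_id=patient,
                subsite=subsite,
                histology=hist,
                ploidy="aneuploid" if aneuploid else "diploid",
                exclusive=bool(n_subsites[patient] == 1),
                biopsy_ids=tuple(grp["biopsy_id"]),
            )
        )
    return units


def _event_matches(event: CNAEventCall, label: str) -> bool:
    """A recurrent-CNA label is '<band> gain', '<band> loss' (focal) or
    '<arm> gain'/'<arm> loss' (broad); arm labels end in p or q."""
    target, _, direction = label.rpartition(" ")
    if direction != event.direction:
        return False
    if event.klass == "broad":
        chrom_num = event.chrom[3:] if event.chrom.startswith("chr") else event.chrom
        return target == f"{chrom_num}{event.arm}"
    return target in event.bands


def unit_cna_presence(
    units: list[StatisticalUnit],
    events: list[CNAEventCall],
    labels: list[str],
) -> pd.DataFrame:
    """Any-biopsy presence of each recurrent-CNA label per unit.

    Returns a 0/1 DataFrame (units x labels, index 'patient|subsite') and
    fills each unit's ``presence`` dict in place.
    """
    by_biopsy: dict[str, list[CNAEventCall]] = {}
    for ev in events:
        by_biopsy.setdefault(ev.sample_id, []).append(ev)
    known = {b for u in units for b in u.biopsy_ids}
    orphans = set(by_biopsy) - known
    if orphans:
        raise ValidationError(f"events for unknown biopsies: {sorted(orphans)[:10]}")
    rows = []
    for u in units:
        unit_events = [ev for b in u.biopsy_ids for ev in by_biopsy.get(b, [])]
        u.presence = {
            lab: any(_event_matches(ev, lab) for ev in unit_events) for lab in labels
        }
        rows.append([int(u.presence[lab]) for lab in labels])
    idx = [f"{u.patient_id}|{u.subsite}" for u in units]
    return pd.DataFrame(rows, index=idx, columns=labels)


def total_scores(unit_events: list[CNAEventCall]) -> tuple[int, int, int, int]:
    """(TFG, TBG, TFL, TBL) for the pooled events of one unit's biopsies."""
    focal_gain_bands: set[str] = set()
    focal_loss_bands: set[str] = set()
    broad_gain_arms: set[tuple[str, str]] = set()
    broad_loss_arms: set[tuple[str, str]] = set()
    for ev in unit_events:
        if ev.klass == "focal":
            (focal_gain_bands if ev.direction == "gain" else focal_loss_bands).update(
                ev.bands
            )
        else:
            (broad_gain_arms if ev.direction == "gain" else broad_loss_arms).add(
                (ev.chrom, ev.arm)
            )
    return (
        len(focal_gain_bands),
        len(broad_gain_arms),
        len(focal_loss_bands),
        len(broad_loss_arms),
    )


def attach_scores(
    units: list[StatisticalUnit], events: list[CNAEventCall]
) -> None:
    by_biopsy: dict[str, list[CNAEventCall]] = {}
    for ev in events:
        by_biopsy.setdefault(ev.sample_id, []).append(ev)
    for u in units:
        pooled = [ev for b in u.biopsy_ids for ev in by_biopsy.get(b, [])]
        u.tfg, u.tbg, u.tfl, u.tbl = total_scores(pooled)


def units_frame(units: list[StatisticalUnit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                u.patient_id, u.subsite, u.histology, u.ploidy,
                u.exclusive, u.tfg, u.tbg, u.tfl, u.tbl,
            )
            for u in units
        ],
        columns=[
            "patient_id", "subsite", "histology", "ploidy",
            "exclusive", "TFG", "TBG", "TFL", "TBL",
        ],
    )
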