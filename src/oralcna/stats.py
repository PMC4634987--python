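"""Hypothesis tests and multiple-testing machinery for the cohort analyses.

Covers Fisher's exact 2x2 test with odds ratio and Woolf CI, Breslow-Day
homogeneity across strata, the two-tailed Mann-Whitney U test, Cohen's
kappa, Benjamini-Hochberg step-up q-values with an explicit family size,
and a discrete false-discovery-rate estimator for families of 2x2 tables
that exploits each table's attainable hypergeometric p-value distribution
(with optional filtering of tables that cannot reach significance).

The two-sided Fisher convention is the sum of hypergeometric probabilities
of all tables, with the observed margins, no more probable than the
observed one - the convention that reproduces the published p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "fisher_2x2",
    "breslow_day",
    "mann_whitney",
    "cohens_kappa",
    "bh_qvalues",
    "carlson_fdr",
    "run_association_suite",
    "default_plan",
]

_REL_EPS = 1.0 + 1e-9


class UndefinedTestError(ValueError):
    pass


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are the two groups, columns
    absent/present."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v:
                raise ValueError("counts must be integers")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins_positive(self) -> bool:
        return (
            min(self.a + self.b, self.c + self.d) > 0
            and min(self.a + self.c, self.b + self.d) > 0
        )


@dataclass(frozen=True)
class AssociationResult:
    family: str
    test: str
    outcome: str
    counts: tuple | None
    statistic: float
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float
    q: float | None
    prevalence: str | None
    significant: bool | None


def fisher_2x2(
    table: ContingencyTable2x2, or_method: str = "woolf"
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided Fisher exact p, odds ratio and 95% CI.

    The OR is ad/bc with the Haldane-Anscombe +0.5 correction applied to
    all cells when any cell is zero; the CI is the Woolf logit interval on
    the (corrected) counts.  ``or_method='cmle'`` instead returns the
    conditional-MLE odds ratio and exact CI.
    """
    if not table.margins_positive():
        raise UndefinedTestError("both margins must be positive")
    p = float(sps.fisher_exact(table.array, alternative="two-sided")[1])
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if or_method == "cmle":
        res = sps.contingency.odds_ratio(table.array, kind="conditional")
        ci = res.confidence_interval(0.95)
        return p, float(res.statistic), (float(ci.low), float(ci.high))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.975)
    lo, hi = math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)
    return p, orr, (lo, hi)


def breslow_day(
    strata: list[ContingencyTable2x2], tarone: bool = False
) -> tuple[float, int, float]:
    """Breslow-Day homogeneity of odds ratios against the Mantel-Haenszel
    common OR.  Returns (chi2, df, p).  Strata with an empty margin are
    dropped with a warning; fewer than two usable strata is an error.

    The expected top-left cell under the common OR solves a quadratic
    (linear when the common OR is exactly 1, where the closed form is the
    usual independence expectation).  ``tarone=True`` applies Tarone's
    correction term.
    """
    usable = []
    for i, t in enumerate(strata):
        if t.margins_positive():
            usable.append(t)
        else:
            warnings.warn(f"stratum {i} has an empty margin; dropped")
    if len(usable) < 2:
        raise UndefinedTestError("Breslow-Day needs >= 2 usable strata")
    # Mantel-Haenszel common odds ratio
    num = sum(t.a * t.d / t.n for t in usable)
    den = sum(t.b * t.c / t.n for t in usable)
    if den == 0 or num == 0:
        raise UndefinedTestError("MH common OR not estimable")
    or_mh = num / den
    chi2 = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    for t in usable:
        r1, c1, n = t.a + t.b, t.a + t.c, t.n
        if abs(or_mh - 1.0) < 1e-12:
            e = r1 * c1 / n
        else:
            # (OR-1) e^2 - [(r1+c1)OR + n - r1 - c1] e + OR r1 c1 = 0
            qa = or_mh - 1.0
            qb = -((r1 + c1) * or_mh + (n - r1 - c1))
            qc = or_mh * r1 * c1
            disc = math.sqrt(qb * qb - 4 * qa * qc)
            e = (-qb - disc) / (2 * qa)
            lo, hi = max(0.0, r1 + c1 - n), min(r1, c1)
            if not lo <= e <= hi:
                e = (-qb + disc) / (2 * qa)
        v = 1.0 / (
            1.0 / e + 1.0 / (r1 - e) + 1.0 / (c1 - e) + 1.0 / (n - r1 - c1 + e)
        )
        chi2 += (t.a - e) ** 2 / v
        resid_sum += t.a - e
        var_sum += v
    if tarone:
        chi2 -= resid_sum**2 / var_sum
    df = len(usable) - 1
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U (U for the first sample).

    Exact enumeration when min(n1, n2) <= 8 and there are no ties; normal
    approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise UndefinedTestError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:  # degenerate: identical constant groups
        return float(x.size * y.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cohens_kappa(u, v) -> float:
    """Cohen's kappa for two equal-length binary vectors."""
    u = np.asarray(u).astype(int)
    v = np.asarray(v).astype(int)
    if u.shape != v.shape or u.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    n = u.size
    po = float(np.mean(u == v))
    pe = 0.0
    for k in (0, 1):
        pe += (np.sum(u == k) / n) * (np.sum(v == k) / n)
    if pe >= 1.0 - 1e-12:
        raise UndefinedTestError("kappa undefined: degenerate marginals")
    return (po - pe) / (1.0 - pe)


def bh_qvalues(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with explicit family size ``m``
    (>= the number of supplied p-values; defaults to it)."""
    p = np.asarray(pvals, float)
    if p.size and (np.min(p) <= 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    q = np.empty_like(p)
    run = 1.0
    for rank in range(p.size, 0, -1):
        i = order[rank - 1]
        run = min(run, p[i] * m / rank)
        q[i] = run
    return q


def _table_null(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Attainable two-sided p-values and their probabilities under the
    hypergeometric null with the table's margins fixed."""
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    n = table.n
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    pvals = np.array([pmf[pmf <= pk * _REL_EPS].sum() for pk in pmf])
    return np.minimum(pvals, 1.0), pmf


def carlson_fdr(
    tables: list[ContingencyTable2x2],
    filter: bool = True,
    alpha_cap: float = 0.05,
) -> pd.DataFrame:
    """Discrete FDR q-values for a family of 2x2 tables.

    For each candidate threshold t among the observed two-sided Fisher
    p-values, the expected number of discoveries under the null is the sum
    over family members of P_j(P_j <= t) computed from each table's own
    attainable hypergeometric p-value distribution; FDR(t) divides that by
    the observed discovery count, and q_i is the minimum estimated FDR over
    thresholds >= p_i (clipped at 1).  With ``filter`` on, tables whose
    minimum attainable p exceeds ``alpha_cap`` are removed from the family
    first (reported with filtered=True and q = NaN).
    """
    if not tables:
        return pd.DataFrame(columns=["p", "q", "filtered", "min_attainable_p"])
    obs_p, nulls, min_att = [], [], []
    for t in tables:
        if not t.margins_positive():
            raise UndefinedTestError("both margins must be positive")
        obs_p.append(float(sps.fisher_exact(t.array)[1]))
        null_p, pmf = _table_null(t)
        nulls.append((null_p, pmf))
        min_att.append(float(null_p.min()))
    obs_p = np.array(obs_p)
    min_att = np.array(min_att)
    keep = ~(filter & (min_att > alpha_cap))
    q = np.full(obs_p.size, np.nan)
    idx = np.flatnonzero(keep)
    if idx.size:
        thresholds = np.sort(obs_p[idx])
        # expected null discoveries at each threshold, summed over the family
        e_null = np.zeros(thresholds.size)
        for j in idx:
            null_p, pmf = nulls[j]
            e_null += [
                pmf[null_p <= t * _REL_EPS].sum() for t in thresholds
            ]
        n_disc = np.array(
            [(obs_p[idx] <= t * _REL_EPS).sum() for t in thresholds], float
        )
        fdr_t = e_null / np.maximum(n_disc, 1.0)
        # q_i = min FDR over thresholds >= p_i  (suffix minimum)
        suffix_min = np.minimum.accumulate(fdr_t[::-1])[::-1]
        for j in idx:
            k = np.searchsorted(thresholds, obs_p[j] / _REL_EPS, side="left")
            q[j] = min(suffix_min[k], 1.0)
    return pd.DataFrame(
        {"p": obs_p, "q": q, "filtered": ~keep, "min_attainable_p": min_att}
    )


# ---------------------------------------------------------------------------
# analysis-plan driver


def _with_histology2(units_df: pd.DataFrame) -> pd.DataFrame:
    df = units_df.copy()
    df["histology2"] = np.where(
        df["histology"] == "ND-OPMD", "ND-OPMD", "D-OPMD/OSCC"
    )
    return df


def default_plan() -> list[dict]:
    """The published analysis layout: CNA x ploidy within each histology
    group, CNA x histology, CNA x subsite (TNG vs BM), and the four burden
    scores compared by Mann-Whitney within the same groupings (each figure
    panel a BH family of 4)."""
    score_cols = ["TFG", "TBG", "TFL", "TBL"]
    return [
        {"name": "cna_ploidy_ND-OPMD", "kind": "fisher",
         "subset": {"histology": ["ND-OPMD"]},
         "group_col": "ploidy", "levels": ["diploid", "aneuploid"],
         "display": {"diploid": "DI = 1", "aneuploid": "DI ≠ 1"},
         "qmethod": "carlson"},
        {"name": "cna_ploidy_D-OPMD/OSCC", "kind": "fisher",
         "subset": {"histology": ["D-OPMD", "OSCC"]},
         "group_col": "ploidy", "levels": ["diploid", "aneuploid"],
         "display": {"diploid": "DI = 1", "aneuploid": "DI ≠ 1"},
         "qmethod": "carlson"},
        {"name": "cna_histology", "kind": "fisher",
         "group_col": "histology2", "levels": ["ND-OPMD", "D-OPMD/OSCC"],
         "qmethod": "carlson"},
        {"name": "cna_subsite", "kind": "fisher",
         "subset": {"subsite": ["BM", "TNG"]},
         "group_col": "subsite", "levels": ["BM", "TNG"],
         "qmethod": "carlson"},
        {"name": "scores_histology", "kind": "mw",
         "group_col": "histology2", "levels": ["ND-OPMD", "D-OPMD/OSCC"],
         "outcomes": score_cols, "qmethod": "bh", "m": 4},
        {"name": "scores_ploidy", "kind": "mw",
         "group_col": "ploidy", "levels": ["diploid", "aneuploid"],
         "outcomes": score_cols, "qmethod": "bh", "m": 4},
        {"name": "scores_subsite", "kind": "mw",
         "subset": {"subsite": ["BM", "TNG"]},
         "group_col": "subsite", "levels": ["BM", "TNG"],
         "outcomes": score_cols, "qmethod": "bh", "m": 4},
    ]


def run_association_suite(
    units_df: pd.DataFrame,
    presence: pd.DataFrame,
    plan: list[dict] | None = None,
    q_threshold: float = 0.1,
    alpha_cap: float = 0.05,
) -> pd.DataFrame:
    """Run every family in ``plan`` over the units table and its 0/1 CNA
    presence matrix (rows aligned with ``units_df``).

    Returns one row per test with counts, statistic, OR/CI (2x2 only), p,
    family q-value and a significance flag at q < ``q_threshold``.
    """
    plan = plan if plan is not None else default_plan()
    df = _with_histology2(units_df.reset_index(drop=True))
    pres = presence.reset_index(drop=True)
    if len(pres) != len(df):
        raise PlanError("presence matrix and units table have different lengths")
    results: list[AssociationResult] = []
    for fam in plan:
        kind = fam.get("kind", "fisher")
        name = fam["name"]
        sel = pd.Series(True, index=df.index)
        for col, allowed in fam.get("subset", {}).items():
            if col not in df.columns:
                raise PlanError(f"{name}: unknown subset column {col!r}")
            sel &= df[col].isin(allowed)
        sub = df[sel]
        gcol = fam["group_col"]
        if gcol not in sub.columns:
            raise PlanError(f"{name}: unknown group column {gcol!r}")
        lv0, lv1 = fam["levels"]
        disp = fam.get("display", {})
        g0 = sub[gcol] == lv0
        g1 = sub[gcol] == lv1
        if kind == "fisher":
            outcomes = fam.get("outcomes") or list(pres.columns)
            fam_rows = []
            for lab in outcomes:
                if lab not in pres.columns:
                    raise PlanError(f"{name}: unknown outcome {lab!r}")
                y = pres.loc[sub.index, lab].astype(int)
                a = int(((~y.astype(bool)) & g0).sum())
                b = int((y.astype(bool) & g0).sum())
                c = int(((~y.astype(bool)) & g1).sum())
                d = int((y.astype(bool) & g1).sum())
                t = ContingencyTable2x2(a, b, c, d)
                if not t.margins_positive():
                    continue
                fam_rows.append((lab, t))
            if not fam_rows:
                continue
            tabs = [t for _, t in fam_rows]
            if fam.get("qmethod", "carlson") == "carlson":
                qtab = carlson_fdr(tabs, filter=True, alpha_cap=alpha_cap)
                ps, qs = qtab["p"].to_numpy(), qtab["q"].to_numpy()
            else:
                ps = np.array([fisher_2x2(t)[0] for t in tabs])
                qs = bh_qvalues(ps, m=fam.get("m"))
            for (lab, t), p, qv in zip(fam_rows, ps, qs):
                _, orr, (lo, hi) = fisher_2x2(t)
                rate0 = t.b / (t.a + t.b)
                rate1 = t.d / (t.c + t.d)
                prev = disp.get(lv1, lv1) if rate1 >= rate0 else disp.get(lv0, lv0)
                results.append(
                    AssociationResult(
                        name, "fisher", lab, (t.a, t.b, t.c, t.d), orr, orr,
                        lo, hi, float(p),
                        None if np.isnan(qv) else float(qv), prev,
                        bool(qv < q_threshold) if not np.isnan(qv) else False,
                    )
                )
        elif kind == "mw":
            tested, ps, stats_u, prevs = [], [], [], []
            for col in fam["outcomes"]:
                if col not in sub.columns:
                    raise PlanError(f"{name}: unknown outcome {col!r}")
                x = sub.loc[g0, col].to_numpy(float)
                y = sub.loc[g1, col].to_numpy(float)
                if x.size == 0 or y.size == 0:
                    warnings.warn(f"{name}/{col}: empty group, skipped")
                    continue
                u, p = mann_whitney(x, y)
                higher = lv1 if np.mean(y) >= np.mean(x) else lv0
                tested.append(col)
                stats_u.append(u)
                ps.append(p)
                prevs.append(disp.get(higher, higher))
            if not tested:
                continue
            m = fam.get("m")
            if m is not None and m < len(ps):
                m = len(ps)
            qs = bh_qvalues(np.array(ps), m=m)
            for col, u, p, qv, prev in zip(tested, stats_u, ps, qs, prevs):
                results.append(
                    AssociationResult(
                        name, "mann-whitney", col, None, u, None, None, None,
                        float(p), float(qv), prev, bool(qv < q_threshold),
                    )
                )
        elif kind == "breslow_day":
            scol = fam["strata_col"]
            if scol not in sub.columns:
                raise PlanError(f"{name}: unknown strata column {scol!r}")
            for lab in fam["outcomes"]:
                strata = []
                for _, s in sub.groupby(scol):
                    y = pres.loc[s.index, lab].astype(bool)
                    i0 = s[gcol] == lv0
                    i1 = s[gcol] == lv1
                    strata.append(
                        ContingencyTable2x2(
                            int((~y & i0).sum()), int((y & i0).sum()),
                            int((~y & i1).sum()), int((y & i1).sum()),
                        )
                    )
                chi2, dfree, p = breslow_day(strata, tarone=fam.get("tarone", False))
                results.append(
                    AssociationResult(
                        name, "breslow-day", lab, None, chi2, None, None,
                        None, float(p), None, None, None,
                    )
                )
        else:
            raise PlanError(f"{name}: unknown kind {kind!r}")
    rows = []
    for r in results:
        counts = r.counts or (None, None, None, None)
        rows.append(
            (
                r.family, r.test, r.outcome, *counts, r.statistic,
                r.odds_ratio, r.ci_low, r.ci_high, r.p, r.q, r.prevalence,
                r.significant,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "test", "outcome", "a", "b", "c", "d", "statistic",
            "odds_ratio", "ci_low", "ci_high", "p", "q", "prevalence",
            "significant",
        ],
    )
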