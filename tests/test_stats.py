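import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from helpers import oracle_carlson, random_table
from oralcna.stats import (
    ContingencyTable2x2,
    PlanError,
    UndefinedTestError,
    bh_qvalues,
    breslow_day,
    carlson_fdr,
    cohens_kappa,
    default_plan,
    fisher_2x2,
    mann_whitney,
    run_association_suite,
)


class TestFisher:
    # published contingency rows with their printed two-sided p-values
    @pytest.mark.parametrize(
        "counts, printed",
        [
            ((35, 0, 7, 4), 0.0020),
            ((10, 25, 9, 2), 0.0036),
            ((26, 0, 13, 9), 0.0003),
            ((46, 0, 40, 8), 0.0057),
            ((20, 7, 15, 28), 0.0029),
            ((19, 8, 14, 29), 0.0030),
            ((26, 1, 30, 13), 0.0064),
            ((35, 0, 8, 3), 0.0109),
        ],
    )
    def test_published_rows_to_printed_precision(self, counts, printed):
        p, _, _ = fisher_2x2(ContingencyTable2x2(*counts))
        assert round(p, 4) == printed

    def test_symmetric_table(self):
        p, orr, _ = fisher_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert p == 1.0 and orr == 1.0

    def test_invariant_under_row_and_column_swap(self, rng):
        for _ in range(30):
            a, b, c, d = random_table(rng, max_n=40)
            p1, _, _ = fisher_2x2(ContingencyTable2x2(a, b, c, d))
            p2, _, _ = fisher_2x2(ContingencyTable2x2(d, c, b, a))
            assert p1 == pytest.approx(p2, rel=1e-10)

    def test_haldane_correction_on_zero_cell(self):
        _, orr, (lo, hi) = fisher_2x2(ContingencyTable2x2(35, 0, 7, 4))
        expect = (35.5 * 4.5) / (0.5 * 7.5)
        assert orr == pytest.approx(expect)
        assert lo < orr < hi

    def test_ci_contains_point_or(self, rng):
        for _ in range(20):
            t = ContingencyTable2x2(*random_table(rng, max_n=30))
            _, orr, (lo, hi) = fisher_2x2(t)
            assert lo <= orr <= hi

    def test_cmle_option(self):
        p, orr, (lo, hi) = fisher_2x2(ContingencyTable2x2(10, 5, 4, 12), "cmle")
        assert lo <= orr <= hi and 0 < p <= 1

    def test_empty_margin_rejected(self):
        with pytest.raises(UndefinedTestError):
            fisher_2x2(ContingencyTable2x2(3, 0, 5, 0))


class TestBreslowDay:
    def test_identical_balanced_strata_homogeneous(self):
        t = ContingencyTable2x2(10, 10, 10, 10)
        stat, df, p = breslow_day([t, t])
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert df == 1 and p == pytest.approx(1.0, abs=1e-6)

    def test_opposite_association_detected(self):
        strata = [ContingencyTable2x2(20, 5, 5, 20), ContingencyTable2x2(4, 16, 16, 4)]
        stat, df, p = breslow_day(strata)
        assert stat > 3.84 and p < 0.05

    def test_single_stratum_rejected(self):
        with pytest.raises(UndefinedTestError):
            breslow_day([ContingencyTable2x2(5, 5, 5, 5)])

    def test_matches_statsmodels_on_nondegenerate_strata(self):
        import statsmodels.api as sm

        strata = [ContingencyTable2x2(12, 5, 7, 16), ContingencyTable2x2(9, 8, 6, 13)]
        stat, df, p = breslow_day(strata)
        tables = np.stack([t.array for t in strata], axis=-1).astype(float)
        res = sm.stats.StratifiedTable(tables).test_equal_odds()
        assert stat == pytest.approx(float(res.statistic), rel=1e-6)
        assert p == pytest.approx(float(res.pvalue), rel=1e-6)

    def test_tarone_correction_reduces_statistic(self):
        strata = [ContingencyTable2x2(12, 5, 7, 16), ContingencyTable2x2(9, 8, 6, 13)]
        plain, _, _ = breslow_day(strata)
        adj, _, _ = breslow_day(strata, tarone=True)
        assert adj <= plain + 1e-12

    def test_empty_margin_stratum_dropped(self):
        strata = [
            ContingencyTable2x2(10, 10, 10, 10),
            ContingencyTable2x2(10, 10, 10, 10),
            ContingencyTable2x2(5, 0, 7, 0),
        ]
        with pytest.warns(UserWarning, match="dropped"):
            stat, df, p = breslow_day(strata)
        assert df == 1


class TestMannWhitney:
    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_tiny_exact_enumeration(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0 and p == pytest.approx(1 / 3, abs=1e-9)

    def test_complete_separation(self):
        u, p = mann_whitney(range(1, 11), range(11, 21))
        assert u == 0.0 and p < 0.01

    def test_exact_close_to_asymptotic_n8(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        _, p_exact = mann_whitney(x, y)  # exact path (no ties)
        p_asym = sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(UndefinedTestError):
            mann_whitney([], [1, 2])


class TestKappa:
    def test_perfect_agreement(self):
        v = [0, 1, 0, 1, 1]
        assert cohens_kappa(v, v) == pytest.approx(1.0)

    def test_independent_marginals_zero(self):
        # agreement table [[9,21],[21,49]]: p_o = p_e exactly
        u = [0] * 30 + [1] * 70
        v = [0] * 9 + [1] * 21 + [0] * 21 + [1] * 49
        assert cohens_kappa(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_strong_agreement_case(self):
        u = [0] * 33 + [1] * 37
        v = [0] * 30 + [1] * 3 + [0] * 2 + [1] * 35
        assert round(cohens_kappa(u, v), 4) == 0.8564

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(UndefinedTestError):
            cohens_kappa([1, 1, 1], [1, 1, 1])


class TestBH:
    def test_published_family_of_three(self):
        p = [1.3e-15, 1.9e-3, 2.8e-3]
        q = bh_qvalues(p, m=3)
        assert q[0] == pytest.approx(3.9e-15, rel=0.01)
        assert q[1] == pytest.approx(2.8e-3, rel=0.02)
        assert q[2] == pytest.approx(2.8e-3, rel=0.01)

    def test_single_p(self):
        assert bh_qvalues([0.04], m=1)[0] == pytest.approx(0.04)

    def test_all_equal_fixed_point(self):
        q = bh_qvalues([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_q_geq_p_and_monotone(self, rng):
        p = rng.uniform(1e-6, 1, 40)
        q = bh_qvalues(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels_when_m_equals_n(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1, 25)
        q = bh_qvalues(p)
        q_sm = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, q_sm)

    def test_external_family_size(self):
        # one observed p from a family of 10 planned tests
        assert bh_qvalues([0.01], m=10)[0] == pytest.approx(0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.0, 0.5])


class TestCarlsonFdr:
    def test_single_sparse_table_enumeration(self):
        out = carlson_fdr([ContingencyTable2x2(2, 0, 0, 2)], filter=False)
        assert out["p"][0] == pytest.approx(1 / 3)
        assert out["q"][0] == pytest.approx(1 / 3)

    def test_filtering_removes_hopeless_tables(self):
        # min attainable p = 1/3 > 0.05 -> filtered
        out = carlson_fdr([ContingencyTable2x2(2, 0, 0, 2)], filter=True)
        assert out["filtered"].all() and out["q"].isna().all()

    def test_q_nondecreasing_in_p(self, rng):
        tables = [ContingencyTable2x2(*random_table(rng, max_n=20)) for _ in range(12)]
        out = carlson_fdr(tables, filter=False)
        kept = out.sort_values("p")
        assert (kept["q"].diff().dropna() >= -1e-12).all()

    def test_matches_enumeration_oracle_small_families(self, rng):
        for _ in range(25):
            fam = [random_table(rng, max_n=12) for _ in range(int(rng.integers(1, 5)))]
            out = carlson_fdr([ContingencyTable2x2(*t) for t in fam], filter=False)
            p_o, q_o = oracle_carlson(fam)
            assert np.allclose(out["p"], p_o, atol=1e-10)
            assert np.allclose(out["q"], q_o, atol=1e-10)

    def test_approaches_bh_from_below_as_tables_densify(self, rng):
        # discreteness makes P_j(P <= t) <= t, so the discrete q never
        # exceeds BH and converges to it as attainable p-values densify
        def family(lo, hi):
            return [
                ContingencyTable2x2(*(int(rng.integers(lo, hi)) for _ in range(4)))
                for _ in range(8)
            ]

        for lo, hi, tol in [(5, 15, None), (40, 90, 0.05)]:
            tables = family(lo, hi)
            out = carlson_fdr(tables, filter=False)
            q_bh = np.minimum(bh_qvalues(out["p"].to_numpy()), 1.0)
            assert (out["q"] <= q_bh + 1e-9).all()
            if tol is not None:
                assert np.allclose(out["q"], q_bh, atol=tol)


class TestAssociationSuite:
    def _cohort(self, rng, n=60, or_target=5.0, base=0.25):
        aneu = rng.random(n) < 0.4
        odds = base / (1 - base)
        p1 = odds * or_target / (1 + odds * or_target)
        carrier = np.where(aneu, rng.random(n) < p1, rng.random(n) < base)
        units = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "subsite": rng.choice(["TNG", "BM"], n),
                "histology": rng.choice(["ND-OPMD", "D-OPMD", "OSCC"], n),
                "ploidy": np.where(aneu, "aneuploid", "diploid"),
                "exclusive": True,
                "TFG": rng.poisson(1, n),
                "TBG": rng.poisson(1, n),
                "TFL": rng.poisson(1, n),
                "TBL": rng.poisson(1, n),
            }
        )
        presence = pd.DataFrame({"8q24.3 gain": carrier.astype(int)})
        return units, presence

    def test_planted_ploidy_association_flagged(self):
        rng = np.random.default_rng(42)
        plan = [
            {"name": "cna_ploidy", "kind": "fisher", "group_col": "ploidy",
             "levels": ["diploid", "aneuploid"],
             "display": {"aneuploid": "DI ≠ 1", "diploid": "DI = 1"},
             "qmethod": "carlson"}
        ]
        hits = 0
        for _ in range(50):
            units, presence = self._cohort(rng)
            res = run_association_suite(units, presence, plan=plan)
            row = res[res["outcome"] == "8q24.3 gain"]
            if len(row) and bool(row["significant"].iloc[0]):
                hits += 1
                assert row["prevalence"].iloc[0] == "DI ≠ 1"
        assert hits >= 40  # >= 80% of seeds

    def test_null_cohort_flagged_fraction_controlled(self):
        rng = np.random.default_rng(7)
        flagged = tested = 0
        for _ in range(20):
            units, presence = self._cohort(rng, or_target=1.0)
            res = run_association_suite(units, presence)
            fisher = res[res["test"] == "fisher"]
            tested += len(fisher)
            flagged += int(fisher["significant"].sum())
        assert tested > 0
        assert flagged / tested <= 0.1

    def test_default_plan_layout_runs(self):
        rng = np.random.default_rng(1)
        units, presence = self._cohort(rng)
        res = run_association_suite(units, presence)
        fams = set(res["family"])
        assert {"cna_ploidy_ND-OPMD", "cna_histology", "scores_histology"} <= fams
        mw = res[res["test"] == "mann-whitney"]
        assert set(mw["outcome"]) == {"TFG", "TBG", "TFL", "TBL"}
        assert ((mw["q"] >= mw["p"] - 1e-12)).all()

    def test_unknown_column_is_plan_error(self):
        rng = np.random.default_rng(2)
        units, presence = self._cohort(rng)
        plan = [{"name": "x", "kind": "fisher", "group_col": "nope",
                 "levels": ["a", "b"]}]
        with pytest.raises(PlanError):
            run_association_suite(units, presence, plan=plan)

    def test_breslow_day_family(self):
        rng = np.random.default_rng(3)
        units, presence = self._cohort(rng, n=120)
        plan = [{"name": "bd", "kind": "breslow_day", "group_col": "ploidy",
                 "levels": ["diploid", "aneuploid"], "strata_col": "subsite",
                 "outcomes": ["8q24.3 gain"]}]
        res = run_association_suite(units, presence, plan=plan)
        assert res["test"].tolist() == ["breslow-day"]
        assert 0 < res["p"].iloc[0] <= 1
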