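import numpy as np
import pandas as pd
import pytest

from histpheno.curation import (
    CurationConfig,
    cv_outlier_years,
    phenology_consistency_filter,
    plausibility_filter,
    record_residual_outliers,
    run_curation,
    tukey_outlier_mask,
    year_cv_outliers,
)
from histpheno.simulate import SimulationParams, simulate_trial


def _records(values, trait="FTS", year=2000, acc_prefix="A"):
    return pd.DataFrame(
        {
            "accession_id": [f"{acc_prefix}{i}" for i in range(len(values))],
            "trait": trait,
            "year": year,
            "experiment": "field",
            "convariety": "sativum",
            "value": list(map(float, values)),
            "status": "kept",
            "removal_stage": "none",
            "removal_reason": "",
        }
    )


class TestPlausibility:
    def test_gross_value_removed(self):
        """20 records at 10 and one at 1000: bounds ~[-591, 706]."""
        df = _records([10.0] * 20 + [1000.0])
        kept, removed = plausibility_filter(df)
        assert len(removed) == 1
        assert removed["value"].iloc[0] == 1000.0
        assert (removed["removal_stage"] == "plausibility").all()

    def test_constant_trait_untouched(self):
        df = _records([5.0] * 10)
        kept, removed = plausibility_filter(df)
        assert len(removed) == 0

    def test_tight_spread_untouched(self):
        kept, removed = plausibility_filter(_records([10, 11, 12]))
        assert len(removed) == 0

    def test_too_few_records_noop_with_warning(self):
        df = _records([1.0, 2.0])
        with pytest.warns(UserWarning, match="fewer than 3"):
            kept, removed = plausibility_filter(df)
        assert len(kept) == 2 and len(removed) == 0


class TestPhenologyConsistency:
    def _phenology(self, shift_traits, shift_acc="A0", shift=30.0, n_acc=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        base = {"EmDays": 20.0, "FTS": 60.0, "FTE": 80.0, "Ripe": 110.0}
        for trait, mu in base.items():
            for i in range(n_acc):
                v = mu + rng.normal(0, 1)
                if f"A{i}" == shift_acc and trait in shift_traits:
                    v += shift
                rows.append(
                    {
                        "accession_id": f"A{i}",
                        "trait": trait,
                        "year": 2000,
                        "experiment": "field",
                        "convariety": "sativum",
                        "value": v,
                        "status": "kept",
                        "removal_stage": "none",
                        "removal_reason": "",
                    }
                )
        return pd.DataFrame(rows)

    def test_coherent_shift_retained(self):
        """A whole accession-year shifted late is biology, not error."""
        df = self._phenology({"EmDays", "FTS", "FTE", "Ripe"})
        kept, removed = phenology_consistency_filter(df)
        assert len(removed) == 0

    def test_lone_shift_removed(self):
        df = self._phenology({"FTS"})
        kept, removed = phenology_consistency_filter(df)
        assert len(removed) == 1
        assert removed["trait"].iloc[0] == "FTS"
        assert "criterion ii" in removed["removal_reason"].iloc[0]

    def test_no_flags_is_identity(self):
        df = self._phenology(set())
        kept, removed = phenology_consistency_filter(df)
        assert len(removed) == 0
        assert len(kept) == len(df)

    def test_rejects_non_phenology_traits(self):
        df = self._phenology(set())
        df.loc[0, "trait"] = "HGW"
        with pytest.raises(ValueError, match="HGW"):
            phenology_consistency_filter(df)


def _multi_year(yr_sd, n_acc=40, mu=50.0, seed=0):
    """Complete design with per-year residual SDs yr_sd (dict year->sd)."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, 1, n_acc)
    rows = []
    for yi, (yr, sd) in enumerate(sorted(yr_sd.items())):
        for i in range(n_acc):
            rows.append(
                {
                    "accession_id": f"A{i:02d}",
                    "trait": "FTS",
                    "year": yr,
                    "experiment": "field",
                    "convariety": "sativum",
                    "value": mu + g[i] + rng.normal(0, sd),
                    "status": "kept",
                    "removal_stage": "none",
                    "removal_reason": "",
                }
            )
    return pd.DataFrame(rows)


class TestYearCV:
    def test_inflated_year_removed_at_12_years(self):
        sds = {2000 + i: 1.0 for i in range(11)}
        sds[2011] = 12.0
        df = _multi_year(sds)
        kept, removed, cv = year_cv_outliers(df)
        assert set(removed["year"]) == {2011}
        assert 2011 not in set(kept["year"])
        assert cv.loc["2011", "removed"]

    def test_homogeneous_years_untouched(self):
        df = _multi_year({2000 + i: 1.0 for i in range(12)})
        kept, removed, cv = year_cv_outliers(df)
        assert len(removed) == 0

    def test_single_deviant_masked_below_eleven_years(self):
        """With n <= 10 CVs the max deviation is (n-1)/sqrt(n) < 3 sample SDs."""
        sds = {2000 + i: 1.0 for i in range(9)}
        sds[2009] = 50.0
        df = _multi_year(sds)
        kept, removed, cv = year_cv_outliers(df)
        assert len(removed) == 0

    def test_cv_rule_arithmetic(self):
        """CVs 5 x 11 and 60: threshold mean + 3 SD ~ 57.2 -> 60 removed."""
        cv = pd.Series([5.0] * 11 + [60.0], index=[str(2000 + i) for i in range(12)])
        out = cv_outlier_years(cv, 3.0)
        assert out.sum() == 1 and bool(out.iloc[-1])
        cv10 = pd.Series([5.0] * 9 + [60.0])
        assert cv_outlier_years(cv10, 3.0).sum() == 0


class TestResidualOutliers:
    def test_tukey_fence_arithmetic(self):
        """{1,2,3,4,5,100}: Q1=2.25 Q3=4.75 IQR=2.5 fences [-1.5, 8.5]."""
        z = np.array([1, 2, 3, 4, 5, 100.0])
        mask, (lo, hi) = tukey_outlier_mask(z, 1.5, "linear")
        assert lo == pytest.approx(-1.5) and hi == pytest.approx(8.5)
        assert mask.tolist() == [False] * 5 + [True]

    def test_degenerate_iqr_fallback(self):
        z = np.zeros(20)
        z[0] = 2.0  # |z| < 3 under the fallback rule
        mask, fences = tukey_outlier_mask(z, 1.5)
        assert fences == (-3.0, 3.0)
        assert not mask.any()

    def test_gross_record_removed_two_sided(self):
        df = _multi_year({2000 + i: 1.0 for i in range(6)}, seed=4)
        hi = df.copy()
        hi.loc[hi.index[0], "value"] += 30
        kept, removed = record_residual_outliers(hi)
        assert hi.index[0] in removed.index
        lo = df.copy()
        lo.loc[lo.index[0], "value"] -= 30
        kept, removed = record_residual_outliers(lo)
        assert lo.index[0] in removed.index

    def test_perfect_fit_removes_nothing(self):
        # additive data, zero residual variance
        rows = []
        for i in range(6):
            for yr in (2000, 2001, 2002):
                rows.append(
                    {
                        "accession_id": f"A{i}",
                        "trait": "FTS",
                        "year": yr,
                        "experiment": "field",
                        "convariety": "sativum",
                        "value": 10.0 + i + (yr - 2000) * 2.0,
                        "status": "kept",
                        "removal_stage": "none",
                        "removal_reason": "",
                    }
                )
        df = pd.DataFrame(rows)
        kept, removed = record_residual_outliers(df)
        assert len(removed) == 0


class TestRunCuration:
    def test_audit_trail_consistency(self, small_trial):
        records, truth = small_trial
        curated, report = run_curation(records)
        removed = curated[curated["status"] == "removed"]
        assert len(removed) == len(report.log)
        # no double counting: each record appears at most once in the log
        key = report.log[["accession_id", "trait", "year", "experiment", "value"]]
        assert not key.duplicated().any()
        # kept records carry no removal stage
        keptrows = curated[curated["status"] == "kept"]
        assert (keptrows["removal_stage"] == "none").all()

    def test_deviant_year_removed_and_h2_improves(self, small_trial):
        records, truth = small_trial
        curated, report = run_curation(records)
        removed_years = set(
            curated.loc[curated["removal_stage"] == "year_cv", "year"]
        )
        assert removed_years == {2005}
        row = report.summary.loc["FTS"]
        assert row["h2_final"] >= row["h2_initial"]

    def test_injected_outliers_recalled(self, small_trial):
        records, truth = small_trial
        curated, _ = run_curation(records)
        removed = curated[curated["status"] == "removed"]
        rem = set(zip(removed["accession_id"], removed["year"]))
        inj = truth.records[truth.records["outlier"]]
        recall = np.mean(
            [(a, y) in rem for a, y in zip(inj["accession_id"], inj["year"])]
        )
        assert recall >= 0.9

    def test_clean_data_essentially_untouched(self, clean_trial):
        records, _ = clean_trial
        curated, report = run_curation(records)
        frac = (curated["status"] == "removed").mean()
        assert frac <= 0.05
        row = report.summary.loc["FTS"]
        assert abs(row["h2_final"] - row["h2_initial"]) < 0.1
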