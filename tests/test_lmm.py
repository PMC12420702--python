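import warnings

import numpy as np
import pandas as pd
import pytest

from histpheno.lmm import (
    MixedModelREML,
    ModelSpec,
    SpecificationError,
    fit_blues,
    reduce_model,
    reml_fit,
)
from histpheno.simulate import SimulationParams, simulate_trial

from conftest import anova_oneway_components, balanced_oneway


class TestBalancedOneWayOracle:
    def test_textbook_design(self):
        """3 genotypes x 2 reps with values (0,2),(3,5),(6,8)."""
        df = pd.DataFrame(
            {"accession_id": list("AABBCC"), "value": [0, 2, 3, 5, 6, 8]}
        )
        m = MixedModelREML(random=["accession_id"]).fit(df)
        assert m.variance_components_["residual"] == pytest.approx(2.0, rel=1e-6)
        assert m.variance_components_["accession_id"] == pytest.approx(8.0, rel=1e-6)
        assert m.converged_

    @pytest.mark.parametrize("seed", range(5))
    def test_random_designs_match_anova(self, seed):
        rng = np.random.default_rng(seed)
        df = balanced_oneway(
            rng, n_groups=int(rng.integers(3, 11)), n_reps=int(rng.integers(2, 7))
        )
        s2g, s2e = anova_oneway_components(df)
        m = MixedModelREML(random=["accession_id"]).fit(df)
        assert m.variance_components_["accession_id"] == pytest.approx(
            s2g, rel=1e-6, abs=1e-10
        )
        assert m.variance_components_["residual"] == pytest.approx(s2e, rel=1e-6)

    def test_boundary_never_negative(self):
        """Between-group mean square below within: component pinned at 0."""
        rng = np.random.default_rng(42)
        # groups drawn from one population -> MSB < MSE happens readily
        for seed in range(30):
            df = balanced_oneway(np.random.default_rng(seed), 4, 3, sd_g=0.0)
            s2g, s2e = anova_oneway_components(df)
            if s2g == 0.0:
                m = MixedModelREML(random=["accession_id"]).fit(df)
                assert m.variance_components_["accession_id"] == 0.0
                assert m.variance_components_["residual"] == pytest.approx(
                    s2e, rel=1e-6
                )
                return
        pytest.fail("no truncated design found")


def test_identical_observations_all_zero_components():
    df = pd.DataFrame({"accession_id": list("AABBCC"), "value": [7.0] * 6})
    m = MixedModelREML(random=["accession_id"]).fit(df)
    assert m.variance_components_["accession_id"] == 0.0
    assert m.variance_components_["residual"] == 0.0
    assert m.fixed_effects_["intercept"] == pytest.approx(7.0)


def test_single_level_factor_raises_named_error():
    df = pd.DataFrame({"accession_id": ["A"] * 5, "value": range(5)})
    with pytest.raises(SpecificationError, match="accession_id"):
        MixedModelREML(random=["accession_id"]).fit(df)


def test_residuals_sum_to_zero_with_intercept(small_trial):
    records, _ = small_trial
    df = records[records["trait"] == "FTS"]
    m = MixedModelREML(fixed=["year"], random=["accession_id"]).fit(df)
    assert abs(m.residuals_.sum()) < 1e-6 * len(df)


def test_crossed_components_match_statsmodels():
    """Independent oracle: MixedLM with variance components on a dummy group."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(3)
    n = 150
    g = rng.integers(0, 30, n)
    yr = rng.integers(0, 8, n)
    val = (
        5
        + rng.normal(0, 1.3, 30)[g]
        + rng.normal(0, 0.8, 8)[yr]
        + rng.normal(0, 1, n)
    )
    d = pd.DataFrame(
        {
            "accession_id": [f"g{i:02d}" for i in g],
            "year": [f"y{j}" for j in yr],
            "value": val,
        }
    )
    mine = MixedModelREML(random=["accession_id", "year"]).fit(d)
    d["grp"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = smf.mixedlm(
            "value ~ 1",
            d,
            groups="grp",
            vc_formula={"acc": "0 + C(accession_id)", "yr": "0 + C(year)"},
            re_formula="0",
        ).fit(reml=True, method="lbfgs")
    assert mine.variance_components_["accession_id"] == pytest.approx(
        float(ref.vcomp[0]), rel=1e-4
    )
    assert mine.variance_components_["year"] == pytest.approx(
        float(ref.vcomp[1]), rel=1e-4
    )
    assert mine.variance_components_["residual"] == pytest.approx(
        float(ref.scale), rel=1e-4
    )
    assert mine.loglik_ == pytest.approx(float(ref.llf), abs=1e-6)


def test_constant_shift_changes_only_intercept(small_trial):
    records, _ = small_trial
    df = records[records["trait"] == "FTS"].copy()
    m1 = MixedModelREML(fixed=["accession_id"], random=["year"]).fit(df)
    df2 = df.copy()
    df2["value"] = df2["value"] + 100.0
    m2 = MixedModelREML(fixed=["accession_id"], random=["year"]).fit(df2)
    for k in m1.variance_components_:
        assert m1.variance_components_[k] == pytest.approx(
            m2.variance_components_[k], rel=1e-4, abs=1e-8
        )
    assert m2.fixed_effects_["intercept"] - m1.fixed_effects_["intercept"] == pytest.approx(
        100.0, abs=1e-4
    )
    d1 = m1.fixed_effects_.drop("intercept")
    d2 = m2.fixed_effects_.drop("intercept")
    assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-4)


def test_loglik_invariant_to_row_permutation(small_trial):
    records, _ = small_trial
    df = records[records["trait"] == "FTS"]
    m1 = MixedModelREML(fixed=["year"], random=["accession_id"]).fit(df)
    shuffled = df.sample(frac=1.0, random_state=0)
    m2 = MixedModelREML(fixed=["year"], random=["accession_id"]).fit(shuffled)
    assert m1.loglik_ == pytest.approx(m2.loglik_, abs=1e-8)
    for k in m1.variance_components_:
        assert m1.variance_components_[k] == pytest.approx(
            m2.variance_components_[k], rel=1e-6, abs=1e-10
        )


class TestModelSpec:
    def test_interaction_requires_parents(self):
        with pytest.raises(ValueError, match="accession:experiment"):
            ModelSpec(roles={"accession:experiment": "random"})

    def test_roles_validated(self):
        with pytest.raises(ValueError, match="bad role"):
            ModelSpec(roles={"accession": "sometimes"})

    def test_without_drops_interaction_with_parent(self):
        spec = ModelSpec(
            roles={
                "accession": "random",
                "experiment": "fixed",
                "accession:experiment": "random",
            }
        )
        red = spec.without("experiment")
        assert "accession:experiment" not in red.roles


class TestReduceModel:
    def _data(self, offsets, seed, n=240):
        rng = np.random.default_rng(seed)
        convs = list(offsets)
        rows = []
        for i in range(n):
            c = convs[i % len(convs)]
            rows.append(
                {
                    "accession_id": f"A{i % 60:02d}",
                    "year": 2000 + (i % 6),
                    "convariety": c,
                    "value": 50 + offsets[c] + rng.normal(0, 1),
                }
            )
        return pd.DataFrame(rows)

    def test_candidate_not_in_spec_is_noop(self, small_trial):
        records, _ = small_trial
        df = records[records["trait"] == "FTS"]
        spec = ModelSpec(roles={"accession_id": "random", "year": "random"})
        assert reduce_model(df, spec, "convariety") is spec

    def test_null_fixed_term_mostly_dropped(self):
        dropped = 0
        for seed in range(10):
            df = self._data({"a": 0.0, "b": 0.0, "c": 0.0}, seed)
            spec = ModelSpec(
                roles={"accession_id": "random", "year": "random", "convariety": "fixed"}
            )
            out = reduce_model(df, spec, "convariety", alpha=0.05)
            if "convariety" not in out.roles:
                dropped += 1
        assert dropped >= 8

    def test_strong_fixed_term_retained(self):
        df = self._data({"a": 0.0, "b": 3.0, "c": 6.0}, 1)
        spec = ModelSpec(
            roles={"accession_id": "random", "year": "random", "convariety": "fixed"}
        )
        out = reduce_model(df, spec, "convariety", alpha=0.05)
        assert out.roles.get("convariety") == "fixed"

    def test_null_random_term_dropped(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "accession_id": [f"A{i % 40}" for i in range(200)],
                "year": [2000 + i % 5 for i in range(200)],
                "value": 10
                + rng.normal(0, 1, 40)[[i % 40 for i in range(200)]]
                + rng.normal(0, 1, 200),
            }
        )
        spec = ModelSpec(roles={"accession_id": "random", "year": "random"})
        out = reduce_model(df, spec, "year", alpha=0.05)
        assert "year" not in out.roles


class TestBlues:
    def test_balanced_no_year_variance_equals_means(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(8):
            for yr in (2000, 2001, 2002):
                rows.append(
                    {
                        "accession_id": f"A{i}",
                        "year": yr,
                        "value": 10 + i + rng.normal(0, 0.5),
                    }
                )
        df = pd.DataFrame(rows)
        blues, missing = fit_blues(df)
        means = df.groupby("accession_id")["value"].mean()
        assert missing == []
        assert np.allclose(blues["estimate"], means[blues.index], atol=1e-6)

    def test_single_accession_blue_is_mean(self):
        df = pd.DataFrame(
            {"accession_id": ["A"] * 5, "year": range(2000, 2005), "value": [1, 2, 3, 4, 5.0]}
        )
        blues, _ = fit_blues(df)
        assert blues.loc["A", "estimate"] == pytest.approx(3.0)

    def test_missing_accessions_reported(self):
        df = pd.DataFrame(
            {
                "accession_id": ["A", "A", "B", "B"],
                "year": [2000, 2001, 2000, 2001],
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        _, missing = fit_blues(df, all_accessions=["A", "B", "C"])
        assert missing == ["C"]

    def test_blue_beats_raw_mean_under_year_effects(self):
        wins = 0
        for seed in range(5):
            params = SimulationParams(
                n_accessions=120,
                year_span=(2000, 2014),
                mean_years_per_accession=4.0,
                sigma2_g=1.0,
                sigma2_year=3.0,
                sigma2_e=1.0,
                seed=100 + seed,
            )
            records, truth = simulate_trial(params)
            df = records[records["trait"] == "FTS"]
            blues, _ = fit_blues(df)
            g = truth.accession_effects.set_index("accession_id")["g"]
            raw = df.groupby("accession_id")["value"].mean()
            idx = blues.index
            r_blue = np.corrcoef(blues["estimate"], g[idx])[0, 1]
            r_raw = np.corrcoef(raw[idx], g[idx])[0, 1]
            wins += r_blue >= r_raw
        assert wins >= 4
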