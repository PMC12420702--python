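"""Simulation-based validation harness for the whole pipeline.

Each check regenerates its inputs from a seed, runs the relevant package
machinery from scratch and returns summary metrics.  The checks mirror the
properties the pipeline is designed around: exactness of the REML engine on
balanced designs, unbiased heritability recovery, recall and safety of the
outlier control, correctness of the letter display, weather QC/imputation
quality, and the advantage of BLUEs over raw means under year effects.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .curation import CurationConfig, run_curation
from .heritability import heritability_recovery_check
from .lmm import MixedModelREML, fit_blues
from .post import compact_letter_display
from .simulate import SimulationParams, simulate_trial, simulate_weather
from .weather import impute_gaps, qc_min_temp

__all__ = [
    "reml_oracle_check",
    "h2_recovery_check",
    "curation_efficacy_check",
    "clean_data_safety_check",
    "cld_property_check",
    "weather_qc_imputation_check",
    "blue_superiority_check",
]


def _balanced_oneway(rng, n_groups: int, n_reps: int, sd_g: float) -> pd.DataFrame:
    g = rng.normal(0, sd_g, n_groups)
    rows = [
        {"accession_id": f"G{i:02d}", "value": 10 + g[i] + rng.normal(0, 1)}
        for i in range(n_groups)
        for _ in range(n_reps)
    ]
    return pd.DataFrame(rows)


def reml_oracle_check(n_designs: int = 20, seed: int = 0) -> Dict[str, float]:
    """REML vs closed-form ANOVA estimators on random balanced one-way designs.

    For each design sigma2_g is compared with max(0, (MSB - MSE) / r); at the
    boundary the residual oracle is SS_total / (n - 1), otherwise MSE.
    Returns the maximum relative discrepancy over all designs and components.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for d in range(n_designs):
        sd_g = 0.0 if d % 5 == 4 else float(rng.uniform(0.5, 3.0))
        df = _balanced_oneway(
            rng, int(rng.integers(3, 11)), int(rng.integers(2, 7)), sd_g
        )
        groups = df.groupby("accession_id")["value"]
        r = int(groups.size().iloc[0])
        msb = r * groups.mean().var(ddof=1)
        mse = groups.apply(lambda v: v.var(ddof=1)).mean()
        s2g = (msb - mse) / r
        if s2g > 0:
            exp_g, exp_e = float(s2g), float(mse)
        else:
            exp_g, exp_e = 0.0, float(df["value"].var(ddof=1))
        m = MixedModelREML(random=["accession_id"]).fit(df)
        got_g = m.variance_components_["accession_id"]
        got_e = m.variance_components_["residual"]
        err_g = abs(got_g - exp_g) / max(exp_g, 1e-12) if exp_g > 0 else abs(got_g)
        err_e = abs(got_e - exp_e) / exp_e
        max_err = max(max_err, err_g, err_e)
    return {"max_relative_error": float(max_err), "n_designs": n_designs}


def h2_recovery_check(
    targets: Sequence[float] = (0.1, 0.5, 0.9),
    n_accessions: int = 500,
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean heritability-estimation bias at low/medium/high true h2.

    sigma2_g is chosen so the nominal entry-mean heritability hits each
    target at the design's mean plot count; the per-replicate truth uses the
    realised effective counts.
    """
    rows = []
    p_nominal = 4.36
    for i, target in enumerate(targets):
        s2g = target / (1 - target) / p_nominal
        params = SimulationParams(
            n_accessions=n_accessions,
            year_span=(1990, 2019),
            mean_years_per_accession=4.36,
            sigma2_g=s2g,
            sigma2_year=1.0,
            sigma2_e=1.0,
            seed=seed,
        )
        out = heritability_recovery_check(params, n_reps=n_reps, seed=seed + 1000 * i)
        rows.append(
            {
                "target": target,
                "mean_h2_true": float(out["h2_true"].mean()),
                "mean_h2_hat": float(out["h2_hat"].mean()),
                "bias": out.attrs["bias"],
                "rmse": out.attrs["rmse"],
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def _efficacy_params(seed: int, n_accessions: int, outliers: bool) -> SimulationParams:
    return SimulationParams(
        n_accessions=n_accessions,
        year_span=(1990, 2019),
        mean_years_per_accession=4.36,
        mu=60.0,
        sigma2_g=1.0,
        sigma2_year=1.0,
        sigma2_e=1.0,
        record_outlier_rate=0.05 if outliers else 0.0,
        record_outlier_shift=8.0,
        year_cv_inflation={2005: 12.0} if outliers else {},
        seed=seed,
    )


def curation_efficacy_check(
    n_seeds: int = 10, n_accessions: int = 300, seed: int = 0
) -> Dict[str, float]:
    """Recall of injected gross errors and removal of the inflated year.

    Each replicate injects 5% record outliers (8 residual-SD shifts) and one
    12x variance-inflated year into a 30-year design, runs the full curation
    and measures: the fraction of injected outliers removed (any stage), the
    fraction of replicates in which the deviant year is removed by the CV
    rule, and in how many replicates heritability improves.
    """
    rng = np.random.default_rng(seed)
    n_inj = n_rec = 0
    year_hits = 0
    improved = 0
    for _ in range(n_seeds):
        params = _efficacy_params(int(rng.integers(0, 2**31 - 1)), n_accessions, True)
        records, truth = simulate_trial(params)
        curated, report = run_curation(records, CurationConfig())
        removed = curated[curated["status"] == "removed"]
        rem = set(zip(removed["accession_id"], removed["year"]))
        inj = truth.records[truth.records["outlier"]]
        n_inj += len(inj)
        n_rec += sum((a, y) in rem for a, y in zip(inj["accession_id"], inj["year"]))
        year_hits += set(
            curated.loc[curated["removal_stage"] == "year_cv", "year"]
        ) >= {2005}
        row = report.summary.iloc[0]
        improved += bool(row["h2_final"] >= row["h2_initial"])
    return {
        "outlier_recall": n_rec / n_inj,
        "inflated_year_removal_rate": year_hits / n_seeds,
        "h2_improved_seeds": improved,
        "n_seeds": n_seeds,
    }


def clean_data_safety_check(
    n_seeds: int = 10, n_accessions: int = 300, seed: int = 0
) -> Dict[str, float]:
    """Removal fraction and heritability drift on outlier-free data."""
    rng = np.random.default_rng(seed)
    fracs, deltas = [], []
    for _ in range(n_seeds):
        params = _efficacy_params(int(rng.integers(0, 2**31 - 1)), n_accessions, False)
        records, _ = simulate_trial(params)
        curated, report = run_curation(records, CurationConfig())
        fracs.append((curated["status"] == "removed").mean())
        row = report.summary.iloc[0]
        deltas.append(abs(row["h2_final"] - row["h2_initial"]))
    return {
        "mean_removal_fraction": float(np.mean(fracs)),
        "mean_abs_delta_h2": float(np.mean(deltas)),
        "n_seeds": n_seeds,
    }


def cld_property_check(n_draws: int = 200, max_groups: int = 6, seed: int = 0) -> Dict[str, float]:
    """Exhaustive verification of the letter-display property on random matrices."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_draws):
        k = int(rng.integers(2, max_groups + 1))
        sig = np.zeros((k, k), bool)
        iu = np.triu_indices(k, 1)
        draws = rng.random(len(iu[0])) < rng.uniform(0.2, 0.8)
        sig[iu] = draws
        sig |= sig.T
        groups = [f"g{i}" for i in range(k)]
        letters = compact_letter_display(sig, groups)
        for a in range(k):
            for b in range(a + 1, k):
                share = bool(set(letters[groups[a]]) & set(letters[groups[b]]))
                if share == bool(sig[a, b]):
                    violations += 1
    return {"violations": violations, "n_draws": n_draws}


def weather_qc_imputation_check(n_seeds: int = 10, seed: int = 0) -> Dict[str, float]:
    """Spike detection by the QC rules and imputation accuracy vs mean fill."""
    rng = np.random.default_rng(seed)
    n_spikes = n_caught = 0
    rmse_model, rmse_mean = [], []
    for _ in range(n_seeds):
        w = simulate_weather(
            (2000, 2000),
            seed=int(rng.integers(0, 2**31 - 1)),
            gap_rate=0.10,
            implausible_rate=0.03,
        )
        flagged = qc_min_temp(w)
        spikes = w["truth_spike"]
        n_spikes += int(spikes.sum())
        n_caught += int((flagged.loc[spikes, "qc_flag"] != "ok").sum())
        filled = impute_gaps(flagged)
        gaps = w["truth_gap_tmin5"]
        truth = w.loc[gaps, "truth_tmin5"]
        rmse_model.append(
            float(np.sqrt(np.mean((filled.loc[gaps, "tmin5"] - truth) ** 2)))
        )
        rmse_mean.append(float(np.sqrt(np.mean((w["tmin5"].mean() - truth) ** 2))))
    return {
        "spike_detection_rate": n_caught / n_spikes if n_spikes else 1.0,
        "rmse_state_space": float(np.mean(rmse_model)),
        "rmse_mean_fill": float(np.mean(rmse_mean)),
        "rmse_ratio": float(np.mean(rmse_model) / np.mean(rmse_mean)),
        "n_seeds": n_seeds,
    }


def blue_superiority_check(
    n_seeds: int = 20, n_accessions: int = 200, seed: int = 0
) -> Dict[str, float]:
    """How often BLUEs track true genotypic values better than raw means."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_seeds):
        params = SimulationParams(
            n_accessions=n_accessions,
            year_span=(2000, 2019),
            mean_years_per_accession=4.0,
            sigma2_g=1.0,
            sigma2_year=3.0,
            sigma2_e=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        records, truth = simulate_trial(params)
        df = records[records["trait"] == "FTS"]
        blues, _ = fit_blues(df)
        g = truth.accession_effects.set_index("accession_id")["g"]
        raw = df.groupby("accession_id")["value"].mean()
        idx = blues.index
        r_blue = np.corrcoef(blues["estimate"], g[idx])[0, 1]
        r_raw = np.corrcoef(raw[idx], g[idx])[0, 1]
        wins += int(r_blue >= r_raw)
    return {"wins": wins, "n_seeds": n_seeds}
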