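"""Synthetic regeneration-trial phenotypes and daily winter weather.

Historical genebank records are unreplicated and severely unbalanced: each
accession is grown in a handful of non-consecutive years out of a multi-decade
span, with one plot per accession-year.  The generator mirrors the additive
model fitted downstream,

    y = mu + g_i + a_j + t_k + v_l + (g:t)_ik + e_ijkl,

with independent normal effects for accession (g), year (a), experiment (t),
accession x experiment interaction (g:t), a fixed convariety offset (v) and a
residual whose standard deviation can be inflated in selected "deviant" years.
Gross record errors are injected as symmetric two-sided shifts of a configurable
multiple of the residual SD, and every injected artefact is truth-flagged so
that curation recall can be measured exactly.

The weather generator emulates a station series for the frost window
(Nov 1 - Apr 30): minimum temperature at 2 m from a seasonal sinusoid plus
AR(1) noise, ground minimum at 5 cm offset below it, occasional precipitation,
and snow depth from an accumulation-melt recursion.  Missing days and gross
temperature spikes are injected with truth flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .registry import CONVARIETIES, _ensure_status_columns

__all__ = [
    "SimulationParams",
    "TruthTable",
    "simulate_trial",
    "simulate_weather",
    "SPRING_CONVARIETY_COUNTS",
]

#: Convariety composition of the spring collection (accession counts).
SPRING_CONVARIETY_COUNTS: Dict[str, int] = {
    "sativum": 1043,
    "speciosum": 590,
    "axiphium": 163,
    "medullare": 900,
    "medullosaccharatum": 30,
    "unknown": 315,
}


@dataclass
class SimulationParams:
    """Generating conditions for one simulated trial series.

    Defaults follow the spring-collection design: a multi-decade span with a
    mean of 4.36 cultivation years per accession, one unreplicated plot per
    accession-year, and the observed convariety imbalance.
    """

    n_accessions: int = 500
    year_span: Tuple[int, int] = (1990, 2019)
    mean_years_per_accession: float = 4.36
    mu: float = 50.0
    sigma2_g: float = 1.0
    sigma2_year: float = 1.0
    sigma2_exp: float = 0.0
    sigma2_gt: float = 0.0
    sigma2_e: float = 1.0
    convariety_effects: Mapping[str, float] = field(default_factory=dict)
    convariety_probs: Optional[Mapping[str, float]] = None
    year_cv_inflation: Mapping[int, float] = field(default_factory=dict)
    record_outlier_rate: float = 0.0
    record_outlier_shift: float = 8.0
    experiments: Sequence[str] = ("field",)
    experiment_probs: Optional[Sequence[float]] = None
    traits: Sequence[str] = ("FTS",)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_year", "sigma2_exp", "sigma2_gt", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.record_outlier_rate <= 1:
            raise ValueError("record_outlier_rate must lie in [0, 1]")
        lo, hi = self.year_span
        span = hi - lo + 1
        if span < 1:
            raise ValueError("year_span is empty")
        if not 1 <= self.mean_years_per_accession <= span:
            raise ValueError(
                "mean_years_per_accession must lie between 1 and the span length"
            )
        if self.n_accessions < 1:
            raise ValueError("n_accessions must be positive")


@dataclass
class TruthTable:
    """Ground truth underlying one simulated trial.

    ``records`` is aligned row-by-row with the simulated phenotype table and
    carries the residual draw, the injected outlier shift and flag.  Effect
    tables are keyed by (trait, level).
    """

    records: pd.DataFrame
    accession_effects: pd.DataFrame  # columns: trait, accession_id, g
    year_effects: pd.DataFrame       # columns: trait, year, a
    experiment_effects: pd.DataFrame # columns: trait, experiment, t
    interaction_effects: pd.DataFrame  # columns: trait, accession_id, experiment, gt
    deviant_years: Tuple[int, ...]


def _sample_year_counts(rng, n: int, span: int, mean: float) -> np.ndarray:
    # 1 + Binomial(span-1, p): guarantees >=1 year; p calibrated to the mean.
    if span == 1:
        return np.ones(n, dtype=int)
    p = (mean - 1.0) / (span - 1.0)
    return 1 + rng.binomial(span - 1, p, size=n)


def simulate_trial(params: SimulationParams) -> Tuple[pd.DataFrame, TruthTable]:
    """Simulate an unbalanced multi-year trial with known ground truth.

    Returns
    -------
    records : pandas.DataFrame
        Long-format phenotype table (kept status throughout).
    truth : TruthTable
        Generating effects, per-record residuals and outlier flags.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.year_span
    years = np.arange(lo, hi + 1)
    span = len(years)
    n = params.n_accessions
    acc_ids = np.array([f"ACC{i:05d}" for i in range(n)])

    counts = _sample_year_counts(rng, n, span, params.mean_years_per_accession)

    probs = params.convariety_probs
    if probs is None:
        total = sum(SPRING_CONVARIETY_COUNTS.values())
        labels = list(SPRING_CONVARIETY_COUNTS)
        pvec = np.array([SPRING_CONVARIETY_COUNTS[k] / total for k in labels])
    else:
        labels = list(probs)
        pvec = np.asarray([probs[k] for k in labels], dtype=float)
        pvec = pvec / pvec.sum()
    convariety = rng.choice(labels, size=n, p=pvec)

    exp_labels = list(params.experiments)
    if params.experiment_probs is None:
        eprobs = np.full(len(exp_labels), 1.0 / len(exp_labels))
    else:
        eprobs = np.asarray(params.experiment_probs, dtype=float)
        eprobs = eprobs / eprobs.sum()

    # Design: accession x year assignment shared across traits (one plot).
    acc_idx, year_idx = [], []
    for i in range(n):
        chosen = rng.choice(span, size=counts[i], replace=False)
        acc_idx.extend([i] * counts[i])
        year_idx.extend(chosen.tolist())
    acc_idx = np.asarray(acc_idx)
    year_idx = np.asarray(year_idx)
    m = len(acc_idx)
    exp_idx = rng.choice(len(exp_labels), size=m, p=eprobs)

    sd_e = np.sqrt(params.sigma2_e)
    infl = np.ones(span)
    for yr, mult in params.year_cv_inflation.items():
        if lo <= yr <= hi:
            infl[yr - lo] = mult

    frames = []
    truth_frames = []
    eff_g, eff_a, eff_t, eff_gt = [], [], [], []
    for trait in params.traits:
        g = rng.normal(0.0, np.sqrt(params.sigma2_g), size=n)
        a = rng.normal(0.0, np.sqrt(params.sigma2_year), size=span)
        t = rng.normal(0.0, np.sqrt(params.sigma2_exp), size=len(exp_labels))
        gt = rng.normal(0.0, np.sqrt(params.sigma2_gt), size=(n, len(exp_labels)))
        v = np.array(
            [params.convariety_effects.get(c, 0.0) for c in convariety]
        )
        e = rng.normal(0.0, 1.0, size=m) * sd_e * infl[year_idx]
        out_flag = rng.random(m) < params.record_outlier_rate
        signs = rng.choice([-1.0, 1.0], size=m)
        shift = np.where(out_flag, signs * params.record_outlier_shift * sd_e, 0.0)
        y = (
            params.mu
            + g[acc_idx]
            + a[year_idx]
            + t[exp_idx]
            + v[acc_idx]
            + gt[acc_idx, exp_idx]
            + e
            + shift
        )
        frames.append(
            pd.DataFrame(
                {
                    "accession_id": acc_ids[acc_idx],
                    "trait": trait,
                    "year": years[year_idx],
                    "experiment": np.asarray(exp_labels)[exp_idx],
                    "convariety": convariety[acc_idx],
                    "value": y,
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "trait": trait,
                    "accession_id": acc_ids[acc_idx],
                    "year": years[year_idx],
                    "residual": e,
                    "outlier": out_flag,
                    "injected_shift": shift,
                }
            )
        )
        eff_g.append(pd.DataFrame({"trait": trait, "accession_id": acc_ids, "g": g}))
        eff_a.append(pd.DataFrame({"trait": trait, "year": years, "a": a}))
        eff_t.append(pd.DataFrame({"trait": trait, "experiment": exp_labels, "t": t}))
        eff_gt.append(
            pd.DataFrame(
                {
                    "trait": trait,
                    "accession_id": np.repeat(acc_ids, len(exp_labels)),
                    "experiment": np.tile(exp_labels, n),
                    "gt": gt.ravel(),
                }
            )
        )

    records = pd.concat(frames, ignore_index=True)
    records = _ensure_status_columns(records)
    truth = TruthTable(
        records=pd.concat(truth_frames, ignore_index=True),
        accession_effects=pd.concat(eff_g, ignore_index=True),
        year_effects=pd.concat(eff_a, ignore_index=True),
        experiment_effects=pd.concat(eff_t, ignore_index=True),
        interaction_effects=pd.concat(eff_gt, ignore_index=True),
        deviant_years=tuple(
            yr for yr, mult in params.year_cv_inflation.items() if mult != 1.0
        ),
    )
    return records, truth


def simulate_weather(
    year_span: Tuple[int, int],
    seed: int = 0,
    gap_rate: float = 0.0,
    implausible_rate: float = 0.0,
    ar1: float = 0.7,
    noise_sd: float = 3.5,
    spike_magnitude: float = 40.0,
    snow_ratio: float = 1.0,
    melt_rate: float = 0.5,
) -> pd.DataFrame:
    """Simulate daily winter weather (Nov 1 - Apr 30) for each sowing year.

    Returns a frame with one row per day and columns ``date, season_year,
    tmin5, tmin200, precip, snow`` plus truth columns ``truth_tmin5,
    truth_snow, truth_spike`` and per-field gap flags.  Spikes are isolated
    (never on adjacent days) additive excursions of ``spike_magnitude`` deg C
    on the 5 cm minimum.
    """
    if not 0 <= gap_rate <= 1 or not 0 <= implausible_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = year_span
    frames = []
    for sow_year in range(lo, hi + 1):
        dates = pd.date_range(f"{sow_year}-11-01", f"{sow_year + 1}-04-30", freq="D")
        T = len(dates)
        tt = np.arange(T)
        seasonal = 4.0 - 10.0 * np.sin(np.pi * tt / (T - 1))
        noise = np.empty(T)
        noise[0] = rng.normal(0, noise_sd)
        innov_sd = noise_sd * np.sqrt(1 - ar1**2)
        for i in range(1, T):
            noise[i] = ar1 * noise[i - 1] + rng.normal(0, innov_sd)
        tmin200 = seasonal + noise
        # Ground minimum sits below the 2 m value on calm clear nights.
        tmin5 = tmin200 - np.abs(rng.normal(2.0, 1.0, size=T))
        wet = rng.random(T) < 0.35
        precip = np.where(wet, rng.exponential(2.0, size=T), 0.0)
        snow = np.zeros(T)
        for i in range(T):
            prev = snow[i - 1] if i else 0.0
            acc = snow_ratio * precip[i] if tmin5[i] < 0 else 0.0
            melt = melt_rate * max(0.0, tmin5[i])
            snow[i] = max(0.0, prev + acc - melt)

        df = pd.DataFrame(
            {
                "date": dates,
                "season_year": sow_year,
                "truth_tmin5": tmin5,
                "tmin200": tmin200,
                "precip": precip,
                "truth_snow": snow,
            }
        )
        # Spikes: isolated interior days, gross warm excursion at 5 cm only.
        spike = np.zeros(T, dtype=bool)
        n_spikes = rng.binomial(T, implausible_rate)
        candidates = rng.permutation(np.arange(1, T - 1))
        for c in candidates:
            if n_spikes == 0:
                break
            if not spike[max(0, c - 2) : c + 3].any():
                spike[c] = True
                n_spikes -= 1
        obs5 = tmin5 + np.where(spike, spike_magnitude, 0.0)
        gap5 = (rng.random(T) < gap_rate) & ~spike
        gap_snow = rng.random(T) < gap_rate
        df["tmin5"] = np.where(gap5, np.nan, obs5)
        df["snow"] = np.where(gap_snow, np.nan, snow)
        df["truth_spike"] = spike
        df["truth_gap_tmin5"] = gap5
        df["truth_gap_snow"] = gap_snow
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    cols = [
        "date",
        "season_year",
        "tmin5",
        "tmin200",
        "precip",
        "snow",
        "truth_tmin5",
        "truth_snow",
        "truth_spike",
        "truth_gap_tmin5",
        "truth_gap_snow",
    ]
    return out[cols]
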