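"""Weather QC, gap imputation, snow reconstruction and frost exposure.

Winter survival in pea is driven by exposure of unhardened or thinly
insulated plants to radiative frost near the soil surface.  The relevant
series is the daily minimum temperature at 5 cm above ground over the frost
window (Nov 1 - Apr 30): a day counts as *mild* frost stress below -6 deg C
and *severe* below -14 deg C, in either case only when snow cover is thinner
than 5 cm (a closed snow blanket decouples the crop from air temperature).

Station series require cleaning first: gross sensor errors are removed when a
5 cm minimum deviates by more than 20 deg C from its adjacent days (both
neighbours by default: a genuine cold front deviates from one side only) or
by more than 15 deg C from the simultaneous 2 m minimum.  Gaps left by QC or
by missing records are filled with the smoothed state of a local-level
state-space model (two variances, estimated by maximum likelihood); snow
gaps are filled by a two-parameter accumulation-melt recursion driven by
precipitation and the 5 cm minimum.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "qc_min_temp",
    "impute_gaps",
    "impute_snow",
    "frost_days",
    "accession_exposure",
    "survival_to_percent",
    "percent_to_survival",
    "MinTempQC",
    "LocalLevelImputer",
    "SnowModel",
    "MILD_FROST_C",
    "SEVERE_FROST_C",
    "SNOW_COVER_CM",
]

#: Frost-stress thresholds on the 5 cm daily minimum (deg C) and the snow
#: depth (cm) below which the crop is considered unprotected.
MILD_FROST_C = -6.0
SEVERE_FROST_C = -14.0
SNOW_COVER_CM = 5.0


# ------------------------------------------------------------------------- QC
class MinTempQC(BaseEstimator):
    """Flag implausible 5 cm minima against neighbours and the 2 m series."""

    def __init__(
        self,
        adjacent_threshold: float = 20.0,
        vs_2m_threshold: float = 15.0,
        require_both_neighbours: bool = True,
    ):
        self.adjacent_threshold = adjacent_threshold
        self.vs_2m_threshold = vs_2m_threshold
        self.require_both_neighbours = require_both_neighbours

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        group = df["season_year"] if "season_year" in df.columns else pd.Series(0, index=df.index)
        flags = pd.Series("ok", index=df.index, dtype=object)
        raw = df["tmin5"].copy()
        for _, idx in df.groupby(group.values).groups.items():
            t = df.loc[idx, "tmin5"].to_numpy(float)
            prev = np.r_[np.nan, t[:-1]]
            nxt = np.r_[t[1:], np.nan]
            dprev = np.abs(t - prev)
            dnxt = np.abs(t - nxt)
            if self.require_both_neighbours:
                # a missing neighbour is treated as agreeing (fewest removals)
                adj = (
                    (np.nan_to_num(dprev, nan=0.0) > self.adjacent_threshold)
                    & (np.nan_to_num(dnxt, nan=0.0) > self.adjacent_threshold)
                )
            else:
                adj = (dprev > self.adjacent_threshold) | (dnxt > self.adjacent_threshold)
            t200 = df.loc[idx, "tmin200"].to_numpy(float)
            vs2m = np.abs(t - t200) > self.vs_2m_threshold
            adj &= ~np.isnan(t)
            vs2m &= ~np.isnan(t)
            loc = pd.Index(idx)
            flags.loc[loc[adj]] = "removed_adjacent"
            flags.loc[loc[vs2m & ~adj]] = "removed_vs_2m"
        removed = flags != "ok"
        df["qc_flag"] = flags
        df["tmin5_raw"] = raw
        df.loc[removed, "tmin5"] = np.nan
        return df

    def fit_transform(self, X: pd.DataFrame, y=None):
        return self.fit(X).transform(X)


def qc_min_temp(series: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`MinTempQC`."""
    return MinTempQC(**kwargs).fit_transform(series)


# -------------------------------------------------------------------- imputers
class LocalLevelImputer(BaseEstimator):
    """Fill gaps with the smoothed state of a local-level state-space model.

    Both the level-innovation and observation-noise variances are estimated
    from the observed values by maximum likelihood.  Series with fewer than
    ``min_observed`` observations fall back to linear interpolation.
    """

    def __init__(self, column: str = "tmin5", min_observed: int = 10):
        self.column = column
        self.min_observed = min_observed

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from statsmodels.tsa.statespace.structural import UnobservedComponents

        df = X.copy()
        col = self.column
        group = df["season_year"] if "season_year" in df.columns else pd.Series(0, index=df.index)
        imputed = pd.Series(False, index=df.index)
        for _, idx in df.groupby(group.values).groups.items():
            y = df.loc[idx, col].to_numpy(float)
            missing = np.isnan(y)
            if not missing.any():
                continue
            n_obs = int((~missing).sum())
            if n_obs < self.min_observed:
                warnings.warn(
                    f"{col}: only {n_obs} observed values; "
                    "falling back to linear interpolation"
                )
                filled = (
                    pd.Series(y).interpolate(limit_direction="both").to_numpy()
                )
            elif np.nanstd(y) == 0:
                filled = np.where(missing, np.nanmean(y), y)
            else:
                model = UnobservedComponents(y, level="local level")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(disp=0)
                filled = np.where(missing, res.smoothed_state[0], y)
            df.loc[idx, col] = filled
            imputed.loc[pd.Index(idx)[missing]] = True
        df[f"imputed_{col}"] = imputed
        return df

    def fit_transform(self, X: pd.DataFrame, y=None):
        return self.fit(X).transform(X)


def impute_gaps(series: pd.DataFrame, column: str = "tmin5", **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`LocalLevelImputer`."""
    return LocalLevelImputer(column=column, **kwargs).fit_transform(series)


class SnowModel(BaseEstimator):
    """Accumulation-melt recursion for missing snow-depth days.

    snow_t = max(0, snow_{t-1} + ratio * precip_t * [tmin5_t < 0]
                     - melt_rate * max(0, tmin5_t))

    ``ratio`` is cm of fresh snow per mm of sub-zero precipitation,
    ``melt_rate`` cm per positive deg C day.  Observed snow days are never
    altered; a leading gap with no anchor starts from 0 with a warning.
    """

    def __init__(self, ratio: float = 1.0, melt_rate: float = 0.5):
        self.ratio = ratio
        self.melt_rate = melt_rate

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        group = df["season_year"] if "season_year" in df.columns else pd.Series(0, index=df.index)
        imputed = pd.Series(False, index=df.index)
        for _, idx in df.groupby(group.values).groups.items():
            snow = df.loc[idx, "snow"].to_numpy(float)
            tmin5 = df.loc[idx, "tmin5"].to_numpy(float)
            precip = df.loc[idx, "precip"].to_numpy(float)
            miss = np.isnan(snow)
            if not miss.any():
                continue
            if miss[0]:
                warnings.warn("leading missing snow depth: initialised at 0 cm")
            prev = 0.0
            filled = snow.copy()
            for i in range(len(snow)):
                if miss[i]:
                    acc = (
                        self.ratio * precip[i]
                        if (not np.isnan(precip[i]) and not np.isnan(tmin5[i]) and tmin5[i] < 0)
                        else 0.0
                    )
                    melt = self.melt_rate * max(0.0, tmin5[i]) if not np.isnan(tmin5[i]) else 0.0
                    filled[i] = max(0.0, prev + acc - melt)
                prev = filled[i]
            df.loc[idx, "snow"] = filled
            imputed.loc[pd.Index(idx)[miss]] = True
        df["imputed_snow"] = imputed
        return df

    def fit_transform(self, X: pd.DataFrame, y=None):
        return self.fit(X).transform(X)


def impute_snow(series: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`SnowModel`."""
    return SnowModel(**kwargs).fit_transform(series)


# ---------------------------------------------------------------------- frost
def frost_days(
    series: pd.DataFrame,
    mild_threshold: float = MILD_FROST_C,
    severe_threshold: float = SEVERE_FROST_C,
    snow_threshold: float = SNOW_COVER_CM,
) -> pd.DataFrame:
    """Per-season frost-stress summary over the Nov 1 - Apr 30 window.

    Returns one row per ``season_year`` with columns ``n_mild, n_severe,
    min_tmin5_under_thin_snow, n_missing`` (days still lacking temperature or
    snow after imputation are excluded from the counts and tallied).
    """
    if len(series) == 0:
        raise ValueError("empty weather window")
    rows = []
    for season, grp in series.groupby("season_year"):
        t = grp["tmin5"].to_numpy(float)
        s = grp["snow"].to_numpy(float)
        complete = ~np.isnan(t) & ~np.isnan(s)
        thin = complete & (s < snow_threshold)
        mild = thin & (t < mild_threshold)
        severe = thin & (t < severe_threshold)
        rows.append(
            {
                "season_year": season,
                "n_mild": int(mild.sum()),
                "n_severe": int(severe.sum()),
                "min_tmin5_under_thin_snow": (
                    float(np.min(t[thin])) if thin.any() else np.nan
                ),
                "n_missing": int((~complete).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("season_year")


def accession_exposure(
    cultivations: pd.DataFrame, season_summaries: pd.DataFrame
) -> pd.DataFrame:
    """Join cultivation years to per-season frost summaries.

    One row per accession x season-year; cultivation years without weather
    are emitted with missing exposure and a warning.  The per-accession
    cultivation-year count is included.
    """
    out = cultivations.merge(
        season_summaries.reset_index(),
        left_on="year",
        right_on="season_year",
        how="left",
    ).drop(columns=["season_year"])
    missing_years = sorted(out.loc[out["n_mild"].isna(), "year"].unique())
    if missing_years:
        warnings.warn(
            f"no weather summary for cultivation year(s): {missing_years}"
        )
    out["n_cultivation_years"] = out.groupby("accession_id")["year"].transform("size")
    return out


# ------------------------------------------------------------------- survival
def survival_to_percent(score) -> np.ndarray | float:
    """Linear map of the 1-9 survival score to 0-100 %."""
    s = np.asarray(score, dtype=float)
    if np.any((s < 1) | (s > 9)):
        raise ValueError("survival score must lie in [1, 9]")
    pct = (s - 1.0) / 8.0 * 100.0
    return float(pct) if np.isscalar(score) else pct


def percent_to_survival(pct) -> np.ndarray | float:
    """Inverse of :func:`survival_to_percent`."""
    p = np.asarray(pct, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentage must lie in [0, 100]")
    s = p / 100.0 * 8.0 + 1.0
    return float(s) if np.isscalar(pct) else s
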