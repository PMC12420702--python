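"""Three-step outlier control for unreplicated multi-year trial records.

Stage 1 — plausibility: per trait, records farther than ``sd_multiplier``
standard deviations from the trait mean (single pass over all years) are
excluded.  For the phenological traits a consistency screen follows: a value
flagged within its trait x year distribution is discarded only when the
whole growing season is abnormal (at least half of that year's phenology
values flagged) or when the accession's other phenology traits in the same
year do not deviate in the same direction — a lone early flowering date with
normal emergence and ripeness dates is an error, while a coherently shifted
season is biology and is retained.

Stage 2 — deviant years: the trial model is fitted with accessions random and
years fixed; each year's coefficient of variation CV_j = 100 * sd_e,j /
(mu + a_j) combines the year mean with a per-year residual SD, and years
whose CV sits more than ``cv_sd_multiplier`` standard deviations from the
mean CV lose all their records.  With a 3-SD rule, a single deviant year is
mathematically undetectable among <= 10 years (the deviation of one point
from the mean of n points cannot exceed (n-1)/sqrt(n) sample SDs), so the
stage requires at least ``min_years_cv`` years and is skipped (with a report
note) otherwise.

Stage 3 — record residuals: the model is refitted with accessions fixed and
years random; conditional residuals are standardised to unit SD and records
outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR] are excluded (two-sided;
falls back to a plain |z| > sd_multiplier rule when the IQR degenerates).

Every removal is logged with its stage and reason, and the report compares
heritability before (after stage 1) and after full curation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .heritability import heritability_from_records
from .lmm import MixedModelREML, SpecificationError
from .registry import CURATION_LOG_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "CurationConfig",
    "CurationReport",
    "CurationError",
    "PlausibilityFilter",
    "PhenologyConsistencyFilter",
    "YearCVFilter",
    "ResidualOutlierFilter",
    "tukey_outlier_mask",
    "cv_outlier_years",
    "plausibility_filter",
    "phenology_consistency_filter",
    "year_cv_outliers",
    "record_residual_outliers",
    "run_curation",
]


class CurationError(RuntimeError):
    """A curation stage could not be completed for a trait."""


def tukey_outlier_mask(
    z: np.ndarray,
    k: float = 1.5,
    quartile_method: str = "linear",
    fallback_sd: float = 3.0,
) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Boolean outlier mask under Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    When the IQR degenerates to zero the rule falls back to |z| >
    ``fallback_sd``.  Returns the mask and the fences used.
    """
    z = np.asarray(z, dtype=float)
    q1, q3 = np.percentile(z, [25, 75], method=quartile_method)
    iqr = q3 - q1
    if iqr > 0:
        lo, hi = q1 - k * iqr, q3 + k * iqr
    else:
        lo, hi = -fallback_sd, fallback_sd
    return (z < lo) | (z > hi), (float(lo), float(hi))


def cv_outlier_years(
    cv: pd.Series, k: float = 3.0, two_sided: bool = True
) -> pd.Series:
    """Years whose CV deviates more than ``k`` sample SDs from the mean CV.

    Undefined CVs (NaN) never test positive and are excluded from the mean
    and SD of the CV distribution.
    """
    defined = cv.dropna()
    m, s = defined.mean(), defined.std(ddof=1)
    dev = cv - m
    out = dev.abs() > k * s if two_sided else dev > k * s
    return out.fillna(False)


@dataclass
class CurationConfig:
    """Tunable thresholds of the curation pipeline (defaults as analysed)."""

    sd_multiplier: float = 3.0
    phenology_traits: Tuple[str, ...] = ("EmDays", "FTS", "FTE", "Ripe")
    cv_sd_multiplier: float = 3.0
    cv_two_sided: bool = True
    min_years_cv: int = 12
    tukey_k: float = 1.5
    quartile_method: str = "linear"
    alpha_reduction: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0 or self.cv_sd_multiplier <= 0 or self.tukey_k <= 0:
            raise ValueError("multipliers must be positive")


@dataclass
class CurationReport:
    """Audit trail of one curation run."""

    log: pd.DataFrame
    summary: pd.DataFrame
    cv_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    notes: List[str] = field(default_factory=list)


def _mark_removed(df: pd.DataFrame, mask, stage: str, reason) -> pd.DataFrame:
    out = df.copy()
    out.loc[mask, "status"] = "removed"
    out.loc[mask, "removal_stage"] = stage
    out.loc[mask, "removal_reason"] = reason
    return out


def _log_rows(removed: pd.DataFrame) -> pd.DataFrame:
    log = removed[["accession_id", "trait", "year", "experiment", "value"]].copy()
    log["stage"] = removed["removal_stage"].values
    log["reason"] = removed["removal_reason"].values
    return log[CURATION_LOG_COLUMNS]


# --------------------------------------------------------------------- stage 1
class PlausibilityFilter(BaseEstimator):
    """3-SD plausibility screen on one trait (single pass, no iteration)."""

    def __init__(self, sd_multiplier: float = 3.0):
        self.sd_multiplier = sd_multiplier

    def fit(self, X: pd.DataFrame, y=None):
        v = X["value"].to_numpy(float)
        if len(v) < 3:
            self.mean_ = np.nan
            self.sd_ = np.nan
            return self
        self.mean_ = float(np.mean(v))
        self.sd_ = float(np.std(v, ddof=1))
        return self

    def transform(self, X: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
        if len(X) < 3 or not np.isfinite(self.sd_):
            warnings.warn("fewer than 3 records: plausibility screen skipped")
            return X, X.iloc[0:0]
        lo = self.mean_ - self.sd_multiplier * self.sd_
        hi = self.mean_ + self.sd_multiplier * self.sd_
        out = (X["value"] < lo) | (X["value"] > hi)
        removed = _mark_removed(
            X[out],
            slice(None),
            "plausibility",
            f"value outside [{lo:.4g}, {hi:.4g}] "
            f"(mean {self.mean_:.4g} +/- {self.sd_multiplier:g} SD)",
        )
        return X[~out], removed

    def fit_transform(self, X: pd.DataFrame, y=None):
        return self.fit(X).transform(X)


def plausibility_filter(
    records: pd.DataFrame, config: Optional[CurationConfig] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`PlausibilityFilter` for one trait."""
    config = config or CurationConfig()
    return PlausibilityFilter(config.sd_multiplier).fit_transform(records)


# --------------------------------------------------------------------- stage 1b
class PhenologyConsistencyFilter(BaseEstimator):
    """Cross-trait consistency screen for flagged phenology values."""

    def __init__(
        self,
        sd_multiplier: float = 3.0,
        phenology_traits: Sequence[str] = ("EmDays", "FTS", "FTE", "Ripe"),
    ):
        self.sd_multiplier = sd_multiplier
        self.phenology_traits = tuple(phenology_traits)

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
        df = X.copy()
        bad = set(df["trait"]) - set(self.phenology_traits)
        if bad:
            raise ValueError(
                f"non-phenology trait(s) passed to consistency filter: {sorted(bad)}"
            )
        stats = df.groupby(["trait", "year"])["value"].agg(["mean", "std"])
        joined = df.join(stats, on=["trait", "year"])
        sd = joined["std"].fillna(0.0)
        dev = joined["value"] - joined["mean"]
        flagged = (sd > 0) & (dev.abs() > self.sd_multiplier * sd)
        direction = np.sign(dev).where(flagged, 0.0)
        df["_flag"] = flagged.to_numpy()
        df["_dir"] = direction.to_numpy()

        # (i) abnormal season: >= half of that year's phenology values flagged
        year_frac = df.groupby("year")["_flag"].mean()
        abnormal_years = set(year_frac.index[year_frac >= 0.5])

        remove = np.zeros(len(df), dtype=bool)
        reasons = np.empty(len(df), dtype=object)
        pos = {idx: i for i, idx in enumerate(df.index)}
        for (acc, yr), grp in df.groupby(["accession_id", "year"]):
            for idx, row in grp.iterrows():
                if not row["_flag"]:
                    continue
                i = pos[idx]
                if yr in abnormal_years:
                    remove[i] = True
                    reasons[i] = (
                        f"flagged in abnormal season {yr} (criterion i)"
                    )
                    continue
                others = grp[grp["trait"] != row["trait"]]
                consistent = len(others) > 0 and bool(
                    (others["_dir"] == row["_dir"]).all()
                )
                if not consistent:
                    remove[i] = True
                    reasons[i] = (
                        "flagged value inconsistent with the accession-year's "
                        "other phenology traits (criterion ii)"
                    )
        df = df.drop(columns=["_flag", "_dir"])
        removed = df[remove].copy()
        removed["status"] = "removed"
        removed["removal_stage"] = "phenology_consistency"
        removed["removal_reason"] = [r for r in reasons[remove]]
        return df[~remove], removed

    def fit_transform(self, X: pd.DataFrame, y=None):
        return self.fit(X).transform(X)


def phenology_consistency_filter(
    records: pd.DataFrame, config: Optional[CurationConfig] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`PhenologyConsistencyFilter`."""
    config = config or CurationConfig()
    return PhenologyConsistencyFilter(
        config.sd_multiplier, config.phenology_traits
    ).fit_transform(records)


# --------------------------------------------------------------------- stage 2
class YearCVFilter(BaseEstimator):
    """Remove whole trait-years with deviant coefficients of variation."""

    def __init__(
        self,
        cv_sd_multiplier: float = 3.0,
        two_sided: bool = True,
        fit_kwargs: Optional[dict] = None,
    ):
        self.cv_sd_multiplier = cv_sd_multiplier
        self.two_sided = two_sided
        self.fit_kwargs = fit_kwargs

    def fit(self, X: pd.DataFrame, y=None):
        fixed = ["year"]
        if "experiment" in X.columns and X["experiment"].nunique() > 1:
            fixed.append("experiment")
        model = MixedModelREML(
            fixed=fixed, random=["accession_id"], **(self.fit_kwargs or {})
        ).fit(X)
        if not model.converged_:
            raise CurationError("year-CV model did not converge")
        means = model.fixed_level_means("year")
        sd_year = np.sqrt(
            model.per_group_residual_variance(X["year"].astype(str).to_numpy())
        )
        cv = pd.DataFrame(
            {
                "year_mean": means["estimate"],
                "sd_e": sd_year.reindex(means.index),
                "n": X.groupby(X["year"].astype(str)).size().reindex(means.index),
            }
        )
        cv["cv"] = np.where(
            cv["year_mean"] > 0, 100.0 * cv["sd_e"] / cv["year_mean"], np.nan
        )
        cv["undefined_mean"] = cv["year_mean"] <= 0
        cv["removed"] = cv_outlier_years(
            cv["cv"], self.cv_sd_multiplier, self.two_sided
        )
        cv["flag_manual_review"] = cv["undefined_mean"]
        cv.index.name = "year"
        self.cv_table_ = cv
        self.removed_years_ = [int(y) for y in cv.index[cv["removed"]]]
        return self

    def transform(self, X: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
        mask = X["year"].isin(self.removed_years_)
        cvs = self.cv_table_.loc[[str(y) for y in X.loc[mask, "year"]], "cv"] if mask.any() else []
        removed = X[mask].copy()
        removed["status"] = "removed"
        removed["removal_stage"] = "year_cv"
        removed["removal_reason"] = [
            f"year CV {c:.3g} deviates > {self.cv_sd_multiplier:g} SD from mean CV"
            for c in np.asarray(cvs)
        ]
        return X[~mask], removed

    def fit_transform(self, X: pd.DataFrame, y=None):
        return self.fit(X).transform(X)


def year_cv_outliers(
    records: pd.DataFrame,
    config: Optional[CurationConfig] = None,
    **fit_kwargs,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`YearCVFilter` for one trait.

    Returns (kept, removed, cv_table).
    """
    config = config or CurationConfig()
    f = YearCVFilter(
        config.cv_sd_multiplier, config.cv_two_sided, fit_kwargs or None
    )
    kept, removed = f.fit_transform(records)
    return kept, removed, f.cv_table_


# --------------------------------------------------------------------- stage 3
class ResidualOutlierFilter(BaseEstimator):
    """Tukey-fence screen on standardised conditional residuals."""

    def __init__(
        self,
        tukey_k: float = 1.5,
        quartile_method: str = "linear",
        sd_multiplier: float = 3.0,
        fit_kwargs: Optional[dict] = None,
    ):
        self.tukey_k = tukey_k
        self.quartile_method = quartile_method
        self.sd_multiplier = sd_multiplier
        self.fit_kwargs = fit_kwargs

    def fit_transform(self, X: pd.DataFrame, y=None):
        fixed = ["accession_id"]
        random = ["year"]
        if "experiment" in X.columns and X["experiment"].nunique() > 1:
            fixed.append("experiment")
        model = MixedModelREML(
            fixed=fixed, random=random, **(self.fit_kwargs or {})
        ).fit(X)
        if not model.converged_:
            raise CurationError("residual-outlier model did not converge")
        self.model_ = model
        resid = model.residuals_
        sd = float(np.std(resid, ddof=1))
        z = resid / sd if sd > 0 else np.zeros_like(resid)
        mask, (lo, hi) = tukey_outlier_mask(
            z, self.tukey_k, self.quartile_method, self.sd_multiplier
        )
        reason_tpl = (
            f"standardized residual {{z:.3g}} outside fences "
            f"[{lo:.3g}, {hi:.3g}] (k={self.tukey_k:g})"
        )
        self.fences_ = (float(lo), float(hi))
        removed = X[mask].copy()
        removed["status"] = "removed"
        removed["removal_stage"] = "residual"
        removed["removal_reason"] = [reason_tpl.format(z=v) for v in z[mask]]
        return X[~mask], removed


def record_residual_outliers(
    records: pd.DataFrame,
    config: Optional[CurationConfig] = None,
    **fit_kwargs,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`ResidualOutlierFilter` for one trait."""
    config = config or CurationConfig()
    return ResidualOutlierFilter(
        config.tukey_k,
        config.quartile_method,
        config.sd_multiplier,
        fit_kwargs or None,
    ).fit_transform(records)


# ------------------------------------------------------------------- pipeline
def _safe_h2(records: pd.DataFrame) -> float:
    try:
        return heritability_from_records(records).h2
    except (SpecificationError, ValueError):
        return float("nan")


def run_curation(
    records: pd.DataFrame,
    config: Optional[CurationConfig] = None,
    registry=None,
) -> Tuple[pd.DataFrame, CurationReport]:
    """Run the full three-step curation over every trait in ``records``.

    Returns the annotated record table (removed rows keep their values but
    carry status/stage/reason) and a :class:`CurationReport` whose summary
    lists, per trait, the record and genotype counts and heritability before
    (post-plausibility) and after curation.
    """
    config = config or CurationConfig()
    notes: List[str] = []
    cv_tables: Dict[str, pd.DataFrame] = {}
    removed_frames: List[pd.DataFrame] = []
    kept_frames: List[pd.DataFrame] = []
    summary_rows = []

    base = records[records["status"] == "kept"].copy()
    pre_removed = records[records["status"] == "removed"]
    if len(pre_removed):
        removed_frames.append(pre_removed)

    # Stage 1 per trait, then the cross-trait phenology consistency screen.
    stage1: Dict[str, pd.DataFrame] = {}
    for trait, df_t in base.groupby("trait"):
        kept, removed = plausibility_filter(df_t, config)
        logger.info("%s: plausibility removed %d of %d", trait, len(removed), len(df_t))
        if len(removed):
            removed_frames.append(removed)
        stage1[trait] = kept
    phen = [t for t in stage1 if t in config.phenology_traits]
    if phen:
        pooled = pd.concat([stage1[t] for t in phen])
        kept, removed = phenology_consistency_filter(pooled, config)
        logger.info("phenology consistency removed %d records", len(removed))
        if len(removed):
            removed_frames.append(removed)
        for t in phen:
            stage1[t] = kept[kept["trait"] == t]

    for trait, df_t in stage1.items():
        n_data = len(df_t)
        genos = set(df_t["accession_id"])
        h2_initial = _safe_h2(df_t)
        trait_removed: List[pd.DataFrame] = []

        n_years = df_t["year"].nunique()
        if n_years >= config.min_years_cv:
            try:
                df_t, removed, cv_table = year_cv_outliers(df_t, config)
                cv_tables[trait] = cv_table
                if len(removed):
                    trait_removed.append(removed)
                logger.info("%s: year-CV removed %d records", trait, len(removed))
            except (CurationError, SpecificationError) as exc:
                notes.append(f"{trait}: year-CV stage failed ({exc})")
        else:
            notes.append(
                f"{trait}: year-CV stage skipped ({n_years} years < "
                f"{config.min_years_cv}; a 3-SD rule cannot flag a single "
                "year at this size)"
            )

        try:
            df_t, removed = record_residual_outliers(df_t, config)
            if len(removed):
                trait_removed.append(removed)
            logger.info("%s: residual screen removed %d records", trait, len(removed))
        except (CurationError, SpecificationError) as exc:
            notes.append(f"{trait}: residual stage failed ({exc}); trait halted")
            summary_rows.append(
                {
                    "trait": trait,
                    "n_data": n_data,
                    "n_outlier": 0,
                    "n_genotypes": len(genos),
                    "n_genotypes_fully_removed": 0,
                    "h2_initial": h2_initial,
                    "h2_final": float("nan"),
                }
            )
            kept_frames.append(df_t)
            removed_frames.extend(trait_removed)
            continue

        kept_frames.append(df_t)
        removed_frames.extend(trait_removed)
        n_outlier = int(sum(len(r) for r in trait_removed))
        genos_left = set(df_t["accession_id"])
        h2_final = _safe_h2(df_t)
        summary_rows.append(
            {
                "trait": trait,
                "n_data": n_data,
                "n_outlier": n_outlier,
                "n_genotypes": len(genos),
                "n_genotypes_fully_removed": len(genos - genos_left),
                "h2_initial": h2_initial,
                "h2_final": h2_final,
            }
        )

    curated = pd.concat(kept_frames + removed_frames, ignore_index=False).sort_index() \
        if (kept_frames or removed_frames) else records.iloc[0:0]
    summary = pd.DataFrame(summary_rows).set_index("trait") if summary_rows else pd.DataFrame()
    if len(summary):
        with np.errstate(divide="ignore", invalid="ignore"):
            summary["delta_h2_pct"] = (
                100.0 * (summary["h2_final"] - summary["h2_initial"])
                / summary["h2_initial"]
            )
    log = (
        pd.concat([_log_rows(r) for r in removed_frames], ignore_index=True)
        if removed_frames
        else pd.DataFrame(columns=CURATION_LOG_COLUMNS)
    )
    return curated, CurationReport(
        log=log, summary=summary, cv_tables=cv_tables, notes=notes
    )
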