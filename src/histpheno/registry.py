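"""Trait registry and tabular I/O for historical genebank phenotype records.

The package operates on long-format ("tidy") phenotype tables: one row per
accession x trait x year x experiment, carried as a :class:`pandas.DataFrame`
with the columns in :data:`PHENO_COLUMNS`.  Curation state travels with the
record: ``status`` is ``"kept"`` or ``"removed"``, and removed rows carry the
stage and reason of their exclusion.

The default registry describes the sixteen quantitative traits recorded for
the pea collection during seed regeneration: phenological dates (days after a
season-specific reference date), plant architecture (cm), yield components,
protein content and the two 1-9 winter-survival scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "TraitDefinition",
    "TraitRegistry",
    "default_registry",
    "PHENO_COLUMNS",
    "STATUS_COLUMNS",
    "CONVARIETIES",
    "UnknownTraitError",
    "SchemaError",
    "read_pheno_table",
    "write_pheno_table",
    "read_cultivation_table",
    "write_curation_report",
]

#: Mandatory columns of a phenotype table.
PHENO_COLUMNS = ["accession_id", "trait", "year", "experiment", "convariety", "value"]

#: Curation-state columns appended by the pipeline.
STATUS_COLUMNS = ["status", "removal_stage", "removal_reason"]

#: Recognised infraspecific groups (Alefeld's convarieties) plus "unknown".
CONVARIETIES = (
    "sativum",
    "speciosum",
    "axiphium",
    "medullare",
    "medullosaccharatum",
    "unknown",
)

_UNITS = {"days", "cm", "g", "%", "class", "count", "score"}
_SEASONS = {"spring", "winter", "both"}
_CLASSES = {"phenology", "agronomic", "yield", "survival"}


class UnknownTraitError(KeyError):
    """A trait code not present in the registry was encountered."""


class SchemaError(ValueError):
    """A delimited input violates the declared column schema."""


@dataclass(frozen=True)
class TraitDefinition:
    """One entry of the trait registry.

    Parameters
    ----------
    code : str
        Short identifier, e.g. ``"FTS"`` for start of flowering.
    name : str
        Human-readable trait name.
    unit : str
        One of ``days, cm, g, %, class, count, score``.
    season : str
        ``"spring"``, ``"winter"`` or ``"both"`` — the cultivation season(s)
        in which the trait is recorded.
    trait_class : str
        ``"phenology"``, ``"agronomic"``, ``"yield"`` or ``"survival"``.
    hard_bounds : tuple of float, optional
        Closed interval of physically possible values, used for validation
        only (never for outlier removal, which is statistical).
    """

    code: str
    name: str
    unit: str
    season: str
    trait_class: str
    hard_bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r} for trait {self.code}")
        if self.season not in _SEASONS:
            raise ValueError(f"unknown season {self.season!r} for trait {self.code}")
        if self.trait_class not in _CLASSES:
            raise ValueError(f"unknown class {self.trait_class!r} for trait {self.code}")
        if self.hard_bounds is not None and self.hard_bounds[0] > self.hard_bounds[1]:
            raise ValueError(f"empty hard_bounds for trait {self.code}")


class TraitRegistry:
    """An ordered, code-unique collection of :class:`TraitDefinition`."""

    def __init__(self, traits: Iterable[TraitDefinition]):
        self._traits: dict[str, TraitDefinition] = {}
        for t in traits:
            if t.code in self._traits:
                raise ValueError(f"duplicate trait code {t.code!r}")
            self._traits[t.code] = t

    def __contains__(self, code: str) -> bool:
        return code in self._traits

    def __getitem__(self, code: str) -> TraitDefinition:
        try:
            return self._traits[code]
        except KeyError:
            raise UnknownTraitError(code) from None

    def __iter__(self):
        return iter(self._traits.values())

    def __len__(self) -> int:
        return len(self._traits)

    @property
    def codes(self) -> Tuple[str, ...]:
        return tuple(self._traits)

    def phenology_codes(self) -> Tuple[str, ...]:
        return tuple(t.code for t in self if t.trait_class == "phenology")

    def for_season(self, season: str) -> Tuple[str, ...]:
        return tuple(
            t.code for t in self if t.season == season or t.season == "both"
        )


def default_registry() -> TraitRegistry:
    """The sixteen regeneration-trial traits of the pea collection."""
    d = TraitDefinition
    return TraitRegistry(
        [
            d("EmDays", "Days to emergence", "days", "both", "phenology", (0, 365)),
            d("FTS", "Start of flowering time", "days", "both", "phenology", (0, 365)),
            d("FTE", "End of flowering time", "days", "both", "phenology", (0, 365)),
            d("Ripe", "Date of picking ripeness", "days", "both", "phenology", (0, 365)),
            d("FTdur", "Duration of flowering", "days", "both", "phenology", (0, 365)),
            d("PHFT", "Plant height at flowering time", "cm", "both", "agronomic", (0, 500)),
            d("PHmin", "Plant height (minimum)", "cm", "both", "agronomic", (0, 500)),
            d("PHmax", "Plant height (maximum)", "cm", "both", "agronomic", (0, 500)),
            d("PHpod", "Height of the first pod", "cm", "both", "agronomic", (0, 500)),
            d("Flr", "Number of flowers per inflorescence", "class", "spring", "agronomic", (1, 5)),
            d("Ss", "Seed size", "class", "spring", "yield", (1, 3)),
            d("Spp", "Number of seeds per pod", "count", "spring", "yield", (0, 30)),
            d("HGW", "Hundred grain weight", "g", "both", "yield", (0, 200)),
            d("Prot", "Protein content", "%", "spring", "yield", (0, 100)),
            d("Surv", "Survival rate", "score", "winter", "survival", (1, 9)),
            d("PWSurv", "Post-winter survival rate", "score", "winter", "survival", (1, 9)),
        ]
    )


def _ensure_status_columns(df: pd.DataFrame) -> pd.DataFrame:
    if "status" not in df.columns:
        df["status"] = "kept"
    if "removal_stage" not in df.columns:
        df["removal_stage"] = "none"
    if "removal_reason" not in df.columns:
        df["removal_reason"] = ""
    df["removal_reason"] = df["removal_reason"].fillna("").astype(str)
    return df


def read_pheno_table(
    path, registry: Optional[TraitRegistry] = None
) -> pd.DataFrame:
    """Read a long-format phenotype CSV into a validated record table.

    Every row becomes one kept record.  Trait codes are validated against
    ``registry`` (the default registry when omitted); rows with non-numeric
    values are rejected with their row indices named in the error.
    """
    registry = registry if registry is not None else default_registry()
    df = pd.read_csv(path, comment="#", dtype={"accession_id": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    unknown = sorted(set(df["trait"]) - set(registry.codes))
    if unknown:
        raise UnknownTraitError(
            f"unknown trait code(s): {', '.join(map(str, unknown))}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() & df["value"].notna()]
    if len(bad):
        raise SchemaError(
            f"non-numeric value in row(s): {', '.join(map(str, bad.tolist()))}"
        )
    df = df.copy()
    df["value"] = values
    df["year"] = df["year"].astype(int)
    df = df[values.notna()].reset_index(drop=True)
    return _ensure_status_columns(df)


def write_pheno_table(df: pd.DataFrame, path) -> None:
    """Write a phenotype table as UTF-8 comma-separated text.

    A declaration header records encoding, delimiter and decimal convention
    so every artifact file is self-describing.
    """
    buf = io.StringIO()
    buf.write("# histpheno phenotype table; encoding=UTF-8 delimiter=, decimal=.\n")
    cols = [c for c in PHENO_COLUMNS + STATUS_COLUMNS if c in df.columns]
    df.to_csv(buf, index=False, columns=cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_cultivation_table(path) -> pd.DataFrame:
    """Read an accession x sowing-year cultivation table.

    Columns: ``accession_id, year, season``; (accession_id, year) must be
    unique within each season.
    """
    df = pd.read_csv(path, comment="#", dtype={"accession_id": str})
    missing = [c for c in ("accession_id", "year", "season") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df["year"] = df["year"].astype(int)
    dup = df.duplicated(subset=["accession_id", "year", "season"])
    if dup.any():
        raise SchemaError(
            f"duplicate (accession_id, year) within season at rows "
            f"{', '.join(map(str, df.index[dup].tolist()))}"
        )
    return df


#: Columns of the per-record curation log.
CURATION_LOG_COLUMNS = [
    "accession_id",
    "trait",
    "year",
    "experiment",
    "stage",
    "reason",
    "value",
]


def write_curation_report(report, path, summary_path=None) -> None:
    """Write a curation report: per-record exclusion log and per-trait summary.

    ``report`` is a :class:`histpheno.curation.CurationReport`.  The log lists
    every removed record with its stage and reason; the summary's per-stage
    counts are recomputed from the log (they agree by construction).
    """
    log = report.log.copy()
    for c in CURATION_LOG_COLUMNS:
        if c not in log.columns:
            log[c] = pd.NA
    header = "# histpheno curation log; encoding=UTF-8 delimiter=, decimal=.\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        log.to_csv(fh, index=False, columns=CURATION_LOG_COLUMNS)
    if summary_path is not None:
        with open(summary_path, "w", encoding="utf-8") as fh:
            fh.write("# histpheno curation summary; encoding=UTF-8 delimiter=, decimal=.\n")
            report.summary.to_csv(fh, index=True)
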