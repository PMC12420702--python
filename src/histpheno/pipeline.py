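"""End-to-end orchestration: simulate -> curate -> fit -> summarise.

A single YAML/dict configuration drives every stage; all artifacts are
plain CSV/JSON files in the output directory, and a machine-readable run
manifest records the configuration echo, package version, seed and per-stage
record counts.  Identical configuration and seed yield byte-identical
numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .curation import CurationConfig, run_curation
from .lmm import fit_blues
from .post import convariety_contrasts, trait_correlations
from .registry import (
    default_registry,
    read_cultivation_table,
    read_pheno_table,
    write_curation_report,
    write_pheno_table,
)
from .simulate import SimulationParams, simulate_trial, simulate_weather
from .weather import accession_exposure, frost_days, impute_gaps, impute_snow, qc_min_temp

logger = logging.getLogger(__name__)

__all__ = ["run_all", "validate_config"]

_HEADER = "# histpheno output; encoding=UTF-8 delimiter=, decimal=.\n"


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=index, float_format="%.10g")


def validate_config(config: Dict) -> Dict:
    """Check the run configuration before any computation."""
    cfg = dict(config)
    if "simulation" not in cfg and "pheno_path" not in cfg:
        raise ValueError(
            "config must provide either a 'simulation' block or 'pheno_path'"
        )
    if "simulation" in cfg and "seed" not in cfg:
        raise ValueError("'seed' is mandatory when simulation is requested")
    cfg.setdefault("alpha", 0.05)
    return cfg


def run_all(config: Dict, out_dir) -> Dict:
    """Execute the full pipeline and return the run manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "config": cfg,
        "seed": cfg.get("seed"),
        "stages": {},
    }
    registry = default_registry()

    # ---- input records -----------------------------------------------------
    if "simulation" in cfg:
        params = SimulationParams(**{**cfg["simulation"], "seed": cfg["seed"]})
        records, truth = simulate_trial(params)
        write_pheno_table(records, out / "pheno.csv")
        _write_csv(truth.records, out / "truth_records.csv")
        _write_csv(truth.accession_effects, out / "truth_accessions.csv")
        manifest["stages"]["simulate"] = {"n_records": int(len(records))}
    else:
        records = read_pheno_table(cfg["pheno_path"], registry)
        manifest["stages"]["read"] = {"n_records": int(len(records))}

    # ---- curation ----------------------------------------------------------
    cur_cfg = CurationConfig(**cfg.get("curation", {}))
    curated, report = run_curation(records, cur_cfg, registry)
    write_pheno_table(curated, out / "curated.csv")
    write_curation_report(report, out / "curation_log.csv", out / "curation_summary.csv")
    for trait, cv in report.cv_tables.items():
        _write_csv(cv, out / f"cv_table_{trait}.csv", index=True)
    _write_csv(
        report.summary.reset_index(), out / "heritability_before_after.csv"
    )
    manifest["stages"]["curate"] = {
        "n_removed": int(len(report.log)),
        "notes": report.notes,
    }

    # ---- BLUEs -------------------------------------------------------------
    kept = curated[curated["status"] == "kept"]
    blues_frames = {}
    skipped = []
    for trait, df_t in kept.groupby("trait"):
        try:
            blues, missing = fit_blues(df_t)
        except Exception as exc:  # single-trait failure must not kill the run
            skipped.append(f"{trait}: {exc}")
            continue
        blues = blues.reset_index()
        blues.insert(0, "trait", trait)
        blues_frames[trait] = blues
    if blues_frames:
        _write_csv(pd.concat(blues_frames.values(), ignore_index=True), out / "blues.csv")
    manifest["stages"]["blues"] = {
        "n_traits": len(blues_frames),
        "skipped": skipped,
    }

    # ---- contrasts and correlations ---------------------------------------
    conv_map = kept.drop_duplicates("accession_id").set_index("accession_id")["convariety"]
    contrast_rows = []
    for trait, blues in blues_frames.items():
        s = blues.set_index("accession_id")["estimate"]
        try:
            table = convariety_contrasts(s, conv_map, alpha=cfg["alpha"])
        except ValueError:
            continue
        stats = table.group_stats.reset_index().rename(columns={"index": "group"})
        stats.insert(0, "trait", trait)
        stats["letters"] = [table.letters[g] for g in stats["group"]]
        contrast_rows.append(stats)
        pw = table.pairwise.copy()
        pw.insert(0, "trait", trait)
        _write_csv(pw, out / f"pairwise_{trait}.csv")
    if contrast_rows:
        _write_csv(pd.concat(contrast_rows, ignore_index=True), out / "contrasts.csv")
    if len(blues_frames) >= 2:
        corr = trait_correlations(
            {t: b.set_index("accession_id")["estimate"] for t, b in blues_frames.items()},
            method=cfg.get("correlation_method", "pearson"),
            alpha=cfg["alpha"],
        )
        _write_csv(corr.r, out / "correlations.csv", index=True)
        _write_csv(corr.p_holm, out / "correlations_p_holm.csv", index=True)
    manifest["stages"]["post"] = {"n_contrast_traits": len(contrast_rows)}

    # ---- weather / frost ---------------------------------------------------
    if "weather" in cfg or "weather_path" in cfg:
        if "weather_path" in cfg:
            weather = pd.read_csv(cfg["weather_path"], comment="#", parse_dates=["date"])
        else:
            wcfg = dict(cfg["weather"])
            weather = simulate_weather(
                tuple(wcfg.pop("year_span")), seed=cfg.get("seed", 0), **wcfg
            )
        weather = qc_min_temp(weather)
        weather = impute_gaps(weather)
        weather = impute_snow(weather)
        summaries = frost_days(weather)
        _write_csv(weather, out / "weather_qc.csv")
        _write_csv(summaries, out / "frost_summaries.csv", index=True)
        if "cultivations_path" in cfg:
            cult = read_cultivation_table(cfg["cultivations_path"])
            exposure = accession_exposure(cult, summaries)
            _write_csv(exposure, out / "frost_exposure.csv")
        manifest["stages"]["weather"] = {
            "n_days": int(len(weather)),
            "n_removed_qc": int((weather["qc_flag"] != "ok").sum()),
        }

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
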