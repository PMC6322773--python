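"""Readers, writers and run configuration.

Delimited-text dialect throughout: comma-separated, UTF-8, header row,
"." decimal — the distribution format family of open anthropometric
datasets.  The cohort schema is
``country, year, sex, age_months, weight_kg, height_cm, mac_cm`` with
optional pre-computed z-score columns ``waz, haz, whz, baz`` and optional
``id``/``region``; sex accepts m/f/male/female/M/F/boy/girl.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COHORT_COLUMNS",
    "OPTIONAL_COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_region_map",
    "assign_regions",
    "write_report",
    "forest_table",
    "RunConfig",
    "provenance_block",
]

REQUIRED_COHORT_COLUMNS = ("country", "year", "sex", "age_months", "weight_kg",
                           "height_cm", "mac_cm")
OPTIONAL_COHORT_COLUMNS = ("id", "region", "waz", "haz", "whz", "baz")

_SEX_ALIASES = {
    "m": "male", "male": "male", "boy": "male", "boys": "male", "1": "male",
    "f": "female", "female": "female", "girl": "female", "girls": "female", "2": "female",
}


class CohortSchemaError(ValueError):
    """The cohort file violates the declared column schema."""


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; normalises sex labels, adds ``id`` if absent."""
    df = pd.read_csv(Path(path))
    missing = set(REQUIRED_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortSchemaError(f"cohort file missing columns: {sorted(missing)}")
    sex = df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    if sex.isna().any():
        bad = df.loc[sex.isna(), "sex"].unique()[:5]
        raise CohortSchemaError(f"unrecognised sex values: {list(bad)}")
    df = df.copy()
    df["sex"] = sex
    for col in ("age_months", "weight_kg", "height_cm", "mac_cm"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["weight_kg"] <= 0).any() or (df["height_cm"] <= 0).any() or (df["mac_cm"] <= 0).any():
        raise CohortSchemaError("weight, height and MAC must be strictly positive")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)


def read_region_map(path=None) -> dict:
    """country -> region lookup; the shipped editable file by default."""
    if path is None:
        src = resources.files("tapeweight").joinpath("data/regions.csv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(Path(path))
    return dict(zip(table["country"].astype(str), table["region"].astype(str)))


def assign_regions(df: pd.DataFrame, region_map: dict | None = None) -> pd.DataFrame:
    """Fill/derive the region column from country; unknown -> "unassigned"."""
    region_map = region_map or read_region_map()
    out = df.copy()
    mapped = out["country"].astype(str).map(region_map)
    if "region" in out.columns:
        out["region"] = out["region"].fillna(mapped)
    else:
        out["region"] = mapped
    out["region"] = out["region"].fillna("unassigned")
    return out


# ---------------------------------------------------------------------------
# Report output


def forest_table(report) -> pd.DataFrame:
    """Forest-plot-ready overall bias/precision rows: method, mpe, loa_low, loa_high."""
    rows = []
    for method, s in report.overall.items():
        if s is None:
            continue
        rows.append({"method": method, "mpe": s.mpe, "loa_low": s.loa_low, "loa_high": s.loa_high})
    return pd.DataFrame(rows)


def write_report(report, outdir, *, provenance: dict | None = None) -> dict:
    """Write an AnalysisReport as CSV + JSON; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cells_path = outdir / "cells.csv"
    report.cells.to_csv(cells_path, index=False, float_format="%.6g")
    paths["cells"] = cells_path

    forest_path = outdir / "forest.csv"
    forest_table(report).to_csv(forest_path, index=False, float_format="%.6g")
    paths["forest"] = forest_path

    if report.comparisons:
        comp_path = outdir / "comparisons.csv"
        report.comparisons_frame().to_csv(comp_path, index=False, float_format="%.6g")
        paths["comparisons"] = comp_path

    doc = {
        "overall": {m: (s.as_dict() if s else None) for m, s in report.overall.items()},
        "acceptability": report.acceptability,
        "exclusions": report.exclusions,
    }
    if provenance is not None:
        doc["provenance"] = provenance
    json_path = outdir / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["report"] = json_path
    return paths


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    cohort: str
    calibrations: list
    output_dir: str
    growth_tables: str | None = None     # None -> shipped synthetic fixture reference
    methods: list = field(default_factory=list)   # empty -> all loaded calibrations
    dimensions: list = field(default_factory=lambda: ["sex", "age", "weight",
                                                      "bmi_for_age_z",
                                                      "weight_for_height_z", "region"])
    reference_method: str | None = None
    p10_threshold: float = 70.0
    p20_threshold: float = 95.0
    alpha: float = 0.001
    clinical_margin: float = 10.0
    seed: int = 0
    passthrough_zscores: bool = True

    def validate(self) -> "RunConfig":
        for p in [self.cohort, *(self.calibrations or []),
                  *( [self.growth_tables] if self.growth_tables else [])]:
            if not Path(p).exists():
                raise FileNotFoundError(f"referenced path does not exist: {p}")
        for name, v in (("p10_threshold", self.p10_threshold),
                        ("p20_threshold", self.p20_threshold)):
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


def provenance_block(config: dict, seed: int) -> dict:
    """Reproducibility stamp: configuration hash, seed, package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
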