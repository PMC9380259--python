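"""Readers and writers for the package's delimited-text dialects.

Plate CSV: ``sample_id, drug, dose_nM, rep1..repN`` with one row per dose
including dose 0; ``NA`` marks a missing well.

Phosphosite TSV (MaxQuant-style site table): ``protein, position, residue,
localization_prob, window`` followed by one intensity column per sample
named ``<batch>.<condition>.<sample_id>`` with an optional ``.<fraction>``
suffix.

All writers use '.' as decimal separator regardless of locale and 6
significant digits; readers skip ``#`` comment lines (used for run
metadata headers).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import ViabilityPlate
from .phospho_stats import PhosphoSiteTable
from .synergy import CombinationGrid, SynergyMatrix

__all__ = [
    "SchemaError",
    "read_plate_csv",
    "write_plate_csv",
    "read_phospho_tsv",
    "write_phospho_tsv",
    "read_scores_tsv",
    "write_scores_tsv",
    "read_kinase_map_tsv",
    "write_kinase_map_tsv",
    "read_gmt",
    "read_grid_tsv",
    "write_grid_tsv",
    "write_synergy_tsv",
]

FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """Input file does not match the documented dialect."""


def _read_table(path, sep) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", na_values=["NA"], keep_default_na=True)


def _write_lines(path, df: pd.DataFrame, sep: str, header_comment: str | None, index=False):
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=sep, index=index, float_format=FLOAT_FMT, na_rep="NA")


# --- viability plates ---------------------------------------------------------


def read_plate_csv(path) -> list[ViabilityPlate]:
    """Parse a plate CSV into one ViabilityPlate per (sample_id, drug)."""
    df = _read_table(path, sep=",")
    required = {"sample_id", "drug", "dose_nM"}
    if not required.issubset(df.columns):
        raise SchemaError(f"plate CSV needs columns {sorted(required)}, got {list(df.columns)}")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise SchemaError("plate CSV needs at least one repN column")
    plates = []
    for (sample_id, drug), sub in df.groupby(["sample_id", "drug"], sort=False):
        doses = sub["dose_nM"].to_numpy(dtype=float)
        if np.unique(doses).size != doses.size:
            raise SchemaError(f"duplicated dose row for sample {sample_id!r}")
        if 0 not in doses:
            raise SchemaError(f"sample {sample_id!r} is missing the dose-0 reference row")
        readings = sub[rep_cols].to_numpy(dtype=float)
        plates.append(
            ViabilityPlate(sample_id=str(sample_id), drug=str(drug), doses=doses, readings=readings)
        )
    return plates


def write_plate_csv(plates: list[ViabilityPlate], path, header_comment: str | None = None):
    n_rep = max(p.n_replicates for p in plates)
    rows = []
    for p in plates:
        for d, row in zip(p.doses, p.readings):
            rec = {"sample_id": p.sample_id, "drug": p.drug, "dose_nM": d}
            for r in range(n_rep):
                rec[f"rep{r + 1}"] = row[r] if r < p.n_replicates else np.nan
            rows.append(rec)
    _write_lines(path, pd.DataFrame(rows), ",", header_comment)


# --- phosphosite tables -------------------------------------------------------

SITE_COLS = ["protein", "position", "residue", "localization_prob", "window"]


def _parse_sample_column(name: str):
    parts = name.split(".")
    if len(parts) == 3:
        batch, condition, sample_id = parts
        fraction = None
    elif len(parts) == 4:
        batch, condition, sample_id, fraction = parts
        if not fraction.isdigit():
            raise SchemaError(f"malformed sample column {name!r}: fraction must be an integer")
        fraction = int(fraction)
    else:
        raise SchemaError(
            f"malformed sample column {name!r}: expected <batch>.<condition>.<sample>[.<fraction>]"
        )
    if not (batch and condition and sample_id):
        raise SchemaError(f"malformed sample column {name!r}: empty component")
    return batch, condition, sample_id, fraction


def read_phospho_tsv(path) -> PhosphoSiteTable:
    """Parse the phosphosite TSV dialect; zero intensities become missing."""
    df = _read_table(path, sep="\t")
    missing = [c for c in SITE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"phosphosite TSV is missing site columns {missing}")
    sample_cols = [c for c in df.columns if c not in SITE_COLS]
    if not sample_cols:
        raise SchemaError("phosphosite TSV has no sample intensity columns")
    meta = [_parse_sample_column(c) for c in sample_cols]
    site_index = pd.Index(
        [f"{p}:{r}{pos}" for p, r, pos in zip(df["protein"], df["residue"], df["position"])],
        name="site_id",
    )
    sites = df[SITE_COLS].set_index(site_index)
    values = df[sample_cols].set_index(site_index).astype(float)
    n_zero = int((values == 0).sum().sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero intensities treated as missing (log-scale requirement)")
        values = values.replace(0.0, np.nan)
    samples = pd.DataFrame(
        {
            "batch": [m[0] for m in meta],
            "condition": [m[1] for m in meta],
            "fraction": [m[3] for m in meta],
        },
        index=pd.Index(sample_cols, name="sample_id"),
    )
    if samples["fraction"].isna().all():
        samples = samples.drop(columns="fraction")
    return PhosphoSiteTable(values=values, sites=sites, samples=samples, log2=False)


def write_phospho_tsv(table: PhosphoSiteTable, path, header_comment: str | None = None):
    """Write a table in the dialect; sample columns encode batch/condition."""
    cols = {}
    for sid, row in table.samples.iterrows():
        name = f"{row['batch']}.{row['condition']}.{sid.split('.')[-1]}"
        if "fraction" in table.samples.columns and pd.notna(row.get("fraction")):
            name += f".{int(row['fraction'])}"
        cols[sid] = name
    out = table.sites[SITE_COLS].copy()
    vals = table.values.rename(columns=cols)
    out = pd.concat([out.reset_index(drop=True), vals.reset_index(drop=True)], axis=1)
    _write_lines(path, out, "\t", header_comment)


# --- annotation tables --------------------------------------------------------


def read_scores_tsv(path) -> pd.DataFrame:
    df = _read_table(path, sep="\t")
    need = {"protein", "position", "score"}
    if not need.issubset(df.columns):
        raise SchemaError(f"functional-score TSV needs columns {sorted(need)}")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise SchemaError("functional scores must be in [0, 1]")
    return df[["protein", "position", "score"]]


def write_scores_tsv(scores: pd.DataFrame, path, header_comment: str | None = None):
    _write_lines(path, scores[["protein", "position", "score"]], "\t", header_comment)


def read_kinase_map_tsv(path) -> pd.DataFrame:
    df = _read_table(path, sep="\t")
    need = {"kinase", "protein", "position"}
    if not need.issubset(df.columns):
        raise SchemaError(f"kinase-map TSV needs columns {sorted(need)}")
    return df[["kinase", "protein", "position"]]


def write_kinase_map_tsv(kmap: pd.DataFrame, path, header_comment: str | None = None):
    _write_lines(path, kmap[["kinase", "protein", "position"]], "\t", header_comment)


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name <tab> description <tab> member1 <tab> ..."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"malformed GMT line: {line[:50]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


# --- combination grids --------------------------------------------------------


def read_grid_tsv(path, drug_a: str = "drug_a", drug_b: str = "drug_b") -> CombinationGrid:
    """Long-format grid TSV: dose_a_nM, dose_b_nM, response."""
    df = _read_table(path, sep="\t")
    need = {"dose_a_nM", "dose_b_nM", "response"}
    if not need.issubset(df.columns):
        raise SchemaError(f"grid TSV needs columns {sorted(need)}")
    wide = df.pivot(index="dose_a_nM", columns="dose_b_nM", values="response")
    return CombinationGrid(
        drug_a=drug_a,
        drug_b=drug_b,
        doses_a=wide.index.to_numpy(dtype=float),
        doses_b=wide.columns.to_numpy(dtype=float),
        measured=wide.to_numpy(dtype=float),
    )


def write_grid_tsv(grid: CombinationGrid, path, header_comment: str | None = None):
    rows = [
        {"dose_a_nM": a, "dose_b_nM": b, "response": grid.measured[i, j]}
        for i, a in enumerate(grid.doses_a)
        for j, b in enumerate(grid.doses_b)
    ]
    _write_lines(path, pd.DataFrame(rows), "\t", header_comment)


def write_synergy_tsv(result: SynergyMatrix, path, header_comment: str | None = None):
    grid = result.grid
    rows = [
        {
            "dose_a_nM": a,
            "dose_b_nM": b,
            "measured": grid.measured[i, j],
            "expected": result.expected[i, j],
            "score": result.scores[i, j],
            "clamped": bool(result.clamped[i, j]),
        }
        for i, a in enumerate(grid.doses_a)
        for j, b in enumerate(grid.doses_b)
    ]
    _write_lines(path, pd.DataFrame(rows), "\t", header_comment)
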