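"""Tabular I/O for the pipeline.

All files are plain TSV (UTF-8, period decimal separator, no quoting).
Protein-group tables follow a MaxQuant-proteinGroups-like dialect with one
file per replicate; a missing, empty, ``NaN`` or em-dash ("—") ratio cell
parses to null, and null ratios are never silently converted to zero or
dropped.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

#: Column names of the protein-group TSV dialect.
DIALECT = {
    "protein_id": "Majority protein IDs",
    "gene_name": "Gene names",
    "intensity_h": "Intensity H",
    "intensity_l": "Intensity L",
    "ratio_hl": "Ratio H/L",
    "ratio_hl_norm": "Ratio H/L normalized",  # optional on read
    "ratio_count": "Ratio H/L count",
}

REQUIRED_DIALECT_KEYS = (
    "protein_id",
    "gene_name",
    "intensity_h",
    "intensity_l",
    "ratio_hl",
    "ratio_count",
)

NULL_TOKENS = {"", "—", "-", "NaN", "nan", "NA"}

#: Genes of the packaged worked example curated as tier III by default.
DEFAULT_CURATED = ("MYO1C", "MYH10", "LIMA1", "PPP1R12A", "MPRIP", "MYO6")


def _parse_number(cell, column: str, line: int, allow_null: bool) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        cell = ""
    text = str(cell).strip()
    if text in NULL_TOKENS:
        if allow_null:
            return np.nan
        raise FormatError(f"line {line}: missing value in column '{column}'")
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"line {line}: non-numeric value '{text}' in column '{column}'"
        ) from None


def read_protein_groups(
    path: str | Path,
    replicate: int,
    dialect: Mapping[str, str] = DIALECT,
) -> pd.DataFrame:
    """Read one replicate's protein-group table.

    Returns a DataFrame with the internal column names (``protein_id``,
    ``gene_name``, ``intensity_h``, ``intensity_l``, ``ratio_hl``,
    ``ratio_count``, ``ratio_provenance``) plus a ``replicate`` column set
    to the given index. Raises :class:`FormatError` when a required column
    is absent or an intensity cell is non-numeric (with its line number).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in REQUIRED_DIALECT_KEYS:
        column = dialect[key]
        if column not in raw.columns:
            raise FormatError(f"{path}: missing required column '{column}'")
    records = pd.DataFrame()
    records["protein_id"] = raw[dialect["protein_id"]].astype(str)
    records["gene_name"] = raw[dialect["gene_name"]].fillna("").astype(str)
    lines = raw.index + 2  # header is line 1
    for key in ("intensity_h", "intensity_l"):
        records[key] = [
            _parse_number(cell, dialect[key], line, allow_null=False)
            for cell, line in zip(raw[dialect[key]], lines)
        ]
    records["ratio_hl"] = [
        _parse_number(cell, dialect["ratio_hl"], line, allow_null=True)
        for cell, line in zip(raw[dialect["ratio_hl"]], lines)
    ]
    counts = [
        _parse_number(cell, dialect["ratio_count"], line, allow_null=True)
        for cell, line in zip(raw[dialect["ratio_count"]], lines)
    ]
    records["ratio_count"] = [0 if np.isnan(c) else int(c) for c in counts]
    records["replicate"] = replicate
    records["ratio_provenance"] = np.where(records["ratio_hl"].notna(), "computed", "none")
    bad = records["ratio_hl"].notna() & (records["ratio_hl"] <= 0)
    if bad.any():
        line = int(lines[bad.to_numpy()][0])
        raise FormatError(f"line {line}: ratio must be positive when present")
    return records


def write_protein_groups(records: pd.DataFrame, path: str | Path) -> None:
    """Write one replicate's protein-group table in the dialect."""
    out = pd.DataFrame(
        {
            DIALECT["protein_id"]: records["protein_id"],
            DIALECT["gene_name"]: records["gene_name"],
            DIALECT["intensity_h"]: records["intensity_h"],
            DIALECT["intensity_l"]: records["intensity_l"],
            DIALECT["ratio_hl"]: records["ratio_hl"],
            DIALECT["ratio_count"]: records["ratio_count"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="")


TABLE1_REPLICATES = ("log2_ap1", "log2_ap2", "log2_ap3")


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 42-row worked-example table.

    Columns: ``uniprot_id``, ``protein_name``, ``gene_name``, one printed
    per-replicate log2(H/L) column per purification (``log2_ap1``..``3``,
    nullable), and the ``class_label`` (I/II/III) the original analysis
    assigned. One accession (D6RGI3) appears twice as printed; ``gene_name``
    is the primary key.
    """
    source = importlib.resources.files("silacmap.data").joinpath("table1.tsv")
    with importlib.resources.as_file(source) as path:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in TABLE1_REPLICATES:
        table[column] = [
            _parse_number(cell, column, line, allow_null=True)
            for cell, line in zip(table[column], table.index + 2)
        ]
    return table


def read_precomputed_log2(path: str | Path) -> pd.DataFrame:
    """Read a precomputed-log2 table: ``gene_name``, one ``log2_ap<k>``
    column per replicate, optional ``significant_ap<k>`` flag columns
    (0/1/true/false)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_name" not in table.columns:
        raise FormatError(f"{path}: missing required column 'gene_name'")
    log2_cols = sorted(c for c in table.columns if c.startswith("log2_ap"))
    if not log2_cols:
        raise FormatError(f"{path}: no 'log2_ap<k>' columns found")
    for column in log2_cols:
        table[column] = [
            _parse_number(cell, column, line, allow_null=True)
            for cell, line in zip(table[column], table.index + 2)
        ]
    for column in [c for c in table.columns if c.startswith("significant_ap")]:
        table[column] = (
            table[column].str.strip().str.lower().isin({"1", "true", "yes"})
        )
    return table


_KEY_CANDIDATES = (
    "gene_name",
    "Gene names",
    "Gene name",
    "uniprot_id",
    "Majority protein IDs",
    "Protein IDs",
)


def read_wide_stats_table(path: str | Path) -> tuple[pd.DataFrame, str, list[str], list[str]]:
    """Read a wide per-protein statistics table (one row per protein, one
    normalized-log2 and one outlier-p column per replicate), auto-detecting
    the key column and the per-replicate column pairs.

    Intended for externally produced evaluation tables whose exact header
    wording varies. Returns ``(table, key_column, log2_columns, p_columns)``
    with the log2/p columns in replicate order.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    key = next((c for c in _KEY_CANDIDATES if c in table.columns), None)
    if key is None:
        raise FormatError(f"{path}: no recognisable key column among {_KEY_CANDIDATES}")
    log2_cols = [
        c
        for c in table.columns
        if ("log2" in c.lower() or "normalized" in c.lower()) and c != key
    ]
    p_cols = [c for c in table.columns if "significance b" in c.lower() or "sigb" in c.lower()]
    if not log2_cols or not p_cols:
        raise FormatError(f"{path}: could not detect per-replicate log2/p column pairs")
    for column in log2_cols + p_cols:
        table[column] = [
            _parse_number(cell, column, line, allow_null=True)
            for cell, line in zip(table[column], table.index + 2)
        ]
    return table, key, sorted(log2_cols), sorted(p_cols)


def read_curated_list(path: str | Path) -> list[str]:
    """Curated-gene file: one gene name per line; blank lines and ``#``
    comments ignored."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            genes.append(name)
    return genes


def read_annotations(path: str | Path) -> dict[str, str]:
    """Annotation TSV (gene_name, category) to a mapping."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene_name", "category"}.issubset(table.columns):
        raise FormatError(f"{path}: annotation file needs columns gene_name, category")
    return dict(zip(table["gene_name"], table["category"]))


def write_results(
    assignments: pd.DataFrame,
    significance: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the result tables with a deterministic column order.

    Produces ``candidates.tsv`` (one row per protein with tier and
    category) and, when significance results exist, ``significance.tsv``
    (one row per protein per replicate). Written floats round-trip at full
    printed precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    candidates = out_dir / "candidates.tsv"
    assignments.to_csv(candidates, sep="\t", index=False, na_rep="")
    paths["candidates"] = candidates
    if significance is not None:
        sig_path = out_dir / "significance.tsv"
        significance.to_csv(sig_path, sep="\t", index=False, na_rep="")
        paths["significance"] = sig_path
    return paths


def read_candidates(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for ``candidates.tsv``."""
    return pd.read_csv(path, sep="\t", keep_default_na=True, na_values=[""])
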