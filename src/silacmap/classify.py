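"""Replicate-based interactor classification and interaction-map export.

A protein is *enriched* in a replicate when its normalized log2(H/L)
strictly exceeds the enrichment threshold (default 2, i.e. four-fold), and
*significant* when its intensity-binned outlier p-value is strictly below
alpha (default 0.05). Candidates are then tiered:

* tier I  — enriched AND significant in at least two replicates;
* tier II — enriched-and-significant in exactly one replicate, or enriched
  in at least two replicates without reaching tier I;
* tier III — below those thresholds but on a user-supplied curated list
  (manual curation by biological function);
* none    — everything else.

Precedence is I > II > III: curation never demotes a tier I/II call.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_tables import DEFAULT_CURATED, TABLE1_REPLICATES

logger = logging.getLogger(__name__)

DEFAULT_LOG2_THRESHOLD = 2.0
DEFAULT_ALPHA = 0.05

#: Functional-category vocabulary for annotating called interactors.
CATEGORIES = (
    "cytoskeleton associated",
    "proliferation, differentiation and apoptosis",
    "cell surface",
    "metabolism",
    "signal transduction",
    "nucleic acid associated",
    "plasma membrane associated",
)
UNASSIGNED = "unassigned"

TIERS = ("I", "II", "III", "none")
_TIER_RANK = {tier: rank for rank, tier in enumerate(TIERS)}

FLAG_COLUMNS = [
    "protein_id",
    "gene_name",
    "replicate",
    "log2_hl_norm",
    "detected",
    "enriched",
    "significant",
]


def replicate_flags(
    scored: pd.DataFrame,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-protein per-replicate detection/enrichment/significance flags.

    ``scored`` needs columns ``protein_id``, ``gene_name``, ``replicate``,
    ``log2_hl_norm`` (nullable) and ``p_sigb`` (nullable). A missing ratio
    yields ``detected = enriched = significant = False``; both thresholds
    are strict inequalities.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    out = scored.copy()
    log2 = out["log2_hl_norm"]
    p = out["p_sigb"] if "p_sigb" in out.columns else pd.Series(np.nan, index=out.index)
    out["detected"] = log2.notna()
    out["enriched"] = log2.notna() & (log2 > log2_threshold)
    out["significant"] = log2.notna() & p.notna() & (p < alpha)
    return out[FLAG_COLUMNS]


def assign_tiers(
    flags: pd.DataFrame,
    curated: Iterable[str] = DEFAULT_CURATED,
) -> pd.DataFrame:
    """Collapse per-replicate flags into one tier per protein.

    A curated gene absent from the data is retained with zero counts (and a
    logged warning) so the curation list is always fully accounted for.
    """
    curated = set(curated)
    grouped = (
        flags.assign(both=flags["enriched"] & flags["significant"])
        .groupby(["protein_id", "gene_name"], sort=True)
        .agg(
            n_detected=("detected", "sum"),
            n_enriched=("enriched", "sum"),
            n_enriched_and_significant=("both", "sum"),
        )
        .reset_index()
    )
    grouped["curated"] = grouped["gene_name"].isin(curated)

    def tier_of(row) -> str:
        if row["n_enriched_and_significant"] >= 2:
            return "I"
        if row["n_enriched_and_significant"] == 1 or row["n_enriched"] >= 2:
            return "II"
        if row["curated"]:
            return "III"
        return "none"

    grouped["tier"] = grouped.apply(tier_of, axis=1)

    missing = sorted(curated - set(grouped["gene_name"]))
    if missing:
        logger.warning("curated genes absent from the data: %s", ", ".join(missing))
        extra = pd.DataFrame(
            {
                "protein_id": missing,
                "gene_name": missing,
                "n_detected": 0,
                "n_enriched": 0,
                "n_enriched_and_significant": 0,
                "curated": True,
                "tier": "III",
            }
        )
        grouped = pd.concat([grouped, extra], ignore_index=True)
    cols = [
        "protein_id",
        "gene_name",
        "n_detected",
        "n_enriched",
        "n_enriched_and_significant",
        "curated",
        "tier",
    ]
    return grouped[cols]


def annotate_categories(
    assignments: pd.DataFrame,
    annotation: Mapping[str, str],
    vocabulary: Iterable[str] = CATEGORIES,
) -> pd.DataFrame:
    """Attach a functional category to each assignment.

    Unannotated genes get :data:`UNASSIGNED`; an annotation with a label
    outside the vocabulary raises :class:`ConfigError`. Annotation never
    changes tiers.
    """
    vocabulary = set(vocabulary)
    unknown = sorted(set(annotation.values()) - vocabulary)
    if unknown:
        raise ConfigError(f"unknown category label(s): {', '.join(unknown)}")
    out = assignments.copy()
    out["category"] = [annotation.get(g, UNASSIGNED) for g in out["gene_name"]]
    return out


def build_interaction_map(assignments: pd.DataFrame, bait: str) -> nx.Graph:
    """Bait-centric star graph over all called (tier != none) interactors.

    Nodes carry ``tier`` and ``category`` attributes; node insertion order
    is deterministic (tier I, II, III, then gene name).
    """
    if not bait:
        raise ConfigError("bait gene name must be non-empty")
    graph = nx.Graph()
    graph.add_node(bait, tier="bait", category="bait")
    called = assignments.loc[assignments["tier"] != "none"].copy()
    called["_rank"] = called["tier"].map(_TIER_RANK)
    called = called.sort_values(["_rank", "gene_name"], kind="mergesort")
    for row in called.itertuples():
        category = getattr(row, "category", UNASSIGNED)
        graph.add_node(row.gene_name, tier=row.tier, category=category)
        graph.add_edge(bait, row.gene_name)
    return graph


def export_sif(graph: nx.Graph, path) -> None:
    """Write the map as SIF lines ``BAIT pp PREY`` (deterministic order)."""
    bait = next(n for n, d in graph.nodes(data=True) if d.get("tier") == "bait")
    lines = [f"{bait} pp {prey}" for prey in graph.neighbors(bait)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def export_node_attributes(graph: nx.Graph, path) -> None:
    """Write node attributes (gene_name, tier, category) as TSV."""
    rows = [
        {"gene_name": n, "tier": d.get("tier", ""), "category": d.get("category", "")}
        for n, d in graph.nodes(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- worked-example helpers -------------------------------------------------

_MYOSIN_ASSOCIATED = {"MPRIP", "PPP1R12A", "MYPT1"}


def is_myosin_related(gene: str) -> bool:
    """Myosin-family or myosin-associated gene, by symbol convention
    (MYO*/MYH*/MYL* motors and light chains) plus the myosin-phosphatase
    regulators MPRIP and PPP1R12A (MYPT1)."""
    symbol = gene.upper()
    return symbol.startswith(("MYO", "MYH", "MYL")) or symbol in _MYOSIN_ASSOCIATED


def reconstruct_table1_flags(
    fixture: pd.DataFrame,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
) -> pd.DataFrame:
    """Per-replicate flags for the packaged worked-example table.

    The printed table carries log2 ratios and final class labels but not
    the per-replicate significance calls, so those are reconstructed by the
    only rule consistent with the class definitions and the printed rows:
    class I rows are significant in every enriched replicate, class II rows
    only in their highest-ratio enriched replicate, class III rows in none.
    """
    rows = []
    for record in fixture.itertuples():
        values = [getattr(record, col) for col in TABLE1_REPLICATES]
        enriched = [v is not None and not np.isnan(v) and v > log2_threshold for v in values]
        if record.class_label == "I":
            significant = enriched
        elif record.class_label == "II":
            best = None
            for i, v in enumerate(values):
                if enriched[i] and (best is None or v > values[best]):
                    best = i
            significant = [i == best for i in range(len(values))]
        else:
            significant = [False] * len(values)
        for i, v in enumerate(values):
            rows.append(
                {
                    "protein_id": record.uniprot_id,
                    "gene_name": record.gene_name,
                    "replicate": i + 1,
                    "log2_hl_norm": v,
                    "detected": not np.isnan(v),
                    "enriched": enriched[i],
                    "significant": significant[i],
                }
            )
    return pd.DataFrame(rows, columns=FLAG_COLUMNS)


def tiers_from_wide_table(
    table: pd.DataFrame,
    key: str,
    log2_cols: list[str],
    p_cols: list[str],
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    curated: Iterable[str] = (),
) -> pd.DataFrame:
    """Recompute tiers from a wide per-protein table of normalized log2
    ratios and outlier p-values (one column pair per replicate), as read by
    :func:`silacmap.io_tables.read_wide_stats_table`."""
    if len(log2_cols) != len(p_cols):
        raise ConfigError("need one p column per log2 column")
    rows = []
    for rec in table.to_dict("records"):
        for i, (lc, pc) in enumerate(zip(log2_cols, p_cols), start=1):
            value, p = rec[lc], rec[pc]
            detected = not pd.isna(value)
            rows.append(
                {
                    "protein_id": rec[key],
                    "gene_name": rec[key],
                    "replicate": i,
                    "log2_hl_norm": value if detected else np.nan,
                    "detected": detected,
                    "enriched": detected and value > log2_threshold,
                    "significant": detected and not pd.isna(p) and p < alpha,
                }
            )
    return assign_tiers(pd.DataFrame(rows, columns=FLAG_COLUMNS), curated)


def flags_from_precomputed(
    table: pd.DataFrame,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
) -> pd.DataFrame:
    """Flags from a precomputed-log2 table (see
    :func:`silacmap.io_tables.read_precomputed_log2`).

    Enrichment comes from the log2 columns; significance from the optional
    ``significant_ap<k>`` columns (absent columns mean never significant).
    """
    log2_cols = sorted(c for c in table.columns if re.fullmatch(r"log2_ap\d+", c))
    rows = []
    for record in table.itertuples(index=False):
        rec = record._asdict()
        for i, col in enumerate(log2_cols, start=1):
            value = rec[col]
            detected = value is not None and not pd.isna(value)
            sig = bool(rec.get(f"significant_ap{i}", False))
            rows.append(
                {
                    "protein_id": rec.get("uniprot_id", rec["gene_name"]),
                    "gene_name": rec["gene_name"],
                    "replicate": i,
                    "log2_hl_norm": value if detected else np.nan,
                    "detected": detected,
                    "enriched": detected and value > log2_threshold,
                    "significant": detected and sig,
                }
            )
    return pd.DataFrame(rows, columns=FLAG_COLUMNS)
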