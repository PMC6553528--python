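"""End-to-end composition of the analysis stages.

``run_classify`` applies the stages in order — manual ratio fill, per-
replicate median normalization, intensity-binned outlier statistic,
replicate flags, tiering, annotation, map export — and writes the result
tables plus a JSON run manifest capturing every tunable, so a run can be
reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import classify, io_tables, ratios, significance, synthetic
from .errors import ConfigError, SilacMapError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the classification pipeline."""

    intensity_threshold: float = 1e6
    min_ratio_count: int = 2
    log2_threshold: float = 2.0
    alpha: float = 0.05
    bin_size: int = 300
    normalize: bool = True
    include_manual_in_median: bool = True
    bait: str = "SEPT9"
    curated: tuple[str, ...] = io_tables.DEFAULT_CURATED
    annotation: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("intensity_threshold", "log2_threshold", "bin_size", "min_ratio_count"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["curated"] = list(self.curated)
        return out

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "curated" in raw:
            raw["curated"] = tuple(raw["curated"])
        return cls(**raw)


def _write_manifest(out_dir: Path, payload: dict) -> None:
    try:
        pkg_version = _pkg_version("silacmap")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    payload = dict(payload, package_version=pkg_version)
    (out_dir / "manifest.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_simulate(
    sim_config: synthetic.SimConfig,
    out_dir: str | Path,
    min_ratio_count: int = 2,
    force: bool = False,
) -> dict[str, Path]:
    """Simulate one experiment and write per-replicate protein-group TSVs,
    a ground-truth TSV and a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    existing = sorted(out_dir.glob("replicate_*.tsv"))
    if existing and not force:
        raise SilacMapError(
            f"{out_dir} already contains replicate files; pass force=True to overwrite"
        )
    observations, truth = synthetic.simulate_experiment(sim_config)
    groups = synthetic.aggregate_to_protein_groups(observations, min_ratio_count)
    paths: dict[str, Path] = {}
    for rep in range(1, sim_config.n_replicates + 1):
        rep_path = out_dir / f"replicate_{rep}.tsv"
        io_tables.write_protein_groups(
            groups.loc[groups["replicate"] == rep], rep_path
        )
        paths[f"replicate_{rep}"] = rep_path
    truth_path = out_dir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["ground_truth"] = truth_path
    _write_manifest(
        out_dir,
        {"stage": "simulate", "sim_config": sim_config.to_dict(), "min_ratio_count": min_ratio_count},
    )
    return paths


def classify_protein_groups(
    records: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """Run the in-memory pipeline on combined per-replicate protein groups.

    Returns the intermediate and final frames: ``normalized``,
    ``significance``, ``flags``, ``assignments`` and ``ip_specific``.
    """
    config.validate()
    filled = ratios.manual_ratio_fill(records, config.intensity_threshold)
    n_manual = int((filled["ratio_provenance"] == "manual").sum())
    n_ip = int(filled["ip_specific"].sum())
    logger.info("manual ratio fills: %d; IP-specific proteins: %d", n_manual, n_ip)
    normalized = ratios.normalize_all(
        filled, config.include_manual_in_median, center=config.normalize
    )
    sig_parts = []
    for _, group in normalized.groupby("replicate", sort=True):
        sig_parts.append(significance.significance_b(group, config.bin_size))
    sig = pd.concat(sig_parts, ignore_index=True)

    scored = normalized.merge(
        sig[["protein_id", "replicate", "p_sigb", "bin_index", "side"]],
        on=["protein_id", "replicate"],
        how="left",
    )
    flags = classify.replicate_flags(scored, config.log2_threshold, config.alpha)
    assignments = classify.assign_tiers(flags, config.curated)
    assignments = classify.annotate_categories(assignments, config.annotation)
    ip_specific = normalized.loc[normalized["ip_specific"]].copy()
    return {
        "normalized": normalized,
        "significance": sig,
        "flags": flags,
        "assignments": assignments,
        "ip_specific": ip_specific,
    }


def run_classify(
    replicate_paths: Sequence[str | Path],
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Read per-replicate protein-group TSVs, classify, and write results."""
    if not replicate_paths:
        raise SilacMapError("need at least one replicate file")
    frames = [
        io_tables.read_protein_groups(path, replicate=i)
        for i, path in enumerate(replicate_paths, start=1)
    ]
    records = pd.concat(frames, ignore_index=True)
    if records.empty:
        raise SilacMapError("replicate files contain no records")
    results = classify_protein_groups(records, config)
    return _write_outputs(results, config, out_dir, extra={"replicates": [str(p) for p in replicate_paths]})


def run_classify_precomputed(
    path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Classify a precomputed-log2 table (gene, log2 per replicate,
    optional per-replicate significance flags); the ratio and statistic
    stages are skipped."""
    table = io_tables.read_precomputed_log2(path)
    flags = classify.flags_from_precomputed(table, config.log2_threshold)
    assignments = classify.assign_tiers(flags, config.curated)
    assignments = classify.annotate_categories(assignments, config.annotation)
    results = {
        "normalized": None,
        "significance": None,
        "flags": flags,
        "assignments": assignments,
        "ip_specific": None,
    }
    return _write_outputs(results, config, out_dir, extra={"precomputed_log2": str(path)})


def _write_outputs(
    results: dict,
    config: PipelineConfig,
    out_dir: str | Path,
    extra: dict | None = None,
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignments = results["assignments"]
    flags = results["flags"]
    wide_flags = flags.pivot_table(
        index=["protein_id", "gene_name"],
        columns="replicate",
        values=["log2_hl_norm", "enriched", "significant"],
        aggfunc="first",
    )
    wide_flags.columns = [f"{a}_ap{b}" for a, b in wide_flags.columns]
    candidates = assignments.merge(
        wide_flags.reset_index(), on=["protein_id", "gene_name"], how="left"
    )
    paths = io_tables.write_results(candidates, results["significance"], out_dir)
    if results["ip_specific"] is not None:
        ip_path = out_dir / "ip_specific.tsv"
        results["ip_specific"].to_csv(ip_path, sep="\t", index=False, na_rep="")
        paths["ip_specific"] = ip_path
    graph = classify.build_interaction_map(assignments, config.bait)
    sif_path = out_dir / "map.sif"
    classify.export_sif(graph, sif_path)
    paths["map"] = sif_path
    nodes_path = out_dir / "map_nodes.tsv"
    classify.export_node_attributes(graph, nodes_path)
    paths["map_nodes"] = nodes_path
    _write_manifest(out_dir, {"stage": "classify", "config": config.to_dict(), **(extra or {})})
    return paths


def run_report(results_dir: str | Path) -> str:
    """Summarise a results directory: tier counts, category breakdown and
    the parameters the run used."""
    results_dir = Path(results_dir)
    candidates_path = results_dir / "candidates.tsv"
    if not candidates_path.exists():
        raise SilacMapError(f"no candidates.tsv in {results_dir}")
    candidates = io_tables.read_candidates(candidates_path)
    lines = []
    for tier in ("I", "II", "III"):
        count = int((candidates["tier"] == tier).sum()) if len(candidates) else 0
        lines.append(f"Class {tier}: {count}")
    called = candidates.loc[candidates["tier"].isin(["I", "II", "III"])] if len(candidates) else candidates
    if "category" in candidates.columns and len(called):
        lines.append("Categories:")
        for category, count in called["category"].value_counts().sort_index().items():
            lines.append(f"  {category}: {count}")
    manifest_path = results_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        lines.append("Parameters:")
        for key, value in sorted(manifest.get("config", {}).items()):
            lines.append(f"  {key} = {value}")
    return "\n".join(lines)
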