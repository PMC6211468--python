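"""End-to-end orchestration: ingest → build → screen → null → enrich → report.

Each stage reads the previous stage's serialised artifacts from the run
directory and writes its own, so any stage can be re-run standalone with
results identical to the end-to-end run.  Canonical artifact names:

    putative_targets.tsv, disease_targets.tsv, ppi_merged.tsv   (ingest)
    network.graphml, network_summary.json                       (build)
    screen.tsv, screen_summary.json                             (screen)
    null_report.json, null_replicates.tsv                       (null)
    enrichment.tsv, enrichment_summary.json, modules.json       (enrich)
    report.json                                                 (report)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as npio
from . import __version__
from .enrichment import assign_modules, enrich, results_frame, significant_pathways, top_pathways
from .network import build_interaction_network, network_summary
from .nullmodel import null_screen
from .synthetic import SyntheticConfig, generate_study_fixture, write_dataset
from .topology import PAPER_THRESHOLDS, ScreenThresholds, screen_network

logger = logging.getLogger(__name__)

STAGES = ("ingest", "build", "screen", "null", "enrich", "report")

_DEFAULTS: dict[str, Any] = {
    "inputs": {
        "herb_target_tables": [],      # list of {path, label}
        "disease_target_tables": [],   # list of {path, label}
        "ppi_tables": [],              # list of {path, label}
        "gene_sets": None,
        "id_map": None,
    },
    "network": {
        "expansion_rule": "first_neighbor",
    },
    "screen": {
        "hub_factor": 2.0,
        "threshold_mode": "median_derived",   # median_derived | explicit | paper
        "degree_min": None,
        "betweenness_min": None,
        "closeness_min": None,
        "coreness_min": None,
        "profile_graph": "hub_subnetwork",
        "disconnected_rule": "wf",
    },
    "null_model": {
        "enabled": True,
        "replicates": 100,
    },
    "enrichment": {
        "enabled": True,
        "alpha": 0.05,
        "use_q": False,
        "top_k": 10,
        "universe": "network",                # network | annotation
        "category_map": None,
    },
    "seed": 0,
    "output_dir": "netpharm_run",
}


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid; lists all violations."""


def _merge_defaults(defaults: dict, given: dict, prefix: str, errors: list[str]) -> dict:
    out = {}
    for key, default in defaults.items():
        if isinstance(default, dict) and key in given and not isinstance(given[key], dict):
            errors.append(f"{prefix}{key}: expected a mapping")
            out[key] = default
        elif isinstance(default, dict):
            out[key] = _merge_defaults(default, given.get(key, {}), f"{prefix}{key}.", errors)
        else:
            out[key] = given.get(key, default)
    for key in given:
        if key not in defaults:
            errors.append(f"{prefix}{key}: unknown key")
    return out


def validate_config(source: str | Path | dict) -> dict:
    """Load and validate a pipeline config, filling defaults.

    ``source`` may be a YAML path or an already-parsed mapping.  Unknown
    keys are rejected and all schema violations are reported together.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            raw = yaml.safe_load(handle) or {}
        base = Path(source).parent
    else:
        raw, base = dict(source), Path(".")
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    config = _merge_defaults(_DEFAULTS, raw, "", errors)

    def _resolve(path):
        p = Path(path)
        return p if p.is_absolute() else base / p

    for section in ("herb_target_tables", "disease_target_tables", "ppi_tables"):
        entries = config["inputs"][section]
        if not isinstance(entries, list):
            errors.append(f"inputs.{section}: expected a list")
            continue
        normalised = []
        for entry in entries:
            if isinstance(entry, str):
                entry = {"path": entry, "label": Path(entry).stem}
            if not isinstance(entry, dict) or "path" not in entry:
                errors.append(f"inputs.{section}: each entry needs a 'path'")
                continue
            entry = {"path": str(_resolve(entry["path"])), "label": entry.get("label", Path(entry["path"]).stem)}
            if not Path(entry["path"]).exists():
                errors.append(f"inputs.{section}: missing file {entry['path']}")
            normalised.append(entry)
        config["inputs"][section] = normalised
    for key in ("gene_sets", "id_map"):
        if config["inputs"][key] is not None:
            resolved = str(_resolve(config["inputs"][key]))
            if not Path(resolved).exists():
                errors.append(f"inputs.{key}: missing file {resolved}")
            config["inputs"][key] = resolved
    if config["enrichment"]["category_map"] is not None:
        config["enrichment"]["category_map"] = str(_resolve(config["enrichment"]["category_map"]))

    if config["screen"]["hub_factor"] is None or config["screen"]["hub_factor"] <= 0:
        errors.append("screen.hub_factor: must be positive")
    if config["screen"]["threshold_mode"] not in ("median_derived", "explicit", "paper"):
        errors.append("screen.threshold_mode: expected median_derived, explicit or paper")
    if config["screen"]["threshold_mode"] == "explicit":
        for key in ("degree_min", "betweenness_min", "closeness_min", "coreness_min"):
            if config["screen"][key] is None:
                errors.append(f"screen.{key}: required in explicit mode")
    if not isinstance(config["seed"], int):
        errors.append("seed: must be an integer")
    if config["null_model"]["replicates"] < 1:
        errors.append("null_model.replicates: must be >= 1")
    if not 0 < config["enrichment"]["alpha"] <= 1:
        errors.append("enrichment.alpha: must lie in (0, 1]")
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return config


def _thresholds_from_config(config: dict) -> ScreenThresholds | None:
    screen = config["screen"]
    if screen["threshold_mode"] == "paper":
        return dataclasses.replace(PAPER_THRESHOLDS, hub_factor=screen["hub_factor"])
    if screen["threshold_mode"] == "explicit":
        return ScreenThresholds(
            degree_min=screen["degree_min"],
            betweenness_min=screen["betweenness_min"],
            closeness_min=screen["closeness_min"],
            coreness_min=screen["coreness_min"],
            hub_factor=screen["hub_factor"],
            mode="explicit",
        )
    return None


def _out_dir(config: dict) -> Path:
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# stages


def stage_ingest(config: dict) -> dict:
    """Read, normalise and merge all declared inputs; write canonical tables."""
    out = _out_dir(config)
    inputs = config["inputs"]
    id_map = npio.read_id_map(inputs["id_map"]) if inputs["id_map"] else {}

    def _load_targets(entries, tag):
        sets = []
        for entry in entries:
            ts = npio.read_target_table(entry["path"], source_label=entry["label"], tag=tag)
            if id_map:
                ts = npio.apply_id_map(ts, id_map)
            sets.append(ts)
        return sets

    herb_sets = _load_targets(inputs["herb_target_tables"], "herb")
    disease_sets = _load_targets(inputs["disease_target_tables"], "disease")
    if not herb_sets and not disease_sets:
        raise ConfigError("no target tables declared")
    putative = npio.merge_target_sets(herb_sets) if herb_sets else npio.TargetSet()
    disease = npio.merge_target_sets(disease_sets) if disease_sets else npio.TargetSet()

    ppi_parts = [
        npio.read_edge_list(entry["path"], source_label=entry["label"])
        for entry in inputs["ppi_tables"]
    ]
    if not ppi_parts:
        raise ConfigError("no PPI tables declared")
    ppi = npio.merge_ppi_sources(ppi_parts)

    putative.to_frame().to_csv(out / "putative_targets.tsv", sep="\t", index=False)
    disease.to_frame().to_csv(out / "disease_targets.tsv", sep="\t", index=False)
    ppi.to_frame().to_csv(out / "ppi_merged.tsv", sep="\t", index=False)
    summary = {
        "n_putative_targets": len(putative),
        "n_disease_targets": len(disease),
        "per_herb_table_counts": {e["label"]: len(s) for e, s in zip(inputs["herb_target_tables"], herb_sets)},
        "per_disease_table_counts": {e["label"]: len(s) for e, s in zip(inputs["disease_target_tables"], disease_sets)},
        "n_ppi_edges": len(ppi),
        "n_ppi_nodes": len(ppi.node_ids),
    }
    if len(herb_sets) == 2:
        summary["herb_target_overlap"] = len(npio.intersect_target_sets(herb_sets[0], herb_sets[1]))
    _write_json(out / "ingest_summary.json", summary)
    return summary


def _read_ingested(config: dict):
    out = _out_dir(config)
    putative = npio.read_target_table(out / "putative_targets.tsv", source_label="putative")
    disease = npio.read_target_table(out / "disease_targets.tsv", source_label="disease")
    ppi = npio.read_edge_list(out / "ppi_merged.tsv")
    return putative, disease, ppi


def stage_build(config: dict) -> dict:
    """Assemble and label the interaction network; export GraphML + summary."""
    out = _out_dir(config)
    putative, disease, ppi = _read_ingested(config)
    network = build_interaction_network(
        putative, disease, ppi, expansion_rule=config["network"]["expansion_rule"]
    )
    npio.write_network(network, out / "network.graphml", format="graphml")
    summary = network_summary(network)
    _write_json(out / "network_summary.json", summary)
    return summary


def stage_screen(config: dict) -> dict:
    """Two-stage hub → major-hub screen on the built network."""
    out = _out_dir(config)
    network = npio.read_network(out / "network.graphml")
    result = screen_network(
        network,
        hub_factor=config["screen"]["hub_factor"],
        thresholds=_thresholds_from_config(config),
        profile_graph=config["screen"]["profile_graph"],
        disconnected_rule=config["screen"]["disconnected_rule"],
    )
    table = result.to_frame()
    table.to_csv(out / "screen.tsv", sep="\t")
    summary = {
        "n_hubs": len(result.hub_ids),
        "n_major_hubs": len(result.major_hub_ids),
        "major_hub_class_counts": result.class_counts,
        "thresholds_used": result.thresholds_used.as_dict(),
        "major_hub_ids": sorted(result.major_hub_ids),
    }
    _write_json(out / "screen_summary.json", summary)
    return summary


def stage_null(config: dict) -> dict:
    """Erdős–Rényi null contrast with the same threshold policy."""
    out = _out_dir(config)
    network = npio.read_network(out / "network.graphml")
    report = null_screen(
        network,
        n_replicates=config["null_model"]["replicates"],
        base_seed=config["seed"],
        thresholds=_thresholds_from_config(config),
        hub_factor=config["screen"]["hub_factor"],
    )
    _write_json(out / "null_report.json", report.to_dict())
    report.to_frame().to_csv(out / "null_replicates.tsv", sep="\t", index=False)
    return report.to_dict()


def stage_enrich(config: dict) -> dict:
    """Over-representation of the major hubs against the gene-set annotation."""
    out = _out_dir(config)
    gmt = config["inputs"]["gene_sets"]
    if gmt is None:
        raise ConfigError("enrichment requires inputs.gene_sets")
    annotation = npio.read_gene_sets(gmt)
    screen_summary = json.loads((out / "screen_summary.json").read_text())
    query = screen_summary["major_hub_ids"]
    if config["enrichment"]["universe"] == "network":
        network = npio.read_network(out / "network.graphml")
        universe = network.node_ids & annotation.universe
    else:
        universe = annotation.universe
    results = enrich(query, annotation, universe=universe)
    results_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    alpha, use_q = config["enrichment"]["alpha"], config["enrichment"]["use_q"]
    significant = significant_pathways(results, alpha=alpha, use_q=use_q)
    top = top_pathways(results, k=config["enrichment"]["top_k"], alpha=alpha, use_q=use_q)
    summary = {
        "universe_rule": config["enrichment"]["universe"],
        "universe_size": len(universe),
        "n_tested": len(results),
        "alpha": alpha,
        "use_q": use_q,
        "n_significant": len(significant),
        "significant": [r.name for r in significant],
        "top_pathways": [
            {"pathway": r.name, "p_value": r.p_value, "q_value": r.q_value, "k": r.k, "K": r.K}
            for r in top
        ],
    }
    if config["enrichment"]["category_map"]:
        # pathway names are not identifiers: no case normalisation here
        category_map = _read_category_map(config["enrichment"]["category_map"])
        modules = assign_modules(significant, category_map)
        _write_json(out / "modules.json", modules)
        summary["modules"] = {name: module["n_members"] for name, module in modules.items()}
    _write_json(out / "enrichment_summary.json", summary)
    return summary


def _read_category_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2 and fields[0].strip():
                mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def stage_report(config: dict) -> dict:
    """Bundle all stage summaries plus config echo into report.json."""
    out = _out_dir(config)
    report: dict[str, Any] = {
        "netpharm_version": __version__,
        "seed": config["seed"],
        "config": config,
    }
    for name, filename in [
        ("ingest", "ingest_summary.json"),
        ("network", "network_summary.json"),
        ("screen", "screen_summary.json"),
        ("null_model", "null_report.json"),
        ("enrichment", "enrichment_summary.json"),
    ]:
        path = out / filename
        if path.exists():
            report[name] = json.loads(path.read_text())
    _write_json(out / "report.json", report)
    return report


def run_pipeline(config: dict | str | Path) -> dict:
    """Run every stage in order and return the bundled report."""
    config = validate_config(config) if not _is_validated(config) else config
    stage_ingest(config)
    stage_build(config)
    stage_screen(config)
    if config["null_model"]["enabled"]:
        stage_null(config)
    if config["enrichment"]["enabled"] and config["inputs"]["gene_sets"]:
        stage_enrich(config)
    return stage_report(config)


def _is_validated(config) -> bool:
    return isinstance(config, dict) and set(_DEFAULTS) <= set(config)


# ---------------------------------------------------------------------------
# simulation entry point


def simulate_to_dir(
    out_dir: str | Path,
    synthetic_overrides: dict | None = None,
    seed: int | None = None,
) -> tuple[Path, dict]:
    """Write a synthetic study to ``out_dir`` plus a ready-to-run pipeline config.

    The emitted config points at the generated files and analyses them under
    the study conditions the fixture emulates: the synthetic PPI *is* the
    study network, so the expansion rule is ``full`` and the hub cutoff is
    the twofold median degree.
    """
    overrides = dict(synthetic_overrides or {})
    if seed is not None:
        overrides["seed"] = seed
    if "pathway_size_range" in overrides:
        overrides["pathway_size_range"] = tuple(overrides["pathway_size_range"])
    if "disease_sources" in overrides:
        overrides["disease_sources"] = tuple(
            (str(lbl), int(cnt)) for lbl, cnt in overrides["disease_sources"]
        )
    elif "n_disease_targets" in overrides:
        # keep the default source proportions when only the total is changed
        total = overrides["n_disease_targets"]
        defaults = SyntheticConfig.__dataclass_fields__["disease_sources"].default
        default_total = sum(count for _, count in defaults)
        scaled = [(label, count * total // default_total) for label, count in defaults]
        deficit = total - sum(count for _, count in scaled)
        if scaled and deficit:
            scaled[0] = (scaled[0][0], scaled[0][1] + deficit)
        overrides["disease_sources"] = tuple(scaled)
    synth_config = SyntheticConfig(**overrides)
    dataset = generate_study_fixture(synth_config)
    out = Path(out_dir).resolve()
    paths = write_dataset(dataset, out)
    pipeline_config = {
        "inputs": {
            "herb_target_tables": [
                {"path": str(paths["herb_a"]), "label": "herb_a"},
                {"path": str(paths["herb_b"]), "label": "herb_b"},
            ],
            "disease_target_tables": [{"path": str(paths["disease"]), "label": "disease"}],
            "ppi_tables": [{"path": str(paths["ppi"]), "label": "synthetic_ppi"}],
            "gene_sets": str(paths["gene_sets"]),
        },
        "network": {"expansion_rule": "full"},
        "seed": synth_config.seed,
        "output_dir": str(out / "run"),
    }
    config_path = out / "pipeline_config.yaml"
    config_path.write_text(yaml.safe_dump(pipeline_config, sort_keys=True))
    return config_path, dataset.truth
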