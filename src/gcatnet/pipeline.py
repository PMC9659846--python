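"""End-to-end GCAT runs: configuration, orchestration, artifact writing.

A run reads the wild-type structure, builds its AAN, computes rASA and the
SE/buried split, obtains the 19·N mutants from the configured provider,
builds and classifies the GCAT network, runs the attribute sub-network
analyses, and writes Gephi-compatible exports plus CSV/JSON reports and a
manifest. Runs are deterministic: the same config and inputs reproduce the
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import gcatnet
from gcatnet.aan import build_aan, write_edge_csv, write_gexf, write_graphml
from gcatnet.gcat import (
    aggregate_influences,
    build_gcat,
    category_counts,
    classify_gcat,
    excluded_positions,
    mean_degree,
)
from gcatnet.measures import AnnotationTable, influence_mixing
from gcatnet.mutants import (
    DEFAULT_NAMING,
    load_external_mutants,
    naive_mutant_set,
)
from gcatnet.structure_io import ResidueId, read_pdb
from gcatnet.surface import SE, classify_se, compute_rasa, rasa_table_frame

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Everything a reproducible GCAT run needs."""

    wt_pdb: str
    output_dir: str
    chains: list[str] | None = None
    cutoff: float = 5.0
    rasa_threshold: float = 0.2
    rasa_scale: str = "Sander"
    rasa_backend: str = "shrake-rupley"
    mutant_provider: str = "naive"
    mutant_dir: str | None = None
    naming_pattern: str = DEFAULT_NAMING
    annotations_csv: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff}")
        if not 0 < self.rasa_threshold < 1:
            raise ConfigError(f"rasa_threshold must be in (0, 1), got {self.rasa_threshold}")
        if self.mutant_provider not in ("naive", "external-dir"):
            raise ConfigError(f"unknown mutant provider {self.mutant_provider!r}")
        if self.mutant_provider == "external-dir" and not self.mutant_dir:
            raise ConfigError("mutant_dir is required with the external-dir provider")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full GCAT run; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    wildtype = read_pdb(config.wt_pdb, chains=config.chains, label="WT")
    logger.info("wild type: %d residues", len(wildtype))

    wt_aan = build_aan(wildtype, cutoff=config.cutoff)
    logger.info("WT AAN: %d nodes, %d edges", wt_aan.number_of_nodes(), wt_aan.number_of_edges())
    write_graphml(wt_aan, out / "wt_aan.graphml")
    write_edge_csv(wt_aan, out / "wt_aan_edges.csv")

    rasa = compute_rasa(
        wildtype,
        max_asa_scale=config.rasa_scale,
        threshold=config.rasa_threshold,
        backend=config.rasa_backend,
    )
    se_classes = classify_se(rasa)
    rasa_table_frame(rasa).to_csv(out / "rasa.csv", index=False)

    if config.mutant_provider == "naive":
        mutant_set = naive_mutant_set(wildtype)
    else:
        mutant_set = load_external_mutants(
            wildtype, config.mutant_dir, naming=config.naming_pattern, chains=config.chains
        )
    logger.info("mutant set (%s): %d structures", mutant_set.provider, len(mutant_set))

    gcat = build_gcat(wt_aan, mutant_set, cutoff=config.cutoff)
    labels = classify_gcat(gcat)
    logger.info(
        "GCAT: %d nodes, %d edges, mean degree %.3f, categories %s",
        gcat.number_of_nodes(), gcat.number_of_edges(), mean_degree(gcat),
        category_counts(labels),
    )

    annotations = _assemble_annotations(config, gcat, se_classes)
    _write_gcat_exports(out, gcat, labels, rasa, annotations)
    reports = _write_reports(out, gcat, annotations)

    manifest = {
        "tool": "gcatnet",
        "version": gcatnet.__version__,
        "config": config.to_dict(),
        "wt_residues": len(wildtype),
        "wt_aan_edges": wt_aan.number_of_edges(),
        "mutants": len(mutant_set),
        "mutant_coverage": {str(k): v for k, v in sorted(mutant_set.coverage().items())},
        "rejected_mutants": mutant_set.rejected,
        "gcat_nodes": gcat.number_of_nodes(),
        "gcat_edges": gcat.number_of_edges(),
        "gcat_mean_degree": mean_degree(gcat) if gcat.number_of_nodes() else None,
        "category_counts": category_counts(labels),
        "excluded_positions": [str(p) for p in excluded_positions(wt_aan, gcat)],
        "reports": reports,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _assemble_annotations(config, gcat, se_classes) -> AnnotationTable:
    """Merge the computed SE flag with any user-supplied annotation CSV."""
    flags: dict[ResidueId, dict[str, bool]] = {
        rid: {"se": cls == SE} for rid, cls in se_classes.items()
    }
    if config.annotations_csv:
        user = AnnotationTable.from_csv(config.annotations_csv)
        for rid, user_flags in user.flags.items():
            flags.setdefault(rid, {}).update(user_flags)
    return AnnotationTable(flags)


def _write_gcat_exports(out, gcat, labels, rasa, annotations) -> None:
    attrs = annotations.attributes()
    export = gcat.copy()
    for node in export.nodes:
        export.nodes[node]["k_in"] = export.in_degree(node)
        export.nodes[node]["k_out"] = export.out_degree(node)
        export.nodes[node]["category"] = labels[node]
        if node in rasa.values:
            export.nodes[node]["rasa"] = round(rasa.values[node], 6)
        for attr in attrs:
            export.nodes[node][attr] = annotations.get(node, attr)
    write_graphml(export, out / "gcat.graphml")
    write_gexf(export, out / "gcat.gexf")
    write_edge_csv(gcat, out / "gcat_edges.csv")

    rows = []
    for node in sorted(gcat.nodes):
        row = {
            "residue_id": str(node),
            "k_in": gcat.in_degree(node),
            "k_out": gcat.out_degree(node),
            "category": labels[node],
            "rasa": round(rasa.values[node], 6) if node in rasa.values else "",
        }
        row.update({attr: int(annotations.get(node, attr)) for attr in attrs})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "gcat_nodes.csv", index=False)


def _write_reports(out, gcat, annotations) -> list[str]:
    reports_dir = out / "reports"
    reports_dir.mkdir(exist_ok=True)
    written = []
    summary_rows = []
    for attr in annotations.attributes():
        for value in (True, False):
            report = influence_mixing(gcat, annotations, attr, value=value)
            name = f"{attr}_{'true' if value else 'false'}"
            report.write_json(reports_dir / f"{name}.json")
            written.append(f"reports/{name}.json")
            summary_rows.append(
                {
                    "attribute": attr,
                    "value": value,
                    "n_nodes": report.n_nodes,
                    "n_edges": report.n_edges,
                    "n_scc": report.n_scc,
                    "global_cc": round(report.global_cc, 6),
                    "n_bidirectional_nodes": report.n_bidirectional_nodes,
                }
            )
    pd.DataFrame(summary_rows).to_csv(reports_dir / "summary.csv", index=False)
    written.append("reports/summary.csv")
    return written


def replay_diffs(diffs_json: str | Path, out_dir: str | Path) -> Path:
    """Rebuild and export a GCAT from precomputed neighborhood diffs.

    The JSON input is a list of ``{"site": "<residue id>", "changed":
    ["<residue id>", ...]}`` objects, one per mutation. This decouples the
    aggregation and measure layers from any structural input.
    """
    data = json.loads(Path(diffs_json).read_text())
    stream = [
        (ResidueId.parse(entry["site"]), [ResidueId.parse(c) for c in entry["changed"]])
        for entry in data
    ]
    gcat = aggregate_influences(stream)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_graphml(gcat, out / "gcat.graphml")
    write_edge_csv(gcat, out / "gcat_edges.csv")
    if gcat.number_of_nodes():
        labels = classify_gcat(gcat)
        rows = [
            {
                "residue_id": str(n),
                "k_in": gcat.in_degree(n),
                "k_out": gcat.out_degree(n),
                "category": labels[n],
            }
            for n in sorted(gcat.nodes)
        ]
        pd.DataFrame(rows).to_csv(out / "gcat_nodes.csv", index=False)
    return out
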