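"""Readers, writers, run configuration, and the end-to-end pipeline.

Interchange formats are deliberately plain: CSV/TSV with explicit headers
for tables, GraphML and SIF for networks (both consumed by standard
viewers such as Cytoscape), JSON for metrics and the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .errors import SchemaError
from .network import (
    CorrelationNetwork,
    NetworkMetrics,
    build_network,
    correlation_matrix,
    edge_overlap,
    network_metrics,
)
from .qpcr import CtTable, expression_table
from .quant import AbundanceMatrix, PeptideTable, SampleSheet, quantify
from .stability import stability_report
from .stats import diff_table

logger = logging.getLogger("cartnet")

__all__ = [
    "RunConfig",
    "read_peptide_table",
    "read_sample_sheet",
    "read_annotation",
    "read_ct_table",
    "read_abundance",
    "write_abundance",
    "write_edges",
    "write_graphml",
    "write_sif",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on; YAML round-trippable."""

    peptide_table: str = "peptide_table.csv"
    sample_sheet: str = "sample_sheet.tsv"
    annotation: str = "annotation.tsv"
    ct_table: str | None = None
    out_dir: str = "results"
    spikein_id: str = "BSA"
    reference_id: str = "MDH1"
    anchor_groups: list[str] | None = None  # None -> auto-detect
    missing_peptide_policy: str = "drop"
    batch_median: str = "per-protein"
    min_detect_fraction: float = 1.0
    r_min: float = 0.8
    alpha: float = 0.05
    fdr: str = "features"
    scale: str = "log2"
    density_universe: str = "connected"
    overlap_signed: bool = False
    stability_grid: list[float] = field(
        default_factory=lambda: [round(0.3 + 0.05 * i, 2) for i in range(13)]
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Readers


def read_peptide_table(path: str | Path, spikein_id: str = "BSA") -> PeptideTable:
    """Read a wide CSV: protein_id, peptide_id, then one column per sample."""
    df = pd.read_csv(path)
    for col in ("protein_id", "peptide_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["protein_id", "peptide_id"])
    if dup.any():
        line = int(dup.idxmax()) + 2  # header + 1-based
        raise SchemaError(f"{path}:{line}: duplicate (protein_id, peptide_id) row")
    data = df.set_index(["protein_id", "peptide_id"])
    table = PeptideTable(data=data, spikein_id=spikein_id)
    table.validate()
    return table


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'sample_id'")
    sheet = SampleSheet(data=df.set_index("sample_id"))
    sheet.validate()
    return sheet


def read_annotation(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "pathway"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    dup = df["protein_id"].duplicated()
    if dup.any():
        raise SchemaError(f"{path}: duplicate protein_id {df['protein_id'][dup].iloc[0]!r}")
    return dict(zip(df["protein_id"], df["pathway"]))


def read_ct_table(path: str | Path, reference_genes=("B2m", "Gapdh", "Actb")) -> CtTable:
    """Read a CSV: gene_id then one column per sample; refs given separately."""
    df = pd.read_csv(path)
    if "gene_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'gene_id'")
    table = CtTable(
        data=df.set_index("gene_id"), reference_genes=tuple(reference_genes)
    )
    table.validate()
    return table


def read_abundance(path: str | Path, sheet: SampleSheet) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sheet.validate(samples=list(df.columns))
    return AbundanceMatrix(values=df, samples=sheet.data.loc[list(df.columns)])


# ---------------------------------------------------------------------------
# Writers


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")
    sidecar = Path(path).with_suffix(".provenance.json")
    sidecar.write_text(json.dumps({"steps": matrix.provenance}, indent=2))


def write_edges(net: CorrelationNetwork, path: str | Path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def write_graphml(net: CorrelationNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def write_sif(net: CorrelationNetwork, path: str | Path) -> None:
    """Simple interaction format: `a <pos|neg> b` per edge."""
    lines = [
        f"{row.protein_a}\t{'pos' if row.sign > 0 else 'neg'}\t{row.protein_b}"
        for row in net.edges.itertuples(index=False)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Quantify -> differential stats -> per-group networks -> stability.

    Deterministic given (inputs, config): writes all outputs under
    ``config.out_dir`` and returns the manifest (also written as
    ``manifest.json``) keyed by config hash and per-output checksums.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    table = read_peptide_table(config.peptide_table, spikein_id=config.spikein_id)
    sheet = read_sample_sheet(config.sample_sheet)
    annotation = read_annotation(config.annotation)
    logger.info("loaded %d proteins x %d samples", len(table.proteins()) - 1,
                len(table.samples()))

    matrix = quantify(
        table,
        sheet,
        spikein_id=config.spikein_id,
        reference_id=config.reference_id,
        anchor_groups=set(config.anchor_groups) if config.anchor_groups else None,
        missing_policy=config.missing_peptide_policy,
        min_detect_fraction=config.min_detect_fraction,
        batch_median=config.batch_median,
    )
    logger.info("quantified %d proteins (%s)", matrix.values.shape[0],
                "; ".join(matrix.provenance))
    abundance_path = out_dir / "abundance.tsv"
    write_abundance(matrix, abundance_path)
    outputs += [abundance_path, abundance_path.with_suffix(".provenance.json")]

    diff = diff_table(
        matrix.values,
        matrix.samples["group"],
        transform="log2" if config.scale == "log2" else "none",
        alpha=config.alpha,
        fdr=config.fdr,
    )
    n_sig = int(diff["significant"].sum())
    logger.info("differential testing: %d/%d significant at alpha=%s (fdr=%s)",
                n_sig, diff.shape[0], config.alpha, config.fdr)
    diff_path = out_dir / "diff_table.tsv"
    diff.drop(columns=["posthoc"]).to_csv(diff_path, sep="\t")
    outputs.append(diff_path)

    if config.ct_table:
        ct = read_ct_table(config.ct_table)
        expr = expression_table(ct)
        expr_path = out_dir / "expression.tsv"
        expr.rename_axis("gene_id").to_csv(expr_path, sep="\t")
        outputs.append(expr_path)

    networks: list[CorrelationNetwork] = []
    metrics: dict[str, NetworkMetrics] = {}
    for group in matrix.groups():
        corr = correlation_matrix(matrix, group, scale=config.scale)
        net = build_network(corr, r_min=config.r_min, alpha=config.alpha)
        networks.append(net)
        m = network_metrics(
            net, annotation=annotation, universe_size=matrix.values.shape[0]
        )
        metrics[group] = m
        logger.info("network %s: %d nodes, %d links, density %.4f",
                    group, m.n_nodes, m.n_links, m.density)
        for writer, suffix in (
            (write_edges, "edges.tsv"),
            (write_graphml, "network.graphml"),
            (write_sif, "network.sif"),
        ):
            path = out_dir / f"{group}.{suffix}"
            writer(net, path)
            outputs.append(path)

    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(
        json.dumps({g: m.to_dict() for g, m in metrics.items()}, indent=2, sort_keys=True)
    )
    outputs.append(metrics_path)

    venn = edge_overlap(networks, signed=config.overlap_signed)
    venn_path = out_dir / "venn.json"
    venn_path.write_text(json.dumps(venn, indent=2, sort_keys=True))
    outputs.append(venn_path)

    stability = {}
    for group in matrix.groups():
        rep = stability_report(
            matrix,
            config.stability_grid,
            group=group,
            alpha=config.alpha,
            scale=config.scale,
        )
        stability[group] = rep.to_dict()
    stability_path = out_dir / "stability.json"
    stability_path.write_text(json.dumps(stability, indent=2, sort_keys=True))
    outputs.append(stability_path)

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {p.name: _file_sha256(p) for p in sorted(outputs)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
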