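"""Per-stratum pipeline orchestration, phylum summaries, and GEXF export.

Eight networks are built by default: one per domestication group within each
fertilization level, plus a combined network per fertilization level. Each
stratum runs the same stages — sample/taxon filtering, all-pairs Spearman,
FDR adjustment, threshold optimization, graph construction, node metrics,
module detection — and the combined networks are additionally screened for
keystone taxa. A run manifest records the selected thresholds and the
counts surviving every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from rhizonet.community import Partition, fast_greedy
from rhizonet.correlation import adjust_fdr, spearman_all_pairs
from rhizonet.datasets import (
    AbundanceTable,
    FilterConfig,
    SampleMetadata,
    TaxonomyTable,
    filter_samples,
    filter_taxa,
)
from rhizonet.errors import InsufficientDataError, ValidationError
from rhizonet.keystones import KeystoneCriteria, identify_keystones
from rhizonet.network import build_network, node_metrics, summarize
from rhizonet.threshold import (
    DEFAULT_FALLBACK,
    DEFAULT_GRID,
    ThresholdScan,
    optimize_threshold,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratumSpec:
    """A subset of samples defined by factor levels (None = any)."""

    label: str
    group: str | None = None
    fertilization: str | None = None

    def sample_ids(self, metadata: SampleMetadata):
        return metadata.samples_where(self.group, self.fertilization)


def default_strata() -> list[StratumSpec]:
    strata = [
        StratumSpec("unfertilized_combined", None, "unfertilized"),
        StratumSpec("fertilized_combined", None, "fertilized"),
    ]
    for fert in ("unfertilized", "fertilized"):
        for group in ("wild", "traditional", "modern"):
            strata.append(StratumSpec(f"{group}_{fert}", group, fert))
    return strata


@dataclass(frozen=True)
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.01
    positive_only: bool = True
    optimize: bool = True
    fixed_threshold: float = DEFAULT_FALLBACK  # used when optimize=False
    grid_min: float = 0.50
    grid_max: float = 0.90
    grid_step: float = 0.01
    fallback: float = DEFAULT_FALLBACK
    criteria: KeystoneCriteria = field(default_factory=KeystoneCriteria)
    min_samples: int = 4
    strata: tuple = ()
    keystone_strata: tuple = ("unfertilized_combined", "fertilized_combined")

    def grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.grid_min, self.grid_max + 1e-9, self.grid_step),
            10,
        )

    def stratum_specs(self) -> list[StratumSpec]:
        return list(self.strata) if self.strata else default_strata()


@dataclass(frozen=True)
class StratumResult:
    label: str
    network: nx.Graph
    summary: "object"
    partition: Partition
    metrics: pd.DataFrame
    threshold_scan: ThresholdScan | None
    keystones: pd.DataFrame | None
    stage_counts: dict


def run_stratum(
    table: AbundanceTable,
    taxonomy: TaxonomyTable,
    spec: StratumSpec,
    metadata: SampleMetadata,
    config: PipelineConfig,
    keystone_filter: bool = False,
) -> StratumResult:
    """Run the full stage sequence for one sample stratum."""
    sample_ids = [s for s in spec.sample_ids(metadata) if s in table.sample_ids]
    if len(sample_ids) < config.min_samples:
        raise InsufficientDataError(
            f"stratum {spec.label!r} has {len(sample_ids)} samples "
            f"(< {config.min_samples})"
        )
    subset = table.subset_samples(sample_ids)
    n_samples_in = subset.n_samples
    subset = filter_samples(subset, config.filters)
    # relative abundances are fixed before the taxon filter so dropping rare
    # taxa does not renormalize the survivors
    rel_full = subset.to_relative()
    filtered = filter_taxa(subset, config.filters)
    rel = rel_full[filtered.taxon_ids]

    cset = adjust_fdr(spearman_all_pairs(rel))
    scan = None
    if config.optimize:
        try:
            scan = optimize_threshold(cset, config.grid(), fallback=config.fallback)
            threshold = scan.selected
        except InsufficientDataError:
            logger.warning(
                "stratum %s: too few taxa for threshold scan; using fallback %.2f",
                spec.label, config.fallback,
            )
            threshold = config.fallback
    else:
        threshold = config.fixed_threshold

    graph = build_network(
        cset,
        threshold=threshold,
        alpha=config.alpha,
        positive_only=config.positive_only,
        phyla=taxonomy.phyla(cset.taxa),
        mean_abundance=rel.mean(axis=0),
    )
    partition = fast_greedy(graph)
    metrics = node_metrics(graph, partition.membership)
    summary = summarize(graph, modularity=partition.modularity)
    keystones = (
        identify_keystones(metrics, config.criteria) if keystone_filter else None
    )
    stage_counts = {
        "samples_in": n_samples_in,
        "samples_retained": subset.n_samples,
        "taxa_in": subset.n_taxa,
        "taxa_retained": filtered.n_taxa,
        "pairs_tested": cset.n_pairs,
        "pairs_fdr_significant": int((cset.pairs["p_adj"] < config.alpha).sum()),
        "edges": graph.number_of_edges(),
        "nodes": graph.number_of_nodes(),
        "threshold": float(threshold),
        "n_keystones": int(len(keystones)) if keystones is not None else None,
    }
    return StratumResult(
        label=spec.label,
        network=graph,
        summary=summary,
        partition=partition,
        metrics=metrics,
        threshold_scan=scan,
        keystones=keystones,
        stage_counts=stage_counts,
    )


def run_pipeline(
    table: AbundanceTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict[str, StratumResult]:
    """Build every configured stratum network; optionally write outputs.

    Strata with too few samples are skipped with a warning. When ``out_dir``
    is given, per-stratum metrics/partition/summary files, GEXF graphs, and
    a manifest JSON are written with stratum-labeled names.
    """
    if config is None:
        config = PipelineConfig()
    metadata.require(table.sample_ids)
    results: dict[str, StratumResult] = {}
    for spec in config.stratum_specs():
        try:
            results[spec.label] = run_stratum(
                table,
                taxonomy,
                spec,
                metadata,
                config,
                keystone_filter=spec.label in config.keystone_strata,
            )
        except InsufficientDataError as exc:
            logger.warning("skipping stratum %s: %s", spec.label, exc)
    if out_dir is not None:
        write_outputs(results, taxonomy, Path(out_dir))
    return results


def write_outputs(results, taxonomy: TaxonomyTable, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for label, res in sorted(results.items()):
        res.metrics.to_csv(out_dir / f"{label}.metrics.tsv", sep="\t")
        pd.Series(res.partition.membership, name="module").rename_axis("taxon").to_csv(
            out_dir / f"{label}.modules.tsv", sep="\t"
        )
        shares = chord_matrix(res.network, taxonomy)
        shares.matrix.to_csv(out_dir / f"{label}.chord.tsv", sep="\t")
        export_gexf(res.network, res.partition, out_dir / f"{label}.gexf")
        if res.keystones is not None:
            res.keystones.to_csv(out_dir / f"{label}.keystones.tsv", sep="\t")
        if res.threshold_scan is not None:
            res.threshold_scan.write_tsv(out_dir / f"{label}.threshold_scan.tsv")
        summary = res.summary.to_dict()
        summary["module_sizes"] = {
            str(k): v for k, v in sorted(res.partition.module_sizes().items())
        }
        manifest[label] = {"summary": summary, "stages": res.stage_counts}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Phylum influence


@dataclass(frozen=True)
class PhylumShareTable:
    """Phylum edge-endpoint shares and the phylum x phylum edge-count matrix."""

    shares: pd.Series  # phylum -> fraction of edge endpoints, sums to 1
    matrix: pd.DataFrame  # symmetric edge counts between phyla


def phylum_shares(g: nx.Graph, taxonomy: TaxonomyTable) -> PhylumShareTable:
    """Share of network connections per phylum.

    A phylum's share is its fraction of edge endpoints (each edge contributes
    two), so shares sum to one. The matrix entry (P, Q) counts edges joining
    a P node to a Q node; within-phylum edges sit on the diagonal.
    """
    if g.number_of_edges() == 0:
        return PhylumShareTable(
            shares=pd.Series(dtype=float), matrix=pd.DataFrame(dtype=int)
        )
    phyla = {v: taxonomy.phylum_of(v) for v in g.nodes}
    names = sorted(set(phyla.values()))
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    endpoint_counts = pd.Series(0, index=names, dtype=int)
    for u, v in g.edges:
        pu, pv = phyla[u], phyla[v]
        matrix.loc[pu, pv] += 1
        if pu != pv:
            matrix.loc[pv, pu] += 1
        endpoint_counts[pu] += 1
        endpoint_counts[pv] += 1
    shares = endpoint_counts / (2 * g.number_of_edges())
    return PhylumShareTable(shares=shares.sort_values(ascending=False), matrix=matrix)


def chord_matrix(
    g: nx.Graph, taxonomy: TaxonomyTable, top_k: int = 10
) -> PhylumShareTable:
    """Phylum share table restricted to the top_k phyla by share.

    Remaining phyla are aggregated into an "Other" row/column; the total edge
    count is conserved.
    """
    full = phylum_shares(g, taxonomy)
    if full.shares.empty or len(full.shares) <= top_k:
        return full
    top = list(full.shares.index[:top_k])
    rest = [p for p in full.matrix.index if p not in top]
    order = top + rest
    mat = full.matrix.loc[order, order]
    k = len(top)
    collapsed = pd.DataFrame(
        0, index=top + ["Other"], columns=top + ["Other"], dtype=int
    )
    collapsed.iloc[:k, :k] = mat.iloc[:k, :k].to_numpy()
    collapsed.iloc[:k, k] = mat.iloc[:k, k:].sum(axis=1).to_numpy()
    collapsed.iloc[k, :k] = mat.iloc[k:, :k].sum(axis=0).to_numpy()
    # within-"Other" edges: diagonal + one triangle of the off-diagonal block
    rest_block = mat.iloc[k:, k:].to_numpy()
    collapsed.iloc[k, k] = int(
        np.diag(rest_block).sum() + np.triu(rest_block, 1).sum()
    )
    shares = full.shares.copy()
    other_share = shares.iloc[top_k:].sum()
    shares = shares.iloc[:top_k]
    shares["Other"] = other_share
    return PhylumShareTable(shares=shares, matrix=collapsed)


def chord_total_edges(table: PhylumShareTable) -> int:
    """Total edges represented by a chord matrix (diagonal counted once)."""
    mat = table.matrix.to_numpy()
    if mat.size == 0:
        return 0
    return int(np.triu(mat, 1).sum() + np.diag(mat).sum())


# ---------------------------------------------------------------------------
# GEXF export


def export_gexf(g: nx.Graph, partition: Partition | None, path) -> None:
    """Write the graph as GEXF 1.2 with metric and module node attributes."""
    out = g.copy()
    metrics = node_metrics(out)
    for v in out.nodes:
        row = metrics.loc[v]
        out.nodes[v]["degree"] = int(row["degree"])
        out.nodes[v]["weighted_degree"] = float(row["weighted_degree"])
        out.nodes[v]["closeness"] = float(row["closeness"])
        out.nodes[v]["betweenness"] = float(row["betweenness"])
        out.nodes[v]["clustering"] = float(row["clustering"])
        if partition is not None:
            out.nodes[v]["module"] = int(partition.membership.get(v, -1))
    nx.write_gexf(out, path, version="1.2draft")


def layout_positions(g: nx.Graph, seed: int = 0) -> dict:
    """Optional Fruchterman-Reingold coordinates for plotting convenience."""
    return nx.spring_layout(g, seed=seed)
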