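"""miRNA-target transcript network construction and interrogation.

Candidate pairs are database entries whose miRNA and gene are both
differentially expressed; a pair becomes a network edge when its expression
profiles across the shared samples show a strong negative Pearson
correlation (strictly R < -0.7 and p < 0.05 by default, both inequalities
strict). The result is a bipartite graph of repressive candidate
interactions annotated with differential-expression directions, from which
summary percentages, a degree-stratified correlation comparison and
evidence-based target prioritization are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import TargetPairDB

logger = logging.getLogger("mirtarnet")


@dataclass
class MirnaTargetNetwork:
    """Bipartite edge set plus node differential-expression annotations.

    ``edges`` columns: mirna, gene, pearson_r, p_value, n_samples,
    validated, sources (frozenset). Annotations are per-node frames with
    ``lfc`` and ``direction`` ('up'/'down' in cases).
    """

    edges: pd.DataFrame
    mirna_annotations: pd.DataFrame | None = None
    gene_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["pearson_r"] >= 0).any():
                raise ValueError("network admits only negative-correlation edges")
            if (self.edges["n_samples"] < 3).any():
                raise ValueError("edges need n_samples >= 3")
            overlap = set(self.edges["mirna"]) & set(self.edges["gene"])
            if overlap:
                raise ValueError(f"ids on both layers break bipartiteness: {sorted(overlap)[:5]}")

    @property
    def mirnas(self) -> list[str]:
        return sorted(set(self.edges["mirna"]))

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.edges["gene"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene_degree(self) -> pd.Series:
        return self.edges.groupby("gene")["mirna"].nunique()

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        for node in self.mirnas:
            graph.add_node(node, layer="mirna", **self._node_attrs(node, "mirna"))
        for node in self.genes:
            graph.add_node(node, layer="gene", **self._node_attrs(node, "gene"))
        for row in self.edges.itertuples(index=False):
            graph.add_edge(
                row.mirna,
                row.gene,
                pearson_r=float(row.pearson_r),
                p_value=float(row.p_value),
                n_samples=int(row.n_samples),
                validated=bool(row.validated),
                sources=";".join(sorted(row.sources)),
            )
        return graph

    def _node_attrs(self, node: str, layer: str) -> dict:
        ann = self.mirna_annotations if layer == "mirna" else self.gene_annotations
        if ann is None or node not in ann.index:
            return {}
        return {
            "lfc": float(ann.loc[node, "lfc"]),
            "direction": str(ann.loc[node, "direction"]),
        }


# ---------------------------------------------------------------------------
# candidate selection and correlation
# ---------------------------------------------------------------------------


def candidate_pairs(
    de_mirna: pd.DataFrame,
    de_gene: pd.DataFrame,
    db: TargetPairDB,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Database pairs whose miRNA and gene both pass FDR < alpha.

    Pairs are deduplicated across source databases; ``sources`` is the
    union and ``validated`` is true if any contributing source carries
    experimental evidence.
    """
    shared = set(de_mirna.index) & set(de_gene.index)
    if shared:
        raise ValueError(f"feature ids shared across layers: {sorted(shared)[:5]}")
    sig_mirna = set(de_mirna.index[de_mirna["fdr"] < alpha])
    sig_gene = set(de_gene.index[de_gene["fdr"] < alpha])
    if not sig_mirna or not sig_gene:
        logger.warning(
            "no significant features on %s layer; candidate list empty",
            "miRNA" if not sig_mirna else "gene",
        )
        return pd.DataFrame(columns=["mirna", "gene", "sources", "validated"])
    collapsed = db.collapse()
    keep = collapsed["mirna"].isin(sig_mirna) & collapsed["gene"].isin(sig_gene)
    out = collapsed[keep].reset_index(drop=True)
    out["sources"] = out["sources"].map(lambda s: frozenset(s.split(";")))
    return out


def pearson_with_p(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-reference p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def build_network(
    candidates: pd.DataFrame,
    rlog_mirna: pd.DataFrame,
    rlog_mrna: pd.DataFrame,
    r_threshold: float = -0.7,
    p_threshold: float = 0.05,
    de_mirna: pd.DataFrame | None = None,
    de_gene: pd.DataFrame | None = None,
    restrict_status: str | None = None,
    metadata: pd.DataFrame | None = None,
) -> MirnaTargetNetwork:
    """Admit candidate pairs with r < r_threshold and p < p_threshold.

    Correlations run over the intersection of samples assayed on both
    layers, statuses pooled (pooling is what makes differential-expression
    driven anticorrelation detectable at small n); ``restrict_status``
    optionally limits to one group. Both admission inequalities are strict.
    Pairs with a constant expression vector are skipped with a logged
    reason.
    """
    shared = [s for s in rlog_mirna.columns if s in set(rlog_mrna.columns)]
    if restrict_status is not None:
        if metadata is None:
            raise ValueError("restrict_status requires metadata")
        keep = set(metadata.index[metadata["status"].astype(str) == restrict_status])
        shared = [s for s in shared if s in keep]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    rows = []
    for cand in candidates.itertuples(index=False):
        if cand.mirna not in rlog_mirna.index or cand.gene not in rlog_mrna.index:
            continue
        x = rlog_mirna.loc[cand.mirna, shared].to_numpy(dtype=float)
        y = rlog_mrna.loc[cand.gene, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.info("skipping %s-%s: constant expression vector", cand.mirna, cand.gene)
            continue
        r, p = pearson_with_p(x, y)
        if r < r_threshold and p < p_threshold:
            rows.append((cand.mirna, cand.gene, r, p, len(shared), cand.validated, cand.sources))
    edges = pd.DataFrame(
        rows,
        columns=["mirna", "gene", "pearson_r", "p_value", "n_samples", "validated", "sources"],
    )
    logger.info(
        "build_network: %d/%d candidate pairs admitted over %d samples",
        len(edges), len(candidates), len(shared),
    )
    return MirnaTargetNetwork(
        edges,
        mirna_annotations=_annotate(de_mirna, set(edges["mirna"])),
        gene_annotations=_annotate(de_gene, set(edges["gene"])),
    )


def _annotate(de: pd.DataFrame | None, nodes: set[str]) -> pd.DataFrame | None:
    if de is None:
        return None
    present = [n for n in sorted(nodes) if n in de.index]
    ann = de.loc[present, ["lfc"]].copy()
    ann["direction"] = np.where(ann["lfc"] > 0, "up", "down")
    return ann


# ---------------------------------------------------------------------------
# summaries and tests
# ---------------------------------------------------------------------------


def network_summary(network: MirnaTargetNetwork, de_gene: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Headline counts plus targeted-percentage per DE direction.

    The directional percentages answer: of all significantly down- (up-)
    regulated genes, what whole-percent fraction appears as a network
    target?
    """
    targets = set(network.genes)
    sig = de_gene[de_gene["fdr"] < alpha]
    down = set(sig.index[sig["lfc"] < 0])
    up = set(sig.index[sig["lfc"] > 0])
    pct = lambda hit, pool: round(100.0 * len(hit & pool) / len(pool)) if pool else 0
    return {
        "n_edges": network.n_edges,
        "n_mirnas": len(network.mirnas),
        "n_genes": len(network.genes),
        "n_validated_edges": int(network.edges["validated"].sum()) if network.n_edges else 0,
        "n_de_genes_down": len(down),
        "n_de_genes_up": len(up),
        "n_targeted_down": len(targets & down),
        "n_targeted_up": len(targets & up),
        "pct_down_targeted": pct(targets, down),
        "pct_up_targeted": pct(targets, up),
    }


@dataclass
class DegreeCorrelationReport:
    median_multi: float | None
    iqr_multi: tuple[float, float] | None
    median_single: float | None
    iqr_single: tuple[float, float] | None
    mwu_p: float | None
    n_multi: int
    n_single: int


def degree_correlation_test(
    network: MirnaTargetNetwork, aggregate: str = "mean"
) -> DegreeCorrelationReport:
    """Compare per-transcript correlation strength between degree classes.

    Each transcript's edges are aggregated (default: arithmetic mean of
    edge r values; ``aggregate='pooled'`` keeps every edge r separately),
    split into degree > 1 versus degree = 1, and compared by a two-sided
    Mann-Whitney U (exact enumeration when both classes have <= 8 values,
    tie-corrected normal approximation otherwise).
    """
    if aggregate not in ("mean", "pooled"):
        raise ValueError("aggregate must be 'mean' or 'pooled'")
    if not network.n_edges:
        return DegreeCorrelationReport(None, None, None, None, None, 0, 0)
    degree = network.gene_degree()
    per_gene = network.edges.groupby("gene")["pearson_r"]
    if aggregate == "mean":
        values = per_gene.mean()
        multi = values[degree > 1].to_numpy()
        single = values[degree == 1].to_numpy()
    else:
        multi = network.edges.loc[
            network.edges["gene"].isin(degree.index[degree > 1]), "pearson_r"
        ].to_numpy()
        single = network.edges.loc[
            network.edges["gene"].isin(degree.index[degree == 1]), "pearson_r"
        ].to_numpy()

    def _stats(arr):
        if arr.size == 0:
            return None, None
        lo, hi = np.percentile(arr, [25, 75])
        return float(np.median(arr)), (float(lo), float(hi))

    median_multi, iqr_multi = _stats(multi)
    median_single, iqr_single = _stats(single)
    if multi.size and single.size:
        method = "exact" if max(multi.size, single.size) <= 8 else "asymptotic"
        mwu_p = float(
            stats.mannwhitneyu(multi, single, alternative="two-sided", method=method).pvalue
        )
    else:
        mwu_p = None
    return DegreeCorrelationReport(
        median_multi, iqr_multi, median_single, iqr_single, mwu_p,
        int(multi.size), int(single.size),
    )


@dataclass
class PrioritizedTargets:
    tier_a: list[str]              # targeted by >= 2 miRNAs
    tier_b: list[str]              # tier A with >= 1 validated edge
    pct_validated: int             # whole-percent |B| / |A|


def prioritize_targets(network: MirnaTargetNetwork) -> PrioritizedTargets:
    """Multi-miRNA targets, and the subset with experimental support."""
    if not network.n_edges:
        return PrioritizedTargets([], [], 0)
    degree = network.gene_degree()
    tier_a = sorted(degree.index[degree >= 2])
    validated_genes = set(network.edges.loc[network.edges["validated"], "gene"])
    tier_b = [g for g in tier_a if g in validated_genes]
    pct = round(100.0 * len(tier_b) / len(tier_a)) if tier_a else 0
    return PrioritizedTargets(tier_a, tier_b, pct)


@dataclass
class OverlapReport:
    n_list: int
    n_expressed: int
    n_in_network: int
    genes_in_network: list[str]
    subnetwork: MirnaTargetNetwork


def overlap_prioritized_genes(
    network: MirnaTargetNetwork,
    gene_list: list[str],
    expressed: set[str],
) -> OverlapReport:
    """Overlap of an externally prioritized gene list with the network.

    Reports how many listed genes are expressed at all, how many appear as
    network targets, and the induced subnetwork (those genes plus every
    incident miRNA edge, validated flags preserved).
    """
    listed = set(gene_list)
    in_network = sorted(listed & set(network.genes))
    sub_edges = network.edges[network.edges["gene"].isin(in_network)].reset_index(drop=True)
    subnetwork = MirnaTargetNetwork(
        sub_edges,
        mirna_annotations=network.mirna_annotations,
        gene_annotations=network.gene_annotations,
    )
    return OverlapReport(
        n_list=len(listed),
        n_expressed=len(listed & expressed),
        n_in_network=len(in_network),
        genes_in_network=in_network,
        subnetwork=subnetwork,
    )
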