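"""Hypergeometric over-representation analysis of network target genes.

A query gene set (e.g. the network targets with a given differential-
expression direction, or one miRNA's targets) is tested against each
annotated gene set restricted to a background universe — by default the
genes expressed in the mRNA dataset, not the genome. The p-value is the
upper-tail hypergeometric mass P(X >= k) for drawing k annotated genes in
a query of size n from a background of N containing K annotated genes;
BH adjustment runs within each query's result list.

Two gene-ratio conventions circulate for dot-plot style reporting: the
query fraction k/n and the set fraction k/K. Both are emitted
(``gene_ratio_kn``, ``gene_ratio_kK``) rather than guessing which one a
downstream figure wants.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .io import GeneSetCollection
from .network import MirnaTargetNetwork

RESULT_COLUMNS = [
    "set_name", "k", "K", "n", "N", "p_value", "fdr",
    "gene_ratio_kn", "gene_ratio_kK", "hit_genes",
]


def ora(
    query: Iterable[str],
    sets: GeneSetCollection,
    background: Iterable[str],
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of one query against every set.

    Sets are intersected with the background first; sets whose restricted
    size falls outside [min_set_size, max_set_size] (or is zero) are not
    tested. Results are sorted by p-value.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    N, n = len(background), len(query)
    rows = []
    for name, members in sets:
        restricted = members & background
        K = len(restricted)
        if K < max(min_set_size, 1) or (max_set_size is not None and K > max_set_size):
            continue
        hits = sorted(restricted & query)
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p, np.nan,
                     k / n if n else 0.0, k / K, hits))
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(frame):
        frame["fdr"] = bh_fdr(frame["p_value"].to_numpy())
        frame = frame.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return frame


def directional_ora(
    network: MirnaTargetNetwork,
    de_gene: pd.DataFrame,
    sets: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
    **ora_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ORA of network targets split by DE direction, with miRNA coverage.

    The extra ``n_mirnas`` column counts the distinct miRNAs targeting at
    least one hit gene of the set — a sort key ranking pathways by how many
    regulators converge on them.
    """
    background = set(background)
    targets = set(network.genes)
    sig = de_gene[de_gene["fdr"] < alpha]
    down_query = targets & set(sig.index[sig["lfc"] < 0]) & background
    up_query = targets & set(sig.index[sig["lfc"] > 0]) & background
    results = []
    for query in (down_query, up_query):
        if not query:
            results.append(pd.DataFrame(columns=RESULT_COLUMNS + ["n_mirnas"]))
            continue
        frame = ora(query, sets, background, **ora_kwargs)
        frame["n_mirnas"] = [
            _mirna_coverage(network, hits) for hits in frame["hit_genes"]
        ]
        results.append(frame)
    return results[0], results[1]


def _mirna_coverage(network: MirnaTargetNetwork, genes: list[str]) -> int:
    mask = network.edges["gene"].isin(set(genes))
    return int(network.edges.loc[mask, "mirna"].nunique())


def per_mirna_ora(
    network: MirnaTargetNetwork,
    sets: GeneSetCollection,
    background: Iterable[str],
    **ora_kwargs,
) -> dict[str, pd.DataFrame]:
    """One ORA per network miRNA, query = its surviving targets.

    miRNAs whose targets all fall outside the background are omitted.
    Each result frame carries ``n_targets`` (that miRNA's query size).
    """
    background = set(background)
    out: dict[str, pd.DataFrame] = {}
    for mirna, group in network.edges.groupby("mirna"):
        query = set(group["gene"]) & background
        if not query:
            continue
        frame = ora(query, sets, background, **ora_kwargs)
        frame["n_targets"] = len(query)
        out[str(mirna)] = frame
    return out


def collapse_redundant(
    results: pd.DataFrame,
    sets: GeneSetCollection,
    jaccard_threshold: float = 0.5,
) -> pd.DataFrame:
    """Greedy Jaccard-overlap collapse of redundant result sets.

    Walks results in ascending p order and drops any set whose member
    overlap (Jaccard) with an already-kept set exceeds the threshold. A
    deliberately simple term-redundancy reduction; it is not a semantic-
    similarity method.
    """
    kept_rows, kept_members = [], []
    for _, row in results.sort_values("p_value", kind="mergesort").iterrows():
        members = sets.sets.get(row["set_name"], set())
        redundant = any(
            len(members & other) / len(members | other) > jaccard_threshold
            for other in kept_members if members | other
        )
        if not redundant:
            kept_rows.append(row)
            kept_members.append(members)
    return pd.DataFrame(kept_rows).reset_index(drop=True)
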