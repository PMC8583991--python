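"""Readers, writers and validated in-memory containers.

All tabular artifacts are UTF-8 TSV; gene sets use the standard GMT layout;
networks export as edge-list TSV or bipartite GraphML. Feature and gene
identifiers are opaque strings: no symbol/accession harmonization is
attempted, the caller supplies consistent ids across the count matrices,
the target-pair table and the atlas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("mirtarnet")

EVIDENCE_CLASSES = ("predicted", "validated")

#: columns of an edge-list export, in order
EDGE_COLUMNS = (
    "mirna",
    "gene",
    "pearson_r",
    "p_value",
    "n_samples",
    "validated",
    "sources",
    "mirna_direction",
    "gene_direction",
)


class FormatError(ValueError):
    """Malformed external input (bad cell, duplicate id, missing sample)."""


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A feature x sample count matrix plus aligned per-sample metadata.

    ``counts`` has feature ids as the index and sample ids as columns;
    entries are non-negative integers. ``metadata`` is indexed by sample id
    and carries at least ``status`` (two-level: control/case); ``age`` and
    ``sex`` are expected by the differential-expression defaults.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dupes)[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts matrix contains non-numeric entries")
        if (values < 0).any():
            f, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at feature {self.counts.index[f]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            f, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise FormatError(
                f"non-integer count {values[f, s]!r} at feature "
                f"{self.counts.index[f]!r}, sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        # align metadata rows to the count columns, dropping unassayed samples
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionDataset":
        keep = [s for s in sample_ids if s in self.counts.columns]
        return ExpressionDataset(self.counts[keep].copy(), self.metadata.loc[keep].copy())


def read_counts(path: str | Path, metadata_path: str | Path) -> ExpressionDataset:
    """Read a count TSV (features in rows, header = sample ids) plus metadata."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        f, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric count {raw.iat[f, s]!r} at feature "
            f"{raw.index[f]!r}, sample {raw.columns[s]!r}"
        )
    frac = numeric.to_numpy() % 1
    if (frac != 0).any():
        f, s = np.argwhere(frac != 0)[0]
        raise FormatError(
            f"{path}: non-integer count {numeric.iat[f, s]!r} at feature "
            f"{numeric.index[f]!r}, sample {numeric.columns[s]!r}"
        )
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return ExpressionDataset(numeric, metadata)


def write_counts(
    dataset: ExpressionDataset, path: str | Path, metadata_path: str | Path
) -> None:
    dataset.counts.to_csv(path, sep="\t")
    dataset.metadata.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# miRNA -> gene target-pair database
# ---------------------------------------------------------------------------


@dataclass
class TargetPairDB:
    """Candidate miRNA->gene pairs with per-source provenance.

    ``table`` columns: mirna, gene, source, evidence. A (mirna, gene, source)
    triple appears at most once; ``evidence`` is the class of the source
    database ('predicted' for sequence-based prediction tools, 'validated'
    for experimental-evidence collections) and must be constant per source.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["mirna", "gene", "source", "evidence"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"target DB missing columns: {missing}")
        self.table = self.table[required].reset_index(drop=True)
        bad = set(self.table["evidence"]) - set(EVIDENCE_CLASSES)
        if bad:
            raise FormatError(f"unknown evidence class: {sorted(bad)}")
        if self.table.duplicated(["mirna", "gene", "source"]).any():
            raise FormatError("duplicate (mirna, gene, source) rows in target DB")
        per_source = self.table.groupby("source")["evidence"].nunique()
        mixed = per_source[per_source > 1]
        if len(mixed):
            raise FormatError(
                f"sources with inconsistent evidence class: {list(mixed.index)}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["mirna"], self.table["gene"]))

    def collapse(self) -> pd.DataFrame:
        """One row per (mirna, gene): union of sources, any-validated flag."""
        grouped = self.table.groupby(["mirna", "gene"], sort=True)
        out = grouped.agg(
            sources=("source", lambda s: ";".join(sorted(set(s)))),
            validated=("evidence", lambda e: bool((e == "validated").any())),
        ).reset_index()
        return out


def read_target_db(path: str | Path) -> TargetPairDB:
    return TargetPairDB(pd.read_csv(path, sep="\t", dtype=str))


def write_target_db(db: TargetPairDB, path: str | Path) -> None:
    db.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r lists %d duplicate member(s); deduplicated",
                    path, lineno, name, len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Cell-type miRNA atlas
# ---------------------------------------------------------------------------


@dataclass
class CellTypeAtlas:
    """cell_type x miRNA enrichment-value matrix from a reference atlas."""

    table: pd.DataFrame  # index = cell types, columns = miRNA ids

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError("duplicate cell types in atlas")
        if not np.isfinite(self.table.to_numpy(dtype=float)).all():
            raise FormatError("non-finite enrichment values in atlas")
        self.table = self.table.astype(float)

    @property
    def cell_types(self) -> list[str]:
        return list(self.table.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.table.columns)


def read_atlas(path: str | Path) -> CellTypeAtlas:
    return CellTypeAtlas(pd.read_csv(path, sep="\t", index_col=0))


def write_atlas(atlas: CellTypeAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain text, one gene id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def _edge_frame(network) -> pd.DataFrame:
    frame = network.edges.copy()
    for col, ann in (("mirna", network.mirna_annotations), ("gene", network.gene_annotations)):
        direction = frame[col].map(
            ann["direction"] if ann is not None and "direction" in ann else {}
        )
        frame[f"{col}_direction"] = direction.fillna("")
    frame["sources"] = frame["sources"].map(
        lambda s: ";".join(sorted(s)) if not isinstance(s, str) else s
    )
    return frame[list(EDGE_COLUMNS)]


def write_network(network, path: str | Path, format: str = "edge_tsv") -> None:
    """Export a bipartite miRNA-target network as edge TSV or GraphML."""
    if format == "edge_tsv":
        _edge_frame(network).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_edges(path: str | Path) -> pd.DataFrame:
    """Read an edge_tsv export back into a frame with parsed source sets."""
    frame = pd.read_csv(path, sep="\t")
    frame["validated"] = frame["validated"].astype(bool)
    frame["sources"] = frame["sources"].map(
        lambda s: frozenset(str(s).split(";")) if pd.notna(s) and s != "" else frozenset()
    )
    for col in ("mirna_direction", "gene_direction"):
        frame[col] = frame[col].fillna("")
    return frame
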