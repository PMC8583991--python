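"""Synthetic paired miRNA/mRNA cohorts with planted regulatory structure.

The generator emulates a case/control biopsy study in which

* each sample is a mixture of cell types (default: intestinal epithelium
  and T cells) whose proportions are Dirichlet-distributed and shift with
  disease status (cases: less epithelium, more T cells — the composition
  change accompanying villous atrophy and lymphocyte influx);
* each feature's latent log2 abundance is the composition-weighted mixture
  of cell-type baselines, plus an optional direct status effect;
* planted miRNA->gene repressions subtract ``slope * (x_m - mean(x_m))``
  from the target gene's latent log2 mean, where ``x_m`` is the miRNA's
  realized latent abundance (so repression tracks the miRNA sample to
  sample, creating a negative expression correlation);
* observed counts are negative-binomial draws around
  ``libsize * 2**latent`` with a common overdispersion.

Alongside the counts the module fabricates the study's side inputs — a
target-pair database with decoys and predicted/validated provenance, a
gene-set collection containing a module of repressed targets, a cell-type
miRNA atlas whose top-ranked miRNAs are the planted markers, and a
prioritized-gene list biased toward case-upregulated genes — plus the
ground truth needed to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionDataset, GeneSetCollection, CellTypeAtlas, TargetPairDB

PREDICTED_SOURCES = ("predicted_db_a", "predicted_db_b")
VALIDATED_SOURCES = ("validated_db_a", "validated_db_b")

_DEFAULT_CELL_TYPES = ("epithelial", "t_cell")
# cases: epithelial fraction drops, T-cell fraction rises
_DEFAULT_COMPOSITION = {
    "control": (8.0, 2.0),
    "case": (5.0, 5.0),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 10 controls and 33 cases with
    the miRNA layer on every sample and the mRNA layer on a 5 + 6 subset
    (``rna_subset``), two cell types with a status-dependent composition
    shift, and 100 planted repressions with slope 1.5 at NB overdispersion
    0.05.
    """

    n_control: int = 10
    n_case: int = 33
    n_mirna: int = 150
    n_gene: int = 600
    n_true_pairs: int = 100
    repression_slope: float = 1.5
    dispersion: float = 0.05
    libsize_log_sd: float = 0.15
    celltype_profiles: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None
    composition_shift: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITION)
    )
    de_fraction_mirna: float = 0.2
    de_fraction_gene: float = 0.15
    predicted_sensitivity: float = 0.9
    validated_sensitivity: float = 0.4
    decoy_rate: float = 4.0
    seed: int = 0
    # generator shape parameters
    cell_types: tuple[str, ...] = _DEFAULT_CELL_TYPES
    marker_fraction: float = 0.1
    marker_effect: float = 3.0          # log2 boost of a marker in its own cell type
    latent_noise_sd: float = 0.3        # per-sample latent log2 noise on miRNAs
    effect_size_range: tuple[float, float] = (1.0, 2.0)
    age_range: tuple[float, float] = (2.0, 17.0)
    rna_subset: tuple[int, int] | None = (5, 6)  # (controls, cases) with mRNA data

    def __post_init__(self) -> None:
        for name in ("n_control", "n_case", "n_mirna", "n_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_true_pairs < 0:
            raise ValueError("n_true_pairs must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be >= 0")
        for name in (
            "de_fraction_mirna", "de_fraction_gene",
            "predicted_sensitivity", "validated_sensitivity",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be >= 0")
        for status, conc in self.composition_shift.items():
            conc = np.asarray(conc, dtype=float)
            if len(conc) != len(self.cell_types):
                raise ValueError(
                    f"composition_shift[{status!r}] has {len(conc)} entries "
                    f"for {len(self.cell_types)} cell types"
                )
            if (conc <= 0).any():
                raise ValueError("Dirichlet concentrations must be > 0")
        if self.celltype_profiles is not None:
            unknown = set(self.celltype_profiles) - set(self.cell_types)
            if unknown:
                raise ValueError(f"unknown cell types in profiles: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_case

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirna)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_gene)]


@dataclass
class GroundTruth:
    """Planted structure of one simulated cohort."""

    true_pairs: set[tuple[str, str, float]]
    de_mirna: set[str]
    de_gene: set[str]
    composition: pd.DataFrame          # sample x cell type proportions
    mirna_effects: dict[str, float]    # signed direct log2 status effects
    gene_effects: dict[str, float]
    mirna_markers: dict[str, list[str]]  # cell type -> marker miRNA ids
    gene_markers: dict[str, list[str]]
    latent_mirna: pd.DataFrame         # latent log2 abundance before NB noise
    latent_gene: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.composition.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.true_pairs}


@dataclass
class RecoveryReport:
    """Network edges scored against the planted pairs."""

    n_edges: int
    n_true_pairs: int
    true_positives: int
    precision: float | None
    recall: float
    f1: float | None
    validated_true_positives: int
    validated_edges: int


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _baselines(
    config: SimulationConfig, rng: np.random.Generator, n_features: int
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Feature x cell-type log2 baselines with disjoint marker blocks.

    Marker features gain ``marker_effect`` in their own cell type and lose
    it in the others, so the mixture abundance tracks that cell type's
    proportion. Marker blocks sit at the start of the feature list.
    """
    n_types = len(config.cell_types)
    # 16-1024 expected counts: the abundance band where features are
    # reliably quantified in small-RNA and bulk RNA-seq
    base = rng.uniform(4.0, 10.0, size=n_features)
    profiles = np.tile(base[:, None], (1, n_types))
    n_marker = int(round(config.marker_fraction * n_features))
    markers: dict[str, list[int]] = {}
    cursor = 0
    for c, cell_type in enumerate(config.cell_types):
        block = list(range(cursor, min(cursor + n_marker, n_features)))
        markers[cell_type] = block
        for f in block:
            profiles[f, :] -= config.marker_effect
            profiles[f, c] += 2 * config.marker_effect
        cursor += n_marker
    return profiles, markers


def _pick_de(
    rng: np.random.Generator,
    ids: list[str],
    marker_idx: set[int],
    fraction: float,
    effect_range: tuple[float, float],
) -> dict[str, float]:
    """Direct status effects on non-marker features, random sign."""
    eligible = [i for i in range(len(ids)) if i not in marker_idx]
    n_de = min(int(round(fraction * len(ids))), len(eligible))
    chosen = rng.choice(eligible, size=n_de, replace=False) if n_de else []
    effects = {}
    for i in chosen:
        magnitude = rng.uniform(*effect_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effects[ids[i]] = sign * magnitude
    return effects


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Draw one paired miRNA/mRNA cohort with planted ground truth."""
    rng = _rng(config, 1)
    statuses = ["control"] * config.n_control + ["case"] * config.n_case
    sample_ids = [
        f"{'ctrl' if s == 'control' else 'case'}{i + 1:02d}"
        for i, s in enumerate(statuses)
    ]
    metadata = pd.DataFrame(
        {
            "status": statuses,
            "age": rng.uniform(*config.age_range, size=config.n_samples).round(1),
            "sex": rng.choice(["F", "M"], size=config.n_samples),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    is_case = np.array([s == "case" for s in statuses], dtype=float)

    # per-sample cell-type proportions
    composition = np.empty((config.n_samples, len(config.cell_types)))
    for i, status in enumerate(statuses):
        conc = np.asarray(config.composition_shift[status], dtype=float)
        composition[i] = rng.dirichlet(conc)
    composition_df = pd.DataFrame(
        composition, index=sample_ids, columns=list(config.cell_types)
    )

    # cell-type baselines (caller-supplied profiles override the generated ones)
    if config.celltype_profiles is not None:
        mirna_profiles = np.column_stack(
            [np.asarray(config.celltype_profiles[c][0], float) for c in config.cell_types]
        )
        gene_profiles = np.column_stack(
            [np.asarray(config.celltype_profiles[c][1], float) for c in config.cell_types]
        )
        mirna_marker_idx: dict[str, list[int]] = {c: [] for c in config.cell_types}
        gene_marker_idx: dict[str, list[int]] = {c: [] for c in config.cell_types}
    else:
        mirna_profiles, mirna_marker_idx = _baselines(config, rng, config.n_mirna)
        gene_profiles, gene_marker_idx = _baselines(config, rng, config.n_gene)

    mirna_ids, gene_ids = config.mirna_ids, config.gene_ids
    mirna_marker_flat = {i for block in mirna_marker_idx.values() for i in block}
    gene_marker_flat = {i for block in gene_marker_idx.values() for i in block}

    mirna_effects = _pick_de(
        rng, mirna_ids, mirna_marker_flat, config.de_fraction_mirna,
        config.effect_size_range,
    )
    gene_effects = _pick_de(
        rng, gene_ids, gene_marker_flat, config.de_fraction_gene,
        config.effect_size_range,
    )

    # planted pairs: regulating miRNAs drawn from the direct-effect set (the
    # workflow only ever pairs differentially expressed features), target
    # genes drawn from unaffected non-marker genes, some reused so that a
    # subset of targets has degree > 1
    true_pairs: set[tuple[str, str, float]] = set()
    if config.n_true_pairs:
        regulators = sorted(mirna_effects) or mirna_ids
        target_pool = [
            g for i, g in enumerate(gene_ids)
            if g not in gene_effects and i not in gene_marker_flat
        ] or gene_ids
        n_unique = max(1, int(round(0.8 * config.n_true_pairs)))
        uniques = list(
            rng.choice(target_pool, size=min(n_unique, len(target_pool)), replace=False)
        )
        attempts = 0
        while len(true_pairs) < config.n_true_pairs and attempts < 50 * config.n_true_pairs:
            attempts += 1
            gene = (
                uniques[len(true_pairs)]
                if len(true_pairs) < len(uniques)
                else str(rng.choice(uniques))
            )
            mirna = str(rng.choice(regulators))
            if (mirna, gene, config.repression_slope) not in true_pairs:
                true_pairs.add((mirna, gene, config.repression_slope))

    # latent log2 abundances
    mirna_status = np.array([mirna_effects.get(m, 0.0) for m in mirna_ids])
    latent_mirna = (
        composition @ mirna_profiles.T
        + np.outer(is_case, mirna_status)
        + rng.normal(0.0, config.latent_noise_sd, size=(config.n_samples, config.n_mirna))
    ).T  # miRNA x sample

    gene_status = np.array([gene_effects.get(g, 0.0) for g in gene_ids])
    latent_gene = (
        composition @ gene_profiles.T + np.outer(is_case, gene_status)
    ).T  # gene x sample
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for mirna, gene, slope in sorted(true_pairs):
        x_m = latent_mirna[mirna_index[mirna]]
        latent_gene[gene_index[gene]] -= slope * (x_m - x_m.mean())

    # libraries and NB sampling
    lib_mirna = np.exp(rng.normal(0.0, config.libsize_log_sd, size=config.n_samples))
    lib_gene = np.exp(rng.normal(0.0, config.libsize_log_sd, size=config.n_samples))
    mu_mirna = lib_mirna[None, :] * np.exp2(latent_mirna)
    mu_gene = lib_gene[None, :] * np.exp2(latent_gene)
    counts_mirna = _nb_counts(rng, mu_mirna, config.dispersion)
    counts_gene = _nb_counts(rng, mu_gene, config.dispersion)

    mirna_ds = ExpressionDataset(
        pd.DataFrame(counts_mirna, index=mirna_ids, columns=sample_ids),
        metadata.copy(),
    )
    gene_counts = pd.DataFrame(counts_gene, index=gene_ids, columns=sample_ids)
    if config.rna_subset is not None:
        n_ctrl, n_case = config.rna_subset
        controls = [s for s, st in zip(sample_ids, statuses) if st == "control"]
        cases = [s for s, st in zip(sample_ids, statuses) if st == "case"]
        keep = sorted(rng.choice(controls, size=min(n_ctrl, len(controls)), replace=False)) + \
            sorted(rng.choice(cases, size=min(n_case, len(cases)), replace=False))
        gene_counts = gene_counts[keep]
    gene_ds = ExpressionDataset(gene_counts, metadata.loc[gene_counts.columns].copy())

    truth = GroundTruth(
        true_pairs=true_pairs,
        de_mirna=set(mirna_effects),
        de_gene=set(gene_effects),
        composition=composition_df,
        mirna_effects=mirna_effects,
        gene_effects=gene_effects,
        mirna_markers={c: [mirna_ids[i] for i in idx] for c, idx in mirna_marker_idx.items()},
        gene_markers={c: [gene_ids[i] for i in idx] for c, idx in gene_marker_idx.items()},
        latent_mirna=pd.DataFrame(latent_mirna, index=mirna_ids, columns=sample_ids),
        latent_gene=pd.DataFrame(latent_gene, index=gene_ids, columns=sample_ids),
    )
    return mirna_ds, gene_ds, truth


def simulate_target_db(truth: GroundTruth, config: SimulationConfig) -> TargetPairDB:
    """Target-pair table: noisy listing of true pairs plus random decoys.

    Each true pair enters each predicted source with probability
    ``predicted_sensitivity`` and each validated source with probability
    ``validated_sensitivity``. ``decoy_rate * n_true_pairs`` unique non-true
    pairs are added, each under one randomly chosen predicted source.
    """
    rng = _rng(config, 2)
    rows: list[tuple[str, str, str, str]] = []
    for mirna, gene, _ in sorted(truth.true_pairs):
        for source in PREDICTED_SOURCES:
            if rng.random() < config.predicted_sensitivity:
                rows.append((mirna, gene, source, "predicted"))
        for source in VALIDATED_SOURCES:
            if rng.random() < config.validated_sensitivity:
                rows.append((mirna, gene, source, "validated"))

    n_decoys = int(round(config.decoy_rate * len(truth.pair_set)))
    forbidden = set(truth.pair_set)
    decoys: set[tuple[str, str]] = set()
    mirna_ids, gene_ids = config.mirna_ids, config.gene_ids
    attempts = 0
    while len(decoys) < n_decoys and attempts < 100 * max(n_decoys, 1):
        attempts += 1
        pair = (str(rng.choice(mirna_ids)), str(rng.choice(gene_ids)))
        if pair not in forbidden and pair not in decoys:
            decoys.add(pair)
    for mirna, gene in sorted(decoys):
        source = PREDICTED_SOURCES[int(rng.integers(len(PREDICTED_SOURCES)))]
        rows.append((mirna, gene, source, "predicted"))

    table = pd.DataFrame(rows, columns=["mirna", "gene", "source", "evidence"])
    return TargetPairDB(table)


def simulate_fixtures(
    truth: GroundTruth, config: SimulationConfig, n_sets: int = 20,
    n_prioritized: int = 40,
) -> tuple[GeneSetCollection, CellTypeAtlas, list[str]]:
    """Gene sets, cell-type miRNA atlas and prioritized-gene list.

    The collection contains one module of planted repression targets (so
    over-representation analysis has signal) among random sets; the atlas
    ranks each cell type's planted marker miRNAs on top, making the top-10
    signatures disjoint between cell types; the prioritized list mixes
    case-upregulated genes, repression targets and unaffected genes.
    """
    rng = _rng(config, 3)
    gene_ids = config.gene_ids

    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    target_genes = sorted({g for _, g, _ in truth.true_pairs})
    if target_genes:
        module = list(rng.choice(target_genes, size=min(30, len(target_genes)), replace=False))
        padding = list(rng.choice(gene_ids, size=5, replace=False))
        sets["repressed_module"] = set(module) | set(padding)
        descriptions["repressed_module"] = "planted module of repression targets"
    up_genes = sorted(g for g, e in truth.gene_effects.items() if e > 0)
    if up_genes:
        module = list(rng.choice(up_genes, size=min(25, len(up_genes)), replace=False))
        sets["induced_module"] = set(module) | set(rng.choice(gene_ids, size=5, replace=False))
        descriptions["induced_module"] = "planted module of case-upregulated genes"
    hi = min(40, config.n_gene)
    lo = min(15, max(2, config.n_gene // 4))
    while len(sets) < n_sets:
        name = f"SET{len(sets) + 1:03d}"
        size = int(rng.integers(lo, hi)) if hi > lo else hi
        sets[name] = set(rng.choice(gene_ids, size=size, replace=False))
        descriptions[name] = "random gene set"
    collection = GeneSetCollection(sets, descriptions)

    # atlas: each miRNA is enriched in exactly one "home" cell type (planted
    # markers keep theirs, the rest are assigned round-robin). Home values sit
    # on a strictly higher support than away values, so per-cell-type top-k
    # lists are disjoint whenever k does not exceed the home-list size, with
    # markers ranking above ordinary home miRNAs.
    n_types = len(config.cell_types)
    home = np.empty(config.n_mirna, dtype=int)
    marked = set()
    for c, cell_type in enumerate(config.cell_types):
        for mirna in truth.mirna_markers.get(cell_type, []):
            j = config.mirna_ids.index(mirna)
            home[j] = c
            marked.add(j)
    unmarked = [j for j in range(config.n_mirna) if j not in marked]
    for i, j in enumerate(unmarked):
        home[j] = i % n_types
    values = rng.uniform(-1.0, 0.0, size=(n_types, config.n_mirna))
    for j in range(config.n_mirna):
        values[home[j], j] = rng.uniform(0.5, 1.5)
        if j in marked:
            values[home[j], j] += config.marker_effect
    atlas = CellTypeAtlas(
        pd.DataFrame(values, index=list(config.cell_types), columns=config.mirna_ids)
    )

    pool_rest = [g for g in gene_ids if g not in truth.de_gene and g not in set(target_genes)]
    n_prioritized = min(n_prioritized, config.n_gene)
    n_up = min(int(round(0.6 * n_prioritized)), len(up_genes))
    n_tg = min(int(round(0.2 * n_prioritized)), len(target_genes))
    n_rest = min(max(n_prioritized - n_up - n_tg, 0), len(pool_rest))
    prioritized = (
        list(rng.choice(up_genes, size=n_up, replace=False))
        + list(rng.choice(target_genes, size=n_tg, replace=False))
        + list(rng.choice(pool_rest, size=n_rest, replace=False))
    )
    # preserve order, drop accidental duplicates
    seen: set[str] = set()
    prioritized = [str(g) for g in prioritized if not (g in seen or seen.add(g))]
    return collection, atlas, prioritized


def evaluate_recovery(network, truth: GroundTruth) -> RecoveryReport:
    """Precision/recall/F1 of network edges against the planted pairs."""
    edges = set(zip(network.edges["mirna"], network.edges["gene"]))
    validated_edges = set(
        zip(
            network.edges.loc[network.edges["validated"], "mirna"],
            network.edges.loc[network.edges["validated"], "gene"],
        )
    )
    true = truth.pair_set
    tp = len(edges & true)
    precision = tp / len(edges) if edges else None
    recall = tp / len(true) if true else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision not in (None, 0) and recall > 0
        else (0.0 if edges else None)
    )
    return RecoveryReport(
        n_edges=len(edges),
        n_true_pairs=len(true),
        true_positives=tp,
        precision=precision,
        recall=recall,
        f1=f1,
        validated_true_positives=len(validated_edges & true),
        validated_edges=len(validated_edges),
    )
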