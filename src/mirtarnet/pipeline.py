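"""End-to-end orchestration: simulate/load -> DE -> network -> ORA -> cell type.

A single :class:`RunConfig` (YAML-loadable) drives the whole workflow and
captures every threshold — DE FDR cutoff alpha, the anticorrelation edge
filter (r < -0.7, p < 0.05), the composition-corrected FDR (0.1) and the
signature size (top 10). Each stage logs one structured line (inputs,
thresholds, output counts), and the run ends with a machine-readable
summary JSON of every headline number plus a MANIFEST recording completed
stages and input checksums. Stage outputs are pure functions of the inputs
and the config, so a rerun with the same config reproduces the summary
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import celltype as ct
from . import diffexp, enrichment, network as net
from . import io as mio
from . import simulate as sim

logger = logging.getLogger("mirtarnet")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    outdir: str = "mirtarnet_run"
    # inputs; ignored when simulate=True (the generator writes them)
    simulate: bool = True
    mirna_counts: str | None = None
    mirna_metadata: str | None = None
    mrna_counts: str | None = None
    mrna_metadata: str | None = None
    target_db: str | None = None
    gene_sets: str | None = None
    atlas: str | None = None
    prioritized_genes: str | None = None
    # thresholds (defaults are the workflow's canonical values)
    alpha: float = 0.05
    r_threshold: float = -0.7
    p_threshold: float = 0.05
    corrected_fdr: float = 0.1
    top_k: int = 10
    tau: float = 0.25
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    cell_types: list[str] = field(default_factory=lambda: ["epithelial", "t_cell"])
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("alpha and p_threshold must lie in (0, 1)")
        if not -1 <= self.r_threshold <= 0:
            raise ValueError("r_threshold must lie in [-1, 0]")
        if not 0 < self.corrected_fdr < 1:
            raise ValueError("corrected_fdr must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not self.simulate:
            required = [
                "mirna_counts", "mirna_metadata", "mrna_counts", "mrna_metadata",
                "target_db", "gene_sets", "atlas", "prioritized_genes",
            ]
            missing = [r for r in required if getattr(self, r) is None]
            if missing:
                raise ValueError(f"simulate=False requires paths for: {missing}")
            absent = [
                r for r in required if not Path(getattr(self, r)).exists()
            ]
            if absent:
                raise ValueError(
                    f"input paths do not exist: {[getattr(self, r) for r in absent]}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            payload = yaml.safe_load(handle) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; return (and write) the run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    manifest_path = outdir / "MANIFEST.tsv"

    def _finish_stage(stage: str, note: str = "") -> None:
        manifest.append(f"{stage}\tok\t{note}")
        manifest_path.write_text("\n".join(manifest) + "\n", encoding="utf-8")

    def _fail(stage: str, cause: Exception) -> PipelineError:
        manifest.append(f"{stage}\tfailed\t{cause}")
        manifest_path.write_text("\n".join(manifest) + "\n", encoding="utf-8")
        return PipelineError(stage, cause)

    summary: dict = {
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "r_threshold": config.r_threshold,
            "p_threshold": config.p_threshold,
            "corrected_fdr": config.corrected_fdr,
            "top_k": config.top_k,
            "tau": config.tau,
        },
    }

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulate:
            sim_config = sim.SimulationConfig(seed=config.seed, **config.sim_overrides)
            mirna_ds, mrna_ds, truth = sim.simulate_dataset(sim_config)
            db = sim.simulate_target_db(truth, sim_config)
            sets, atlas, prioritized = sim.simulate_fixtures(truth, sim_config)
            mio.write_counts(mirna_ds, outdir / "mirna_counts.tsv", outdir / "mirna_metadata.tsv")
            mio.write_counts(mrna_ds, outdir / "mrna_counts.tsv", outdir / "mrna_metadata.tsv")
            mio.write_target_db(db, outdir / "target_db.tsv")
            mio.write_gmt(sets, outdir / "gene_sets.gmt")
            mio.write_atlas(atlas, outdir / "atlas.tsv")
            mio.write_gene_list(prioritized, outdir / "prioritized_genes.txt")
            truth.composition.to_csv(outdir / "truth_composition.tsv", sep="\t")
            with open(outdir / "truth_summary.json", "w", encoding="utf-8") as handle:
                json.dump(
                    {
                        "n_true_pairs": len(truth.true_pairs),
                        "n_de_mirna": len(truth.de_mirna),
                        "n_de_gene": len(truth.de_gene),
                    },
                    handle, indent=2,
                )
            note = ""
        else:
            mirna_ds = mio.read_counts(config.mirna_counts, config.mirna_metadata)
            mrna_ds = mio.read_counts(config.mrna_counts, config.mrna_metadata)
            db = mio.read_target_db(config.target_db)
            sets = mio.read_gmt(config.gene_sets)
            atlas = mio.read_atlas(config.atlas)
            prioritized = mio.read_gene_list(config.prioritized_genes)
            truth = None
            note = ";".join(
                f"{name}={_checksum(Path(getattr(config, name)))}"
                for name in ("mirna_counts", "mrna_counts", "target_db", "gene_sets", "atlas")
            )
        logger.info(
            "inputs: miRNA %dx%d, mRNA %dx%d, DB rows %d, %d gene sets",
            mirna_ds.n_features, mirna_ds.n_samples,
            mrna_ds.n_features, mrna_ds.n_samples, len(db), len(sets),
        )
    except Exception as err:  # noqa: BLE001 - rewrapped with stage context
        raise _fail("inputs", err) from err
    _finish_stage("inputs", note)

    # ---- stage: differential expression --------------------------------
    try:
        de_mirna = diffexp.nb_wald_de(mirna_ds, covariates=config.covariates)
        de_gene = diffexp.nb_wald_de(mrna_ds, covariates=config.covariates)
        de_mirna.to_csv(outdir / "de_mirna.tsv", sep="\t")
        de_gene.to_csv(outdir / "de_gene.tsv", sep="\t")
        rlog_mirna = diffexp.rlog_transform(mirna_ds)
        rlog_mrna = diffexp.rlog_transform(mrna_ds)
        for name, de in (("mirna", de_mirna), ("gene", de_gene)):
            sig = de[de["fdr"] < config.alpha]
            summary[f"n_de_{name}"] = int(len(sig))
            summary[f"n_de_{name}_up"] = int((sig["lfc"] > 0).sum())
            summary[f"n_de_{name}_down"] = int((sig["lfc"] < 0).sum())
    except Exception as err:  # noqa: BLE001
        raise _fail("diffexp", err) from err
    _finish_stage("diffexp")

    # ---- stage: network -------------------------------------------------
    try:
        candidates = net.candidate_pairs(de_mirna, de_gene, db, alpha=config.alpha)
        graph = net.build_network(
            candidates, rlog_mirna, rlog_mrna,
            r_threshold=config.r_threshold, p_threshold=config.p_threshold,
            de_mirna=de_mirna, de_gene=de_gene,
        )
        mio.write_network(graph, outdir / "network_edges.tsv", "edge_tsv")
        mio.write_network(graph, outdir / "network.graphml", "graphml")
        summary["n_candidate_pairs"] = int(len(candidates))
        summary.update(net.network_summary(graph, de_gene, alpha=config.alpha))
        prioritization = net.prioritize_targets(graph)
        summary["n_tier_a_targets"] = len(prioritization.tier_a)
        summary["n_tier_b_targets"] = len(prioritization.tier_b)
        summary["pct_tier_a_validated"] = prioritization.pct_validated
        overlap = net.overlap_prioritized_genes(
            graph, prioritized, expressed=set(mrna_ds.feature_ids)
        )
        summary["n_prioritized"] = overlap.n_list
        summary["n_prioritized_expressed"] = overlap.n_expressed
        summary["n_prioritized_in_network"] = overlap.n_in_network
        if truth is not None:
            recovery = sim.evaluate_recovery(graph, truth)
            summary["recovery_precision"] = recovery.precision
            summary["recovery_recall"] = recovery.recall
    except Exception as err:  # noqa: BLE001
        raise _fail("network", err) from err
    _finish_stage("network")

    # ---- stage: enrichment ----------------------------------------------
    try:
        background = set(mrna_ds.feature_ids)
        down, up = enrichment.directional_ora(
            graph, de_gene, sets, background, alpha=config.alpha
        )
        down.to_csv(outdir / "ora_down.tsv", sep="\t", index=False)
        up.to_csv(outdir / "ora_up.tsv", sep="\t", index=False)
        per_mirna = enrichment.per_mirna_ora(graph, sets, background)
        summary["n_ora_down_sig"] = int((down["fdr"] < 0.05).sum()) if len(down) else 0
        summary["n_ora_up_sig"] = int((up["fdr"] < 0.05).sum()) if len(up) else 0
        summary["n_mirnas_with_ora"] = len(per_mirna)
    except Exception as err:  # noqa: BLE001
        raise _fail("enrichment", err) from err
    _finish_stage("enrichment")

    # ---- stage: cell type ------------------------------------------------
    try:
        signatures = ct.extract_signatures(atlas, config.cell_types, k=config.top_k)
        scores = ct.score_matrix(rlog_mirna, signatures, tau=config.tau)
        scores.to_csv(outdir / "celltype_scores.tsv", sep="\t")
        group_test = ct.score_group_test(scores, mirna_ds.metadata)
        summary["celltype_group_test"] = {
            signature: {
                col: float(group_test.loc[signature, col]) for col in group_test.columns
            }
            for signature in group_test.index
        }
        summary["lfc_atlas_correlation"] = {}
        for cell_type in config.cell_types:
            r, p, n = ct.lfc_atlas_correlation(de_mirna, atlas, cell_type)
            summary["lfc_atlas_correlation"][cell_type] = {"r": r, "p": p, "n": n}
        report = ct.corrected_de(
            mirna_ds, scores,
            covariates=config.covariates, fdr_threshold=config.corrected_fdr,
        )
        report.corrected.to_csv(outdir / "de_mirna_corrected.tsv", sep="\t")
        summary["n_significant_before_correction"] = len(report.previously_significant)
        summary["n_retained_after_correction"] = len(report.retained)
        # sample-level enrichment of the prioritized genes in the mRNA layer
        expressed_prioritized = set(prioritized) & set(mrna_ds.feature_ids)
        if expressed_prioritized and len(expressed_prioritized) < mrna_ds.n_features:
            prio_scores = ct.ss_enrichment(rlog_mrna, expressed_prioritized, tau=config.tau)
            prio_test = ct.score_group_test(
                prio_scores.to_frame("prioritized"), mrna_ds.metadata
            )
            summary["prioritized_gene_score"] = {
                col: float(prio_test.loc["prioritized", col]) for col in prio_test.columns
            }
    except Exception as err:  # noqa: BLE001
        raise _fail("celltype", err) from err
    _finish_stage("celltype")

    # ---- stage: report ---------------------------------------------------
    try:
        with open(outdir / "summary.json", "w", encoding="utf-8") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
    except Exception as err:  # noqa: BLE001
        raise _fail("report", err) from err
    _finish_stage("report")
    return summary
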