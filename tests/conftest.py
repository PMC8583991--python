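import numpy as np
import pandas as pd
import pytest

import mirtarnet as mt


def make_dataset(counts: np.ndarray, statuses: list[str], seed: int = 0,
                 prefix: str = "f") -> mt.ExpressionDataset:
    """Wrap a raw count array with minimal metadata."""
    rng = np.random.default_rng(seed)
    n = counts.shape[1]
    samples = [f"s{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "status": statuses,
            "age": rng.uniform(2, 17, n).round(1),
            "sex": rng.choice(["F", "M"], n),
        },
        index=pd.Index(samples, name="sample"),
    )
    frame = pd.DataFrame(
        counts, index=[f"{prefix}{i:04d}" for i in range(counts.shape[0])],
        columns=samples,
    )
    return mt.ExpressionDataset(frame, meta)


def make_network(edge_rows, de_mirna=None, de_gene=None) -> mt.MirnaTargetNetwork:
    """Build a network from (mirna, gene, r, p, validated[, sources]) tuples."""
    rows = []
    for row in edge_rows:
        mirna, gene, r, p, validated = row[:5]
        sources = row[5] if len(row) > 5 else frozenset({"predicted_db_a"})
        rows.append((mirna, gene, r, p, 11, validated, frozenset(sources)))
    edges = pd.DataFrame(
        rows,
        columns=["mirna", "gene", "pearson_r", "p_value", "n_samples",
                 "validated", "sources"],
    )
    return mt.MirnaTargetNetwork(edges, de_mirna, de_gene)


@pytest.fixture(scope="session")
def small_cfg() -> mt.SimulationConfig:
    return mt.SimulationConfig(
        seed=5, n_control=10, n_case=10, n_mirna=40, n_gene=120,
        n_true_pairs=20, rna_subset=None,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return mt.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_db(small_cohort, small_cfg):
    _, _, truth = small_cohort
    return mt.simulate_target_db(truth, small_cfg)


@pytest.fixture(scope="session")
def small_fixtures(small_cohort, small_cfg):
    _, _, truth = small_cohort
    return mt.simulate_fixtures(truth, small_cfg)


@pytest.fixture(scope="session")
def small_de(small_cohort):
    mirna_ds, mrna_ds, _ = small_cohort
    return mt.nb_wald_de(mirna_ds), mt.nb_wald_de(mrna_ds)


@pytest.fixture(scope="session")
def small_network(small_cohort, small_db, small_de):
    mirna_ds, mrna_ds, _ = small_cohort
    de_mirna, de_gene = small_de
    candidates = mt.candidate_pairs(de_mirna, de_gene, small_db)
    return mt.build_network(
        candidates,
        mt.rlog_transform(mirna_ds),
        mt.rlog_transform(mrna_ds),
        de_mirna=de_mirna,
        de_gene=de_gene,
    )
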