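import numpy as np
import pandas as pd
import pytest

from refstab import AggregatedCqMatrix, CqObservation, CqTable


def matrix_from_rows(rows: dict, groups: dict | None = None) -> AggregatedCqMatrix:
    """Build an AggregatedCqMatrix from {gene: [cq per sample]}."""
    n = len(next(iter(rows.values())))
    samples = [f"s{i+1}" for i in range(n)]
    cq = pd.DataFrame(rows, dtype=float).T
    cq.columns = samples
    n_used = cq.notna().astype(int) * 3
    return AggregatedCqMatrix(
        mean_cq=cq,
        n_used=n_used,
        group_of=groups or {s: "all" for s in samples},
    )


def random_matrix(rng: np.random.Generator, n_genes: int = 5,
                  n_samples: int = 8) -> AggregatedCqMatrix:
    """A random, complete Cq matrix: gene level + sample shift + noise."""
    base = rng.uniform(18, 30, n_genes)
    shift = rng.normal(0, 0.7, n_samples)
    noise = rng.normal(0, 0.5, (n_genes, n_samples))
    rows = {
        f"g{i+1}": (base[i] + shift + noise[i]).tolist() for i in range(n_genes)
    }
    return matrix_from_rows(rows)


def table_from_replicates(reps: dict, run_id: str = "run1") -> CqTable:
    """Build a CqTable from {(gene, sample): [replicate cq values]}."""
    obs = []
    for (gene, sample), values in reps.items():
        for i, cq in enumerate(values, start=1):
            obs.append(CqObservation(gene, sample, i, run_id, cq))
    return CqTable(observations=obs)


@pytest.fixture
def three_gene_lq_matrix() -> AggregatedCqMatrix:
    """Hand-checkable fixture: A and B track exactly, C wobbles."""
    return matrix_from_rows(
        {"A": [20, 21, 22, 23], "B": [22, 23, 24, 25], "C": [20, 22, 21, 24]}
    )
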