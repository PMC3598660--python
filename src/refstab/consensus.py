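"""RefFinder-style aggregation, rank-sum consensus, and algorithm agreement.

The consensus layer never looks at stability values, only at ranks: each
algorithm contributes its fractional rank vector, RefFinder condenses the
four base algorithms into the geometric mean of a gene's four ranks, and
the final ordering sums a gene's ranks across all five algorithms (four
base + RefFinder), lowest sum first.  Including RefFinder in the sum
double-counts the base algorithms to a degree; it is kept because the
five-algorithm rank sum is the procedure this package standardises.

Agreement between algorithms is summarised as the Pearson correlation
between their rank vectors, with two-sided p-values from the usual
t-transform on G-2 degrees of freedom.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .stability import StabilityResult, _ranks_from_values


@dataclass
class ConsensusReport:
    """Final gene ordering plus everything it was derived from."""

    per_algorithm_ranks: dict[str, dict[str, float]]
    reffinder_geomean: dict[str, float]
    rank_sum: dict[str, float]
    final_order: list[str]
    correlation: pd.DataFrame | None = field(default=None, repr=False)
    correlation_pvalues: pd.DataFrame | None = field(default=None, repr=False)
    tie_breaks: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _common_genes(results: list[StabilityResult]) -> list[str]:
    gene_sets = [set(r.values) for r in results]
    union = set.union(*gene_sets)
    inter = set.intersection(*gene_sets)
    if union != inter:
        raise ValidationError(
            f"gene sets differ between algorithms: {sorted(union - inter)}"
        )
    return sorted(inter)


def reffinder_aggregate(base_results: list[StabilityResult]) -> StabilityResult:
    """Geometric mean of a gene's ranks across the four base algorithms.

    The comprehensive-ranking convention: each base algorithm's rank is the
    gene's weight, the four weights are combined by geometric mean, and the
    genes are re-ranked ascending on that mean (fractional ties).
    """
    if len(base_results) != 4:
        raise ValidationError(
            f"expected 4 base results, got {len(base_results)}"
        )
    genes = _common_genes(base_results)
    values = {
        g: float(stats.gmean([r.ranks[g] for r in base_results])) for g in genes
    }
    return StabilityResult("reffinder", values, _ranks_from_values(values))


def rank_sum_consensus(all_results: list[StabilityResult]) -> ConsensusReport:
    """Sum each gene's ranks over the five algorithms; lowest sum wins.

    Ties in the rank sum are broken by the RefFinder geometric-mean rank,
    then lexicographically by gene id; every applied tie-break is recorded
    in ``tie_breaks``.
    """
    if len(all_results) != 5:
        raise ValidationError(f"expected 5 results, got {len(all_results)}")
    by_alg = {r.algorithm: r for r in all_results}
    if "reffinder" not in by_alg or len(by_alg) != 5:
        raise ValidationError(
            "need four distinct base algorithms plus reffinder, got "
            + ", ".join(sorted(r.algorithm for r in all_results))
        )
    genes = _common_genes(all_results)
    reff = by_alg["reffinder"]
    rank_sum = {
        g: float(sum(r.ranks[g] for r in all_results)) for g in genes
    }
    geo = {g: reff.values[g] for g in genes}
    final_order = sorted(genes, key=lambda g: (rank_sum[g], geo[g], g))
    tie_breaks = []
    for a, b in zip(final_order, final_order[1:]):
        if rank_sum[a] == rank_sum[b]:
            how = (
                "reffinder geometric-mean rank"
                if geo[a] != geo[b]
                else "lexicographic gene id"
            )
            tie_breaks.append(
                f"{a} before {b}: equal rank sum {rank_sum[a]}, broken by {how}"
            )
    report = ConsensusReport(
        per_algorithm_ranks={a: dict(by_alg[a].ranks) for a in by_alg},
        reffinder_geomean=geo,
        rank_sum=rank_sum,
        final_order=final_order,
        tie_breaks=tie_breaks,
    )
    corr, pvals, warns = algorithm_correlation(all_results)
    report.correlation = corr
    report.correlation_pvalues = pvals
    report.warnings.extend(warns)
    return report


def algorithm_correlation(
    all_results: list[StabilityResult], on_values: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pearson correlation between the algorithms' rank vectors.

    Returns (r matrix, p matrix, warnings).  ``on_values=True`` correlates
    raw stability values instead of ranks, for sensitivity analysis.  A
    constant vector (all genes tied) makes r undefined for every pair it
    enters; those cells are NaN and a warning is emitted.
    """
    genes = _common_genes(all_results)
    if len(genes) < 4:
        raise InsufficientDataError(
            f"correlation needs >= 4 genes, got {len(genes)}"
        )
    names = [r.algorithm for r in all_results]
    vectors = {
        r.algorithm: np.array(
            [(r.values if on_values else r.ranks)[g] for g in genes]
        )
        for r in all_results
    }
    r_mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p_mat = pd.DataFrame(np.nan, index=names, columns=names)
    warns: list[str] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.ptp(vectors[a]) == 0 or np.ptp(vectors[b]) == 0:
                r_mat.loc[a, b] = r_mat.loc[b, a] = np.nan
                warns.append(
                    f"correlation {a} vs {b} undefined: constant rank vector"
                )
                continue
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                r, p = stats.pearsonr(vectors[a], vectors[b])
            r_mat.loc[a, b] = r_mat.loc[b, a] = float(r)
            p_mat.loc[a, b] = p_mat.loc[b, a] = float(p)
    return r_mat, p_mat, warns
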