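"""The four base expression-stability algorithms.

All four operate on an aggregated gene x sample Cq matrix and emit a
stability value per gene where *lower means more stable*, plus a fractional
(average-on-ties) rank vector, so their outputs are directly comparable and
can feed rank aggregation.

* geNorm: a gene's M value is the mean, over all other candidates, of the
  sample standard deviation of the pairwise log2 expression ratio.  The
  least stable gene (largest M) is removed and M recomputed until two genes
  remain; those two cannot be separated and tie for the top rank.
* comparative dCt: mean, over partners, of the SD of the pairwise Cq
  difference.  With a common amplification factor of 2 this is identical to
  geNorm's first-pass M, because the log2 ratio of quantities is exactly
  the negated dCq.
* BestKeeper: descriptive-statistics based.  A gene's dispersion is the
  mean absolute deviation of its Cq from its own mean (the original tool's
  "SD (+/- Cq)" convention); the BestKeeper index -- the per-sample
  geometric mean of all genes' Cq -- serves as a pseudo-reference against
  which each gene's Pearson correlation is reported.
* NormFinder: a model-based variance decomposition.  Log2 quantities are
  modelled as gene effect + sample effect + noise; the per-gene noise
  variance is estimated from the two-way residuals with a bias correction
  that removes the leakage of other genes' variance through the sample
  means.  With group labels, intra-group variance and inter-group
  expression deviation are combined into a single stability value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, GroupingError, InsufficientDataError
from .qc import AggregatedCqMatrix

ALGORITHMS = ("genorm", "normfinder", "bestkeeper", "delta_ct", "reffinder")


@dataclass
class LogQuantityMatrix:
    """Gene x sample log2 relative quantities.

    Each gene's row is anchored at its own minimum Cq, so the maximum logq
    per gene is 0 and all entries are <= 0.  The anchor is arbitrary --
    every downstream statistic uses only within-gene differences, in which
    any per-gene constant cancels -- and is chosen to keep the numbers
    small and interpretable (logq = fold-change below the most abundant
    sample, in log2 units).
    """

    logq: pd.DataFrame
    base_efficiencies: dict[str, float]

    @property
    def genes(self) -> list[str]:
        return list(self.logq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.logq.columns)


@dataclass
class StabilityResult:
    """Per-gene stability values and ranks from one algorithm.

    ``values`` maps gene -> stability (lower = more stable); ``ranks`` maps
    gene -> fractional rank (1 = most stable; tied genes share the average
    of their positions).  ``details`` carries algorithm-specific extras,
    e.g. the geNorm removal order or the BestKeeper descriptive table.
    """

    algorithm: str
    values: dict[str, float]
    ranks: dict[str, float]
    details: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if set(self.values) != set(self.ranks):
            raise ValueError("values and ranks cover different gene sets")

    def rank_vector(self, genes: list[str]) -> np.ndarray:
        return np.array([self.ranks[g] for g in genes], dtype=float)


def _ranks_from_values(values: dict[str, float]) -> dict[str, float]:
    genes = list(values)
    ranks = stats.rankdata([values[g] for g in genes], method="average")
    return dict(zip(genes, ranks.astype(float)))


def to_log_quantities(
    matrix: AggregatedCqMatrix,
    efficiencies: dict[str, float] | None = None,
) -> LogQuantityMatrix:
    """Convert mean Cq to log2 relative quantities.

    ``logq[g, s] = (min_u Cq[g, u] - Cq[g, s]) * log2(E_g)`` where ``E_g``
    is the gene's amplification factor per cycle (default exactly 2.0,
    i.e. ideal doubling).  ``efficiencies`` maps gene -> amplification
    factor; convert a percent efficiency with ``1 + pct / 100``.
    """
    eff = dict(efficiencies or {})
    cq = matrix.mean_cq
    rows = {}
    factors = {}
    for gene in cq.index:
        factor = float(eff.get(gene, 2.0))
        if factor <= 1.0 or not math.isfinite(factor):
            raise DomainError(
                f"gene {gene}: amplification factor must be > 1, got {factor}"
            )
        row = cq.loc[gene]
        if row.notna().sum() < 2:
            raise InsufficientDataError(
                f"gene {gene}: needs >= 2 non-missing samples"
            )
        rows[gene] = (row.min() - row) * math.log2(factor)
        factors[gene] = factor
    logq = pd.DataFrame(rows).T.reindex(index=cq.index, columns=cq.columns)
    return LogQuantityMatrix(logq=logq, base_efficiencies=factors)


def _pairwise_sd(a: pd.Series, b: pd.Series, min_overlap: int = 3) -> float:
    """Sample SD of (a - b) over pairwise-complete entries."""
    diff = (a - b).dropna()
    if len(diff) < min_overlap:
        raise InsufficientDataError(
            f"pairwise overlap {len(diff)} < {min_overlap} samples"
        )
    return float(diff.std(ddof=1))


def _m_values(logq: pd.DataFrame) -> pd.Series:
    """geNorm M per gene: mean over partners of the pairwise log-ratio SD."""
    genes = list(logq.index)
    m = {}
    for g in genes:
        sds = [_pairwise_sd(logq.loc[g], logq.loc[k]) for k in genes if k != g]
        m[g] = float(np.mean(sds))
    return pd.Series(m)


def genorm_m_values(lq: LogQuantityMatrix) -> dict[str, float]:
    """First-pass geNorm M for every gene, before any exclusion step.

    With a common amplification factor of exactly 2 this coincides with
    the comparative-dCt stability value gene by gene.
    """
    if len(lq.logq.index) < 3:
        raise InsufficientDataError(
            f"geNorm needs >= 3 genes, got {len(lq.logq.index)}"
        )
    return _m_values(lq.logq).to_dict()


def genorm(lq: LogQuantityMatrix) -> StabilityResult:
    """geNorm stepwise-exclusion stability ranking.

    Computes M for all genes, removes the gene with the largest M (ties
    broken toward the lexicographically larger gene id, recorded in
    ``details``), and repeats until two genes remain.  A gene's reported
    value is its M at the iteration of its removal; the surviving pair
    keeps its final M and ties for the top rank (1.5 each), since geNorm
    cannot order the last two genes.
    """
    logq = lq.logq
    if len(logq.index) < 3:
        raise InsufficientDataError(
            f"geNorm needs >= 3 genes, got {len(logq.index)}"
        )
    remaining = list(logq.index)
    values: dict[str, float] = {}
    removal_log: list[tuple[int, str, float]] = []
    iteration = 0
    while len(remaining) > 2:
        iteration += 1
        m = _m_values(logq.loc[remaining])
        worst_m = m.max()
        worst = sorted(g for g in remaining if m[g] == worst_m)[-1]
        values[worst] = float(m[worst])
        removal_log.append((iteration, worst, float(m[worst])))
        remaining.remove(worst)
    final_m = _m_values(logq.loc[remaining])
    for g in remaining:
        values[g] = float(final_m[g])

    # Ordering by removal: survivors first (tied), then reverse removal order.
    order = sorted(remaining) + [g for _, g, _ in reversed(removal_log)]
    base_rank = {g: float(i + 1) for i, g in enumerate(order)}
    for g in remaining:
        base_rank[g] = 1.5
    # Merge rank ties for genes with exactly equal stability values.
    ranks: dict[str, float] = {}
    for v in set(values.values()):
        tied = [g for g in values if values[g] == v]
        mean_rank = float(np.mean([base_rank[g] for g in tied]))
        for g in tied:
            ranks[g] = mean_rank
    details = pd.DataFrame(
        removal_log, columns=["iteration", "gene", "m_at_removal"]
    )
    return StabilityResult("genorm", values, ranks, details)


@dataclass
class PairwiseVariationResult:
    """geNorm V(n/n+1) sequence and the implied number of references."""

    v_values: list[float]  # V(2/3), V(3/4), ..., V(G-1/G)
    gene_order: list[str]  # most stable first
    optimal_n: int | None  # smallest n with V(n/n+1) < threshold
    threshold: float


def genorm_pairwise_variation(
    lq: LogQuantityMatrix, threshold: float = 0.15
) -> PairwiseVariationResult:
    """Pairwise variation V(n/n+1) between successive normalization factors.

    For the top-n genes in geNorm order the (log2) normalization factor of
    sample s is the mean of their logq values -- the log of the geometric
    mean of their relative quantities.  V(n/n+1) is the sample SD, across
    samples, of the difference between the n-gene and (n+1)-gene factors.
    The smallest n with V below ``threshold`` (conventionally 0.15) is
    reported as the number of reference genes that suffices; None if no n
    reaches it.
    """
    result = genorm(lq)
    order = sorted(result.ranks, key=lambda g: (result.ranks[g], g))
    logq = lq.logq
    v_values: list[float] = []
    for n in range(2, len(order)):
        nf_n = logq.loc[order[:n]].mean(axis=0)
        nf_n1 = logq.loc[order[: n + 1]].mean(axis=0)
        v_values.append(float((nf_n - nf_n1).dropna().std(ddof=1)))
    optimal_n = next(
        (n for n, v in zip(range(2, len(order)), v_values) if v < threshold), None
    )
    return PairwiseVariationResult(v_values, order, optimal_n, threshold)


def delta_ct_stability(matrix: AggregatedCqMatrix) -> StabilityResult:
    """Comparative dCt stability: mean pairwise SD of Cq differences.

    For each gene pair the per-sample Cq difference is formed and its
    sample SD taken; a gene's stability is the mean of these SDs over all
    partners.  A gene whose expression tracks every other gene (constant
    differences) scores 0.
    """
    cq = matrix.mean_cq
    genes = list(cq.index)
    if len(genes) < 3:
        raise InsufficientDataError(
            f"comparative dCt needs >= 3 genes, got {len(genes)}"
        )
    values = {}
    for g in genes:
        sds = [_pairwise_sd(cq.loc[g], cq.loc[k]) for k in genes if k != g]
        values[g] = float(np.mean(sds))
    return StabilityResult("delta_ct", values, _ranks_from_values(values))


def bestkeeper(
    matrix: AggregatedCqMatrix, use_sample_sd: bool = False
) -> StabilityResult:
    """BestKeeper descriptive statistics and index correlation.

    Per gene: arithmetic and geometric mean, min and max Cq, the dispersion
    SD+ (mean absolute deviation from the gene's arithmetic mean, or the
    n-1 sample SD when ``use_sample_sd``), and CV% = 100 * SD+ / mean.  The
    BestKeeper index is the per-sample geometric mean of Cq over all genes
    (samples with a missing value are omitted from the index); each gene's
    Pearson r against the index and its two-sided p-value are reported in
    ``details``.  The stability value is SD+; genes with SD+ > 1 cycle are
    flagged inconsistent.
    """
    cq = matrix.mean_cq
    genes = list(cq.index)
    if len(genes) < 2 or len(cq.columns) < 3:
        raise InsufficientDataError(
            "BestKeeper needs >= 2 genes and >= 3 samples"
        )
    if (cq <= 0).any().any():
        raise DomainError(
            "BestKeeper requires positive Cq values (geometric mean undefined)"
        )
    complete = cq.columns[cq.notna().all(axis=0)]
    index = np.exp(np.log(cq[complete]).mean(axis=0))
    rows = []
    values = {}
    for g in genes:
        row = cq.loc[g].dropna()
        mean = float(row.mean())
        dev = (
            float(row.std(ddof=1))
            if use_sample_sd
            else float((row - mean).abs().mean())
        )
        values[g] = dev
        aligned = cq.loc[g, complete]
        if len(complete) >= 3 and aligned.std(ddof=1) > 0 and index.std(ddof=1) > 0:
            r, p = stats.pearsonr(aligned, index)
        else:
            r, p = float("nan"), float("nan")
        rows.append(
            {
                "gene": g,
                "n": int(row.size),
                "mean_cq": mean,
                "geo_mean_cq": float(np.exp(np.log(row).mean())),
                "min_cq": float(row.min()),
                "max_cq": float(row.max()),
                "sd_plus": dev,
                "cv_percent": 100.0 * dev / mean,
                "r_vs_index": float(r),
                "p_value": float(p),
                "inconsistent": dev > 1.0,
            }
        )
    details = pd.DataFrame(rows).set_index("gene")
    details.attrs["index_values"] = index
    return StabilityResult("bestkeeper", values, _ranks_from_values(values), details)


def _normfinder_variances(y: np.ndarray) -> np.ndarray:
    """Per-gene noise variance estimates from a complete log-quantity matrix.

    Two-way residuals r[g,s] = y[g,s] - rowmean - colmean + grandmean give
    raw per-gene mean squares u_g = sum_s r[g,s]^2 / (n-1).  Because the
    column means mix all genes' noise, E[u_g] = (1 - 2/k) sigma_g^2 +
    sum_h sigma_h^2 / k^2; solving the resulting linear system yields the
    unbiased estimator implemented here, truncated at zero.
    """
    k, n = y.shape
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    u = (resid**2).sum(axis=1) / (n - 1)
    total = u.sum()
    var = (k / (k - 2)) * (u - total / (k * (k - 1)))
    return np.maximum(var, 0.0)


def normfinder(
    matrix: AggregatedCqMatrix,
    use_groups: bool = False,
    efficiencies: dict[str, float] | None = None,
) -> StabilityResult:
    """NormFinder model-based stability estimation.

    Works on log2 quantities (see :func:`to_log_quantities`).  Ungrouped,
    the stability value is the estimated per-gene noise SD sigma_g.  With
    ``use_groups``, the noise variance is estimated within each sample
    group and combined with the gene's inter-group expression deviation
    d_{g,grp} (how far the gene's group mean departs from the panel
    average) as mean over groups of ``|d| + sqrt(sigma^2_grp / n_grp)``, so
    genes whose expression is confounded with the grouping are penalised
    even when their within-group noise is small.  No shrinkage is applied
    to d by default.

    Requires a complete matrix (no missing cells): subset with
    :meth:`AggregatedCqMatrix.complete_subset` first if needed.  Needs at
    least 4 genes; every group must have at least 3 samples.
    """
    lq = to_log_quantities(matrix, efficiencies)
    y_df = lq.logq
    genes = list(y_df.index)
    k = len(genes)
    if k < 4:
        raise InsufficientDataError(f"NormFinder needs >= 4 genes, got {k}")
    if y_df.isna().any().any():
        raise InsufficientDataError(
            "NormFinder requires a complete matrix; drop incomplete samples"
            " first (AggregatedCqMatrix.complete_subset)"
        )
    y = y_df.to_numpy(dtype=float)
    samples = list(y_df.columns)

    if not use_groups:
        sigma = np.sqrt(_normfinder_variances(y))
        values = {g: float(s) for g, s in zip(genes, sigma)}
        details = pd.DataFrame({"sigma_hat": sigma}, index=genes)
        return StabilityResult(
            "normfinder", values, _ranks_from_values(values), details
        )

    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(matrix.group_of.get(s, "all"), []).append(i)
    for label, idx in groups.items():
        if len(idx) < 3:
            raise GroupingError(
                f"group {label!r} has {len(idx)} samples, need >= 3"
            )
    z = y - y.mean(axis=0, keepdims=True)  # remove per-sample loading effect
    overall = z.mean(axis=1)
    rows = []
    values = {}
    for gi, g in enumerate(genes):
        terms = []
        for label, idx in groups.items():
            var_grp = _normfinder_variances(y[:, idx])[gi]
            d = z[gi, idx].mean() - overall[gi]
            terms.append(abs(d) + math.sqrt(var_grp / len(idx)))
            rows.append(
                {"gene": g, "group": label, "d": d,
                 "sigma2_group": var_grp, "n_group": len(idx)}
            )
        values[g] = float(np.mean(terms))
    details = pd.DataFrame(rows)
    return StabilityResult("normfinder", values, _ranks_from_values(values), details)
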