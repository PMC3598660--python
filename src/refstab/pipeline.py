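"""End-to-end convenience: raw Cq table -> consensus report."""

from __future__ import annotations

from .consensus import ConsensusReport, rank_sum_consensus, reffinder_aggregate
from .qc import AggregatedCqMatrix, aggregate_replicates
from .io import CqTable
from .stability import (
    StabilityResult,
    bestkeeper,
    delta_ct_stability,
    genorm,
    normfinder,
    to_log_quantities,
)


def run_stability_pipeline(
    data: CqTable | AggregatedCqMatrix,
    efficiencies: dict[str, float] | None = None,
    use_groups: bool | None = None,
    max_cq: float = 35.0,
) -> tuple[ConsensusReport, dict[str, StabilityResult]]:
    """Run QC, the four base algorithms, RefFinder and the rank-sum consensus.

    ``data`` may be a replicate-level :class:`CqTable` (aggregated here
    with the ``max_cq`` filter) or an already aggregated matrix.
    ``use_groups`` controls whether NormFinder uses the sample group
    labels; ``None`` autodetects (groups are used when more than one label
    is present and every group has at least 3 samples).  NormFinder runs
    on the complete-sample subset of the matrix; the other algorithms use
    all pairwise-complete data.

    Returns the consensus report and the five per-algorithm results.
    """
    if isinstance(data, CqTable):
        matrix, _ = aggregate_replicates(data, max_cq=max_cq)
    else:
        matrix = data

    labels = set(matrix.group_of.values())
    if use_groups is None:
        counts = {g: 0 for g in labels}
        for g in matrix.group_of.values():
            counts[g] += 1
        use_groups = len(labels) > 1 and all(c >= 3 for c in counts.values())

    lq = to_log_quantities(matrix, efficiencies)
    base = [
        genorm(lq),
        delta_ct_stability(matrix),
        bestkeeper(matrix),
        normfinder(
            matrix.complete_subset(), use_groups=use_groups,
            efficiencies=efficiencies,
        ),
    ]
    reff = reffinder_aggregate(base)
    report = rank_sum_consensus(base + [reff])
    return report, {r.algorithm: r for r in base + [reff]}
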