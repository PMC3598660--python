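"""Replicate filtering, aggregation and technical-variability QC.

The filtering rule is the conventional late-amplification cutoff: replicate
Cq values above ``max_cq`` (default 35 cycles) are treated as unreliable --
at that point the signal is close to the stochastic detection limit -- and
are excluded before averaging.  Filtering happens at replicate level rather
than on the replicate mean, so a single failed well cannot drag an otherwise
clean triplicate above the cutoff.

Negative controls (no-template and no-reverse-transcriptase wells) are
judged by the same cutoff: amplification later than ``max_cq`` indicates
negligible contamination, earlier amplification is a genuine failure.  A
failing control is reported, never auto-excluded -- whether a gene with a
dirty control stays in the panel is the analyst's call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .io import CqTable

#: Closed vocabulary of replicate-exclusion reasons.
EXCLUSION_REASONS = ("cq_above_cutoff", "missing", "control_fail")


@dataclass
class QcFlags:
    """Everything the QC layer excluded or found suspicious.

    ``contamination`` rows are (gene, control_type, cq, verdict) where the
    verdict is ``"negligible"`` (amplification after the cutoff) or
    ``"fail"`` (amplification at or before it).  ``excluded_observations``
    rows are (gene, sample, replicate_index, reason) with reasons drawn from
    :data:`EXCLUSION_REASONS`.
    """

    contamination: list[tuple[str, str, float, str]] = field(default_factory=list)
    excluded_observations: list[tuple[str, str, int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for (_, _, _, reason) in self.excluded_observations:
            if reason not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason {reason!r}")


@dataclass
class AggregatedCqMatrix:
    """Gene x sample matrix of mean Cq after replicate filtering.

    ``mean_cq`` is a genes-by-samples DataFrame (NaN = no surviving
    replicate); ``n_used`` counts the replicates behind each mean;
    ``group_of`` carries the sample group labels for subgroup analyses.
    """

    mean_cq: pd.DataFrame
    n_used: pd.DataFrame
    group_of: dict[str, str]

    @property
    def genes(self) -> list[str]:
        return list(self.mean_cq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.mean_cq.columns)

    def complete_subset(self) -> "AggregatedCqMatrix":
        """Drop samples with any missing gene value (needed by NormFinder)."""
        keep = self.mean_cq.columns[self.mean_cq.notna().all(axis=0)]
        return AggregatedCqMatrix(
            mean_cq=self.mean_cq[keep].copy(),
            n_used=self.n_used[keep].copy(),
            group_of={s: g for s, g in self.group_of.items() if s in set(keep)},
        )


def aggregate_replicates(
    table: CqTable, max_cq: float = 35.0
) -> tuple[AggregatedCqMatrix, QcFlags]:
    """Filter replicate Cq values and average the survivors per (gene, sample).

    Replicates with missing Cq or Cq > ``max_cq`` are excluded and logged in
    the returned :class:`QcFlags`; the remaining replicates are averaged
    arithmetically.  A cell with no surviving replicate is NaN; a gene with
    no surviving value in any sample is kept as an all-missing row and
    flagged with a warning rather than silently dropped.
    """
    if not (0 < max_cq):
        raise DomainError(f"max_cq must be positive, got {max_cq}")
    flags = QcFlags()
    genes = table.gene_ids
    samples = table.sample_ids
    sums = pd.DataFrame(0.0, index=genes, columns=samples)
    counts = pd.DataFrame(0, index=genes, columns=samples)
    for obs in table.observations:
        if obs.well_role != "sample":
            continue
        if obs.cq is None:
            flags.excluded_observations.append(
                (obs.gene_id, obs.sample_id, obs.replicate_index, "missing")
            )
        elif obs.cq > max_cq:
            flags.excluded_observations.append(
                (obs.gene_id, obs.sample_id, obs.replicate_index, "cq_above_cutoff")
            )
        else:
            sums.loc[obs.gene_id, obs.sample_id] += obs.cq
            counts.loc[obs.gene_id, obs.sample_id] += 1
    mean_cq = sums.where(counts > 0) / counts.where(counts > 0)
    for gene in genes:
        if counts.loc[gene].sum() == 0:
            flags.warnings.append(f"gene {gene}: no surviving Cq value in any sample")
    return (
        AggregatedCqMatrix(mean_cq=mean_cq, n_used=counts, group_of=table.group_of()),
        flags,
    )


def flag_contamination(table: CqTable, max_cq: float = 35.0) -> QcFlags:
    """Judge negative-control wells against the late-amplification cutoff.

    No amplification (missing Cq) emits no flag; amplification later than
    ``max_cq`` is flagged ``negligible``; amplification at or before it is
    flagged ``fail``.  If the table carries no control wells at all, a
    warning is recorded and the flag list stays empty.
    """
    flags = QcFlags()
    n_controls = 0
    for obs in table.observations:
        if obs.well_role == "sample":
            continue
        n_controls += 1
        if obs.cq is None:
            continue
        verdict = "negligible" if obs.cq > max_cq else "fail"
        flags.contamination.append((obs.gene_id, obs.well_role, obs.cq, verdict))
    if n_controls == 0:
        flags.warnings.append("no negative-control wells present in table")
    return flags


def coefficient_of_variation(values) -> float:
    """Percent CV: 100 x sample SD (n-1 denominator) / arithmetic mean.

    Raises :class:`InsufficientDataError` for fewer than two values and
    :class:`DomainError` when the mean is zero (CV undefined).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"CV needs at least 2 values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise DomainError("CV requires finite values")
    mean = arr.mean()
    if mean == 0:
        raise DomainError("CV undefined: mean of values is zero")
    return 100.0 * arr.std(ddof=1) / mean


def assay_variability(table: CqTable, mode: str) -> pd.DataFrame:
    """Intra- or inter-assay CV of Cq, per gene.

    mode="intra": CV across replicate Cq within each (gene, sample, run),
    averaged per gene.  mode="inter": per-run mean Cq is formed for each
    (gene, sample), the CV is taken across runs, then averaged per gene.
    Returns a DataFrame indexed by gene with columns ``cv_percent`` and
    ``n_units`` (the number of (sample[, run]) units that contributed).
    """
    if mode not in ("intra", "inter"):
        raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")
    rows = [
        (o.gene_id, o.sample_id, o.run_id, o.cq)
        for o in table.observations
        if o.well_role == "sample" and o.cq is not None
    ]
    df = pd.DataFrame(rows, columns=["gene", "sample", "run", "cq"])
    per_gene: dict[str, tuple[float, int]] = {}
    for gene, sub in df.groupby("gene", sort=False):
        cvs: list[float] = []
        if mode == "intra":
            for _, grp in sub.groupby(["sample", "run"], sort=False):
                if len(grp) >= 2:
                    cvs.append(coefficient_of_variation(grp["cq"]))
        else:
            run_means = sub.groupby(["sample", "run"], sort=False)["cq"].mean()
            for _, by_sample in run_means.groupby(level=0, sort=False):
                if len(by_sample) >= 2:
                    cvs.append(coefficient_of_variation(by_sample))
        if not cvs:
            raise InsufficientDataError(
                f"gene {gene}: no unit with the replication required for"
                f" {mode}-assay CV"
            )
        per_gene[gene] = (float(np.mean(cvs)), len(cvs))
    out = pd.DataFrame.from_dict(
        per_gene, orient="index", columns=["cv_percent", "n_units"]
    )
    out.index.name = "gene"
    out["n_units"] = out["n_units"].astype(int)
    return out
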