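"""Reading and writing the delimited-text formats used throughout refstab.

The canonical on-disk representation of quantification-cycle (Cq) data is a
long-format CSV with one well (one replicate of one gene in one sample) per
row.  Long format keeps replicate- and run-level structure that a wide
gene x sample matrix would lose, and that structure is exactly what the QC
and assay-variability computations need.

Non-detects (wells that never crossed the fluorescence threshold) are encoded
as an empty field or the literal ``ND`` on disk and as ``None`` in memory --
never as 0 or as the terminal cycle count, because a non-detect is a distinct
state from a late but real amplification.

All text I/O is UTF-8 with ``.`` as the decimal separator and ``,`` as the
field delimiter.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ValidationError

#: Well roles understood by the QC layer.
WELL_ROLES = ("sample", "no_template_control", "no_rt_control")

#: Default total number of PCR cycles; Cq values cannot exceed it.
TOTAL_CYCLES = 40.0

_MISSING_TOKENS = {"", "ND", "nd", "NA", "NaN", "nan"}


@dataclass(frozen=True)
class CqObservation:
    """A single replicate-level Cq measurement.

    Parameters
    ----------
    gene_id, sample_id, run_id
        Identifiers of the assay, the biological sample and the plate/run.
    replicate_index
        1-based index of the technical replicate within (gene, sample, run).
    cq
        Quantification cycle, or ``None`` for a non-detect.
    well_role
        ``"sample"`` for measurement wells, ``"no_template_control"`` (NTC)
        or ``"no_rt_control"`` (reverse-transcriptase-negative) for the two
        contamination controls.
    """

    gene_id: str
    sample_id: str
    replicate_index: int
    run_id: str
    cq: float | None
    well_role: str = "sample"

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be >= 1, got {self.replicate_index}"
            )
        if self.well_role not in WELL_ROLES:
            raise ValidationError(
                f"well_role {self.well_role!r} not one of {WELL_ROLES}"
            )
        if self.cq is not None:
            if not math.isfinite(self.cq) or self.cq < 0 or self.cq > TOTAL_CYCLES:
                raise ValidationError(
                    f"cq must be finite and within [0, {TOTAL_CYCLES}], got {self.cq}"
                )

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.gene_id, self.sample_id, self.replicate_index, self.run_id)


@dataclass
class CqTable:
    """A validated collection of Cq observations plus per-sample metadata.

    ``sample_meta`` maps each sample id to at least a ``group_label`` (used
    for subgroup stability analyses) and an optional free-text description.
    Samples that appear in measurement wells but carry no explicit metadata
    are assigned the default group ``"all"`` at validation time.
    """

    observations: list[CqObservation]
    sample_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, int, str]] = set()
        for obs in self.observations:
            if obs.key in seen:
                raise ValidationError(f"duplicate observation key {obs.key}")
            seen.add(obs.key)
        for obs in self.observations:
            if obs.well_role == "sample" and obs.sample_id not in self.sample_meta:
                self.sample_meta[obs.sample_id] = {
                    "group_label": "all",
                    "description": "",
                }

    @property
    def gene_ids(self) -> list[str]:
        out: list[str] = []
        for obs in self.observations:
            if obs.well_role == "sample" and obs.gene_id not in out:
                out.append(obs.gene_id)
        return out

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for obs in self.observations:
            if obs.well_role == "sample" and obs.sample_id not in out:
                out.append(obs.sample_id)
        return out

    def group_of(self) -> dict[str, str]:
        return {
            s: self.sample_meta.get(s, {}).get("group_label", "all")
            for s in self.sample_ids
        }


@dataclass(frozen=True)
class DilutionPoint:
    """One point of a standard-curve dilution series.

    ``input_amount`` is the template amount (ng of RNA-equivalent before
    reverse transcription); ``cq_replicates`` are the replicate Cq values at
    that amount, ``None`` marking non-detects.
    """

    gene_id: str
    input_amount: float
    cq_replicates: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if not (self.input_amount > 0 and math.isfinite(self.input_amount)):
            raise ValidationError(
                f"input_amount must be positive and finite, got {self.input_amount}"
            )

    @property
    def mean_cq(self) -> float | None:
        vals = [c for c in self.cq_replicates if c is not None]
        if not vals:
            return None
        return sum(vals) / len(vals)


@dataclass
class DilutionSeries:
    """Per-gene dilution points (descending amount) plus parse warnings."""

    points_by_gene: dict[str, list[DilutionPoint]]
    warnings: list[str] = field(default_factory=list)


def _parse_cq(token: str, row_number: int) -> float | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"row {row_number}: invalid Cq literal {token!r}"
        ) from None


def read_cq_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> CqTable:
    """Read a long-format Cq CSV (columns gene,sample,replicate,run,cq,role).

    Missing Cq values (empty field or ``ND``) are preserved as missing.
    ``metadata_path`` optionally points to a sample,group CSV; samples not
    listed there fall into the default group ``"all"``.

    Raises
    ------
    FormatError
        If a required column is absent or a Cq literal does not parse.
    ValidationError
        If the same (gene, sample, replicate, run) tuple occurs twice.
    """
    path = Path(path)
    required = ["gene", "sample", "replicate", "run", "cq", "role"]
    observations: list[CqObservation] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(
                f"{path.name}: missing required column(s) {', '.join(missing)}"
            )
        for row_number, row in enumerate(reader, start=2):
            try:
                replicate = int(row["replicate"])
            except ValueError:
                raise FormatError(
                    f"row {row_number}: invalid replicate index"
                    f" {row['replicate']!r}"
                ) from None
            observations.append(
                CqObservation(
                    gene_id=row["gene"].strip(),
                    sample_id=row["sample"].strip(),
                    replicate_index=replicate,
                    run_id=row["run"].strip(),
                    cq=_parse_cq(row["cq"], row_number),
                    well_role=row["role"].strip(),
                )
            )
    sample_meta: dict[str, dict[str, str]] = {}
    if metadata_path is not None:
        sample_meta = read_sample_metadata(metadata_path)
    return CqTable(observations=observations, sample_meta=sample_meta)


def read_sample_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a sample,group[,description] CSV into the CqTable metadata map."""
    path = Path(path)
    out: dict[str, dict[str, str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("sample", "group"):
            if col not in header:
                raise FormatError(f"{path.name}: missing required column(s) {col}")
        for row in reader:
            out[row["sample"].strip()] = {
                "group_label": row["group"].strip(),
                "description": (row.get("description") or "").strip(),
            }
    return out


def write_cq_table(
    table: CqTable,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a CqTable back to long-format CSV (round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene", "sample", "replicate", "run", "cq", "role"])
        for obs in table.observations:
            cq = "" if obs.cq is None else format(obs.cq, ".17g")
            writer.writerow(
                [obs.gene_id, obs.sample_id, obs.replicate_index, obs.run_id,
                 cq, obs.well_role]
            )
    if metadata_path is not None:
        with Path(metadata_path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample", "group", "description"])
            for sample, meta in table.sample_meta.items():
                writer.writerow(
                    [sample, meta.get("group_label", "all"),
                     meta.get("description", "")]
                )


def read_dilution_series(path: str | Path) -> DilutionSeries:
    """Read a dilution-series CSV (columns gene,amount[,_ng],cq1..cqR).

    Points are grouped by gene and ordered by descending input amount.
    Duplicate amounts within a gene raise; genes with fewer than three
    distinct amounts are kept but flagged in ``warnings``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if "gene" not in header:
            raise FormatError(f"{path.name}: missing required column(s) gene")
        amount_col = next((c for c in ("amount", "amount_ng") if c in header), None)
        if amount_col is None:
            raise FormatError(f"{path.name}: missing required column(s) amount")
        cq_cols = sorted(
            (c for c in header if c.startswith("cq") and c[2:].isdigit()),
            key=lambda c: int(c[2:]),
        )
        if not cq_cols:
            raise FormatError(f"{path.name}: missing required column(s) cq1..cqR")
        by_gene: dict[str, list[DilutionPoint]] = {}
        for row_number, row in enumerate(reader, start=2):
            try:
                amount = float(row[amount_col])
            except ValueError:
                raise FormatError(
                    f"row {row_number}: invalid amount {row[amount_col]!r}"
                ) from None
            if amount <= 0:
                raise ValidationError(
                    f"row {row_number}: non-positive input amount {amount}"
                )
            reps = tuple(_parse_cq(row[c] or "", row_number) for c in cq_cols)
            by_gene.setdefault(row["gene"].strip(), []).append(
                DilutionPoint(row["gene"].strip(), amount, reps)
            )
    warnings: list[str] = []
    for gene, points in by_gene.items():
        amounts = [p.input_amount for p in points]
        if len(set(amounts)) != len(amounts):
            dupes = sorted({a for a in amounts if amounts.count(a) > 1})
            raise ValidationError(f"gene {gene}: duplicate input amount(s) {dupes}")
        points.sort(key=lambda p: -p.input_amount)
        if len(points) < 3:
            warnings.append(
                f"gene {gene}: only {len(points)} distinct amounts (<3);"
                " a standard curve cannot be fitted"
            )
    return DilutionSeries(points_by_gene=by_gene, warnings=warnings)


def write_report(
    consensus,  # ConsensusReport; imported lazily to avoid a cycle
    stability_results: Iterable,
    out_dir: str | Path,
    extra_summary: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write per-algorithm tables, the consensus table and a key=value summary.

    One CSV per stability algorithm (gene, value, rank), one consensus CSV
    (gene, ranks per algorithm, geometric-mean rank, rank sum, final rank)
    and ``summary.txt`` with run provenance.  Floats are written with 17
    significant digits so a re-read reproduces them bit-exactly.

    Returns a mapping from logical table name to the written path.
    """
    from . import __version__

    results = list(stability_results)
    if not consensus.final_order:
        raise ValidationError("empty gene list: nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def fmt(x: float) -> str:
        return format(float(x), ".17g")

    for res in results:
        p = out_dir / f"stability_{res.algorithm}.csv"
        with p.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["gene", "value", "rank"])
            for gene in sorted(res.values):
                writer.writerow([gene, fmt(res.values[gene]), fmt(res.ranks[gene])])
        written[res.algorithm] = p

    p = out_dir / "consensus.csv"
    algorithms = list(consensus.per_algorithm_ranks)
    with p.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["gene"] + [f"rank_{a}" for a in algorithms]
            + ["reffinder_geomean", "rank_sum", "final_rank"]
        )
        for final_rank, gene in enumerate(consensus.final_order, start=1):
            writer.writerow(
                [gene]
                + [fmt(consensus.per_algorithm_ranks[a][gene]) for a in algorithms]
                + [fmt(consensus.reffinder_geomean[gene]),
                   fmt(consensus.rank_sum[gene]), final_rank]
            )
    written["consensus"] = p

    p = out_dir / "correlation.csv"
    if consensus.correlation is not None:
        consensus.correlation.to_csv(p, float_format="%.17g")
        written["correlation"] = p

    p = out_dir / "summary.txt"
    with p.open("w", encoding="utf-8") as fh:
        fh.write(f"refstab_version={__version__}\n")
        fh.write(f"n_genes={len(consensus.final_order)}\n")
        fh.write(f"algorithms={','.join(algorithms)}\n")
        fh.write(f"final_order={','.join(consensus.final_order)}\n")
        for key, value in (extra_summary or {}).items():
            fh.write(f"{key}={value}\n")
    written["summary"] = p
    return written
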