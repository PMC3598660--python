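"""Synthetic Cq data with known ground truth.

The generator produces exactly the structure the stability algorithms
assume: an additive model on the log2 expression scale,

    x[g, s] = -(beta_s + d_{g, grp(s)} + eps_{g, s}),

where ``beta_s`` is a shared per-sample loading/pipetting shift (the reason
normalization is needed at all), ``d`` is a per-(gene, group) offset that
plants group-confounded genes, and ``eps`` is gene-specific biological
noise with per-gene SD.  The latent expression is mapped to cycles through
each gene's amplification factor (1 log2 unit = 1 cycle at perfect
doubling) and technical replicate noise is added directly on the Cq scale;
the two noise sources are deliberately separate because intra-assay
variability probes the technical one only.  Replicate values above the
dropout threshold are emitted as non-detects, exercising the QC path.

Everything stochastic flows from one seeded generator in a fixed draw
order (sample shifts, then biological noise, then replicate noise), so a
config with the same seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import CqObservation, CqTable, DilutionPoint


@dataclass
class SimulationConfig:
    """Parameters of one synthetic Cq panel.

    Units: ``gene_noise_sd``, ``sample_shift_sd`` and ``group_offsets`` are
    in log2 expression units; ``base_cq``, ``replicate_noise_sd`` and
    ``dropout_cq`` are in cycles.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    replicates: int = 3
    group_labels: dict[str, str] = field(default_factory=dict)
    gene_noise_sd: dict[str, float] = field(default_factory=dict)
    sample_shift_sd: float = 0.5
    group_offsets: dict[tuple[str, str], float] = field(default_factory=dict)
    base_cq: dict[str, float] = field(default_factory=dict)
    efficiency_factor: dict[str, float] = field(default_factory=dict)
    replicate_noise_sd: float = 0.15
    dropout_cq: float = 35.0
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids) or not self.gene_ids:
            raise ValidationError("gene_ids must be unique and non-empty")
        if len(set(self.sample_ids)) != len(self.sample_ids) or not self.sample_ids:
            raise ValidationError("sample_ids must be unique and non-empty")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for name, sd in [("sample_shift_sd", self.sample_shift_sd),
                         ("replicate_noise_sd", self.replicate_noise_sd)]:
            if sd < 0:
                raise ValidationError(f"{name} must be >= 0, got {sd}")
        for g in self.gene_ids:
            if self.gene_noise_sd.get(g, 0.0) < 0:
                raise ValidationError(f"gene_noise_sd[{g}] must be >= 0")
            base = self.base_cq.get(g, 25.0)
            if not (0 < base < 40):
                raise ValidationError(f"base_cq[{g}] must be in (0, 40), got {base}")
            if self.efficiency_factor.get(g, 2.0) <= 1:
                raise ValidationError(f"efficiency_factor[{g}] must be > 1")

    def group_of(self, sample: str) -> str:
        return self.group_labels.get(sample, "all")


@dataclass
class SyntheticTruth:
    """The realized latent variables behind one simulated panel.

    Sufficient, together with the config, to reconstruct every expected Cq
    exactly.  ``planted_stable_set`` identifies the genes a correct
    stability pipeline should rank on top: those sharing the smallest
    noise SD and carrying no group offset.
    """

    seed: int
    sample_shifts: dict[str, float]
    biological_noise: dict[tuple[str, str], float]
    group_offsets: dict[tuple[str, str], float]
    planted_stable_set: frozenset[str]

    def expected_cq(self, config: SimulationConfig, gene: str, sample: str) -> float:
        x = -(
            self.sample_shifts[sample]
            + self.group_offsets.get((gene, config.group_of(sample)), 0.0)
            + self.biological_noise[(gene, sample)]
        )
        factor = config.efficiency_factor.get(gene, 2.0)
        return config.base_cq.get(gene, 25.0) + x / math.log2(factor)


def simulate_cq_dataset(config: SimulationConfig) -> tuple[CqTable, SyntheticTruth]:
    """Draw one synthetic replicate-level Cq table plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, samples = config.gene_ids, config.sample_ids
    # Draw order is part of the contract: shifts, biological noise, replicate noise.
    beta = rng.normal(0.0, config.sample_shift_sd, size=len(samples))
    eps = np.empty((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        eps[gi] = rng.normal(0.0, config.gene_noise_sd.get(g, 0.0), len(samples))
    tech = rng.normal(
        0.0, config.replicate_noise_sd,
        size=(len(genes), len(samples), config.replicates),
    )

    truth = SyntheticTruth(
        seed=config.seed,
        sample_shifts=dict(zip(samples, beta.tolist())),
        biological_noise={
            (g, s): float(eps[gi, si])
            for gi, g in enumerate(genes)
            for si, s in enumerate(samples)
        },
        group_offsets=dict(config.group_offsets),
        planted_stable_set=_planted_stable_set(config),
    )

    observations = []
    sample_meta = {
        s: {"group_label": config.group_of(s), "description": "synthetic"}
        for s in samples
    }
    for gi, g in enumerate(genes):
        for si, s in enumerate(samples):
            expected = truth.expected_cq(config, g, s)
            for rep in range(config.replicates):
                cq = expected + tech[gi, si, rep]
                observations.append(
                    CqObservation(
                        gene_id=g,
                        sample_id=s,
                        replicate_index=rep + 1,
                        run_id="run1",
                        cq=None if cq > config.dropout_cq else float(np.clip(cq, 0.0, 40.0)),
                        well_role="sample",
                    )
                )
    return CqTable(observations=observations, sample_meta=sample_meta), truth


def _planted_stable_set(config: SimulationConfig) -> frozenset[str]:
    offset_genes = {g for (g, _), d in config.group_offsets.items() if d != 0.0}
    clean = [g for g in config.gene_ids if g not in offset_genes]
    if not clean:
        return frozenset()
    min_sd = min(config.gene_noise_sd.get(g, 0.0) for g in clean)
    return frozenset(
        g for g in clean if config.gene_noise_sd.get(g, 0.0) == min_sd
    )


def study_panel_config(seed: int = 0) -> SimulationConfig:
    """The default benchmark panel: 12 genes x 25 samples in triplicate.

    Mirrors the shape of a typical cell-line reference-gene screen: 25
    samples split into three biological subgroups (11 ovarian, 9 colon, 5
    other), three planted stable genes (biological noise SD 0.1 log2
    units), seven genes with noise SDs spread from 0.5 to 1.5, and two
    group-confounded genes (offset magnitude 1.0 log2 units) whose
    within-group noise alone would look acceptable.  Sample loading shifts
    have SD 0.5 log2 units and technical replicate noise SD 0.15 cycles --
    consistent with intra-assay CVs well under 2%.  Base Cq levels span
    18-30 cycles so dropouts at Cq > 35 stay rare.
    """
    genes = [f"REF{i:02d}" for i in range(1, 13)]
    samples = [f"S{i:02d}" for i in range(1, 26)]
    groups = {}
    for i, s in enumerate(samples):
        groups[s] = "ovarian" if i < 11 else ("colon" if i < 20 else "other")
    noise = {
        "REF01": 0.1, "REF02": 0.1, "REF03": 0.1,
        "REF04": 0.5, "REF05": 0.65, "REF06": 0.8, "REF07": 1.0,
        "REF08": 1.15, "REF09": 1.3, "REF10": 1.5,
        "REF11": 0.5, "REF12": 0.5,
    }
    offsets = {
        ("REF11", "ovarian"): 1.0, ("REF11", "colon"): -1.0,
        ("REF12", "colon"): 1.0,
    }
    base = {
        "REF01": 20.0, "REF02": 22.5, "REF03": 19.0, "REF04": 24.0,
        "REF05": 21.0, "REF06": 26.0, "REF07": 18.0, "REF08": 27.5,
        "REF09": 23.0, "REF10": 29.0, "REF11": 25.0, "REF12": 30.0,
    }
    return SimulationConfig(
        gene_ids=genes,
        sample_ids=samples,
        replicates=3,
        group_labels=groups,
        gene_noise_sd=noise,
        sample_shift_sd=0.5,
        group_offsets=offsets,
        base_cq=base,
        replicate_noise_sd=0.15,
        dropout_cq=35.0,
        seed=seed,
    )


def simulate_dilution_series(
    gene_id: str,
    true_slope: float,
    true_intercept: float,
    amounts: list[float],
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> list[DilutionPoint]:
    """Simulate a standard-curve dilution series for one gene.

    Replicate Cq at each amount is ``intercept + slope * log10(amount)``
    plus N(0, noise_sd^2) technical noise.  Amounts must be positive and
    distinct; the slope must be negative (Cq falls with template amount).
    """
    if true_slope >= 0 or not math.isfinite(true_slope):
        raise ValidationError(f"true_slope must be negative, got {true_slope}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if any(a <= 0 for a in amounts):
        raise ValidationError("amounts must be positive")
    if len(set(amounts)) != len(amounts):
        raise ValidationError(f"duplicate amounts in {amounts}")
    rng = np.random.default_rng(seed)
    points = []
    for amount in sorted(amounts, reverse=True):
        expected = true_intercept + true_slope * math.log10(amount)
        reps = expected + rng.normal(0.0, noise_sd, size=replicates)
        points.append(DilutionPoint(gene_id, amount, tuple(float(c) for c in reps)))
    return points
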