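# Methods

This note documents the models, conventions and numerical choices behind
refstab, and what the synthetic benchmark does and does not demonstrate.

## Data model and QC

The raw unit is one well: a replicate-level Cq observation annotated with
gene, sample, run and well role (`sample`, `no_template_control`,
`no_rt_control`). Non-detects are an explicit missing state, distinct from
any numeric Cq — they are never encoded as 0 or as the terminal cycle
count, because "no amplification" and "late amplification" carry different
information (contamination verdicts, dropout handling).

Filtering applies the conventional late-amplification cutoff, Cq > 35
cycles by default, at **replicate level** before averaging. Filtering the
replicates rather than the replicate mean is the stricter choice and keeps
one failed well from dragging an otherwise clean triplicate over the
threshold; of a triplicate (34.9, 35.2, 36.1) only 34.9 survives and the
two exclusions are logged with machine-readable reasons. Count conservation
(wells in = survivors + logged exclusions) is enforced by tests.

Negative controls are judged by the same cutoff: amplification later than
the cutoff is reported as `negligible` contamination, earlier as `fail`. A
failing control never auto-excludes a gene — panels are routinely retained
after a judged-negligible control signal, so the verdict is surfaced and
the decision left to the analyst.

Coefficients of variation use the n−1 sample SD over the arithmetic mean,
in percent. Intra-assay CV is computed within (gene, sample, run) and
averaged per gene; inter-assay CV is computed on per-run means across runs.

## Standard curves and efficiency

The calibration model is `Cq = intercept + slope · log₁₀(amount)`, fitted
by ordinary least squares with replicates averaged per amount first (each
concentration then carries equal weight regardless of surviving replicate
count). The regression is of Cq on log-amount, not the reverse; this is
the orientation under which a 10-fold dilution step costs
`−1/log₁₀(E_factor)` cycles and typical slopes are ≈ −3.3.

Percent efficiency is `E = (10^(−1/slope) − 1) × 100`, undefined for
slope ≥ 0 (a domain error). E is deliberately **not clamped** to the
customary 90–110% band: out-of-band values are real, diagnostically
useful, and only flagged.

`select_linear_range` automates trimming of dilution series that lose
linearity at the extremes (non-detects at the dilute end, saturation at
the concentrated end): amounts with no detected replicate are dropped,
every contiguous sub-range with ≥ `min_points` (default 4) amounts is
fitted, and the highest R² wins. R² ties (within 1e−9, which absorbs
floating-point noise on exactly linear data) resolve toward the wider
range, then toward larger amounts, preserving dynamic range.

## Log-quantity transform

Stability algorithms that work on expression ratios use
`logq[g,s] = (min_u Cq[g,u] − Cq[g,s]) · log₂(E_g)`, with `E_g` the
per-gene amplification factor. Anchoring each gene at its own minimum Cq
makes `logq ≤ 0` with max 0; the anchor is immaterial (any per-gene
constant cancels in every downstream statistic) and is chosen purely for
numerical hygiene. The default factor is exactly 2.0 — fitted efficiencies
can be supplied but are not silently injected, keeping runs reproducible
whether or not curves were measured.

## Stability algorithms

**geNorm.** `M_g` = mean over partners of the sample SD of the pairwise
logq difference; the gene with the largest M is removed (ties broken to
the lexicographically larger id, recorded) and M recomputed until two
genes remain. A gene's reported value is its M at removal; the surviving
pair keeps its final M and ties at rank 1.5, since the algorithm cannot
order the last two. Genes with exactly equal values share their average
rank, so fully degenerate inputs (all genes identical) tie completely.
The pairwise variation V(n/n+1) is the SD across samples of the difference
between the log₂ normalization factors (mean logq) of the top-n and
top-(n+1) genes, with 0.15 as the conventional, configurable sufficiency
threshold.

**Comparative ΔCt.** Mean over partners of the SD of the pairwise Cq
difference. With a common amplification factor of 2 it equals geNorm's
first-pass M gene for gene; the test suite asserts this identity to 1e−10
on random matrices.

**BestKeeper.** Dispersion SD⁺ is the mean absolute deviation of a gene's
Cq from its own mean — the convention of the original spreadsheet tool —
with a flag to switch to the n−1 SD. The BestKeeper index is the
per-sample geometric mean of Cq over genes (samples with missing values
are omitted from the index); per-gene Pearson r against the index and its
two-sided p-value are reported descriptively. The stability value is SD⁺;
SD⁺ > 1 cycle flags a gene `inconsistent`. Note BestKeeper is the one
algorithm sensitive to per-sample loading shifts — deliberately so, since
it operates on raw Cq dispersion; the invariance tests assert this
asymmetry in both directions.

**NormFinder.** On a complete logq matrix, two-way residuals
`r = y − rowmean − colmean + grand mean` give raw per-gene mean squares
`u_g = Σ_s r²/(n−1)`. Because per-sample means mix all genes' noise,
`E[u_g] = (1−2/k)σ²_g + Σσ²/k²`; inverting this linear map gives
`σ̂²_g = max(0, k/(k−2)·(u_g − U/(k(k−1))))`, unbiased for σ²_g wherever
the zero-truncation is inactive. The ungrouped stability value is σ̂_g.
With groups, the variance is estimated within each group and combined with
the inter-group deviation `d_{g,grp}` (the gene's column-centred group
mean minus its overall column-centred mean) as
`mean_grp(|d| + √(σ̂²_grp/n_grp))`; no shrinkage is applied to d, keeping
the combination transparent and directly testable. NormFinder requires at
least 4 genes (the k/(k−2) correction needs k ≥ 4 for stability), groups
of at least 3 samples, and a complete matrix — callers subset to complete
samples first (`AggregatedCqMatrix.complete_subset`), since the two-way
decomposition has no principled treatment of holes.

A known small-sample caveat: σ̂²_g is unbiased for the **variance**, but
the reported SD σ̂_g is not unbiased for σ_g. When a gene's true variance
is small relative to the estimator's sampling noise — which is dominated
by the Σσ²/k² leak from the noisiest panel members — the square root's
concavity biases mean σ̂ downward by ~15% and the zero-truncation biases
σ̂² upward; at k = 6, n = 100 this becomes material below roughly σ = 0.2
log₂ units. This does not affect rankings (the bias is monotone) but
matters if σ̂ is read as an absolute noise estimate.

## Consensus

All aggregation runs on fractional ranks (ties get the average of their
positions, so ranks are ≥ 1 and geometric means stay well-defined). The
RefFinder aggregate is the geometric mean of a gene's four base ranks,
re-ranked ascending. The final ordering sums ranks over all five
algorithms — the four base plus RefFinder, which double-counts the base
algorithms but is exactly the consensus procedure this package
standardises. Rank-sum ties break by RefFinder geometric mean, then
lexicographic gene id, and every applied tie-break is recorded in the
report rather than hidden. Algorithm agreement is the Pearson correlation
between rank vectors (a flag switches to raw values for sensitivity
analysis); constant rank vectors make r undefined and are reported as
missing with a warning, not as 0.

## Synthetic data generator

Latent log₂ expression is `x[g,s] = −(β_s + d_{g,grp(s)} + ε_{g,s})` with
`β_s ~ N(0, τ²)` the shared loading shift, `d` fixed group offsets and
`ε ~ N(0, σ²_g)` gene-specific biological noise; expected Cq is
`base_cq_g + x/log₂(E_g)` and technical noise N(0, sd²) is added per
replicate directly on the Cq scale. Keeping biological noise on the
expression scale and technical noise on the cycle scale separates the two
variance sources that intra-/inter-assay CVs and stability values probe.
Dropout is a hard threshold (replicates above Cq 35 become non-detects),
the simplest mechanism that exercises the QC path. All draws flow from one
seeded generator in documented order (sample shifts, biological noise,
replicate noise), so identical configs give byte-identical tables.

The default benchmark (`study_panel_config`) emulates a cell-line screen:
12 genes × 25 samples × 3 replicates, subgroups of 11 ovarian / 9 colon /
5 other samples, 3 planted stable genes at σ = 0.1, seven genes with σ
from 0.5 to 1.5, and two group-confounded genes with offsets of magnitude
1.0 log₂ units (one ±1 between the two large groups, one +1 in colon
only), τ = 0.5, technical SD 0.15 cycles (intra-assay CV well under 2% at
Cq ≈ 20), base Cq spread over 18–30 cycles so dropouts stay rare. The
suite's recovery benchmark runs 200 seeds of this panel and requires the
consensus top-3 to equal the planted set in ≥ 95% of runs.

What passing that benchmark shows — and what it does not: the generator
realises exactly the additive log-linear model the algorithms assume, with
Gaussian noise, a shared per-sample shift and clean group structure. Real
Cq data add amplification-efficiency heterogeneity between samples,
non-Gaussian and occasionally multimodal expression, correlated regulation
between candidate genes (the classic co-regulation blind spot of pairwise
methods), plate/batch effects and informative dropout. Recovery on the
benchmark therefore validates the implementation and the procedure's
behaviour under its own assumptions, not the biological correctness of any
particular panel choice.

## Problem sizes and runtimes

Test-suite simulation sizes were chosen to give stable Monte-Carlo
verdicts at desk scale: 200 seeds for the recovery benchmark (binomial SE
≈ 1.5% at the 95% criterion), 500 replicates for estimator-bias checks
(3·SE rules), 100 random matrices for the algebraic identity. The whole
suite runs in about two minutes on one core.
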