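# refstab

Reference-gene stability analysis for RT-qPCR.

Relative quantification by RT-qPCR divides every target-gene measurement by
one or more internal reference ("housekeeping") genes, so the whole
experiment silently inherits any instability in those references. refstab is
for anyone screening a candidate reference-gene panel on quantification-cycle
(Cq) data — e.g. a dozen candidates across a collection of cell lines or
tissues — and implements the standard workflow end to end:

* **QC** — replicate-level filtering (Cq > 35 excluded by default),
  arithmetic averaging of surviving replicates, negative-control
  (NTC / no-RT) contamination verdicts, intra-/inter-assay coefficients of
  variation.
* **Standard curves** — per-gene OLS fit of mean Cq on log₁₀(template
  amount), percent amplification efficiency
  *E* = (10^(−1/slope) − 1) × 100, and automatic trimming to the best
  contiguous linear dilution range.
* **Four stability algorithms** — geNorm (stepwise-exclusion *M* values and
  the pairwise variation *V*(n/n+1)), NormFinder (model-based variance
  decomposition, with or without sample groups), BestKeeper (descriptive
  dispersion and correlation with the geometric-mean index), and the
  comparative ΔCt method. All emit lower-is-more-stable values and
  fractional ranks.
* **Consensus** — RefFinder-style geometric mean of the four base ranks,
  a five-algorithm rank-sum ordering, and the Pearson correlation matrix
  between the algorithms' rankings.
* **Synthetic data** — a seeded generator for Cq panels with known ground
  truth (planted stable genes, sample loading shifts, group-confounded
  genes, dropouts), so the entire pipeline is testable without instrument
  data.

## The statistics in brief

On log₂ relative quantities `y[g,s] = (min_u Cq[g,u] − Cq[g,s])·log₂E_g`:

* geNorm: `M_g = mean_{k≠g} SD_s(y[g,s] − y[k,s])`; the gene with the
  largest M is removed and M recomputed until two genes remain.
* ΔCt: the same pairwise SDs taken directly on Cq — identical to first-pass
  M when all genes share E = 2.
* BestKeeper: dispersion SD⁺ = mean |Cq − mean Cq| per gene; index =
  per-sample geometric mean of Cq; per-gene Pearson r against the index.
* NormFinder: two-way decomposition `y = gene + sample + noise`; the
  per-gene noise variance is `σ̂²_g = max(0, k/(k−2)·(u_g − U/(k(k−1))))`
  with `u_g` the residual mean square and `U = Σ u_g`; grouped mode adds
  the inter-group deviation, `mean_grp(|d_{g,grp}| + √(σ̂²_{g,grp}/n_grp))`.
* Consensus: rank sum over the five algorithms (four base + their
  geometric-mean aggregate), lowest sum = most stable.

## Worked example

`python examples/04_stability_ranking.py` simulates the default benchmark
panel (12 genes × 25 samples × 3 replicates, seed 42) and runs the full
pipeline:

```
gene      geNorm    dCt  BestK  NormF  rank-sum
REF03      0.106  0.813  0.341  0.081       7.5
REF02      0.106  0.817  0.337  0.108      11.0
REF01      0.160  0.820  0.336  0.097      11.5
REF04      0.438  0.884  0.516  0.164      20.0
...
REF09      1.951  1.951  1.523  1.158      60.0

consensus top-3: ['REF03', 'REF02', 'REF01']
planted truth:   ['REF01', 'REF02', 'REF03']
geNorm V(2/3) = 0.051 -> 2 reference genes suffice (threshold 0.15)
```

Each column is one algorithm's stability value (lower = more stable); the
rank sum aggregates the five rankings. The consensus top-3 recovers exactly
the three genes the generator planted with low biological noise, and
V(2/3) < 0.15 says two of them would already make an adequate
normalization factor. The other examples cover simulation (`01`), QC
(`02`) and standard curves (`03`).

A thin CLI wraps the same functions: `refstab simulate`, `refstab qc`,
`refstab efficiency`, `refstab stability`, `refstab consensus`
(see `refstab --help`).

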