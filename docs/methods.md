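# Methods

## Data model

Expression values live on a nonnegative "Et" scale where larger means more
expressed and exactly 0 encodes "not detected"; the detection mask is
implied (`value > 0`), never stored. For raw Ct input the packaged
transform is `Et = max(lod_ct − Ct, 0)` with a default limit of detection
of 24 cycles, a common multiplexed-qPCR convention. The package is
agnostic about the precise ΔCt reference used upstream: any nonnegative
"higher = more expressed" scale is a valid input, but absolute values are
then not comparable across studies.

## Hurdle differential expression

Single-cell qPCR expression is semi-continuous: a point mass at zero and a
continuous positive component. For a two-group contrast the model is

* detection: `z_ij ~ Bernoulli(p_g)` per group g;
* magnitude: `y_ij | z_ij = 1 ~ N(m_g, s²)` with a shared variance
  (a per-group-variance variant is available via `equal_var=False`).

Both parts have closed-form maximum-likelihood estimates, so the
likelihood-ratio statistic decomposes: the Bernoulli deviance plus
`n_det · ln(RSS_null / RSS_alt)` for the Gaussian part with the variance
profiled out. The sum is referred to chi-square. Degenerate detection
patterns get explicit bookkeeping, chosen to keep the statistic defined on
very small groups (cohorts here contain groups as small as 7 cells):

* both groups need ≥ 1 detected cell and ≥ 3 detected in total for the
  continuous part; otherwise the test is discrete-only with df = 1;
* a gene undetected in both groups is `undefined` (p = NA);
* zero residual variance under the alternative yields statistic 0 when the
  null residuals also vanish, +∞ (p = 0) otherwise.

The reference distribution is the asymptotic chi-square, matching standard
practice for this model family; no permutation null is implemented.
Multiple-testing adjustment defaults to none (per-gene significance
reporting); Benjamini–Hochberg is available by flag and is applied only
across genes with a defined p-value. Correctness is checked against an
independent numeric maximization of the full two-part likelihood
(Nelder–Mead on unconstrained transforms) on random small instances, and
the empirical type-I error at the 5% level is verified on 2000 null genes.

## Confounder correction

Sampling confounders (batch, plate) are removed per gene by ordinary least
squares on the *detected values only*: corrected = residual + grand mean
of detected values, floored at 1e-6 so correction can never turn a
detected value into an apparent nondetect. Zeros pass through untouched.
Correcting zeros would destroy the two-part structure the hurdle test
relies on, which is why the model is fitted on the positive part only. A
covariate with one level overall is a no-op; a gene whose detected cells
do not span two levels of a covariate is skipped with a warning.

## Cell-cycle phase assignment

1. Max normalization: each signature gene divided by its maximum over the
   full analysis set. Reference and test cells are normalized together so
   they share one scale — the normalization scope matters and is fixed to
   "whole cohort including reference".
2. Scores: the G1 score and S/G2/M score are means of normalized
   expression over the 4 G1 genes and the 11 S/G2/M genes; both lie in
   [0, 1].
3. Calibration: the S/G2/M cutoff is the lower-tail-inclusive empirical
   quantile of the reference (control HSC) S/G2/M scores at the default
   fraction 0.90 — the known quiescent fraction of C57Bl/6 HSCs. The
   implementation takes the smallest observed score whose inclusive
   empirical CDF reaches the fraction, verified against an exhaustive scan
   under ties. At least 10 reference cells are required.
4. Call: S/G2/M iff the score is strictly above the cutoff; a tie goes to
   G0/G1 (conservative toward quiescence, reading the ~90% reference level
   as a floor). The decision boundary is one-dimensional on the S/G2/M
   score; the G1 score is computed and reported for the phase scatter but
   does not enter the call.

A known property of quantile calibration: the reference cohort's true
quiescent fraction fluctuates binomially around 0.90, and in draws where
it falls below the calibration fraction the cutoff climbs into the S/G2/M
score distribution, costing a few percent of S/G2/M recall. This is
intrinsic to the procedure, not to its implementation, and bounds the
achievable classification accuracy near ~95% in unlucky reference draws.

## Division gating

Under the halving model, generation g sits at `base − g` on the log2
intensity scale. The standard gate calls a cell undivided iff its log2
intensity exceeds the reference median minus 0.5 — the midpoint between
generations 0 and 1 — and the stringent gate adds a ±0.25 buffer
(undivided above −0.25, divided below −0.75, ambiguous between), trading
yield for purity. The original gates were drawn by eye on cytometry plots;
these constants are a documented surrogate, not a reconstruction, and are
configurable. The median (not mean) of the reference is used for
robustness to outliers. With the default dye noise of 0.2 log2 units the
analytic normal tails give generation-0 recall `Φ(0.5/0.2) ≈ 0.994` and
generation-1 leakage `≈ 0.006` at the standard gate. Gate calls are
invariant to global rescaling of all intensities.

## Population structure

Distances are Euclidean on the expression scale as given (no
standardization by default; a z-score flag exists because "normalized
data" is ambiguous in this field). "Reproducible k-means" is made concrete
as consensus-over-restarts: 50 independent k-means runs, the best-inertia
labeling is the consensus, and stability is the fraction of restarts whose
partition equals the consensus up to label permutation. Cells are
processed in id-sorted order so the consensus is invariant to input row
order. t-SNE is delegated to scikit-learn and treated as qualitative
output: only determinism-given-seed is contractual, coordinates are
arbitrary units. Agreement between labelings is the adjusted Rand index
plus accuracy under the best label matching (Hungarian assignment,
verified against exhaustive permutation search for small k).

## Synthetic-data generator

The generator emulates the study conditions the analyses assume:

* **Cohort**: populations HSC, CMP, PreME, PreMeg with 42, 7, 15, 20 cells
  by default (the sorted undivided-donor cohort size).
* **Expression**: per (population, gene), detection probability π and,
  when detected, `N(μ, σ²)` truncated to be strictly positive by
  rejection redraws — so 0 unambiguously means "not detected" and the
  hurdle model's two parts stay identifiable.
* **Phases**: each cell draws G0/G1 vs S/G2/M with population-specific
  probability (defaults: HSC 0.90/0.10 — matching the quiescent reference
  level; CMP 0.50/0.50; PreME and PreMeg 0.33/0.67, i.e. about a third of
  restricted progenitors still quiescent). Phase-matched signature genes
  (S/G2/M genes in S/G2/M cells, G1 genes in G0/G1 cells) get an additive
  `phase_effect` on the positive mean, default 3.0 = 3σ.
* **Defaults** (π, μ, σ per population × category) place MEP/platelet
  genes low in HSCs (0.20, 3, 1) and high in PreMegs (0.95, 10, 1), HSC
  genes the mirror image, and cell-cycle genes population-invariant
  (0.95, 4, 1). The high cell-cycle detection rate reflects that core
  cycle regulators are detected in nearly all Kit+ progenitors after
  preamplification. The defaults are deliberately calibrated so that the
  structure the analyses are meant to expose is actually present: HSC vs
  PreMeg separate on MEP/platelet genes at ARI ≥ 0.9, phases separate on
  cell-cycle genes but not on MEP/platelet genes, and the phase effect
  sits at the 3σ level the classification contract assumes.
* **Batches**: additive offsets on detected values, assigned round-robin;
  the default is a single batch (offset 0).
* **Dye**: `log2(intensity) = base − generation + N(0, 0.2)`.
* **Seeding**: one global seed spawns an independent stream per
  (population, gene), keyed by CRC32 of the names, so adding genes or
  populations never perturbs existing draws; identical seeds give
  bit-identical output.

The packaged gene panel carries the 15 real cell-cycle signature genes
plus 12 MEP/platelet-tagged and 8 HSC-tagged genes whose *membership* is a
synthetic stand-in (the symbols are real murine lineage markers, but the
measured panel of the motivating study is not public).

What the generator does **not** emulate: PCR chemistry and amplification
efficiency, probe-level fluorescence, gene–gene correlation beyond the
phase/population block structure, continuous cell-state gradients
(populations are discrete), doublets, and index-sort marker distributions.
Tests passing on this generator therefore demonstrate that the procedures
recover the structure they are designed for — not that real data contain
that structure.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: reference
calibration at n = 1000 cells; hurdle oracle equivalence on 200 random
instances of ≤ 12 cells per group (tolerance 1e-6 on the LRT); type-I
error on 2000 null genes of 50 cells per group; recovery checks on a
4×-scaled cohort (336 cells) and on 100 + 100 PreME/PreMeg cells for the
phase-independence analysis, sizes chosen so Monte-Carlo noise is small
relative to the margins being tested. Ties at the calibration quantile
resolve to the smallest achieving cutoff; k-means ties resolve by best
inertia; all stochastic stages derive their substream from a single
top-level seed.

## Pipeline

`run_pipeline` chains simulate → divide-gate → confounder-correct →
hurdle DE (HSC vs PreMeg) → phase calls (reference-calibrated) →
consensus clustering, writing per-stage TSVs and a JSON summary that is
byte-identical across runs with the same seed. The simulated cohort
includes a configurable divided fraction (default 0.30 at generation 1)
so the division gate has both classes to separate; the study's actual
sorted cohort is all-undivided by construction.
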