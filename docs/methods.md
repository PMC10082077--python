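# Methods

`diauxflux` re-implements, at desk scale and with fully synthetic inputs,
an analysis chain for studying the *Saccharomyces cerevisiae* diauxic
shift: constraint-based simulation of regulatory-knockout strains to
select informative deletants, untargeted-metabolomics preprocessing and
differential testing of their metabolic profiles, diffusion-based pathway
enrichment, and flux-sum-based scoring of two competing regulatory model
variants. This note records the models, the defaults that matter, and the
choices made where the design was open.

## Toy metabolic model and regulatory rule sets

The generated stoichiometric model is the minimal network that exhibits a
diauxic shift under dynamic FBA: a linear glycolytic chain
(glucose → … → 2 pyruvate + 2 ATP), a fermentative branch
(pyruvate → ethanol + CO₂) that exports ethanol, a capacity-limited
respiratory branch (ethanol → 3 ATP + 2 CO₂, upper bound drawn from
U(4, 6) mmol gDW⁻¹ h⁻¹ per seed), a gluconeogenic route
(2 ethanol + 2 ATP → pyruvate + CO₂), and a biomass drain
(10 pyruvate + 40 ATP). With a glucose uptake bound of
10 mmol gDW⁻¹ h⁻¹ this yields a fast fermentative phase (μ ≈ 0.88 h⁻¹
with ethanol overflow) and a slow respiratory phase on ethanol
(μ ≈ 0.15 h⁻¹), which is the qualitative physiology the analysis needs;
absolute rates are arbitrary for a toy network.

Regulatory rules extend the structural gene–reaction (GPR) associations:
a rule `(gene, phase, reaction, action)` states that the regulator is
required in that growth phase for the reaction to operate normally, so
the action — `disable`, or `scale_bound` with an explicit factor — is
applied only when the gene is deleted. The two rule sets share a
background rule; the revised variant (M1Smart) additionally encodes that
one regulator is required post-shift for ethanol transport (its knockout
abolishes post-shift growth) and that a second sustains full respiratory
capacity post-shift (its knockout reroutes flux and slows growth). These
two planted discrepancies are what strain ranking and the rerouting
statistics are tested against. Glucose repression of ethanol uptake is
not a rule: it is implemented kinetically (below), which keeps the rule
semantics single-signed.

## FBA, dFBA and replicate simulations

FBA maximizes the biomass objective by linear programming (GLPK via
cobrapy); among alternate optima the minimum-total-|flux| (pFBA)
solution is returned so that downstream paired statistics see
deterministic flux vectors. An infeasible problem reports objective 0.

The dynamic simulation is the standard static-optimization (SOA) Euler
loop, default step 0.1 h: uptake bounds follow Michaelis–Menten kinetics
(glucose: Vmax 10, Km 0.5 mmol/L; ethanol: Vmax 6, Km 0.5), with
catabolite repression of ethanol uptake through the multiplicative term
Ki/(Ki + [glc]), Ki = 0.2 mmol/L. The regulatory phase flips pre → post
when glucose falls below 1% of its initial concentration. Per-phase
growth rates are biomass-weighted means of the instantaneous rate. The
first-order integrator is accurate to ≈1% in the pre-shift rate at
dt = 0.05 h (convergence-tested); trajectories conserve carbon as an
inequality (glucose carbon in ≥ ethanol pool + biomass carbon).

Strain ranking scores each deletion by |post-shift growth(M1Smart) −
post-shift growth(M1)|, evaluating growth against static per-phase media
(post: glucose absent, ethanol at its reference uptake bound). This is
equivalent to the dFBA-derived ranking for the planted rules and far
cheaper; a `method="dfba"` path exists. Strains with zero growth under
both variants in both phases are excluded as non-viable.

Replicate simulations (default 13 per condition) jitter every exchange
bound by an independent U(1−j, 1+j) factor, j = 0.05, from a seeded
generator. The variation source across replicate simulations is a
modelling choice — the jitter is explicit, controllable, and shared
between a knockout and its wild-type counterpart when they are solved
with the same seed, so paired tests see exactly zero differences
wherever the knockout has no mechanism of action.

## Growth-curve processing

Raw OD₅₆₀ readings are background-corrected by subtracting the
per-timepoint blank mean (floored at 0) and linearized once with the
cubic calibration x_adj = −0.01454 + 1.231x − 0.6393x² + 0.4985x³, valid
on the reader's 0–2 range, where it is strictly increasing (the
derivative's discriminant is negative). Phase segmentation replaces
Gaussian-process growth modelling with a deterministic estimator: the
specific growth rate is the least-squares slope of ln OD in a rolling
window (default 5 readings); the shift is the deepest local minimum of
that rate series lying between two local maxima that exceed 10% of the
global maximum rate, with the additional requirement that the minimum
itself falls below that floor — without the depth requirement a
noiseless single-exponential curve (a constant rate series) would
qualify everywhere. Rates below 10⁻⁹ h⁻¹ are treated as numerically
flat.

## Peak-table generation

Intensities are log-normal: 2^(μ_f + batch + drift + effect + ε) with
per-feature baselines μ_f ~ N(16, 2) (log2 of a typical LC-MS count),
residual σ = 0.3 log2 units, multiplicative batch effects
~ N(0, 0.3 log2), and a per-batch quadratic injection-order drift
(amplitude 0.15 log2) applied identically to QC and study samples —
the representativeness assumption QC-RLSC relies on. Pooled QC samples
(σ = 0.05) are injected at the start, end, and every `qc_interval` = 5
study injections; two blanks per batch sit ≈7 log2 units below the
signal. Missing values are zeros planted at rate 2% in study samples
only. Defaults: 4 strains × 2 phases × 6 replicates (typical such
designs use 3–6 per condition; the upper end is used for power) over
2 batches, 100 features (a real processed run yields several hundred).

`paired_noise=True` switches on common random numbers: the residual ε is
drawn once per (feature, batch, phase, replicate index) and shared
across strains. A strain with no planted effect is then observationally
identical to the reference, so its null linear-model p-value is exactly
1. This is what makes exact closed-loop validation possible under a raw
p < 0.1 decision rule, which otherwise carries an irreducible 10%
false-positive rate per null comparison. It is a property of the
simulation design, not of real data.

## Preprocessing chain

Order: filter → QC-RLSC → batch alignment → quantile normalization,
with per-batch filtering and drift correction.

* Filtering removes the union of four rules: mean over study samples not
  above the blank mean; fill (fraction of study samples with a detected
  peak) below 0.1; signal-to-noise below 10 (instrument-reported `sn`
  metadata when present, else blank-relative); and detection in fewer
  than two-thirds of samples in every batch — i.e. a feature survives
  the detection rule if it reaches two-thirds in at least one batch (the
  stricter every-batch reading is available via `detection_any_batch=False`).
  The log attributes each removal to the first firing rule, fill before
  blank so an entirely undetected feature reads as a fill failure.
* QC-RLSC fits a robust local linear regression (tricube weights, three
  robustifying iterations, span 0.75) of QC intensity against injection
  order per batch per feature; samples are divided by fitted drift /
  median QC. Fewer than 4 positive QC values fall back to median
  scaling; all-zero QCs pass through with a warning.
* Alignment merges features across batches only when identification and
  adduct match and |Δm/z| ≤ 0.01 Da and |ΔRT| ≤ 0.75 min, by greedy
  nearest-m/z matching in ascending m/z (deterministic and symmetric in
  batch order). Unmatched features stay batch-specific, zero-filled
  elsewhere.
* Quantile normalization implements the rank-mean algorithm directly;
  zeros participate as values, and ties receive the mean of their
  ranks' means. With ties present, tie-averaging necessarily perturbs
  the identical-marginals property slightly (as in the reference R
  implementation); for untied data the property is exact. Note that at
  small feature counts quantile normalization can attenuate or even
  flip effects carried by features in the sparse tails of the intensity
  distribution — rank resolution is coarse there. This is a property of
  the method, visible in the synthetic studies, and one reason the
  calibration/power experiments are run on generated tables directly.

## Differential statistics

Per-feature ordinary least squares on log2 intensities (zeros offset by
half the feature's minimum positive value) with the contrast (phase
post-vs-pre, or strain vs reference) plus covariate dummies; the
contrast coefficient is t-tested. Confounded designs are rejected by a
rank check. Fold change is model-based, 2^|coef|, with the sign carried
separately. No multiple-testing correction is applied by default,
matching the raw-p decision rules used throughout; empirical-Bayes
variance moderation (inverse-chi-square prior fitted by log-scale moment
matching, trigamma inversion by Newton iteration) is available via
`moderate=True`. At 50 replicates/group the moderated and raw p-values
agree to a median |Δp| of about 0.01 — the residual disagreement scales
with sd(s²)/s² = √(2/df), so exact agreement is only asymptotic.

Volcano classification flags features with raw p strictly below 0.1 and
fold change strictly above 1.5 (strict inequalities throughout, both
configurable). Correlation profiling averages replicates per
(strain, phase) group, clusters groups by 1 − Pearson r and features by
Euclidean distance on z-scores, with average linkage (linkage is
configurable; the choice is not critical at desk scale).

OPLS-DA follows the orthogonal-projections formulation: k y-orthogonal
components are deflated before a single predictive PLS component is
fitted (default k = 1); the predictive scores are exactly orthogonal to
every orthogonal score vector by construction. Classification is
nearest class mean on the predictive score; per-class 95% confidence
ellipses come from the within-class score covariance and the χ²₂
quantile. Training accuracy is an optimistic measure: with many more
features than samples a discriminant fitted to permuted labels can
reach near-perfect training accuracy, so the permutation control is run
in a sample-rich design (n = 200, p = 10) where the null training
accuracy concentrates near chance.

## Diffusion enrichment

Significant features (raw p < 0.1) are mapped through identification
labels to compound nodes (duplicates collapsed) on a typed pathway /
reaction / compound graph. Node scores solve the regularized-Laplacian
system (L + λI)f = b, λ = 0.01, with b the input-compound indicator; the
sparse factorization is reused across permutations. Empirical p-scores
compare each node's score to a null of random same-size compound sets:
p = (1 + #{null ≥ observed}) / (1 + n_permutations), n ≥ 1000 (default
2000), so p is never below 1/(1+n). Monte-Carlo permutation was chosen
over a normal approximation of the null because it is exact at this
scale and assumption-free. The synthetic graphs plant enriched pathways
with exclusive compound pools (≥ 3 compounds, disjoint from decoy
pathways), chained by hierarchy edges to guarantee connectivity.

## Flux-sum validation

The flux-sum Φ_i = ½ Σ_j |S_ij v_j| equals a metabolite's turnover
(total production = total consumption) at steady state; this identity is
tested against a brute-force oracle on random null-space flux vectors.
Replicate flux matrices of two model variants are compared per reaction
with two-sided Wilcoxon signed-rank tests (zero differences dropped;
all-zero → p = 1; exact null for n ≤ 25, normal approximation when tied
|differences| occur), and per cross-replicate-pair Spearman correlations
over reactions, which separate genuine rerouting (low median ρ) from
uniform rescaling (ρ ≈ 1).

Validation treats flux-sum changes as predictors of observed metabolite
accumulation: a prediction is positive iff the paired knockout-vs-wild-
type flux-sum Wilcoxon gives p < 0.1; an observation is positive iff the
strain/phase linear model gives p < 0.1 for the mapped feature. The
"and/or" in the decision rule is resolved as prediction and observation
being tested independently on their own arms; a direction-matched
variant is intentionally not the default. Per metabolite, comparisons
are pooled across strains and phases into a confusion matrix;
sensitivity and specificity average into balanced accuracy, with a
zero-member class contributing rate 0 — so an all-negative truth met by
all-negative predictions scores 0.5, and a variant with no correct
positives can score exactly 0.

The closed-loop experiment plants observations from the revised
variant's own seeded decision rule: the metabolites it predicts to
change for each knockout/phase receive 4-fold effects in a
paired-residual peak table (no drift, no missingness — those nuisances
are tested in their own modules), and both variants are then scored
against that table. The oracle variant recovers balanced accuracy 1.0 on
the planted metabolites for any seed; the unrevised variant misses the
post-shift physiology and scores lower, and permuting the observation
matrix collapses the mean to ≈ 0.5.

## Pipeline and problem sizes

`run_pipeline` executes generate → growth → FBA → metabolomics → stats →
enrichment → validation from one flat YAML config whose defaults are the
pipeline's decision thresholds (raw p 0.1, fold change 1.5, fill 0.1,
S/N 10, two-thirds detection, m/z ±0.01 Da, RT ±0.75 min, 13 replicate
simulations, enrichment significance 0.01/0.05). Default synthetic
sizes — 100 features, 4 strains, 2 batches, 6 replicates, 6-pathway
graphs, 2000 permutations, 20 seeded model pairs in the recovery
experiments — were chosen so every recovery experiment is well-powered
while a full run stays in the seconds-to-minutes range on a single CPU.
Reruns with the same config are identical apart from timestamps.

## What the synthetic data does and does not show

The generators emulate the statistical structure the methods rely on
(two-phase growth, log-normal intensities, shared QC/sample drift,
batch shifts, planted differential features and enriched pathways) but
not chromatography, adduct chemistry, isotope patterns, compositional
effects of normalization on real metabolomes, or genome-scale network
complexity. Passing recovery tests therefore demonstrates that each
method is implemented correctly and is well-calibrated under its own
assumptions — not that those assumptions hold for any particular real
dataset, nor that the toy model's growth-rate differences have
biological meaning.
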