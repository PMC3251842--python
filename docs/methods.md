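# Methods

This note documents the models, defaults and numerical choices behind
`mirsig`, and what the synthetic-data tests do and do not establish about
real data.

## Ct processing

qPCR arrays report a cycle threshold per well; a well that never crosses the
detection threshold is "Undetermined". We impute such wells at the maximum
cycle of the run (Ct = 40, configurable), flag them as imputed, and carry
the flag downstream — fold changes involving imputed wells emit a warning,
because the true Ct exceeds the ceiling and the fold change is a lower-bound
artefact.

ΔCt normalization subtracts the endogenous-control mean. Two modes exist:

* `per_sample` (default): each sample's own control mean. This is the
  standard comparative-Ct convention and cancels per-sample RNA-loading
  offsets exactly; after it, every sample's control-probe ΔCt mean is 0.
* `global`: one scalar, the control mean pooled over all samples. This is a
  literal reading of "the average of the control Ct values across all
  samples" that some legacy workflows used; it does not correct loading and
  is provided for reproducing such runs. The mode used is recorded in the
  output object.

Fold change is 2^−ΔΔCt with replicate ΔCt values averaged on the cycle scale
before exponentiation.

## Differential-expression screen

Per probe, a classical two-sample pooled-variance Student's t (not Welch;
Welch is available behind a flag) between sensitive and resistant training
samples, two-sided p from the t distribution with n₁+n₂−2 df. The pooled SD
is floored at 1e−8 cycles so constant probes (e.g. rows fully imputed at the
ceiling) yield t = 0 rather than ±∞; floored probes are flagged. The default
screening threshold is α = 0.1, applied strictly (p < α), and the retained
probes are ordered by ascending p with |t| and then probe id breaking ties —
this ordering is the candidate ranking the signature search consumes. No
multiple-testing correction is applied at the screen; family-wise control
comes from the downstream permutation null.

## DLDA classifier

Diagonal linear discriminant analysis: Gaussian classes with class-specific
means and one shared diagonal covariance. Scores are

    score_k(x) = −½ Σ_j (x_j − μ_kj)² / σ_j²,

the log-likelihood up to an additive constant shared between classes — the
shared −½ Σ log(2π σ_j²) term cancels in the comparison and is omitted, so
the (score_resistant, score_sensitive) geometry and the identity-line rule
are exact. Pooled variances use the n−2 denominator
σ_j² = Σ_k Σ_i (x_ij − μ_kj)²/(n−2), floored at 1e−8 cycles²; a per-class
variance variant sits behind `pooled=False`. Priors are equal by default
(balanced 4v4 training); unbalanced designs can pass explicit priors, which
enter as additive log-terms.

A zero margin (a sample exactly on the identity line) is called *resistant*:
for a borderline tumour, withholding an EGFR inhibitor it may not respond to
is the conservative error direction. The tie rule is explicit and tested.

LOOCV refits the model per held-out sample and requires ≥ 3 labelled samples
per class so every fold keeps ≥ 2.

## Signature reduction

The reduction from the screened candidate list (≈ 38 probes under the
default design) to a compact predictor evaluates *nested prefixes* of the
p-ranked candidate list at every size k, scoring each by LOOCV accuracy,
with external-validation accuracy (never used for fitting) and then smaller
k breaking ties. Exhaustive subset search is combinatorially hopeless
(C(38,13) ≈ 10¹⁰) and greedy wrappers are order-unstable; nested prefixes
keep the search deterministic given the candidate ranking.

A known consequence, visible in the acceptance measurements: when the class
effect is strong, both LOOCV (8-sample grid) and validation accuracy
(16-sample grid) saturate at 1.0 from very short prefixes, and the
smaller-k tie rule then returns 1–3 probes rather than the full planted set.
That is the correct behaviour of the stated selection rule at this
signal-to-noise level, not a defect of the search; with noisier or scarcer
validation data the selected k grows.

## Permutation null

`n` random k-probe signatures are drawn uniformly without replacement from
the 378 assay probes (controls excluded), each is fitted on the training
samples and scored on the evaluation cohort, and the empirical adjusted p is
(n − #strictly-outperformed)/n. Ties count against the candidate and no
pseudo-count is added, so counts reproduce printed summaries exactly
(9,510/10,000 → 0.049); the (b+1)/(n+1) estimator is available via
`plus_one=True`. Because DLDA statistics are per-probe, the implementation
precomputes per-probe margin contributions once and sums them per signature
— mathematically identical to refitting per signature, and verified against
an explicit refit loop in the tests.

With accuracy on a 16-sample cohort as the metric, the p-value lives on a
coarse grid and is *conservative*: random signatures that happen to include
planted probes can tie a perfect candidate, so the achievable p is bounded
below by the tie fraction (several percent at this cohort size). The null
calibration check therefore asserts validity — the empirical CDF of the
null p never exceeds the uniform beyond Monte-Carlo tolerance, and its mean
sits above 0.4 — rather than exact uniformity, which a discrete tied
statistic cannot attain.

## Clustering and heatmaps

Pearson-correlation distance (1 − r) with average linkage, the conventional
defaults for expression heatmaps; Euclidean and complete/single linkage are
available. Items are sorted lexicographically before linkage so the tree is
invariant to input order up to a deterministic tie rule. Constant rows are
rejected under correlation distance (the distance is undefined) with the
offending row named. Heatmaps colour −ΔCt so red = high expression, and the
sign convention is printed on the figure. GCT 1.2 and CDT/GTR/ATR exports
follow the clustered orders; GTR/ATR similarity is 1 − merge height.

## Target filtering

mirSVR-style scores are filtered strictly below −1.25 (boundary excluded);
duplicate (miRNA, gene) site predictions are deduplicated keeping the most
negative score, since enrichment tools operate on gene sets. Pathway
enrichment itself is not reimplemented — published enrichment p-values
depend on proprietary knowledge bases — the module exports plain GMT sets.

## Synthetic-data generator

The generator emulates the study design on the Ct scale:

    Ct[j, s] = baseline_j + loading_s + effect[j, s] + ε[j, s]

| parameter | default | meaning |
|---|---|---|
| `n_probes` / `n_controls` | 381 / 3 | total card features; 378 assay probes + U6-snRNA, RNU44, RNU48 controls |
| `n_sensitive_train` / `n_resistant_train` | 4 / 4 | training cell lines |
| `n_validation` | 8 / 4 / 4 | validation cell lines / primary / metastatic tumours (16 unknowns) |
| `signature_size`, `n_up_in_sensitive`, `n_down_in_sensitive` | 13, 11, 2 | planted signature and directions (up = lower Ct) |
| `effect_cycles` | 3.0 | Ct shift of planted probes in sensitive-profile samples (≈ 8-fold); a modelling choice, not a reported value |
| `noise_sd` | 0.75 | per-well Gaussian noise, cycles |
| `baseline_ct_range` | (18, 32) | per-probe abundance baselines, the realistic TLDA dynamic range; controls draw from the abundant end |
| `sample_loading_sd` | 0.5 | per-sample RNA-input offset, removed exactly by per-sample ΔCt |
| `dropout_ceiling`, `dropout_slope` | 40, 0.05 | undetected above the ceiling; linear dropout ramp per cycle over the last 5 cycles |
| `discordant_sample` | False | one resistant training line expresses the sensitive profile (a resistant line carrying a sensitizing genotype); it becomes the single LOOCV failure |
| `tumor_purity`, `tumor_noise_multiplier` | 1.0, 1.0 | optional tumour-specimen effect attenuation (stromal dilution) and noise inflation (FFPE degradation); neutral by default so tumour wells follow the same law as cell-line wells |
| `primary_sensitive_fraction` | 0.5 | label split of primary tumours; metastatic tumours are labelled and profiled resistant |

What it does **not** emulate: sequence-level biology, amplification
efficiency curves, plate/spatial batch effects, correlated co-regulation
among non-signature probes, or heavy-tailed outliers. Passing tests
demonstrate that the pipeline's statistics behave correctly under the
assumed Gaussian planted-effect model at study scale; they do not establish
classifier performance on real tumours.

## Problem sizes and numerical choices

Acceptance measurements use: 1,000 random instances for the DLDA/oracle
agreement; 100 simulated studies for screen recovery, signature reduction,
LOOCV and clustering separation; 50 studies × 10,000 random signatures for
permutation power; 50 null studies for t-test calibration (≈ 19,000 tests);
200 null replicates × 500 random signatures for p-value validity. All
randomness flows from explicit seeds (`numpy.random.default_rng`); reruns
are bit-identical. Variance floors are 1e−8 (cycles for the screen's SD,
cycles² for DLDA); the per-sample control-mean-zero identity holds to 1e−9
cycles; correlation distances are clipped to [0, 2] against floating-point
drift.

## Known limitations

* The nested-prefix search explores one path through subset space; it can
  miss non-nested optima by construction.
* Accuracy-based permutation metrics are coarse at 16 evaluation samples;
  the empirical p is conservative and cannot fall below the random-tie
  fraction (see above).
* The screen's type-I behaviour is calibrated marginally per probe; within a
  card, probes share control-well noise, so rejection *counts* across probes
  are mildly over-dispersed relative to binomial.
* GCT/CDT writers target GenePattern-style viewers; exotic dialect
  variations of CDT are not parsed back.
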