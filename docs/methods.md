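# Methods

This note documents the models and procedures implemented in `ezmetric`,
their assumptions, the tunable parameters, and the numerical and design
choices made where more than one reasonable convention exists.

## The weighted EZ score

An exposure group is one nanomaterial at one concentration, nominally twelve
dechorionated embryos in one row of a 96-well plate (one embryo per well).
Twenty-one endpoints are scored binary: mortality at 24 hpf (weight 1.0),
mortality between 24 and 120 hpf (0.95), and 19 sub-lethal endpoints scored
on embryos alive at 120 hpf, with severity weights from 0.12 (heart, brain
malformation) down to 0.02 (e.g. atypical pigmentation). The 19 sub-lethal
weights sum to 0.94.

The group score is

EZ = w_m24·(d24/n) + w_m120·(d120/n) + (v/n)·Σᵢ wᵢ·(cᵢ/v),

where n = exposed, d24/d120 = deaths in each window, v = viable at 120 hpf
and cᵢ counts viable embryos showing endpoint *i*. The sub-lethal sum is
defined as 0 when v = 0.

**Normalization choice.** Endpoint frequencies are normalized by the viable
count *and* scaled by the surviving fraction. The phrase "normalized by the
number of viable embryos" alone would allow scores above 1 when mortality
and malformations co-occur; the scaled form is exactly the mean of
per-embryo severities (1.0 if dead at 24 hpf, 0.95 if dead by 120 hpf, else
the sum of observed endpoint weights), which bounds EZ in [0, 1] and makes
EZ = 0.5 interpretable as a 50 % integrated effect — the reading the EC50
definition relies on. The unscaled variant remains available via
`weighted_ez_score(..., scaled=False)` for sensitivity analysis. Because
0.94 < 0.95 < 1.0, converting any surviving embryo to a death never lowers
the group score (mortality dominance), and adding one endpoint flag raises
it by exactly wᵢ/n.

Sub-lethal observations on embryos that later die by 120 hpf are not
recorded (such records are rejected as invalid input for embryos dead at
24 hpf, and embryos dead by 120 hpf contribute only the 0.95 weight): the
mortality weight already exceeds the entire sub-lethal sum.

**Profiles and sumEZ.** A material's scores ordered by ascending
concentration form its concentration profile. Replicate plates at the same
dose are pooled; because the score is a per-embryo mean, pooling is the
exposure-count-weighted mean of replicate scores, identical to scoring the
joint tally. The control (0 ppm) point is stored but excluded from sumEZ
(the sum of scores over treatment concentrations) and from EC
interpolation, where log concentration is undefined. With the default
eight-level design, sumEZ sums eight treatment scores and lies in [0, 8].

## EC estimation and ranking

Screens of weakly toxic materials routinely fail to reach a 50 % effect at
the top dose, which makes sigmoidal regression ill-posed; the package
therefore interpolates. Treatment points are scanned in ascending
concentration for the first adjacent pair with score_j < t ≤ score_j+1 and
the ECt is 10^x with x interpolated linearly between the pair's log10
concentrations ("first crossing from below" resolves non-monotone
profiles). Profiles never reaching t are `not_reached` (no extrapolation);
profiles at or above t at the lowest tested dose are `below_range`, and the
lowest tested concentration is reported as a conservative upper bound
rather than extrapolating outside the tested range.

Rankings list EC50-resolved materials first (including `below_range`
bounds), ascending, then materials resolved only at the fallback target 0.1;
ties break lexicographically on material id. Spearman correlation is the
Pearson correlation of mid-ranks with the t approximation on n−2 degrees of
freedom; correlating categorical factors (core, surface chemistry) against
EC50s requires a numeric encoding that the caller must choose, and the
choice changes the coefficient — no default encoding is imposed.

## Clustering and classification

Profiles aligned on a common concentration grid (missing cells: error by
default; optional zero-fill or interior interpolation linear in log10
concentration) are clustered agglomeratively under Ward's minimum-variance
criterion. The implementation tracks cluster sizes and centroids and merges
the pair minimizing the increase in within-cluster sum of squares,
ΔSSE = nᵢnⱼ/(nᵢ+nⱼ)·‖μᵢ−μⱼ‖²; ties break deterministically on the smallest
pair of original row indices. Dendrogram **heights are these merge costs**
(squared-Euclidean scale). Conventions differ across packages — SciPy's
Ward heights h satisfy ΔSSE = h²/2 — but any monotone transform leaves the
topology, and hence the two-cluster cut, unchanged; the test suite verifies
both the h²/2 relation against SciPy and step-by-step agreement with an
exhaustive-search oracle on small matrices. Dendrograms export to Newick
with branch lengths equal to height differences.

Cutting at the root yields clusters A and B, with B the cluster of larger
mean sumEZ (the more toxic group); per-cluster sumEZ box summaries (min,
quartiles, mean, max) are returned. An exact tie assigns B to the cluster
containing the lexicographically smallest id, with a warning.

Cluster membership is then predicted from four boolean surface-group
features (TMAT, phosphate, phosphatidylcholine, amine) by a gain-ratio
decision tree: greedy top-down induction choosing the split with maximal
information gain divided by split information, among unused features with
strictly positive gain; leaves take the majority label (ties to A). No
pruning is applied — with four binary features and two classes the
hypothesis space is too small for pruning to matter. Both leave-one-out
(deterministic, the default) and seeded stratified ten-fold cross-validation
are provided; folds whose training split is single-class train as a
majority leaf.

## The gold-nanoparticle response surface

For the four-ligand gold series the mod-scale score,
mod EZ = 100·EZ + 0.1 (the offset keeps ln defined for clean groups), is
modeled as the exponential of a ten-term linear predictor in ln
concentration (ppm, natural log), primary size (nm), three ligand
descriptors (SASA/polar ratio, molar refractivity in m³/mol, HOMO–LUMO band
gap in kcal/mol) and the interactions ln C·(SASA/Polar), Size·Gap, (ln C)²,
Size². The packaged descriptor table covers MEE, MEEE, TMAT and MES;
descriptors that do not improve predictability (logD/logP, polarizability,
van der Waals surface area) are excluded from the design. A reference
coefficient set estimated from the original gold-nanoparticle screen ships
with the package (`GOLD_REFERENCE_COEFFICIENTS`) and is the default
generating truth for simulated observations.

**Fitting.** Unweighted least squares on the mod scale, minimized by
Levenberg–Marquardt with an analytic Jacobian, initialized from the OLS fit
of ln(mod EZ) on the same design matrix. Noise-free model data are exactly
log-linear, so the initialization is already the optimum and the optimizer
terminates after its initial evaluations. Tolerances: ftol 1e-12 on the
cost, 500·p function evaluations max; rank deficiency is detected by QR and
reported with the collinear column names. Standard errors come from
s²(JᵀJ)⁻¹ at the optimum, p-values from t with n−10 df. R² is reported on
the mod scale (1 − SSE/SST) together with a log-scale companion computed
over positive responses; which scale the original analysis used is not
determinable, so both are exposed. The linear predictor is clipped at 700
(with a warning) to guard exp overflow. Concentration enters in ppm; a unit
change shifts only the intercept.

**Outliers.** Observations with externally studentized residual |t| > 3
(leverages from the linearized model's hat matrix, variance re-estimated
with the point deleted) are flagged; `fit_model(remove_outliers=True)`
applies one screen-and-refit pass. Two caveats are documented deliberately.
First, an essentially interpolating fit (max relative residual < 1e-8)
reports no outliers, since studentizing floating-point noise is
meaningless. Second, because the Jacobian row of an exponential mean scales
with the fitted response, a *gross* contaminant (orders of magnitude above
the response range) acquires enough influence that the optimizer bends the
surface through it — the contaminant's own residual vanishes and the
diagnostic flags its distorted neighbors instead (masking). The rule is
reliable for contamination up to roughly two orders of magnitude; beyond
that, no residual-based diagnostic on this model is.

## The synthetic-data generator

The generator emulates the screen's design, not any specific measured
dataset: fivefold serial dilutions from 250 ppm (eight levels by default,
spanning 250 ppm to 0.0032 ppm; seven levels end at the ~16 ppb mark) plus
a fishwater control, twelve embryos per group, one per well.

Per-embryo outcomes are independent Bernoulli draws against Hill curves
H(c) = cʰ/(ED50ʰ + cʰ): death by 24 hpf with H₂₄(c), surviving embryos die
by 120 hpf with H₁₂₀(c), and viable embryos acquire each sub-lethal endpoint
independently with its own Hᵢ(c). Baseline ED50s place mortality near the
middle of the tested range (60/40 ppm at Hill slope 1.8) with severe
malformations at somewhat lower doses than mild ones (18–120 ppm, slopes
1.2–1.5) — the ordering typical of developmental screens; a material's
potency multiplier divides every ED50. Controls are clean by default
(background malformation rate 0, configurable), and an optional
shared-severity correlation knob couples one embryo-level draw to all
endpoints for robustness studies. Independence across endpoints is a
simplification: real malformation syndromes co-occur, so observed endpoint
correlations in real data will exceed the generator's. Passing tests on
synthetic panels therefore demonstrate pipeline correctness and statistical
behavior under the stated model, not biological fidelity of any particular
material.

Panels assign roughly half the materials (default 68, matching a realistic
screen breadth) one of the four surface groups with a potency drawn from a
potent lognormal stratum (scale 8, log-sd 0.4 → mortality ED50s of a few
ppm) and the rest a benign stratum (scale 0.05 → ED50s far above the top
dose); cores, charges and surface-chemistry labels are drawn consistently
with the group (TMAT/phosphatidylcholine on gold, phosphate on silver/gold,
amine on dendrimers). A `label_noise` fraction flips potency strata relative
to chemistry, reproducing the occasional chemistry/toxicity mismatch of real
panels. Ground truth (effective Hill curves, strata, potencies) is returned
beside every dataset.

Model observations invert the response surface on a 4-ligand × 4-size
(0.8, 2, 5, 10 nm) × 8-concentration grid (n = 128). Gaussian noise on the
mod scale is truncated below at the offset 0.1 by default — a real reading
can never fall below the floor — but truncation biases near-zero responses
upward, so `truncate=False` provides the plain Gaussian condition under
which least-squares estimates are unbiased and the 3-standard-error
intervals attain their nominal coverage; the coverage test uses that
condition, and noise-free generation is never truncated so a refit recovers
the generating coefficients to machine precision.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed or `numpy` Generator; equal
seeds give byte-identical CSV output. The test suite runs the full
68-material panel pipeline once, a 200-replicate coverage study at n = 128,
law-of-large-numbers checks at 10⁴ embryos per group, and exhaustive Ward
oracles at n ≤ 6 — a few seconds in total on one CPU; these sizes were
chosen as the smallest at which the corresponding asymptotic statements are
cleanly visible.

## Known limitations

- Endpoint independence in the generator (see above).
- The EC interpolation inherits sampling error from the dose grid; it
  converges to the true ECx only as the grid densifies, and reports bounds,
  not estimates, outside the tested range.
- The response surface is unbounded above and extrapolates poorly outside
  the calibrated ligand/size/concentration region (mod-scale predictions can
  exceed the observable ceiling of 100.1).
- Residual-based outlier screening is masked by gross contamination (see
  above).
- The Spearman operation leaves categorical encodings to the caller by
  design; published coefficients for categorical factors are not
  reproducible without the original encoding.
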