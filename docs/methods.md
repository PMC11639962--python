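# Methods

`mshts` implements the analysis side of a microliter-scale high-throughput
screen (MSHTS) for amyloid-β (Aβ) aggregation inhibitors. In the assay,
Aβ42 is co-incubated with a quantum-dot-labeled Aβ40 nanoprobe and a
candidate inhibitor in a 1536-well plate; after 24 h each well is imaged by
fluorescence microscopy. Aggregates appear as bright puncta, so the spatial
heterogeneity of the image — not its mean brightness — tracks aggregation.
This note records the models, the defaults and their rationale, and the
limits of what the synthetic benchmark can show.

## The aggregation score

The score of a well is the population standard deviation (divisor N) of
pixel intensities in the central 432 × 432 px crop of the well image
(origin at `floor((dim − size)/2)`, 0-based half-open indexing). A uniform
(fully inhibited) well scores near the read-noise floor; a well full of
bright puncta scores high. The SD is invariant to adding a constant offset
and scales linearly with detector gain, so expressing scores as a
percentage of the mean score of aggregation-only control wells cancels
gain and exposure differences. The divisor is configurable (`ddof`) and
recorded in the score table. RGB images are collapsed to one channel
before scoring; the default policy takes the red plane, where QD605
emission lands through a TRITC filter; a Rec. 601 luminance policy is
available. No background subtraction or flat-fielding is applied.

The deposition score for cell-surface Aβ uses the mean gray value over
five areas (default 1608 × 1608 px). The area layout is a configuration
input stored with the results; the default — four corners plus center —
is a convention of this package, chosen because no standard layout exists.

## Dose–response model and EC50

Normalized scores versus inhibitor concentration x are fitted with the
asymmetric five-parameter logistic (5PL)

    y(x) = d + (a − d) / (1 + (x/c)^b)^g

with plateaus a, d (% of control), location c (µg/mL), slope b > 0 and
asymmetry g > 0. Two EC50 definitions are implemented:

* **relative** (closed form): `EC50 = c·(2^(1/g) − 1)^(1/b)`, the x where
  y is halfway between the *fitted* plateaus; reduces to c for g = 1.
* **absolute50** (default): the x where the fitted curve crosses 50 % of
  control.

The absolute definition is the default because (i) it is the natural
partner of the ND rule, which is likewise phrased in % of control, and
(ii) it does not inherit extrapolation error in the plateau estimates,
which matters on short dilution series that stop at only ~2.5× the EC50.
On the synthetic benchmark the relative definition showed a −12…−19 %
median bias for the weakest recoverable samples, driven entirely by
lower-plateau extrapolation; the absolute definition is unbiased there.

**ND rule.** A sample whose mean normalized score at the highest tested
concentration is **not less than 50 %** of control (inclusive at exactly
50 %) is reported ND (not determined) and never fitted. The rule uses the
top concentration only; the threshold is configurable.

**Fitting.** Plain (unweighted) nonlinear least squares via
`scipy.optimize.least_squares`, parameterized in (a, d, log₁₀c, log₁₀b,
log₁₀g). Points at x = 0 are excluded from the fit (they enter through
normalization); fits need ≥ 3 distinct positive concentrations, and with
fewer than 5 points the asymmetry is fixed at g = 1 (4PL fallback).
Bounds: c within 0.01–100× the tested range; b, g within (0.01, 50]; the
upper plateau is constrained to 90–110 % of control — the usual
"constrain Top" convention for control-normalized data, without which the
plateau (and hence the EC50) is unidentifiable for potent samples whose
whole tested range lies on the descending limb; the lower plateau is
bounded to [0, 70] %. Pass `a_bounds=None` for data-driven bounds.
Multistart: the heuristic start (a = max y, d = min y, c = geometric
mid-concentration, b = g = 1) with five deterministic jitters of (b, g),
plus profile starts from a coarse (c, b, g) grid solved linearly in
(a, d). Best residual sum of squares wins; near-ties resolve to the
smaller g. Single-start 5PL fits of short series reproducibly land in
c–g trade-off valleys (c pinned at its bound with g ≈ 30); the profile
starts eliminate this.

**Replicate handling.** `global` mode pools all points into one fit.
`per_replicate` mode (default) reports EC50 as mean ± SD over replicates;
by default the shape parameters (b, g) are shared — estimated once from
the pooled points, then fixed while each replicate refits (a, d, c). Five
free parameters per 7-point replicate are under-determined; sharing shape
across replicate curves is the same idea as a shared-parameter global fit
while preserving mean ± SD reporting. `share_shape=False` restores fully
independent replicate fits.

**A degenerate series** (all responses equal) yields a non-convergence
flag with diagnostics, not an exception.

## Screening products

A sample is *active* when its EC50 is determined and strictly below
50 µg/mL (boundary configurable, and the inclusive variant is available).
Actives are ranked ascending by EC50 with lexicographic sample-id
tie-breaks; the report carries rank, display names, EC50, cell viability
and sample number, with screened/active counts (active percentage rounded
to the nearest integer) in the footer. Viability significance is attached
only when Welch-test results are supplied — it is never inferred from
viability values alone. The packaged `table1.csv` fixture is a
transcription of the published 11-hit screening table used by the worked
examples and tests.

## Assay statistics

MTT viability is the group mean absorbance (570 nm) as a percentage of
the vehicle-treated control mean; the Aβ-only group is a comparison
group, not the baseline. Group comparisons use the two-tailed Welch
t-test with Welch–Satterthwaite degrees of freedom; the tail probability
comes from the t distribution via scipy (regularized incomplete beta).
When both sample variances are zero the test is degenerate and p = 1 (equal
means) or p = 0 (different means) by documented convention. Two star
profiles exist side by side because both appear in common practice:
(0.05, 0.01, 0.005) is the default and (0.05, 0.01, 0.001) is selectable;
the profile used is recorded in every output.

ThT kinetics are summarized by the endpoint at the final time point
(assays run 24 h, by which aggregation is saturated). "Concentration
dependence" is operationalized — a definition of this package, since no
standard test exists — as the Spearman rank agreement between
concentration and endpoint, with a one-sided exact permutation p-value
(full enumeration up to 8 concentrations, asymptotic beyond). −1 means
perfectly decreasing; constant endpoints give agreement 0 ("no trend").

## Synthetic plates and ground truth

The generator renders wells from a forward model: at concentration x a
sample leaves a fraction

    level(x) = floor_frac + (1 − floor_frac)/(1 + (x/c)^hill_b)^asym_g

of the control aggregate density; the well image draws
`n ~ Poisson(level·lambda_max)` isotropic Gaussian puncta (σ = psf_sigma)
with normally distributed amplitudes at uniform positions on a constant
background, adds Gaussian read noise, and clips to the bit depth. Every
output is a pure function of its arguments including the seed.

Because puncta placement is a Poisson process, image variance is
proportional to aggregate density (Campbell's theorem), so the expected
SD readout scales as √level — the readout of a 5PL load curve is itself a
5PL with asymmetry g/2. `ec50_true` is therefore defined **on the readout
scale**: it is the concentration where the expected normalized SD crosses
50 % of control, i.e. exactly the estimand of the fitting stage. The
latent load at `ec50_true` is 1/4 (for floor_frac = 0), not 1/2; c is set
to `ec50_to_c(ec50_true, hill_b, asym_g/2)`. Defining truth on the load
scale instead would make any SD-based pipeline look ~2–3× biased for
ordinary slopes — an artifact of comparing different estimands, not an
error of the pipeline.

Defaults, chosen once from this analysis to mimic a 16-bit fluorescence
camera and held fixed: 1000 × 1000 px images (the 432 px crop sits
strictly inside), background 500 counts, read-noise SD 20 counts,
lambda_max 1500 puncta/image, psf_sigma 3 px, amplitudes 2000 ± 400
counts, hill_b 1.5, asym_g 1.0, floor_frac 0 (complete inhibition
achievable). These give a control-well SD of ≈ 420 counts and a
blank/control SD ratio of ≈ 0.05, so blanks normalize to ≈ 5 % and the
ND dynamic range is wide. The default dilution series is 7-point 2-fold
from 100 µg/mL — the customary top test concentration for crude-extract
screens of this kind — with 3 replicates; all of it is configurable.

What the generator does **not** emulate: fibrillar aggregate morphology
(puncta suffice because the SD statistic is morphology-agnostic),
quantum-dot photophysics, optical aberrations and illumination gradients,
plate-position effects, and pipetting error across the dilution ladder.
Passing the recovery benchmark therefore shows the pipeline is correct
and well-conditioned for Poisson-puncta images; it does not certify
accuracy on real micrographs with structured backgrounds.

The recovery harness renders 20 seeded plates with true EC50s of 2, 10
and 40 µg/mL plus an inert sample (floor_frac = 1), runs the full
pipeline (score → normalize → ND rule → per-replicate shared-shape fit),
and checks that estimates land within ±25 % of truth (and that the inert
sample is flagged ND). Problem sizes throughout the test-suite and the
acceptance script — 20 runs, 3 replicates, 1000 random parameter sets for
the closed-form oracle, 2000 Welch null replicates — are the package's
benchmark conditions; unit tests use crop-sized (432 × 432) images with
density matched to the default model.

## Known limitations

* The 5PL parameters (other than the EC50 read-off) are not individually
  comparable to other software's asymmetric-sigmoid parameterizations;
  the curve families are equivalent but the parameter values differ.
* EC50 SDs from per-replicate fits understate uncertainty when the shape
  is shared (the shape estimate is common to all replicates).
* The ND rule reads only the top concentration; a non-monotone series
  that dips below 50 % at an intermediate concentration is still ND if
  its top-concentration response rebounds above 50 %.
* No multiple-testing correction is applied across samples in the assay
  statistics; per-comparison p-values are reported as-is.
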