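# Methods

This note records the scientific and numerical choices behind the package:
what is computed, which conventions were genuinely open and how they were
pinned, what the synthetic cohorts do and do not emulate.

## Dose-response and AUC

Raw readouts are ATP-luminescence values from a dilution series (default
7 points, 3-fold from 50 µM) plus DMSO vehicle wells, three technical
replicates per condition. Replicates are aggregated by arithmetic mean with
no outlier rejection — with n = 3 any robust trimming is noise itself.
Viability is the per-dose mean divided by the DMSO mean; there is a single
vehicle condition, so no plate-median or positive-control normalization is
attempted. Values may exceed 1 (wells outgrowing control) and are kept
unclipped for QC; clipping to [0, 1] happens only inside the AUC integral.

The four-parameter logistic is parameterized with a positive Hill slope and
a decreasing curve: `v = bottom + (top − bottom)/(1 + 10^(h(x − L)))` with
`x = log₁₀ c`, `L = log₁₀ EC₅₀`. Fit constraints: `bottom ∈ [0, 1]`,
`top ∈ [0.5, 1.5]`, `h ∈ (0, 10]`, `L` within the dose grid ± 1 decade.
Initialization reads `top`/`bottom` off the raw curve and puts the EC₅₀ at
the dose nearest the half-range; three Hill starts (0.7, 1, 2) guard
against local minima; `scipy.optimize.least_squares` (trust-region
reflective, tolerances 1e-14) does the work. Degenerate profiles are not
forced through the fit: a viability range under 0.05 (no dose effect), an
uphill step above 0.25 between adjacent dose means (non-monotone beyond
noise), a failed optimizer, or an inverted `bottom > top` optimum all mark
the profile `fallback_used`.

AUC is the integral of clipped viability over `x` across the tested range,
divided by the range width: dimensionless, in [0, 1], comparable across
dose grids, with 1 = fully resistant. Fitted curves are integrated by
adaptive quadrature (abs/rel tolerance 1e-10, checked against a dense
trapezoid to 1e-6); fallback profiles use the trapezoid on the observed
dose means. Which axis, normalization and curve the original assay software
used is not recorded anywhere authoritative; these conventions are fixed
here and exposed (`method` flag on every AUC) so their influence can be
examined.

A noiseless fit recovers its generating parameters exactly only when the
true `L` lies inside the bounded search range (grid ± 1 decade); outside,
the optimum sits on the bound. The recovery study therefore samples truths
inside the identifiable regime (EC₅₀ at least 0.3 decades inside the grid,
Hill 0.8–2.5, bottom ≤ 0.3). At 10% replicate CV the median |ΔL| over 100
profiles is ≈ 0.05 decades, comfortably identifiable on a 2.9-decade grid.

## Indices and classification

All Z-scores are cohort statistics per drug, never pooled across drugs, and
use the sample SD (n − 1) by default (`sd_mode="population"` exists for
sensitivity checks; n = 14 makes the distinction visible but not decisive).
Zero spread raises a named zero-variance error rather than returning NaNs.

Growth rate is `(area_day3 − area_day1)/area_day1` from vehicle-control
wells — it is a property of the sample, not of any drug — with the day-1
baseline as default endpoints. The CODRP distance is Euclidean from
`(−4.5, −4.5)` in `(Z_growth, Z_AUC)` space; −4.5 is the Z below which less
than 0.003% of a normal distribution falls, i.e. an idealized maximally
sensitive, non-growing sample, so distance increases with resistance.
Distances are re-Z-scored per drug to give the index.

The classification cutoff −0.17 is a stored constant of the method, applied
inclusively on the sensitive side (`≤`); no tie rule is documented upstream
so one is fixed here for determinism. A Youden-J cutoff-derivation utility
(`derive_cutoff_youden`, via `sklearn.metrics.roc_curve`) is provided for
exploration but never feeds headline outputs, since how −0.17 was
originally identified is not documented. AUC-only mode classifies on
`Z_AUC` with the same cutoff semantics, which is what makes the two modes
head-to-head comparable.

One numerical convention is deliberate: if a cohort's growth column is
constant up to numerical jitter (SD ≤ 1e-8 relative), its Z-scores are set
to 0 instead of being amplified — Z-scoring is scale-free, so without the
floor an infinitesimally jittered constant would produce arbitrary O(1)
scores. With the floor, a growth-homogeneous cohort's CODRP index becomes a
strictly increasing transform of `Z_AUC`: identical ranking, and calls that
coincide with AUC-only calls except for patients squeezed between the two
modes' effective thresholds. `zscore()` itself stays strict and raises on
exactly zero variance.

## Clinical adjudication

RECIST labels are taken at the time the effusion was sampled: PR →
sensitive, PD → resistant, NE → not evaluable. SD follows the direction of
the documented tumor-size change (decrease → sensitive, increase →
resistant, undocumented → not evaluable) — stable disease with a measurable
shrinkage is treated as clinical benefit. Not-evaluable lines are excluded
from every denominator. In the bundled cohort, second-generation TKI lines
are filed under `afatinib` and third-generation lines under `osimertinib`
(the two screened drugs), with the actual agent (dacomitinib, lazertinib)
recorded in the notes; patients sampled at progression on a drug carry PD
for that drug even when an earlier response occurred, because the organoids
were grown from the progressing disease.

## Synthetic cohorts

`simulate_cohort` draws, per patient: a latent sensitive/resistant class
(Bernoulli, default 0.5) that is also the clinical label (optional label
noise, default 0 to isolate index performance); a class-conditional
intrinsic log₁₀ IC₅₀ (defaults −1 and +1 log₁₀ µM — two decades apart,
within the dose grid — SD 0.5); a Hill slope uniform on [0.8, 1.5];
multiplicative Gaussian replicate noise with CV 0.10, a typical screening
replicate CV; and a growth rate (mean 0.5, SD 0.2 relative increase over
two days).

The growth–AUC coupling is mechanistic. The growth score loads weakly on
the resistant class (loading 0.3 — clinically aggressive tumors grow
somewhat faster), and the assay-realized IC₅₀ is shifted against the
class-independent growth component: a slow-growing organoid under-reports
drug kill in a short ATP endpoint, inflating its apparent AUC, and a fast
grower deflates it. The shift strength γ is calibrated by bisection on a
fixed 4096-draw internal reference sample pushed through the exact
(closed-form) AUC map, so the empirical Pearson corr(growth, noiseless AUC)
matches the configured target (default −0.3; the calibration absorbs the
attenuation from AUC saturation at the grid edges). Under this coupling the
growth axis carries exactly the de-confounding information the CODRP
distance uses, and an AUC-only reading is systematically misled for
growth-extreme patients — at a target correlation of −0.5 and cohorts of
30, mean AUC-only accuracy sits near 0.75 while the composite index reaches
≈ 0.92. A pure rank-copula coupling was considered and rejected: it ties
growth to the AUC without giving it any independent clinical content, so it
can only dilute the AUC signal and contradicts the phenomenon the index
exists to exploit. `truth.csv` records the assay-realized IC₅₀ and Hill
(what a noiseless refit recovers) plus the noiseless AUC.

What the generator does **not** emulate: spatial plate effects and edge
wells, organoid imaging and segmentation (the growth table is consumed, not
produced), inter-drug correlation structure within a patient, mixed or
evolving clones, and clinical-label ambiguity beyond a flat flip
probability. Passing simulation benchmarks therefore demonstrates the
statistical machinery under the assumed generative structure, not clinical
performance.

## Problem sizes

Default analysis runs mirror the motivating cohort (14 patients, one or two
drugs). The simulation head-to-head uses 100 cohorts of 30 patients; the
correlation check uses one 200-patient cohort; recovery studies use 40
noiseless and 100 noisy profiles. These sizes give Monte-Carlo standard
errors well below the effects being demonstrated while keeping a full run
in the minutes range on a single core.

## Known limitations

* The −0.17 cutoff and −4.5 reference are adopted constants; nothing here
  re-derives them, and the cutoff's transfer to other drugs or cohorts is
  untested.
* AUC conventions (log axis, [0, 1] normalization, clipping) are this
  package's pinned choices; absolute AUC values are not comparable with
  tools using other conventions, although Z-scored indices largely are.
* Concordance on 14 patients carries wide (uncomputed) confidence
  intervals; the package deliberately reports raw counts alongside
  percentages.
* With fewer than ~3 patients per drug the cohort Z-scores are undefined or
  fragile; the pipeline refuses cohorts of fewer than 2.
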