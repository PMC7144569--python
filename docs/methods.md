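# Methods

## Problem and model

Crude serum autofluorescence under 310 or 366 nm excitation is a broad
emission band (≈390–630 nm) composed of overlapping contributions from
endogenous fluorophores: retinol (largely bound to retinol-binding
protein), the fluorescing free fatty acids arachidonic, linoleic and
oleic acid, a short-wavelength tail from serum proteins (mostly
albumin), an unassigned band near 440 nm (compatible with fatty-acid /
NAD(P)H emission), a negative compensation band near 410 nm for
hemoglobin re-absorption from residual hemolysis (relevant under 310 nm
excitation), and, in ischemia/reperfusion (I/R) serum under 366 nm
excitation, a flavin band near 560 nm.

Each component is modeled as a **half-Gaussian-modified Gaussian (GMG)**
band: the convolution of a Gaussian (width σ_g, center c) with a
one-sided half-Gaussian (width σ_h), which has the closed form

    f(λ) = A · φ((λ−c)/s)/s · [1 + erf( σ_h (λ−c) / (σ_g √2 s) )],
    s = √(σ_g² + σ_h²),

i.e. a skew-normal-shaped peak with area A, skewed toward longer
wavelengths.  σ_h = 0 recovers the symmetric Gaussian.  Amplitude is
normalized to band *area*, not peak height (the other convention would
only rescale amplitudes; area normalization makes amplitudes directly
comparable to integrated contributions).

Tables of band parameters give the *observable* description — peak
wavelength λ and FWHM of the realized skewed curve — which does not
coincide with (c, σ_g).  Because the family is location–scale at fixed
asymmetry ratio ρ = σ_h/σ_g, one standardized numerical shape
measurement (mode offset and FWHM at c = 0, σ_g = 1) inverts (λ, FWHM,
ρ) into (c, σ_g, σ_h) in closed form; the shape solver does this and
verifies the realized mode/FWHM to 0.05 / 0.1 nm.  Shape descriptors
are measured on a 0.01 nm grid with bisection refinement, two orders
below instrument resolution.

The source band tables print only (λ, FWHM), never the asymmetry, so ρ
is an explicit parameter: default 0.3 for every library component,
fit-bounded in [0, 1.5].  The printed (λ, FWHM) pairs are enforced on
the *realized* band for any ρ, so the tabulated values stay honored
regardless of the asymmetry actually fitted.

## Component library

Starting (λ, FWHM) in nm, from pure-compound emission spectra:

| component | 310 nm | 366 nm |
|---|---|---|
| retinol | (490, 112) | (490, 112) |
| arachidonic acid | (425, 120) | (470, 93) |
| oleic acid | (370, 85) | (462, 90) |
| linoleic acid | (417, 92) | (428, 73) |

Minor bands have no printed widths; starts are 80 nm (proteins tail,
peak free below 420 nm), 60 nm (unassigned 440 nm), 30 nm (hemoglobin,
negative amplitude), 60 nm (flavin 560 nm), all width-free within
[20, 150] nm.  Fluorophore peaks may move ±10 nm around their start in
reference fits (solvent/matrix shifts) and FWHM ±25%.  Only the
hemoglobin band may take negative amplitude.  The registry round-trips
through a YAML config for overrides.

## Fitting

Spectra are peak-normalized to 100 a.u. (the pre-normalization
trapezoidal integral over the 390–600 nm quantification window is kept
for absolute rescaling) and decomposed by bounded trust-region least
squares (`scipy.optimize.least_squares`, TRF; tolerances 1e-10 cost /
1e-8 step, ≤2000 evaluations) over per-component parameters (peak,
FWHM, ρ, area).  The protocol is two-stage: reference fits (sham) start
from the library; their converged solutions are pooled by per-parameter
medians into one reference combination; comparative fits (treated
samples) start there with peak bounds tightened to ±5 nm and FWHM to
±10% (amplitudes fully free).  A deterministic 5-restart multi-start
(seeded jitter: peaks ±5 nm, widths ±10%, amplitudes ×[0.5, 2]
log-uniform) keeps the lowest objective, tie-broken toward the start.

**Shape anchoring.**  Several band pairs are nearly collinear as area-
normalized profiles (arachidonic 470/93 vs oleic 462/90 at 366 nm:
cosine 0.989; the linoleic/arachidonic/proteins trio at 310 nm), so the
pure sum-of-squares objective has almost-flat ridges along which shapes
and amplitudes trade at sub-noise cost, and the minimizer's stopping
point on such a ridge would be arbitrary.  The fit therefore augments
the data residuals with light quadratic anchor residuals
w·(θ−θ₀)/range on each band's peak (w = 4, range 10 nm), FWHM and ρ
(w = 5, ranges 5% and 0.1); amplitudes are never penalized.  For
noise ≈ 0.5 a.u. these weights correspond to a Gaussian prior on peak
position with SD ≈ 1.25 nm — of the order of genuine solvent/sample
band-position variability — and effectively fix width/asymmetry at the
reference shape.  On noiseless data the anchor is inert (the SSE
minimum dominates); on flat ridges it selects the closest-to-start
point, the continuous form of the tie-break rule.  Reported SSE and r²
use the data residuals only; `shape_anchor=False` restores the pure
objective.

Goodness of fit is reported as r² = 1 − SSE/SStot on the fitted window,
residual mean/extreme, and a Wald–Wolfowitz runs test on residual
signs; the pass flag requires r² ≥ 0.95 and |residual mean| ≤ 0.5 a.u.
No baseline term is fitted; flat or non-positive spectra are rejected.

## Quantification

Component areas are trapezoidal integrals of each fitted band over the
390–600 nm window on the spectrum's grid (so signed areas sum exactly
to the model-curve area).  Percent contribution = 100 × area / Σ
positive areas; the negative hemoglobin band is excluded from the
denominator and reported separately.  Absolute contribution = percent ×
measured pre-normalization window integral / 100, exactly.  The AA/Ret
index is the arachidonic/retinol percent ratio; on group means it is
rounded to 2 decimals for report parity.  Group summaries report
mean ± SE (SD/√n) with two-sided Welch tests versus the reference group
(Mann–Whitney selectable), starred * p ≤ 0.05 / ** p ≤ 0.01.
Components whose group-mean percent is ≤5% in every group are dropped
from rendered reports (kept in raw records), matching the minor-band
reporting convention.

Note that the quantification window truncates bands extending outside
390–600 nm.  At 310 nm the oleic band (370 nm peak) lies half below the
window, so window-realized shares differ from full-band composition
shares; the synthetic truth is bookkept in window-realized terms so
that fit and truth are compared on the same footing.

## Synthetic cohorts

The generator emulates the sham / I/R 60-60 / I/R 60-120 design, n = 7
per group.  Per sample it draws component percentages from truncated
normals (means = the published group compositions; SD = SE·√7;
unreported "≤5%" cells set to 2.0 ± 0.5; the remainder to 100 assigned
to the unassigned 440 nm band), renormalizes to 100, builds one GMG
band per component from the library shapes with uniform ±2 nm
per-sample peak jitter, sums on a 1 nm grid over 390–630 nm, scales the
curve so its window integral equals a lognormal total area (mean = the
published per-group absolute-contribution row sum; CV 0.15), adds the
hemoglobin dip (5% of peak, 310 nm) or flavin share (3%, I/R at
366 nm), and finally adds homoscedastic Gaussian noise of 0.5 a.u. on
the normalized scale.  Serum noise magnitude and dip depth are declared
defaults, not inferred quantities.  Per-sample seeds spawn from the
master seed via `numpy.random.SeedSequence`, so cohorts are
reproducible sample by sample.  A truth-only draw
(`generate_truth_cohort`) samples the same composition distribution
without rendering spectra, for replicate-level power studies.

What the generator does **not** emulate: wavelength-dependent
instrument response, heteroscedastic/shot noise, solvent-dependent band
reshaping (only rigid peak jitter), inner-filter effects beyond the
single empirical negative band, and any correlation between composition
and total area.  Passing recovery tests therefore demonstrate correct
inference *under the stated band model*, not robustness to
misspecified lineshapes.

## Identifiability limits (measured)

With noise 0.5 a.u. and ±2 nm jitter, the arachidonic/oleic pair at
366 nm carries a per-sample exchange SD of ≈6 percentage points in the
sham composition and ≈11 in the I/R compositions even for an oracle
estimator given the exact per-sample shapes; the realizable fit reaches
≈6 and ≈12.  The amplitude ≥ 0 constraint folds this ridge noise into a
systematic positive bias on near-zero components (the 2% linoleic share
at 310 nm acquires ≈+5 points, mirrored on arachidonic acid).  Group
means over n = 7 samples and 5 cohorts inherit ≈1–2 points of sampling
SD on these degenerate directions.  Well-separated components (retinol,
proteins, the 440 nm band, flavin) are recovered to well under 1 point.
These are properties of the study conditions (band overlap, noise,
jitter), not of the optimizer: frozen-shape non-negative linear
unmixing and anchored nonlinear fits across a 4× range of anchor
weights bracket the same numbers.

## Pipeline sizes and defaults

Default end-to-end runs fit 21 spectra (3 groups × 7) per excitation;
one cohort completes in well under a minute on one CPU.  The analysis
drivers use seed 42; replicate-level power studies use 100 seeded
truth-only cohorts.  Runs record a manifest (config, library hash,
package version) sufficient to reproduce all JSON outputs
byte-identically.
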