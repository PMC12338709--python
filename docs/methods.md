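# Methods

## Voxel mask and tissue-fraction extraction

The MRS voxel is described by its center (mm, world/RAS), edge lengths
and a row-orthonormal orientation matrix; probability maps are used on
their native grid with the NIfTI affine taken verbatim (no resampling).
Each image voxel's weight is the fraction of its volume inside the
(possibly oblique) MRS box, estimated from `supersample^3` regularly
spaced interior sample points (default `supersample = 3`).  This
partial-volume weighting bounds the discretization error by roughly one
part in `supersample` per boundary voxel, which the phantom suite
verifies directly; binary nearest-center masking would leave an
untestable bias at oblique orientations.  Tissue fractions are the
weighted mean probabilities inside the mask followed by sum-to-one
normalization.  If the pre-normalization probability sum inside the
voxel falls below 0.5, the voxel is mostly non-brain and extraction
fails loudly rather than silently rescaling noise.  Sessions are
assumed co-registered upstream; no registration is performed here.

## Quantification model

Water-referenced concentration with tissue and relaxation correction:

    [M] = (S_M/S_H2O) * sum_x f_x d_x R_x / ((1 - f_CSF) R_M) * [H2O]

- Water densities d_GM/d_WM/d_CSF = 0.78/0.65/0.97; [H2O] = 55.51 mol/L.
- Relaxation attenuation uses the standard exponential form
  `R = exp(-TE/T2) * (1 - exp(-TR/T1))`; the form is configurable in
  case a variant saturation model is preferred.
- Default acquisition TE/TR = 35/2000 ms (stored in seconds; inputs
  accepted in ms with explicit keys `te_ms`/`tr_ms`).
- Default water relaxation (3 T literature values, seconds):
  GM T1=1.331, T2=0.110; WM T1=0.832, T2=0.0799; CSF T1=4.163,
  T2=0.503.  Default metabolite (tCr) T1=1.35, T2=0.166.  These
  defaults are literature stand-ins intended to be overridden per
  study from the config file; no relaxation value is hard-coded in the
  numerical operations.
- The number of protons per metabolite is assumed absorbed into the
  modeled amplitude by the fitting basis set; **no proton-count
  division is applied**.  Tissue-specific metabolite concentrations and
  tissue-specific metabolite relaxation are deliberately out of scope.

`forward_signal` is the exact algebraic inverse and round-trips with
`molar_concentration` to relative 1e-10 over the full valid domain
(property-tested).  `TissueFractions` produced by the extraction sum to
1 within 1e-9; the constructor additionally accepts fractions quoted to
two decimals (published marginal means), which are used verbatim rather
than rescaled, since rescaling rounded values would distort the very
comparisons they are quoted for.

## Statistics

The design is complete and balanced: n participants x 2 sessions x m
methods, one observation per cell.  The Method*Session linear
mixed-effects model with a participant random intercept is, on this
design, algebraically identical to the balanced repeated-measures
ANOVA, which is what is implemented: sums of squares from cell means,
with the three within-participant interaction strata pooled into one
error term with (n-1)(ms-1) degrees of freedom (60 at n=13, m=3) that
serves as the denominator for all fixed-effect F tests.  Unbalanced or
incomplete tables are rejected rather than approximated by REML — this
keeps every number deterministic and checkable against an
OLS-with-dummies oracle, which the test suite does to 1e-8.

Estimated marginal means are cell means averaged over the other
factor; their standard errors use the variance decomposition
sigma_u^2/n + sigma_e^2/(n*s), with the participant variance
sigma_u^2 = (MS_participant - MS_error)/(m*s) clipped at zero and t
critical values on the pooled error df.  Tukey HSD contrasts use
SE = sqrt(2*MS_error/(n*s)) (the participant intercept cancels in
within-participant contrasts) and the studentized-range distribution
with the pooled error df.

Steiger's Z for dependent correlations sharing a common variable
(age) is the Fisher-z difference scaled by the asymptotic standard
error with the pooled mean correlation (Steiger 1980, Z1*):

    Z = (z1 - z2) * sqrt((n-3) / (2 (1 - s))),
    s = [r_yz (1 - 2 rb^2) - rb^2 (1 - 2 rb^2 - r_yz^2)/2] / (1 - rb^2)^2

with rb the mean of the two compared correlations.  The test suite
validates it against a frozen independently evaluated example and a
Monte-Carlo null calibration (unit-scale Z, ~5% rejection).

Normality is screened with Shapiro-Wilk per metabolite x method x
session group at a Bonferroni-corrected threshold (m = number of
groups); paired session t-tests use a Bonferroni factor of 3 by default
(three QC metrics), configurable.  All tests are two-sided at
alpha = 0.05.

## Synthetic study generator

The generator emulates the test-retest design rather than any
segmentation algorithm's internals.  Per participant i, session k,
method j:

    f_obs(ijk) = mu_j + u_i + a_i + eps_ijk        (observed fractions)
    f_true(ik) = mu_bar + u_i + a_i + eps'_ik      (true composition)

where mu_j are the method mean fraction vectors (defaults ANTs
(0.45, 0.33, 0.22), FSL (0.43, 0.30, 0.26), SPM (0.56, 0.27, 0.17),
simplex-normalized on input), mu_bar their average, u_i a shared
participant deviation (per-component SD 0.03), a_i an age-linked
GM<->WM shift, and eps iid per-row noise (SD 0.01).  All deviations are
projected onto the sum-zero subspace, so rows stay on the simplex
(additive-with-renormalization rather than Dirichlet, which keeps the
configured method centers exact and the no-session-effect null exact);
draws that would still leave the simplex in more than 1% of rows are an
error.  The participant and noise SDs are back-derived from the
printed 95% CIs of the method marginal means (CI half-width ~0.02 at
n=13 implies a between-participant SD of ~0.03) and are approximations,
not measured quantities.

The age slope is computed from a target age~normalized-GM correlation
(default -0.7) by linearizing g = f_GM/(f_GM+f_WM) at the grand-mean
composition; ages are uniform on 19-66 years.  True concentrations
default to tCr = 7.2 mM with an optional age slope (off by default).

Signals: `s_met = forward_signal(true_conc, f_true, ...) * exp(eps)`
with multiplicative log-normal noise (SD 0.02) drawn per row, water
amplitude fixed.  Because the signal derives from the *true*
composition while quantification uses each method's fractions, method
biases propagate into concentrations exactly as in a real study where
all methods reanalyze the same spectra; quantifying with the true
fractions recovers the true concentration exactly at zero noise.

What the generator does **not** emulate: spectral lineshapes, fitting
(amplitudes are consumed as given), spatially structured segmentation
errors, scanner drift, or any correlation between segmentation error
and anatomy beyond the age-GM trend.  Passing tests therefore
demonstrate correctness of the propagation arithmetic and the
calibration of the inference battery under the assumed
random-intercept structure — not the accuracy of any real segmentation
tool.

## Phantoms and oracles

Geometric phantoms place a planar GM/WM interface (optionally a
logistic profile of configurable width) and a CSF slab on a grid
centered on the world origin.  Analytic voxel fractions are available
in closed form for axis-aligned boxes (1-D integrals, including the
smoothed interface) and, by central symmetry, for arbitrarily oriented
boxes whose interface plane passes through the box center; other
oblique configurations raise rather than approximate.  Extraction
agrees with the analytic values to < 0.01 at `supersample = 5`.

## Problem sizes and numerical choices

The analysis scripts and test suite run the study at its native size
(13 participants, 2 sessions, 3 methods); stochastic calibration checks
use 150-1000 replicates, chosen so Monte-Carlo error is well inside the
asserted bands.  Phantom grids are 40^3 at 1-2 mm spacing — large
enough that discretization error, not grid extent, dominates.
Degenerate inputs fail loudly: pure-CSF voxels, unpaired sessions,
incomplete designs, zero-variance differences and sub-0.5
pre-normalization probability sums are all errors, not warnings.
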