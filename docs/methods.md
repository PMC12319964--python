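# Methods

## Model

The neural contrast sensitivity function (nCSF) of a cortical location is
the composition of two classical descriptions of early visual responses.

**CSF.** Sensitivity as a function of spatial frequency is an asymmetric
parabola in log10–log10 coordinates,

    f(SF) = 10^( log10(CS_p) − (log10 SF − log10 SF_p)² · width² ),

with separate fall-off rates for the two branches: `width_L` below the
peak and `width_R` at/above it. `width` is a *rate*, so larger values
mean a narrower curve. `width_L` is fixed at 0.68 — low-frequency fall-off
is shallow and poorly constrained by six stimulus frequencies — leaving a
three-parameter CSF (`CS_p`, `SF_p`, `width_R`). Sensitivity is
100 / threshold-contrast-%, so `CS_p = 150` means a 0.67% threshold at the
peak.

**CRF.** The transition from no response to full response at a given SF
is a Naka–Rushton sigmoid `R(C) = a·C^q/(C^q + Q^q)` with fitted exponent
`q` (`slope_CRF`) and saturation amplitude `a`. The semisaturation
contrast is not free: the default rule sets `Q(SF) = 100/f(SF)`, the
CSF-implied threshold contrast, which is the only mapping consistent with
the definition of sensitivity and makes the response reach `a/2` exactly
at threshold. The rule is pluggable (`CrfParams.semisaturation_rule`).
Sensitivity is floored at 1e-6 before forming `Q` to avoid division
blow-ups far from the peak. The model operates on the stimulus contrast
axis (Michelson %); a Michelson→RMS factor (1/√2 for sine gratings) is a
config flag, off by default — fitting is invariant to a global rescaling
of the contrast axis, which is absorbed by `Q`.

**Forward model.** The per-volume neural drive is the nCSF response to
that volume's (SF, contrast) condition (zero on mean-luminance blanks).
It is convolved with a two-gamma HRF — canonical gamma peaking at 6 s
minus an undershoot gamma at 16 s scaled by 1/6, truncated at 32 s, with
temporal-derivative and dispersion-derivative basis terms at weights
(1, 1, 0) by default — normalized to unit canonical peak so amplitudes
stay in percent-signal-change units. Convolution is linear, causal, and
zero-padded before the run start; runs begin with a 15 s blank, so edge
effects are negligible. The baseline is an additive offset of the
measured signal.

## Stimulus protocol

TR 1.5 s. Six spatial frequencies (0.5, 1, 3, 6, 12, 18 c/deg), each in
one ascending- and one descending-contrast block of 18 s (12 volumes, one
contrast per volume); a 15 s blank precedes every block pair and one ends
the run: 12·12 + 7·10 = 214 volumes = 321 s. Twelve Michelson contrasts
within 0.25–80% per block. The per-SF grid is 12 log-spaced values from
`max(0.25, threshold(SF)/4)` to 80%, with the threshold from the standard
CSF — high-SF blocks therefore start at higher contrasts (2.4% at
18 c/deg) than low-SF blocks (0.25%), keeping the sampling straddled
around the expected threshold. Block order is a deterministic
pseudo-random permutation from a documented seed (default 2024), recorded
in the design metadata. Within-volume micro-events (three 300 ms gratings
with orientation changes) are collapsed to one condition per volume: the
model is fit at volume resolution and orientation is not modeled.

## Fitting

Stage 1 precomputes unit-amplitude predictions for every node of a
4-D grid — `SF_p` 12 log-spaced nodes over 0.25–18 c/deg, `CS_p` 10 over
5–500, `width_R` 8 linear over 0.3–3, `slope_CRF` 6 log-spaced over
0.5–8 (5760 nodes) — and solves amplitude and baseline per node in closed
form (OLS of the unit prediction plus intercept). The minimal-RSS node
wins; exact ties go to the lowest flat index, making the stage
deterministic. Stage 2 refines the four nonlinear parameters with
L-BFGS-B in log10 space, bounded by the grid extremes, amplitude/baseline
re-solved inside the objective (tolerance 1e-6 on RSS, ≤500 evaluations);
if the optimizer fails to improve on the grid RSS, the grid solution is
returned with `converged=False`, so refinement is never worse than its
initialization. Because the total sum of squares depends only on the
data, minimizing RSS and maximizing variance explained
(r² = 100·(1 − RSS/TSS), TSS about the data mean) select the same
parameters. Negative fitted amplitudes are permitted but flagged.
Batch fitting is row-independent and vectorized; a `chunk_size` option
splits the coarse stage into row blocks that are bitwise-identical to
unchunked execution (this, rather than process-level parallelism, is the
determinism-preserving way to stage large batches). Rows failing the
default r² > 30% threshold are flagged excluded; per-row errors are
isolated and never abort a batch.

## Simulation-based validation

Two ground-truth models: "green" (SF_p = 1 c/deg, CS_p = 150,
width_R = 1.3) and "red" (SF_p = 2, CS_p = 100, width_R = 1), both with
slope_CRF = 3, amplitude 1, baseline 0 (mid-grid values avoiding bound
effects; the CRF/baseline truths are a package choice). The noiseless
prediction is normalized to unit standard deviation, and standard-normal
noise scaled by 0.4, 0.7 or 1.1 is added; 100 replicates per condition.
Noise streams derive deterministically from (master seed, truth index,
scale index, replicate), so a seed fully reproduces a dataset. Refits are
categorized by variance explained — high ≥ 50%, medium [30, 50), low
[10, 30), excluded below 10, boundaries assigned upward — and the
recovery report gives medians and 25th/75th percentiles of each parameter
and the derived normalized AUC per (truth × noise × category), plus an
"all" rollup.

What the generator emulates: the deterministic forward structure of
block-design responses and graded, seeded measurement noise. What it does
not: temporally correlated physiological noise, HRF variability across
cortex, vein effects, run-to-run drift (removable with the DCT tools),
and surround-suppressed (negative-amplitude) responses — so passing
recovery tests demonstrates estimator correctness under white noise, not
robustness to every property of real data. Alternative generation-time
HRFs and stretched designs are supported generically through the config.

Observed behavior of the seeded default run (computed by the tests and
the acceptance script, not asserted from literature): mean refit r² falls
≈86 → 68 → 46% across the three noise scales; median recovered SF_p is
within a few percent of truth at scale 0.4; interquartile spread of
SF_p, CS_p, width_R and AUC grows monotonically with noise, while
slope_CRF's spread saturates against its fitting bounds at high noise;
normalized AUC is by far the most stable quantity (relative IQR ≈ 0.02–0.1
versus ≈ 0.1–0.5 for CS_p). SF_p, in contrast, shows *larger* relative
spread than CS_p under these conditions — with only six stimulus
frequencies (none between 1 and 3 c/deg) the peak location is weakly
localized, and a multistart-refinement control shows this is intrinsic to
the likelihood rather than an optimizer artifact. Users comparing
locations should prefer AUC, and treat single-voxel SF_p values with the
spread the recovery report quantifies.

## AUC summary

Normalized AUC integrates `max(0, log10 f(SF))` over log10 SF on 200
log-spaced points across 0.5–18 c/deg (trapezoid rule; quadrature error
≪ reporting precision, verified against a 10×-density oracle) and divides
by the same integral for the standard CSF (CS_p = 166, SF_p = 2.5,
width_L = 0.68, width_R = 1.28), in percent. Clamping log-sensitivity at
0 (sensitivity floor 1) keeps the area nonnegative and matches the
convention of area above the sensitivity-1 axis.

## Preprocessing

Detrending removes the per-unit mean and the projection onto the first
three non-constant orthonormal DCT-II basis vectors ("first three" = the
three lowest non-constant frequencies; the mean is a separate demeaning
step). Three components capture ~98% of a linear ramp's power over a
214-volume run. Percent signal change divides the detrended series by the
per-unit mean of the *raw* series (detrended series are zero-mean, which
would make PSC undefined); units with nonpositive raw mean are masked
out. Run averaging expects time-locked runs of identical shape; averaging
then converting to PSC equals converting the averaged series. Motion,
distortion and vein corrections are out of scope — inputs are assumed
corrected.

## Problem sizes and defaults

The validation suite and the acceptance script run the full protocol: 100
replicates × 2 truths × 3 noise scales = 600 voxels of 214 volumes
against the 5760-node grid plus per-voxel refinement (≈15 s on one CPU);
unit tests use 3×3×3×3 grids and small batches where an exhaustive
oracle is the point. All constants live in `ncsf.config` and round-trip
through YAML/JSON.

## Known limitations

- The `Q = 100/f(SF)` link is a modeling choice; other monotone links
  change the meaning of `slope_CRF` but are absorbed into the same fitting
  machinery via the pluggable rule.
- The per-SF contrast grids and the block order are substitute rules, not
  reconstructions of any specific experiment's tables; both are fully
  overridable via config or design files.
- `slope_CRF` is weakly identified at high noise (its posterior spread
  fills the fitting bounds); report it only for high-r² locations.
- The unit-SD signal normalization makes noise scales interpretable as
  noise-to-signal ratios, but the mapping from noise scale to r² band
  depends on it; with peak-normalized signals the same scales land
  roughly one r² category lower.
- Alternative CSF parameterizations (log-Gaussian, two-parameter forms)
  and suppression/divisive-normalization extensions are out of scope.
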