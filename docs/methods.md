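# Methods

This note records the models, numerical choices and design decisions behind
the package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Signal model and relaxometry

All signal modelling assumes a spoiled gradient-recalled echo (SPGR)
sequence in steady state,

    S = S0 sin(θ) (1 − E1) / (1 − cos(θ) E1),  E1 = exp(−R1 TR),

with R2\* decay neglected (valid for TE ≪ 1/R2\*). Flip angles cross every
public boundary in degrees and are converted to radians exactly once; all
other inputs are SI (times in seconds), except Ktrans/kep which follow the
community convention of min⁻¹.

**Variable-flip-angle fitting.** Voxels whose mean multiflip intensity is
below a configurable fraction (default 0.10) of the image maximum are
treated as noise and skipped (0 sentinel in the maps). The remaining voxels
are fitted by the in-package Levenberg–Marquardt solver, initialised by the
DESPOT1 linearisation (S/sin θ regressed on S/tan θ), which is exact on
noise-free data; the regression slope is clamped to (0, 1) so noisy voxels
still yield finite starting values. Voxel fits are independent, so results
do not depend on how work is distributed.

**Dynamic inversion.** The dynamic signal is normalised to the pre-contrast
signal S(x,0) and inverted with the sin(θ)-free rearrangement of the signal
equation, which reduces sensitivity to B1 transmit inhomogeneity. When an
S0 map is supplied, S(x,0) is *computed from the signal equation* at
(S0, R1(x,0)) rather than taken as S0 itself — S0 is an equilibrium
magnetisation scale, not a measured baseline — which also keeps the
normalisation valid when the dynamic series and the S0 map are on different
scales. Voxels with no usable S0 fall back to the mean of the first three
(pre-contrast) dynamics. The physical branch of the inversion requires both
the numerator and denominator of the log argument to be positive;
enhancement beyond the signal-equation ceiling (possible in noisy, strongly
enhancing voxels) violates that and produces a NaN sentinel, counted but
non-fatal, so isolated bad voxels never abort a volume. Spatially varying
flip angles (B1 maps) are not supported; supply an externally computed R1
map instead.

## Tracer-kinetic models and fitting

The Extended Tofts-Kety model, its Standard (vp = 0) and plasma-only
(Ktrans = 0) reductions, and their analytic Jacobians are implemented over
a shared trapezoidal convolution on the (possibly non-uniform) acquisition
grid; tissue curve and AIF must share that grid (no interpolation is
performed — resample upstream if needed). The convolution is evaluated
directly at each output time; all exponents are non-positive, so the
evaluation is stable for arbitrarily large kep. For long fine-grid forward
simulations an O(N) first-order recurrence is used instead; it is
term-by-term algebraically identical to the direct trapezoid and is checked
against an independent per-time-point `np.trapezoid` oracle in the tests.

Fits run in (Ktrans, kep, vp) space — decoupling the exponential rate from
the Ktrans prefactor conditions the problem better than (Ktrans, ve) — and
ve = Ktrans/kep is derived afterwards, with the kep = 0 case mapped to
ve = 0 (no measurable efflux ⇒ no estimable ve). The (Ktrans, ve)
parameterization and its Jacobian are retained for conditioning analysis:
at small ve the two columns become nearly collinear and the condition
number grows, which is exactly where the phantom error maps light up.

**Solver.** A classic Levenberg–Marquardt iteration (damped normal
equations with Marquardt diagonal scaling; λ×10 on rejection, λ/10 on
acceptance; defaults λ₀ = 10⁻³, tol_g = tol_x = tol_f = 10⁻⁸,
max_iter = 200) written in-package, unconstrained. Physical bounds are
enforced by post-hoc clamping (ve, vp → [0,1], Ktrans → [0,5] min⁻¹),
never inside the solver, and pre-clamp residuals are kept so users can do
their own residual filtering — no automatic residual threshold is applied.
DCE fits start from (Ktrans, kep, vp) = (0.1, 0.5, 0.01), mid-range of the
phantom grids; noise-free tests confirm insensitivity to the start. Trial
steps into unphysical territory (e.g. kep < 0 far enough to overflow the
exponential) produce a non-finite cost and are simply rejected.

**Parallelism.** Voxels are split into contiguous index blocks and
reassembled by index, so outputs are bit-for-bit identical for any worker
count — a standing regression test, not an aspiration.

**Model selection.** With several models in the bitmask, the per-voxel
winner minimises the reduced χ² = SSR/(N − p) under unit noise variance
(no per-voxel σ is estimated; that is valid for comparing models at a fixed
voxel). Ties go to the model with fewer parameters.

**Masking.** The signal enhancement ratio is the mean of the last three
dynamics over the mean of the first three (three pre-contrast acquisitions
required; zero baselines are flagged and given SER 0). The automatic mask
keeps voxels with SER strictly above the cutoff (default 2.0 — "above"
means the tie is excluded). No frame rejection is attempted for
motion-corrupted dynamics.

## Synthetic phantom

The generator emulates the QIBA digital-reference-object layout: every
combination of the printed parameter grids (Standard: Ktrans ∈ {0.01, 0.02,
0.05, 0.1, 0.2, 0.35} min⁻¹ × ve ∈ {0.01, 0.05, 0.1, 0.2, 0.5} = 30
regions; Extended: Ktrans ∈ {0, 0.01, 0.02, 0.05, 0.1, 0.2} × ve ∈ {0.1,
0.2, 0.5} × vp ∈ {0.001, 0.005, 0.01, 0.02, 0.05, 0.1} = 108 regions) as
10×10 uniform patches, with a vessel strip at the bottom carrying the AIF
through the same R1→signal chain.

Acquisition and tissue constants are configuration, chosen once as typical
rather than measured from any particular phantom: TR = 5 ms, flip = 30°,
frame spacing 0.5 s, 721 frames (6 min), tissue R10 = 1.0 s⁻¹, blood
R10 = 1/1.4 s⁻¹, S0 = 1000, relaxivity 4.5 s⁻¹ mM⁻¹, bolus arrival 30 s.
When a real QIBA DICOM stack is loaded, TR/flip/frame count come from the
headers instead.

The AIF is a parametric population curve — a gamma-variate first-pass bolus
(peak ≈ 5.6 mM) plus a gated biexponential recirculation/washout tail —
standing in for the population AIFs used in vivo without claiming any
specific published shape.

Ground-truth concentration curves are simulated on an 8× finer time grid
and sampled at the acquisition times. This matters: it gives the fitting
stage a genuine O(Δt²) discretisation mismatch, like real phantom data,
so noise-free errors are small but *structured* — they concentrate in the
ill-conditioned corners (ve = 0.01 for the Standard layout, Ktrans = 0.01
for the Extended layout) instead of collapsing to solver-tolerance dust.

**Noise.** Rician corruption adds independent real/imaginary Gaussian
components of SD σ·(pre-contrast tissue baseline) and takes the magnitude.
The baseline is the global mean of the first three frames over the tissue
block (the definition "relative to baseline" is ambiguous; global was
chosen and is configurable). The vessel strip is left noise-free by
default. Gaussian and Rician statistics agree closely above SNR ≈ 10,
which the tests verify.

**Scoring.** Noise-free runs analyse one voxel per region (all 100 are
identical — verified bit-for-bit); noisy runs keep every voxel. Extended
runs exclude the Ktrans = 0 regions (90 remain): zero transfer violates the
two-compartment assumptions and makes ve unidentifiable. RMS percent error
is the RMS of per-voxel relative errors ×100 (consistent with reporting the
maximum error as a percentage of truth); CCC uses population (1/n)
moments, with the degenerate zero-variance cases defined as 1 (equal
means) or 0. No other exclusions or outlier trimming are applied.

**What passing does not show.** The synthetic phantom shares its *layout*
with the QIBA objects, not their generator: the QIBA AIF, signal scaling
and temporal sampling differ, so synthetic noisy-run metrics are not
comparable number-for-number with results on the downloaded QIBA DICOMs,
and none of the phantoms exercise motion, B1 inhomogeneity, partial volume
or water exchange — the in-vivo failure modes. The pipeline on real data is
validated only insofar as the same code path is exercised.

## MAT contract and CLI

Inputs: `t` (s), `Cp` (mM), `DCEdata` (time-first), and either `R10`/`S0`
maps or `T1data`/`T1flip` (exactly one of the two); optional `mask`,
`models` (bitmask 1=plasma-only, 2=Standard, 4=Extended; default 2),
`relaxivity` (4.5), `TR` (5 ms), `DCEflip` (30°), `SERcutoff` (2.0),
`outfile` (default: input stem + `_results.mat`). Outputs: `Ktrans`, `kep`,
`ve`, `vp`, `resid`, `modelmap`, `R10`, `S0`, `SER`, `mask` on the input
spatial grid. The `dcefit` tool is a thin argparse wrapper over the library
and never prompts, so it is safe in batch scripts. DICOM export/PACS
archival is out of scope.

## Problem sizes and limitations

The shipped validation studies use the full 10×10-patch layouts: 30 voxels
(Standard) and 90 (Extended) noise-free, 3000 voxels for the noisy Standard
study; each noise-free study runs in seconds and the noisy study in about a
minute on one CPU. Known limitations: shared time grid required for AIF and
tissue; no bounded optimisation (clamping only); no spatially regularised
fitting; no additional kinetic models (two-compartment exchange, Patlak,
reference region) — the model/solver separation makes adding them
straightforward.
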