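# Methods

This note documents the models implemented in `t1epi`, the parameter choices
behind the shipped defaults, what the synthetic phantom does and does not
emulate, and the numerical decisions a user extending the package should
know about.

## The Bloch model of the two-inversion loop

One inversion-recovery (IR) cycle of duration `TR_IR` contains:

1. a non-selective inversion at t = 0, modelled as `Mz → −ε·Mz` with
   inversion efficiency ε (`eps_inv`, default 1.0, exposed in config because
   adiabatic pulses in practice fall a few percent short of full inversion);
2. two blocks of `n_exc = ceil(N_z/Rz)` excitations spaced `TR_exc` apart,
   one block per inversion time, each pulse scaling `Mz → Mz·cos(α_i·b1)`;
3. free relaxation `Mz → Mz·E + M0(1−E)`, `E = exp(−Δt/T1)`, between all
   events and until the cycle repeats.

Each block is positioned so that its k-space-centre excitation (index
`n_exc//2` under linear kz ordering) falls exactly on the nominal TI — image
contrast is decided at the centre of k-space, so TI is defined to that pulse
rather than to the block start. The per-TI signal is the pre-pulse Mz at
that excitation times `sin(α_i·b1)`, kept signed: before the zero crossing
of the recovery the signal is negative, and the phase-sensitive
reconstruction preserves that sign.

Because every event is affine in Mz, the one-cycle map is
`Mz_end = a·Mz_start + b` with `|a| < 1` for any T1 > 0, and the periodic
steady state is the exact fixed point `b/(1−a)`. No iteration or tolerance
enters the production path; a 500-cycle event-by-event iteration is kept in
the test suite as an independent oracle and agrees to better than 1e−10
relative.

`TR_exc` defaults to the largest spacing that fits both blocks around their
TIs without overlap, scaled by a 0.9 packing margin (≈ 23 ms for the default
protocol). This is a scheduling convention, not physics: the loop order
constrains but does not determine the spacing, and the value is overridable
in config.

**Not modelled:** T2*/magnetization-transfer decay during the echo train,
RF pulse shapes and slice profiles (pulses are non-selective), and
B0-dependent excitation. These limit fidelity to real acquisitions but do
not affect the self-consistency of the simulation/estimation loop.

## Timing accounting

- `TA = n_combo · seg · TR_IR`: one IR cycle acquires one segment per TI
  block, a volume needs `seg` cycles, and the whole acquisition repeats over
  the `n_combo = 4` polarity combinations. For the default protocol this is
  4 × 14 × 3.8 s = 212.8 s.
- `ETL = ceil(N_y·pF/seg)` ky lines per shot (13 for 232 lines at partial
  Fourier 6/8 and segmentation 14). Published parameter sheets for
  comparable protocols sometimes quote one echo more than this count; a
  navigator or reference echo at the train start is the usual reason. The
  timing report prints its formulas so the convention is visible.
- `TE` counts the echoes from the train start to the ky = 0 echo
  (`ceil((pF−0.5)·N_y/seg)`, asymmetric coverage under partial Fourier)
  times the *within-train* echo spacing. Interleaved ky segmentation divides
  the within-train spacing by `seg` to give the effective spacing `esp_eff`
  that governs distortion, so the within-train spacing is `esp_eff·seg`.
  The default `esp_eff = 0.10 ms` corresponds to a 1.4 ms within-train
  spacing at segmentation 14 — a realistic value for a 232-point readout —
  and gives TE = 7.0 ms.

## Flip-angle design

Noise is modelled as independent, equal-variance additive Gaussian on the
two signals (the simplest assumption consistent with complex averaging of
thermal noise; configurable). The UNI statistic's standard deviation comes
from the first-order delta method with analytic partials; the design
objective divides the GM–WM UNI contrast by the root-sum-square noise of
both tissues.

Two caveats are documented deliberately:

- Where `|S1| = |S2|` the UNI statistic sits at its extremum ±½ and its
  first derivatives vanish, so the first-order noise estimate goes to zero
  and the CNR surface develops narrow artificial ridges. The optimizer can
  land on such a ridge; the log warns when the optimum falls at or below
  10° because second-order noise terms (not modelled) dominate there.
- Whether segmentation contrast is better served by the UNI statistic or by
  a raw signal difference is a modelling choice; both are implemented
  (`statistic="uni"|"difference"`), UNI being the default for consistency
  with the reconstruction.

The optimizer returns the global grid maximum (ties broken toward the
smaller α₁+α₂) refined by the vertex of the 1-D parabola through each
3-point neighbourhood, clipped to one grid step.

### Default protocol flip angles

TI₁ = 800 ms, TI₂ = 2700 ms and TR_IR = 3.8 s are stated assumptions of the
default protocol. The flip angles (α₁ = 12°, α₂ = 4°) were chosen by the
package's own design analysis at the default 7 T tissue parameters: the
UNI-CNR surface has its high ridge at moderate α₁ and small α₂, and the
voxelwise T1 conditioning σ_T1(α₁,α₂) — the statistic's noise divided by
its T1 sensitivity — has its optimum in the same region (σ_T1 ≈ 4% per
voxel at image SNR 20, versus ≈ 18% at e.g. 25°/14°). A small α₂ keeps the
second block from saturating the recovery, so S₂ acts as a long-TI
reference while S₁ carries the T1 sensitivity.

## Lookup-table T1 quantification

The signed ratio S₁/S₂ is tabulated on a T1 grid (default 300–5000 ms,
10 ms step) for each of 41 B1 scales (0.6–1.4, step 0.02). Each curve is
restricted to its longest strictly monotone branch (the ratio has a pole at
the S₂ zero crossing for long T1 at small effective flip angles; trimming
is logged). Inversion interpolates the statistic linearly between the two
bracketing B1 curves — quantizing B1 to 5·10⁻⁴ to bound the number of
interpolated curves — and then inverts the monotone branch by linear
interpolation. Round-trip error over T1 ∈ [600, 3000] ms and B1 ∈ [0.7, 1.3]
is below one T1 grid step.

Out-of-branch statistics are clamped to the branch end and flagged
(`clamped-low`/`clamped-high`); zero-signal voxels are flagged `no-signal`
and carry NaN rather than a number. Complex inputs are combined
phase-sensitively (`Re(S1·conj(S2))/|S2|²`), preserving the recovery sign; a
magnitude-only mode exists for magnitude data, with the reduced valid range
that loss of sign implies.

Histogram modes use a Gaussian KDE with Scott's rule evaluated on a 5 ms
grid; near-ties within float noise of the maximum break toward lower T1.
At low SNR the voxelwise T1 distribution is right-skewed (the statistic's
noise maps through a convex inverse), so the distribution's mode sits
slightly below the generating T1; at the default protocol's conditioning
this shift is well under 1% at SNR 20.

## Polarity combination

Complex averaging assumes the four acquisitions share a global phase; each
image is therefore aligned to the first by the phase of their masked inner
product before the mean (coil-combined data normally satisfy this, but a
residual global phase would otherwise destroy signal). Averaging in
acquisition space is the default and is exact when distortions are matched
or negligible; `unwarp-first` removes each phase-polarity's distortion with
a supplied field map before averaging. UNI is computed from the averaged
complex pair rather than averaging four UNIs — consistent with
complex-valued averaging upstream; the per-image-UNI alternative can be
built from `uni_image` directly if wanted for comparison.

## Distortion model and field estimation

Displacement is the standard 1-D phase-encode shift approximation:
`s = d·ΔB0·esp_eff·N_pe` voxels; readout-axis distortion is not modelled
(readout-axis artifacts are represented only by the ripple model). The
forward warp inverts the monotone map `y → y + s(y)` per PE line and
applies Jacobian intensity modulation so the line integral is conserved;
interpolation is monotone cubic (PCHIP) by default with a linear option for
speed. Displacements beyond half the PE field of view raise — fold-over is
out of scope. Unwarping uses the closed-form inverse
`I(y) = A(y+s(y))·(1+ds/dy)`, which undoes the forward model up to
interpolation error (< 1% RMSE on smooth inputs at 4-voxel warps).

Field estimation from a reversed-polarity pair is a symmetric demons-style
scheme: at each image-smoothing scale (Gaussian σ = 4, 2, 1 voxels, 60
iterations each) both magnitude images are unwarped by ∓s with Jacobian
correction, and the residual drives the classic normalized optical-flow
update `Δs = −½·diff·g/(g²+diff²)`, smoothed with σ = 2 voxels (fluid
regularization) plus a light σ = 0.5 diffusion of the field. The
`g²+diff²` denominator bounds the step where gradients vanish; without it
the iteration is unstable. The symmetric construction makes the result
exactly antisymmetric under swapping the inputs. On smooth phantoms with
4-voxel peak displacement the recovered field is accurate to ≈ 0.15–0.35
voxel RMSE; uniform-intensity regions are genuinely unconstrained (aperture
problem) and are filled in by the regularization.

The corrected image of a reversed-PE pair is the mean of the two unwarped
polarities — symmetric residual errors cancel there, which is why this
combination, rather than a single unwarped image, is the standard output of
reversed-polarity pipelines.

Echo-spacing matching exploits `esp_eff = esp_within-train/seg`: the
within-train spacing is fixed by hardware, so the integer segmentation is
chosen to bring the structural displacement-per-Hz closest to the
functional target, with the residual mismatch reported and an error (listing
the nearest feasible settings) if no integer is within tolerance.

## The phantom: what it emulates, what it does not

The phantom is a concentric geometry — WM core, GM ribbon, CSF rim — with an
optional sinusoidal angular folding, per-tissue T1/M0 (GM 1800 ms / 0.80,
WM 1200 ms / 0.70, CSF 4000 ms / 1.00 in arbitrary M0 units; plausible 7 T
simulation values, not measurements), a band-limited Gaussian random B0
field (default 20 Hz peak; smooth across the support edge, since real
susceptibility fields do not step to zero at the brain boundary), and a
smooth B1 bowl of mean 1 (default ±15%). Acquisition simulation evaluates
the Bloch signals voxelwise, applies a multiplicative sinusoidal ripple
along the readout axis whose sign flips with read polarity, warps along PE
with the phantom's B0, and adds complex Gaussian noise. Everything is
deterministic under a fixed seed.

The ripple is a synthetic stand-in: real trajectory-imperfection artifacts
arise at ramp-sampling corners of k-space and have richer structure; an
odd-in-read-polarity multiplicative low-frequency modulation is the
simplest model with the property that dual-polarity averaging cancels it.
There is no k-space-level simulation — no partial-Fourier blurring, no T2*
decay across the train, no coil sensitivities, no motion, no physiological
noise. Passing tests therefore demonstrate the self-consistency and
numerical correctness of the model/estimation loop, not performance on real
scanner data.

Test and validation problem sizes are 32³–48³ phantoms, 20 noise
realizations for recovery statistics and 100 for noise-averaging statistics
— large enough that the measured biases (≪ 1%) are far from the thresholds
they are compared against.

## Noise convention

"SNR 20 at TI2" means the per-acquisition noise σ (per complex channel)
equals the mean |S₂| over the phantom support divided by 20. Four-way
complex averaging then doubles the effective SNR of the combined pair.

## Known limitations

- The delta-method CNR is first-order only and degenerates on the
  |S₁|=|S₂| ridge (see above).
- The B1 handling is a first-order flip-angle scaling; it does not model
  B1-dependent inversion efficiency.
- The field estimator assumes the two polarity images differ only by the
  displacement field; intensity differences from other sources (e.g.,
  polarity-dependent ghosting) would bias it.
- Magnitude-only T1 mapping loses the recovery sign and with it the short-T1
  half of the lookup range.
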