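# Methods

## Signal model and timing

One nonselective inversion is followed by a continuous FLASH readout that
cycles through the slices spoke by spoke; slice `s` receives global pulses
`j` with `j mod n_sl = s` at pulse times `j·TR`. Each slice therefore sees
an effective repetition time `n_sl·TR`, which is what enters both the
apparent relaxation rate `R1* = 1/T1 − ln(cos α)/(n_sl·TR)` and the exact
T1 correction. The model assumes perfect inversion (`M(0) = −M0`), ideal
spoiling, a pure longitudinal signal (no T2*/off-resonance decay), and no
delay between inversion and the first pulse; the sampling instant of a
spoke is its pulse time plus TE. `Mss` and `M0` are complex (they share the
receive phase); `R1*` is real and constrained nonnegative. The discrete
pulse-to-pulse Bloch recursion `M⁺ = M·cosα·E1 + M0(1−E1)` is implemented
as an independent oracle; it coincides with the exponential model exactly
at multiples of `n_sl·TR` because `cosα·E1 = exp(−n_sl·TR·R1*)`, and the
test suite asserts this identity at machine precision.

The T1 conversion uses the real part of `Mss/M0` after phase alignment to
`M0` (`Re(Mss·conj(M0))/|M0|²`). The magnitude-vs-real-part choice is not
fixed by the model; with a common receive phase both coincide, and the
real-part form degrades more gracefully when noise rotates the two maps
slightly against each other. Pixels where the logarithm leaves its domain,
or whose `|M0|` falls below 5% of the 99th percentile (background), are
masked rather than reported.

## Trajectory and binning

Angles advance per slice by the small golden angle `ψ_N = 180°/(τ+N−1)`
(τ the golden ratio), each slice running its own golden-angle sequence so
every slice's k-space is covered homogeneously. The index N is a protocol
input (8/4/2 for the 1-/3-/5–7-slice head protocols); it is not derivable
from a stated rule, so the registry carries the published values. For
reconstruction, `m` consecutive spokes of a slice share one model
evaluation time `t_k` (the mean of their pulse times); `m` is chosen per
protocol so the bin spans at most 80 ms. A trailing group of fewer than
`m` spokes is dropped, keeping all bins the same duration. During
*simulation* the signal is evaluated at the exact per-spoke echo time, so
the bin-center approximation of the reconstruction is honestly stressed
rather than assumed.

## Analytical phantom (what it emulates, what it does not)

The digital phantom is a background disk (T1 = 2000 ms) with three
circular inserts (300/800/1500 ms), all order-one proton density. Its
k-space is evaluated in closed form from the elliptical "jinc" transform;
insert regions are made single-T1 by adding, for every insert, a negative
copy of the background ellipse restricted to the same support. Coil
sensitivities are smooth inverse-distance loop profiles of four coils at
90° spacing just outside the FOV, least-squares approximated by nine
complex plane waves on a 1/3-cycle/FOV lattice (fit error ≈1.4% RMS); coil
modulation is then a set of analytic frequency shifts of the ellipse
transform. Simulated data therefore never pass through the discrete
gridding used by the reconstruction — the inverse-crime safeguard at the
core of the simulator. Complex Gaussian noise (SD 0.1, i.e. sd/√2 per real
component) is added on a documented scale: data are normalized so the
root-sum-of-squares steady-state DC response of the coil array equals the
matrix size. The phantom does not emulate off-resonance, motion, slice
cross-talk, B1 inhomogeneity or imperfect inversion; passing tests
demonstrate correctness of the estimation chain under the stated model,
not robustness to those effects.

## Encoding operators

Non-uniform sampling is handled by convolution gridding with a
Kaiser-Bessel kernel (width 4, 2× oversampling, Beatty shape parameter)
and *no density compensation* anywhere; the iterative solver weights
samples implicitly. The centered DFT is folded into an unshifted FFT with
a per-frequency sign absorbed into the sparse interpolation matrix, and
deapodization uses the kernel's continuous Fourier transform. The adjoint
is the exact conjugate transpose, so the operator pair passes dot-product
tests at machine precision, and the forward map agrees with a brute-force
DFT to ~7·10⁻⁴ relative. Coil compression is an eigendecomposition of the
coil covariance per slice (virtual channels); with the phantom's four
coils it is lossless. Gradient-delay handling is out of scope (simulated
trajectories are delay-free).

## Solver

Unknowns per slice are the three parameter maps plus coil maps stored in
Sobolev-preconditioned k-space form (`(1 + 220·|k|²)^16` weighting, k in
cycles/pixel over [−0.5, 0.5)), so a plain L2 penalty on the stored coil
variable equals the Sobolev norm; the constants are configuration fields.
IRGNM runs 10 Gauss–Newton steps with `α_n = max(3^{1−n}, 0.0015)` and
`β_n = 3^{1−n}` (no floor on β, in line with the protocol description).
Initialization is `Mss = M0 = 1`, `R1* = 1.5 s⁻¹`, coils zero — the first
step then behaves like a linear coil-calibration problem. Data are scaled
to a fixed norm (100) before solving; the returned `Mss`/`M0` are rescaled
back so the estimate is equivariant under scaling of the input data, while
T1 is scale-free by construction.

Each linearized subproblem (squared data term, β-L2 on coils, α joint
wavelet-L1 on the maps, `R1* ≥ 0`) is solved by FISTA with Nesterov
momentum and gradient-based adaptive restart. Two numerical choices matter
here:

- **Block step sizes.** The parameter and coil blocks have curvatures that
  differ by orders of magnitude (the product `M·c` is fixed by the data,
  the split between the factors is not). A single global Lipschitz
  constant stalls the parameter maps, so FISTA runs in a block-diagonal
  metric with per-block largest eigenvalues of `JᴴJ` estimated by
  warm-started power iteration; twice the block diagonal majorizes the
  full normal operator, so convergence guarantees are retained. When a
  block has zero curvature (coils at the first step), it is frozen for
  that subproblem.
- **Inner budget.** The inner iteration count ramps from 22 to 110 per
  Gauss–Newton step (doubling every other step): early linearizations are
  crude and not worth solving accurately, late ones (small α) dominate the
  final bias. The defaults are chosen so a desk-scale slice (128², ~350
  spokes) reconstructs in about two minutes on one CPU core; the
  acceptance script and the default test run use these problem sizes.

The joint L1 penalty soft-thresholds each wavelet coefficient triple
(Daubechies-4, periodized, up to 4 levels) on its joint magnitude across
the three maps; the coarsest approximation band is not thresholded, since
it carries the mean signal level rather than the edges the penalty is
meant to promote. The quadratic (L2) variant of the subproblem solver is
kept purely as a verification path and is checked against an independent
LSQR solution of the augmented least-squares system. Divergence (residual
growth over three consecutive Gauss–Newton steps) aborts with diagnostics.

Slices are reconstructed independently: the interleave couples only the
timing, not the data. `forward_model` at the rasterized ground truth
leaves a relative residual of a few percent — the honest discretization
floor of rasterization plus temporal binning — and the solver converges to
that floor on noiseless data.

## Desk scale and accuracy

The validation study runs at scale 1/3 by default: matrix 384→128 and
spokes reduced proportionally (undersampling ratio preserved; timing, flip
angles and bin sizes untouched). Note that proportional spoke reduction
also shortens the sampled inversion-recovery window (≈1.35 s instead of
≈4 s), which is hardest on the long-T1 background compartment. At this
scale, noiseless single-slice recovery is within 1% for all compartments,
and the noisy (SD 0.1) 1-, 3- and 7-slice studies recover the compartment
means within ~2%, with ROI standard deviations growing with slice count as
expected from the increased undersampling. Full-scale runs are supported
through the same API and configuration but take hours per slice on CPU.

## Known limitations

- CPU-only; no accelerated or multi-device variants.
- The binning approximation and rasterized-truth comparisons leave a
  percent-level discretization floor at desk scale; it shrinks with
  matrix size and spoke count.
- The phantom geometry (compartment positions/radii) is a documented
  package default; ROI statistics are insensitive to it because masks are
  derived from the same definition and eroded by 2 pixels.
- Real scanner data ingestion (vendor raw formats, gradient-delay
  estimation, RF-spoiling imperfections) is out of scope.
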