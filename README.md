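# t1shot — single-shot multislice T1 mapping by model-based reconstruction

`t1shot` estimates quantitative T1 maps of several slices at once from a
*single* inversion-recovery (IR) radial FLASH experiment of a few seconds.
Instead of reconstructing a series of images and fitting them afterwards,
the package solves the nonlinear inverse problem directly: the Look-Locker
parameter maps and the coil sensitivity profiles of each slice are
estimated straight from the highly undersampled multi-coil radial k-space
data. It is aimed at researchers in quantitative MRI who want a
self-contained, CPU-only reference implementation of this class of
reconstruction, complete with an analytical digital phantom for honest
(inverse-crime-free) validation.

## The model

After a nonselective inversion pulse, radial spokes are acquired
continuously, cycling through the `n_sl` slices (spoke-interleaved), so
each slice is excited every `n_sl·TR`. The longitudinal magnetization of a
slice follows the three-parameter model

    M(t) = Mss − (Mss + M0) · exp(−t · R1*),

relaxing from perfect inversion `M(0) = −M0` toward the driven steady
state `Mss` at the apparent rate

    R1* = 1/T1 − ln(cos α) / (n_sl · TR).

The signal of coil `j` at spoke time `t` and k-space position `k(t)` is

    y_j(t) = ∫ M_t(r) c_j(r) e^(−i r·k(t)) dr.

All unknowns `x = (Mss, M0, R1*, c_1..c_N)` are estimated by solving

    min_{x, R1* ≥ 0}  ‖F(x) − y‖² + α R(x_p) + β Q(x_c)

with `R` a joint (group) wavelet-L1 penalty coupling the three parameter
maps and `Q` a Sobolev norm keeping the coil maps smooth. The problem is
solved by the iteratively regularized Gauss–Newton method (IRGNM); each
linearized subproblem is solved by FISTA, with `α, β` starting at 1 and
reduced by 3 per Gauss–Newton step (`α` floored at 0.0015 for the head
protocols). T1 is then obtained pixelwise from the exact correction

    T1 = −n_sl·TR / ln(1 − (Mss/M0)(1 − e^(−n_sl·TR·R1*))).

## Worked example

Simulate the single-slice head protocol at desk scale (128×128 matrix, 354
spokes) on the analytical four-compartment T1 phantom, reconstruct, and
summarize the compartment ROIs:

```python
from t1shot import InversionRecoveryModel, get_protocol
from t1shot.experiments import phantom_rois, simulate_protocol

seq = get_protocol("head1", scale=1/3)           # published protocol, desk scale
kdata = simulate_protocol(seq, seed=1, noise_sd=0.1)
fit = InversionRecoveryModel(kdata).fit()
print(fit.roi_stats(phantom_rois(seq), 0))
```

Output (about 2 minutes on one CPU core):

```
          roi  n_pixels      mean_ms      sd_ms
0        roi1       295   302.256901   8.782289
1        roi2       297   799.391013  14.675571
2        roi3       297  1500.232671  21.195304
3  background      6008  2029.980922  99.080955
```

The four ROIs are the eroded compartment masks of the phantom (true T1 =
300, 800, 1500 and 2000 ms): the reconstructed means recover the ground
truth to about one percent at this scale, and the standard deviations
reflect the remaining noise and undersampling artefacts. The same pipeline
is exposed on the command line:

```
t1shot simulate --protocol head3 --scale 0.333 --seed 1 --out k.h5
t1shot reconstruct --in k.h5 --out maps.h5
t1shot study --scale 0.333 --seeds 1,2,3 --out study.csv
```

## Package layout

- `t1shot.signal_model` — Look-Locker model, exact T1 conversion, Bloch
  pulse-train oracle
- `t1shot.trajectory` — spoke-interleaved small-golden-angle schedules and
  temporal binning
- `t1shot.phantom` — analytical ellipse phantom, plane-wave coil models,
  noise
- `t1shot.encoding` — Kaiser-Bessel gridding (no density compensation) and
  coil compression
- `t1shot.recon` — IRGNM/FISTA solver; `InversionRecoveryModel.fit()` →
  `T1FitResults`
- `t1shot.postprocess` — T1 maps, ROI tables, difference maps
- `t1shot.experiments` — protocol registry and scripted phantom studies

See `docs/methods.md` for the numerical details and design decisions.
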