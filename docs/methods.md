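# Methods

This note records the model equations as implemented, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic fixtures do and do not establish.

## Oscillator dynamics

A bank of N Hopf oscillators evolves in polar coordinates (amplitude `r_i ≥
0`, unwrapped phase `θ_i`, intrinsic frequency `ω_i > 0`):

```
ṙ_i = (μ + β r_i²) r_i + C_i^r + ε e(t) cos θ_i
θ̇_i = ω_i + C_i^θ − ε e(t) sin θ_i / max(r_i, 1e-6)
```

In the supercritical regime (`μ > 0`, `β < 0`) the uncoupled attractor
amplitude is `√(−μ/β)`; the defaults `μ = 1`, `β = −20` give ≈ 0.224.

**Phases are stored unwrapped.** The power-coupling argument depends on
`θ/ω` ratios and `ω_i/ω_j` exponents whose continuity breaks under mod-2π
reduction; all formulas below assume the unwrapped convention.

Coupling terms `C^r, C^θ` per scheme (`g_ij = ξw·A_ij` is the effective
gain, zero off the connectivity mask; the mask diagonal is always off):

- **power** (the default):
  `C_i^r = Σ_j g_ij r_j^{ω_i/ω_j} cos Φ_ij`,
  `C_i^θ = Σ_j g_ij r_j^{ω_i/ω_j} sin Φ_ij / r_i`,
  with `Φ_ij = ω_i(θ_j/ω_j − θ_i/ω_i + Ø_ij/(ω_i ω_j))`. The fixed point of
  the pair dynamics is a constant normalized phase difference `θ_i/ω_i −
  θ_j/ω_j`, for *any* frequency ratio — the property that distinguishes
  power coupling from classical diffusive coupling, whose locking region
  (Arnold tongue) shrinks with |ω_i − ω_j|.
- **complex**: `A_ij e^{iØ_ij} z_j`, no exponent scaling.
- **linear_all / linear_nn**: real diffusive `k(x_j − x_i)` on `x = Re z`,
  applied as a real-axis forcing; `linear_nn` masks to adjacent pairs.

The two printed source forms of the coupling phase disagree by a factor
`ω_j²`; we integrate the polar form exactly as written above. Under the
Hebbian rule (below) the learned angle therefore does not exactly
reproduce the phase-reinforcing offset; at the reference gain
(`ξw·A ≈ 5·10⁻⁵`) the lateral term is a weak perturbation either way.

**Numerical guards.** The `1/r_i` factors are clamped at `r = 1e-6` so
transient near-zero amplitudes never fault; amplitudes are floored at 0
after each step; intrinsic frequencies are floored at `2π·0.05 rad/s`
everywhere (initialization, adaptation). Any non-finite state raises a
typed divergence error naming the offending oscillator or epoch.

**Integrators.** Fixed-step RK4 (dt = 2 ms by default) for autonomous
simulation and generation; forward Euler locked to the sampling grid
(dt = 1/fs) during training, because the teaching signal and the update
rules are defined per sample. Both are selectable.

## Stage-1 training

Per sample, in this order: compute `s(t) = Σ α_i cos θ_i` and
`e(t) = D(t) − s(t)` from the pre-step state; advance `(r, θ)` one Euler
step with the coupled, error-driven dynamics; then apply, with that same
`e(t)` and the post-step phases,

```
ω_j ← clip(ω_j − η_ω e sin θ_j,  2π·0.05,  2π(f_max + 5))
α_j ← α_j + η_α e cos θ_j
W′  ← W′ + (dt/τ_w)(−W′ + z_i (z_j*)^{ω_i/ω_j})        (masked)
```

Defaults: `η_ω = η_α = 1e-4`, `α_0 = 0.2`, `ξw = 1e-3`, frequencies
initialized uniformly over 0–10 Hz, 30 epochs over a 10 s window at
fs = 500 Hz, `ε = 1` (the error-drive gain is not fixed by the source
equations; it is a config knob). The rates are *per-sample* rates at the
reference 500 Hz sampling — scaling them by dt instead would make
adaptation ~500× slower and frequency recovery impossible within 30
epochs; this was verified by simulation before freezing the convention.
`τ_w` (Hebbian time constant) is likewise unstated upstream; default 1 s,
acting only as a low-pass on the lateral weights.

The frequency rule is the classic adaptive-frequency-oscillator mechanism:
an oscillator within its entrainment basin of a spectral component locks
to it and its `ω` converges to the component frequency. The basin width
scales with the component amplitude (≈ ε·a/r on the phase axis, i.e.
roughly ±0.3–0.7 Hz for unit-amplitude tones at the default settings);
oscillators outside every basin simply idle and end up with near-zero
readout weight. Multichannel teachers drive the shared bank with the mean
error across channels (the single-teacher equations generalize this way;
channel-specific structure is carried by the stage-2 readout).

## Stage-2 readouts

The phase trajectory used for readout fitting is recorded during one
additional *driven* pass with all learned parameters frozen — the
reservoir-computing convention. (Recording autonomously would let the
residual `O(10⁻²)` Hz frequency errors accumulate ~π of phase drift over a
10 s window and cap reconstruction accuracy at tens of percent.) The final
state of this pass is the boundary state from which generation starts, so
reconstruction and continuation are seamless by construction.

- **Complex linear**: `Yp_i = Σ_j K_ij cos(θ_j + ξ_ij)`; full-batch descent
  `K += η_K Σ_t e cos(θ+ξ)`, `ξ −= η_ξ K Σ_t e sin(θ+ξ)` (the printed
  update rules are used with the descent sign). Defaults `η_K = 3e-5`,
  `η_ξ = 1e-6`, 5000 epochs. Negative magnitudes are folded into the
  angles (`K ← |K|`, `ξ ← ξ+π`) so `K ≥ 0` is an invariant of the type.
- **Hidden layer**: `h = tanh(Re(W_in e^{iθ}) + b_h)`,
  `Yp = act(W_out h + b_o)·scale`, with complex `W_in` (a pure-real
  variant, first layer acting on `cos θ` only, is a config switch), tanh or
  identity output, and per-channel `scale = max|target|/0.9` so tanh
  targets stay inside its range. Trained by full-batch gradient descent on
  mean squared error with classical momentum (0.9) at `η_h = η_o = 1e-3`
  by default; a full-batch Adam option exists for when plain GD's late
  plateau (~1e-4 relative MSE) matters, e.g. exact representation-recovery
  checks. Amplitudes `r` are *not* fed to either readout: on the attractor
  they are constant and absorbed into the weight magnitudes.
- **Divergence guard** (both trainers): training aborts when the loss
  exceeds 100× the best loss seen for 10 consecutive epochs, or goes
  non-finite. A literal "10 consecutive increases" rule false-alarms on
  benign momentum oscillations.

Why the hidden layer helps: tanh applied to a sum of sinusoids emits
inter-modulation products `Σ n_k ω_k` (odd total order), so the output
layer can draw on a spectrum far richer than the N oscillator lines. On
the odd-harmonic fixture (harmonics 1–7 of 2 Hz, oscillators only at 2, 6,
10 Hz) the hidden readout reaches ~0.27× the linear readout's RMSE at the
default demo settings — the unreachable 14 Hz line is synthesized as a
third-order product.

## Generation

`run_free` integrates the trained autonomous system (`ε = 0`, Hebbian
learning frozen) with RK4 at dt = 1/fs from the boundary state and applies
the readout each sample; the first emitted sample is the readout of the
boundary state itself (no reset, no randomness). Save → load → generate is
bit-exact: archives are `.npz` with a JSON header, format version, and a
SHA-256 checksum over all arrays.

## Spatial geometry

Spherical shell: oscillator positions are uniform in shell *volume*
(isotropic directions × inverse-CDF radii `(r₁³ + u(r₂³−r₁³))^{1/3}`),
seeded; defaults 1000 oscillators in 70–75 mm under electrodes at 85 mm.
Rectangular grid: one oscillator per lattice unit, 18×18×3 at 10 mm
spacing by default, electrodes coplanar 12 mm above the top layer.
Electrode assignment uses strict `D < ξ1` (default 32 mm) and lateral
connectivity strict `D < ξ2` (default 10 mm; newly connected pairs start
at `A = 0.001`), so long-range lateral connections cannot occur. Electrodes
that end up with no oscillators produce a warning and a constant-zero
readout stub, not an error — unequal assignment is an expected property of
curved geometry. Montages are plain-text tables `label, theta_deg,
phi_deg, r_mm` with `x = r cosφ cosθ, y = r cosφ sinθ, z = r sinφ`
(azimuth/elevation in degrees; the upstream coordinate convention is not
stated, so the built-in 10–20 montages are constructed in this convention
and any user file in the same dialect can replace them).

## Metrics

- **MAE**: `mean_t |Yp − Yd|`, reported in percent of a per-channel scale
  (default: the reference channel's max-abs; zero-reference channels fall
  back to raw units). The raw (unnormalized) value is also available.
- **Spectral error**: `100·Σ_band |Pp − Pd| / Σ_band Pd` over 0.1–20 Hz,
  from Welch spectra (Hamming window, 1 s, 50% overlap → 1 Hz resolution).
  The normalization makes "prediction has twice the power" exactly 100%.
  The upstream formula is unstated; this normalized L1 form is the module
  contract. Channels with spectral error > 50% are flagged `poor_fit`.
- **Hurst**: rescaled-range analysis over dyadic windows (16 … n/4) with
  the Anis–Lloyd small-sample correction (`H = 0.5 + slope of log(R/S) −
  log E[R/S]`); without the correction finite-sample R/S overestimates H by
  ~0.05–0.1 at these lengths.
- **Higuchi fractal dimension**: standard curve-length slope, `kmax = 10`,
  clipped to [1, 2.1]; constant signals return 1.

## Synthetic fixtures — what a green test establishes

The generators produce exactly the structure the model assumes: stationary
band-limited (0.1–20 Hz) oscillatory content, optionally on a 1/f
background, with known ground truth stored in signal metadata. Fixture
tones default to unit amplitude (teachers are DC-free; they are *not*
max-abs rescaled, which would shrink the entrainment basins below what
0.1 Hz frequency recovery requires at the reference rates). The fixtures
are deterministic functions of their seed.

They do **not** emulate real sleep EEG's nonstationarity (stage
transitions, spindles, K-complexes), measurement noise structure, volume
conduction, or channel count; a green suite establishes that the training
and generation machinery behaves as specified on signals inside the
model's assumptions, not that clinical-grade EEG forecasts are achieved.

## Known limitations

- Frequency recovery requires an oscillator initialized within the
  component's entrainment basin; with 20 oscillators over 0–10 Hz a rare
  initialization leaves a tone uncovered (~1 seed in 10 at the default
  settings misses the 0.1 Hz tolerance on one tone).
- With plain complex coupling at the reference gain the normalized phase
  difference of a detuned pair is *also* nearly constant (it neither locks
  nor drifts); the advantage of power coupling is that the relationship is
  an attractor, which a variance-only statistic does not separate.
- The per-sample learning rules make training behaviour mildly dependent
  on the sampling rate; rates are calibrated for fs = 500 Hz.
- Lateral Hebbian weights at the reference `ξw` are a weak perturbation;
  their main role is structural (geometry-masked connectivity), consistent
  with the upstream sensitivity finding that increasing `ξw` degrades fit.
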