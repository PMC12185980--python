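# Methods

`v1ssn` implements a spatially extended stabilized supralinear network (SSN)
model of layer 2/3 of primary visual cortex, together with the measurement
protocols used to characterize center–surround interactions in it.  This
note records the model, its numerical treatment, and the design choices made
where more than one reading was defensible.

## Model

### Geometry and orientation map

The cortex is a 75×75 periodic lattice with one excitatory (E) and one
inhibitory (I) cell per node (5,625 of each).  The lattice spans 16°×16° of
visual space; with a cortical magnification factor of 0.5 mm/deg each grid
interval is 0.213° and 107 µm.  Distances between cells wrap on the torus.

The orientation preference map superposes `n = 30` complex plane waves with
wavenumber `k = 8` cycles per grid side, random signs `l_j ∈ {±1}` and random
phases `φ_j ∈ [0, 2π)`:

    z(x) = Σ_j exp(i (l_j k_j·x + φ_j)),   k_j ∝ (cos(jπ/n), sin(jπ/n)),

with preferred orientation `arg(z)/2 ∈ [0°, 180°)`.  The map itself is not
periodic (there is an orientation discontinuity at the borders) while
positions and connections do wrap; measurement protocols therefore sample
cells from the interior region only (grid indices 21–59 of 1–75 per axis).
The signs and phases are drawn uniformly — the construction only specifies
"random" — in a fixed documented order (phases first, then signs) so a seed
reproduces a map bit-identically.  Radial autocorrelation of the orientation
similarity exp(2iθ) decorrelates within ~4 grid intervals and recurs at the
map period 75/8 ≈ 9.4 intervals (~1 mm of cortex).

### Connectivity

The weight from a presynaptic cell of type Y at b onto a postsynaptic cell of
type X at a factorizes into strength, distance and orientation terms:

    W_XY[a,b] = J_XY · p_XY(|x_a − x_b|) · q_XY(|θ_a − θ_b|).

E projections have a flat plateau out to `L_o = 3` grid intervals and a
Gaussian tail beyond it, anchored at the plateau edge so the profile is
continuous: `p_XE(x) = exp(−(x − L_o)²/2σ²)` for `x > L_o` with σ_EE = 3 and
σ_IE = 6 intervals.  I projections are centered Gaussians with σ = 2
intervals.  The orientation factor is a Gaussian with baseline,
`q = A + B exp(−Δθ²/2σ_ori²)` with `A + B = 1`: broad for all short-range and
inhibitory connections (A = 0.2, B = 0.8, σ_ori = 55°), narrow for long-range
excitatory connections (A = 0.14, B = 0.86, σ_ori = 25°).  Strengths:
J_EI = 0.0528, J_II = 0.0288; E projections J_EE = 0.072 / J_IE = 0.06 at
short range and 0.036 at long range (the spiking backend replaces the J's
with conductances g_EI = 3.3, g_II = 2, g_EE = 1.8/0.7, g_IE = 1.76/0.65 nS
through the same kernels).  Connectivity is fully deterministic given the
map.

Two conventions are not pinned down by the connection rule alone and were
fixed by matching the reported regime diagnostics Ω_E = W̄_II − W̄_EI ≈ −0.49
and Ω_I = W̄_IE − W̄_EE ≈ 3.59 (W̄ = mean total incoming weight):

* **Short/long boundary.** The short-range (J, A, B, σ_ori) values apply
  strictly below L_o; at exactly L_o the long-range values apply with p = 1.
* **Autapses.** Same-site connections are included for every class,
  including E→E and I→I self-connections (toggleable via
  `ConnectivityParams.include_autapses`).

With these choices the default build gives Ω_E ≈ −0.51 and Ω_I ≈ 3.58,
stable across map seeds, and the rate-model suppression statistics land on
the reported values (see below); the alternative readings miss one or both.
Ω_E < 0 places the network in the SSN regime in which excitatory responses
saturate with increasing drive; Ω values are computed from raw weights
without the rate-model gain K.

Sparse weight blocks drop pairs whose spatial factor falls below 1e-4
(≈4.3σ into the tail); a dense mode keeps every pair for oracle testing on
small grids.

### Stimulus → external input

Stimuli have three features: contrast, orientation and size.  A square
grating of contrast C, orientation θ_s, width ℓ centered at x_s drives a
cell at x_o with preferred orientation θ_o by

    Σ(x_o) = f(C) · h_ℓ(x_s − x_o) · g(|θ_s − θ_o|),

where f is a Naka–Rushton function `f(C) = f_max C^3.5/(C50^3.5 + C^3.5)`
(f_max = 50, C50 = 11; f(16.4) ≈ 80 %, f(50) ≈ 99.5 % of maximum), h is the
square aperture blurred by a Gaussian of σ_in = 0.09° (a separable erf
product), and `g = exp(−Δθ²/2σ_f²)` with σ_f = 20°.  Annuli are differences
of two concentric squares (exact by linearity of the blur); plaids and
center+surround composites sum their components linearly, each component at
its stated contrast — any cross-orientation interaction must emerge from the
network, not the input stage.  Both members of an E/I pair receive the same
external input.  Drive values below 1e-12 (the far erf tail) are flushed to
exact zero; see *Numerics*.

### Rate dynamics

    τ_E dr_E/dt = −r_E + K[I_ext + W_EE r_E − W_EI r_I]₊^n
    τ_I dr_I/dt = −r_I + K[I_ext + W_IE r_E − W_II r_I]₊^n

with τ_E = 10 ms, τ_I = 6.67 ms, K = 0.01, n = 2.2 for both populations.
The exponent enters as a rectified power law r = K[I]₊^n — the supralinear
transfer function that makes effective synaptic gain grow with drive, the
core SSN mechanism.  At the operating point the model shows the SSN
signatures: the recurrent share of a driven cell's input grows from a few
percent at low contrast to ~70 % at C ≳ 13, the network input becomes
increasingly inhibition-dominated with contrast, a near surround flips from
facilitating to suppressing as center contrast grows, and at high contrast
the excitatory subnetwork alone is linearly unstable while the full
linearization is stable (inhibition-stabilized regime).

### Spiking dynamics

A conductance-based leaky integrate-and-fire network with the same
architecture: τ_m = 15 ms, reversal potentials R_L = −70, R_E = 0,
R_I = −80 mV, g_L = 10 nS, threshold −50 mV, reset −56 mV, refractory 3 ms,
synaptic decay τ_E = τ_I = 3 ms.  Synaptic conductances jump by g_XY per
presynaptic spike and decay exponentially (exact per-step decay factors).
External input is an Ornstein–Uhlenbeck conductance standing in for
N_input = 200 Poisson afferents at the stimulus rate r_ext (g_ext = 0.1 nS
per spike): mean ḡ_in = N·r_ext·τ_E·g_ext and stationary variance
σ²_gin/2 = N·r_ext·τ_E·g²_ext/2, implemented with the exact OU update so the
stationary moments hold at any step size.  Membrane noise is white with the
amplitude chosen so the stationary voltage fluctuation is σ_V = 6.85 mV;
this alone sustains spontaneous firing of ≈1.5 Hz (E) and ≈3 Hz (I).  The
noise terms are scaled to these stated stationary moments (the target
moments, not a particular typographic form, define the model).  During the
refractory period the voltage is clamped at reset and noise is not
integrated.  The OU conductance is a Gaussian approximation and may dip
below zero at low rates; it is not clipped, preserving the stated moments.

## Measurement protocols

Cells are sampled from a seeded pool of 100 interior locations; each
experiment subsamples from the pool.  Stimuli are centered on the recorded
cell's retinotopic position at its preferred orientation unless stated.

* **Size tuning** sweeps the grating width over grid-aligned values — the
  width grows by ±1 grid spacing per step (0.43°, 0.85°, … ≈ even multiples
  of the grid interval) through the summation-field range, then coarser
  grid-aligned widths to 16° — at contrasts {8, 10, 16.4} (rate) or
  {10, 100} (spiking).  Suppression index SI = (r_max − r_inf)/r_max with
  r_inf the response at the largest tested size; summation field size (SFS)
  is the argmax width (rate; flat-topped curves quantize on the tested
  lattice, so the lattice is part of the measurement) or the analytic peak
  of a difference-of-Gaussian-integrals fit
  `R(s) = k_e erf(s/√2σ_e)² − k_i erf(s/√2σ_i)²` (spiking; R² ≥ 0.6 or the
  cell is dropped).
* **Current comparison** measures excitatory and inhibitory inputs at the
  near-optimal width d_s (median over cells of the per-cell peak width) and
  at the largest width, from the stored steady states.
* **Surround tuning**: center width 1.3°, annulus 4.3°–21.6°, both at
  C = 100; center and surround orientations sweep preferred ±40° in 10°
  steps.  Modulation maps divide center+surround by center-only responses
  and subtract each row's minimum; the most-suppressive surround is the row
  argmin (ties toward the center orientation).
* **Feature-specific suppression**: plaid center 1.7°, annulus 3.9°–21.6°,
  per-component contrast 16.4 (rate) / 50 (spiking).  Population = E cells
  within 5 grid intervals of an anchor, binned by preferred orientation in
  5° bins.  Von Mises fits (180°-periodic, with baseline) to the
  component-alone responses give P1, P2; nonnegative least squares fits the
  plaid (and plaid+surround) response as w₁P1 + w₂P2, with no additive
  baseline.  Fits with R² < 0.6 are recorded as missing; a 0° plaid makes
  the design collinear and is flagged degenerate with the summed weight
  reported.
* **Activity decay**: steady state under a 2° or 10° stimulus at C = 17 or
  9; the external input is removed at 200 ms and an exponential is fitted to
  the log rate from 1 ms after removal until the rate falls below 1 % of its
  value at removal.

## Numerics

* **Integrator.** Forward Euler from zero rates for every stimulus (results
  are stimulus-order independent), batched over stimuli against the shared
  sparse weight blocks (float32 in protocol runs; float64 available and used
  for precision tests).  Steady state is accepted when
  max |dr|·τ/(r + 1e-6) < tol for both populations; the default tol is 1e-6,
  protocols use 1e-4 (rates converge to ~0.01 % there; tightening to 1e-6
  does not move any reported statistic).  Columns are retired from the batch
  as they converge; divergence (rate > 1e4) restarts with a halved step and
  ultimately raises an error rather than returning garbage.
* **Step size.** The stability bound is dt ≤ min(τ_E, τ_I)/5.  The default
  dt is 1 ms; protocol runs use dt = 1.3 ms — the Euler *fixed point* is
  independent of dt, and steady states at dt = 1.0 and 1.3 agree to ~1e-6
  relative.
* **Decay recording.** A forward-Euler step of size dt shortens a pure
  exponential decay constant τ to −dt/ln(1 − dt/τ) (≈ −5 % at dt = 1 ms for
  τ = 10 ms).  The decay phase is therefore re-integrated at a fine step
  (0.2 ms in protocols, bias < 0.13 ms; 0.01 ms in closed-form tests).
* **Subnormal flush.** Far from the stimulus the erf-tail drive underflows
  toward the subnormal float range and K·drive^2.2 would populate the state
  with subnormal numbers, which the CPU processes orders of magnitude more
  slowly.  Drives and rates below 1e-12 are flushed to exact zero — ~1e9
  times smaller than any meaningful rate.
* **Spiking integration.** Euler–Maruyama at dt = 0.05 ms (0.1 ms in the
  test suite; spontaneous and stimulated rates agree between the two within
  sampling error), exact exponential synaptic decay, exact OU update for the
  input conductance.  Noise is generated in chunks by a seeded Generator, so
  trials are reproducible bit-for-bit given (seed, dt, chunk size).
* **Eigen-diagnostics.** ISN checks use ARPACK on the sparse linearization
  (leading-real-part eigenvalues of the E-subnetwork block and the full
  2N×2N Jacobian, with the rectified power law linearized at the operating
  point).

## Problem sizes in the shipped runs

The full-scale characterization protocols use 80 (size
tuning), 67 (surround tuning), 80 populations (plaids), 50 (decay) and 30
(spiking) cells.  The package defaults keep those counts, and every runner
takes the count from its config.  The shipped summary script
(`scripts/acceptance.py`) records 40 locations for size tuning and 24 for
decay; the test suite runs 8 (rate sweeps), 6 (decay), 4 (spiking), and 1–2
(surround/plaid) — sizes chosen so population means carry standard errors
well inside the tolerances asserted against them (per-cell spreads: SI
0.07–0.1, SFS 0.3–0.7°, τ ≈ 0.05 ms).  Mean SFS of I cells deserves note:
its distribution is broad and lattice-quantized (most cells snap to 1.28°,
1.71° or 2.13°), so sample means fluctuate by ±0.2° between samples of this
size; E-cell statistics are much tighter.

## What the model does and does not capture

Heterogeneity across cells arises solely from each cell's position in the
deterministic orientation map — there is no random connectivity, so the
model cannot reproduce the full variability of biological tuning curves.
Stimulus features other than contrast, orientation and size (spatial
frequency, phase, drift) are ignored; cells behave as ideal complex cells
with time-static drive.  Stimulus-onset transients are out of scope; the
only dynamical measurement is the input-removal decay.  The surround/center
matching the model produces is partial — the most-suppressive surround
tracks the center orientation with a slope around 0.5 rather than 1, a known
limitation of this connectivity.  Passing tests demonstrate the circuit
mechanisms (SSN transition, ISN stabilization, feature-specific input-gain
suppression) in this idealized setting, not quantitative agreement with any
particular biological dataset.
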