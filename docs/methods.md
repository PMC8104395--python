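# Methods

This note documents the model implemented by `v1surround`, the parameters
that matter, the provenance of the packaged defaults, the numerical choices,
and what the tests do and do not establish.

## Model structure

The circuit has three tiers: an LGN sheet acting as a fixed spatial filter,
and two cortical layers (4Cα and 6) of interacting excitatory (E) and
inhibitory (I) neuron groups. Groups, not neurons, are the dynamical units:
each represents a few tens of cells with a common retinotopic position and
orientation preference, and carries a single scalar output (total current
produced by the group). The model is a steady-state (fixed-point) description;
there is no temporal dynamics.

### Geometry

* Patch: `n_hc_per_side` = 17 hypercolumns per side, `hc_size` = 0.25° —
  a 4.25° × 4.25° region, ~300 hypercolumns.
* Groups: `groups_per_hc_side` = 7 per hypercolumn side, so the lattice Ω has
  119 × 119 positions with spacing h = 1/28° at
  (h/2 + m·h, h/2 + n·h), 0 ≤ m, n ≤ 118. `groups_per_hc_side` must be odd so
  each hypercolumn has a center point.
* Orientation map: each hypercolumn square is split by its two diagonals into
  N/E/S/W triangles, one orientation per triangle. Points exactly on a
  diagonal are binned by their angle from the hypercolumn center
  ([−45°, 45°) → E, [45°, 135°) → N, …); the center point takes the
  N-triangle's orientation. The triangle→orientation assignment
  (N = 90°, E = 45°, S = 0°, W = 135°) is swapped N↔S, E↔W in hypercolumns of
  odd (row + col) parity. This checkerboard mirroring makes facing triangles
  across every hypercolumn border share an orientation, and places the patch
  center in a 90°-preferring domain, so the default vertical grating
  optimally drives the center group. The true cortical layout (pinwheels,
  continuous preference) is deliberately not modeled; four discrete domains
  per hypercolumn preserve the length scales that matter for surround
  interactions at far lower cost.

### LGN front end

`LGN(z*) = max{Σ_z h² f_DoG(z − z*) g_R(z), 0}` with

    f_DoG(z) = (1/Z) [ (1+Σ)/(2π R_in²) e^{−|z|²/2R_in²}
                       − Σ/(2π R_out²) e^{−|z|²/2R_out²} ],

Σ = 4.1, R_in = 0.1°, R_out = 0.31°, Z = 3.62283. The h² cell-area weighting
makes the sum a Riemann approximation of the underlying integral and is
consistent with the h² factor carried by the cortical coupling kernels; it
can be disabled (`area_weight=False`), which only rescales the field. With
these constants the center response over the default radius grid rises to a
single peak at R = 0.25° and levels off near 1/Z for large gratings. The
grating is reduced to its support indicator: drift, spatial frequency and
contrast are abstracted away (full contrast only). The LGN shares the
cortical lattice for simplicity; no ON/OFF mosaic is modeled.

Orientation gain: E groups receive the LGN current scaled by ω = 1 (matched
orientation), 0.4 (±45°), or 0.1 (orthogonal); I groups are ungated. The gain
is applied at system-assembly time, on the LGN term of the E-group equations
only.

### Connectivity

Local/inter-laminar projections are truncated Gaussians

    q(z, z*) = h² W/(2πσ²) e^{−|z−z*|²/2σ²} · 1{|z−z*| ≤ cutoff·σ}.

The Methods-style kernel is used literally — no renormalization of the
truncated Gaussian to unit mass, and the standard bivariate normalizer
1/(2πσ²). Both conventions appear in the literature; the packaged weights
were calibrated jointly with this choice, so changing it requires
recalibration. The self-coupling term (d = 0) is included: within-group
recurrence is part of the local sum in a group-level mean-field model.

Projection topology (all other pairs are absent): LGN→{4E,4I,6E,6I};
4E→{4E,4I,6E,6I}; 4I→{4E,4I}; 6E→{4E,4I,6E,6I}; 6I→{6E,6I}. The 6E→4E weight
is the control parameter `w_6e4e` (explored range 0.44–0.48; packaged default
0.48).

Long-range connections exist only for 6E sources, only to layer-6 groups of
like orientation preference, and only beyond the local-circuit radius 0.15°:

    q_LR(z, z*) = q0 · p(d) · π(z, z*),   d = |z − z*| ∈ (0.15, 1.6],

where π is the like-orientation indicator, p is p_E for E targets and p_I for
I targets, and q0 is the local 6E kernel evaluated at its cutoff radius so the
long-range profile continues the local circuit exactly at d = 0.15 (both 6E
local kernels cut off at 2 SD × 0.075° = 0.15°, so there is no double
counting).

### Steady state

Each group's output equals the sum of its inputs (proportionality constant
c = 1, absorbed into the weights): excitatory cortical currents minus
inhibitory ones, plus the (gated) LGN current and a small constant ambient
drive standing in for unmodeled modulatory input. Stacking the four
population fields gives H Θ = b with H = I − K and 4 × 119² = 56,644
unknowns. Size-tuning responses are center outputs minus the background
solution (LGN ≡ 0), over 32 radii 0.05, 0.10, …, 1.6°.

The system is solved unconstrained. Negative outputs are physically invalid;
they are *flagged* on the returned state (`nonnegative`), never silently
clipped, because clipping would change the model. A rectified fixed-point
variant (clamping at 0 per iteration) exists but is off by default. With the
packaged defaults all solutions on the default grid are nonnegative.

### Nonlinearity

The rate-dependent variant multiplies the 6E→4I, 4E→4E and 6E→6E couplings by

    m(η) = min(1 + κ·max(η − η_th, 0), m_max)

of the presynaptic group output η — a minimal piecewise-linear realization of
"threshold, linear increase, cap". The 6E→6E multiplier applies to both the
local and the long-range branch of that projection (they are one projection
physiologically); the 6E→6I long-range branch is untouched. This mimics
high-threshold interneuron recruitment: when layer 6 is strongly driven, its
net-inhibitory effect on layer 4 strengthens, steepening the descent of the
4E size-tuning curve precisely where the linear model is too shallow.

## Solvers

* **Linear.** Matrix-free H: each projection block is a zero-padded 2D
  convolution evaluated with cached kernel FFTs; long-range blocks are
  decomposed by orientation (mask, convolve, re-mask). Systems ≤ 20,000
  unknowns use an explicit sparse LU by default; larger ones restarted GMRES
  (restart 150, relative residual 1e−10 by default). Both operator
  representations produce identical matrix-vector products to machine
  precision (tested). Consecutive radius solves are warm-started; this
  changes iteration counts, not results.
* **Nonlinear.** Damped Picard iteration
  Θ_{k+1} = (1−α)Θ_k + α·solve(H(Θ_k), b) from the linear solution, default
  α = 0.5, tolerance 1e−8 on both the relative state change and the true
  fixed-point residual ‖H(Θ)Θ − b‖/‖b‖, max 500 iterations. Inner solves use
  an adaptive tolerance (a fraction of the current outer change, floored at
  the linear tolerance). Picard was chosen over Newton because H(Θ) changes
  mildly per step and robustness matters more than speed here. Uniqueness of
  the fixed point is not assumed: agreement across damping values is checked
  empirically (tested at α = 0.5 and 1.0), and divergence raises an error
  carrying the residual history rather than returning a questionable state.

## Packaged defaults and their provenance

Two classes of constants must be distinguished:

1. **Published local-circuit parameters** (`[projections]` in
   `table1_defaults.toml`): coupling weights, Gaussian SDs and cutoffs for
   LGN→cortex and the local/inter-laminar projections. These are reproduced
   exactly and verified field-by-field by a fixture-integrity test.
2. **Calibrated stand-ins** (`[longrange]`, `[ambient]`,
   `[nonlinear.multipliers]`): the long-range knot tables, ambient drives and
   multiplier constants are *not published*; only structural constraints are:
   p_E(0.15) = p_I(0.15) = 1, p_E(1.6) = p_I(1.6) = 0, net-excitatory
   interaction (p_E > p_I) below the d = 0.6° cross-over and net-inhibitory
   above, and ambient drives small relative to the other terms. The shipped
   values are synthetic calibrated defaults chosen once, by manual search
   within those constraints, so that the packaged model reproduces the
   qualitative targets: 4E size-tuning peak at 0.4°, 6E peak ≥ 0.7°,
   SI(4E) > SI(4I) and SI(4E) > SI(6E), nonnegative outputs, and a coupling
   operator with spectral radius < 1 (≈ 0.93 at the default point; the linear
   model has no steady state without this). `scripts/calibrate_defaults.py`
   re-runs the full verification of the frozen values; the values themselves
   are committed so nothing depends on re-running it.

During that calibration two regularities were found, and they shaped the
defaults: pushing p_E down (or p_I up) below 0.6° pulls the 6E peak leftward;
lowering the far-surround p_I tail raises the 6E tail, which in turn lifts the
4I tail more than the 4E tail (the 6E→4I weight exceeds 6E→4E) and thereby
fixes the SI(4E) > SI(4I) ordering. The multiplier caps are small (1.2 on
6E→4I, 1.02 on the E→E pairs) because larger E→E caps push the coupling
operator's spectral radius past 1 and the fixed point disappears; thresholds
sit above the background outputs so the background state is the same in the
linear and nonlinear models.

## Numerical choices

* FFT padding uses `next_fast_len`; all kernels share one frame so per-target
  contributions accumulate in the frequency domain. Kernel-footprint
  inclusion is `d ≤ R·(1 + 1e−12)` to keep exact-boundary offsets stable
  against rounding.
* GMRES convergence is verified a posteriori against the requested relative
  residual; failure raises with diagnostics rather than returning a partial
  answer.
* The DoG-area fit is bound-constrained least squares on
  (k_e, σ_e, k_i, σ_i − σ_e) with a deterministic 3 × 3 × 3 multi-start grid;
  the σ_i > σ_e constraint is enforced by construction.
* Sensitivities use central differences with relative step 1e−4 by default.
  H and b are affine in every registered scalar (weights, ambients,
  long-range knot values), so the analytic path
  dΘ = H⁻¹(∂b/∂p − (∂H/∂p)Θ) computes ∂H/∂p exactly from a single admissible
  displacement; finite-difference and analytic routes agree to 1e−4
  (tested) on reduced lattices.
* SI uses the response at the largest grid radius as the asymptote (the mean
  of the last k points is available via `tail=`). Because the model only
  reaches R = 1.6°, where curves may not have finished descending, its SI
  values understate what a larger patch would give. `si_dog_variant`
  (k_iσ_i/k_eσ_e) is provided as a clearly-labeled exploratory measure only;
  it is not the published area-ratio definition and is excluded from any
  validation.

## What the tests do and do not show

The suite verifies internal correctness (dense-oracle equivalence of the
operator and solvers, conservation of the input decomposition, linearity in
LGN drive, reduction of the nonlinear solver to the linear one, closed-form
and bisection oracles on single-group toys) and the behavioral properties of
the packaged defaults (peak radii, SI orderings, control-weight
monotonicity). Reduced 3×3 and 5×5-hypercolumn lattices are used wherever the
property does not depend on patch size; the full 17×17 lattice is used for
the behavioral checks.

Passing these tests shows the implementation solves the stated model and that
the calibrated defaults occupy a regime with the intended qualitative
behavior. It does **not** show that the defaults equal the original
calibrated values (which are unavailable), nor that the model generalizes
beyond full-contrast, single-orientation gratings of radius ≤ 1.6°: absolute
output magnitudes are meaningful only relative to one another, contrast
dependence is absent, and I-group tuning in layer 6 has no experimental
counterpart to compare against.

## Known limitations

* Supplementary exact values of the original long-range/ambient/multiplier
  tables are unavailable; the packaged stand-ins reproduce qualitative, not
  quantitative, published curves (absolute Fig-level values are out of reach
  by construction).
* The truncated-Gaussian normalization convention is ambiguous in the
  literature; the non-renormalized reading is implemented (configurable only
  by recalibrating weights).
* Whether the real fixed point of the nonlinear system is unique is unknown;
  the solver probes this empirically.
* No temporal dynamics, no spiking statistics, no ocular dominance or
  retinotopic distortion, no feedback from cortex to LGN.
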