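# Methods

## Model

The cell is a two-dimensional rectangle of length `2L` along x and width `2R`
along y. The nucleus is a rigid sphere of radius `r_nuc` whose periphery
carries `max((N_r + N_l) ÷ 4, 1)` MT-anchoring (MTOC) sites at angles ψ fixed
in the nucleus frame; the most populated site is the SPB and defines ψ = 0.
Each microtubule has a side (right/left), an axis angle θ measured from the
long axis in the world frame, and a length `l(t)`.

**Dynamic instability.** Growth at `v_g` (free) or `v_c` (wall contact),
shrinkage at `v_s`, instantaneous rescue at `l = 0` with a fresh axis angle
and a fresh catastrophe time `τ* ~ Gamma(N, T)` (shape `N`, timescale `T`,
both allowed non-integer; Γ evaluated through log-Γ). Load shortens the
catastrophe time to `τ₀ + (τ* − τ₀)·v_c/v_g`, where `τ₀` is the mean
catastrophe time at stall. Bookkeeping uses a catastrophe clock that runs at
rate 1 in free growth and at rate `τ*/rescaled(τ*) ≥ 1` during contact, so a
permanently touching filament lives exactly the rescaled time. An equivalent
per-step hazard formulation, `P_e = 1 − exp(−Δt/τ_T(age))` with
`τ_T = S/p` (survival over density), is provided in
`mt_dynamics.sample_catastrophe_ages_hazard` and verified against direct
gamma sampling (KS < 0.01 at n = 10⁵); whether load rescaling acts on the
drawn time or on the hazard is not distinguishable from the available
statements, and the clock form is the production choice because it realizes
the stated mean relation exactly.

**Forces.** A growing MT whose tip coordinate reaches its end wall
(`tip_x ≥ +L` right, `≤ −L` left; side walls exert no force by design) pushes
along its axis with magnitude `min(f_p, f_e)`: the polymerization force
`f_p = f_s(1 − v_c/v_g)` and the Euler force `f_e = max(κπ²/l², κπ²/l_io²)`,
where `l_io` is the anchor-to-wall distance along the axis latched at the
first contact of the current growth excursion (a buckled filament confined by
the cell cannot exert less force than it did when it first spanned the gap).
Torque is the 2-D cross product of the anchor lever arm `r_nuc·n̂` with the
force. Shrinking filaments exert nothing.

**Nucleus motion.** Overdamped forward-Euler updates of `(x, y, ω)`:
per-axis translational drag is the series (dashpot) combination of the Stokes
drag `6πηr_nuc` with the summed slender-body drag of the longest MT per
anchor site (`2πηl_par/(ln(l_par/2r_MT) − 0.2)` parallel,
`4πηl_perp/(ln(l_perp/2r_MT) + 0.84)` perpendicular; projections use
absolute values and any term whose log argument is ≤ 1, or whose denominator
is non-positive, is skipped — the formulas hold only in the long-rod limit
and would otherwise give negative drag). Rotation uses `8πηr_nuc³`. With no
filament contribution the series reduces to the nucleus drag alone. Thermal
forces are omitted: measured nuclear diffusion is two orders of magnitude
below the active displacement scale.

**Left/right correlation modes.** `independent` (default): every rescue
draws a fresh θ. `correlated`: MTOC sites come in mirror pairs about the
transverse axis (SPB site pinned at ψ = 0 to preserve the mirror axis) and a
rescued left MT reuses its right partner's current angle — a model of
perfectly correlated force generators. `mirrored` is a diagnostic mode in
which the left half is the exact mirror image of the right half; the net
longitudinal force is then identically zero and a centered nucleus stays
centered to machine precision (used as the symmetry regression test).

## Parameters (calibration defaults, all config-overridable)

| parameter | default | units | note |
|---|---|---|---|
| cell length 2L | 14 | µm | WT-like at mitotic commitment |
| cell width 2R | 3.5 | µm | |
| nucleus radius r_nuc | 1.4 | µm | |
| MT radius r_MT | 0.0125 | µm | |
| viscosity η | 2.0 | pN·s/µm² (= Pa·s) | see below |
| v_g, v_c, v_s | 0.05, 0.017, 0.15 | µm/s | in-vivo-plausible tip kinetics |
| stall force f_s | 5 | pN | mid-range of the 4–6 pN estimate |
| flexural rigidity κ | 1.25 | pN·µm² | |
| catastrophe N, T, τ₀ | 3.6, 35 s, 25 s | — | reference (Mal3-like) fit |
| N_r = N_l | 9 | — | 18 MTs, ~4 bundles |
| θ spread | 0.3 | rad | narrow axial alignment of bundles |
| dt | 0.05 | s | see numerics |
| duration | 7200 | s | one generation time |
| burn-in (stationary analyses) | 1800 | s | see protocol |

η is the one parameter calibrated against emergent behavior: with η = 2 Pa·s
the failure-coefficient profile over cell length rises markedly beyond the
WT-like 14 µm at fixed 18 MTs, as it should; at 1 Pa·s the rise is weak.
Organelle-scale effective viscosities of order 1 Pa·s are realistic for yeast
cytoplasm and crowding plausibly raises the value felt by a nucleus-sized
inclusion. The septum-placement noise used when deriving the failure
threshold from a synthetic septum sample is 0.2 µm (a small positioning error
of the division machinery relative to the nucleus).

## Statistical protocol

Two windows are used deliberately:

* **stationary statistics** (`summarize(traj, burn_in=1800)`) discard the
  approach from the tip-start and describe the steady state — used for the
  robustness trends (σx versus MT number and cell length) and for comparisons
  with surrogate stationary series;
* **generation-time statistics** (sweep drivers, failure maps) use the whole
  7200 s record including the transient: a real cell starts off-center after
  division and must center within one generation, so slow centering in long
  cells legitimately degrades δ and σx. `reproduce_fig7_maps`,
  `phi_length_profile` and the acceptance script use this protocol.

δ is the absolute time-mean of the SPB x-position per cell (orientation
convention: cells are oriented so the mean displacement is non-negative);
σx is the per-cell standard deviation. Standard errors use a moving-block
bootstrap with overlapping blocks of length equal to the autocorrelation time
(first 1/e crossing of the empirical ACF; at least one sample; a constant
series is defined fully correlated). `Φ(δ, σx, x_f)` is the one-sided upper
Gaussian tail beyond `x_f` (two-sided variant available); `x_f` defaults to
the 95th percentile of absolute wild-type-like septum offsets; `S_f` is the
empirical counterpart with case-resampling SE.

## Inference

The grid posterior uses the untruncated gamma likelihood on
`N ∈ [1:10]` (step 0.05) × `T ∈ [10:500] s` (step 1 s), computed in closed
form from sufficient statistics and normalized with a log-sum-exp shift (it
cannot underflow). Truncation by the observation window enters the
goodness-of-fit comparison (`truncated_fit_check`: KS distance of the
window-truncated CDF plus a parametric-bootstrap p-value); a
truncated-likelihood mode is available as an option. The informative prior
mixes the normalized anchor-likelihood surface with a uniform table,
`w·p_anchor + (1−w)·U`, with `w` solved by Brent root finding so that
max/min = 10 within 1%; the anchor surface is generated from the synthetic
reference dataset (200 events by default) because the experimental event list
is not published. `mle_fit` pins the gamma location at zero and is
deterministic given the data.

## Synthetic data

The generators define the study conditions: catastrophe times are
rejection-sampled Gamma(3.6, 35 s) inside a (10, 400) s observation window
(the window bounds are a plausible reconstruction of an imaging-limited
observation window and are configurable); surrogate SPB tracks are stationary
AR(1) processes — the simplest process with the stationarity and
autocorrelation structure the statistics layer assumes, so that layer can be
tested independently of the mechanistic simulator; septum offsets are folded
Gaussians; cell lengths are truncated normals (mean 14 µm). What the
surrogates deliberately lack: measurement noise spikes, segmentation
artifacts, nonstationary drift, and any coupling between x and y — so green
tests certify the statistical machinery and the model's internal consistency,
not agreement with real microscopy.

## Numerics

dt = 0.05 s keeps the largest per-step displacement (force/drag · dt) below
10⁻³ µm at the calibrated defaults; halving dt under paired seeds (the random
event sequence is consumed per rescue, not per step, so paired runs share
their event sequence) changes δ and σx by less than the replicate SEM.
Forward Euler is adequate because the dynamics are overdamped and
piecewise-smooth between discrete MT events. A hard-wall clamp at
`|x| = L − r_nuc` (and the corresponding y bound) is a numerical guard;
x-clamp events are counted and are zero in healthy runs. Buckling at
near-zero lengths is regularized at 10⁻⁹ µm (the polymerization force caps
the result). Replicate seeds derive from the base seed through a
counter-based `SeedSequence`, so grids are reproducible and order-independent;
the integration kernel (numba) uses a legacy NumPy generator seeded once per
run, making trajectories bit-reproducible.

## Known limitations

* Two-dimensional geometry; side-wall (y) contacts exert no force; the cell
  does not grow during a run; no mitotic-entry signaling or septum mechanics.
* The per-strain kinetic velocities of real mutant panels are not modeled;
  only the reference calibration is provided.
* With the calibrated defaults the model centers short (10–12 µm) cells
  about as well as the 14 µm condition: mean Φ over the short branch of the
  length sweep is flat within Monte-Carlo error, so the location of the Φ
  minimum on the grid {10…20} µm is a noisy draw from {10, 12, 14} even at
  20 replicates (the rising branch beyond 14 µm is robust). Producing a
  strictly interior minimum would require σx(10 µm)/σx(14 µm) ≳ 1.16 under
  the generation-time protocol; the implemented mechanism gives ≈ 1.14 in
  the stationary regime and ≈ 1.0 with the transient included.
* δ is not strictly monotone in cell length beyond 14 µm: near the length
  where the typical MT excursion (`v_g·N·T ≈ 6.3` µm plus contact growth)
  matches the center-to-wall gap, centering is locally strongest and δ dips
  (the dip sits at 18–20 µm at the defaults).
* In `correlated` mode the replicate spread of δ is *wider* than in
  `independent` mode, not narrower: with orientations and sites mirrored,
  simultaneous left/right contacts cancel exactly, which removes part of the
  effective centering stiffness while orientation noise was already tiny
  (sd(cos θ) ≈ 0.03 at the default spread). The corresponding trend test is
  expected to fail and documents this property.
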