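"""Monte-Carlo integration of the full nucleus-centering model and parameter sweeps.

A simulation holds ``n_right + n_left`` microtubules anchored at MTOC sites on
the nucleus periphery.  Each run starts with the nucleus at the left cell tip
(the biological configuration after cell division leaves the nucleus off
center) and integrates for one fission-yeast generation time (about 7200 s) of
which an initial burn-in window is discarded before statistics, so that the
reported quantities describe the stationary regime.

The production integrator is a numba kernel (:mod:`mtpush._kernel`); the
object-level :func:`step` implements the same update on dataclass states and is
kept as the readable reference used in unit tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mtpush import mechanics
from mtpush._kernel import MODE_CORRELATED, MODE_INDEPENDENT, MODE_MIRRORED, run_sim
from mtpush.mt_dynamics import (
    CatastropheModel,
    KineticParams,
    MicrotubuleState,
    Phase,
    Side,
    draw_catastrophe_time,
    step_microtubule,
)
from mtpush.mechanics import CellGeometry, DragEnvironment

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "NucleusState",
    "Trajectory",
    "default_config",
    "initialize",
    "sample_axis_angle",
    "step",
    "simulate",
    "sweep",
    "replicate_seed",
]

_MODE_CODES = {
    "independent": MODE_INDEPENDENT,
    "correlated": MODE_CORRELATED,
    "mirrored": MODE_MIRRORED,
}


def _default_kinetics() -> KineticParams:
    # calibration defaults: velocities in um/s, forces in pN, rigidity pN um^2
    return KineticParams(
        v_grow=0.05,
        v_contact=0.017,
        v_shrink=0.15,
        stall_force=5.0,
        flexural_rigidity=1.25,
        catastrophe=CatastropheModel(step_parameter=3.6, timescale_parameter=35.0, tau0=25.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Complete specification of one simulation run.

    ``lr_mode``: 'independent' draws a fresh axis angle at every rescue;
    'correlated' shares each rescue draw with the partner MT on the opposite
    side (perfectly correlated left/right force generators); 'mirrored' is a
    diagnostic mode in which the left half is the exact mirror image of the
    right half.  ``theta_spread`` is the scale (radians) of the zero-centered
    truncated-normal axis-angle distribution.
    """

    geometry: CellGeometry = field(default_factory=lambda: CellGeometry(7.0, 1.75))
    kinetics: KineticParams = field(default_factory=_default_kinetics)
    drag: DragEnvironment = field(default_factory=DragEnvironment)
    n_right: int = 9
    n_left: int = 9
    lr_mode: str = "independent"
    theta_spread: float = 0.3
    duration: float = 7200.0
    dt: float = 0.05
    burn_in: float = 1800.0
    out_dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 <= self.burn_in < self.duration):
            raise ValueError("require 0 <= burn_in < duration")
        if self.out_dt < self.dt:
            raise ValueError("out_dt must be >= dt")
        if self.lr_mode not in _MODE_CODES:
            raise ValueError(f"lr_mode must be one of {sorted(_MODE_CODES)}")
        if self.lr_mode in ("correlated", "mirrored") and self.n_right != self.n_left:
            raise ValueError("correlated/mirrored modes require n_right == n_left")
        if self.n_right < 0 or self.n_left < 0 or self.n_right + self.n_left == 0:
            raise ValueError("need at least one MT")
        if self.theta_spread < 0:
            raise ValueError("theta_spread must be >= 0")
        if self.geometry.half_width <= self.drag.nucleus_radius:
            raise ValueError("nucleus must fit inside the cell width")

    @property
    def n_mt(self) -> int:
        return self.n_right + self.n_left


def default_config(**overrides) -> SimConfig:
    """WT-like calibration default (2L = 14 um, 18 MTs) with field overrides."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


@dataclass
class NucleusState:
    """Nucleus centroid position (um) and rotation omega (radians) of the
    center-to-SPB vector relative to the cell long axis."""

    position: tuple[float, float]
    rotation: float = 0.0


@dataclass
class Trajectory:
    """Uniformly sampled nucleus/SPB track.

    ``spb_x``/``spb_y`` follow the anchor at psi = 0 (the SPB), always at
    distance ``nucleus_radius`` from the centroid.  ``clamp_events`` counts
    steps on which the hard-wall numerical guard fired; it is zero in healthy
    runs.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    omega: np.ndarray
    spb_x: np.ndarray
    spb_y: np.ndarray
    dt_out: float
    seed: int | None = None
    clamp_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "x_um": self.x,
                "y_um": self.y,
                "omega_rad": self.omega,
                "spb_x_um": self.spb_x,
                "spb_y_um": self.spb_y,
            }
        )


def sample_axis_angle(
    config: SimConfig,
    side: Side,
    partner_angle: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw an MT axis angle theta, radians in (-pi/2, pi/2).

    Angles follow a zero-centered normal with scale ``theta_spread`` truncated
    to (-pi/2, pi/2) (a stand-in for the measured orientation statistics of MT
    bundles, which are narrowly aligned with the long axis).  In correlated
    mode a left-side MT reuses the mirrored angle of its right-side partner;
    with the side-dependent growth direction convention (right grows toward +x,
    left toward -x) the mirror image of angle theta is theta itself.
    """
    if config.lr_mode in ("correlated", "mirrored") and partner_angle is not None:
        return float(partner_angle)
    if config.theta_spread == 0.0:
        return 0.0
    if rng is None:
        raise ValueError("rng required for a stochastic draw")
    while True:
        th = rng.normal(0.0, config.theta_spread)
        if -math.pi / 2 < th < math.pi / 2:
            return float(th)


def initialize(config: SimConfig, rng: np.random.Generator) -> tuple[NucleusState, list[MicrotubuleState]]:
    """Initial state: nucleus at the left cell tip, all MTs at length zero.

    The number of anchor (bundle) sites is the integer quotient of
    ``(n_right + n_left) / 4`` (at least 1); anchor angles are uniform on the
    circle, MTs are assigned to anchors uniformly at random, and the
    most-populated anchor — the SPB — is rotated to psi = 0 (ties broken by
    lowest anchor index, deterministic under a fixed seed).
    """
    n = config.n_mt
    n_bundles = n // 4
    if n_bundles < 1:
        logger.warning("fewer than 4 MTs; clamping bundle count to 1")
        n_bundles = 1
    mirrored_sites = config.lr_mode in ("correlated", "mirrored")
    if mirrored_sites:
        # perfectly correlated force generators: MTOC sites come in mirror
        # pairs (psi, pi - psi) about the transverse axis, with the SPB site
        # pinned at psi = 0 so the mirror axis is preserved
        half = (n_bundles + 1) // 2
        base = np.concatenate([[0.0], rng.uniform(0.0, 2.0 * math.pi, size=max(half - 1, 0))])
        psi_anchor = np.concatenate([base, math.pi - base])[:n_bundles]
        mirror_of = np.array(
            [k + half if k + half < n_bundles else k for k in range(half)]
            + [k - half for k in range(half, n_bundles)],
            dtype=int,
        )
        assignment = rng.integers(0, n_bundles, size=n)
    else:
        psi_anchor = rng.uniform(0.0, 2.0 * math.pi, size=n_bundles)
        assignment = rng.integers(0, n_bundles, size=n)
        counts = np.bincount(assignment, minlength=n_bundles)
        spb = int(np.argmax(counts))  # argmax -> lowest index on ties
        psi_anchor = np.mod(psi_anchor - psi_anchor[spb], 2.0 * math.pi)
        mirror_of = None

    model = config.kinetics.catastrophe
    mts: list[MicrotubuleState] = []
    mirrored_pairs = config.lr_mode in ("correlated", "mirrored")
    for i in range(n):
        side = Side.RIGHT if i < config.n_right else Side.LEFT
        partner: int | None = None
        if mirrored_pairs:
            partner = i + config.n_right if i < config.n_right else i - config.n_right
        if mirrored_pairs and side is Side.LEFT:
            # the left member of a pair mirrors its partner's orientation and
            # sits on the mirror image of its partner's MTOC site
            theta = mts[partner].axis_angle
            anchor_id = int(mirror_of[mts[partner].anchor_id])
            anchor_angle = float(psi_anchor[anchor_id])
        else:
            theta = sample_axis_angle(config, side, rng=rng)
            anchor_angle = float(psi_anchor[assignment[i]])
            anchor_id = int(assignment[i])
        mts.append(
            MicrotubuleState(
                anchor_angle=anchor_angle,
                axis_angle=theta,
                side=side,
                drawn_tau=draw_catastrophe_time(model, rng),
                anchor_id=anchor_id,
                partner=partner,
            )
        )
    L, rnuc = config.geometry.half_length, config.drag.nucleus_radius
    x0 = 0.0 if config.lr_mode == "mirrored" else -(L - rnuc)
    return NucleusState(position=(x0, 0.0)), mts


def _net_force_and_drags(
    nucleus: NucleusState, mts: list[MicrotubuleState], config: SimConfig
) -> tuple[float, float, float, float, float, float, list[bool]]:
    """Assemble net force/torque and per-axis effective drags; also return the
    per-MT contact flags (used to advance the catastrophe clocks)."""
    geom, kin, env = config.geometry, config.kinetics, config.drag
    fx = fy = tq = 0.0
    flags: list[bool] = []
    for mt in mts:
        if mt.buckling_ref_length is None and mt.phase is Phase.GROWING:
            # latch the geometric buckling floor at first contact
            res_probe = mechanics.contact_force(
                mt, nucleus.position, nucleus.rotation, geom, kin, env.nucleus_radius
            )
            if res_probe.contact_flag:
                mt.buckling_ref_length = mechanics.wall_contact_distance(
                    mt, nucleus.position, nucleus.rotation, env.nucleus_radius, geom.half_length
                )
        res = mechanics.contact_force(
            mt, nucleus.position, nucleus.rotation, geom, kin, env.nucleus_radius
        )
        flags.append(res.contact_flag)
        fx += res.force_vector[0]
        fy += res.force_vector[1]
        tq += res.torque
    longest: dict[int, tuple[float, float]] = {}
    for mt in mts:
        if mt.length > 0 and (mt.anchor_id not in longest or mt.length > longest[mt.anchor_id][0]):
            longest[mt.anchor_id] = (mt.length, mt.axis_angle)
    zpar, zperp = mechanics.mt_drag_components(list(longest.values()), env)
    znuc_t, znuc_r = mechanics.nucleus_drags(env)
    zx = mechanics.effective_translational_drag(znuc_t, zpar)
    zy = mechanics.effective_translational_drag(znuc_t, zperp)
    return fx, fy, tq, zx, zy, znuc_r, flags


def step(
    nucleus: NucleusState,
    mts: list[MicrotubuleState],
    config: SimConfig,
    rng: np.random.Generator,
    dt: float | None = None,
) -> NucleusState:
    """One forward-Euler step of the reference (object-level) integrator.

    Mutates ``mts`` in place and returns the updated nucleus state.  Contact
    flags, forces and drags are evaluated on the state at the start of the
    step, exactly as in the production kernel.
    """
    dt = config.dt if dt is None else dt
    fx, fy, tq, zx, zy, zr, flags = _net_force_and_drags(nucleus, mts, config)
    for i, mt in enumerate(mts):
        sampler = lambda r, s=mt.side: sample_axis_angle(config, s, rng=r)
        mts[i] = step_microtubule(mt, dt, flags[i], config.kinetics, rng, axis_angle_sampler=sampler)
    x, y = nucleus.position
    x += fx / zx * dt
    y += fy / zy * dt
    om = nucleus.rotation + tq / zr * dt
    L, R = config.geometry.half_length, config.geometry.half_width
    rnuc = config.drag.nucleus_radius
    x = min(max(x, -(L - rnuc)), L - rnuc)
    y = min(max(y, -(R - rnuc)), R - rnuc)
    return NucleusState(position=(x, y), rotation=om)


def simulate(config: SimConfig, init: tuple[NucleusState, list[MicrotubuleState]] | None = None) -> Trajectory:
    """Run the model for ``config.duration`` seconds; reproducible from the seed.

    The initial state is built in Python from ``config.seed``; the kernel RNG
    is seeded with a value derived from the same seed, so two calls with equal
    configs are bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    nucleus, mts = initialize(config, rng) if init is None else init
    n = len(mts)
    psi = np.array([mt.anchor_angle for mt in mts])
    side = np.array([1 if mt.side is Side.RIGHT else -1 for mt in mts], dtype=np.int64)
    anchor = np.array([mt.anchor_id for mt in mts], dtype=np.int64)
    theta = np.array([mt.axis_angle for mt in mts])
    tau_star = np.array([mt.drawn_tau for mt in mts])
    n_anchors = int(anchor.max()) + 1

    mode = _MODE_CODES[config.lr_mode]
    if mode == MODE_MIRRORED:
        keep = side > 0
        psi, side, anchor, theta, tau_star = (
            psi[keep], side[keep], anchor[keep], theta[keep], tau_star[keep],
        )

    n_steps = int(round(config.duration / config.dt))
    out_every = max(int(round(config.out_dt / config.dt)), 1)
    kernel_seed = int(np.random.SeedSequence([config.seed, 0x6B65]).generate_state(1)[0] & 0x7FFFFFFF)

    geom, kin, env = config.geometry, config.kinetics, config.drag
    times, xs, ys, oms, clamps = run_sim(
        kernel_seed,
        n_steps,
        out_every,
        config.dt,
        geom.half_length,
        geom.half_width,
        env.nucleus_radius,
        env.mt_radius,
        env.viscosity,
        kin.v_grow,
        kin.v_contact,
        kin.v_shrink,
        kin.stall_force,
        kin.flexural_rigidity,
        kin.catastrophe.tau0,
        kin.catastrophe.step_parameter,
        kin.catastrophe.timescale_parameter,
        config.theta_spread,
        mode,
        nucleus.position[0],
        nucleus.position[1],
        nucleus.rotation,
        psi,
        side,
        anchor,
        n_anchors,
        theta.copy(),
        tau_star.copy(),
    )
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys)) and np.all(np.isfinite(oms))):
        raise FloatingPointError(
            f"non-finite state in simulation (seed={config.seed}, config={config})"
        )
    if clamps:
        logger.warning("hard-wall clamp fired %d times (seed=%d)", clamps, config.seed)
    rnuc = env.nucleus_radius
    return Trajectory(
        times=times,
        x=xs,
        y=ys,
        omega=oms,
        spb_x=xs + rnuc * np.cos(oms),
        spb_y=ys + rnuc * np.sin(oms),
        dt_out=config.out_dt,
        seed=config.seed,
        clamp_events=int(clamps),
    )


def replicate_seed(base_seed: int, *indices: int) -> int:
    """Counter-based replicate seed: deterministic, collision-free across the
    sweep grid, and independent of evaluation order."""
    ss = np.random.SeedSequence([int(base_seed)] + [int(i) for i in indices])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def sweep(
    base: SimConfig,
    cell_lengths,
    mt_numbers,
    replicates: int,
    xf: float | None = None,
    n_boot: int = 0,
) -> pd.DataFrame:
    """Grid sweep over cell length (2L, um) and total MT number.

    Each grid cell runs ``replicates`` simulations with distinct derived seeds
    and summarizes delta, sigma_x, sigma_y per replicate (post burn-in); if
    ``xf`` is given a per-replicate failure coefficient Phi is attached.
    Returns a tidy frame with one row per replicate; failed replicates are kept
    as rows with NaN statistics and ``ok = False``.
    """
    from mtpush.stats import failure_coefficient, summarize  # local import: avoid cycle

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for il, two_l in enumerate(cell_lengths):
        for im, n_mt in enumerate(mt_numbers):
            if n_mt < 2 or n_mt % 2:
                raise ValueError("MT numbers must be even (n_right = n_left)")
            for rep in range(replicates):
                cfg = replace(
                    base,
                    geometry=CellGeometry(two_l / 2.0, base.geometry.half_width),
                    n_right=n_mt // 2,
                    n_left=n_mt // 2,
                    seed=replicate_seed(base.seed, il, im, rep),
                )
                row = {"length": two_l, "n_mt": n_mt, "replicate": rep}
                try:
                    traj = simulate(cfg)
                    summ = summarize(traj, burn_in=base.burn_in, n_boot=n_boot)
                    row.update(
                        delta=summ.delta,
                        sigma_x=summ.sigma_x,
                        sigma_y=summ.sigma_y,
                        ok=True,
                    )
                    if xf is not None:
                        row["phi"] = failure_coefficient(summ.delta, summ.sigma_x, xf)
                except Exception:  # noqa: BLE001 - record and continue
                    logger.exception("replicate failed: 2L=%s n_mt=%s rep=%s", two_l, n_mt, rep)
                    row.update(delta=np.nan, sigma_x=np.nan, sigma_y=np.nan, ok=False)
                rows.append(row)
    return pd.DataFrame(rows)
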