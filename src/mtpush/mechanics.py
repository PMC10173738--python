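"""Forces, torques, and hydrodynamic drags coupling MTs, nucleus, and cell wall.

Geometry: the cell is a 2-D rectangle of length ``2 L`` (long axis = x) and
width ``2 R``; the nucleus is a rigid sphere of radius ``r_nuc`` whose periphery
carries the MT anchors.  An MT pushes only while its tip touches an end wall
(x = +L or x = -L); the pushing force is the polymerization force
``f_p = f_s (1 - v_contact / v_grow)`` capped by the Euler buckling force
``f_e = kappa pi^2 / l^2`` (floored at the value for the anchor-to-wall distance
recorded at first contact, since a buckled filament is geometrically confined by
the cell).  Drags combine the Stokes drag of the nucleus and the anisotropic
slender-body drag of the longest MT per anchor, in series (the two dissipate
in the same cytoplasm, like dashpots in series).

Unit system: micrometers, seconds, piconewtons; viscosity in pN s / um^2
(1 Pa s = 1 pN s / um^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from mtpush.mt_dynamics import KineticParams, MicrotubuleState, Phase, Side

logger = logging.getLogger(__name__)

__all__ = [
    "CellGeometry",
    "DragEnvironment",
    "ForceResult",
    "polymerization_force",
    "buckling_force",
    "contact_force",
    "anchor_world_position",
    "nucleus_drags",
    "mt_drag_components",
    "effective_translational_drag",
]


@dataclass(frozen=True)
class CellGeometry:
    """Rectangular cell: half-length ``L`` and half-width ``R``, micrometers."""

    half_length: float
    half_width: float

    def __post_init__(self) -> None:
        if not (self.half_length > self.half_width > 0):
            raise ValueError("require half_length > half_width > 0")


@dataclass(frozen=True)
class DragEnvironment:
    """Cytoplasmic viscosity and the radii entering the drag laws.

    Defaults are calibration values, overridable in the config: effective
    cytoplasmic viscosity eta = 2 pN s / um^2 (organelle-scale yeast cytoplasm
    is of order 1 Pa s; crowding raises the effective value for a
    nucleus-sized inclusion), nucleus radius 1.4 um, MT radius 12.5 nm.
    """

    viscosity: float = 2.0
    nucleus_radius: float = 1.4
    mt_radius: float = 0.0125

    def __post_init__(self) -> None:
        if min(self.viscosity, self.nucleus_radius, self.mt_radius) <= 0:
            raise ValueError("viscosity and radii must be > 0")


@dataclass(frozen=True)
class ForceResult:
    """Per-MT contact force (pN, 2-vector), torque about the nucleus center
    (pN um, scalar z-component), and whether the tip touches an end wall."""

    force_vector: tuple[float, float]
    torque: float
    contact_flag: bool

    @classmethod
    def zero(cls) -> "ForceResult":
        return cls((0.0, 0.0), 0.0, False)


def polymerization_force(kinetics: KineticParams) -> float:
    """Pushing force implied by the force-velocity relation, ``f_s (1 - v_c/v_g)``."""
    return kinetics.stall_force * (1.0 - kinetics.v_ratio)


def buckling_force(length: float, ref_length: float, rigidity: float) -> float:
    """Euler critical force with the geometric floor:
    ``max(kappa pi^2 / l^2, kappa pi^2 / l_ref^2)``.

    ``ref_length`` is the anchor-to-wall distance at first contact; the floor
    keeps the force of a long buckled filament from decaying below the value it
    had when buckling against the wall first became possible.
    """
    if length <= 0 or ref_length <= 0:
        raise ValueError("length and ref_length must be > 0")
    c = rigidity * math.pi**2
    return max(c / length**2, c / ref_length**2)


def anchor_world_position(
    nucleus_position: tuple[float, float],
    nucleus_rotation: float,
    anchor_angle: float,
    nucleus_radius: float,
) -> tuple[float, float]:
    """World coordinates of an anchor: ``X + r_nuc (cos(omega+psi), sin(omega+psi))``."""
    a = nucleus_rotation + anchor_angle
    return (
        nucleus_position[0] + nucleus_radius * math.cos(a),
        nucleus_position[1] + nucleus_radius * math.sin(a),
    )


def mt_direction(mt: MicrotubuleState) -> tuple[float, float]:
    """Unit growth direction: right-side MTs grow toward +x, left toward -x,
    with axis angle theta measured from the long axis."""
    s = 1.0 if mt.side is Side.RIGHT else -1.0
    return (s * math.cos(mt.axis_angle), math.sin(mt.axis_angle))


def tip_position(
    mt: MicrotubuleState,
    nucleus_position: tuple[float, float],
    nucleus_rotation: float,
    nucleus_radius: float,
) -> tuple[float, float]:
    ax, ay = anchor_world_position(nucleus_position, nucleus_rotation, mt.anchor_angle, nucleus_radius)
    dx, dy = mt_direction(mt)
    return (ax + mt.length * dx, ay + mt.length * dy)


def wall_contact_distance(
    mt: MicrotubuleState,
    nucleus_position: tuple[float, float],
    nucleus_rotation: float,
    nucleus_radius: float,
    half_length: float,
) -> float:
    """Distance from the anchor to the end wall along the MT axis (inf if the
    axis never meets the wall, i.e. theta at +-pi/2)."""
    ax, _ = anchor_world_position(nucleus_position, nucleus_rotation, mt.anchor_angle, nucleus_radius)
    dx, _ = mt_direction(mt)
    if mt.side is Side.RIGHT:
        gap = half_length - ax
    else:
        gap = ax + half_length
    if abs(dx) < 1e-12:
        return math.inf
    return max(gap / abs(dx), 1e-9)


def contact_force(
    mt: MicrotubuleState,
    nucleus_position: tuple[float, float],
    nucleus_rotation: float,
    geom: CellGeometry,
    kinetics: KineticParams,
    nucleus_radius: float,
) -> ForceResult:
    """Force and torque exerted by one MT on the nucleus.

    Contact iff the MT is growing and its tip has reached its end wall
    (tip x >= +L for right-side MTs, <= -L for left-side).  The force magnitude
    is ``min(f_p, f_e)`` directed against the growth direction; the torque is
    the 2-D cross product of the anchor lever arm with the force.  Shrinking or
    non-touching MTs exert nothing.
    """
    if mt.phase is Phase.SHRINKING or mt.length <= 0:
        return ForceResult.zero()
    tx, _ = tip_position(mt, nucleus_position, nucleus_rotation, nucleus_radius)
    L = geom.half_length
    touching = tx >= L if mt.side is Side.RIGHT else tx <= -L
    if not touching:
        return ForceResult.zero()
    fp = polymerization_force(kinetics)
    ref = mt.buckling_ref_length
    if ref is None:
        ref = wall_contact_distance(mt, nucleus_position, nucleus_rotation, nucleus_radius, L)
    if math.isfinite(ref):
        fe = buckling_force(max(mt.length, 1e-9), ref, kinetics.flexural_rigidity)
    else:
        fe = math.inf
    f = min(fp, fe)
    dx, dy = mt_direction(mt)
    fx, fy = -f * dx, -f * dy
    a = nucleus_rotation + mt.anchor_angle
    rx, ry = nucleus_radius * math.cos(a), nucleus_radius * math.sin(a)
    torque = rx * fy - ry * fx
    return ForceResult((fx, fy), torque, True)


def nucleus_drags(env: DragEnvironment) -> tuple[float, float]:
    """Stokes drags of a rigid sphere: translational ``6 pi eta r`` (pN s/um)
    and rotational ``8 pi eta r^3`` (pN s um)."""
    eta, r = env.viscosity, env.nucleus_radius
    return 6.0 * math.pi * eta * r, 8.0 * math.pi * eta * r**3


def mt_drag_components(
    longest_per_anchor: list[tuple[float, float]],
    env: DragEnvironment,
) -> tuple[float, float]:
    """Anisotropic slender-body drag summed over the longest MT of each anchor.

    parallel      = sum  2 pi eta l |cos th| / (ln(l |cos th| / 2 r_MT) - 0.2)
    perpendicular = sum  4 pi eta l |sin th| / (ln(l |sin th| / 2 r_MT) + 0.84)

    The formulas hold in the long-rod limit; a term whose projected length gives
    a log argument <= 1 (or a non-positive denominator) would produce a negative
    drag and is skipped.  Projections use absolute values: drag cannot depend on
    the orientation sign.
    """
    eta, rmt = env.viscosity, env.mt_radius
    par = perp = 0.0
    for length, theta in longest_per_anchor:
        if length <= 0:
            raise ValueError("MT lengths must be > 0")
        lpar = length * abs(math.cos(theta))
        lperp = length * abs(math.sin(theta))
        if lpar > 0:
            arg = lpar / (2.0 * rmt)
            denom = math.log(arg) - 0.2
            if arg > 1.0 and denom > 0.0:
                par += 2.0 * math.pi * eta * lpar / denom
            else:
                logger.debug("skipping parallel drag term (l_par=%.3g um outside slender-body range)", lpar)
        if lperp > 0:
            arg = lperp / (2.0 * rmt)
            denom = math.log(arg) + 0.84
            if arg > 1.0 and denom > 0.0:
                perp += 4.0 * math.pi * eta * lperp / denom
            else:
                logger.debug("skipping perpendicular drag term (l_perp=%.3g um outside slender-body range)", lperp)
    return par, perp


def effective_translational_drag(nucleus_drag: float, mt_drag_axis: float) -> float:
    """Series (dashpot) combination ``1/zeta = 1/zeta_nuc + 1/zeta_MT``.

    With no MT contribution the nucleus drag alone remains (a dashpot in series
    with a free element), which is the physical limit the bare formula leaves
    undefined at ``zeta_MT = 0``.
    """
    if nucleus_drag <= 0:
        raise ValueError("nucleus_drag must be > 0")
    if mt_drag_axis < 0:
        raise ValueError("mt_drag_axis must be >= 0")
    if mt_drag_axis == 0.0:
        return nucleus_drag
    return 1.0 / (1.0 / nucleus_drag + 1.0 / mt_drag_axis)
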