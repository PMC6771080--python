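"""Applied magnetic field of a circular-loop / solenoid applicator.

The impressed field is computed analytically from the exact single current
loop solution (complete elliptic integrals) and superposed over the turns of
the applicator.  The azimuthal vector potential A of the same solution feeds
the magneto-quasi-static eddy-current solver; because the tissues are
non-magnetic and weakly conducting at ~171 kHz, the phantom is assumed not to
perturb the applied field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ellipe, ellipk

from .constants import MU0
from .phantom import VoxelPhantom

__all__ = ["CoilSpec", "loop_field", "calibrate_current", "field_on_grid", "default_coil"]


class FilamentError(ValueError):
    """Evaluation point coincides with the coil filament."""


@dataclass(frozen=True)
class CoilSpec:
    """Circular-loop applicator: ``n_turns`` coaxial loops of ``radius`` (m).

    ``turn_positions`` are the axial offsets of the turns from ``centre``
    along ``axis`` (m).  ``current`` is the amplitude of the (common) loop
    current in amperes; the field scales linearly with it.
    """

    radius: float
    turn_positions: tuple[float, ...]
    current: float = 1.0
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    #: per-turn loop radii for non-solenoidal windings (pancake/spiral);
    #: defaults to ``radius`` for every turn
    turn_radii: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if len(self.turn_positions) < 1:
            raise ValueError("need at least one turn")
        if not np.all(np.isfinite(self.turn_positions)):
            raise ValueError("turn positions must be finite")
        if self.turn_radii is not None:
            if len(self.turn_radii) != len(self.turn_positions):
                raise ValueError("turn_radii must match turn_positions in length")
            if not all(r > 0 for r in self.turn_radii):
                raise ValueError("turn radii must be > 0")
        if not np.linalg.norm(self.axis) > 0:
            raise ValueError("axis must be a nonzero vector")

    @property
    def radii(self) -> tuple[float, ...]:
        return self.turn_radii if self.turn_radii is not None else (self.radius,) * self.n_turns

    @property
    def n_turns(self) -> int:
        return len(self.turn_positions)

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2, e3) with e3 along the coil axis."""
        e3 = np.asarray(self.axis, dtype=float)
        e3 = e3 / np.linalg.norm(e3)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e3 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(helper, e3)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(e3, e1)
        return e1, e2, e3


def default_coil(centre: tuple[float, float, float], radius: float = 110.0e-3,
                 n_turns: int = 17, length: float = 120.0e-3) -> CoilSpec:
    """Regional solenoid applicator enclosing the chest crop.

    Turns are spread uniformly over ``length`` and centred on ``centre`` with
    the axis along z (through the breast), wide enough that the whole phantom
    sits inside a near-uniform field calibrated at the applicator centre.
    """
    if n_turns == 1:
        positions = (0.0,)
    else:
        positions = tuple(np.linspace(-length / 2.0, length / 2.0, n_turns))
    return CoilSpec(radius=radius, turn_positions=positions, centre=centre)


def pancake_coil(
    centre: tuple[float, float, float],
    r_inner: float = 15.0e-3,
    r_outer: float = 50.0e-3,
    n_turns: int = 17,
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> CoilSpec:
    """Flat spiral (pancake) applicator in the plane through ``centre``.

    Turns are concentric loops with radii spread uniformly between
    ``r_inner`` and ``r_outer``.  Placed with its plane just above the breast
    apex, the winding concentrates the field on the nearby skin while the
    centre of the applicator is calibrated to the prescribed amplitude.
    """
    radii = tuple(np.linspace(r_inner, r_outer, n_turns))
    return CoilSpec(
        radius=r_outer,
        turn_positions=(0.0,) * n_turns,
        centre=centre,
        axis=axis,
        turn_radii=radii,
    )


def _single_loop(a: float, current: float, rho: np.ndarray, dz: np.ndarray):
    """Exact field of one loop of radius ``a`` in its own cylindrical frame.

    Returns (H_rho, H_z, A_phi) at cylindrical coordinates (rho, dz) relative
    to the loop centre.  Uses the standard complete-elliptic-integral forms;
    on-axis points are handled by the closed-form limit.
    """
    rho = np.asarray(rho, dtype=float)
    dz = np.asarray(dz, dtype=float)
    H_rho = np.zeros(np.broadcast(rho, dz).shape)
    H_z = np.zeros_like(H_rho)
    A_phi = np.zeros_like(H_rho)

    d2 = (a - rho) ** 2 + dz**2
    if np.any(d2 < (1e-6 * a) ** 2):
        raise FilamentError("evaluation point lies on (or numerically at) the coil filament")

    on_axis = rho < 1e-9 * a
    off = ~on_axis

    # on-axis closed form
    H_z = np.where(on_axis, current * a**2 / (2.0 * (a**2 + dz**2) ** 1.5), 0.0)

    r = np.where(off, rho, 0.5 * a)  # dummy value on axis, masked out below
    denom2 = (a + r) ** 2 + dz**2
    m = 4.0 * a * r / denom2
    K = ellipk(m)
    E = ellipe(m)
    sq = np.sqrt(denom2)
    pref = current / (2.0 * math.pi * sq)
    hz_off = pref * (K + (a**2 - r**2 - dz**2) / ((a - r) ** 2 + dz**2) * E)
    hr_off = pref * (dz / r) * (-K + (a**2 + r**2 + dz**2) / ((a - r) ** 2 + dz**2) * E)
    k = np.sqrt(m)
    a_off = MU0 * current / (math.pi * k) * np.sqrt(a / r) * ((1.0 - m / 2.0) * K - E)

    H_z = np.where(off, hz_off, H_z)
    H_rho = np.where(off, hr_off, H_rho)
    A_phi = np.where(off, a_off, A_phi)
    return H_rho, H_z, A_phi


def loop_field(spec: CoilSpec, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """H (A/m) and vector potential A (T·m) of the applicator at ``points``.

    ``points`` is an (..., 3) array of Cartesian coordinates in phantom
    space.  The field of each turn is evaluated exactly and superposed.

    Raises
    ------
    FilamentError
        If a point lies on the coil filament.
    """
    pts = np.asarray(points, dtype=float)
    e1, e2, e3 = spec.frame()
    rel = pts - np.asarray(spec.centre)
    u = rel @ e1
    v = rel @ e2
    w = rel @ e3
    rho = np.hypot(u, v)
    # azimuthal unit vector in the coil frame; arbitrary (e1) on the axis
    with np.errstate(invalid="ignore", divide="ignore"):
        cphi = np.where(rho > 0, u / np.where(rho > 0, rho, 1.0), 1.0)
        sphi = np.where(rho > 0, v / np.where(rho > 0, rho, 1.0), 0.0)

    H_rho = np.zeros_like(rho)
    H_w = np.zeros_like(rho)
    A_phi = np.zeros_like(rho)
    for z0, a in zip(spec.turn_positions, spec.radii):
        hr, hz, ap = _single_loop(a, spec.current, rho, w - z0)
        H_rho += hr
        H_w += hz
        A_phi += ap

    # back to Cartesian phantom coordinates
    H = (
        (H_rho * cphi)[..., None] * e1
        + (H_rho * sphi)[..., None] * e2
        + H_w[..., None] * e3
    )
    A = (-A_phi * sphi)[..., None] * e1 + (A_phi * cphi)[..., None] * e2
    return H, A


def calibrate_current(spec: CoilSpec, target_H: float, at: np.ndarray) -> float:
    """Current (A) so that |H| at point ``at`` equals ``target_H`` (A/m).

    The field is linear in the current, so the calibration is a single
    unit-current evaluation.

    Raises
    ------
    ValueError
        If the unit-current field vanishes at the calibration point.
    """
    unit = replace(spec, current=1.0)
    H, _ = loop_field(unit, np.asarray(at, dtype=float))
    mag = float(np.linalg.norm(H))
    if mag == 0.0:
        raise ValueError("unit-current field vanishes at the calibration point")
    return target_H / mag


def field_on_grid(spec: CoilSpec, phantom: VoxelPhantom) -> tuple[np.ndarray, np.ndarray]:
    """H and A maps on the phantom voxel centres: arrays of shape (nx, ny, nz, 3)."""
    X, Y, Z = phantom.voxel_centres()
    nx, ny, nz = phantom.shape
    pts = np.empty((nx, ny, nz, 3))
    pts[..., 0] = np.broadcast_to(X, (nx, ny, nz))
    pts[..., 1] = np.broadcast_to(Y, (nx, ny, nz))
    pts[..., 2] = np.broadcast_to(Z, (nx, ny, nz))
    return loop_field(spec, pts)
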