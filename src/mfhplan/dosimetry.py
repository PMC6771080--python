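"""Thermal dose metrics and ferrofluid-concentration planning.

CEM43 (cumulative equivalent minutes at 43 degC) converts an arbitrary
temperature-time history into the exposure time at the 43 degC reference that
would produce equivalent thermal damage:

    CEM43 = sum_i R^(43 - T_i) * dt_i / 60 ,   R = 0.5 (T >= 43), 0.25 (T < 43).

Planning inverts the monotone tumour-temperature response to the relative
ferrofluid concentration phi_r by bisection, either on the tumour-centre
temperature (coverage goal 0) or on the fraction of tumour volume at or above
the target temperature.  The field-frequency safety index is the
Atkinson-Brezovich product Hmax*f compared against the eddy-current pain
threshold of 4.85e8 A/(m*s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import bioheat
from .bioheat import BioheatParams, ThermalRun, mnp_source_map
from .mnp import FieldExposure
from .phantom import VoxelPhantom

__all__ = [
    "DoseReport",
    "PlanResult",
    "SafetyIndex",
    "cem43",
    "cem43_map",
    "isotherm_volume",
    "plan_concentration",
    "safety_index",
    "PAIN_THRESHOLD_HF",
]

#: eddy-current pain threshold for the Hmax*f product (A/(m*s))
PAIN_THRESHOLD_HF = 4.85e8


class PlanningError(RuntimeError):
    """The planning target cannot be bracketed or reached."""


def cem43(T_series: np.ndarray, dt: float) -> float | np.ndarray:
    """Cumulative equivalent minutes at 43 degC.

    ``T_series`` is a uniformly sampled temperature history in degC — either
    a 1-D series (returns a scalar, minutes) or an (n_times, ...) stack
    (returns a map).  ``dt`` is the sampling interval in seconds.

    Raises
    ------
    ValueError
        On an empty series or nonpositive dt.
    """
    T = np.asarray(T_series, dtype=float)
    if T.size == 0:
        raise ValueError("empty temperature series")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    R = np.where(T >= 43.0, 0.5, 0.25)
    dose = np.sum(R ** (43.0 - T) * dt / 60.0, axis=0)
    return float(dose) if np.ndim(dose) == 0 else dose


def cem43_map(run: ThermalRun) -> np.ndarray:
    """CEM43 map (minutes) from the saved snapshots of a thermal run.

    Snapshot intervals are integrated with the trapezoidal weights of the
    (possibly non-uniform) save times.
    """
    times = run.times
    if len(times) < 2:
        raise ValueError("need at least two snapshots for a dose map")
    stack = np.stack(run.snapshots)
    R = np.where(stack >= 43.0, 0.5, 0.25)
    rate = R ** (43.0 - stack)  # equivalent minutes at 43 per minute of exposure
    w = np.gradient(times)
    w[0] *= 0.5
    w[-1] *= 0.5
    dose = np.tensordot(w, rate, axes=(0, 0)) / 60.0
    return np.where(np.isfinite(dose), dose, 0.0)


def isotherm_volume(
    T_field: np.ndarray,
    threshold: float,
    phantom: VoxelPhantom,
) -> tuple[float, float]:
    """Tissue volume (m^3) at or above ``threshold`` degC, and tumour coverage.

    Volume counts tissue voxels only; coverage is the fraction of tumour
    voxels at or above the threshold (0.0 if the phantom has no tumour).
    """
    above = (T_field >= threshold) & phantom.tissue_mask & np.isfinite(T_field)
    volume = float(np.count_nonzero(above)) * phantom.spacing**3
    tum = phantom.tumour_mask
    coverage = float(np.count_nonzero(above & tum) / np.count_nonzero(tum)) if tum.any() else 0.0
    return volume, coverage


@dataclass
class SafetyIndex:
    """Atkinson-Brezovich field-frequency product with pass/fail flag."""

    product: float  # Hmax*f (A/(m*s))
    threshold: float
    ok: bool


def safety_index(exposure: FieldExposure, threshold: float = PAIN_THRESHOLD_HF) -> SafetyIndex:
    """Hmax*f product versus the pain threshold (fails only when strictly above)."""
    product = exposure.Hmax * exposure.f
    return SafetyIndex(product=product, threshold=threshold, ok=not product > threshold)


@dataclass
class PlanResult:
    """Outcome of concentration planning.

    ``phi_r``: required relative concentration; ``power_W_m3``: the
    corresponding volumetric power density; ``achieved_C``: the realised
    criterion temperature; ``coverage``: tumour coverage at the target
    temperature; ``n_simulations``: bioheat runs spent.
    """

    phi_r: float
    power_W_m3: float
    achieved_C: float
    coverage: float
    n_simulations: int


def plan_concentration(
    phantom: VoxelPhantom,
    reference_power: float,
    target_C: float = 43.0,
    coverage_goal: float = 0.0,
    params: BioheatParams = BioheatParams(),
    duration: float = 1800.0,
    extra_sources: np.ndarray | None = None,
    bracket: tuple[float, float] = (0.1, 2.0),
    tol: float = 0.02,
    max_iter: int = 20,
    T0: np.ndarray | None = None,
) -> PlanResult:
    """Bisect the relative concentration phi_r to reach the thermal target.

    ``reference_power`` is the volumetric tumour power density at phi_r = 1
    (W/m^3); the source scales linearly with phi_r.  With
    ``coverage_goal = 0`` the criterion is the tumour-centre temperature at
    the end of the run; otherwise it is the tumour coverage fraction at
    ``target_C``.  The upper bracket is doubled (up to 3 times) if it does
    not reach the target.

    Raises
    ------
    PlanningError
        If the target is unreachable inside the expanded bracket.
    """
    if not phantom.tumour_mask.any():
        raise PlanningError("phantom has no tumour to plan for")
    disc_centre = tuple(
        np.round(np.argwhere(phantom.tumour_mask).mean(axis=0)).astype(int)
    )
    if T0 is None:
        T0 = bioheat.steady_state(phantom, params)
    n_sims = 0

    def criterion(phi: float) -> tuple[float, float, float]:
        nonlocal n_sims
        src = mnp_source_map(phantom, reference_power * phi)
        if extra_sources is not None:
            src = src + extra_sources
        run = bioheat.simulate(phantom, T0, src, params, duration=duration)
        n_sims += 1
        Tc = float(run.final[disc_centre])
        _, cov = isotherm_volume(run.final, target_C, phantom)
        value = Tc if coverage_goal == 0.0 else cov
        return value, Tc, cov

    goal = target_C if coverage_goal == 0.0 else coverage_goal
    lo, hi = bracket
    v_lo, *_ = criterion(lo)
    if v_lo >= goal:
        raise PlanningError(
            f"lower bracket phi_r={lo} already reaches the target ({v_lo:.3f} >= {goal})"
        )
    v_hi, Tc_hi, cov_hi = criterion(hi)
    expansions = 0
    while v_hi < goal and expansions < 3:
        hi *= 2.0
        v_hi, Tc_hi, cov_hi = criterion(hi)
        expansions += 1
    if v_hi < goal:
        raise PlanningError(
            f"target unreachable: criterion {v_hi:.3f} < {goal} at phi_r={hi} "
            f"(reference power {reference_power:.1f} W/m^3, duration {duration} s)"
        )

    Tc, cov = Tc_hi, cov_hi
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        v_mid, Tc, cov = criterion(mid)
        if v_mid >= goal:
            hi = mid
        else:
            lo = mid
    return PlanResult(
        phi_r=hi,
        power_W_m3=reference_power * hi,
        achieved_C=Tc,
        coverage=cov,
        n_simulations=n_sims,
    )


@dataclass
class DoseReport:
    """Aggregated dosimetry of one exposure scenario."""

    cem43_tumour_median_min: float
    cem43_tumour_min_min: float
    isotherm_volumes_m3: dict[float, float]
    tumour_coverage: dict[float, float]
    safety: SafetyIndex
    required_phi_r: float | None = None

    @staticmethod
    def from_run(
        run: ThermalRun,
        phantom: VoxelPhantom,
        exposure: FieldExposure,
        thresholds: tuple[float, ...] = (40.0, 43.0),
        required_phi_r: float | None = None,
    ) -> "DoseReport":
        dose = cem43_map(run)
        tum = phantom.tumour_mask
        volumes = {}
        coverage = {}
        for thr in thresholds:
            vol, cov = isotherm_volume(run.final, thr, phantom)
            volumes[thr] = vol
            coverage[thr] = cov
        return DoseReport(
            cem43_tumour_median_min=float(np.median(dose[tum])) if tum.any() else 0.0,
            cem43_tumour_min_min=float(dose[tum].min()) if tum.any() else 0.0,
            isotherm_volumes_m3=volumes,
            tumour_coverage=coverage,
            safety=safety_index(exposure),
            required_phi_r=required_phi_r,
        )
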