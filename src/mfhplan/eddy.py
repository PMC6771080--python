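"""Magneto-quasi-static eddy-current solve on the voxel conductivity map.

A time-harmonic impressed vector potential A (from the applicator, angular
frequency omega) induces currents J = -sigma*grad(u) - j*sigma*omega*A in the
conducting tissue.  Charge conservation div(J) = 0 with no current leaving
the conductor gives a scalar-potential problem

    div( sigma * (grad(u) + j*omega*A) ) = 0 ,

discretised with a 7-point finite-volume stencil (harmonic conductivity
averaging at faces) and solved with a Jacobi-preconditioned conjugate
gradient.  Writing u = j*omega*v reduces it to a real symmetric system for v.
The solution is defined up to a constant per connected conductive component;
the gauge fixes each component to zero mean.

Power is reported as the time-averaged volumetric density
P = |J|^2/(2*sigma) for peak-amplitude phasors (a ``peak`` convention
without the factor 2 is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .phantom import Label, VoxelPhantom

__all__ = ["EMSolution", "solve_scalar_potential", "eddy_power", "find_hot_spots", "solve_eddy"]


class SolverError(RuntimeError):
    """Iterative solve failed to reach the requested residual."""


@dataclass
class EMSolution:
    """Per-voxel electromagnetic solution.

    ``A_map``: impressed vector potential (T·m, shape (nx,ny,nz,3), real
    amplitude); ``u_map``: complex scalar potential (V); ``J_map``: complex
    eddy current density phasor (A/m^2, peak amplitude); ``P_eddy``:
    time-averaged volumetric power density (W/m^3); ``f``: frequency (Hz).
    """

    A_map: np.ndarray
    u_map: np.ndarray
    J_map: np.ndarray
    P_eddy: np.ndarray
    f: float


def _face_sigma(sigma: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean conductivity at the internal faces along ``axis``."""
    s0 = np.moveaxis(sigma, axis, 0)[:-1]
    s1 = np.moveaxis(sigma, axis, 0)[1:]
    num = 2.0 * s0 * s1
    den = s0 + s1
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(den > 0, num / den, 0.0)
    return np.moveaxis(f, 0, axis)


def solve_scalar_potential(
    phantom: VoxelPhantom,
    A_map: np.ndarray,
    f: float,
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> np.ndarray:
    """Solve the charge-conservation equation for the scalar potential.

    Returns the complex scalar potential ``u = j*omega*v`` per voxel (zero
    outside the conductor), gauge-fixed to zero mean on every connected
    conductive component.

    Raises
    ------
    SolverError
        With the achieved residual if CG does not converge.
    """
    sigma = phantom.property_map("sigma")
    h = phantom.spacing
    omega = 2.0 * np.pi * f
    cond = sigma > 0
    n_cond = int(np.count_nonzero(cond))
    if n_cond == 0:
        return np.zeros(phantom.shape, dtype=complex)

    idx = -np.ones(phantom.shape, dtype=np.int64)
    idx[cond] = np.arange(n_cond)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_cond)
    b = np.zeros(n_cond)
    for axis in range(3):
        sf = _face_sigma(sigma, axis)  # internal faces along axis
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        i_lo = idx[tuple(sl_lo)]
        i_hi = idx[tuple(sl_hi)]
        active = (sf > 0) & (i_lo >= 0) & (i_hi >= 0)
        g = (sf * h)[active]  # conductance sigma_f * area / distance = sigma_f * h
        lo = i_lo[active]
        hi = i_hi[active]
        rows += [lo, hi]
        cols += [hi, lo]
        vals += [-g, -g]
        np.add.at(diag, lo, g)
        np.add.at(diag, hi, g)
        # source term: with L = sum_f g*(v_i - v_nb) on the left, the face
        # contribution sigma_f*A.n_out*h^2 enters the right-hand side with
        # the outward normal of each cell (+ for the lower cell, - upper)
        A_ax = A_map[..., axis]
        A_face = 0.5 * (A_ax[tuple(sl_lo)] + A_ax[tuple(sl_hi)])[active]
        flux = g * h * A_face  # sigma_f * A_n * h^2
        np.add.at(b, lo, flux)
        np.subtract.at(b, hi, flux)

    rows.append(np.arange(n_cond))
    cols.append(np.arange(n_cond))
    vals.append(diag)
    L = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_cond, n_cond),
    ).tocsr()

    inv_diag = np.where(diag > 0, 1.0 / np.where(diag > 0, diag, 1.0), 1.0)
    M = LinearOperator((n_cond, n_cond), matvec=lambda x: inv_diag * x)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        v = np.zeros(n_cond)
    else:
        v, info = cg(L, b, M=M, rtol=rtol, maxiter=maxiter)
        if info != 0:
            res = np.linalg.norm(L @ v - b) / bnorm
            raise SolverError(
                f"scalar-potential CG did not converge: info={info}, relative residual={res:.3e}"
            )

    v_map = np.zeros(phantom.shape)
    v_map[cond] = v
    # gauge: zero mean per connected conductive component
    comp, n_comp = ndimage.label(cond, structure=ndimage.generate_binary_structure(3, 1))
    for c in range(1, n_comp + 1):
        mask = comp == c
        v_map[mask] -= v_map[mask].mean()
    return 1j * omega * v_map


def eddy_power(
    phantom: VoxelPhantom,
    A_map: np.ndarray,
    u_map: np.ndarray,
    f: float,
    convention: str = "time_average",
) -> tuple[np.ndarray, np.ndarray]:
    """Eddy current density J and volumetric power density P_eddy.

    J = -sigma*grad(u) - j*sigma*omega*A (complex phasor, peak amplitude);
    P = |J|^2/(2*sigma) where sigma > 0 (``"peak"`` drops the factor 2).
    The potential gradient is evaluated with central differences inside the
    conductor and one-sided differences at its surface.
    """
    if convention not in ("time_average", "peak"):
        raise ValueError(f"unknown power convention {convention!r}")
    sigma = phantom.property_map("sigma")
    h = phantom.spacing
    omega = 2.0 * np.pi * f
    cond = sigma > 0

    grad_u = np.zeros(phantom.shape + (3,), dtype=complex)
    for axis in range(3):
        g = np.zeros(phantom.shape, dtype=complex)
        u = u_map
        nb_lo = np.roll(cond, 1, axis=axis)
        nb_lo[(slice(None),) * axis + (0,)] = False
        nb_hi = np.roll(cond, -1, axis=axis)
        nb_hi[(slice(None),) * axis + (-1,)] = False
        u_lo = np.roll(u, 1, axis=axis)
        u_hi = np.roll(u, -1, axis=axis)
        both = nb_lo & nb_hi
        only_lo = nb_lo & ~nb_hi
        only_hi = nb_hi & ~nb_lo
        g[both] = (u_hi[both] - u_lo[both]) / (2.0 * h)
        g[only_lo] = (u[only_lo] - u_lo[only_lo]) / h
        g[only_hi] = (u_hi[only_hi] - u[only_hi]) / h
        grad_u[..., axis] = np.where(cond, g, 0.0)

    J = -sigma[..., None] * grad_u - 1j * sigma[..., None] * omega * A_map
    J[~cond] = 0.0
    P = np.zeros(phantom.shape)
    amp2 = np.sum(np.abs(J) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P[cond] = amp2[cond] / sigma[cond]
    if convention == "time_average":
        P *= 0.5
    return J, P


def solve_eddy(
    phantom: VoxelPhantom,
    A_map: np.ndarray,
    f: float,
    rtol: float = 1e-8,
    convention: str = "time_average",
) -> EMSolution:
    """Full eddy-current solve: scalar potential, currents and power map."""
    u = solve_scalar_potential(phantom, A_map, f, rtol=rtol)
    J, P = eddy_power(phantom, A_map, u, f, convention=convention)
    return EMSolution(A_map=A_map, u_map=u, J_map=J, P_eddy=P, f=f)


def find_hot_spots(
    P_eddy: np.ndarray,
    phantom: VoxelPhantom,
    exclude: set[int] | None = None,
    k: int = 5,
) -> list[tuple[float, tuple[int, int, int]]]:
    """Top-k local maxima of the eddy power density outside excluded labels.

    By default the skin layer is excluded (its surface values dominate the
    map).  Returns ``[(P_W_per_m3, (i, j, k)), ...]`` sorted by decreasing
    power.  Plateaus yield a single representative voxel per 26-connected
    plateau component.

    Raises
    ------
    ValueError
        If the search region is empty.
    """
    exclude = {Label.SKIN} if exclude is None else set(exclude)
    sigma = phantom.property_map("sigma")
    region = (sigma > 0) & ~np.isin(phantom.labels, list(exclude))
    if not region.any():
        raise ValueError("hot-spot search region is empty")

    P = np.where(region, P_eddy, -np.inf)
    local_max = (P == ndimage.maximum_filter(P, size=3, mode="constant", cval=-np.inf)) & region
    # deduplicate plateau components
    comp, n_comp = ndimage.label(local_max, structure=np.ones((3, 3, 3), dtype=bool))
    spots = []
    for c in range(1, n_comp + 1):
        pos = np.argwhere(comp == c)[0]
        spots.append((float(P_eddy[tuple(pos)]), tuple(int(i) for i in pos)))
    spots.sort(key=lambda s: -s[0])
    return spots[:k]
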