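"""Axisymmetric membrane field of the partially electroded, clamped stretcher.

The prestretched membrane is clamped at the frame and carries a circular
compliant electrode around its center.  With principal stretches
lam_r = dr/dR and lam_t = r/R (R the reference radius, r the deformed one),
thickness-integrated equilibrium in the reference configuration reads

    d(R * P_r) / dR = P_t,

with nominal (first Piola-Kirchhoff) in-plane stresses from the
incompressible plane-stress Yeoh law

    P_r = 2 W1 (lam_r - lam_r^-3 lam_t^-2),
    P_t = 2 W1 (lam_t - lam_t^-3 lam_r^-2),
    I1  = lam_r^2 + lam_t^2 + lam_r^-2 lam_t^-2.

Inside the electrode both in-plane true stresses are reduced by the Maxwell
stress sigma_M (constant under the fixed-initial-thickness convention,
thickness-coupled under "true"), i.e. P_i -> P_i - sigma_M / lam_i.  Boundary
conditions are regularity at the center and clamping at the prestretch
position, r(frame_radius) = lam_p * frame_radius.

Within a region of constant electrode load the unique regular solution is
the uniform equibiaxial field r = lam_c * R, so the interior of the
electrode is exactly uniform and equiaxial; the field develops structure
only at the electrode edge - where the total radial traction is continuous
but lam_r jumps - and across the passive annulus out to the clamp.  The
solver shoots on the center stretch lam_c (bisection to 1e-10), carrying the
states (r, m = R * P_r_total) through the annulus by fixed-grid RK4 with a
Newton inversion of the radial tension for lam_r at every stage.

The electrode boundary is specified in the prestretched configuration and
mapped to the reference one, R_e = electrode_radius / lam_p (the electrode
is deposited after prestretching).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .actuation import MembraneGeometry, prestretch_thickness
from .materials import YeohMaterial, maxwell_stress

__all__ = [
    "AxisymmetricField",
    "PathProfile",
    "SolverError",
    "solve_field",
    "actuating_strain_from_total",
    "path_profile",
    "equiaxiality_index",
]


class SolverError(RuntimeError):
    """Shooting failed to bracket or converge; carries diagnostics."""


@dataclass(frozen=True)
class AxisymmetricField:
    """Radial/hoop stretch and actuating-strain field on a reference grid.

    ``residual`` is the per-node closure residual of the returned solution,
    |P_r(lam_r, lam_t) - m / R| / C10 (dimensionless tension units).
    """

    r_ref: np.ndarray
    lam_r: np.ndarray
    lam_t: np.ndarray
    strain_r_act: np.ndarray
    strain_t_act: np.ndarray
    residual: np.ndarray
    lam_p: float
    electrode_radius_ref: float
    voltage: float

    @property
    def frame_radius(self) -> float:
        return float(self.r_ref[-1])


@dataclass(frozen=True)
class PathProfile:
    """Actuating strains interpolated along a radial segment (reference coords)."""

    arclength: np.ndarray
    strain_r: np.ndarray
    strain_t: np.ndarray


def actuating_strain_from_total(total_strain, lam_p: float = 3.0):
    """Actuating strain from total engineering strain.

    The field's total engineering strain contains the prestretch
    contribution lam_p - 1 (equal to 2 for the standard 200% radial
    prestretch); the actuating strain subtracts it.
    """
    total = np.asarray(total_strain, dtype=float)
    out = total - (lam_p - 1.0)
    return float(out) if out.ndim == 0 else out


def _w1(mat: YeohMaterial, i1):
    x = i1 - 3.0
    return mat.c10 + 2.0 * mat.c20 * x + 3.0 * mat.c30 * x**2


def _p_elastic(mat: YeohMaterial, lam_r, lam_t):
    """Elastic nominal stresses (P_r, P_t) in MPa."""
    i1 = lam_r**2 + lam_t**2 + lam_r**-2 * lam_t**-2
    w1 = _w1(mat, i1)
    p_r = 2.0 * w1 * (lam_r - lam_r**-3 * lam_t**-2)
    p_t = 2.0 * w1 * (lam_t - lam_t**-3 * lam_r**-2)
    return p_r, p_t


def _dpr_dlamr(mat: YeohMaterial, lam_r, lam_t):
    """d P_r / d lam_r at fixed lam_t (MPa)."""
    i1 = lam_r**2 + lam_t**2 + lam_r**-2 * lam_t**-2
    x = i1 - 3.0
    w1 = mat.c10 + 2.0 * mat.c20 * x + 3.0 * mat.c30 * x**2
    w2 = 2.0 * mat.c20 + 6.0 * mat.c30 * x
    di1 = 2.0 * lam_r - 2.0 * lam_r**-3 * lam_t**-2
    return 2.0 * w2 * di1 * (lam_r - lam_r**-3 * lam_t**-2) + 2.0 * w1 * (
        1.0 + 3.0 * lam_r**-4 * lam_t**-2
    )


def _sigma_m_mpa(
    mat: YeohMaterial, geom: MembraneGeometry, voltage: float, lam_r, lam_t, convention: str
):
    """Maxwell stress in MPa at local stretches, per thickness convention."""
    if convention == "initial":
        t = prestretch_thickness(geom)
    else:
        t = geom.t_init / (lam_r * lam_t)
    return maxwell_stress(mat, voltage, t) * 1e-6


def _invert_lam_r(mat: YeohMaterial, p_target: float, lam_t: float, guess: float) -> float:
    """Solve P_r_elastic(lam_r, lam_t) = p_target for lam_r.

    Newton iteration with analytic derivative, bracketed brentq fallback.
    """
    lam = guess
    for _ in range(60):
        p_r, _ = _p_elastic(mat, lam, lam_t)
        err = p_r - p_target
        if abs(err) < 1e-13:
            return lam
        step = err / _dpr_dlamr(mat, lam, lam_t)
        new = lam - step
        if not 0.05 < new < 8.0:
            break
        lam = new
    else:
        return lam

    def h(l):
        return _p_elastic(mat, l, lam_t)[0] - p_target

    return brentq(h, 0.05, 8.0, xtol=1e-14)


def _integrate_annulus(
    mat: YeohMaterial,
    geom: MembraneGeometry,
    lam_c: float,
    grid_out: np.ndarray,
    voltage: float,
    convention: str,
):
    """RK4 from the electrode edge to the clamp; returns nodal (r, m, lam_r).

    States are r and m = R * P_r (total radial tension; elastic only in the
    annulus).  The initial condition applies traction continuity across the
    electrode edge: the uniform interior carries P_r_total = P_el(lam_c) -
    sigma_M / lam_c, and lam_r just outside the edge is the elastic stretch
    carrying the same tension at the same hoop stretch.
    """
    r_e = grid_out[0]
    sig_m = _sigma_m_mpa(mat, geom, voltage, lam_c, lam_c, convention)
    p_in, _ = _p_elastic(mat, lam_c, lam_c)
    p_tot = p_in - sig_m / lam_c
    lam_r0 = _invert_lam_r(mat, p_tot, lam_c, lam_c)

    n = grid_out.size
    r_arr = np.empty(n)
    m_arr = np.empty(n)
    lam_r_arr = np.empty(n)
    r, m = lam_c * r_e, r_e * p_tot
    lam_guess = lam_r0
    r_arr[0], m_arr[0], lam_r_arr[0] = r, m, lam_r0

    def rhs(R, r_val, m_val, guess):
        lam_t = r_val / R
        lam_r = _invert_lam_r(mat, m_val / R, lam_t, guess)
        _, p_t = _p_elastic(mat, lam_r, lam_t)
        return lam_r, p_t

    for i in range(n - 1):
        R0, R1 = grid_out[i], grid_out[i + 1]
        h = R1 - R0
        k1r, k1m = rhs(R0, r, m, lam_guess)
        k2r, k2m = rhs(R0 + h / 2, r + h / 2 * k1r, m + h / 2 * k1m, k1r)
        k3r, k3m = rhs(R0 + h / 2, r + h / 2 * k2r, m + h / 2 * k2m, k2r)
        k4r, k4m = rhs(R1, r + h * k3r, m + h * k3m, k3r)
        r = r + h / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
        m = m + h / 6 * (k1m + 2 * k2m + 2 * k3m + k4m)
        lam_guess, _ = rhs(R1, r, m, k4r)
        r_arr[i + 1], m_arr[i + 1], lam_r_arr[i + 1] = r, m, lam_guess

    return r_arr, m_arr, lam_r_arr


def solve_field(
    mat: YeohMaterial,
    geom: MembraneGeometry,
    voltage: float,
    n_nodes: int = 400,
    convention: str = "initial",
) -> AxisymmetricField:
    """Solve the axisymmetric membrane equilibrium field.

    Shooting on the center stretch lam_c with Brent bisection to 1e-10 in
    stretch; the mismatch function is the clamp condition
    r(frame_radius) - lam_p * frame_radius.  Raises :class:`SolverError`
    when no bracket exists or the clamp residual does not converge.
    """
    if n_nodes < 50:
        raise ValueError(f"n_nodes must be >= 50, got {n_nodes}")
    if voltage < 0:
        raise ValueError(f"voltage must be non-negative, got {voltage}")
    if convention not in ("initial", "true"):
        raise ValueError(f"unknown convention {convention!r}")

    lam_p = geom.lam_p
    b = geom.frame_radius
    r_e = geom.electrode_radius / lam_p  # electrode edge in reference coords

    # node split chosen so that doubling n_nodes doubles the annulus interval
    # count: nodal values at shared radii are then directly comparable under
    # mesh refinement (the interior field is uniform, so its node count is free)
    n_in = max(10, (n_nodes + 2) // 3)
    n_out = n_nodes - n_in
    grid_in = np.linspace(0.0, r_e, n_in)
    grid_out = np.linspace(r_e, b, n_out + 1)

    def mismatch(lam_c: float) -> float:
        r_arr, _, _ = _integrate_annulus(mat, geom, lam_c, grid_out, voltage, convention)
        return r_arr[-1] - lam_p * b

    # bracket the center stretch; at V=0 the root is exactly lam_p
    lo, hi = max(lam_p - 0.1, 1.0), min(lam_p + 1.0, 4.0)
    scan = np.linspace(lo, hi, 41)
    vals = np.array([mismatch(x) for x in scan])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise SolverError(
            f"shooting failed to bracket the center stretch in [{lo}, {hi}] "
            f"at {voltage} V; mismatch range [{vals.min():.3e}, {vals.max():.3e}] m"
        )
    i = sign_change[0]
    lam_c = brentq(mismatch, scan[i], scan[i + 1], xtol=1e-10)

    r_arr, m_arr, lam_r_out = _integrate_annulus(mat, geom, lam_c, grid_out, voltage, convention)
    clamp_resid = abs(r_arr[-1] - lam_p * b)
    if clamp_resid > 1e-8 * b:
        raise SolverError(f"clamp residual {clamp_resid:.3e} m did not converge")

    # assemble nodal field; the edge node belongs to the electrode (interior value)
    r_ref = np.concatenate([grid_in, grid_out[1:]])
    lam_r = np.concatenate([np.full(n_in, lam_c), lam_r_out[1:]])
    lam_t = np.concatenate(
        [np.full(n_in, lam_c), r_arr[1:] / grid_out[1:]]
    )

    # closure residual: stored lam_r must carry the stored radial tension
    resid = np.zeros_like(r_ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_r_out, _ = _p_elastic(mat, lam_r_out[1:], r_arr[1:] / grid_out[1:])
        resid[n_in:] = np.abs(p_r_out - m_arr[1:] / grid_out[1:]) / mat.c10

    strain_r = (lam_r - lam_p) / lam_p
    strain_t = (lam_t - lam_p) / lam_p
    return AxisymmetricField(
        r_ref=r_ref,
        lam_r=lam_r,
        lam_t=lam_t,
        strain_r_act=strain_r,
        strain_t_act=strain_t,
        residual=resid,
        lam_p=lam_p,
        electrode_radius_ref=r_e,
        voltage=voltage,
    )


def path_profile(
    field: AxisymmetricField, r_start: float, r_end: float, n_points: int = 200
) -> PathProfile:
    """Actuating strains along a radial segment (reference coordinates)."""
    if not 0 <= r_start < r_end <= field.frame_radius + 1e-15:
        raise ValueError(
            f"path [{r_start}, {r_end}] outside the field domain "
            f"[0, {field.frame_radius}]"
        )
    s = np.linspace(r_start, r_end, n_points)
    return PathProfile(
        arclength=s,
        strain_r=np.interp(s, field.r_ref, field.strain_r_act),
        strain_t=np.interp(s, field.r_ref, field.strain_t_act),
    )


def equiaxiality_index(field: AxisymmetricField, radius: float, floor: float = 1e-6) -> float:
    """|eps_r - eps_t| / max(|eps_r|, |eps_t|, floor) at a reference radius.

    Zero means perfectly equiaxial actuation; the floor guards the 0/0
    case of an unactuated field, for which 0 is returned.
    """
    if not 0 <= radius <= field.frame_radius + 1e-15:
        raise ValueError(f"radius {radius} outside the grid")
    er = float(np.interp(radius, field.r_ref, field.strain_r_act))
    et = float(np.interp(radius, field.r_ref, field.strain_t_act))
    denom = max(abs(er), abs(et))
    if denom < floor:
        return 0.0
    return abs(er - et) / denom
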