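"""Homogeneous electromechanical equilibrium and viscoelastic drift simulation.

The stretcher membrane is prestretched equibiaxially to ``lam_p`` and then
actuated by a voltage.  The homogeneous (single-stretch) model closes the
problem with a dead prestress: the passive annulus holds the in-plane true
stress at its prestretch value, so the equilibrium stretch lam >= lam_p
solves

    sigma_el(lam) = sigma_el(lam_p) + sigma_M(V, t),

where sigma_el is the equibiaxial Yeoh Cauchy stress and sigma_M the Maxwell
stress.  Two thickness conventions are offered for sigma_M:

* ``"initial"`` (the default): t is frozen at the post-prestretch thickness
  t_init / lam_p**2, so sigma_M is independent of lam and no electromechanical
  pull-in exists.
* ``"true"``: t = t_init / lam**2 follows the deformation; sigma_M then grows
  as lam**4 and a snap-through voltage exists.

Actuating strain is engineering strain relative to the prestretched state,
(lam - lam_p) / lam_p.

Viscoelastic warm-up and cyclic drift are modeled phenomenologically: a
Prony-type multi-exponential creep kernel on top of the elastic equilibrium
strain, optionally gated by a cyclic conditioning state (Mullins-type
softening that accumulates at loading onsets and under sustained load and
does not recover).  The shipped :func:`default_drift` profile is frozen; see
docs/methods.md for how it was chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .materials import YeohMaterial, equibiaxial_cauchy_stress, maxwell_stress
from .measurement import StrainTrace

__all__ = [
    "MembraneGeometry",
    "ActuationResult",
    "DriftModel",
    "InstabilityError",
    "DEFAULT_GEOMETRY",
    "prestretch_thickness",
    "solve_actuation",
    "voltage_sweep",
    "snap_through_voltage",
    "simulate_static_tests",
    "simulate_cyclic",
    "default_drift",
]

#: Upper end of the stretch bracket for the equilibrium root; coincides
#: with the constitutive validity window.
LAM_MAX = 4.0

_CONVENTIONS = ("initial", "true")


class InstabilityError(RuntimeError):
    """No stable equilibrium stretch in the bracket (electromechanical pull-in)."""

    def __init__(self, message: str, bracket: tuple[float, float], voltage: float):
        super().__init__(message)
        self.bracket = bracket
        self.voltage = voltage


@dataclass(frozen=True)
class MembraneGeometry:
    """Membrane and frame geometry.

    ``t_init`` is the unstretched film thickness (m); ``lam_p`` the radial
    prestretch ratio; ``electrode_radius`` the active-zone radius in the
    prestretched configuration (m); ``frame_radius`` the clamped inner-frame
    radius in the reference configuration (m).
    """

    t_init: float = 1.0e-3
    lam_p: float = 3.0
    electrode_radius: float = 5.85e-3
    frame_radius: float = 30.0e-3

    def __post_init__(self) -> None:
        if self.t_init <= 0:
            raise ValueError(f"t_init must be positive, got {self.t_init}")
        if self.lam_p < 1:
            raise ValueError(f"lam_p must be >= 1, got {self.lam_p}")
        if not 0 < self.electrode_radius < self.frame_radius:
            raise ValueError("require 0 < electrode_radius < frame_radius")


DEFAULT_GEOMETRY = MembraneGeometry()


def prestretch_thickness(geom: MembraneGeometry) -> float:
    """Thickness after equibiaxial prestretch, t_init / lam_p**2 (incompressible)."""
    return geom.t_init / geom.lam_p**2


@dataclass(frozen=True)
class ActuationResult:
    lam_total: float
    strain_act: float
    sigma_m: float  # Maxwell stress at equilibrium, Pa
    stable: bool


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")


def _residual_mpa(
    mat: YeohMaterial, geom: MembraneGeometry, lam: float, voltage: float, convention: str
) -> float:
    """sigma_el(lam) - sigma_el(lam_p) - sigma_M, in MPa."""
    if convention == "initial":
        t = prestretch_thickness(geom)
    else:
        t = geom.t_init / lam**2
    sm = maxwell_stress(mat, voltage, t) * 1e-6  # Pa -> MPa
    return (
        equibiaxial_cauchy_stress(mat, lam)
        - equibiaxial_cauchy_stress(mat, geom.lam_p)
        - sm
    )


def solve_actuation(
    mat: YeohMaterial,
    geom: MembraneGeometry,
    voltage: float,
    convention: str = "initial",
) -> ActuationResult:
    """Equilibrium stretch under a constant voltage.

    Finds the smallest root lam >= lam_p of
    sigma_el(lam) = sigma_el(lam_p) + sigma_M(V, t(lam)) by bisection
    (Brent) on the bracket [lam_p, 4] to 1e-10 in stretch.  Raises
    :class:`InstabilityError` when the bracket contains no root
    (snap-through under the "true" convention).
    """
    _check_convention(convention)
    if voltage < 0:
        raise ValueError(f"voltage must be non-negative, got {voltage}")

    lam_p = geom.lam_p

    def f(lam: float) -> float:
        return _residual_mpa(mat, geom, lam, voltage, convention)

    if voltage == 0:
        lam = lam_p
    else:
        f_lo = f(lam_p)  # = -sigma_M <= 0
        f_hi = f(LAM_MAX)
        if f_hi < 0:
            raise InstabilityError(
                f"no equilibrium stretch in [{lam_p}, {LAM_MAX}] at {voltage} V "
                "(electromechanical snap-through)",
                bracket=(lam_p, LAM_MAX),
                voltage=voltage,
            )
        lam = brentq(f, lam_p, LAM_MAX, xtol=1e-10) if f_lo < 0 else lam_p

    if convention == "initial":
        t_eq = prestretch_thickness(geom)
    else:
        t_eq = geom.t_init / lam**2
    sigma_m = maxwell_stress(mat, voltage, t_eq)
    # stable when the net restoring force stiffens with stretch at the root
    h = 1e-6
    stable = (f(min(lam + h, LAM_MAX)) - f(max(lam - h, geom.lam_p * (1 - 1e-12)))) > 0 or voltage == 0
    strain_act = (lam - lam_p) / lam_p
    return ActuationResult(lam_total=lam, strain_act=strain_act, sigma_m=sigma_m, stable=stable)


def voltage_sweep(
    mat: YeohMaterial,
    geom: MembraneGeometry,
    voltages,
    convention: str = "initial",
) -> list[ActuationResult]:
    """Element-wise :func:`solve_actuation`; output order follows input order."""
    results = []
    for v in voltages:
        try:
            results.append(solve_actuation(mat, geom, float(v), convention))
        except InstabilityError as err:
            raise InstabilityError(
                f"instability at sweep voltage {v} V: {err}", err.bracket, float(v)
            ) from err
    return results


def _solvable(mat: YeohMaterial, geom: MembraneGeometry, voltage: float, convention: str) -> bool:
    """Whether the equilibrium equation has a root in [lam_p, LAM_MAX].

    The residual is -sigma_M <= 0 at lam_p, so a root exists iff the
    residual becomes non-negative somewhere in the bracket; checked on a
    dense stretch grid.
    """
    lams = np.linspace(geom.lam_p, LAM_MAX, 2001)
    if convention == "initial":
        t = np.full_like(lams, prestretch_thickness(geom))
    else:
        t = geom.t_init / lams**2
    vals = (
        equibiaxial_cauchy_stress(mat, lams)
        - equibiaxial_cauchy_stress(mat, geom.lam_p)
        - maxwell_stress(mat, voltage, t) * 1e-6
    )
    return bool(np.any(vals >= 0))


def snap_through_voltage(
    mat: YeohMaterial,
    geom: MembraneGeometry,
    convention: str = "true",
    v_max: float = 20000.0,
    v_tol: float = 1.0,
) -> float | None:
    """Smallest voltage in (0, v_max] at which the stable root is lost.

    Diagnostic for the thickness-coupled ("true") convention, where the
    Maxwell stress grows as lam**4 and pull-in occurs.  Under the
    "initial" convention sigma_M does not feed back on the stretch, there
    is no pull-in mechanism, and None is returned.  Found by bisection on
    solvability to ``v_tol`` volts; returns None when stable throughout.
    """
    _check_convention(convention)
    if v_max <= 0:
        raise ValueError(f"v_max must be positive, got {v_max}")
    if convention == "initial":
        return None
    if _solvable(mat, geom, v_max, convention):
        return None
    lo, hi = 0.0, v_max  # solvable at lo, unsolvable at hi
    while hi - lo > v_tol:
        mid = 0.5 * (lo + hi)
        if _solvable(mat, geom, mid, convention):
            lo = mid
        else:
            hi = mid
    return hi


# ---------------------------------------------------------------------------
# Phenomenological viscoelastic drift
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftModel:
    """Prony-type creep kernel with optional cyclic conditioning.

    ``g`` are relaxation amplitudes in (0, 1) with sum < 1 and ``tau`` the
    matching time constants (s).  The observable strain is

        eps(t) = eps_el(V(t)) + c(t) * sum_k a_k * s_k(t),

    with creep amplitudes a_k = g_k / (1 - sum g), internal states s_k
    tracking eps_el(V(t)) with time constant tau_k, and a conditioning
    state c that starts at ``cond0``, jumps by ``cond_kappa * (1 - c)`` at
    every loading onset, grows toward 1 with time constant ``cond_tau``
    while loaded, and never recovers.  Under sustained load the strain
    creeps from the elastic value eps_el toward eps_el / (1 - sum g).

    The default constructor disables conditioning (``cond0 = 1``), so a
    bare Prony model behaves as a linear viscoelastic kernel: with a
    single term and full recovery between tests all tests coincide, and
    with ``g`` empty the response is purely elastic.
    """

    g: tuple[float, ...] = ()
    tau: tuple[float, ...] = ()
    cond0: float = 1.0
    cond_kappa: float = 0.0
    cond_tau: float = math.inf

    def __post_init__(self) -> None:
        if len(self.g) != len(self.tau):
            raise ValueError("g and tau must have equal length")
        if any(not 0 < gk < 1 for gk in self.g):
            raise ValueError("all g_k must lie in (0, 1)")
        if sum(self.g) >= 1:
            raise ValueError("sum of g_k must be < 1")
        if any(tk <= 0 for tk in self.tau):
            raise ValueError("all tau_k must be positive")
        if not 0 < self.cond0 <= 1:
            raise ValueError("cond0 must lie in (0, 1]")
        if not 0 <= self.cond_kappa < 1:
            raise ValueError("cond_kappa must lie in [0, 1)")
        if self.cond_tau <= 0:
            raise ValueError("cond_tau must be positive")

    @property
    def n_terms(self) -> int:
        return len(self.g)

    @property
    def creep_amplitudes(self) -> np.ndarray:
        g = np.asarray(self.g, dtype=float)
        return g / (1.0 - g.sum()) if g.size else g


def default_drift() -> DriftModel:
    """Frozen default drift profile for the VHB 4910 stretcher.

    Three Prony terms spanning second-to-minute time scales plus cyclic
    conditioning.  Calibrated once against the device's documented warm-up
    (static response settling within a handful of repeated tests) and its
    0-5 kV cyclic steady band of roughly 5-13% strain; see docs/methods.md.
    """
    return DriftModel(
        g=(0.25, 0.25, 0.20),
        tau=(1.0, 8.0, 25.0),
        cond0=0.35,
        cond_kappa=0.12,
        cond_tau=150.0,
    )


class _DriftState:
    """Exact piecewise-exponential integrator for the drift kernel."""

    def __init__(self, drift: DriftModel):
        self.drift = drift
        self.tau = np.asarray(drift.tau, dtype=float)
        self.a = drift.creep_amplitudes
        self.s = np.zeros_like(self.tau)
        self.c = drift.cond0

    def onset(self) -> None:
        """Loading onset: conditioning jump."""
        self.c += self.drift.cond_kappa * (1.0 - self.c)

    def advance(self, eps_el: float, dt: float, loaded: bool) -> None:
        """Advance the internal states over a constant-load segment of dt s."""
        if self.tau.size:
            decay = np.exp(-dt / self.tau)
            self.s = eps_el + (self.s - eps_el) * decay
        if loaded and math.isfinite(self.drift.cond_tau):
            self.c = 1.0 - (1.0 - self.c) * math.exp(-dt / self.drift.cond_tau)

    def sample(self, eps_el: float, dt: np.ndarray, loaded: bool):
        """Observable strain at offsets ``dt`` into the current segment."""
        if self.tau.size:
            decay = np.exp(-dt[:, None] / self.tau[None, :])
            s = eps_el + (self.s[None, :] - eps_el) * decay
            creep = s @ self.a
        else:
            creep = np.zeros_like(dt)
        if loaded and math.isfinite(self.drift.cond_tau):
            c = 1.0 - (1.0 - self.c) * np.exp(-dt / self.drift.cond_tau)
        else:
            c = np.full_like(dt, self.c)
        return eps_el + c * creep


def simulate_static_tests(
    mat: YeohMaterial,
    geom: MembraneGeometry,
    drift: DriftModel,
    voltage: float,
    n_tests: int,
    hold_s: float = 60.0,
    relax_s: float = 600.0,
) -> np.ndarray:
    """Repeated hold/relax static tests with creep memory across tests.

    Each test applies ``voltage`` for ``hold_s`` seconds and then rests at
    zero voltage for ``relax_s`` seconds; the reported per-test strain
    (engineering, relative to prestretch) is the value at the end of each
    hold.  The sequence is non-decreasing and converges to an asymptote;
    with the default profile the device is warmed up after about six tests.
    """
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if hold_s <= 0 or relax_s <= 0:
        raise ValueError("hold_s and relax_s must be positive")
    eps_on = solve_actuation(mat, geom, voltage, "initial").strain_act
    state = _DriftState(drift)
    out = np.empty(n_tests)
    for i in range(n_tests):
        state.onset()
        out[i] = float(state.sample(eps_on, np.array([hold_s]), loaded=True)[0])
        state.advance(eps_on, hold_s, loaded=True)
        state.advance(0.0, relax_s, loaded=False)
    return out


def simulate_cyclic(
    mat: YeohMaterial,
    geom: MembraneGeometry,
    drift: DriftModel,
    v_low: float,
    v_high: float,
    freq: float,
    duty: float = 0.5,
    duration: float = 60.0,
    sample_rate: float = 50.0,
) -> StrainTrace:
    """Strain trace under a square-wave voltage with viscoelastic drift.

    The voltage is ``v_high`` during the leading ``duty`` fraction of each
    period and ``v_low`` otherwise.  The creep kernel is integrated exactly
    on each constant-voltage segment; per-cycle maxima and minima both
    drift upward and the trace approaches a periodic steady state.
    Returns a percent-strain :class:`~stretchlab.measurement.StrainTrace`
    sampled uniformly at ``sample_rate``.
    """
    if not 0 <= v_low < v_high:
        raise ValueError("require 0 <= v_low < v_high")
    if not 0 < duty < 1:
        raise ValueError(f"duty must lie in (0, 1), got {duty}")
    if freq <= 0 or duration <= 0:
        raise ValueError("freq and duration must be positive")
    if sample_rate <= 2 * freq:
        raise ValueError(
            f"sample_rate {sample_rate} Hz cannot resolve a {freq} Hz square wave"
        )

    eps_hi = solve_actuation(mat, geom, v_high, "initial").strain_act
    eps_lo = solve_actuation(mat, geom, v_low, "initial").strain_act

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    strain = np.empty(n)

    period = 1.0 / freq
    state = _DriftState(drift)
    seg_start = 0.0
    k = 0  # half-segment counter: even -> high, odd -> low
    i = 0
    while i < n:
        on = k % 2 == 0
        seg_end = (k // 2) * period + (duty * period if on else period)
        eps = eps_hi if on else eps_lo
        if on:
            state.onset()
        j = i
        while j < n and t[j] < seg_end - 1e-12:
            j += 1
        if j > i:
            strain[i:j] = state.sample(eps, t[i:j] - seg_start, loaded=on)
        state.advance(eps, seg_end - seg_start, loaded=on)
        seg_start = seg_end
        i = j
        k += 1

    return StrainTrace(time=t, strain=strain * 100.0, sample_rate=sample_rate, unit="percent")
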