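"""Elastic mechanics of a taut fiber retracting after a cut.

The fiber is modelled as a slender elastic rod of radius ``r_f`` held
under tension (elongation dL over rest length L) in a viscous fluid.
The pulling force is F_p = pi r_f^2 E dL/L; cutting the fiber lets the
deformation relax from the free end over a growing "flower" of size x,
where the balance of elastic pull against viscous drag yields a stress-
diffusion law x^2 ~ D t with

    D = pi r_f^2 E / eta = r_f^2 / tau,

eta the fluid viscosity and tau the material relaxation time.  The
observable free-end retraction is X(t) = c sqrt(D t) dL/L with a
dimensionless prefactor c (default 2/sqrt(pi), the standard 1-D
diffusion-front constant; configurable because the exact constant of
the experiment is not pinned down).  The slender-body drag logarithm
2 pi / ln(L/r_f) is folded into c by default; an exact-log form of the
friction force is available for sensitivity analysis.

All functions work in SI units; thin unit helpers cover the reporting
units used at interfaces (mm^2/s, um, ns, ms, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = [
    "DEFAULT_PREFACTOR", "DEFAULT_VISCOSITY", "DEFAULT_RADIUS",
    "MechanicalParameters", "pulling_force", "friction_force",
    "retraction_trajectory", "diffusion_from_slope", "tau_from_D",
    "rupture_time", "youngs_modulus", "tension_profile", "total_cilia",
]

DEFAULT_PREFACTOR = 2.0 / math.sqrt(math.pi)
DEFAULT_VISCOSITY = 1.0e-3   # Pa s, water-like CSF
DEFAULT_RADIUS = 100e-9      # m


def pulling_force(E: float, r_f: float, strain: float) -> float:
    """Elastic pulling force F_p = pi r_f^2 E (dL/L), in newtons."""
    _require_nonneg(E=E, r_f=r_f, strain=strain)
    return math.pi * r_f**2 * E * strain


def friction_force(eta: float, x: float, x_dot: float, strain: float,
                   exact_log: bool = False, L: float | None = None,
                   r_f: float = DEFAULT_RADIUS) -> float:
    """Viscous drag on the relaxing flower of size ``x``.

    Default (reduced) form folds the slender-body logarithm into the
    retraction-law prefactor: F_v = eta x x_dot (dL/L).  With
    ``exact_log`` the full factor 2 pi / ln(L/r_f) is applied.
    """
    _require_nonneg(eta=eta, x=x, strain=strain)
    f = eta * x * x_dot * strain
    if exact_log:
        if L is None or L <= r_f:
            raise ValueError("exact_log form needs L > r_f")
        f *= 2.0 * math.pi / math.log(L / r_f)
    return f


def retraction_trajectory(D: float, strain: float, t,
                          c: float = DEFAULT_PREFACTOR) -> np.ndarray:
    """Free-end retraction X(t) = c sqrt(D t) (dL/L), SI units (m, s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    _require_nonneg(D=D, strain=strain, c=c)
    return c * np.sqrt(D * t) * strain


def diffusion_from_slope(alpha: float, strain: float,
                         c: float = DEFAULT_PREFACTOR) -> float:
    """Stress diffusion coefficient from a fitted sqrt-time slope.

    X(t) = alpha sqrt(t) with alpha = c sqrt(D) (dL/L), so
    D = (alpha / (c strain))^2.  ``alpha`` in m/sqrt(s), D in m^2/s.
    """
    if strain <= 0 or c <= 0:
        raise ValueError("strain and prefactor must be positive")
    if alpha < 0:
        raise ValueError("slope must be >= 0 for a retracting end")
    return (alpha / (c * strain)) ** 2


def tau_from_D(r_f: float, D: float) -> float:
    """Material relaxation time tau = r_f^2 / D, in seconds."""
    if D <= 0:
        raise ValueError("D must be positive")
    _require_nonneg(r_f=r_f)
    return r_f**2 / D


def rupture_time(L: float, D: float) -> float:
    """Total retraction time T_rup = L^2 / D = tau (L/r_f)^2, seconds."""
    if L <= 0 or D <= 0:
        raise ValueError("L and D must be positive")
    return L**2 / D


def youngs_modulus(D: float, eta: float, r_f: float) -> float:
    """Young modulus from the diffusion identity: E = D eta / (pi r_f^2)."""
    if D <= 0 or eta <= 0 or r_f <= 0:
        raise ValueError("D, eta and r_f must be positive")
    return D * eta / (math.pi * r_f**2)


def tension_profile(mode: str, l, L: float, *, D: float | None = None,
                    U: float | None = None, E: float | None = None,
                    r_f: float = DEFAULT_RADIUS, nu: float | None = None,
                    f_p: float | None = None):
    """Rostrocaudal tension build-up under flow or cilia forcing.

    ``l`` is the distance from the caudal end (0 <= l <= L), SI units.

    flow mode
        CSF flowing rostral-to-caudal at speed ``U`` drags the fiber;
        strain(l) = U l / D, maximal at the rostral end l = L.  The force
        profile F_p(l) = pi r_f^2 E strain(l) is returned when E given.
    cilia mode
        ``nu`` cilia-fiber links per metre each pulling with force
        ``f_p`` accumulate F_p(l) = nu f_p l; strain(l) =
        F_p(l) / (pi r_f^2 E).

    Returns ``(force, strain)`` arrays (force is None in flow mode when
    E is not supplied).  Both profiles are non-decreasing in l.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0) or np.any(l > L):
        raise ValueError("positions l must satisfy 0 <= l <= L")
    if mode == "flow":
        if U is None or D is None:
            raise ValueError("flow mode needs U and D")
        strain = U * l / D
        force = None if E is None else math.pi * r_f**2 * E * strain
    elif mode == "cilia":
        if nu is None or f_p is None:
            raise ValueError("cilia mode needs nu and f_p")
        force = nu * f_p * l
        if E is None:
            raise ValueError("cilia mode needs E to convert force to strain")
        strain = force / (math.pi * r_f**2 * E)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'flow' or 'cilia'")
    return force, strain


def total_cilia(linear_density_per_um: float = 6.0,
                canal_length_um: float = 3500.0) -> float:
    """Total motile-cilium count along the central canal.

    Defaults: ~60 cilia per 10 um of canal, canal length 3.5 mm.
    """
    _require_nonneg(linear_density_per_um=linear_density_per_um,
                    canal_length_um=canal_length_um)
    return linear_density_per_um * canal_length_um


@dataclass
class MechanicalParameters:
    """Consistent parameter set of the fiber model (SI units).

    Any subset may be given; :meth:`completed` fills derivable fields via
    the identity chain D = pi r_f^2 E / eta = r_f^2 / tau and checks
    consistency of over-determined inputs to relative round-off.
    """

    r_f: float = DEFAULT_RADIUS      # m
    eta: float = DEFAULT_VISCOSITY   # Pa s
    L: float | None = None           # m
    delta_L: float | None = None     # m
    E: float | None = None           # Pa
    D: float | None = None           # m^2/s
    tau: float | None = None         # s
    prefactor: float = DEFAULT_PREFACTOR

    @property
    def strain(self) -> float | None:
        if self.delta_L is None or self.L is None:
            return None
        return self.delta_L / self.L

    def completed(self, rtol: float = 1e-9) -> "MechanicalParameters":
        D, E, tau = self.D, self.E, self.tau
        if D is None and E is not None:
            D = math.pi * self.r_f**2 * E / self.eta
        if D is None and tau is not None:
            D = self.r_f**2 / tau
        if D is None:
            raise ValueError("need at least one of D, E, tau")
        E2 = youngs_modulus(D, self.eta, self.r_f)
        tau2 = tau_from_D(self.r_f, D)
        for name, given, derived in (("E", E, E2), ("tau", tau, tau2),
                                     ("D", self.D, D)):
            if given is not None and not math.isclose(given, derived,
                                                      rel_tol=rtol):
                raise ValueError(
                    f"inconsistent {name}: given {given}, derived {derived}")
        return MechanicalParameters(
            r_f=self.r_f, eta=self.eta, L=self.L, delta_L=self.delta_L,
            E=E2, D=D, tau=tau2, prefactor=self.prefactor)

    def report(self) -> dict:
        """Quantities in the units used at interfaces."""
        p = self.completed()
        out = {
            "r_f_nm": p.r_f * 1e9,
            "eta_mPa_s": p.eta * 1e3,
            "D_mm2_per_s": p.D * 1e6,
            "tau_ns": p.tau * 1e9,
            "E_Pa": p.E,
            "prefactor": p.prefactor,
        }
        if p.L is not None:
            out["L_mm"] = p.L * 1e3
            out["T_rup_ms"] = rupture_time(p.L, p.D) * 1e3
        if p.strain is not None:
            out["strain"] = p.strain
        return out


def _require_nonneg(**kwargs) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
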