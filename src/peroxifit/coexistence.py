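"""Liquid-vapor slab analysis: density profiles, phase partitioning, vapor
pressure, surface tension, boiling point and critical-point estimation.

A liquid slab equilibrated with its vapor in a prismatic (1x1x3) cell yields
a z-density profile with two interfaces.  Bulk densities come from a
two-interface hyperbolic-tangent fit; the coexistence curve over temperature
feeds the law of rectilinear diameters and the order-parameter scaling law
(critical exponent beta = 0.32, fixed) for the critical point, and the
vapor-pressure curve gives the boiling temperature and, via
Clausius-Clapeyron, the enthalpy of vaporization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .constants import M_H2O, M_H2O2, R_J

__all__ = [
    "SlabProfile",
    "CoexistencePoint",
    "CriticalFit",
    "slab_density_profiles",
    "partition_phases",
    "phase_weight_percent",
    "vapor_pressure",
    "surface_tension",
    "boiling_temperature",
    "critical_point",
    "clausius_clapeyron_dhvap",
]

#: Fixed Ising-like order-parameter critical exponent.
BETA_EXPONENT = 0.32

#: Standard atmosphere used for the boiling-point crossing, bar.
P_BOIL = 1.013

#: Molar masses by species label, g/mol.
MOLAR_MASS = {"H2O2": M_H2O2, "H2O": M_H2O}


@dataclass
class SlabProfile:
    """z-binned mass-density profile (kg/m^3) per species in an orthorhombic box."""

    z: np.ndarray
    density: dict
    box: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.density = {k: np.asarray(v, dtype=float) for k, v in self.density.items()}
        dz = np.diff(self.z)
        if len(dz) and not np.allclose(dz, dz[0]):
            raise ValueError("bins must be uniform")
        for k, v in self.density.items():
            if len(v) != len(self.z):
                raise ValueError("density arrays must match z bins")
            if np.any(v < -1e-12):
                raise ValueError("densities must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.density.values()), axis=0)


@dataclass(frozen=True)
class CoexistencePoint:
    """One coexistence state: T (K), bulk densities (kg/m^3), vapor pressure
    (bar) and weight-percent compositions of the two phases."""

    T: float
    rho_l: float
    rho_v: float
    P_v: float | None = None
    wt_l: float | None = None
    wt_v: float | None = None

    def __post_init__(self) -> None:
        if not self.rho_l > self.rho_v >= 0:
            raise ValueError("need rho_l > rho_v >= 0")


@dataclass(frozen=True)
class CriticalFit:
    """Critical-point estimate: T_c (K), rho_c (kg/m^3), optional P_c (bar),
    rectilinear slope A, scaling amplitude B; beta is fixed, not fitted."""

    T_c: float
    rho_c: float
    A: float
    B: float
    beta: float = BETA_EXPONENT
    P_c: float | None = None


def slab_density_profiles(
    positions: np.ndarray,
    masses: np.ndarray,
    species: np.ndarray,
    box,
    n_bins: int = 100,
) -> SlabProfile:
    """Per-species mass-density profile along z (the long axis).

    Site masses (amu) are histogrammed into ``n_bins`` uniform z bins and
    normalized to kg/m^3; the sum over bins times the bin volume equals the
    total mass exactly.
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    species = np.asarray(species)
    box = np.asarray(box, dtype=float)
    if len(positions) == 0:
        raise ValueError("empty selection")
    lz = box[2]
    z = positions[:, 2] % lz
    edges = np.linspace(0.0, lz, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_vol_nm3 = box[0] * box[1] * lz / n_bins
    amu_per_nm3_to_kg_m3 = 1.66053906660  # 1 amu/nm^3 = 1.6605 kg/m^3
    density = {}
    for sp in np.unique(species):
        sel = species == sp
        hist, _ = np.histogram(z[sel], bins=edges, weights=masses[sel])
        density[str(sp)] = hist / bin_vol_nm3 * amu_per_nm3_to_kg_m3
    return SlabProfile(z=centers, density=density, box=box)


def _two_interface_tanh(z, rho_v, rho_l, z1, z2, w):
    return rho_v + 0.5 * (rho_l - rho_v) * (np.tanh((z - z1) / w) - np.tanh((z - z2) / w))


def partition_phases(profile: SlabProfile, species: str | None = None) -> dict:
    """Bulk liquid/vapor densities from a two-interface tanh fit.

    Fits rho(z) = rho_v + (rho_l - rho_v)/2 [tanh((z-z1)/w) - tanh((z-z2)/w)]
    and returns the plateau densities, interface positions and width.  A
    profile without density contrast signals single-phase input.
    """
    rho = profile.total if species is None else profile.density[species]
    z = profile.z
    lo, hi = float(rho.min()), float(rho.max())
    if hi - lo < 0.05 * max(hi, 1e-12):
        raise ValueError("single-phase input: no density contrast in profile")
    # initial guesses from the half-max crossings of the dense region
    above = rho > 0.5 * (lo + hi)
    idx = np.where(above)[0]
    z1_0, z2_0 = z[idx[0]], z[idx[-1]]
    p0 = [lo, hi, z1_0, z2_0, 0.3]
    popt, _ = curve_fit(
        _two_interface_tanh, z, rho, p0=p0,
        bounds=([0, 0, z[0], z[0], 1e-3], [hi * 2 + 1, hi * 2 + 1, z[-1], z[-1], z[-1] - z[0]]),
        maxfev=20000,
    )
    rho_v, rho_l, z1, z2, w = popt
    if rho_l < rho_v:
        raise ValueError("fit collapsed: liquid density below vapor density")
    return {
        "rho_l": float(rho_l),
        "rho_v": float(rho_v),
        "interfaces": (float(z1), float(z2)),
        "width": float(w),
    }


def phase_weight_percent(rho_peroxide: float, rho_water: float) -> float:
    """Weight percent of peroxide in a phase: 100 rho_per / (rho_per + rho_wat)."""
    if rho_peroxide < 0 or rho_water < 0:
        raise ValueError("densities must be non-negative")
    tot = rho_peroxide + rho_water
    if tot == 0:
        raise ValueError("both species zero: composition undefined")
    return 100.0 * rho_peroxide / tot


def vapor_pressure(
    P_zz: float | None = None,
    rho_v: dict | float | None = None,
    T: float | None = None,
    switch_bar: float = 2.0,
) -> dict:
    """Vapor pressure (bar) by the virial or ideal-gas route.

    The virial route returns the mean normal pressure component <P_zz>.
    The ideal route converts per-species vapor mass densities (kg/m^3) to
    pressure, P = sum_s (rho_s / M_s) R T.  When the virial value falls below
    ``switch_bar`` (2 bar) the ideal route takes over, mirroring the loss of
    precision of the virial estimate at low vapor density.
    """
    ideal = None
    if rho_v is not None:
        if T is None or T <= 0:
            raise ValueError("ideal route needs T > 0")
        if isinstance(rho_v, dict):
            comps = rho_v.items()
        else:
            comps = [("H2O2", float(rho_v))]
        p_pa = 0.0
        for sp, r in comps:
            if r < 0:
                raise ValueError("negative vapor density")
            p_pa += r / (MOLAR_MASS[sp] * 1e-3) * R_J * T
        ideal = p_pa / 1e5
    if P_zz is not None and P_zz >= switch_bar:
        return {"P_v": float(P_zz), "route": "virial"}
    if ideal is not None:
        return {"P_v": float(ideal), "route": "ideal"}
    if P_zz is not None:
        return {"P_v": float(P_zz), "route": "virial"}
    raise ValueError("provide P_zz and/or (rho_v, T)")


def surface_tension(P_xx: float, P_yy: float, P_zz: float, L_z: float) -> float:
    """Virial-route surface tension of a two-interface slab (mN/m).

    lambda = (L_z / 2) [<P_zz> - (<P_xx> + <P_yy>)/2]; pressures in bar, L_z
    in nm.  Positive when the normal component exceeds the lateral mean.
    """
    if L_z <= 0:
        raise ValueError("L_z must be positive")
    anis_bar = P_zz - 0.5 * (P_xx + P_yy)
    return 0.5 * L_z * anis_bar * 0.1  # bar*nm -> mN/m


def boiling_temperature(T: np.ndarray, P_v: np.ndarray, n_low: int = 3) -> float:
    """Boiling temperature from a quadratic fit of P_v(T) crossing 1.013 bar.

    Uses the ``n_low`` smallest pressures bracketing the crossing (default 3,
    extended until the bracket is covered); the root inside the data range is
    returned.
    """
    T = np.asarray(T, dtype=float)
    P_v = np.asarray(P_v, dtype=float)
    if len(T) < 3:
        raise ValueError("need at least 3 points")
    order = np.argsort(P_v)
    k = max(n_low, 3)
    while k <= len(T):
        sel = np.sort(order[:k])
        if P_v[sel].min() <= P_BOIL <= P_v[sel].max():
            break
        k += 1
    else:
        raise ValueError("vapor-pressure data do not bracket 1.013 bar")
    Ts, Ps = T[sel], P_v[sel]
    t0 = Ts.mean()
    c = np.polynomial.polynomial.polyfit(Ts - t0, Ps, 2)
    roots = np.roots([c[2], c[1], c[0] - P_BOIL]) + t0
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots >= Ts.min() - 1e-9) & (roots <= Ts.max() + 1e-9)]
    if len(inside) == 0:
        raise ValueError("no crossing of 1.013 bar inside the data range")
    return float(inside[np.argmin(np.abs(inside - t0))])


def critical_point(
    T: np.ndarray,
    rho_l: np.ndarray,
    rho_v: np.ndarray,
    P_v: np.ndarray | None = None,
) -> CriticalFit:
    """Critical point from rectilinear diameters + the beta = 0.32 scaling law.

    Simultaneous least squares of (rho_l + rho_v)/2 = rho_c + A (T_c - T) and
    rho_l - rho_v = B (T_c - T)^0.32 over (T_c, rho_c, A, B).  When a P_v
    table is supplied, P_c follows from a linear fit of ln P_v vs 1/T
    extrapolated to T_c.
    """
    T = np.asarray(T, dtype=float)
    rho_l = np.asarray(rho_l, dtype=float)
    rho_v = np.asarray(rho_v, dtype=float)
    if len(T) < 4:
        raise ValueError("need at least 4 temperatures")
    if np.any(rho_l <= rho_v):
        raise ValueError("rho_l must exceed rho_v at every temperature")
    mean = 0.5 * (rho_l + rho_v)
    diff = rho_l - rho_v

    t_max = T.max()

    def resid(p):
        t_c, rho_c, a, b = p
        dt = np.clip(t_c - T, 1e-12, None)
        return np.concatenate(
            [mean - (rho_c + a * dt), diff - b * dt**BETA_EXPONENT]
        )

    # initial guesses: diff^(1/beta) is linear in T and vanishes at T_c
    m, q = np.polyfit(T, diff ** (1.0 / BETA_EXPONENT), 1)
    t_c0 = -q / m if m < 0 else t_max + 0.2 * np.ptp(T) + 1.0
    t_c0 = max(t_c0, t_max + 1.0)
    b0 = max(-m, 1e-12) ** BETA_EXPONENT
    md, qd = np.polyfit(T, mean, 1)
    a0 = max(-md, 1e-6)
    rho_c0 = max(md * t_c0 + qd, 1.0)
    res = least_squares(
        resid,
        x0=[t_c0, rho_c0, a0, b0],
        bounds=([t_max + 1e-6, 0.0, -np.inf, 0.0], np.inf),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"critical-point fit failed: {res.message}")
    t_c, rho_c, a, b = res.x
    p_c = None
    if P_v is not None:
        P_v = np.asarray(P_v, dtype=float)
        slope, intercept = np.polyfit(1.0 / T, np.log(P_v), 1)
        p_c = float(np.exp(intercept + slope / t_c))
    return CriticalFit(T_c=float(t_c), rho_c=float(rho_c), A=float(a), B=float(b), P_c=p_c)


def clausius_clapeyron_dhvap(T: np.ndarray, P_v: np.ndarray) -> float:
    """Enthalpy of vaporization (kJ/mol) from Clausius-Clapeyron.

    Two points use the closed form ln(P1/P2) = Delta H (1/T2 - 1/T1)/R; more
    points use the least-squares slope of ln P_v vs 1/T times -R.
    """
    T = np.asarray(T, dtype=float)
    P_v = np.asarray(P_v, dtype=float)
    if len(T) < 2:
        raise ValueError("need at least two points")
    if len(np.unique(T)) < len(T):
        raise ValueError("temperatures must be distinct")
    if np.any(P_v <= 0):
        raise ValueError("pressures must be positive")
    slope = np.polyfit(1.0 / T, np.log(P_v), 1)[0]
    return float(-slope * R_J * 1e-3)
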