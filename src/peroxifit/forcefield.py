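"""The four-site pairwise-additive hydrogen peroxide model.

The molecule is an H1-O1-O2-H2 bonded chain.  Bonded interactions are
harmonic bonds and angles plus a Ryckaert-Bellemans (RB) torsion whose six
coefficients all derive from a single scale ``c2`` through fixed constraints
(c0 = 0.312 c2, c1 = -c2, c3 = 0.300 c2, c4 = c5 = 0).  Nonbonded
interactions are a Lennard-Jones potential on the oxygen sites only and
Coulomb interactions between partial charges +q_H on each hydrogen and -q_H
on each oxygen.  Intramolecular LJ is always excluded; intramolecular
Coulomb is either fully excluded (default) or the 1-4 H-H pair is kept at
half strength in the OPLS convention.

Dihedral convention: ``a_d`` is the IUPAC torsion (cis = 0 deg,
trans = +-180 deg); the RB polynomial is evaluated at psi = a_d - 180 deg,
so cos(psi) = -cos(a_d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEBYE_PER_E_NM, KE, R_KJ

__all__ = [
    "ModelParameters",
    "ParameterRanges",
    "ForceConstants",
    "ExclusionPolicy",
    "MoleculeConformation",
    "EnergyBreakdown",
    "GasReference",
    "expand_rb_coefficients",
    "rb_energy",
    "rb_stationary_points",
    "build_conformation",
    "measure_internal_coordinates",
    "intramolecular_energy",
    "dihedral_profile",
    "gas_minimum",
    "gas_internal_energy",
    "molecular_dipole",
    "intermolecular_energy",
]

# RB constraint ratios tying c0..c5 to c2.
_RB_RATIOS = (0.312, -1.0, 1.0, 0.300, 0.0, 0.0)


@dataclass(frozen=True)
class ModelParameters:
    """The seven physical parameters of the H2O2 model.

    Defaults are the optimized set: bond lengths in nm, the H-O-O angle in
    degrees, the hydrogen partial charge in e (each oxygen carries -q_H),
    oxygen LJ size/depth in nm and kJ/mol, and the RB scale c2 in kJ/mol.
    """

    c2: float = 26.91
    q_H: float = 0.4323
    sigma_OO: float = 0.29989
    eps_OO: float = 0.8912
    d_OO: float = 0.1463
    d_OH: float = 0.0979
    a_HOO: float = 95.79

    def __post_init__(self) -> None:
        for name in ("c2", "q_H", "sigma_OO", "eps_OO", "d_OO", "d_OH", "a_HOO"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not 0.0 < self.a_HOO < 180.0:
            raise ValueError(f"a_HOO must lie in (0, 180) deg, got {self.a_HOO}")

    def as_vector(self) -> np.ndarray:
        """Parameter vector in the canonical order (see PARAMETER_ORDER)."""
        return np.array([getattr(self, n) for n in PARAMETER_ORDER])

    @classmethod
    def from_vector(cls, p) -> "ModelParameters":
        p = np.asarray(p, dtype=float)
        if p.shape != (7,):
            raise ValueError("parameter vector must have 7 entries")
        return cls(**dict(zip(PARAMETER_ORDER, p)))


#: Canonical ordering of the seven parameters in vectors/tables.
PARAMETER_ORDER = ("c2", "q_H", "sigma_OO", "eps_OO", "d_OO", "d_OH", "a_HOO")


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter (lower, upper) sweep bounds; defaults are the printed ranges."""

    c2: tuple = (25.5, 36.0)
    q_H: tuple = (0.43, 0.47)
    sigma_OO: tuple = (0.296, 0.300)
    eps_OO: tuple = (0.7, 0.9)
    d_OO: tuple = (0.145, 0.148)
    d_OH: tuple = (0.094, 0.099)
    a_HOO: tuple = (94.0, 102.0)

    def __post_init__(self) -> None:
        for name in PARAMETER_ORDER:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range for {name} must satisfy lower < upper")

    def lower(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in PARAMETER_ORDER])

    def upper(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in PARAMETER_ORDER])

    def contains(self, p, tol: float = 1e-12) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.lower() - tol) and np.all(p <= self.upper() + tol))


@dataclass(frozen=True)
class ForceConstants:
    """Harmonic force constants: bonds in kJ mol^-1 nm^-2, angle in kJ mol^-1 rad^-2.

    Numeric values are configuration inputs; the defaults are documented
    placeholders of a realistic magnitude for single bonds and H-O-O bending.
    """

    kb_OO: float = 267776.0
    kb_OH: float = 462750.0
    ka_HOO: float = 420.0

    def __post_init__(self) -> None:
        for name in ("kb_OO", "kb_OH", "ka_HOO"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ExclusionPolicy:
    """Intramolecular nonbonded handling.

    ``exclude_all_intra`` zeroes every intramolecular nonbonded term;
    ``opls_14_half`` keeps the single 1-4 pair (H1-H2) Coulomb interaction
    scaled by ``fudge_qq``.  Intramolecular LJ is excluded in both modes.
    """

    mode: str = "exclude_all_intra"
    fudge_qq: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("exclude_all_intra", "opls_14_half"):
            raise ValueError(f"unknown exclusion mode {self.mode!r}")
        if not 0.0 <= self.fudge_qq <= 1.0:
            raise ValueError("fudge_qq must lie in [0, 1]")


@dataclass(frozen=True)
class MoleculeConformation:
    """Cartesian coordinates (nm) of the four sites, ordered H1, O1, O2, H2."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (4, 3):
            raise ValueError("positions must be a (4, 3) array: H1, O1, O2, H2")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def H1(self):
        return self.positions[0]

    @property
    def O1(self):
        return self.positions[1]

    @property
    def O2(self):
        return self.positions[2]

    @property
    def H2(self):
        return self.positions[3]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Intramolecular energy terms, kJ/mol; total is their sum."""

    bond: float
    angle: float
    dihedral: float
    intra_coulomb: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.intra_coulomb


@dataclass(frozen=True)
class GasReference:
    """Isolated-molecule reference: torsion minimum location (deg, reported as
    +-a_d_min by symmetry) and minimum potential energy U_g^min (kJ/mol).

    ``u_g_min`` may be set directly from configuration when the reference
    energy includes terms beyond the ones this module evaluates (e.g. a
    constant offset in the torsion definition of a particular topology file).
    """

    a_d_min: float
    u_g_min: float

    def __post_init__(self) -> None:
        if not 0.0 < self.a_d_min < 180.0:
            raise ValueError("a_d_min must lie in (0, 180) deg")


def expand_rb_coefficients(c2: float):
    """Expand the single RB scale c2 into the six coefficients c0..c5 (kJ/mol)."""
    if not (math.isfinite(c2) and c2 > 0):
        raise ValueError(f"c2 must be strictly positive, got {c2!r}")
    return tuple(r * c2 for r in _RB_RATIOS)


def rb_energy(a_d, coeffs):
    """RB torsion energy at dihedral ``a_d`` (deg): sum_n c_n cos^n(psi), psi = a_d - 180.

    Vectorized in ``a_d``; even in ``a_d`` because cos(psi) = -cos(a_d).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (6,) or not np.all(np.isfinite(coeffs)):
        raise ValueError("coeffs must be six finite RB coefficients")
    x = -np.cos(np.deg2rad(a_d))  # cos(psi)
    return np.polynomial.polynomial.polyval(x, coeffs)


def rb_stationary_points(coeffs) -> list:
    """Analytic stationary points of the RB torsion on a_d in [0, 180] (deg).

    Solves dV/dx = 0 for the polynomial in x = cos(psi), keeps real roots
    with |x| <= 1 and maps them back through a_d = 180 - acos(x) (the
    symmetric negative-a_d branch follows by evenness).  The endpoints 0 and
    180 are always stationary by symmetry and are included.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    deriv = np.polynomial.polynomial.polyder(coeffs)
    pts = {0.0, 180.0}
    for x in np.polynomial.polynomial.polyroots(deriv):
        if abs(x.imag) < 1e-10 and -1.0 < x.real < 1.0:
            pts.add(180.0 - math.degrees(math.acos(x.real)))
    return sorted(pts)


def build_conformation(params: ModelParameters, a_d: float) -> MoleculeConformation:
    """Cartesian coordinates from internal coordinates with dihedral ``a_d`` (deg).

    O1 sits at the origin with O2 along +x; H1 lies in the xy-plane with a
    positive y component; the sign of ``a_d`` sets the chirality.
    """
    a = math.radians(params.a_HOO)
    phi = math.radians(a_d)
    d = params.d_OH
    O1 = np.zeros(3)
    O2 = np.array([params.d_OO, 0.0, 0.0])
    H1 = np.array([d * math.cos(a), d * math.sin(a), 0.0])
    # O2->H2 makes angle a_HOO with O2->O1 (-x); its perpendicular component is
    # rotated about the O-O axis by the dihedral relative to O1->H1's.
    H2 = O2 + np.array(
        [-d * math.cos(a), d * math.sin(a) * math.cos(phi), -d * math.sin(a) * math.sin(phi)]
    )
    return MoleculeConformation(np.array([H1, O1, O2, H2]))


def _angle(v1, v2) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def measure_internal_coordinates(conf: MoleculeConformation) -> dict:
    """Internal coordinates of a conformation.

    Returns d_OO, d_OH1, d_OH2 (nm), a_HOO1, a_HOO2 (deg) and the signed
    dihedral a_d in (-180, 180] deg.  Raises for collinear H-O-O geometry,
    where the dihedral is undefined.
    """
    H1, O1, O2, H2 = conf.positions
    b1 = O1 - H1
    b2 = O2 - O1
    b3 = H2 - O2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear H-O-O geometry: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    a_d = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    if a_d <= -180.0:
        a_d += 360.0
    return {
        "d_OO": float(np.linalg.norm(b2)),
        "d_OH1": float(np.linalg.norm(b1)),
        "d_OH2": float(np.linalg.norm(b3)),
        "a_HOO1": _angle(H1 - O1, O2 - O1),
        "a_HOO2": _angle(H2 - O2, O1 - O2),
        "a_d": a_d,
    }


def intramolecular_energy(
    conf: MoleculeConformation,
    params: ModelParameters,
    fc: ForceConstants,
    policy: ExclusionPolicy = ExclusionPolicy(),
) -> EnergyBreakdown:
    """Bonded + intramolecular nonbonded energy of one molecule (kJ/mol)."""
    ic = measure_internal_coordinates(conf)
    bond = 0.5 * fc.kb_OO * (ic["d_OO"] - params.d_OO) ** 2
    bond += 0.5 * fc.kb_OH * (ic["d_OH1"] - params.d_OH) ** 2
    bond += 0.5 * fc.kb_OH * (ic["d_OH2"] - params.d_OH) ** 2
    th0 = math.radians(params.a_HOO)
    angle = 0.5 * fc.ka_HOO * (math.radians(ic["a_HOO1"]) - th0) ** 2
    angle += 0.5 * fc.ka_HOO * (math.radians(ic["a_HOO2"]) - th0) ** 2
    dihedral = float(rb_energy(ic["a_d"], expand_rb_coefficients(params.c2)))
    if policy.mode == "exclude_all_intra":
        coul = 0.0
    else:  # opls_14_half: only the 1-4 H1-H2 pair survives the exclusions
        r_hh = float(np.linalg.norm(conf.H2 - conf.H1))
        coul = policy.fudge_qq * KE * params.q_H**2 / r_hh
    return EnergyBreakdown(bond=float(bond), angle=float(angle), dihedral=dihedral, intra_coulomb=coul)


def _torsion_energy_curve(params, fc, policy, a_grid):
    """Intramolecular energy vs a_d with bonds/angles held at equilibrium."""
    e = rb_energy(a_grid, expand_rb_coefficients(params.c2))
    e = np.asarray(e, dtype=float).copy()
    if policy.mode == "opls_14_half":
        a = math.radians(params.a_HOO)
        phi = np.deg2rad(np.asarray(a_grid, dtype=float))
        d, doo = params.d_OH, params.d_OO
        hh = np.sqrt(
            (doo - 2 * d * math.cos(a)) ** 2
            + (d * math.sin(a)) ** 2 * ((np.cos(phi) - 1) ** 2 + np.sin(phi) ** 2)
        )
        e += policy.fudge_qq * KE * params.q_H**2 / hh
    return e


def dihedral_profile(
    params: ModelParameters,
    fc: ForceConstants = ForceConstants(),
    policy: ExclusionPolicy = ExclusionPolicy(),
    grid_step: float = 0.5,
) -> dict:
    """Torsional energy profile at equilibrium bonds/angles, plus stationary points.

    Scans a_d on [-180, 180] deg at ``grid_step`` resolution, refines the
    interior minima by golden-section search, and reports the cis barrier
    V(0) - V(min) and trans barrier V(180) - V(min).  Ties in the grid are
    broken toward smaller |a_d|.
    """
    if not 0.0 < grid_step <= 10.0:
        raise ValueError("grid_step must lie in (0, 10] deg")
    grid = np.arange(-180.0, 180.0 + grid_step / 2, grid_step)
    energy = _torsion_energy_curve(params, fc, policy, grid)

    # refine the positive-a_d interior minimum; the mirror is its negative
    pos = grid > 0
    i0 = np.argmin(np.where(pos, energy, np.inf))
    lo = max(grid[i0] - grid_step, 1e-9)
    hi = min(grid[i0] + grid_step, 180.0)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda a: float(_torsion_energy_curve(params, fc, policy, np.array([a]))[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    a_min, v_min = float(res.x), float(res.fun)
    v0 = float(_torsion_energy_curve(params, fc, policy, np.array([0.0]))[0])
    v180 = float(_torsion_energy_curve(params, fc, policy, np.array([180.0]))[0])
    return {
        "a_d": grid,
        "energy": energy,
        "minima": (-a_min, a_min),
        "v_min": v_min,
        "cis_barrier": v0 - v_min,
        "trans_barrier": v180 - v_min,
    }


def gas_minimum(
    params: ModelParameters,
    fc: ForceConstants = ForceConstants(),
    policy: ExclusionPolicy = ExclusionPolicy(),
) -> GasReference:
    """Isolated-molecule minimum over a_d with bonds/angles at equilibrium."""
    prof = dihedral_profile(params, fc, policy, grid_step=0.5)
    return GasReference(a_d_min=prof["minima"][1], u_g_min=prof["v_min"])


def gas_internal_energy(T: float, ref: GasReference) -> float:
    """Gas-phase molecular potential energy U_g(T) = U_g^min + 3RT (kJ/mol).

    Equipartition over the 3*N_sites - 6 internal degrees of freedom of the
    four-site molecule with no constraints (N_c = 0).
    """
    if T < 0:
        raise ValueError("temperature must be non-negative")
    return ref.u_g_min + 3.0 * R_KJ * T


def molecular_dipole(conf: MoleculeConformation, q_H: float):
    """Molecular dipole vector (e*nm) and magnitude (debye).

    mu = q_H (r_H1 + r_H2 - r_O1 - r_O2); independent of origin because the
    molecule is neutral.
    """
    mu = q_H * (conf.H1 + conf.H2 - conf.O1 - conf.O2)
    return mu, float(np.linalg.norm(mu)) * DEBYE_PER_E_NM


def dipole_magnitude_closed_form(params: ModelParameters, a_d: float) -> float:
    """|mu| in debye at equilibrium bonds/angles: 2 q_H d_OH sin(a_HOO) |cos(a_d/2)|."""
    return (
        2.0
        * params.q_H
        * params.d_OH
        * math.sin(math.radians(params.a_HOO))
        * abs(math.cos(math.radians(a_d) / 2.0))
        * DEBYE_PER_E_NM
    )


def intermolecular_energy(
    confA: MoleculeConformation, confB: MoleculeConformation, params: ModelParameters
) -> float:
    """Pair interaction energy of two molecules (kJ/mol): O-O LJ + 16 Coulomb pairs."""
    charges = np.array([params.q_H, -params.q_H, -params.q_H, params.q_H])
    rij = np.linalg.norm(confA.positions[:, None, :] - confB.positions[None, :, :], axis=2)
    if np.any(rij < 1e-12):
        raise ValueError("coincident sites between molecules")
    coul = KE * np.sum(np.outer(charges, charges) / rij)
    r_oo = rij[1:3, 1:3]
    sr6 = (params.sigma_OO / r_oo) ** 6
    lj = np.sum(4.0 * params.eps_OO * (sr6**2 - sr6))
    return float(coul + lj)
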