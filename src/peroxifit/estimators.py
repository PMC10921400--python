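"""Bulk-liquid property estimators from NPT trajectory time series.

Every estimator here consumes trajectory-derived series (energies, volumes,
box dipoles, positions, velocity-profile amplitudes) and reduces them to the
thermodynamic and transport properties of the liquid: fluctuation-formula
response functions, the Kirkwood dielectric constant, Einstein-relation
diffusion, geometric hydrogen-bond counts, cosine-flow shear viscosity, the
enthalpy of vaporization and the self-polarization energy correction.

Energies are molar (kJ/mol for the whole system, the engine convention), so
Boltzmann's constant appears as R throughout.  Fluctuation estimators use
block averaging (10 equal blocks by default) with outlier blocks more than
three standard deviations from the block mean discarded before the final
average.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import BAR_NM3_TO_KJ_MOL, E_NM_PER_DEBYE, KE, R_KJ

__all__ = [
    "ThermoSeries",
    "DipoleSeries",
    "ResponseSet",
    "HBondCriterion",
    "alpha_p_from_fit",
    "npt_fluctuations",
    "derived_caloric",
    "dielectric_constant",
    "diffusion_einstein",
    "hydrogen_bonds",
    "viscosity_cosine_flow",
    "enthalpy_of_vaporization",
    "self_polarization_correction",
]


@dataclass
class ThermoSeries:
    """NPT time series: time (ps), potential energy U and enthalpy H (kJ/mol,
    whole system), volume V (nm^3), temperature T (K), pressure P (bar)."""

    time: np.ndarray
    U: np.ndarray
    V: np.ndarray
    H: np.ndarray
    T: float
    P: float
    n_molecules: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        n = len(self.time)
        if not (len(self.U) == len(self.V) == len(self.H) == n):
            raise ValueError("all columns must have equal length")
        if np.any(self.V <= 0):
            raise ValueError("volumes must be positive")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")


@dataclass
class DipoleSeries:
    """Box-dipole time series: M (e*nm, shape (n, 3)), volume (nm^3), T (K)."""

    time: np.ndarray
    M: np.ndarray
    V: np.ndarray
    T: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.V = np.atleast_1d(np.asarray(self.V, dtype=float))
        if self.V.size == 1:
            self.V = np.full(len(self.time), float(self.V[0]))
        if self.M.shape != (len(self.time), 3) or len(self.V) != len(self.time):
            raise ValueError("M must be (n, 3) and V length n")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("dipole series must be finite")


@dataclass(frozen=True)
class ResponseSet:
    """Response functions: alpha_P (1/K), kappa_T and kappa_S (1/bar),
    C_P and C_V (kJ mol^-1 K^-1 per mole of molecules)."""

    alpha_P: float
    kappa_T: float
    C_P: float
    kappa_S: float | None = None
    C_V: float | None = None

    def __post_init__(self) -> None:
        if self.kappa_T < 0:
            raise ValueError("kappa_T must be non-negative")


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion: donor-acceptor O...O distance cutoff
    (nm) and hydrogen-donor-acceptor angle cutoff (deg)."""

    r_cut: float = 0.35
    theta_cut: float = 30.0
    angle_convention: str = "hydrogen_donor_acceptor"

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if not 0.0 < self.theta_cut < 90.0:
            raise ValueError("theta_cut must lie in (0, 90) deg")
        if self.angle_convention not in ("hydrogen_donor_acceptor", "acceptor_donor_hydrogen"):
            raise ValueError(f"unknown angle convention {self.angle_convention!r}")


def _block_stats(x: np.ndarray, n_blocks: int, sigma_discard: float = 3.0):
    """Means of equal blocks with >3 sigma outlier blocks discarded.

    Returns (kept block values, standard error over kept blocks)."""
    n = len(x) // n_blocks * n_blocks
    blocks = x[:n].reshape(n_blocks, -1)
    return blocks


def _blocked_estimate(series_fn, arrays, n_blocks: int = 10, sigma_discard: float = 3.0):
    """Apply ``series_fn`` per block, discard outlier blocks, return mean and SE.

    ``series_fn`` maps a tuple of equal-length arrays to a scalar estimate.
    Blocks whose estimate lies more than ``sigma_discard`` standard deviations
    from the all-block mean are discarded before the final average.
    """
    n = len(arrays[0])
    n_blocks = min(n_blocks, n)
    m = n // n_blocks * n_blocks
    vals = np.array(
        [
            series_fn(tuple(a[:m].reshape(n_blocks, -1)[i] for a in arrays))
            for i in range(n_blocks)
        ]
    )
    sd = vals.std(ddof=1) if n_blocks > 1 else 0.0
    keep = np.abs(vals - vals.mean()) <= sigma_discard * sd if sd > 0 else np.ones(n_blocks, bool)
    vals = vals[keep]
    se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return float(vals.mean()), float(se)


def alpha_p_from_fit(T: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Thermal expansion coefficient from a cubic fit of rho(T).

    Fits a cubic polynomial to the (T, rho) table and evaluates
    alpha_P = -(1/rho) (d rho / d T)_P at each input temperature.
    """
    T = np.asarray(T, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if len(np.unique(T)) < 4:
        raise ValueError("need at least 4 distinct temperatures for a cubic fit")
    # center T for conditioning; alpha_P is invariant under the shift
    t0 = T.mean()
    coeffs = np.polynomial.polynomial.polyfit(T - t0, rho, 3)
    rho_fit = np.polynomial.polynomial.polyval(T - t0, coeffs)
    drho = np.polynomial.polynomial.polyval(T - t0, np.polynomial.polynomial.polyder(coeffs))
    return -drho / rho_fit


def npt_fluctuations(ts: ThermoSeries, n_blocks: int = 10) -> dict:
    """Fluctuation-formula estimates of kappa_T, alpha_P and C_P.

    kappa_T = <dV^2> / (<V> R T) in bar^-1, alpha_P = <dV dH> / (<V> R T^2)
    in K^-1 and C_P = <dH^2> / (R T^2) per mole of molecules, from the NPT
    variances/covariance of volume and enthalpy.  Estimates carry blocked
    standard errors; outlier blocks (>3 sigma) are discarded.
    """
    if len(ts.time) < 1000:
        raise ValueError("need at least 1000 frames for fluctuation estimates")
    T = ts.T

    def kt_fn(arrs):
        V, = arrs
        return V.var() / (V.mean() * R_KJ * T) * BAR_NM3_TO_KJ_MOL

    def ap_fn(arrs):
        V, H = arrs
        return np.cov(V, H, bias=True)[0, 1] / (V.mean() * R_KJ * T**2)

    def cp_fn(arrs):
        H, = arrs
        return H.var() / (R_KJ * T**2) / ts.n_molecules

    if ts.V.var() == 0 and ts.H.var() == 0:
        warnings.warn("zero fluctuations: returning zero response functions")
        return {
            "kappa_T": 0.0, "kappa_T_err": 0.0,
            "alpha_P": 0.0, "alpha_P_err": 0.0,
            "C_P": 0.0, "C_P_err": 0.0,
        }
    kt, kt_se = _blocked_estimate(kt_fn, (ts.V,), n_blocks)
    ap, ap_se = _blocked_estimate(ap_fn, (ts.V, ts.H), n_blocks)
    cp, cp_se = _blocked_estimate(cp_fn, (ts.H,), n_blocks)
    return {
        "kappa_T": kt, "kappa_T_err": kt_se,
        "alpha_P": ap, "alpha_P_err": ap_se,
        "C_P": cp, "C_P_err": cp_se,
    }


def derived_caloric(alpha_P: float, kappa_T: float, C_P: float, T: float, V: float) -> dict:
    """C_V and kappa_S from the measured responses.

    C_V = C_P - T V alpha_P^2 / kappa_T (per system: C_P in kJ/mol/K for the
    box whose volume V in nm^3 is given) and kappa_S = kappa_T C_V / C_P.
    A non-positive C_V is thermodynamically inconsistent (it would imply a
    negative isothermal compressibility) and raises.
    """
    if kappa_T <= 0 or C_P <= 0:
        raise ValueError("kappa_T and C_P must be positive")
    c_v = C_P - T * V * alpha_P**2 / kappa_T * BAR_NM3_TO_KJ_MOL
    if c_v <= 0:
        raise ValueError("inconsistent inputs: C_V <= 0 would violate the second law")
    return {"C_V": c_v, "kappa_S": kappa_T * c_v / C_P}


def dielectric_constant(ds: DipoleSeries, n_blocks: int = 10) -> dict:
    """Relative dielectric constant from box-dipole fluctuations.

    eps = 1 + 4 pi k_e (<M^2> - <M>^2) / (3 <V> R T) with M in e*nm, V in
    nm^3 and conducting (tin-foil) Ewald boundaries assumed.  The mean is
    subtracted per Cartesian component.  Returns the estimate with a blocked
    standard error (>3 sigma blocks discarded).
    """
    if len(ds.time) == 0:
        raise ValueError("empty dipole series")

    def eps_fn(arrs):
        mx, my, mz, v = arrs
        var = mx.var() + my.var() + mz.var()
        return 1.0 + 4.0 * math.pi * KE * var / (3.0 * v.mean() * R_KJ * ds.T)

    eps, se = _blocked_estimate(
        eps_fn, (ds.M[:, 0], ds.M[:, 1], ds.M[:, 2], ds.V), n_blocks
    )
    return {"epsilon": eps, "epsilon_err": se}


def msd_multi_origin(positions: np.ndarray) -> np.ndarray:
    """Mean-squared displacement averaged over all time origins (FFT method).

    ``positions`` has shape (n_frames, n_particles, 3), unwrapped, in nm.
    Returns MSD(lag) for lag = 0 .. n_frames-1 in nm^2, averaged over
    particles and origins — the estimator trajectory tools use.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    acf = np.empty((n, pos.shape[1]))
    for j0 in range(0, pos.shape[1], 64):  # chunk particles to bound memory
        fft = np.fft.rfft(pos[:, j0 : j0 + 64], n=nfft, axis=0)
        # sum_t r(t).r(t+m), summed over xyz
        acf[:, j0 : j0 + 64] = np.fft.irfft(fft * fft.conj(), axis=0)[:n].real.sum(axis=2)
    norm = n - np.arange(n)
    sq = (pos**2).sum(axis=2)
    css = np.cumsum(sq, axis=0)
    css_rev = np.cumsum(sq[::-1], axis=0)
    # sum over origins t of |r(t)|^2 + |r(t+m)|^2
    s1 = np.empty_like(acf)
    s1[0] = 2.0 * css[-1]
    for m in range(1, n):
        s1[m] = (css[-1] - css[m - 1]) + (css_rev[-1] - css_rev[m - 1])
    msd = (s1 - 2.0 * acf) / norm[:, None]
    return msd.mean(axis=1)


def diffusion_einstein(
    time: np.ndarray,
    msd: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    fit_window: tuple | None = None,
) -> dict:
    """Diffusion coefficient from the Einstein relation MSD(t) -> 6 D t.

    Accepts either a precomputed mean-squared displacement (nm^2) or unwrapped
    positions (nm, shape (n_frames, n_particles, 3)) from which the MSD from
    the initial frame is formed.  D is the least-squares slope over the fit
    window (default the [10%, 50%] span of the series) divided by 6,
    converted to m^2 s^-1 (time in ps).
    """
    time = np.asarray(time, dtype=float)
    if msd is None:
        if positions is None:
            raise ValueError("provide msd or positions")
        msd = msd_multi_origin(positions)
    msd = np.asarray(msd, dtype=float)
    if fit_window is None:
        span = time[-1] - time[0]
        fit_window = (time[0] + 0.1 * span, time[0] + 0.5 * span)
    lo, hi = fit_window
    mask = (time >= lo) & (time <= hi)
    if mask.sum() < 10:
        raise ValueError("fit window must contain at least 10 points")
    t_fit, m_fit = time[mask], msd[mask]
    # inverse-variance weights: for an origin-averaged MSD the variance grows
    # ~ lag^3, so short lags carry most of the information
    lag = t_fit - time[0]
    w = 1.0 / np.maximum(lag, lag[lag > 0].min() if np.any(lag > 0) else 1.0) ** 3
    sw = w.sum()
    tm, mm = (w * t_fit).sum() / sw, (w * m_fit).sum() / sw
    slope = (w * (t_fit - tm) * (m_fit - mm)).sum() / (w * (t_fit - tm) ** 2).sum()
    flagged = slope < 0
    if flagged:
        warnings.warn("negative MSD slope; D clamped to 0 and flagged")
    d = max(slope, 0.0) / 6.0 * 1e-6  # nm^2/ps -> m^2/s
    return {"D": d, "negative_slope": bool(flagged)}


def _min_image(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    return dr - box * np.round(dr / box)


def hydrogen_bonds(
    positions: np.ndarray,
    box,
    species: np.ndarray,
    elements: np.ndarray,
    molecule_ids: np.ndarray,
    crit: HBondCriterion = HBondCriterion(),
) -> dict:
    """Count geometric hydrogen bonds in an orthorhombic periodic box.

    A bond is counted when the donor-O...acceptor-O minimum-image distance is
    within ``crit.r_cut`` and the hydrogen-donor-acceptor angle (at the donor,
    between the O-H bond and the O...O axis) is within ``crit.theta_cut``;
    the acceptor-donor-hydrogen convention is available via the criterion's
    ``angle_convention``.  Sites are labelled by ``species`` ("H2O2"/"H2O"),
    ``elements`` ("O"/"H") and ``molecule_ids``; each hydrogen is assigned to
    the nearest oxygen of its own molecule.

    Returns per-class counts (peroxide-peroxide, water-water, cross, total)
    and the normalized counts n_h: peroxide classes and the cross class per
    peroxide oxygen, water-water per water molecule, total per oxygen atom.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    species = np.asarray(species)
    elements = np.asarray(elements)
    molecule_ids = np.asarray(molecule_ids)

    o_idx = np.where(elements == "O")[0]
    h_idx = np.where(elements == "H")[0]
    if len(h_idx) == 0 or len(o_idx) == 0:
        raise ValueError("configuration must contain O and H sites")

    # covalent assignment: each H to the nearest O in the same molecule
    donor_of_h = {}
    for h in h_idx:
        same = o_idx[molecule_ids[o_idx] == molecule_ids[h]]
        if len(same) == 0:
            raise ValueError(f"hydrogen site {h} has no oxygen in its molecule")
        dr = _min_image(positions[same] - positions[h], box)
        donor_of_h[h] = same[np.argmin(np.linalg.norm(dr, axis=1))]

    counts = {"peroxide-peroxide": 0, "water-water": 0, "cross": 0, "total": 0}
    cos_cut = math.cos(math.radians(crit.theta_cut))
    for h, d_o in donor_of_h.items():
        dr_all = _min_image(positions[o_idx] - positions[d_o], box)
        dist = np.linalg.norm(dr_all, axis=1)
        for a_o, r, dr in zip(o_idx, dist, dr_all):
            if a_o == d_o or molecule_ids[a_o] == molecule_ids[d_o] or r > crit.r_cut:
                continue
            oh = _min_image(positions[h] - positions[d_o], box)
            if crit.angle_convention == "hydrogen_donor_acceptor":
                cosang = np.dot(oh, dr) / (np.linalg.norm(oh) * r)
            else:  # acceptor-donor-hydrogen measured at the donor: same vectors
                cosang = np.dot(dr, oh) / (r * np.linalg.norm(oh))
            if cosang >= cos_cut:
                sd, sa = species[d_o], species[a_o]
                if sd == "H2O2" and sa == "H2O2":
                    counts["peroxide-peroxide"] += 1
                elif sd == "H2O" and sa == "H2O":
                    counts["water-water"] += 1
                else:
                    counts["cross"] += 1
                counts["total"] += 1

    n_o_per = int(np.sum((elements == "O") & (species == "H2O2")))
    n_wat = len(np.unique(molecule_ids[(species == "H2O")])) if np.any(species == "H2O") else 0
    n_o_tot = len(o_idx)
    n_h = {
        "peroxide-peroxide": counts["peroxide-peroxide"] / n_o_per if n_o_per else math.nan,
        "water-water": counts["water-water"] / n_wat if n_wat else math.nan,
        "cross": counts["cross"] / n_o_per if n_o_per else math.nan,
        "total": counts["total"] / n_o_tot,
    }
    return {"counts": counts, "n_h": n_h}


def viscosity_cosine_flow(
    v_amplitude: np.ndarray, A: float, rho: float, L_z: float
) -> float:
    """Shear viscosity from the periodic-perturbation (cosine-flow) method.

    A cosine acceleration profile of amplitude ``A`` (nm/ps^2) and wavevector
    k = 2 pi / L_z drives a stationary velocity profile; the viscosity follows
    from its time-averaged amplitude <v_max> (nm/ps):
    eta = A rho / (<v_max> k^2), with rho in kg/m^3, returned in cP.
    """
    if A <= 0 or L_z <= 0:
        raise ValueError("A and L_z must be positive")
    v = np.asarray(v_amplitude, dtype=float)
    v_mean = v.mean()
    if v_mean <= 0:
        raise ValueError("mean velocity amplitude must be positive")
    k = 2.0 * math.pi / L_z
    eta_pa_s = A * rho / (v_mean * k**2) * 1e-6  # nm^2/ps * kg/m^3 -> Pa s
    return eta_pa_s * 1e3  # Pa s -> cP


def enthalpy_of_vaporization(
    U_l: float, T: float, ref, rigid: bool = False
) -> float:
    """Enthalpy of vaporization (kJ/mol): Delta H = U_g(T) - U_l(T) + RT.

    ``U_l`` is the liquid potential energy per molecule.  U_g(T) follows the
    equipartition form U_g^min + 3RT for the flexible four-site molecule; for
    a rigid reference molecule (``rigid=True``) U_g is the constant U_g^min.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    from .forcefield import gas_internal_energy

    u_g = ref.u_g_min if rigid else gas_internal_energy(T, ref)
    return u_g - U_l + R_KJ * T


#: SPC/E water polarizability volume (nm^3); the H2O2 value defaults to 30% more.
ALPHA_VOLUME_WATER = 1.444e-3
ALPHA_VOLUME_H2O2 = 1.3 * ALPHA_VOLUME_WATER


def self_polarization_correction(
    mu_model: float, mu_gas: float, alpha_volume: float = ALPHA_VOLUME_H2O2
) -> float:
    """Self-polarization energy correction E_pol = k_e (mu_l - mu_g)^2 / (2 alpha').

    Dipoles in debye; ``alpha_volume`` is the polarizability volume in nm^3
    (default 30% above SPC/E water's 1.444e-3).  Returns kJ/mol.
    """
    if alpha_volume <= 0:
        raise ValueError("alpha_volume must be positive")
    dmu = (mu_model - mu_gas) * E_NM_PER_DEBYE
    return KE * dmu**2 / (2.0 * alpha_volume)
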