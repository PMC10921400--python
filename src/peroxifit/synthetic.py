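"""Synthetic fixtures with known ground truth.

Two families of generators live here:

* a smooth parameter->property *oracle* emulating the shape of the
  MD-produced training tables (7 parameters in, 22 properties out, with
  simulation-like relative noise) and built so that a known parameter vector
  p* exactly reproduces the experimental references — hence minimizes the
  default target function;
* statistically controlled trajectory-like series (NPT volume/enthalpy,
  box dipoles, random-walk positions, cosine-flow velocity amplitudes) and
  coexistence fixtures (tanh slab profiles, rectilinear + scaling density
  curves, Clausius-Clapeyron vapor pressures) that formally invert the
  estimators they are meant to exercise.

Every generator draws all randomness from one seeded generator: identical
seeds give identical fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BAR_NM3_TO_KJ_MOL, KE, R_J, R_KJ
from .coexistence import BETA_EXPONENT, SlabProfile
from .estimators import DipoleSeries, ThermoSeries
from .forcefield import ParameterRanges
from .surrogate import (
    PROPERTY_LAYOUT,
    TargetWeights,
    TrainingTable,
    denormalize,
    normalize,
)

__all__ = [
    "OracleSpec",
    "oracle_properties",
    "make_training_tables",
    "gen_fluctuation_series",
    "gen_coexistence_fixtures",
]

#: Simulation-like relative noise per property class (matches the relative
#: uncertainties typical of short MD runs: densities tight, dielectric loose).
DEFAULT_NOISE = {
    "rho": 0.002,
    "epsilon": 0.05,
    "mu": 0.05,
    "P_v": 0.05,
    "lambda": 0.03,
    "wt_v": 0.03,
}


#: Relative response scale of each property class over the swept parameter
#: cube (how strongly short-run MD values move with the model parameters:
#: density weakly, viscosity and vapor pressure strongly).
DEFAULT_RESPONSE = {
    "rho": 0.15,
    "epsilon": 0.4,
    "mu": 0.8,
    "P_v": 0.6,
    "lambda": 0.3,
    "wt_v": 0.3,
}


@dataclass
class OracleSpec:
    """A seeded smooth map from normalized parameters to the 22 properties.

    Each property j responds as
    x_ej * (1 + l_j . du + du^T Q_j du), du = u - u*,
    a linear-plus-quadratic (pairwise-interaction) polynomial with Q_j
    positive semi-definite.  Every property equals its experimental reference
    exactly at the constructed optimum u*, so the default target function —
    a weighted sum of squared relative deviations — is zero there and
    strictly positive elsewhere: u* is its exact global minimum.
    """

    seed: int = 0
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    weights: TargetWeights = field(default_factory=TargetWeights)
    curvature: float = 0.3
    noise_rel: np.ndarray | None = None
    u_star: np.ndarray = field(init=False)
    L: np.ndarray = field(init=False)
    Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.u_star = rng.uniform(0.2, 0.8, size=7)
        n_prop = len(PROPERTY_LAYOUT)
        scales = np.array([DEFAULT_RESPONSE[s[0]] for s in PROPERTY_LAYOUT])
        # linear response: random direction per property, class-scaled so the
        # typical relative excursion over the cube matches DEFAULT_RESPONSE
        L = rng.standard_normal((n_prop, 7))
        L *= (scales / np.linalg.norm(L, axis=1))[:, None] * math.sqrt(7) / 2.0
        self.L = L
        Q = np.empty((n_prop, 7, 7))
        for j in range(n_prop):
            G = rng.standard_normal((7, 7))
            M = G @ G.T
            Q[j] = M / np.trace(M) * self.curvature * scales[j]
        self.Q = Q
        if self.noise_rel is None:
            self.noise_rel = np.array([DEFAULT_NOISE[s[0]] for s in PROPERTY_LAYOUT])
        else:
            self.noise_rel = np.asarray(self.noise_rel, dtype=float)

    @property
    def p_star(self) -> np.ndarray:
        """The constructed optimum on the physical scale."""
        return denormalize(self.u_star, self.ranges)


def oracle_properties(
    p, spec: OracleSpec, noisy: bool = False, seed: int = 0
) -> np.ndarray:
    """The oracle's 22 property values at parameter vector ``p``.

    Deterministic when ``noisy`` is false; otherwise multiplies each property
    by (1 + sigma_j * z) with z standard normal from ``seed``.
    """
    u = normalize(p, spec.ranges)
    du = u - spec.u_star
    dev = spec.L @ du + np.einsum("i,jik,k->j", du, spec.Q, du)
    y = spec.weights.x_e * (1.0 + dev)
    if noisy:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + spec.noise_rel * rng.standard_normal(len(y)))
    return y


def make_training_tables(
    spec: OracleSpec, n_train: int = 1000, n_val: int = 300, seed: int = 0
):
    """Uniformly sampled (train, validation) tables of noisy oracle rows."""
    if n_train < 1 or n_val < 1:
        raise ValueError("table sizes must be >= 1")
    rng = np.random.default_rng(seed)
    tables = []
    for n in (n_train, n_val):
        U = rng.random((n, 7))
        P = np.array([denormalize(u, spec.ranges) for u in U])
        Y = np.array(
            [
                oracle_properties(p, spec, noisy=True, seed=int(rng.integers(2**31)))
                for p in P
            ]
        )
        tables.append(TrainingTable(P=P, Y=Y, ranges=spec.ranges))
    return tuple(tables)


def gen_fluctuation_series(
    targets: dict,
    conditions: dict | None = None,
    seed: int = 0,
) -> dict:
    """Trajectory-like series whose estimators recover the requested targets.

    ``targets`` may contain kappa_T (1/bar), alpha_P (1/K), C_P (kJ/mol/K per
    molecule), epsilon, D (m^2/s) and eta (cP); ``conditions`` sets T (K),
    V (nm^3), n_frames, n_molecules, dt (ps) and, for the viscosity series,
    A (nm/ps^2), L_z (nm), rho (kg/m^3) and the relative noise.

    The (V, H) pair is multivariate Gaussian with covariance inverted from
    the NPT fluctuation formulas; M is isotropic Gaussian inverted from the
    dielectric formula; positions are 3-D Gaussian random walks with per-axis
    step variance 2 D dt; velocity amplitudes are Gaussian around the
    stationary cosine-flow amplitude.
    """
    cond = {
        "T": 293.0,
        "V": 125.0,
        "n_frames": 200_000,
        "n_molecules": 500,
        "dt": 1.0,
        "A": 0.05,
        "L_z": 6.0,
        "rho": 1450.0,
        "eta_noise": 0.05,
        "n_walkers": 512,
        "n_steps": 10_000,
    }
    cond.update(conditions or {})
    rng = np.random.default_rng(seed)
    T, V0, n = cond["T"], cond["V"], int(cond["n_frames"])
    out: dict = {}

    if {"kappa_T", "alpha_P", "C_P"} & set(targets):
        kt = targets.get("kappa_T", 4e-5)
        ap = targets.get("alpha_P", 7e-4)
        cp = targets.get("C_P", 0.09)  # per molecule
        var_v = kt * V0 * R_KJ * T / BAR_NM3_TO_KJ_MOL
        cov_vh = ap * V0 * R_KJ * T**2
        var_h = cp * cond["n_molecules"] * R_KJ * T**2
        cov = np.array([[var_v, cov_vh], [cov_vh, var_h]])
        if np.linalg.eigvalsh(cov)[0] < 0:
            raise ValueError("requested targets give a non-positive-definite covariance")
        if var_v == 0 and var_h == 0:
            samples = np.zeros((n, 2))
        else:
            samples = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        time = np.arange(n) * cond["dt"]
        out["thermo"] = ThermoSeries(
            time=time,
            U=samples[:, 1] - 0.0,
            V=V0 + samples[:, 0],
            H=samples[:, 1],
            T=T,
            P=1.0,
            n_molecules=int(cond["n_molecules"]),
        )

    if "epsilon" in targets:
        eps = targets["epsilon"]
        var_comp = max(eps - 1.0, 0.0) * V0 * R_KJ * T / (4.0 * math.pi * KE)
        M = rng.standard_normal((n, 3)) * math.sqrt(var_comp)
        out["dipole"] = DipoleSeries(time=np.arange(n) * cond["dt"], M=M, V=V0, T=T)

    if "D" in targets:
        d_nm = targets["D"] * 1e6  # m^2/s -> nm^2/ps
        nw, ns = int(cond["n_walkers"]), int(cond["n_steps"])
        steps = rng.standard_normal((ns, nw, 3)) * math.sqrt(2.0 * d_nm * cond["dt"])
        pos = np.concatenate([np.zeros((1, nw, 3)), np.cumsum(steps, axis=0)])
        out["positions"] = pos
        out["msd_time"] = np.arange(ns + 1) * cond["dt"]

    if "eta" in targets:
        eta_pa_s = targets["eta"] * 1e-3
        k = 2.0 * math.pi / cond["L_z"]
        v_true = cond["A"] * cond["rho"] / (eta_pa_s * k**2) * 1e-6
        n_amp = int(cond.get("n_amplitudes", 5000))
        out["v_amplitude"] = v_true * (
            1.0 + cond["eta_noise"] * rng.standard_normal(n_amp)
        )
    return out


def _tanh_profile(z, rho_v, rho_l, z1, z2, w):
    return rho_v + 0.5 * (rho_l - rho_v) * (np.tanh((z - z1) / w) - np.tanh((z - z2) / w))


def gen_coexistence_fixtures(
    truth: dict,
    T_grid,
    dhvap: float = 45.0,
    noise: float = 0.0,
    seed: int = 0,
    T_b: float = 423.3,
    L_z: float = 18.0,
    n_bins: int = 200,
    width: float = 0.4,
) -> dict:
    """Coexistence table, slab profiles and a vapor-pressure curve from truth.

    Densities follow rho_{l,v}(T) = rho_c + A (T_c - T) +- B (T_c - T)^0.32 / 2
    with optional multiplicative Gaussian noise; P_v follows the
    Clausius-Clapeyron form anchored to 1.013 bar at the boiling temperature
    ``T_b``; each row also gets a noise-free two-interface tanh profile
    consistent with its densities.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    t_c, rho_c = truth["T_c"], truth["rho_c"]
    a, b = truth["A"], truth["B"]
    if np.any(T_grid >= t_c):
        raise ValueError("all grid temperatures must lie below T_c")
    rng = np.random.default_rng(seed)
    dt = t_c - T_grid
    mean = rho_c + a * dt
    half = 0.5 * b * dt**BETA_EXPONENT
    rho_l = mean + half
    rho_v = mean - half
    if noise > 0:
        rho_l = rho_l * (1.0 + noise * rng.standard_normal(len(T_grid)))
        rho_v = rho_v * (1.0 + noise * rng.standard_normal(len(T_grid)))
    p_v = 1.013 * np.exp(-dhvap * 1e3 / R_J * (1.0 / T_grid - 1.0 / T_b))
    z = (np.arange(n_bins) + 0.5) * (L_z / n_bins)
    profiles = [
        SlabProfile(
            z=z,
            density={"H2O2": _tanh_profile(z, rv, rl, L_z / 3.0, 2.0 * L_z / 3.0, width)},
            box=np.array([L_z / 3.0, L_z / 3.0, L_z]),
        )
        for rl, rv in zip(rho_l, rho_v)
    ]
    return {
        "T": T_grid,
        "rho_l": rho_l,
        "rho_v": rho_v,
        "P_v": p_v,
        "profiles": profiles,
    }
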