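"""Bulk-liquid estimators: fluctuations, dielectric, diffusion, hydrogen
bonds, viscosity, enthalpy of vaporization, self-polarization."""

import math

import numpy as np
import pytest

from peroxifit.constants import R_KJ
from peroxifit.estimators import (
    DipoleSeries,
    HBondCriterion,
    ThermoSeries,
    alpha_p_from_fit,
    derived_caloric,
    dielectric_constant,
    diffusion_einstein,
    enthalpy_of_vaporization,
    hydrogen_bonds,
    npt_fluctuations,
    self_polarization_correction,
    viscosity_cosine_flow,
)
from peroxifit.forcefield import GasReference
from peroxifit.synthetic import gen_fluctuation_series


class TestAlphaPFromFit:
    def test_constant_density_gives_zero(self):
        T = np.array([273.0, 293.0, 313.0, 333.0, 353.0])
        assert alpha_p_from_fit(T, np.full(5, 1450.0)) == pytest.approx(
            np.zeros(5), abs=1e-12
        )

    def test_exponential_density_recovers_rate(self):
        a, t0 = 5e-4, 300.0
        T = np.linspace(280.0, 320.0, 8)
        rho = 1450.0 * np.exp(-a * (T - t0))
        alpha = alpha_p_from_fit(T, rho)
        assert alpha[np.argmin(np.abs(T - t0))] == pytest.approx(a, abs=1e-6)

    def test_invariant_under_temperature_shift(self):
        T = np.linspace(280.0, 320.0, 8)
        rho = 1450.0 - 0.8 * (T - 280.0) + 1e-3 * (T - 280.0) ** 2
        np.testing.assert_allclose(
            alpha_p_from_fit(T, rho), alpha_p_from_fit(T + 57.0, rho), rtol=1e-8
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            alpha_p_from_fit(np.array([280.0, 290, 300]), np.array([1.0, 2, 3]))


class TestNptFluctuations:
    TARGETS = {"kappa_T": 4e-5, "alpha_P": 7e-4, "C_P": 0.09}

    def test_constant_series_gives_zero(self):
        n = 2000
        ts = ThermoSeries(
            time=np.arange(n), U=np.zeros(n), V=np.full(n, 100.0),
            H=np.full(n, -5.0), T=293.0, P=1.0, n_molecules=100,
        )
        with pytest.warns(UserWarning):
            r = npt_fluctuations(ts)
        assert r["kappa_T"] == r["alpha_P"] == r["C_P"] == 0.0

    def test_recovers_generating_targets(self):
        fx = gen_fluctuation_series(self.TARGETS, {"n_frames": 200_000}, seed=0)
        r = npt_fluctuations(fx["thermo"])
        assert r["kappa_T"] == pytest.approx(self.TARGETS["kappa_T"], rel=0.03)
        assert r["alpha_P"] == pytest.approx(self.TARGETS["alpha_P"], rel=0.03)
        assert r["C_P"] == pytest.approx(self.TARGETS["C_P"], rel=0.03)
        assert r["kappa_T_err"] > 0

    def test_invariant_under_frame_shuffling(self):
        fx = gen_fluctuation_series(self.TARGETS, {"n_frames": 20_000}, seed=1)
        ts = fx["thermo"]
        perm = np.random.default_rng(5).permutation(len(ts.time))
        # moments only: a permutation of frames must not move the estimate
        # beyond block-composition effects; compare single-block estimates
        shuffled = ThermoSeries(
            time=ts.time, U=ts.U[perm], V=ts.V[perm], H=ts.H[perm],
            T=ts.T, P=ts.P, n_molecules=ts.n_molecules,
        )
        r0 = npt_fluctuations(ts, n_blocks=1)
        r1 = npt_fluctuations(shuffled, n_blocks=1)
        for key in ("kappa_T", "alpha_P", "C_P"):
            assert r1[key] == pytest.approx(r0[key], rel=1e-12)

    def test_too_short_series_rejected(self):
        ts = ThermoSeries(
            time=np.arange(10.0), U=np.zeros(10), V=np.ones(10),
            H=np.zeros(10), T=293.0, P=1.0, n_molecules=10,
        )
        with pytest.raises(ValueError):
            npt_fluctuations(ts)


class TestDerivedCaloric:
    def test_zero_expansion_means_cv_equals_cp(self):
        r = derived_caloric(0.0, 4e-5, 50.0, 283.0, 120.0)
        assert r["C_V"] == 50.0
        assert r["kappa_S"] == 4e-5

    def test_ratio_0980_scales_kappa(self):
        # choose alpha so that C_V/C_P = 0.980, the pure-peroxide 283 K ratio
        cp, T, V, kt = 50.0, 283.0, 120.0, 4e-5
        from peroxifit.constants import BAR_NM3_TO_KJ_MOL

        alpha = math.sqrt(0.02 * cp * kt / (T * V * BAR_NM3_TO_KJ_MOL))
        r = derived_caloric(alpha, kt, cp, T, V)
        assert r["C_V"] / cp == pytest.approx(0.980, abs=1e-12)
        assert r["kappa_S"] == pytest.approx(0.980 * kt, rel=1e-12)

    def test_adiabatic_never_exceeds_isothermal(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            kt = 10 ** rng.uniform(-6, -3)
            cp = rng.uniform(10.0, 200.0)
            alpha = rng.uniform(0.0, 2e-3)
            try:
                r = derived_caloric(alpha, kt, cp, 300.0, 100.0)
            except ValueError:
                continue
            assert r["C_V"] <= cp
            assert r["kappa_S"] <= kt
            if alpha == 0.0:
                assert r["kappa_S"] == kt

    def test_inconsistent_inputs_flagged(self):
        with pytest.raises(ValueError, match="second law"):
            derived_caloric(5e-2, 1e-6, 1.0, 300.0, 1000.0)


class TestDielectric:
    def test_constant_dipole_gives_unity(self):
        n = 2000
        ds = DipoleSeries(
            time=np.arange(n), M=np.tile([3.0, -1.0, 2.0], (n, 1)), V=100.0, T=293.0
        )
        assert dielectric_constant(ds)["epsilon"] == pytest.approx(1.0, abs=1e-12)

    def test_recovers_target_epsilon(self):
        fx = gen_fluctuation_series({"epsilon": 25.0}, {"n_frames": 100_000}, seed=2)
        r = dielectric_constant(fx["dipole"])
        assert r["epsilon"] == pytest.approx(25.0, rel=0.05)

    def test_invariant_under_global_rotation(self):
        from scipy.spatial.transform import Rotation

        fx = gen_fluctuation_series({"epsilon": 10.0}, {"n_frames": 20_000}, seed=3)
        ds = fx["dipole"]
        rot = Rotation.random(random_state=1).as_matrix()
        ds_rot = DipoleSeries(time=ds.time, M=ds.M @ rot.T, V=ds.V, T=ds.T)
        # isotropic variance sum is rotation invariant
        assert dielectric_constant(ds_rot)["epsilon"] == pytest.approx(
            dielectric_constant(ds)["epsilon"], rel=1e-10
        )

    def test_empty_series_rejected(self):
        with pytest.raises(Exception):
            dielectric_constant(
                DipoleSeries(time=np.array([]), M=np.empty((0, 3)), V=1.0, T=300.0)
            )


class TestDiffusion:
    def test_immobile_particles(self):
        pos = np.zeros((200, 8, 3))
        r = diffusion_einstein(np.arange(200.0), positions=pos)
        assert r["D"] == 0.0

    def test_exact_linear_msd(self):
        t = np.linspace(0.0, 100.0, 101)
        d_nm = 1.5e-3  # nm^2/ps, i.e. 1.5e-9 m^2/s
        r = diffusion_einstein(t, msd=6.0 * d_nm * t)
        assert r["D"] == pytest.approx(1.5e-9, rel=1e-12)

    def test_recovers_random_walk_coefficient(self):
        fx = gen_fluctuation_series({"D": 1.5e-9}, {}, seed=0)
        r = diffusion_einstein(fx["msd_time"], positions=fx["positions"])
        assert r["D"] == pytest.approx(1.5e-9, rel=0.03)

    def test_negative_slope_flagged(self):
        t = np.linspace(0.0, 100.0, 101)
        with pytest.warns(UserWarning):
            r = diffusion_einstein(t, msd=-(6.0 * 1e-3) * t)
        assert r["D"] == 0.0 and r["negative_slope"]


def _two_waters(r_oo, theta_deg, box=5.0):
    """Two water molecules: donor O-H aimed at the acceptor O with the
    hydrogen-donor-acceptor angle set to theta."""
    th = math.radians(theta_deg)
    d_oh = 0.09572
    positions = np.array(
        [
            [1.0, 1.0, 1.0],                                   # O donor
            [1.0 + d_oh * math.cos(th), 1.0 + d_oh * math.sin(th), 1.0],  # H (donor)
            [1.0 - 0.05, 1.0 - 0.08, 1.0],                      # H spectator
            [1.0 + r_oo, 1.0, 1.0],                             # O acceptor
            [1.0 + r_oo + 0.05, 1.0 + 0.08, 1.0],               # H
            [1.0 + r_oo + 0.05, 1.0 - 0.08, 1.0],               # H
        ]
    )
    return dict(
        positions=positions,
        box=np.array([box, box, box]),
        species=np.array(["H2O"] * 6),
        elements=np.array(["O", "H", "H", "O", "H", "H"]),
        molecule_ids=np.array([0, 0, 0, 1, 1, 1]),
    )


class TestHydrogenBonds:
    def test_inside_both_cutoffs_counts_one(self):
        r = hydrogen_bonds(**_two_waters(0.30, 10.0))
        assert r["counts"]["water-water"] == 1

    def test_distance_cutoff(self):
        assert hydrogen_bonds(**_two_waters(0.36, 10.0))["counts"]["total"] == 0

    def test_angle_cutoff(self):
        assert hydrogen_bonds(**_two_waters(0.30, 40.0))["counts"]["total"] == 0

    def test_translation_and_relabel_invariance(self):
        cfg = _two_waters(0.30, 10.0)
        base = hydrogen_bonds(**cfg)["counts"]["total"]
        shifted = dict(cfg, positions=(cfg["positions"] + np.array([3.7, 4.9, 2.1])))
        assert hydrogen_bonds(**shifted)["counts"]["total"] == base
        order = [3, 4, 5, 0, 1, 2]
        relabeled = dict(
            positions=cfg["positions"][order],
            box=cfg["box"],
            species=cfg["species"][order],
            elements=cfg["elements"][order],
            molecule_ids=cfg["molecule_ids"][order],
        )
        assert hydrogen_bonds(**relabeled)["counts"]["total"] == base

    def test_minimum_image_across_boundary(self):
        cfg = _two_waters(0.30, 10.0, box=2.0)
        cfg["positions"][3:, 0] += 2.0  # acceptor in the next image
        assert hydrogen_bonds(**cfg)["counts"]["total"] == 1

    def test_normalization_classes(self):
        cfg = _two_waters(0.30, 10.0)
        cfg["species"] = np.array(["H2O2"] * 3 + ["H2O"] * 3)
        r = hydrogen_bonds(**cfg)
        assert r["counts"]["cross"] == 1
        assert r["n_h"]["cross"] == 1.0  # one bond per one peroxide oxygen
        assert r["n_h"]["total"] == 0.5

    def test_missing_hydrogen_rejected(self):
        with pytest.raises(ValueError):
            hydrogen_bonds(
                positions=np.array([[0.0, 0, 0], [0.3, 0, 0]]),
                box=np.array([5.0, 5, 5]),
                species=np.array(["H2O", "H2O"]),
                elements=np.array(["O", "O"]),
                molecule_ids=np.array([0, 1]),
            )


class TestViscosity:
    def test_noise_free_inversion_exact(self):
        eta, A, L_z, rho = 1.0, 0.05, 6.0, 1450.0
        k = 2 * math.pi / L_z
        v = A * rho / (eta * 1e-3 * k**2) * 1e-6
        assert viscosity_cosine_flow(np.full(100, v), A, rho, L_z) == pytest.approx(
            eta, rel=1e-10
        )

    def test_linear_in_acceleration_at_fixed_velocity(self):
        v = np.full(10, 0.2)
        e1 = viscosity_cosine_flow(v, 0.05, 1450.0, 6.0)
        e2 = viscosity_cosine_flow(v, 0.10, 1450.0, 6.0)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_recovers_noisy_target(self):
        fx = gen_fluctuation_series({"eta": 1.0}, {"eta_noise": 0.05}, seed=4)
        assert viscosity_cosine_flow(fx["v_amplitude"], 0.05, 1450.0, 6.0) == pytest.approx(
            1.0, rel=0.02
        )

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            viscosity_cosine_flow(np.full(10, -0.1), 0.05, 1450.0, 6.0)


class TestEnthalpyOfVaporization:
    REF = GasReference(a_d_min=114.9, u_g_min=-1.53)

    def test_printed_arithmetic(self):
        assert enthalpy_of_vaporization(-40.0, 300.0, self.REF) == pytest.approx(
            48.447, abs=2e-3
        )

    def test_low_temperature_limit(self):
        assert enthalpy_of_vaporization(-40.0, 1e-12, self.REF) == pytest.approx(
            self.REF.u_g_min + 40.0, abs=1e-9
        )

    def test_rigid_reference_temperature_dependence(self):
        t1, t2, u1, u2 = 280.0, 320.0, -41.0, -39.5
        d = enthalpy_of_vaporization(u2, t2, self.REF, rigid=True) - enthalpy_of_vaporization(
            u1, t1, self.REF, rigid=True
        )
        assert d == pytest.approx(R_KJ * (t2 - t1) - (u2 - u1), rel=1e-12)


class TestSelfPolarization:
    def test_no_shift_no_correction(self):
        assert self_polarization_correction(2.69, 2.69) == 0.0

    @pytest.mark.parametrize("mu_gas, expected", [(2.05, 6.6), (2.26, 3.0)])
    def test_printed_range(self, mu_gas, expected):
        assert round(self_polarization_correction(2.69, mu_gas), 1) == expected
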