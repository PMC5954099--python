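"""Soft-layer electrokinetics: screening, profiles, solvers and fits."""

import math

import numpy as np
import pytest

from glyx import analytic
from glyx.electrokinetics import (
    Electrolyte,
    GlycocalyxModel,
    GraftDistribution,
    build_profile,
    debye_parameter,
    fit_scenario,
    hpg_stokes_radius,
    mobility_curve,
    solve_mobility,
    solve_potential,
)
from glyx.errors import (InvalidParameterError, UnderDeterminedError)
from glyx.synthetic import gen_mobility_dataset

MOLECULES = [0.0, 2.0e5, 4.0e5, 6.0e5, 8.0e5, 9.5e5, 1.2e6]


def two_region_layer(glx: GlycocalyxModel, electrolyte: Electrolyte,
                     L: float) -> analytic.TwoRegionLayer:
    """Analytic description matching a native-only build_profile call."""
    beta = glx.thickness_beta
    f0 = (6.0 * math.pi * electrolyte.viscosity * glx.segment_radius_a
          * glx.segment_surface_density / beta)
    return analytic.TwoRegionLayer(
        beta=beta, rho0=glx.total_surface_charge / beta, f0=f0, L=L,
        sigma_membrane=glx.membrane_surface_charge)


class TestDebye:
    def test_physiological_screening_length(self, electrolyte):
        # closed form evaluated independently: kappa^-1 = 0.799 nm
        assert 1.0 / debye_parameter(electrolyte) == pytest.approx(
            0.799e-9, rel=1e-3)

    def test_square_root_scaling_in_ionic_strength(self, electrolyte):
        stronger = Electrolyte(ionic_strength=4 * electrolyte.ionic_strength)
        assert debye_parameter(stronger) == pytest.approx(
            2 * debye_parameter(electrolyte), rel=1e-12)

    def test_degenerate_electrolyte_rejected(self):
        with pytest.raises(InvalidParameterError):
            Electrolyte(ionic_strength=0.0)


class TestBuildProfile:
    def test_graft_absent_equals_native_only(self, glycocalyx, electrolyte):
        prof = build_profile(glycocalyx, None, electrolyte)
        graft0 = GraftDistribution(molecules_per_cell=0.0, z_lo=2.7e-9,
                                   z_hi=7.8e-9, graft_segment_radius=2.4e-9)
        prof0 = build_profile(glycocalyx, graft0, electrolyte)
        np.testing.assert_array_equal(prof.friction, prof0.friction)

    def test_outer_graft_adds_friction_only_on_its_interval(
            self, glycocalyx, electrolyte):
        native = build_profile(glycocalyx, None, electrolyte)
        graft = GraftDistribution(molecules_per_cell=9.5e5, z_lo=2.7e-9,
                                  z_hi=7.8e-9, graft_segment_radius=2.4e-9)
        grafted = build_profile(glycocalyx, graft, electrolyte)
        grid = native.grid
        dz = native.dz
        inside = (grid > 2.7e-9 + dz) & (grid < 7.8e-9 - dz)
        outside = (grid < 2.7e-9 - dz) | (grid > 7.8e-9 + dz)
        assert np.all(grafted.friction[inside] > native.friction[inside])
        np.testing.assert_allclose(grafted.friction[outside],
                                   native.friction[outside], rtol=1e-12)

    def test_graft_friction_linear_in_molecule_count(
            self, glycocalyx, electrolyte):
        native = build_profile(glycocalyx, None, electrolyte)
        profs = [build_profile(
            glycocalyx,
            GraftDistribution(molecules_per_cell=m, z_lo=0.0, z_hi=7.8e-9,
                              graft_segment_radius=2.4e-9),
            electrolyte) for m in (4.75e5, 9.5e5)]
        single = profs[0].friction - native.friction
        double = profs[1].friction - native.friction
        np.testing.assert_allclose(double, 2 * single, rtol=1e-9)

    def test_fixed_charge_integrates_to_surface_charge(
            self, glycocalyx, electrolyte):
        prof = build_profile(glycocalyx, None, electrolyte)
        assert prof.total_fixed_charge() == pytest.approx(
            glycocalyx.total_surface_charge, rel=1e-6)

    def test_graft_interval_outside_layer_rejected(
            self, glycocalyx, electrolyte):
        bad = GraftDistribution(molecules_per_cell=1e5, z_lo=5e-9,
                                z_hi=9e-9, graft_segment_radius=2.4e-9)
        with pytest.raises(InvalidParameterError):
            build_profile(glycocalyx, bad, electrolyte)


class TestPotential:
    def test_uncharged_system_has_zero_potential(self, electrolyte):
        glx = GlycocalyxModel(total_surface_charge=0.0)
        prof = build_profile(glx, None, electrolyte)
        psi = solve_potential(prof, electrolyte)
        np.testing.assert_allclose(psi, 0.0, atol=1e-18)

    def test_thin_layer_approaches_flat_plate_surface_potential(
            self, electrolyte):
        # all charge compressed to a thin shell: psi(0) -> sigma/(eps*kappa)
        sigma = -0.01
        beta = 0.05e-9
        glx = GlycocalyxModel(thickness_beta=beta,
                              segment_surface_density=0.0,
                              total_surface_charge=sigma)
        prof = build_profile(glx, None, electrolyte,
                             L=beta + 10 / electrolyte.kappa, n_nodes=20000)
        psi = solve_potential(prof, electrolyte)
        expected = sigma / (electrolyte.permittivity * electrolyte.kappa)
        assert psi[0] == pytest.approx(expected, rel=0.04)

    def test_matches_two_region_closed_form(self, glycocalyx, electrolyte):
        prof = build_profile(glycocalyx, None, electrolyte, n_nodes=20000)
        psi = solve_potential(prof, electrolyte)
        layer = two_region_layer(glycocalyx, electrolyte, prof.length)
        psi_ref = analytic.potential_profile(layer, electrolyte, prof.grid)
        err = np.max(np.abs(psi - psi_ref)) / np.max(np.abs(psi_ref))
        assert err < 1e-6


class TestMobility:
    def test_smoluchowski_limit(self, electrolyte):
        zeta = -0.025
        sigma_m = electrolyte.permittivity * electrolyte.kappa * zeta
        glx = GlycocalyxModel(segment_surface_density=0.0,
                              total_surface_charge=0.0,
                              membrane_surface_charge=sigma_m)
        sol = solve_mobility(build_profile(glx, None, electrolyte,
                                           n_nodes=4000), electrolyte)
        mu_ref = analytic.smoluchowski_mobility(zeta, electrolyte)
        assert mu_ref == pytest.approx(-1.95e-8, rel=5e-3)
        assert sol.mobility == pytest.approx(mu_ref, rel=5e-3)
        assert sol.converged

    def test_infinite_drag_screens_flow(self, glycocalyx, electrolyte):
        # friction must also cover the diffuse counterion cloud outside the
        # charged layer, else the cloud still electroosmoses
        from glyx.electrokinetics import LayerProfile
        kappa = electrolyte.kappa
        beta_c = glycocalyx.thickness_beta
        beta_f = beta_c + 8.0 / kappa
        L = beta_f + 10.0 / kappa
        grid = np.linspace(0.0, L, 4000)
        friction = np.where(grid <= beta_f, 1e20, 0.0)
        charge = np.where(grid <= beta_c,
                          glycocalyx.total_surface_charge / beta_c, 0.0)
        prof = LayerProfile(grid=grid, friction=friction, fixed_charge=charge,
                            thickness_beta=beta_f)
        sol = solve_mobility(prof, electrolyte)
        native = solve_mobility(
            build_profile(GlycocalyxModel(), None, electrolyte), electrolyte)
        assert abs(sol.mobility) < 1e-3 * abs(native.mobility)

    def test_matches_two_region_closed_form(self, glycocalyx, electrolyte):
        prof = build_profile(glycocalyx, None, electrolyte)
        sol = solve_mobility(prof, electrolyte)
        layer = two_region_layer(glycocalyx, electrolyte, prof.length)
        mu_ref = analytic.mobility(layer, electrolyte)
        assert sol.mobility == pytest.approx(mu_ref, rel=1e-3)

    def test_short_domain_rejected(self, glycocalyx, electrolyte):
        prof = build_profile(glycocalyx, None, electrolyte,
                             L=glycocalyx.thickness_beta
                             + 5 / electrolyte.kappa)
        with pytest.raises(InvalidParameterError):
            solve_mobility(prof, electrolyte)

    def test_grid_convergence(self, glycocalyx, electrolyte):
        mus = [solve_mobility(build_profile(glycocalyx, None, electrolyte,
                                            n_nodes=n), electrolyte).mobility
               for n in (2000, 4000)]
        assert abs(mus[1] - mus[0]) < 1e-3 * abs(mus[0])


class TestMobilityCurve:
    def test_scenarios_agree_with_no_grafting(self, glycocalyx, electrolyte):
        mus = [mobility_curve(glycocalyx, electrolyte, [0.0], s,
                              n_nodes=800)["mobility"].iloc[0]
               for s in ("uniform", "outer")]
        assert mus[0] == mus[1]

    @pytest.mark.parametrize("scenario", ["uniform", "outer"])
    def test_magnitude_decreases_with_graft_number(
            self, glycocalyx, electrolyte, scenario):
        curve = mobility_curve(glycocalyx, electrolyte, MOLECULES, scenario,
                               n_nodes=800)
        mags = curve["mobility"].abs().to_numpy()
        assert np.all(np.diff(mags) < 0)

    def test_outer_grafting_shields_more(self, glycocalyx, electrolyte):
        mus = {s: mobility_curve(glycocalyx, electrolyte, [9.5e5], s,
                                 n_nodes=800)["mobility"].iloc[0]
               for s in ("uniform", "outer")}
        assert abs(mus["outer"]) < abs(mus["uniform"])

    @pytest.mark.parametrize("param,values", [
        ("graft_segment_radius", [1.5e-9, 2.4e-9, 3.5e-9]),
        ("segment_surface_density", [0.7e17, 1.4e17, 2.8e17]),
    ])
    def test_magnitude_monotone_in_drag_parameters(
            self, glycocalyx, electrolyte, param, values):
        mags = []
        for v in values:
            if param == "graft_segment_radius":
                curve = mobility_curve(glycocalyx, electrolyte, [9.5e5],
                                       "outer", graft_segment_radius=v,
                                       n_nodes=800)
            else:
                glx = GlycocalyxModel(segment_surface_density=v)
                curve = mobility_curve(glx, electrolyte, [9.5e5], "outer",
                                       n_nodes=800)
            mags.append(abs(curve["mobility"].iloc[0]))
        assert mags[0] > mags[1] > mags[2]


class TestFitScenario:
    def test_noiseless_data_identifies_generating_scenario(
            self, glycocalyx, electrolyte):
        data = gen_mobility_dataset(glycocalyx, electrolyte, "uniform",
                                    MOLECULES, noise_sd=0.0, seed=0,
                                    n_nodes=800)
        res = fit_scenario(data, glycocalyx, electrolyte, n_nodes=800)
        assert res.best_scenario == "uniform"
        assert res.fits["uniform"].sse < 1e-6 * res.fits["outer"].sse

    def test_noisy_outer_data_recovers_scenario_and_parameter(
            self, glycocalyx, electrolyte):
        data = gen_mobility_dataset(glycocalyx, electrolyte, "outer",
                                    MOLECULES, noise_sd=0.02, seed=3,
                                    n_nodes=800)
        res = fit_scenario(data, glycocalyx, electrolyte)
        assert res.best_scenario == "outer"
        fitted = res.fits["outer"].params["segment_surface_density"]
        assert fitted == pytest.approx(glycocalyx.segment_surface_density,
                                       rel=0.10)

    def test_fewer_points_than_parameters_rejected(
            self, glycocalyx, electrolyte):
        data = gen_mobility_dataset(glycocalyx, electrolyte, "outer",
                                    [9.5e5], noise_sd=0.0, seed=0,
                                    n_nodes=800)
        with pytest.raises(UnderDeterminedError):
            fit_scenario(data, glycocalyx, electrolyte,
                         free_params=("segment_surface_density",
                                      "total_surface_charge"))

    def test_exactly_determined_fit_warns(self, glycocalyx, electrolyte):
        data = gen_mobility_dataset(glycocalyx, electrolyte, "outer",
                                    [4e5, 9.5e5], noise_sd=0.0, seed=0,
                                    n_nodes=800)
        with pytest.warns(UserWarning, match="exactly determined"):
            fit_scenario(data, glycocalyx, electrolyte,
                         free_params=("segment_surface_density",
                                      "total_surface_charge"),
                         n_starts=1)


def test_hpg_radius_scaling():
    # compact branched polymer: R_h = c * M^0.4
    assert hpg_stokes_radius(20000.0) == pytest.approx(2.42e-9, rel=0.01)
    ratio = hpg_stokes_radius(60000.0) / hpg_stokes_radius(20000.0)
    assert ratio == pytest.approx(3.0 ** 0.4, rel=1e-12)
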