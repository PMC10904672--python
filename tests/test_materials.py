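import numpy as np
import pytest

from ctsim.materials import (EnergyGrid, KermaMeasurement, MaterialError,
                             STANDARD_FILTRATIONS, air_kerma,
                             build_material_db, detector_qe,
                             estimate_bowtie_profile, fit_du_gain,
                             fit_spectrum, kramers_spectrum, Spectrum)
from ctsim.materials import _absorbed_energy
from ctsim.synthetic import (reference_spectrum,
                             synthetic_bowtie_kerma_profile,
                             synthetic_kerma_measurements)


class TestEnergyGrid:
    def test_default_grid_spans_5_to_kvp_in_1_kev_steps(self):
        g = EnergyGrid.default(120.0)
        assert g.energies_kev[0] == 5.0
        assert g.energies_kev[-1] == 120.0
        assert g.spacing_kev == 1.0

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError):
            EnergyGrid(np.array([1.0, 2.0, 4.0]))


class TestMaterialDB:
    def test_vacuum_has_zero_attenuation(self, db120):
        assert np.all(db120.mu("vacuum") == 0.0)

    def test_interpolants_agree_across_grid_resolutions(self):
        coarse = build_material_db(EnergyGrid(np.arange(10.0, 121.0, 2.0)),
                                   ["water"])
        fine = build_material_db(EnergyGrid(np.arange(10.0, 121.0, 1.0)),
                                 ["water"])
        shared = np.arange(10.0, 121.0, 2.0)
        idx = np.searchsorted(fine.grid.energies_kev, shared)
        assert fine.mu("water")[idx] == pytest.approx(coarse.mu("water"))

    def test_mixture_rule_mass_weighted_sum(self, db120):
        """mu/rho of a two-component mixture is the mass-weighted sum."""
        grid = db120.grid
        half = build_material_db(grid, [
            ("mix", ({"H": 0.1119 / 2, "O": 0.8881 / 2, "Al": 0.5}, 1.0)),
            ("water_unit", ({"H": 0.1119, "O": 0.8881}, 1.0)),
            ("al_unit", ({"Al": 1.0}, 1.0)),
        ])
        expected = 0.5 * half.mu("water_unit") + 0.5 * half.mu("al_unit")
        assert half.mu("mix") == pytest.approx(expected, rel=1e-12)

    def test_unknown_composition_names_material(self):
        with pytest.raises(MaterialError, match="mystery"):
            build_material_db(EnergyGrid.default(120.0),
                              [("mystery", ({"Xx": 1.0}, 1.0))])

    def test_csv_table_round_trip(self, tmp_path, db120):
        path = tmp_path / "water.csv"
        with open(path, "w") as fh:
            fh.write("energy_keV,mu_per_mm\n")
            for e, mu in zip(db120.grid.energies_kev, db120.mu("water")):
                fh.write(f"{e},{mu:.12g}\n")
        db = build_material_db(db120.grid, [("water_csv", path)])
        assert db.mu("water_csv") == pytest.approx(db120.mu("water"),
                                                   rel=1e-6)


class TestAirKerma:
    def test_delta_spectrum_closed_form(self, db120):
        """No filtration: kerma = N * E * (mu_en/rho)_air(E)."""
        grid = db120.grid
        n = np.zeros(len(grid))
        e_idx = 55  # 60 keV
        n[e_idx] = 1e4
        spec = Spectrum(grid, n, 120.0)
        expected = 1e4 * grid.energies_kev[e_idx] \
            * db120["air"].mu_en_rho_cm2g[e_idx]
        assert air_kerma(spec, [], db120) == pytest.approx(expected)

    def test_filtration_strictly_decreases_kerma(self, db120):
        spec = reference_spectrum(db120, 120.0)
        k = [air_kerma(spec, [("aluminum", t)], db120)
             for t in (0.0, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(k) < 0)

    def test_monochromatic_double_thickness_ratio_squares(self, db120):
        """K(2t)/K(0) = (K(t)/K(0))^2 for a monochromatic beam."""
        grid = db120.grid
        n = np.zeros(len(grid))
        n[45] = 1.0
        spec = Spectrum(grid, n, 120.0)
        k0 = air_kerma(spec, [], db120)
        k1 = air_kerma(spec, [("copper", 0.3)], db120)
        k2 = air_kerma(spec, [("copper", 0.6)], db120)
        assert k2 / k0 == pytest.approx((k1 / k0) ** 2, rel=1e-12)

    def test_negative_thickness_rejected(self, db120):
        spec = reference_spectrum(db120, 120.0)
        with pytest.raises(ValueError):
            air_kerma(spec, [("aluminum", -1.0)], db120)


class TestSpectrumFit:
    def test_recovers_kerma_under_all_four_filtrations(self, db120):
        truth = reference_spectrum(db120, 120.0)
        meas = synthetic_kerma_measurements(truth, db120)
        fitted = fit_spectrum(meas, 120.0, db120)
        for m in meas:
            k = air_kerma(fitted, m.filtration, db120)
            assert k == pytest.approx(m.kerma, rel=0.01)

    def test_in_span_target_recovers_transmission_curve(self, db120):
        """A target inside the basis family fits with ~zero residual."""
        truth = kramers_spectrum(db120.grid, 120.0, 4.5, db120,
                                 photons_total=3e6)
        meas = synthetic_kerma_measurements(truth, db120)
        fitted = fit_spectrum(meas, 120.0, db120)
        thick = np.linspace(0.0, 10.0, 8)
        t_true = [air_kerma(truth, [("aluminum", t)], db120) for t in thick]
        t_fit = [air_kerma(fitted, [("aluminum", t)], db120) for t in thick]
        assert np.asarray(t_fit) == pytest.approx(np.asarray(t_true),
                                                  rel=0.01)

    def test_support_zero_above_tube_voltage(self):
        db80 = build_material_db(EnergyGrid.default(100.0))
        truth = kramers_spectrum(db80.grid, 80.0, 3.0, db80,
                                 photons_total=1e6)
        meas = synthetic_kerma_measurements(truth, db80)
        fitted = fit_spectrum(meas, 80.0, db80)
        above = db80.grid.energies_kev > 80.0
        assert np.all(fitted.photons_per_mas[above] == 0.0)
        assert np.all(fitted.photons_per_mas >= 0.0)

    def test_negative_measurement_rejected(self, db120):
        with pytest.raises(ValueError):
            KermaMeasurement((), -1.0)

    def test_csv_round_trip(self, tmp_path, db120):
        spec = reference_spectrum(db120, 120.0)
        spec.save_csv(tmp_path / "s.csv")
        again = Spectrum.load_csv(tmp_path / "s.csv", 120.0)
        assert again.photons_per_mas == pytest.approx(spec.photons_per_mas)


class TestDUGain:
    def test_exact_proportionality_recovered(self, db120):
        spec = reference_spectrum(db120, 120.0)
        qe = detector_qe(db120.grid, "csi", 0.6, db120)
        du = [3.5 * _absorbed_energy(spec, qe, f, db120)
              for f in STANDARD_FILTRATIONS]
        got = fit_du_gain(du, STANDARD_FILTRATIONS, spec, qe, db120)
        assert got.gain == pytest.approx(3.5, rel=1e-12)

    def test_noisy_readings_within_two_percent(self, db120, rng):
        spec = reference_spectrum(db120, 120.0)
        qe = detector_qe(db120.grid, "csi", 0.6, db120)
        du = [0.02 * _absorbed_energy(spec, qe, f, db120)
              * (1 + 0.01 * rng.standard_normal())
              for f in STANDARD_FILTRATIONS]
        got = fit_du_gain(du, STANDARD_FILTRATIONS, spec, qe, db120)
        assert got.gain == pytest.approx(0.02, rel=0.02)

    def test_independent_gains_per_bowtie(self, db120, rng):
        spec = reference_spectrum(db120, 120.0)
        qe = detector_qe(db120.grid, "csi", 0.6, db120)
        gains = {}
        for bid, g in (("body", 0.015), ("head", 0.03)):
            du = [g * _absorbed_energy(spec, qe, f, db120)
                  for f in STANDARD_FILTRATIONS]
            gains[bid] = fit_du_gain(du, STANDARD_FILTRATIONS, spec, qe,
                                     db120, bowtie_id=bid)
        assert gains["body"].gain == pytest.approx(0.015)
        assert gains["head"].gain == pytest.approx(0.03)


class TestBowtieEstimation:
    offsets = np.arange(0.0, 165.0, 5.0)

    def test_flat_profile_gives_zero_thickness(self, db120):
        spec = reference_spectrum(db120, 120.0)
        k0 = air_kerma(spec, [], db120)
        bt = estimate_bowtie_profile(self.offsets,
                                     np.full(self.offsets.size, k0),
                                     spec, "aluminum", db120)
        assert np.all(bt.thickness_mm == 0.0)

    def test_round_trips_known_thickness_law(self, db120):
        spec = reference_spectrum(db120, 120.0)
        t_true = 4.0e-4 * self.offsets**2
        prof = synthetic_bowtie_kerma_profile(
            spec, db120, "aluminum", lambda x: 4.0e-4 * x**2, self.offsets)
        bt = estimate_bowtie_profile(self.offsets, prof, spec, "aluminum",
                                     db120)
        nz = t_true > 0
        assert bt.thickness_mm[nz] == pytest.approx(t_true[nz], rel=0.02)

    def test_decreasing_profile_gives_increasing_thickness(self, db120):
        spec = reference_spectrum(db120, 120.0)
        k0 = air_kerma(spec, [], db120)
        prof = k0 * np.exp(-np.linspace(0.0, 2.0, self.offsets.size))
        bt = estimate_bowtie_profile(self.offsets, prof, spec, "aluminum",
                                     db120)
        assert np.all(np.diff(bt.thickness_mm) > 0)

    def test_kerma_above_reference_rejected(self, db120):
        spec = reference_spectrum(db120, 120.0)
        k0 = air_kerma(spec, [], db120)
        with pytest.raises(ValueError, match="exceeds"):
            estimate_bowtie_profile(self.offsets,
                                    np.full(self.offsets.size, 2 * k0),
                                    spec, "aluminum", db120)

    def test_resampled_to_channels_via_geometry(self, db120, desk_geometry):
        spec = reference_spectrum(db120, 120.0)
        prof = synthetic_bowtie_kerma_profile(
            spec, db120, "aluminum", lambda x: 4.0e-4 * x**2, self.offsets)
        bt = estimate_bowtie_profile(self.offsets, prof, spec, "aluminum",
                                     db120, geometry=desk_geometry)
        assert bt.thickness_mm.size == desk_geometry.n_channels
        lat = desk_geometry.source_to_isocenter_mm * np.sin(
            np.abs(desk_geometry.channel_angles_rad()))
        # 5 mm profile steps linearize the law near the center: allow a
        # small absolute floor there on top of the relative tolerance
        assert bt.thickness_mm == pytest.approx(4.0e-4 * lat**2, rel=0.05,
                                                abs=0.005)


class TestDetectorQE:
    def test_zero_thickness_gives_zero_qe(self, db120):
        qe = detector_qe(db120.grid, "csi", 0.0, db120)
        assert np.all(qe.qe == 0.0)

    def test_thick_absorber_limit_is_one(self, db120):
        qe = detector_qe(db120.grid, "csi", 1e6, db120)
        assert np.all(qe.qe[db120.mu("csi") > 0] == pytest.approx(1.0))

    def test_qe_monotone_in_thickness(self, db120):
        qes = [detector_qe(db120.grid, "csi", t, db120).qe
               for t in (0.2, 0.4, 0.8)]
        assert np.all(qes[1] >= qes[0])
        assert np.all(qes[2] >= qes[1])

    def test_negative_thickness_rejected(self, db120):
        with pytest.raises(ValueError):
            detector_qe(db120.grid, "csi", -0.1, db120)
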