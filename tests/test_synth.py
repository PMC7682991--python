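"""Synthetic-data generators: driftscope frames, CE series, kinetics, toy PDBs."""
import numpy as np
import pandas as pd
import pytest

from abeta_ims import chem, structure, synth
from abeta_ims.frames import read_frame, write_frame


@pytest.fixture
def narrow_mz():
    return np.arange(1804.0, 1810.5, 0.01)


class TestDriftscope:
    def test_noiseless_marginal_reproduces_isotope_envelope(self, narrow_mz, drift_grid):
        spec = synth.dimer_conformer_fixture()
        frame = synth.simulate_driftscope([spec], narrow_mz, drift_grid)
        envelope = synth.isotope_envelope(spec, narrow_mz)
        total_abundance = sum(c.abundance for c in spec.conformers)
        assert np.allclose(frame.mz_marginal, total_abundance * envelope, atol=1e-9)

    def test_overlap_fixture_has_three_drift_features_with_charge_spacings(
        self, drift_grid
    ):
        """m/z-degenerate 1+/2, 2/4, 3/6 species: one m/z cluster, three
        drift features, isotope spacings 1.0034/z."""
        mz = np.arange(2254.0, 2264.0, 0.008)
        frame = synth.simulate_driftscope(
            synth.degenerate_overlap_fixture(), mz, drift_grid
        )
        # drift marginal has exactly 3 peaks at the ground-truth centroids
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(frame.drift_marginal, height=0.01)
        assert len(peaks) == 3
        got = drift_grid[peaks]
        assert np.allclose(sorted(got), [5.5, 8.5, 11.5], atol=0.05)
        for truth, expected_spacing in zip(
            frame.metadata["ground_truth"], [0.502, 0.251, 0.167]
        ):
            assert chem.NEUTRON_SPACING / truth["z"] == pytest.approx(
                expected_spacing, abs=1e-3
            )

    def test_same_seed_bit_identical(self, narrow_mz, drift_grid):
        noise = synth.NoiseModel(sigma=0.05, baseline=1e-4, seed=42)
        a = synth.simulate_driftscope(
            [synth.dimer_conformer_fixture()], narrow_mz, drift_grid, noise
        )
        b = synth.simulate_driftscope(
            [synth.dimer_conformer_fixture()], narrow_mz, drift_grid, noise
        )
        assert np.array_equal(a.intensity, b.intensity)
        assert a.metadata["seed"] == 42

    def test_species_outside_grid_rejected(self, drift_grid):
        mz = np.arange(1000.0, 1010.0, 0.01)
        with pytest.raises(ValueError, match="falls outside"):
            synth.simulate_driftscope(
                [synth.dimer_conformer_fixture()], mz, drift_grid
            )

    def test_frame_text_round_trip(self, tmp_path, narrow_mz, drift_grid):
        frame = synth.simulate_driftscope(
            [synth.dimer_conformer_fixture()],
            narrow_mz,
            drift_grid,
            synth.NoiseModel(sigma=0.02, seed=7),
        )
        path = tmp_path / "frame.tsv"
        write_frame(frame, path)
        back = read_frame(path)
        assert back.metadata["seed"] == 7
        assert np.allclose(back.mz, frame.mz, atol=1e-6)
        assert np.allclose(back.intensity, frame.intensity, rtol=1e-8)


class TestCIUSeries:
    def test_unfolded_is_half_at_midpoint(self):
        """Noiseless, cap 1, dissociation far away: the unfolded fraction
        at E = E50 is exactly 0.5 (85 eV hits the grid at 17 V, z=5)."""
        truth = synth.CIUGroundTruth(e50_ciu=85.0, e50_cid=1e9)
        volts = np.arange(5.0, 51.0, 1.0)
        df = synth.simulate_ciu_series(truth, volts, z=5)
        at_midpoint = df.loc[df.energy_ev == 85.0, "unfolded"].iloc[0]
        assert at_midpoint == pytest.approx(0.5, abs=1e-12)

    def test_cap_limits_max_unfolding(self):
        """With a 15% cap and early dissociation the observed CIU product
        never exceeds 15%."""
        truth = synth.CIUGroundTruth(e50_ciu=85.0, e50_cid=70.0, cap=0.15)
        df = synth.simulate_ciu_series(truth, synth.methods_voltage_ramp(), z=5)
        assert df.unfolded.max() <= 0.15 + 1e-12

    def test_survival_is_half_at_cid_midpoint(self):
        truth = synth.CIUGroundTruth(e50_ciu=1e6, e50_cid=125.0)
        volts = np.arange(5.0, 51.0, 1.0)
        df = synth.simulate_ciu_series(truth, volts, z=5)
        assert df.loc[df.energy_ev == 125.0, "surviving"].iloc[0] == pytest.approx(
            0.5, abs=1e-12
        )

    def test_fractions_bounded_and_survival_monotone(self):
        truth = synth.CIUGroundTruth(e50_ciu=85.0, e50_cid=125.0)
        df = synth.simulate_ciu_series(truth, synth.methods_voltage_ramp(), z=5)
        for col in ("folded", "unfolded", "surviving"):
            assert ((df[col] >= 0) & (df[col] <= 1)).all()
        assert (np.diff(df.surviving) <= 1e-12).all()

    def test_lab_frame_energy_axis(self):
        df = synth.simulate_ciu_series(
            synth.CIUGroundTruth(e50_ciu=85.0, e50_cid=1e6),
            synth.methods_voltage_ramp(),
            z=5,
        )
        assert np.allclose(df.energy_ev, 5 * synth.methods_voltage_ramp())

    def test_decreasing_voltages_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_ciu_series(
                synth.CIUGroundTruth(e50_ciu=85.0, e50_cid=1e6),
                np.array([10.0, 5.0]),
                z=5,
            )


class TestKinetics:
    def test_zero_rate_keeps_monomer_only(self):
        truth = synth.KineticsGroundTruth(rate=0.0)
        run = synth.simulate_lilbid_timeseries(truth, np.arange(0.0, 101.0, 10.0))
        clean = run.noiseless
        assert np.allclose(clean[:, 0], truth.monomer_pool, rtol=1e-9)
        assert np.all(clean[:, 1:] == 0)

    def test_inhibitor_order_cap_is_strict(self):
        truth = synth.KineticsGroundTruth(inhibitor=True, order_cap=6)
        run = synth.simulate_lilbid_timeseries(truth, np.arange(0.0, 201.0, 10.0))
        assert np.all(run.noiseless[:, 6:] == 0.0)

    def test_mass_conservation(self):
        truth = synth.KineticsGroundTruth()
        run = synth.simulate_lilbid_timeseries(truth, np.arange(0.0, 201.0, 5.0))
        orders = np.arange(1, truth.n_max + 1)
        mass = (run.noiseless * orders).sum(axis=1)
        assert np.allclose(mass, mass[0], rtol=1e-6)

    def test_replicates_and_determinism(self):
        truth = synth.KineticsGroundTruth()
        noise = synth.NoiseModel(sigma=0.05, seed=3)
        a = synth.simulate_lilbid_timeseries(truth, np.arange(0.0, 51.0, 10.0), 4, noise)
        b = synth.simulate_lilbid_timeseries(truth, np.arange(0.0, 51.0, 10.0), 4, noise)
        assert a.intensities.shape[0] == 4
        assert np.array_equal(a.intensities, b.intensities)

    def test_dataframe_export_schema(self):
        truth = synth.KineticsGroundTruth()
        run = synth.simulate_lilbid_timeseries(truth, np.arange(0.0, 21.0, 10.0))
        df = synth.lilbid_to_dataframe(run, "free")
        assert {"time_min", "replicate", "condition", "I_1", "I_12"} <= set(df.columns)
        assert len(df) == 4 * 3


class TestToyFibril:
    def test_mb_single_layer_atom_count(self):
        pdb = synth.make_toy_fibril_pdb(1, "MB")
        st = structure.read_structure(pdb)
        assert len(st) == 24  # one monomer template

    def test_db_three_layers_has_six_monomers(self):
        pdb = synth.make_toy_fibril_pdb(3, "DB")
        st = structure.read_structure(pdb)
        assert len(st) == 6 * 24
        assert len(set(st.chains)) == 6

    def test_pdb_round_trip_preserves_coordinates(self):
        pdb = synth.make_toy_fibril_pdb(2, "DB")
        st = structure.read_structure(pdb)
        again = structure.read_structure(pdb)
        assert np.allclose(st.coords, again.coords)
        # layer spacing encoded along z
        z_values = np.unique(np.round(st.coords[:, 2], 3))
        assert np.allclose(z_values, [0.0, synth.TOY_LAYER_SPACING])

    def test_invalid_layers_rejected(self):
        with pytest.raises(ValueError):
            synth.make_toy_fibril_pdb(0, "MB")
        with pytest.raises(ValueError):
            synth.make_toy_fibril_pdb(2, "XX")
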