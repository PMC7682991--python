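"""CIU/CID transition fitting, energy-gap regimes, bound-vs-free comparison."""
import numpy as np
import pytest

from abeta_ims import ciu, synth
from abeta_ims.ciu import (
    StabilityCurve,
    build_fingerprint,
    compare_bound_free,
    fit_transition,
    gap_analysis,
    lab_frame_energy,
)


class TestLabFrameEnergy:
    def test_dimer_at_17v(self):
        """17 V on the 5+ dimer is 85 eV — the energy scale on which the
        dimer reaches 50% unfolding."""
        assert lab_frame_energy(17.0, 5) == 85.0

    def test_unit_charge(self):
        assert lab_frame_energy(5.0, 1) == 5.0

    def test_linear_in_charge(self):
        assert lab_frame_energy(10.0, 6) == 2 * lab_frame_energy(10.0, 3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lab_frame_energy(-1.0, 5)


def make_curve(e50_ciu=85.0, e50_cid=1e6, cap=1.0, noise_sigma=0.0, seed=0,
               volts=None, z=5, width_ciu=10.0):
    truth = synth.CIUGroundTruth(
        e50_ciu=e50_ciu, e50_cid=e50_cid, cap=cap, width_ciu=width_ciu
    )
    volts = synth.methods_voltage_ramp() if volts is None else volts
    df = synth.simulate_ciu_series(
        truth, volts, z, synth.NoiseModel(sigma=noise_sigma, seed=seed)
    )
    return StabilityCurve.from_series(df, species=(2, z))


class TestTransitionFit:
    def test_noiseless_round_trip(self):
        fit = fit_transition(make_curve(), "CIU", n_bootstrap=0)
        assert fit.e50_ev == pytest.approx(85.0, abs=1e-6)
        assert fit.width_ev == pytest.approx(10.0, abs=1e-5)
        assert fit.cap == pytest.approx(1.0, abs=1e-8)

    def test_cid_round_trip(self):
        curve = make_curve(e50_ciu=1e5, e50_cid=125.0)
        fit = fit_transition(curve, "CID", n_bootstrap=0)
        assert fit.e50_ev == pytest.approx(125.0, abs=1e-6)

    def test_cap_limited_flag(self):
        """The ligand-bound dimer: 15% cap, early CID — flagged
        cap-limited, absolute 50% never reached, observed max ~0.15."""
        curve = make_curve(e50_cid=135.0, cap=0.15)
        fit = fit_transition(curve, "CIU", n_bootstrap=0)
        assert fit.cap_limited
        assert fit.e50_absolute_ev is None
        assert fit.cap == pytest.approx(0.15, abs=0.02)
        assert curve.extended.max() <= 0.15 + 1e-9

    def test_db_dimer_dissociates_without_unfolding(self):
        """cap 0 (no unfolding channel): CID midpoint recovered, CIU
        flagged absent."""
        curve = make_curve(e50_cid=85.0, cap=0.0, noise_sigma=0.01, seed=3)
        cid = fit_transition(curve, "CID", n_bootstrap=0)
        assert cid.e50_ev == pytest.approx(85.0, abs=3.0)
        ciu_fit = fit_transition(curve, "CIU", n_bootstrap=0)
        assert "absent" in ciu_fit.flags

    def test_all_zero_signal_rejected(self):
        curve = StabilityCurve(
            energy_ev=np.arange(25.0, 275.0, 25.0),
            compact=np.zeros(10),
            extended=np.zeros(10),
        )
        with pytest.raises(ValueError):
            fit_transition(curve, "CID")

    def test_too_few_points_rejected(self):
        curve = StabilityCurve(
            energy_ev=np.array([10.0, 20.0, 30.0, 40.0]),
            compact=np.ones(4) * 0.5,
            extended=np.ones(4) * 0.4,
        )
        with pytest.raises(ValueError):
            fit_transition(curve, "CIU")

    def test_e50_recovery_bias_under_noise(self):
        """2% noise on the 5 V grid: median absolute E50 error < 2 eV over
        100 seeds."""
        errors = []
        for seed in range(100):
            curve = make_curve(noise_sigma=0.02, seed=seed)
            fit = fit_transition(curve, "CIU", n_bootstrap=0)
            errors.append(abs(fit.e50_ev - 85.0))
        assert np.median(errors) < 2.0

    def test_bootstrap_uncertainty_reported(self):
        curve = make_curve(noise_sigma=0.02, seed=5)
        fit = fit_transition(curve, "CIU", n_bootstrap=50, seed=11)
        assert fit.e50_se > 0

    def test_cap_detection_has_no_boundary_flakiness(self):
        """Caps clearly below/above 0.5 are classified correctly."""
        for cap, expect_limited in [(0.30, True), (0.44, True), (0.56, False), (0.8, False)]:
            curve = make_curve(cap=cap, noise_sigma=0.01, seed=7)
            fit = fit_transition(curve, "CIU", n_bootstrap=0)
            assert fit.cap_limited == expect_limited, cap


class TestGapAnalysis:
    def test_two_regime_energy_gaps(self):
        e50 = {2: 85.0, 3: 185.0, 4: 285.0, 5: 335.0, 6: 385.0, 7: 435.0}
        result = gap_analysis(e50)
        assert result.breakpoint_order == 4
        assert result.gap_low_ev == pytest.approx(100.0)
        assert result.gap_high_ev == pytest.approx(50.0)
        assert not result.degenerate

    def test_equidistant_input_degenerate(self):
        e50 = {n: 100.0 * n for n in range(2, 8)}
        result = gap_analysis(e50)
        assert result.degenerate
        assert result.breakpoint_order is None
        assert result.gap_low_ev == pytest.approx(100.0)

    def test_three_orders_rejected(self):
        with pytest.raises(ValueError):
            gap_analysis({2: 85.0, 3: 185.0, 4: 285.0})

    def test_breakpoint_at_moderate_contrast(self):
        """25% gap contrast is still resolved."""
        e50 = {2: 100.0, 3: 200.0, 4: 300.0, 5: 375.0, 6: 450.0, 7: 525.0}
        result = gap_analysis(e50)
        assert result.breakpoint_order == 4
        assert result.gap_high_ev == pytest.approx(75.0)


class TestBoundFree:
    def _fit(self, kind="CID", e50=125.0, se=1.0, cap=1.0, flags=()):
        return ciu.TransitionFit(
            kind=kind, e50_ev=e50, width_ev=10.0, cap=cap, e50_se=se,
            species=(2, 5), flags=list(flags),
        )

    def test_identical_fits_unchanged(self):
        result = compare_bound_free(self._fit(), self._fit())
        assert result.delta_e50_ev == 0.0
        assert result.classes == ["unchanged"]

    def test_cid_stabilized(self):
        result = compare_bound_free(self._fit(e50=125.0), self._fit(e50=140.0))
        assert result.classes == ["CID-stabilized"]
        assert result.delta_e50_ev == pytest.approx(15.0)

    def test_ciu_suppressed_cap_limited(self):
        free = self._fit(kind="CIU", e50=85.0)
        bound = self._fit(kind="CIU", e50=90.0, cap=0.15, flags=["cap-limited"])
        result = compare_bound_free(free, bound)
        assert result.classes == ["CIU-suppressed (cap-limited)"]

    def test_species_mismatch_rejected(self):
        other = ciu.TransitionFit(
            kind="CID", e50_ev=125.0, width_ev=10.0, cap=1.0, species=(3, 7)
        )
        with pytest.raises(ValueError, match="species"):
            compare_bound_free(self._fit(), other)

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            compare_bound_free(self._fit(kind="CIU"), self._fit(kind="CID"))


class TestFingerprint:
    def test_single_conformer_constant_ridge(self, drift_grid):
        profiles = [
            (v, np.exp(-0.5 * ((drift_grid - 8.0) / 0.35) ** 2))
            for v in synth.methods_voltage_ramp()
        ]
        fp = build_fingerprint(profiles, drift_grid)
        ridge_drift = fp.columns[np.argmax(fp.to_numpy(), axis=1)]
        assert np.allclose(ridge_drift, 8.0, atol=0.05)

    def test_rows_normalized(self, drift_grid):
        profiles = [
            (v, 10.0 * v * np.exp(-0.5 * ((drift_grid - 8.0) / 0.35) ** 2))
            for v in (5.0, 10.0, 15.0, 20.0, 25.0)
        ]
        fp = build_fingerprint(profiles, drift_grid)
        assert np.allclose(fp.sum(axis=1), 1.0, atol=1e-9)

    def test_two_state_ridge_handoff_at_midpoint(self, drift_grid):
        """The dominant drift ridge jumps from the compact to the extended
        conformer at the unfolding midpoint energy."""
        truth = synth.CIUGroundTruth(e50_ciu=85.0, e50_cid=1e6)
        df = synth.simulate_ciu_series(truth, synth.methods_voltage_ramp(), z=5)
        profiles = []
        for _, row in df.iterrows():
            p = row.folded * np.exp(-0.5 * ((drift_grid - 8.0) / 0.35) ** 2)
            p += row.unfolded * np.exp(-0.5 * ((drift_grid - 13.0) / 0.45) ** 2)
            profiles.append((row.energy_ev, p))
        fp = build_fingerprint(profiles, drift_grid)
        ridge = np.array(fp.columns[np.argmax(fp.to_numpy(), axis=1)])
        energies = fp.index.to_numpy()
        assert np.all(ridge[energies < 80.0] < 9.0)
        assert np.all(ridge[energies > 90.0] > 12.0)

    def test_mismatched_grid_rejected(self, drift_grid):
        with pytest.raises(ValueError):
            build_fingerprint([(5.0, np.ones(3))], drift_grid)
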