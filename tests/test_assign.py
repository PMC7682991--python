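"""Feature detection, isotope-spacing charge reading, oligomer assignment."""
import numpy as np
import pytest

from abeta_ims import assign, chem, synth
from abeta_ims.chem import NEUTRON_SPACING


@pytest.fixture(scope="module")
def abeta_comp():
    return chem.composition_from_sequence(chem.ABETA42_SEQUENCE)


def make_frame(specs, mz_lo, mz_hi, noise=None, resolving_power=20000.0, mz_step=0.01):
    drift = np.arange(4.0, 16.0, 0.05)
    return synth.simulate_driftscope(
        specs,
        np.arange(mz_lo, mz_hi, mz_step),
        drift,
        noise or synth.NoiseModel(),
        resolving_power=resolving_power,
    )


class TestDetection:
    def test_single_species_single_feature(self):
        spec = synth.SpeciesSpec.from_sequence(
            chem.ABETA42_SEQUENCE, 2, 5, [synth.Conformer(8.0, 0.35, 1.0, "MB")]
        )
        frame = make_frame([spec], 1804.0, 1810.5)
        feats = assign.detect_features(frame)
        assert len(feats) == 1
        assert feats[0].drift_ms == pytest.approx(8.0, abs=0.05)
        assert feats[0].mz == pytest.approx(1806.6, abs=0.1)

    def test_three_conformers_share_one_mz(self):
        frame = make_frame([synth.dimer_conformer_fixture()], 1804.0, 1810.5)
        feats = assign.detect_features(frame)
        assert len(feats) == 3
        assert np.allclose([f.mz for f in feats], feats[0].mz, atol=0.01)
        assert sorted(round(f.drift_ms, 1) for f in feats) == [8.0, 11.0, 13.0]

    def test_blank_noise_frames_rarely_fire(self):
        """Pure-noise frames at SNR threshold 5 yield no features in >= 95%
        of 100 seeds (false-positive control)."""
        blank = np.zeros((60, 120))
        false_positives = 0
        for seed in range(100):
            noise = synth.NoiseModel(sigma=0.0, baseline=1.0, seed=seed)
            intensity = noise.apply(blank, noise.rng())
            from abeta_ims.frames import DriftscopeFrame

            frame = DriftscopeFrame(
                mz=np.linspace(2000.0, 2001.19, 120),
                drift_ms=np.linspace(5.0, 7.95, 60),
                intensity=intensity,
            )
            if assign.detect_features(frame, min_snr=5.0):
                false_positives += 1
        assert false_positives <= 5

    def test_empty_frame_empty_list(self):
        from abeta_ims.frames import DriftscopeFrame

        frame = DriftscopeFrame(
            mz=np.arange(100.0, 101.0, 0.01),
            drift_ms=np.arange(1.0, 2.0, 0.05),
            intensity=np.zeros((20, 100)),
        )
        assert assign.detect_features(frame) == []


class TestSpacing:
    @pytest.mark.parametrize("z,expected", [(5, 0.2007), (4, 0.2509)])
    def test_known_charge_envelopes(self, z, expected):
        spec = synth.SpeciesSpec.from_sequence(
            chem.ABETA42_SEQUENCE, 2, z, [synth.Conformer(8.0, 0.35, 1.0, "MB")]
        )
        s = chem.mz_of_species(spec.species)
        grid = np.arange(s - 3.0, s + 6.0, 0.005)
        profile = synth.isotope_envelope(spec, grid)
        spacing, sigma = assign.estimate_isotope_spacing(grid, profile, z_max=8)
        assert spacing == pytest.approx(expected, abs=0.003)
        assert sigma is not None and sigma > 0

    def test_unresolved_profile_flagged(self):
        grid = np.arange(2256.0, 2260.0, 0.01)
        profile = np.exp(-0.5 * ((grid - 2258.0) / 0.5) ** 2)  # single broad hump
        spacing, sigma = assign.estimate_isotope_spacing(grid, profile)
        assert spacing is None and sigma is None


class TestAssignment:
    def test_dimer_5plus_at_1806(self, abeta_comp):
        frame = make_frame([synth.dimer_conformer_fixture(extended=False)], 1804.0, 1810.5)
        feats = assign.detect_features(frame)
        assign.assign_species(feats, abeta_comp)
        assert all(f.assigned and (f.n, f.z) == (2, 5) for f in feats)

    def test_degenerate_overlap_resolved_by_spacing(self, abeta_comp):
        """The 2258 overlap separates into (1,2), (2,4), (3,6) with
        spacings ~0.502/0.251/0.167 Th."""
        frame = make_frame(synth.degenerate_overlap_fixture(), 2254.0, 2264.0, mz_step=0.008)
        feats = assign.detect_features(frame)
        assign.assign_species(feats, abeta_comp)
        by_drift = sorted(feats, key=lambda f: f.drift_ms)
        assert [(f.n, f.z) for f in by_drift] == [(1, 2), (2, 4), (3, 6)]
        assert np.allclose(
            [f.spacing for f in by_drift], [0.502, 0.251, 0.167], atol=0.003
        )

    def test_unresolved_feature_reports_ambiguous_set(self, abeta_comp):
        feat = assign.Feature(mz=2258.06, drift_ms=8.0, intensity=1.0)
        assign.assign_species([feat], abeta_comp, n_max=6, z_max=6)
        assert not feat.assigned
        assert "ambiguous" in feat.flags
        assert set(feat.candidates) == {(1, 2), (2, 4), (3, 6)}

    @pytest.mark.parametrize("n", range(1, 10))
    def test_full_recovery_monomer_to_nonamer(self, n, abeta_comp):
        """Noiseless frames: every generated (n, z) is recovered with no
        false assignments, up to z = 2n+3 (high-R windows for dense
        isotopologues)."""
        for z in sorted({n + 1, 2 * n + 3}):
            spec = synth.SpeciesSpec.from_sequence(
                chem.ABETA42_SEQUENCE, n, z, [synth.Conformer(8.0, 0.3, 1.0, "MB")]
            )
            center = chem.mz_of_species(spec.species)
            resolving_power = 80000.0
            step = center / resolving_power / 2.3548 / 3.0
            frame = make_frame(
                [spec], center - 3.0, center + 6.0,
                resolving_power=resolving_power, mz_step=step,
            )
            feats = assign.detect_features(frame)
            assign.assign_species(feats, abeta_comp, n_max=12, z_max=24)
            assert [(f.n, f.z) for f in feats if f.assigned] == [(n, z)]

    def test_assignment_invariant_to_intensity_scaling(self, abeta_comp):
        frame = make_frame(synth.degenerate_overlap_fixture(), 2254.0, 2264.0, mz_step=0.008)
        scaled = frame
        scaled.intensity = frame.intensity * 37.5
        feats = assign.detect_features(scaled)
        assign.assign_species(feats, abeta_comp)
        assert sorted((f.n, f.z) for f in feats) == [(1, 2), (2, 4), (3, 6)]


class TestConformerGrouping:
    def _assigned(self, drifts):
        feats = []
        for d in drifts:
            f = assign.Feature(mz=1806.6, drift_ms=d, intensity=1.0)
            f.n, f.z = 2, 5
            f.species = chem.IonSpecies(n=2, z=5, m_avg=4514.1)
            feats.append(f)
        return feats

    def test_mb_db_extended_labels(self):
        feats = self._assigned([8.0, 11.0, 13.0])
        groups = assign.group_conformers(feats)
        assert [f.conformer for f in groups[(2, 5)]["features"]] == [
            "MB",
            "DB",
            "extended-MB",
        ]

    def test_single_conformer_flagged(self):
        feats = self._assigned([8.0])
        groups = assign.group_conformers(feats)
        assert feats[0].conformer == "MB"
        assert "single" in groups[(2, 5)]["flags"]

    def test_db_missing_signature(self):
        """MB + extended only (inhibitor / F19P-like): DB reported missing."""
        feats = self._assigned([8.0, 13.0])
        groups = assign.group_conformers(feats)
        assert [f.conformer for f in feats] == ["MB", "extended-MB"]
        assert "db-missing" in groups[(2, 5)]["flags"]

    def test_no_assigned_features_rejected(self):
        with pytest.raises(ValueError):
            assign.group_conformers([assign.Feature(mz=1.0, drift_ms=1.0, intensity=1.0)])
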