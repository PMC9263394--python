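import json
import logging

import numpy as np
import pytest

from fnirsnet.montage import default_montage, hemisphere_node_sets
from fnirsnet.optics import SingularExtinctionError, hemo_from_od, od_from_hemo
from fnirsnet.paradigm import make_paradigm
from fnirsnet.preprocess import _detect_flags, intensity_to_od
from fnirsnet.synth import (
    ArtifactSpec,
    NoiseSpec,
    SimulationConfig,
    build_target_fc,
    hemo_to_intensity,
    inject_motion_artifacts,
    simulate_cohort,
    simulate_subject,
)


class TestParadigm:
    def test_default_sample_count(self, paradigm):
        # 180 s rest + 5 x (25 + 20) s at 10 Hz
        assert paradigm.n_samples == 4050
        assert paradigm.task_phase_start == 1800

    def test_single_trial_sample_count(self):
        assert make_paradigm(n_trials=1).n_samples == 2250

    @pytest.mark.parametrize("kw", [{"rest_block": 0}, {"task_block": -1},
                                    {"sampling_rate": 0}, {"n_trials": 0}])
    def test_invalid_durations_rejected(self, kw):
        with pytest.raises(ValueError):
            make_paradigm(**kw)

    def test_task_blocks_do_not_overlap(self, paradigm):
        slices = paradigm.task_block_slices()
        assert len(slices) == 5
        for a, b in zip(slices, slices[1:]):
            assert a.stop <= b.start
        assert all(s.stop - s.start == 200 for s in slices)
        assert paradigm.task_boxcar().sum() == 5 * 200


class TestTargetFC:
    def test_exact_blocks_for_lateral_pairs(self, montage):
        fc = build_target_fc(0.6, 0.6, 0.2)
        left, right = hemisphere_node_sets(montage, "inter")  # midline-free
        left, right = sorted(left), sorted(right)
        for i in left:
            for j in left:
                if i != j:
                    assert fc[i - 1, j - 1] == pytest.approx(0.6)
            for j in right:
                assert fc[i - 1, j - 1] == pytest.approx(0.2)
        for i in right:
            for j in right:
                if i != j:
                    assert fc[i - 1, j - 1] == pytest.approx(0.6)
        assert np.allclose(np.diag(fc), 1.0)
        assert np.allclose(fc, fc.T)
        assert np.linalg.eigvalsh(fc).min() >= -1e-10

    def test_jittered_block_means_near_targets(self, montage):
        fc = build_target_fc(0.5, 0.5, 0.1, jitter_sd=0.05, seed=1)
        left, right = hemisphere_node_sets(montage, "inter")
        li = [x - 1 for x in sorted(left)]
        ri = [x - 1 for x in sorted(right)]
        intra = fc[np.ix_(li, li)][~np.eye(13, dtype=bool)]
        inter = fc[np.ix_(li, ri)].ravel()
        assert abs(intra.mean() - 0.5) < 0.02
        assert abs(inter.mean() - 0.1) < 0.02

    def test_extreme_anticorrelated_blocks_remain_psd(self):
        # |inter| <= (1 + 12*intra)/13 for 13-node blocks, so even strongly
        # anti-correlated hemispheres are feasible at high intra coherence
        fc = build_target_fc(0.99, 0.99, -0.9)
        assert np.linalg.eigvalsh(fc).min() >= -1e-10

    def test_infeasible_blocks_projected_with_warning(self, caplog):
        # cross-coupling far above within-block coherence cannot be PSD
        with caplog.at_level(logging.WARNING, logger="fnirsnet.synth"):
            fc = build_target_fc(0.1, 0.1, 0.9)
        assert "nearest-PSD" in caplog.text
        assert np.linalg.eigvalsh(fc).min() >= -1e-10

    @pytest.mark.parametrize("blocks", [(1.0, 0.5, 0.2), (0.5, 0.5, -1.0)])
    def test_block_mean_out_of_range_rejected(self, blocks):
        with pytest.raises(ValueError, match="outside"):
            build_target_fc(*blocks)


class TestMBLLRoundTrip:
    def test_zero_concentration_gives_reference_intensity(self):
        hbo = np.zeros((3, 50))
        intensity = hemo_to_intensity(hbo, hbo, i0=2.5)
        assert np.allclose(intensity, 2.5)

    def test_forward_inverse_identity(self):
        rng = np.random.default_rng(0)
        hbo = rng.normal(0, 0.5, (4, 100))
        hbr = rng.normal(0, 0.2, (4, 100))
        od = od_from_hemo(hbo, hbr)
        hbo2, hbr2 = hemo_from_od(od)
        assert np.allclose(hbo2, hbo, rtol=1e-9, atol=1e-12)
        assert np.allclose(hbr2, hbr, rtol=1e-9, atol=1e-12)

    def test_known_unit_concentration_recovered(self):
        od = od_from_hemo(np.ones((1, 10)), np.zeros((1, 10)))
        hbo, hbr = hemo_from_od(od)
        assert np.allclose(hbo, 1.0)
        assert np.allclose(hbr, 0.0, atol=1e-12)

    def test_singular_extinction_table_rejected(self):
        table = {730.0: (1.0, 2.0), 850.0: (0.5, 1.0)}  # proportional rows
        with pytest.raises(SingularExtinctionError):
            od_from_hemo(np.ones((1, 5)), np.ones((1, 5)), table=table)


class TestSimulateSubject:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=11, artifacts=ArtifactSpec(1, 1, 5.0))
        rec1, _ = simulate_subject(cfg)
        rec2, _ = simulate_subject(cfg)
        np.testing.assert_array_equal(rec1.intensity, rec2.intensity)

    def test_intensities_positive_and_length_matches(self):
        rec, _ = simulate_subject(SimulationConfig(seed=0))
        assert rec.intensity.shape == (29, 2, 4050)
        assert rec.intensity.min() > 0

    def test_noise_free_subject_is_pure_task_response(self):
        cfg = SimulationConfig(seed=0, noise=NoiseSpec.silent(), target_li=0.0)
        rec, truth = simulate_subject(cfg)
        np.testing.assert_allclose(truth.hbo, truth.hbo_task)
        # all channels share one waveform scaled by the amplitude vector
        ref = truth.hbo[0] / truth.amplitudes[0]
        for ch in range(29):
            np.testing.assert_allclose(truth.hbo[ch], truth.amplitudes[ch] * ref,
                                       atol=1e-12)

    def test_invalid_config_rejected(self):
        bad_fc = np.full((29, 29), 0.99)  # diag != 1
        with pytest.raises(ValueError, match="unit diagonal"):
            simulate_subject(SimulationConfig(target_fc=bad_fc))
        with pytest.raises(ValueError, match="target_li"):
            simulate_subject(SimulationConfig(target_li=1.5))
        with pytest.raises(ValueError, match="fma_hand"):
            simulate_subject(SimulationConfig(fma_ul=10.0, fma_hand=14.0))


class TestMotionArtifacts:
    def test_no_artifacts_is_identity(self):
        x = np.random.default_rng(0).normal(size=(3, 500))
        y, log = inject_motion_artifacts(x, 0, 0, 5.0, seed=1)
        np.testing.assert_array_equal(x, y)
        assert log == []

    def test_spike_count_and_locality(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 2000))
        y, log = inject_motion_artifacts(x, 5, 0, 8.0, seed=3)
        assert sum(e["kind"] == "spike" for e in log) == 5
        changed = np.flatnonzero(np.any(y != x, axis=0))
        for t in changed:
            assert any(e["start"] <= t < e["start"] + e["width"] for e in log)

    def test_shift_persists_to_end(self):
        x = np.zeros((1, 1000))
        y, log = inject_motion_artifacts(x, 0, 1, 5.0, seed=4)
        start = log[0]["start"]
        assert np.all(y[0, :start] == 0)
        assert np.all(y[0, start:] != 0)

    def test_nonpositive_magnitude_rejected(self):
        with pytest.raises(ValueError, match="magnitude"):
            inject_motion_artifacts(np.zeros((1, 100)), 1, 0, 0.0)

    def test_large_spikes_detected_in_raw_od(self):
        """10x robust-SD spikes trip the motion detector in >= 16/20 runs."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, artifacts=ArtifactSpec(n_spikes=1, n_shifts=0,
                                                  magnitude=10.0))
            rec, truth = simulate_subject(cfg)
            od = intensity_to_od(rec).od.reshape(-1, 4050)
            flags = _detect_flags(od, 10.0, 2.0, 3.5)
            pos = truth.artifact_log[0]["start"]
            hits += bool(flags[:, max(0, pos - 40):pos + 40].any())
        assert hits >= 16


class TestSimulateCohort:
    def test_empty_cohort(self):
        subjects, records = simulate_cohort(n_per_group=0, seed=0)
        assert subjects == []
        assert len(records) == 0
        assert list(records.columns)[:4] == ["subject_id", "group", "task_hand",
                                             "fma_ul"]

    def test_default_cohort_size_and_metadata(self):
        subjects, records = simulate_cohort(n_per_group=3, seed=1)
        assert len(subjects) == 9  # one recording per subject
        assert set(records.group) == {"HS", "LHS", "RHS"}
        assert (records.fma_hand <= records.fma_ul).all()
        assert (records.loc[records.group == "LHS", "task_hand"] == "right").all()
        assert (records.loc[records.group == "RHS", "task_hand"] == "left").all()

    def test_hs_both_hands_doubles_hs_recordings(self):
        subjects, records = simulate_cohort(n_per_group=2, seed=1,
                                            hs_both_hands=True)
        assert (records.group == "HS").sum() == 4
        assert len(records) == 8

    def test_ground_truth_serializable(self):
        subjects, _ = simulate_cohort(n_per_group=1, seed=2, groups=("LHS",))
        blob = json.dumps(subjects[0][1].to_dict())
        restored = json.loads(blob)
        assert restored["group"] == "LHS"
        assert len(restored["target_fc"]) == 29

    def test_cohort_deterministic_under_seed(self):
        s1, r1 = simulate_cohort(n_per_group=2, seed=9)
        s2, r2 = simulate_cohort(n_per_group=2, seed=9)
        assert r1.equals(r2)
        np.testing.assert_array_equal(s1[0][0].intensity, s2[0][0].intensity)
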