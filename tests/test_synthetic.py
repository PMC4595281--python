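"""Generator correctness: block structure, determinism, parameter recovery."""

import numpy as np
import pytest
from scipy import stats as ss

from hemiscope import (
    GroundTruth,
    compliance_correlation,
    compute_envelope,
    count_movements,
    detrend_resample,
    laterality_index,
    make_label_atlas,
    make_task_boxcar,
    mirror_glove_score,
    percent_mve,
    preprocess_emg,
    simulate_beta_volume,
    simulate_cohort,
    simulate_emg_trace,
    simulate_glove_trace,
)
from hemiscope.emg import safe_pearson


def run_lengths(values):
    edges = np.flatnonzero(np.diff(values)) + 1
    return np.diff(np.concatenate([[0], edges, [values.size]]))


class TestTaskBoxcar:
    def test_default_task_structure(self, boxcar):
        # 6 min at dt=0.5 s: 720 samples, rest first, 9 move blocks of 40
        assert boxcar.n_samples == 720
        assert boxcar.values[0] == 0
        lengths = run_lengths(boxcar.values)
        assert np.all(lengths == 40)
        assert lengths.size == 18  # 9 rest + 9 move
        assert boxcar.values.mean() == pytest.approx(0.5)

    def test_smallest_case(self):
        b = make_task_boxcar(1.0, 4.0, 0.5)
        assert b.values.tolist() == [0, 0, 1, 1, 0, 0, 1, 1]

    @pytest.mark.parametrize(
        "block_s,total_s,dt",
        [(20, 360, 0.63), (20, 350, 0.5), (20, 360, -1), (0, 360, 0.5)],
    )
    def test_non_divisible_durations_rejected(self, block_s, total_s, dt):
        with pytest.raises(ValueError):
            make_task_boxcar(block_s, total_s, dt)

    def test_sampling_beyond_duration_is_rest(self, boxcar):
        assert boxcar.sample(np.array([360.0, 400.0, -1.0])).tolist() == [0, 0, 0]


class TestGloveSimulation:
    def test_no_leakage_gives_null_mirror_correlation(self, boxcar):
        truth = GroundTruth(mirror_gain=0.0, seed=11)
        _, inactive = simulate_glove_trace(boxcar, truth)
        r = mirror_glove_score(detrend_resample(inactive), boxcar)
        assert abs(r) < 0.1

    def test_default_task_movement_count_near_ninety(self, boxcar):
        truth = GroundTruth(seed=12)
        active, _ = simulate_glove_trace(boxcar, truth)
        n = count_movements(detrend_resample(active))
        assert 80 <= n <= 105  # the observed per-task range

    def test_noiseless_count_is_exact(self, boxcar):
        # pure sinusoid in move blocks: rate x total move time extrema pairs
        truth = GroundTruth(movement_rate=1.0, seed=13)
        active, _ = simulate_glove_trace(
            boxcar, truth, amplitude_schedule=(60.0,), noise_sd=0.0, drift_amp=0.0
        )
        n = count_movements(detrend_resample(active))
        assert n == 180  # 9 blocks x 20 s x 1 Hz

    def test_negative_noise_rejected(self, boxcar, truth):
        with pytest.raises(ValueError):
            simulate_glove_trace(boxcar, truth, noise_sd=-1.0)

    def test_amplitude_levels_validated(self, boxcar, truth):
        with pytest.raises(ValueError):
            simulate_glove_trace(boxcar, truth, amplitude_schedule=(100.0,))

    def test_seed_determinism(self, boxcar):
        a1, i1 = simulate_glove_trace(boxcar, GroundTruth(seed=5))
        a2, i2 = simulate_glove_trace(boxcar, GroundTruth(seed=5))
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(i1.values, i2.values)


class TestEmgSimulation:
    def test_low_sampling_rate_names_nyquist(self, boxcar, truth):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_emg_trace(boxcar, truth, fs=200.0)

    def test_notch_removes_huge_artifacts(self, short_boxcar):
        # enormous gradient artifacts, no task modulation: after the chain
        # the envelope carries no boxcar structure
        truth = GroundTruth(target_pct_mve=0.0, seed=21)
        task, _ = simulate_emg_trace(
            short_boxcar, truth, artifact_amps=(50.0, 50.0), drift_amp=0.0
        )
        filtered = preprocess_emg(task)
        env_f = compute_envelope(filtered)
        r_f = safe_pearson(short_boxcar.sample(env_f.sample_times), env_f.values)
        assert abs(r_f) < 0.1

    def test_seed_determinism(self, boxcar):
        t1, m1 = simulate_emg_trace(boxcar, GroundTruth(seed=5))
        t2, m2 = simulate_emg_trace(boxcar, GroundTruth(seed=5))
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(m1.values, m2.values)


class TestLabelAtlas:
    def test_twelve_mirrored_labels(self, atlas):
        labels = sorted(set(np.unique(atlas.data)) - {0})
        assert len(labels) == 12
        flipped = np.flip(atlas.data, axis=0)
        for seg in atlas.segments:
            left = atlas.label_of(seg, "L")
            right = atlas.label_of(seg, "R")
            # mirrored twin occupies exactly the reflected voxels
            np.testing.assert_array_equal(flipped == left, atlas.data == right)

    def test_segments_large_enough_for_proportional_threshold(self, atlas):
        for label in atlas.table["label"]:
            assert (atlas.data == label).sum() >= 20

    def test_odd_first_axis_rejected(self):
        with pytest.raises(ValueError):
            make_label_atlas(shape=(15, 16, 16))


class TestBetaVolume:
    def test_full_lateralization_exact(self, atlas):
        truth = GroundTruth(li_true=1.0, seed=31)
        beta = simulate_beta_volume(atlas, truth, noise_sd=0.0, lesion_side="L")
        for seg in atlas.segments:
            assert laterality_index(beta, atlas, seg, "L") == 1.0

    def test_symmetric_case_is_zero(self, atlas):
        truth = GroundTruth(li_true=0.0, seed=32)
        beta = simulate_beta_volume(atlas, truth, noise_sd=0.0, lesion_side="L")
        for seg in atlas.segments:
            assert laterality_index(beta, atlas, seg, "L") == pytest.approx(
                0.0, abs=0.02
            )


class TestRecoveryMonotonicity:
    """Ground-truth parameters must map monotonically onto their estimates."""

    def test_mirror_gain_to_mm_glove(self, short_boxcar):
        gains = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for gain in gains:
            rs = []
            for seed in range(5):
                truth = GroundTruth(mirror_gain=gain, seed=100 + seed)
                _, inactive = simulate_glove_trace(short_boxcar, truth)
                rs.append(
                    mirror_glove_score(detrend_resample(inactive), short_boxcar)
                )
            means.append(np.mean(rs))
        rho = ss.spearmanr(gains, means).statistic
        assert rho > 0.9

    def test_pct_mve_to_estimate(self, short_boxcar):
        targets = [5.0, 15.0, 30.0, 50.0, 80.0]
        means = []
        for pct in targets:
            vals = []
            for seed in range(5):
                truth = GroundTruth(target_pct_mve=pct, seed=200 + seed)
                task, mve = simulate_emg_trace(short_boxcar, truth)
                t, m = preprocess_emg(task), preprocess_emg(mve)
                vals.append(percent_mve(t, m, short_boxcar.move_mask(t.sample_times)))
            means.append(np.mean(vals))
        rho = ss.spearmanr(targets, means).statistic
        assert rho > 0.9

    def test_li_true_to_estimate(self, atlas):
        targets = [-0.8, -0.4, 0.0, 0.4, 0.8]
        means = []
        for li in targets:
            vals = []
            for seed in range(5):
                truth = GroundTruth(li_true=li, seed=300 + seed)
                beta = simulate_beta_volume(atlas, truth, lesion_side="L")
                vals.append(laterality_index(beta, atlas, "SMA", "L"))
            means.append(np.mean(vals))
        rho = ss.spearmanr(targets, means).statistic
        assert rho > 0.9


class TestCohortOutput:
    def test_byte_identical_reruns(self, tmp_path):
        kwargs = dict(n_patients=2, n_controls=2, seed=1, total_s=80,
                      atlas_shape=(12, 12, 12))
        d1 = simulate_cohort(tmp_path / "a", **kwargs)
        d2 = simulate_cohort(tmp_path / "b", **kwargs)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_clinical_scores_within_scale_bounds(self, tmp_path):
        import pandas as pd

        d = simulate_cohort(tmp_path / "c", n_patients=6, n_controls=2, seed=3,
                            total_s=80, atlas_shape=(12, 12, 12))
        cohort = pd.read_csv(d / "cohort.csv")
        patients = cohort[cohort["group"] == "patient"]
        assert patients["fm"].between(0, 66).all()
        assert patients["arat"].between(0, 57).all()
        assert (patients["nhpt_pct"] > 0).all()

    def test_existing_directory_requires_overwrite(self, tmp_path):
        out = tmp_path / "d"
        simulate_cohort(out, n_patients=2, n_controls=2, seed=1, total_s=80,
                        atlas_shape=(12, 12, 12))
        with pytest.raises(FileExistsError):
            simulate_cohort(out, n_patients=2, n_controls=2, seed=1, total_s=80,
                            atlas_shape=(12, 12, 12))
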