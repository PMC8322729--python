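"""Synthetic motion generator: contracts, determinism, catalogue arithmetic."""

import numpy as np
import pytest

import preimpact as pi
from preimpact.errors import UsageError
from preimpact.features import fft5


class TestADLs:
    def test_standing_is_quiet(self):
        rec = pi.simulate_adl("D01", seed=0)
        acc_m = pi.magnitude(rec, "acc").values
        assert np.abs(acc_m - 1.0).max() < 0.05
        assert np.abs(pi.vertical_velocity(rec).values).max() < 0.05

    def test_walking_has_dominant_gait_bin(self):
        rec = pi.simulate_adl("D06", seed=1)
        acc_m = pi.magnitude(rec, "acc").values
        x = acc_m - acc_m.mean()
        spectrum = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), d=1 / rec.sample_rate_hz)
        dominant = freqs[spectrum.argmax()]
        assert dominant == pytest.approx(1.9, rel=0.15)  # near the nominal cadence

    def test_stumble_has_transient_without_sustained_free_fall(self):
        rec = pi.simulate_adl("D10", seed=2)
        acc_m = pi.magnitude(rec, "acc").values
        assert acc_m.max() > 1.8                    # the catch-step spike
        below = acc_m < 0.6
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, below, 0])))[::2]
        assert (len(runs) == 0) or runs.max() < 10  # no sustained dip

    def test_same_seed_identical(self):
        a = pi.simulate_adl("D06", seed=3)
        b = pi.simulate_adl("D06", seed=3)
        np.testing.assert_array_equal(a.acc_g, b.acc_g)
        np.testing.assert_array_equal(a.euler_deg, b.euler_deg)

    def test_unknown_task_is_usage_error(self):
        with pytest.raises(UsageError):
            pi.simulate_adl("D99")


class TestFalls:
    def test_vertical_fall_envelope(self):
        rec, lab = pi.simulate_fall("F09", seed=0)
        i0, i1 = rec.index_of_frame(lab.onset_frame), rec.index_of_frame(lab.impact_frame)
        acc_m = pi.magnitude(rec, "acc").values
        vv = pi.vertical_velocity(rec).values
        pitch, roll = pi.posture_angles(rec)
        assert acc_m[i0:i1].min() < 0.6             # free-fall dip
        assert vv[i0:i1].max() > 0.5                # downward velocity ramp
        assert abs(pitch.values[i1]) >= 60          # sagittal excursion
        assert abs(roll.values[i1]) < 30            # not a lateral fall
        assert acc_m[i1:i1 + 3].max() >= 3.0        # impact spike

    @pytest.mark.parametrize("task", sorted(pi.FALL_TASKS))
    def test_label_invariant(self, task):
        rec, lab = pi.simulate_fall(task, seed=1)
        assert lab.onset_frame < lab.impact_frame
        assert rec.frame[0] <= lab.onset_frame
        assert lab.impact_frame <= rec.frame[-1]

    def test_falls_trigger_default_detector_pre_impact(self):
        """Generated falls are detectable before impact at a >= 95% rate."""
        hits = total = 0
        for task in pi.FALL_TASKS:
            for seed in range(4):
                rec, lab = pi.simulate_fall(task, seed=seed)
                res = pi.detect(rec.slice_frames(end_frame=lab.impact_frame))
                total += 1
                hits += res.is_fall and res.detection_frame <= lab.impact_frame
        assert hits / total >= 0.95

    def test_unknown_task_is_usage_error(self):
        with pytest.raises(UsageError):
            pi.simulate_fall("F99")


class TestGenerateDataset:
    def test_counting(self):
        spec = pi.SimulationSpec(n_subjects=2, tasks=["D01", "F09"],
                                 trials_per_task=1, seed=0)
        ds = pi.generate_dataset(spec)
        assert len(ds) == 4
        assert sum(lab is not None for _, lab in ds) == 2

    def test_full_catalogue_file_count_per_subject(self):
        # 17 multi-trial ADLs x5 + 4 static ADLs x1 + 15 fall tasks x5 = 164
        spec = pi.SimulationSpec(n_subjects=1, seed=0)
        ds = pi.generate_dataset(spec)
        assert len(ds) == 17 * 5 + 4 * 1 + 15 * 5 == 164

    def test_byte_identical_after_serialization(self, tmp_path):
        spec = pi.fixture_spec(seed=5)
        for d in ("a", "b"):
            pi.write_dataset(pi.generate_dataset(spec), tmp_path / d)
        files_a = sorted((tmp_path / "a").rglob("*.csv"))
        files_b = sorted((tmp_path / "b").rglob("*.csv"))
        assert len(files_a) == len(files_b) > 0
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_subject_effects_vary_between_subjects(self):
        spec = pi.SimulationSpec(n_subjects=3, tasks=["D06"], trials_per_task=1,
                                 seed=2)
        ds = pi.generate_dataset(spec)
        gait_means = [pi.magnitude(rec, "acc").values.std() for rec, _ in ds]
        assert len(set(np.round(gait_means, 6))) == 3
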