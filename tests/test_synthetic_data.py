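import dataclasses
import json

import numpy as np
import pytest

from steadytorque.kinematics import FascicleTrace, lengthening_amplitude, max_lengthening_speed
from steadytorque.synthetic_data import (
    MtuParams,
    SimConfig,
    generate_dataset,
    generate_mvc_trial,
    simulate_trial,
)
from conftest import NOISE_FREE


def fascicle_truth(trial):
    g = trial.ground_truth
    return FascicleTrace(times=g.fascicle_times, lengths=g.true_fascicle, source="simulated")


class TestMtuParams:
    def test_see_curve_continuity_and_inverse(self):
        m = MtuParams()
        for f in (0.1, m.f_toe, 0.5 * m.f_max, m.f_max):
            ext = m.see_extension(f)
            assert m.see_force(ext) == pytest.approx(f, rel=1e-9)
        # C1 junction: slope of toe at ext_toe equals linear stiffness
        h = 1e-7
        slope = (m.see_force(m.ext_toe) - m.see_force(m.ext_toe - h)) / h
        assert slope == pytest.approx(m.linear_stiffness, rel=1e-4)

    def test_extension_at_fmax(self):
        m = MtuParams()
        assert m.see_extension(m.f_max) == pytest.approx(m.ext_at_fmax, rel=1e-9)

    def test_mvt_is_static_fixed_point(self):
        m = MtuParams()
        mvt = m.mvt()
        lf = m.passive_fascicle_length - m.see_extension(mvt)
        assert m.force_length(lf) * m.f_max == pytest.approx(mvt, rel=1e-8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MtuParams(f_max=-1.0)
        with pytest.raises(ValueError):
            MtuParams(see_strain_at_fmax=0.2)


class TestSimulateTrial:
    def test_determinism_same_seed(self):
        cfg = SimConfig(experiment=1, seed=42)
        t1 = simulate_trial(cfg, "1-s")
        t2 = simulate_trial(cfg, "1-s")
        np.testing.assert_array_equal(t1.torque.values, t2.torque.values)
        np.testing.assert_array_equal(t1.emg.values, t2.emg.values)
        np.testing.assert_array_equal(t1.fascicle.values, t2.fascicle.values)

    def test_different_seeds_differ(self):
        t1 = simulate_trial(SimConfig(experiment=1, seed=1), "1-s", channels=("torque",))
        t2 = simulate_trial(SimConfig(experiment=1, seed=2), "1-s", channels=("torque",))
        assert not np.array_equal(t1.torque.values, t2.torque.values)

    def test_recoil_mechanism(self, noise_free_exp2):
        """Fascicles shorten during force development and lengthen during
        the torque reduction (series-elastic recoil)."""
        trial = simulate_trial(noise_free_exp2, "85-15", channels=("torque",))
        g = trial.ground_truth
        t, on, tr = g.fascicle_times, g.onset_time, trial.trace
        dev = g.true_fascicle[(t >= on) & (t <= on + tr.hold1_start)]
        desc = g.true_fascicle[(t >= on + tr.hold1_end) & (t <= on + tr.hold2_start)]
        assert dev[-1] < dev[0] - 5.0  # shortening during development
        assert desc[-1] > desc[0] + 2.0  # lengthening during the drop
        assert np.all(np.diff(desc) > -1e-6)  # monotone recoil, noise-free

    def test_zero_command_stays_passive(self, noise_free_exp1):
        cfg = dataclasses.replace(noise_free_exp1)
        trial = simulate_trial(cfg, "reference", channels=("torque",))
        g = trial.ground_truth
        pre = g.fascicle_times < g.onset_time - 0.1
        assert np.allclose(
            g.true_fascicle[pre], cfg.mtu.passive_fascicle_length, atol=1e-6
        )
        n_pre = int(g.onset_time * trial.torque.sampling_rate) - 100
        assert np.allclose(g.true_torque[:n_pre], 0.0, atol=1e-9)

    def test_tracking_accuracy_noise_free(self, noise_free_exp2):
        for cond in ("85-15", "45"):
            g = simulate_trial(noise_free_exp2, cond, channels=("torque",)).ground_truth
            spec_levels = {"85-15": (85.0, 15.0), "45": (45.0, 45.0)}[cond]
            assert g.hold1_torque_pct == pytest.approx(spec_levels[0], abs=0.5)
            assert g.hold2_torque_pct == pytest.approx(spec_levels[1], abs=0.5)

    def test_linear_see_recoil_equals_force_drop_over_stiffness(self, noise_free_exp1):
        """Between the two steady states (fv = 1, forces above the SEE toe)
        the fascicle length change equals dF / k_linear exactly."""
        cfg = noise_free_exp1
        trial = simulate_trial(cfg, "2-s", channels=("torque",))
        g = trial.ground_truth
        fs = trial.torque.sampling_rate
        on, tr = g.onset_time, trial.trace
        i1 = int((on + tr.hold1_end - 0.1) * fs)
        i2 = int((on + tr.hold2_end - 0.1) * fs)
        f1, f2 = g.true_torque[i1], g.true_torque[i2]
        m = cfg.mtu
        assert f1 > m.f_toe and f2 > m.f_toe
        t_full = np.arange(g.true_torque.size) / fs
        lf = np.interp([i1 / fs, i2 / fs], g.fascicle_times, g.true_fascicle)
        expected = (f1 - f2) / m.linear_stiffness
        assert lf[1] - lf[0] == pytest.approx(expected, abs=0.05)

    def test_controller_divergence_raises(self):
        # an absurdly slow activation time constant cannot track the ramp
        mtu = MtuParams(activation_tau_up=30.0, activation_tau_down=30.0)
        cfg = SimConfig(experiment=1, seed=0, mtu=mtu)
        from steadytorque.synthetic_data import SimulationError

        with pytest.raises(SimulationError):
            simulate_trial(cfg, "0.25-s", channels=("torque",))

    def test_channel_selection_skips_work(self, noise_free_exp1):
        trial = simulate_trial(noise_free_exp1, "1-s", channels=("torque",))
        assert trial.emg is None and trial.fascicle is None
        assert trial.torque is not None


class TestOrderings:
    def test_exp2_lengthening_amplitude_ordering(self, noise_free_exp2):
        amps = {}
        for cond in ("85-15", "85-30", "85-45"):
            trial = simulate_trial(noise_free_exp2, cond, channels=("torque",))
            g = trial.ground_truth
            amp, _ = lengthening_amplitude(
                fascicle_truth(trial),
                g.onset_time + trial.trace.hold1_end,
                g.onset_time + trial.trace.hold2_start,
            )
            amps[cond] = amp
        assert amps["85-15"] > amps["85-30"] > amps["85-45"]

    def test_exp1_speed_ordering_and_small_amplitude_spread(
        self, noise_free_exp1, noise_free_exp2
    ):
        speeds, amps = [], []
        for cond in ("0.25-s", "0.5-s", "1-s", "2-s"):
            trial = simulate_trial(noise_free_exp1, cond, channels=("torque",))
            g = trial.ground_truth
            h1e = g.onset_time + trial.trace.hold1_end
            h2s = g.onset_time + trial.trace.hold2_start
            speeds.append(
                max_lengthening_speed(fascicle_truth(trial), h1e, h2s, smooth_cutoff=None)
            )
            amps.append(lengthening_amplitude(fascicle_truth(trial), h1e, h2s)[0])
        # faster descend -> faster recoil, strictly
        assert speeds[0] > speeds[1] > speeds[2] > speeds[3]
        # amplitude spread far smaller than the Exp 2 spread
        exp2 = []
        for cond in ("85-15", "85-45"):
            trial = simulate_trial(noise_free_exp2, cond, channels=("torque",))
            g = trial.ground_truth
            exp2.append(
                lengthening_amplitude(
                    fascicle_truth(trial),
                    g.onset_time + trial.trace.hold1_end,
                    g.onset_time + trial.trace.hold2_start,
                )[0]
            )
        assert max(amps) - min(amps) < 0.25 * (exp2[0] - exp2[1])


class TestMvcTrial:
    def test_plateau_matches_static_solve(self, noise_free_exp1):
        trial = generate_mvc_trial(noise_free_exp1, channels=())
        peak = np.max(trial.ground_truth.true_torque)
        assert peak == pytest.approx(noise_free_exp1.mtu.mvt(), rel=0.01)

    def test_normalization_recovers_commanded_level(self, noise_free_exp1):
        g = simulate_trial(noise_free_exp1, "reference", channels=("torque",)).ground_truth
        assert g.hold2_torque_pct == pytest.approx(40.0, abs=1.0)

    def test_cv_injection_recovered(self):
        """Injected signal-dependent torque noise of 1.7 % appears as a
        Hold-2 CV of ~1.7 % through the analysis chain."""
        from steadytorque.kinematics import steadiness_cv
        from steadytorque.signal_processing import FilterSpec, dual_pass_butterworth

        cvs = []
        for k in range(10):
            cfg = SimConfig(
                experiment=1, seed=100 + k, torque_noise_cv=1.7,
                baseline_offset=0.0, baseline_noise_sd=0.0,
            )
            trial = simulate_trial(cfg, "reference", channels=("torque",))
            g = trial.ground_truth
            filt = dual_pass_butterworth(trial.torque, FilterSpec("low-pass", (20.0,)))
            h2 = (g.onset_time + trial.trace.hold2_start + 0.25,
                  g.onset_time + trial.trace.hold2_end)
            cvs.append(steadiness_cv(filt, h2))
        assert np.mean(cvs) == pytest.approx(1.7, abs=0.3)


class TestGenerateDataset:
    def test_structure_and_roundtrip(self, tmp_path):
        cfg = SimConfig(experiment=2, seed=5)
        manifest = generate_dataset(
            cfg, n_subjects=2, trials_per_condition=1, out_dir=tmp_path,
            conditions=["85-45", "45"],
        )
        assert manifest.exists()
        lines = manifest.read_text().strip().splitlines()
        # header + 2 subjects * (1 MVC + 2 conditions)
        assert len(lines) == 1 + 2 * 3
        meta = json.loads((tmp_path / "dataset.json").read_text())
        assert meta["experiment"] == 2
        truths = sorted(tmp_path.glob("S01/*_truth.json"))
        assert truths
        truth = json.loads(truths[0].read_text())
        assert truth["model_mvt"] > 0

    def test_subject_parameters_jittered(self, tmp_path):
        cfg = SimConfig(experiment=1, seed=5)
        generate_dataset(cfg, 2, 1, tmp_path, conditions=["reference"])
        t1 = json.loads((tmp_path / "S01" / "S01_reference_b0_truth.json").read_text())
        t2 = json.loads((tmp_path / "S02" / "S02_reference_b0_truth.json").read_text())
        assert t1["model_mvt"] != t2["model_mvt"]

    def test_n_subjects_validation(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(SimConfig(), 1, 1, tmp_path)
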