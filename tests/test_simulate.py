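"""Synthetic sessions: kinematics, wrench forward model, EEG realism, truth."""

import json

import numpy as np
import pytest
from scipy.signal import welch

from texchange import layout as L
from texchange import sensor as S
from texchange import simulate as sim
from texchange.errors import ParameterError


class TestKinematics:
    def test_jitter_free_sweep_duration(self):
        cfg = sim.SessionConfig(n_blocks=1, trials_per_block=2, speed_jitter=0.0, seed=0)
        kin = sim.simulate_kinematics(cfg)
        i0 = int(round(kin.onsets[0] * cfg.wrench_rate_hz))
        i1 = i0 + int(round(cfg.sweep_duration_s * cfg.wrench_rate_hz))
        x = kin.x[i0:i1]
        # full 100 mm traversal in exactly the 4 s sweep at 2.5 cm/s
        assert x[0] == pytest.approx(-50.0)
        assert x[-1] == pytest.approx(50.0, abs=0.05)
        speeds = np.diff(x) * cfg.wrench_rate_hz
        assert np.allclose(speeds, 25.0, atol=1e-6)  # mm/s

    def test_default_session_trial_counts(self):
        cfg = sim.SessionConfig(seed=1)
        kin = sim.simulate_kinematics(cfg)
        assert kin.onsets.size == 120
        dirs = np.array(kin.directions)
        assert (dirs == "smooth_to_rough").sum() == 60
        assert (dirs == "rough_to_smooth").sum() == 60

    def test_directions_alternate_within_block(self):
        cfg = sim.SessionConfig(n_blocks=1, trials_per_block=6, seed=2)
        kin = sim.simulate_kinematics(cfg)
        assert kin.directions == [
            "smooth_to_rough", "rough_to_smooth"] * 3

    def test_counterbalanced_block_starts(self):
        cfg = sim.SessionConfig(n_blocks=4, trials_per_block=2, seed=3)
        assert cfg.block_starts == ["smooth", "rough", "smooth", "rough"]
        kin = sim.simulate_kinematics(cfg)
        # first trial of an odd block sweeps rough -> smooth
        assert kin.directions[2] == "rough_to_smooth"

    def test_crossing_near_mid_sweep(self):
        cfg = sim.SessionConfig(n_blocks=1, trials_per_block=4, seed=4)
        kin = sim.simulate_kinematics(cfg)
        rel = kin.t_cross_true - kin.onsets
        # far-exit of the +/-5 mm band: 2.2 s nominal, jitter bounded
        assert np.all(np.abs(rel - 2.2) < 0.45)

    def test_invalid_config_raises(self):
        with pytest.raises(ParameterError):
            sim.SessionConfig(n_blocks=0)
        with pytest.raises(ParameterError):
            sim.SessionConfig(dropout_rate=1.5)


@pytest.fixture(scope="module")
def clean_cfg():
    return sim.SessionConfig(
        n_blocks=1, trials_per_block=4, speed_jitter=0.0,
        force_noise_n=0.0, torque_noise_nm=0.0, y_wander_mm=0.0,
        load_sd_g=0.0, seed=5,
    )


@pytest.fixture(scope="module")
def short_kin():
    cfg = sim.SessionConfig(n_blocks=1, trials_per_block=4, seed=8)
    return sim.simulate_kinematics(cfg)


class TestWrench:
    def test_noise_free_round_trip(self, clean_cfg):
        kin = sim.simulate_kinematics(clean_cfg)
        wrench, _ = sim.simulate_wrench(kin, clean_cfg)
        traj = S.estimate_contact(S.block_average(wrench, 100.0))
        # compare against the block-averaged true trajectory
        n = (len(kin.x) // 10) * 10
        x_true = kin.x[:n].reshape(-1, 10).mean(axis=1)
        ok = traj.valid
        assert np.abs(traj.x[ok] - x_true[ok]).max() < 0.05

    def test_transition_times_match_truth(self, clean_cfg):
        kin = sim.simulate_kinematics(clean_cfg)
        wrench, _ = sim.simulate_wrench(kin, clean_cfg)
        traj = S.estimate_contact(S.block_average(wrench, 100.0))
        events = S.detect_transitions(traj)
        assert len(events) == kin.t_cross_true.size
        det = np.array([e.t_cross for e in events])
        assert np.abs(det - kin.t_cross_true).max() <= 0.01 + 1e-6

    def test_high_dropout_rejects_trials(self):
        cfg = sim.SessionConfig(n_blocks=1, trials_per_block=4, dropout_rate=0.3, seed=6)
        kin = sim.simulate_kinematics(cfg)
        wrench, _ = sim.simulate_wrench(kin, cfg)
        traj = S.estimate_contact(S.block_average(wrench, 100.0))
        records = S.epoch_trials(traj, kin.onsets)
        fracs = [r.missing_fraction for r in records]
        # realised loss tracks the configured rate, and trials near or
        # above the 25% rule are rejected
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.08)
        assert sum(not r.accepted for r in records) >= 3

    def test_mean_load_recovered(self):
        cfg = sim.SessionConfig(n_blocks=2, trials_per_block=10, seed=7)
        kin = sim.simulate_kinematics(cfg)
        wrench, trial_loads = sim.simulate_wrench(kin, cfg)
        traj = S.estimate_contact(S.block_average(wrench, 100.0))
        loads = [
            S.mean_load(traj, on + 0.5, on + 3.5) for on in kin.onsets
        ]
        # generator consistency: grand mean near the 40 g target
        se = cfg.load_sd_g / np.sqrt(len(loads))
        assert np.nanmean(loads) == pytest.approx(cfg.load_mean_g, abs=4 * se + 2.0)


class TestEEG:
    def test_spectral_slope_within_band(self, short_kin):
        eeg = sim.simulate_eeg(short_kin, rng=np.random.default_rng(8))
        cfg = sim.EEGConfig()
        # fit the 1/f slope on log-log PSD, away from the rhythm bands
        f, psd = welch(eeg.data[:50], fs=eeg.sample_rate, nperseg=4096)
        sel = (f >= 2) & (f <= 40) & ~((f >= 7) & (f <= 13)) & ~((f >= 15) & (f <= 25))
        slopes = []
        for ch in range(50):
            if eeg.ch_names[ch] == L.REFERENCE_NAME:
                continue
            coef = np.polyfit(np.log(f[sel]), np.log(psd[ch][sel]), 1)
            slopes.append(-coef[0])
        assert np.median(slopes) == pytest.approx(cfg.gamma, abs=0.2)

    def test_rhythm_topography_peaks_at_sensorimotor_sites(self, short_kin):
        eeg = sim.simulate_eeg(short_kin, rng=np.random.default_rng(9))
        from scipy.signal import butter, sosfiltfilt

        sos = butter(3, (8, 12), btype="bandpass", fs=eeg.sample_rate, output="sos")
        band = sosfiltfilt(sos, eeg.data, axis=1)
        power = np.mean(band**2, axis=1)
        names, pos = L.idealized_layout()
        near = set(L.nearest_channels(pos, L.sensorimotor_sites()["C3"], 3)) | set(
            L.nearest_channels(pos, L.sensorimotor_sites()["C4"], 3)
        )
        far = [
            i for i, p in enumerate(pos)
            if names[i] != L.REFERENCE_NAME
            and np.arccos(np.clip(p @ L.sensorimotor_sites()["C3"], -1, 1)) > 1.2
            and np.arccos(np.clip(p @ L.sensorimotor_sites()["C4"], -1, 1)) > 1.2
        ]
        assert np.mean(power[list(near)]) > 2.0 * np.mean(power[far])

    def test_reference_channel_is_silent(self, short_kin):
        eeg = sim.simulate_eeg(short_kin, rng=np.random.default_rng(10))
        ref = eeg.ch_names.index(L.REFERENCE_NAME)
        assert np.all(eeg.data[ref] == 0.0)

    def test_unknown_erd_electrode_raises(self, short_kin):
        bad = [sim.ERDSpec(target_electrodes=("nope",))]
        with pytest.raises(ParameterError):
            sim.simulate_eeg(short_kin, erd=bad, rng=np.random.default_rng(0))

    def test_erd_reduces_band_power_at_target_only(self, short_kin):
        from scipy.signal import butter, sosfiltfilt

        names, pos = L.idealized_layout()
        target = names[L.nearest_channels(pos, L.sensorimotor_sites()["C3"], 1)[0]]
        erd = [sim.ERDSpec(target_electrodes=(target,), relative_power_change=-0.5)]
        eeg = sim.simulate_eeg(short_kin, erd=erd, rng=np.random.default_rng(11))
        eeg0 = sim.simulate_eeg(short_kin, erd=[], rng=np.random.default_rng(11))
        sos = butter(3, (8, 12), btype="bandpass", fs=eeg.sample_rate, output="sos")
        ci = names.index(target)
        fs = eeg.sample_rate

        def window_power(data, t0, t1):
            band = sosfiltfilt(sos, data)
            return np.mean(band[int(t0 * fs) : int(t1 * fs)] ** 2)

        tc = short_kin.t_cross_true[0]
        with_p = window_power(eeg.data[ci], tc + 0.05, tc + 0.40)
        without_p = window_power(eeg0.data[ci], tc + 0.05, tc + 0.40)
        assert with_p < 0.75 * without_p  # ~50% power drop injected


class TestErdSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"onset": 0.5, "offset": 0.1},
            {"relative_power_change": -1.2},
            {"band": "delta"},
            {"condition_scope": "sideways"},
        ],
    )
    def test_invalid_specs_raise(self, kwargs):
        with pytest.raises(ParameterError):
            sim.ERDSpec(target_electrodes=("E1",), **kwargs)


class TestGenerateSession:
    def test_same_seed_identical_manifest(self, tmp_path):
        cfg = sim.SessionConfig(n_blocks=1, trials_per_block=2, seed=12)
        p1 = sim.generate_session(cfg, out_dir=tmp_path / "a", seed=12)
        p2 = sim.generate_session(cfg, out_dir=tmp_path / "b", seed=12)
        assert p1["truth"].read_bytes() == p2["truth"].read_bytes()

    def test_manifest_contents(self, tmp_path):
        cfg = sim.SessionConfig(n_blocks=2, trials_per_block=4, seed=13)
        paths = sim.generate_session(cfg, out_dir=tmp_path, seed=13)
        truth = json.loads(paths["truth"].read_text())
        assert truth["n_trials"] == 8
        assert len(truth["onsets"]) == 8
        assert len(truth["directions"]) == 8
        # the wrench CSV round-trips through the sensor stage
        wrench = S.read_wrench_csv(paths["wrench"])
        traj = S.estimate_contact(S.block_average(wrench, 100.0))
        events = S.detect_transitions(traj)
        det = np.array([e.t_cross for e in events])
        assert np.abs(det - np.array(truth["t_cross_true"])).max() <= 0.015
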