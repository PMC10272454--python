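"""Synthetic tactile-contrast sessions with ground truth.

Generates everything the pipeline consumes — fingertip kinematics, six-axis
wrench streams, trial onsets, and 129-channel EEG — for a session of
back-to-back 4 s finger sweeps over the 100 mm stimulus tile at a cued
2.5 cm/s, organised in blocks counterbalanced by starting texture (the
defaults reproduce the study conditions: 4 blocks x 30 trials, 60 sweeps
per transition direction, contact loads around 40 g).

The EEG model is phenomenological: per channel, a 1/f^gamma background
(gamma ~ 1), 10 Hz (mu/alpha) and 20 Hz (beta) narrow-band rhythms with
Gaussian spatial profiles over left/right sensorimotor sites, plus white
sensor noise.  Event-related desynchronisation is injected by scaling a
target channel's band rhythm by sqrt(1 + delta) between a configurable
onset and offset around each true transition (raised-cosine 50 ms ramps),
so the injected relative band-power change equals delta exactly at exactly
the target electrodes.  Every output is a deterministic function of the
configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import layout as layout_mod
from . import sensor as sensor_mod
from .errors import ParameterError
from .tf import EEGRecording

__all__ = [
    "SessionConfig",
    "EEGConfig",
    "ERDSpec",
    "Kinematics",
    "GroundTruth",
    "simulate_kinematics",
    "simulate_wrench",
    "simulate_eeg",
    "simulate_participant",
    "generate_session",
]

#: rhythm centre bands (Hz) used by the generator
RHYTHM_BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (16.0, 24.0)}


@dataclass(frozen=True)
class SessionConfig:
    """Task and sensor parameters of one simulated session.

    Defaults are the study conditions: 4 blocks of 30 back-to-back 4 s
    sweeps (120 trials, 60 per direction) across a 100 mm tile at
    2.5 cm/s, contact load 40 +/- 10 g, wrench sampled at 1 kHz.
    """

    n_blocks: int = 4
    trials_per_block: int = 30
    sweep_speed_cm_s: float = 2.5
    sweep_duration_s: float = 4.0
    tile_length_mm: float = 100.0
    lead_in_s: float = 2.5
    inter_block_gap_s: float = 2.5
    load_mean_g: float = 40.0
    load_sd_g: float = 10.0
    speed_jitter: float = 0.1
    y_wander_mm: float = 3.0
    dropout_rate: float = 0.0
    wrench_rate_hz: float = 1000.0
    force_noise_n: float = 0.002
    torque_noise_nm: float = 2.0e-5
    friction_mu: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ParameterError("need at least one block and one trial")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.sweep_speed_cm_s <= 0:
            raise ParameterError("sweep speed must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def block_starts(self) -> list[str]:
        """Starting texture per block, counterbalanced smooth/rough."""
        return ["smooth" if b % 2 == 0 else "rough" for b in range(self.n_blocks)]


@dataclass(frozen=True)
class EEGConfig:
    """Noise and rhythm parameters of the simulated EEG."""

    sample_rate: float = 1000.0
    background_rms_uv: float = 9.0
    gamma: float = 1.0
    alpha_amp_uv: float = 6.0
    beta_amp_uv: float = 4.0
    theta_amp_uv: float = 0.0
    shared_fraction: float = 0.5
    spatial_sigma_rad: float = 0.55
    sensor_noise_uv: float = 1.5
    subject_amp_sigma: float = 0.2
    subject_erd_sigma: float = 0.1


@dataclass(frozen=True)
class ERDSpec:
    """An event-related power change to inject and later recover.

    ``relative_power_change`` is the fractional band-power change (negative
    = desynchronisation, |value| < 1) applied at ``target_electrodes``
    between ``onset`` and ``offset`` seconds relative to each matching
    trial's true transition time.
    """

    target_electrodes: tuple[str, ...]
    band: str = "alpha"
    onset: float = 0.0
    offset: float = 0.45
    relative_power_change: float = -0.4
    condition_scope: str = "both"  # both | smooth_to_rough | rough_to_smooth

    def __post_init__(self) -> None:
        if self.onset >= self.offset:
            raise ParameterError("ERD onset must precede offset")
        if not abs(self.relative_power_change) < 1.0:
            raise ParameterError("|relative_power_change| must be < 1")
        if self.band not in RHYTHM_BANDS:
            raise ParameterError(f"unknown band {self.band!r}")
        if self.condition_scope not in ("both", "smooth_to_rough", "rough_to_smooth"):
            raise ParameterError(f"unknown condition scope {self.condition_scope!r}")


@dataclass
class Kinematics:
    """Continuous fingertip kinematics plus per-trial truth."""

    time: np.ndarray  # s, wrench rate
    x: np.ndarray  # mm, tile-centre frame
    y: np.ndarray
    contact: np.ndarray  # bool, finger on tile
    onsets: np.ndarray  # per-trial visual cue times, s
    directions: list[str]
    t_cross_true: np.ndarray  # per-trial true far-exit crossing times, s

    @property
    def duration(self) -> float:
        return float(self.time[-1] + (self.time[1] - self.time[0]))


@dataclass
class GroundTruth:
    """Manifest of everything the generator injected."""

    seed: int
    n_trials: int
    onsets: list[float]
    directions: list[str]
    t_cross_true: list[float]
    trial_loads_g: list[float]
    erd: list[dict]
    eeg: dict
    session: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    """Unit-RMS low-pass Gaussian noise (slow wander / jitter processes)."""
    w = rng.standard_normal(n)
    sos = butter(2, cutoff_hz, fs=fs, output="sos")
    s = sosfiltfilt(sos, w)
    rms = np.sqrt(np.mean(s**2))
    return s / rms if rms > 0 else s


def simulate_kinematics(cfg: SessionConfig, rng: np.random.Generator | None = None) -> Kinematics:
    """Simulate the session's fingertip trajectory at the wrench rate.

    Sweeps alternate direction within each block and are completed in
    exactly ``sweep_duration_s`` each: speed jitter (low-pass filtered,
    +/-``speed_jitter`` fractional) perturbs the instantaneous speed but
    the traversal is renormalised so each cue-locked trial spans the full
    tile, matching the paced task.  Between blocks the finger is lifted
    (no contact) and repositioned to the block's counterbalanced start.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    fs = cfg.wrench_rate_hz
    n_sweep = int(round(cfg.sweep_duration_s * fs))
    half = cfg.tile_length_mm / 2.0
    block_len_s = cfg.trials_per_block * cfg.sweep_duration_s
    total_s = (
        cfg.lead_in_s
        + cfg.n_blocks * block_len_s
        + (cfg.n_blocks - 1) * cfg.inter_block_gap_s
        + cfg.lead_in_s
    )
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    contact = np.zeros(n, dtype=bool)
    onsets, directions, t_cross = [], [], []

    for b, start_tex in enumerate(cfg.block_starts):
        b0 = cfg.lead_in_s + b * (block_len_s + cfg.inter_block_gap_s)
        sign = 1.0 if start_tex == "smooth" else -1.0  # +1: smooth end -> rough end
        for j in range(cfg.trials_per_block):
            onset = b0 + j * cfg.sweep_duration_s
            i0 = int(round(onset * fs))
            speed = 1.0 + cfg.speed_jitter * _smooth_noise(rng, n_sweep, fs, 1.0) \
                if cfg.speed_jitter > 0 else np.ones(n_sweep)
            speed = np.clip(speed, 0.2, None)
            s = np.concatenate([[0.0], np.cumsum(speed)[:-1]])
            s = s / (s[-1] + speed[-1])  # normalised progress in [0, 1)
            xi = sign * (-half + cfg.tile_length_mm * s)
            x[i0 : i0 + n_sweep] = xi
            contact[i0 : i0 + n_sweep] = True
            direction = "smooth_to_rough" if sign > 0 else "rough_to_smooth"
            # true far-exit crossing of the +/-5 mm band on the fine grid
            band = 5.0
            beyond = np.flatnonzero(sign * xi >= band)
            t_cross.append(onset + beyond[0] / fs)
            onsets.append(onset)
            directions.append(direction)
            sign = -sign
    y = cfg.y_wander_mm * _smooth_noise(rng, n, fs, 0.3) if cfg.y_wander_mm > 0 else np.zeros(n)
    return Kinematics(
        time=t,
        x=x,
        y=np.clip(y, -20.0, 20.0),
        contact=contact,
        onsets=np.array(onsets),
        directions=directions,
        t_cross_true=np.array(t_cross),
    )


def simulate_wrench(
    kin: Kinematics, cfg: SessionConfig, rng: np.random.Generator | None = None
) -> tuple[sensor_mod.WrenchSeries, np.ndarray]:
    """Forward-model the six-axis wrench from the kinematics.

    Per-trial loads are drawn from N(load_mean_g, load_sd_g) (clipped to
    stay in contact range) with slow within-trial modulation; the normal
    force presses down (Fz < 0), friction opposes the motion, torques are
    T = r x F, and white sensor noise plus optional dropouts complete the
    stream.  Returns the series and the per-trial target loads (g).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    fs = cfg.wrench_rate_hz
    n = kin.time.size
    load_g = np.zeros(n)
    trial_loads = np.maximum(
        rng.normal(cfg.load_mean_g, cfg.load_sd_g, size=kin.onsets.size), 10.0
    )
    n_sweep = int(round(cfg.sweep_duration_s * fs))
    for k, onset in enumerate(kin.onsets):
        i0 = int(round(onset * fs))
        mod = 1.0 + 0.08 * _smooth_noise(rng, n_sweep, fs, 0.5)
        load_g[i0 : i0 + n_sweep] = trial_loads[k] * np.clip(mod, 0.5, 1.5)
    load_g = np.where(kin.contact, load_g, 0.0)

    fz = -load_g / sensor_mod.G_PER_N  # press down
    vx = np.gradient(kin.x, 1.0 / fs)
    fx = cfg.friction_mu * np.abs(fz) * np.sign(vx) * kin.contact
    fy = 0.05 * cfg.friction_mu * np.abs(fz) * _smooth_noise(rng, n, fs, 1.0) * kin.contact
    _, _, _, tx, ty, tz = sensor_mod.forward_wrench(kin.x, kin.y, fz, fx, fy)
    tx = tx * kin.contact
    ty = ty * kin.contact
    tz = tz * kin.contact

    fx = fx + cfg.force_noise_n * rng.standard_normal(n)
    fy = fy + cfg.force_noise_n * rng.standard_normal(n)
    fz = fz + cfg.force_noise_n * rng.standard_normal(n)
    tx = tx + cfg.torque_noise_nm * rng.standard_normal(n)
    ty = ty + cfg.torque_noise_nm * rng.standard_normal(n)
    tz = tz + cfg.torque_noise_nm * rng.standard_normal(n)
    # dropouts arrive as whole 10 ms acquisition frames in short bursts
    # (mean 2 frames), as buffered-DAQ glitches do; i.i.d. single-sample
    # losses would vanish under block averaging
    missing = np.zeros(n, dtype=bool)
    if cfg.dropout_rate > 0:
        frame = 10  # samples per acquisition frame at 1 kHz
        mean_burst = 2  # frames
        n_frames = n // frame
        starts = np.flatnonzero(
            rng.random(n_frames) < cfg.dropout_rate / mean_burst
        )
        lengths = rng.geometric(1.0 / mean_burst, size=starts.size)
        for i, ln in zip(starts, lengths):
            missing[i * frame : (i + ln) * frame] = True
    series = sensor_mod.WrenchSeries(
        time=kin.time, Fx=fx, Fy=fy, Fz=fz, Tx=tx, Ty=ty, Tz=tz,
        sample_rate=fs, missing=missing,
    )
    return series, trial_loads


def _one_over_f(rng: np.random.Generator, n: int, fs: float, gamma: float,
                f_floor: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f^gamma noise (amplitude spectrum f^(-gamma/2))."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    hi = f >= f_floor
    shape[hi] = (f[hi] / f_floor) ** (-gamma / 2.0)
    shape[~hi] = 1.0
    shape[0] = 0.0
    sig = np.fft.irfft(spec * shape, n=n)
    return sig / np.sqrt(np.mean(sig**2))


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS narrow-band Gaussian rhythm (band-passed white noise)."""
    sos = butter(3, band, btype="bandpass", fs=fs, output="sos")
    sig = sosfiltfilt(sos, rng.standard_normal(n))
    return sig / np.sqrt(np.mean(sig**2))


def _erd_gain(
    n: int,
    fs: float,
    trials: list[tuple[float, float]],
    delta: float,
    ramp_s: float = 0.05,
) -> np.ndarray:
    """Multiplicative amplitude gain injecting a relative power change.

    Between each (start, stop) time the gain moves from 1 to
    sqrt(1 + delta) with raised-cosine ramps of ``ramp_s``.
    """
    env = np.zeros(n)
    n_ramp = max(int(round(ramp_s * fs)), 1)
    ramp_up = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    for start, stop in trials:
        i0 = int(round(start * fs))
        i1 = int(round(stop * fs))
        if i1 <= i0 or i0 - n_ramp < 0 or i1 + n_ramp > n:
            continue
        env[i0 - n_ramp : i0] = np.maximum(env[i0 - n_ramp : i0], ramp_up)
        env[i0:i1] = 1.0
        env[i1 : i1 + n_ramp] = np.maximum(env[i1 : i1 + n_ramp], ramp_up[::-1])
    return 1.0 + (np.sqrt(1.0 + delta) - 1.0) * env


def simulate_eeg(
    kin: Kinematics,
    eeg_cfg: EEGConfig | None = None,
    erd: list[ERDSpec] | None = None,
    rng: np.random.Generator | None = None,
    erd_scale: float = 1.0,
    amp_scale: float = 1.0,
) -> EEGRecording:
    """Simulate the 129-channel recording for one session.

    ``erd_scale``/``amp_scale`` carry per-participant variability (drawn
    upstream).  The reference channel (Cz) records zeros, as a physical
    reference does.  Raises when an ERD spec names unknown electrodes.
    """
    eeg_cfg = eeg_cfg or EEGConfig()
    erd = erd or []
    rng = rng or np.random.default_rng(0)
    fs = eeg_cfg.sample_rate
    n = int(round(kin.duration * fs))
    names, pos = layout_mod.idealized_layout()
    name_to_idx = {nm: i for i, nm in enumerate(names)}
    for spec in erd:
        unknown = [e for e in spec.target_electrodes if e not in name_to_idx]
        if unknown:
            raise ParameterError(f"ERD electrodes not in layout: {unknown}")

    sites = layout_mod.sensorimotor_sites()
    angL = np.arccos(np.clip(pos @ sites["C3"], -1, 1))
    angR = np.arccos(np.clip(pos @ sites["C4"], -1, 1))
    sig2 = 2.0 * eeg_cfg.spatial_sigma_rad**2
    wL = np.exp(-(angL**2) / sig2)
    wR = np.exp(-(angR**2) / sig2)
    w_tot = np.maximum(wL, wR)

    band_amp = {
        "alpha": eeg_cfg.alpha_amp_uv,
        "beta": eeg_cfg.beta_amp_uv,
        "theta": eeg_cfg.theta_amp_uv,
    }
    shared = {}
    for bname, band in RHYTHM_BANDS.items():
        if band_amp[bname] > 0:
            shared[bname] = (
                _narrowband(rng, n, fs, band),
                _narrowband(rng, n, fs, band),
            )

    # per-(channel, band) ERD gating windows in session time
    gates: dict[tuple[int, str], list[tuple[float, float, float]]] = {}
    for spec in erd:
        windows = [
            (tc + spec.onset, tc + spec.offset)
            for tc, direction in zip(kin.t_cross_true, kin.directions)
            if spec.condition_scope in ("both", direction)
        ]
        for ename in spec.target_electrodes:
            gates.setdefault((name_to_idx[ename], spec.band), []).extend(
                (a, b, spec.relative_power_change) for a, b in windows
            )

    data = np.zeros((len(names), n), dtype=float)
    ref_idx = name_to_idx[layout_mod.REFERENCE_NAME]
    for c in range(len(names)):
        if c == ref_idx:
            continue
        xch = eeg_cfg.background_rms_uv * amp_scale * _one_over_f(
            rng, n, fs, eeg_cfg.gamma
        )
        for bname, band in RHYTHM_BANDS.items():
            amp = band_amp[bname] * amp_scale
            if amp <= 0:
                continue
            sL, sR = shared[bname]
            sh = eeg_cfg.shared_fraction
            rhythm = amp * (
                sh * (wL[c] * sL + wR[c] * sR)
                + (1.0 - sh) * w_tot[c] * _narrowband(rng, n, fs, band)
            )
            key = (c, bname)
            if key in gates:
                delta = gates[key][0][2] * erd_scale
                delta = max(min(delta, 0.99), -0.99)
                gain = _erd_gain(
                    n, fs, [(a, b) for a, b, _ in gates[key]], delta
                )
                rhythm = rhythm * gain
            xch += rhythm
        xch += eeg_cfg.sensor_noise_uv * rng.standard_normal(n)
        data[c] = xch
    return EEGRecording(
        data=data,
        sample_rate=fs,
        ch_names=names,
        positions=pos,
        reference=layout_mod.REFERENCE_NAME,
    )


def simulate_participant(
    cfg: SessionConfig,
    eeg_cfg: EEGConfig | None = None,
    erd: list[ERDSpec] | None = None,
    seed: int | None = None,
) -> tuple[sensor_mod.WrenchSeries, EEGRecording, Kinematics, GroundTruth]:
    """Simulate one participant's full session (wrench + EEG + truth)."""
    eeg_cfg = eeg_cfg or EEGConfig()
    erd = erd or []
    seed = cfg.seed if seed is None else seed
    root = np.random.default_rng(seed)
    kin = simulate_kinematics(cfg, np.random.default_rng(root.integers(2**31)))
    wrench, trial_loads = simulate_wrench(
        kin, cfg, np.random.default_rng(root.integers(2**31))
    )
    amp_scale = float(np.exp(root.normal(0.0, eeg_cfg.subject_amp_sigma)))
    erd_scale = float(np.exp(root.normal(0.0, eeg_cfg.subject_erd_sigma)))
    eeg = simulate_eeg(
        kin, eeg_cfg, erd,
        rng=np.random.default_rng(root.integers(2**31)),
        erd_scale=erd_scale, amp_scale=amp_scale,
    )
    truth = GroundTruth(
        seed=int(seed),
        n_trials=cfg.n_trials,
        onsets=[round(float(v), 6) for v in kin.onsets],
        directions=list(kin.directions),
        t_cross_true=[round(float(v), 6) for v in kin.t_cross_true],
        trial_loads_g=[round(float(v), 6) for v in trial_loads],
        erd=[asdict(s) | {"erd_scale": round(erd_scale, 6)} for s in erd],
        eeg=asdict(eeg_cfg) | {"amp_scale": round(amp_scale, 6)},
        session=asdict(cfg),
    )
    return wrench, eeg, kin, truth


def generate_session(
    cfg: SessionConfig,
    erd: list[ERDSpec] | None = None,
    out_dir: str | Path = ".",
    eeg_cfg: EEGConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write a complete session to disk; fully reproducible from seed.

    Outputs: ``wrench.csv`` (six-axis stream), ``eeg.h5`` (HDF5 EEG
    container), ``onsets.csv``, ``layout.csv`` and ``truth.json`` (ground
    truth manifest).  Returns the file paths.
    """
    from .tf import save_recording_h5

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wrench, eeg, kin, truth = simulate_participant(cfg, eeg_cfg, erd, seed=seed)
    paths = {
        "wrench": out / "wrench.csv",
        "eeg": out / "eeg.h5",
        "onsets": out / "onsets.csv",
        "layout": out / "layout.csv",
        "truth": out / "truth.json",
    }
    sensor_mod.write_wrench_csv(wrench, paths["wrench"])
    save_recording_h5(eeg, paths["eeg"])
    with open(paths["onsets"], "w") as fh:
        fh.write("trial,onset_s\n")
        for k, onset in enumerate(truth.onsets):
            fh.write(f"{k},{onset}\n")
    layout_mod.write_layout_csv(paths["layout"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
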