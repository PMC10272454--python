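"""Six-axis touch-sensor processing: wrench -> trajectory -> trial events.

The stimulus tile sits on a six-axis load cell recording the contact wrench
(Fx, Fy, Fz, Tx, Ty, Tz) at 1 kHz.  In a right-handed frame with z up and
the finger pressing down (Fz < 0), a single contact at tile coordinate
(x, y, 0) produces torques T = r x F, so the centre of pressure is

    x = -Ty / Fz ,   y = Tx / Fz

independently of the tangential (friction) force components.  Forces and
torques are block-averaged to 100 Hz before contact estimation; the contact
load is reported in gram-force (|Fz| * 1000 / 9.81).

Texture-transition events are detected when the fingertip trajectory
traverses the +/-5 mm band around the tile centre; trials (4 s finger
sweeps, one per visual onset cue) are rejected when 25% or more of their
samples are missing or when the sweep does not produce exactly one
transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .errors import BoundsError, DegenerateInputError, RateError

__all__ = [
    "WrenchSeries",
    "ContactTrajectory",
    "TransitionEvent",
    "TrialRecord",
    "block_average",
    "estimate_contact",
    "detect_transitions",
    "epoch_trials",
    "mean_load",
    "read_wrench_csv",
    "write_wrench_csv",
    "events_to_frame",
]

#: gram-force per newton
G_PER_N = 1000.0 / 9.81

#: tile half extents (mm) used to validate contact positions
TILE_HALF_X = 50.0
TILE_HALF_Y = 25.0

WRENCH_COLUMNS = ("Fx", "Fy", "Fz", "Tx", "Ty", "Tz")


@dataclass
class WrenchSeries:
    """Force/torque time series from the six-axis sensor.

    Forces in N, torques in N*m, time in s.  ``missing`` flags samples
    lost to recording issues; their values are undefined (NaN on disk).
    """

    time: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray
    Fz: np.ndarray
    Tx: np.ndarray
    Ty: np.ndarray
    Tz: np.ndarray
    sample_rate: float
    missing: np.ndarray = dataclass_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in WRENCH_COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.missing is None:
            self.missing = np.zeros(self.time.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = self.time.size
        if any(getattr(self, c).size != n for c in WRENCH_COLUMNS) or self.missing.size != n:
            raise ValueError("wrench channels must share one length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    def wrench_matrix(self) -> np.ndarray:
        """(n, 6) array in column order Fx..Tz."""
        return np.column_stack([getattr(self, c) for c in WRENCH_COLUMNS])


@dataclass
class ContactTrajectory:
    """Fingertip contact trajectory at the block-averaged (100 Hz) rate.

    ``x``/``y`` in mm in the tile-centre frame, ``load`` in gram-force,
    ``valid`` flags samples with usable contact (not missing, load above
    threshold, position on the tile).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    load: np.ndarray
    valid: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class TransitionEvent:
    """A completed traversal of the central transition band."""

    t_cross: float
    direction: str  # "smooth_to_rough" | "rough_to_smooth"
    trial_index: int = -1


@dataclass(frozen=True)
class TrialRecord:
    """Quality-filtered trial epoch derived from one visual onset cue."""

    onset: float
    duration: float
    accepted: bool
    missing_fraction: float
    transition: TransitionEvent | None
    n_transitions: int

    @property
    def relative_t_cross(self) -> float | None:
        """Latency from the visual trigger to the texture transition (s)."""
        if self.transition is None:
            return None
        return self.transition.t_cross - self.onset


def block_average(series: WrenchSeries, target_rate: float = 100.0) -> WrenchSeries:
    """Block-average a wrench series down to ``target_rate`` Hz.

    Each output sample is the arithmetic mean of its contiguous block of
    input samples, ignoring missing samples; a block with every sample
    missing is itself marked missing.  ``target_rate`` must divide the
    input rate.
    """
    ratio = series.sample_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise RateError(
            f"target rate {target_rate} Hz does not divide {series.sample_rate} Hz"
        )
    k = int(round(ratio))
    n_blocks = len(series) // k
    if n_blocks == 0:
        raise RateError("series shorter than one block")
    sl = slice(0, n_blocks * k)
    good = (~series.missing[sl]).reshape(n_blocks, k)
    counts = good.sum(axis=1)
    out_missing = counts == 0
    safe = np.maximum(counts, 1)

    def _mean(vals: np.ndarray) -> np.ndarray:
        v = np.where(good, np.nan_to_num(vals[sl].reshape(n_blocks, k)), 0.0)
        return v.sum(axis=1) / safe

    cols = {c: _mean(getattr(series, c)) for c in WRENCH_COLUMNS}
    t = series.time[sl].reshape(n_blocks, k).mean(axis=1)
    return WrenchSeries(
        time=t, sample_rate=target_rate, missing=out_missing, **cols
    )


def estimate_contact(
    series: WrenchSeries, min_load: float = 5.0
) -> ContactTrajectory:
    """Estimate the fingertip contact point and load from wrench data.

    Centre-of-pressure inversion for a planar contact at z = 0:
    x = -Ty/Fz, y = Tx/Fz (mm), load = |Fz| in gram-force.  Samples that
    are missing, carry less than ``min_load`` gram-force, or resolve to a
    point off the tile are flagged invalid (not errors).
    """
    load = np.abs(series.Fz) * G_PER_N
    enough = (~series.missing) & (load > min_load)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(enough, -series.Ty / series.Fz * 1e3, np.nan)
        y = np.where(enough, series.Tx / series.Fz * 1e3, np.nan)
    on_tile = enough & (np.abs(x) <= TILE_HALF_X + 1.0) & (np.abs(y) <= TILE_HALF_Y + 1.0)
    return ContactTrajectory(
        time=series.time,
        x=x,
        y=y,
        load=np.where(series.missing, np.nan, load),
        valid=on_tile,
        sample_rate=series.sample_rate,
    )


def detect_transitions(
    traj: ContactTrajectory,
    band_halfwidth: float = 5.0,
    rule: str = "far_exit",
) -> list[TransitionEvent]:
    """Detect completed traversals of the central +/-band_halfwidth mm band.

    One event is emitted per monotone traversal from one side of the band
    to the other; entering and retreating on the same side yields nothing.
    The reported instant depends on ``rule``:

    - ``far_exit`` (default): first sample at or beyond the far edge, i.e.
      the finger has fully crossed the transition region;
    - ``entry``: first sample inside the band after approaching;
    - ``centre``: first sample past the tile centre (x = 0).

    Direction follows the travel sign: negative-to-positive x is
    ``smooth_to_rough`` in the tile-centre frame.
    """
    if rule not in ("far_exit", "entry", "centre"):
        raise ValueError(f"unknown crossing rule {rule!r}")
    h = float(band_halfwidth)
    events: list[TransitionEvent] = []
    state = 0  # -1 below band, +1 above band, 0 unknown/inside
    entered_from = 0
    t_entry = np.nan
    t_centre = np.nan
    idx = np.flatnonzero(traj.valid)
    for i in idx:
        x = traj.x[i]
        t = traj.time[i]
        if x <= -h:
            if entered_from == 1 and state == 0:
                events.append(_make_event(rule, t, t_entry, t_centre, "rough_to_smooth"))
            state, entered_from = -1, 0
        elif x >= h:
            if entered_from == -1 and state == 0:
                events.append(_make_event(rule, t, t_entry, t_centre, "smooth_to_rough"))
            state, entered_from = 1, 0
        else:
            if state != 0:
                entered_from, t_entry, t_centre = state, t, np.nan
            state = 0
            if np.isnan(t_centre) and (
                (entered_from == -1 and x >= 0.0) or (entered_from == 1 and x <= 0.0)
            ):
                t_centre = t
    return events


def _make_event(rule, t_exit, t_entry, t_centre, direction) -> TransitionEvent:
    if rule == "far_exit":
        t = t_exit
    elif rule == "entry":
        t = t_entry
    else:
        t = t_centre if not np.isnan(t_centre) else t_exit
    return TransitionEvent(t_cross=float(t), direction=direction)


def epoch_trials(
    traj: ContactTrajectory,
    onsets,
    duration: float = 4.0,
    reject_fraction: float = 0.25,
    band_halfwidth: float = 5.0,
    rule: str = "far_exit",
) -> list[TrialRecord]:
    """Epoch the trajectory at visual onset cues and quality-filter trials.

    A trial is accepted when its fraction of missing (invalid) samples is
    below ``reject_fraction`` and exactly one texture transition falls in
    its window.  Transition events are detected once on the whole
    trajectory and assigned to trials by time.
    """
    onsets = np.asarray(onsets, dtype=float)
    t_end = traj.time[-1] + 1.0 / traj.sample_rate
    if np.any(onsets < traj.time[0]) or np.any(onsets + duration > t_end + 1e-9):
        raise BoundsError("trial window extends beyond the recording")
    events = detect_transitions(traj, band_halfwidth=band_halfwidth, rule=rule)
    ev_times = np.array([e.t_cross for e in events])
    records: list[TrialRecord] = []
    for k, onset in enumerate(onsets):
        in_win = (traj.time >= onset) & (traj.time < onset + duration)
        n = int(in_win.sum())
        miss = 1.0 - float(traj.valid[in_win].sum()) / max(n, 1)
        if ev_times.size:
            hit = np.flatnonzero((ev_times >= onset) & (ev_times < onset + duration))
        else:
            hit = np.array([], dtype=int)
        transition = None
        if hit.size == 1:
            e = events[hit[0]]
            transition = TransitionEvent(e.t_cross, e.direction, trial_index=k)
        accepted = (miss < reject_fraction) and hit.size == 1
        records.append(
            TrialRecord(
                onset=float(onset),
                duration=duration,
                accepted=accepted,
                missing_fraction=miss,
                transition=transition,
                n_transitions=int(hit.size),
            )
        )
    return records


def mean_load(traj: ContactTrajectory, t_start: float, t_stop: float) -> float:
    """Mean contact load (gram-force) over valid samples in [t_start, t_stop).

    Returns NaN (with a warning) when the window holds no valid samples.
    """
    sel = (traj.time >= t_start) & (traj.time < t_stop) & traj.valid
    if not np.any(sel):
        warnings.warn("mean_load: no valid samples in window", stacklevel=2)
        return float("nan")
    return float(np.mean(traj.load[sel]))


def forward_wrench(x_mm, y_mm, fz_n, fx_n=0.0, fy_n=0.0):
    """Forward contact model: wrench produced by a point contact.

    Contact at (x, y, 0) mm with force (fx, fy, fz) N on the tile gives
    T = r x F.  Returns (Fx, Fy, Fz, Tx, Ty, Tz) with torques in N*m.
    Used as the independent oracle for :func:`estimate_contact` and by the
    synthetic wrench generator.
    """
    x = np.asarray(x_mm, dtype=float) * 1e-3
    y = np.asarray(y_mm, dtype=float) * 1e-3
    fx = np.broadcast_to(np.asarray(fx_n, dtype=float), x.shape).astype(float)
    fy = np.broadcast_to(np.asarray(fy_n, dtype=float), x.shape).astype(float)
    fz = np.broadcast_to(np.asarray(fz_n, dtype=float), x.shape).astype(float)
    tx = y * fz
    ty = -x * fz
    tz = x * fy - y * fx
    return fx, fy, fz, tx, ty, tz


# ---------------------------------------------------------------------------
# I/O


def read_wrench_csv(path) -> WrenchSeries:
    """Read a wrench CSV (time,Fx,Fy,Fz,Tx,Ty,Tz; empty fields = missing)."""
    df = pd.read_csv(path)
    need = ("time",) + WRENCH_COLUMNS
    if not set(need).issubset(df.columns):
        raise ValueError(f"wrench CSV must have columns {need}")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise DegenerateInputError("wrench CSV has fewer than 2 samples")
    rate = 1.0 / np.median(np.diff(t))
    vals = {c: df[c].to_numpy(dtype=float) for c in WRENCH_COLUMNS}
    missing = np.zeros(t.size, dtype=bool)
    for c in WRENCH_COLUMNS:
        missing |= np.isnan(vals[c])
    return WrenchSeries(time=t, sample_rate=float(round(rate)), missing=missing, **vals)


def write_wrench_csv(series: WrenchSeries, path) -> None:
    """Write a wrench series as CSV; missing samples become empty fields."""
    df = pd.DataFrame({"time": series.time})
    for c in WRENCH_COLUMNS:
        col = getattr(series, c).copy()
        col[series.missing] = np.nan
        df[c] = col
    df.to_csv(path, index=False, float_format="%.9g", na_rep="")


def events_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records (one row per trial) for CSV export."""
    rows = []
    for k, r in enumerate(records):
        rows.append(
            {
                "trial": k,
                "onset_s": r.onset,
                "t_cross_s": r.transition.t_cross if r.transition else np.nan,
                "direction": r.transition.direction if r.transition else "",
                "accepted": r.accepted,
                "missing_fraction": r.missing_fraction,
            }
        )
    return pd.DataFrame(rows)
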