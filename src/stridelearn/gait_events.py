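"""Left heel-strike detection and step-length computation from lab time series.

The lab convention: kinematics (heel-marker anterior-posterior positions,
laboratory y-axis, +y = walking direction) sampled at 100 Hz; vertical
ground reaction forces (GRF) from the two treadmill belts at 1000 Hz. A left
heel strike is the moment the left foot is loaded (GRF on the left belt)
while the left heel marker's AP velocity first transitions from positive
(swinging forward) to negative (moving backward with the belt). Left step
length is the AP distance between the left and right heel markers at that
moment.

This module mirrors that rule offline: velocity is a centred finite
difference of the 100 Hz AP position smoothed with a short moving average,
GRF gating uses the nearest 1000 Hz sample, and a 0.4 s refractory period
between same-side events suppresses jitter double-detections (stride times
at 1.0-1.2 m/s are far longer).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import PHASE_BASELINE, PHASE_LEARNING, PhaseLayout, classify_success

__all__ = [
    "GaitTimeSeries",
    "HeelStrikeEvent",
    "AlignmentError",
    "detect_left_heel_strikes",
    "compute_left_step_length",
    "build_stride_table",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "STRIDE_TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

STRIDE_TABLE_COLUMNS = [
    "subject", "group", "phase", "stride", "lsl_m", "target_center_pct", "success",
]

#: Minimum separation between consecutive same-side heel strikes (s).
REFRACTORY_S = 0.4


class AlignmentError(ValueError):
    """Kinematic and kinetic streams do not cover the same interval."""


@dataclass
class GaitTimeSeries:
    """Synchronised kinematic (100 Hz) and kinetic (1000 Hz) streams.

    Positions are metres along the laboratory y-axis (+y anterior); forces
    are newtons, vertical component, one channel per belt.
    """

    kin_time: np.ndarray
    left_heel_ap: np.ndarray
    right_heel_ap: np.ndarray
    grf_time: np.ndarray
    left_grf_z: np.ndarray
    right_grf_z: np.ndarray
    kin_rate: float = 100.0
    grf_rate: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("kin_time", "left_heel_ap", "right_heel_ap",
                     "grf_time", "left_grf_z", "right_grf_z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.kin_time) == len(self.left_heel_ap) == len(self.right_heel_ap)):
            raise ValueError("kinematic channels must share one time base")
        if not (len(self.grf_time) == len(self.left_grf_z) == len(self.right_grf_z)):
            raise ValueError("kinetic channels must share one time base")
        for t in (self.kin_time, self.grf_time):
            if len(t) and np.any(np.diff(t) <= 0):
                raise ValueError("time vectors must be strictly increasing")
        if np.any(self.left_grf_z < 0) or np.any(self.right_grf_z < 0):
            raise ValueError("vertical GRFs must be >= 0")
        if len(self.kin_time) and len(self.grf_time):
            tol = 1.0 / self.kin_rate
            if (abs(self.kin_time[0] - self.grf_time[0]) > tol
                    or abs(self.kin_time[-1] - self.grf_time[-1]) > tol):
                raise AlignmentError(
                    "kinematic and kinetic streams must cover the same interval "
                    f"within one kinematic sample: kin [{self.kin_time[0]:.3f}, "
                    f"{self.kin_time[-1]:.3f}] vs grf [{self.grf_time[0]:.3f}, "
                    f"{self.grf_time[-1]:.3f}]"
                )


@dataclass(frozen=True)
class HeelStrikeEvent:
    side: str
    kin_index: int
    time: float


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge shrinkage (window must be odd)."""
    if window <= 1:
        return x
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_left_heel_strikes(
    ts: GaitTimeSeries,
    force_threshold_n: float = 20.0,
    smooth_window: int = 5,
    refractory_s: float = REFRACTORY_S,
) -> list[HeelStrikeEvent]:
    """Left heel strikes: loaded left belt + AP heel velocity turning negative.

    The AP velocity of the left heel is a centred finite difference smoothed
    with a ``smooth_window``-sample moving average. A candidate is the first
    kinematic sample of each positive-to-nonpositive velocity crossing; it
    becomes an event when the left vertical GRF at the nearest kinetic sample
    exceeds ``force_threshold_n``. Events closer than ``refractory_s`` to the
    previous accepted event are discarded.

    An all-zero force channel simply yields no events.
    """
    if force_threshold_n <= 0:
        raise ValueError(f"force_threshold_n must be > 0, got {force_threshold_n}")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    n = len(ts.kin_time)
    if n < 3:
        return []

    vel = np.gradient(ts.left_heel_ap, ts.kin_time)
    vel = _smooth(vel, smooth_window)
    vel[np.abs(vel) < 1e-9] = 0.0  # deadband: float dust is not a sign change

    crossings = np.flatnonzero((vel[:-1] > 0) & (vel[1:] <= 0)) + 1

    # nearest kinetic sample for each candidate kinematic sample
    grf_idx = np.clip(
        np.round((ts.kin_time[crossings] - ts.grf_time[0]) * ts.grf_rate).astype(int),
        0, len(ts.grf_time) - 1,
    ) if len(ts.grf_time) else np.array([], dtype=int)
    loaded = ts.left_grf_z[grf_idx] > force_threshold_n if len(grf_idx) else np.array([], dtype=bool)

    events: list[HeelStrikeEvent] = []
    last_t = -np.inf
    for idx, ok in zip(crossings, loaded):
        t = ts.kin_time[idx]
        if not ok or t - last_t < refractory_s:
            continue
        events.append(HeelStrikeEvent("left", int(idx), float(t)))
        last_t = t
    return events


def compute_left_step_length(ts: GaitTimeSeries, event: HeelStrikeEvent) -> float:
    """AP distance between left and right heel markers at the event sample.

    May be negative for pathological inputs; values are flagged downstream,
    never clamped here.
    """
    i = event.kin_index
    if not 0 <= i < len(ts.kin_time):
        raise IndexError(f"kin_index {i} out of range [0, {len(ts.kin_time)})")
    return float(ts.left_heel_ap[i] - ts.right_heel_ap[i])


def build_stride_table(
    ts: GaitTimeSeries,
    schedule: pd.DataFrame,
    layout: PhaseLayout,
    subject_id: str = "S01",
    group: str = "NA",
    **detect_kwargs,
) -> pd.DataFrame:
    """Detect left heel strikes and assemble the canonical stride table.

    Strides are assigned to phases in layout order; learning strides carry
    the target centre and the binary success flag from the reward window.
    If fewer events are detected than the layout demands, the table is
    truncated with a logged warning.
    """
    events = detect_left_heel_strikes(ts, **detect_kwargs)
    lengths = [compute_left_step_length(ts, e) for e in events]

    if len(events) < layout.total_strides:
        logger.warning(
            "subject %s: detected %d heel strikes but layout demands %d; truncating",
            subject_id, len(events), layout.total_strides,
        )

    rows = []
    k = 0
    for phase in layout.phase_names:
        for stride in range(1, layout.length(phase) + 1):
            if k >= len(events):
                break
            lsl = lengths[k]
            center_pct = np.nan
            success = np.nan
            if phase == PHASE_LEARNING:
                entry = schedule.iloc[stride - 1]
                center_pct = float(entry["center_pct"])
                success = float(classify_success(lsl, entry["lower_m"], entry["upper_m"]))
            rows.append((subject_id, group, phase, stride, lsl, center_pct, success))
            k += 1
    return pd.DataFrame(rows, columns=STRIDE_TABLE_COLUMNS)


def read_timeseries_csv(path, kin_rate: float = 100.0, grf_rate: float = 1000.0,
                        flip_ap_sign: bool = False) -> GaitTimeSeries:
    """Read a time-series CSV with columns time_kin, left_heel_ap, right_heel_ap,
    time_grf, left_grf_z, right_grf_z (kinematic columns shorter than kinetic
    ones are padded with trailing blanks)."""
    df = pd.read_csv(path)
    required = {"time_kin", "left_heel_ap", "right_heel_ap",
                "time_grf", "left_grf_z", "right_grf_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-series file {path} missing columns {sorted(missing)}")
    kin = df[["time_kin", "left_heel_ap", "right_heel_ap"]].dropna()
    grf = df[["time_grf", "left_grf_z", "right_grf_z"]].dropna()
    sign = -1.0 if flip_ap_sign else 1.0
    return GaitTimeSeries(
        kin_time=kin["time_kin"].to_numpy(),
        left_heel_ap=sign * kin["left_heel_ap"].to_numpy(),
        right_heel_ap=sign * kin["right_heel_ap"].to_numpy(),
        grf_time=grf["time_grf"].to_numpy(),
        left_grf_z=grf["left_grf_z"].to_numpy(),
        right_grf_z=grf["right_grf_z"].to_numpy(),
        kin_rate=kin_rate,
        grf_rate=grf_rate,
    )


def write_timeseries_csv(ts: GaitTimeSeries, path) -> None:
    n = max(len(ts.kin_time), len(ts.grf_time))

    def pad(x):
        return np.concatenate([x, np.full(n - len(x), np.nan)])

    pd.DataFrame(
        {
            "time_kin": pad(ts.kin_time),
            "left_heel_ap": pad(ts.left_heel_ap),
            "right_heel_ap": pad(ts.right_heel_ap),
            "time_grf": pad(ts.grf_time),
            "left_grf_z": pad(ts.left_grf_z),
            "right_grf_z": pad(ts.right_grf_z),
        }
    ).to_csv(path, index=False)
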