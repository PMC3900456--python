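"""Split continuous activity recordings into loading cycles.

Cycle boundaries depend on the activity class:

* walking / jogging — cycles run from foot contact to the next foot contact,
  detected as upward crossings of F_res through a contact threshold;
* stair climbing — cycles are separated at the force minima inside the
  low-force swing phases;
* non-cyclic exercises (knee bend, chair rise/sit, one-legged stance) — one
  "cycle" spanning the exercise, padded by a fraction of its length.

Detected cycles are resampled onto a fixed 0-100 % cycle grid for averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .load_model import Trial
from .reference import ACTIVITIES

log = logging.getLogger(__name__)

#: default number of grid points on the 0-100 % cycle (0.5 % steps).
N_GRID = 201
#: default foot-contact threshold on F_res, %BW.
CONTACT_THRESHOLD = 20.0
#: samples F_res must stay below threshold before a new contact counts.
CONTACT_HYSTERESIS = 5

WALKING_LIKE = ("walking", "jogging")
STAIR_LIKE = ("ascending_stairs", "descending_stairs")
NONCYCLIC = ("knee_bend", "standing_up", "sitting_down", "one_legged_stance")


@dataclass
class LoadCycle:
    """One loading cycle on its original time base."""

    subject_id: str
    activity: str
    trial_index: int
    cycle_index: int
    time: np.ndarray  # seconds, starting at 0
    channels: dict[str, np.ndarray]
    duration: float
    start_index: int = -1  # sample index of the boundary in the source record

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("cycle duration must be positive")


@dataclass
class NormalizedCycle:
    """A loading cycle resampled onto the standard % cycle grid."""

    subject_id: str
    activity: str
    trial_index: int
    cycle_index: int
    grid: np.ndarray
    channels: dict[str, np.ndarray]
    duration: float


def _expected_cycle_time(activity: str) -> float:
    if activity in ACTIVITIES.index:
        return float(ACTIVITIES.loc[activity, "cycle_time_s"])
    return 1.0


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge padding; window forced odd >= 1."""
    window = max(1, int(window))
    if window % 2 == 0:
        window += 1
    if window == 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


def _extract_cycles(
    trial: Trial, boundaries: list[int]
) -> list[LoadCycle]:
    cycles = []
    for k, (i0, i1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        t = trial.time[i0 : i1 + 1]
        cycles.append(
            LoadCycle(
                subject_id=trial.meta.subject_id,
                activity=trial.activity,
                trial_index=getattr(trial, "trial_index", 0),
                cycle_index=k,
                time=t - t[0],
                channels={
                    name: arr[i0 : i1 + 1].copy()
                    for name, arr in trial.channels.items()
                },
                duration=float(t[-1] - t[0]),
                start_index=i0,
            )
        )
    return cycles


def detect_contacts(
    fres: np.ndarray,
    threshold: float = CONTACT_THRESHOLD,
    hysteresis: int = CONTACT_HYSTERESIS,
) -> list[int]:
    """Indices of upward crossings of ``fres`` through ``threshold``.

    A crossing only counts if the signal has stayed below the threshold for
    at least ``hysteresis`` consecutive samples before it and stays at or
    above it for ``hysteresis`` samples after it (debouncing against
    swing-phase noise spikes).
    """
    fres = np.asarray(fres, float)
    n = len(fres)
    contacts = []
    below_run = hysteresis  # allow a contact right at the record start
    for i in range(n):
        if fres[i] < threshold:
            below_run += 1
        else:
            if (
                below_run >= hysteresis
                and i > 0
                and i + hysteresis <= n
                and np.all(fres[i : i + hysteresis] >= threshold)
            ):
                contacts.append(i)
            below_run = 0
    return contacts


def segment_walking(
    trial: Trial,
    contact_threshold: float = CONTACT_THRESHOLD,
    hysteresis: int = CONTACT_HYSTERESIS,
) -> list[LoadCycle]:
    """Foot-contact to foot-contact cycles for walking or jogging.

    Incomplete leading/trailing segments (before the first and after the
    last detected contact) are discarded.
    """
    fres = trial.fres()
    contacts = detect_contacts(fres, contact_threshold, hysteresis)
    if len(contacts) < 2:
        log.warning(
            "fewer than 2 foot contacts detected in %s/%s; no cycles",
            trial.meta.subject_id,
            trial.activity,
        )
        return []
    return _extract_cycles(trial, contacts)


def segment_stairs(trial: Trial, swing_fraction: float = 0.30) -> list[LoadCycle]:
    """Minimum-to-minimum cycles for stair ascent/descent.

    Swing phases are the intervals where the smoothed F_res drops below
    ``swing_fraction`` of the median stance peak; the boundary is the force
    minimum within each interior swing interval.
    """
    fres = trial.fres()
    t_c = _expected_cycle_time(trial.activity)
    window = int(round(0.05 * t_c * trial.sample_rate))
    smooth = _smooth(fres, window)
    peaks, _ = find_peaks(smooth, prominence=0.2 * np.ptp(smooth))
    if len(peaks) == 0:
        log.warning("no stance peaks found in %s", trial.meta.subject_id)
        return []
    swing_level = swing_fraction * float(np.median(smooth[peaks]))
    low = smooth < swing_level
    # interior low intervals -> one boundary (argmin) per interval
    boundaries = []
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if i > 0 and j < n:  # interior interval only
                boundaries.append(i + int(np.argmin(smooth[i:j])))
            i = j
        else:
            i += 1
    if len(boundaries) < 2:
        log.warning(
            "fewer than 2 swing minima in %s/%s; no complete cycles",
            trial.meta.subject_id,
            trial.activity,
        )
        return []
    return _extract_cycles(trial, boundaries)


def segment_noncyclic(
    trial: Trial,
    pad_fraction: float = 0.05,
    depart_fraction: float = 0.25,
    min_excursion: float = 5.0,
) -> LoadCycle:
    """One cycle spanning a non-cyclic exercise, padded on both sides.

    The baseline and peak level are estimated from the smoothed F_res (the
    baseline from the first and last 10 % of the record); the exercise
    interval itself is where the raw F_res exceeds the baseline by
    ``depart_fraction`` of the total excursion, so a sharp onset is located
    to the sample.  The interval is extended by ``pad_fraction`` of its own
    length per side and clipped to the record.
    """
    fres = trial.fres()
    n = len(fres)
    t_c = _expected_cycle_time(trial.activity)
    window = int(round(0.05 * t_c * trial.sample_rate))
    smooth = _smooth(fres, window)
    edge = max(1, n // 10)
    baseline = float(np.median(np.concatenate([smooth[:edge], smooth[-edge:]])))
    excursion = float(np.max(smooth)) - baseline
    if excursion < min_excursion:
        raise ValueError("no exercise detected: F_res never departs from baseline")
    level = baseline + depart_fraction * excursion
    above = np.nonzero(fres > level)[0]
    i0, i1 = int(above[0]), int(above[-1])
    pad = int(round(pad_fraction * (i1 - i0)))
    i0 = max(0, i0 - pad)
    i1 = min(n - 1, i1 + pad)
    return _extract_cycles(trial, [i0, i1])[0]


def segment_trial(trial: Trial, **kwargs) -> list[LoadCycle]:
    """Dispatch to the activity-appropriate segmentation rule."""
    if trial.activity in WALKING_LIKE:
        return segment_walking(trial, **kwargs)
    if trial.activity in STAIR_LIKE:
        return segment_stairs(trial, **kwargs)
    if trial.activity in NONCYCLIC:
        return [segment_noncyclic(trial, **kwargs)]
    raise ValueError(f"no segmentation rule for activity {trial.activity!r}")


def normalize_cycle(cycle: LoadCycle, n_grid: int = N_GRID) -> NormalizedCycle:
    """Resample a cycle onto the uniform 0-100 % grid by linear interpolation."""
    if n_grid < 10:
        raise ValueError("n_grid must be at least 10")
    grid = np.linspace(0.0, 100.0, n_grid)
    src = 100.0 * cycle.time / cycle.time[-1]
    channels = {
        name: np.interp(grid, src, arr) for name, arr in cycle.channels.items()
    }
    return NormalizedCycle(
        subject_id=cycle.subject_id,
        activity=cycle.activity,
        trial_index=cycle.trial_index,
        cycle_index=cycle.cycle_index,
        grid=grid,
        channels=channels,
        duration=cycle.duration,
    )
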