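"""EXTREME100 extraction: most extreme single-component peaks across trials.

The standardized levels scale all components by common factors, so they keep
the *average* load directions.  Individual subjects can deviate wildly: a
numbered peak of, say, Fy on the average pattern may be several times larger
in one subject, carry the opposite sign in another, or not exist at all in a
third.  The EXTREME100 analysis therefore

1. locates the numbered relative extrema on the average pattern of each
   component (``locate_reference_peaks``),
2. looks for the corresponding extremum in every single trial within a time
   window around the reference peak (``match_peak_in_trial``), excluding
   trials where the peak has the opposite sign or is missing, and
3. reports the most extreme matched value over all subjects and trials,
   scaled to a 100 kg body weight (``extreme_table``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema, find_peaks

from .load_model import GRAVITY
from .segmentation import NormalizedCycle, _smooth
from .warp_average import AveragedPattern

log = logging.getLogger(__name__)

#: default matching window around a reference peak, in % cycle.
MATCH_WINDOW = 15.0
#: default prominence thresholds for locating reference peaks.
PROMINENCE_FORCE = 5.0  # %BW
PROMINENCE_MOMENT = 0.5  # %BWm

FORCE_COMPONENTS = ("Fres", "Fx", "Fy", "-Fz")
MOMENT_COMPONENTS = ("Mx", "My", "Mz")

MATCHED = "matched"
SIGN_CONFLICT = "sign-conflict"
ABSENT = "absent"


@dataclass(frozen=True)
class PeakSpec:
    """One numbered reference extremum on the average pattern."""

    activity: str
    component: str
    peak_index: int
    kind: str  # 'max' or 'min'
    reference_time: float  # % cycle
    reference_value: float  # %BW or %BWm on the average pattern
    reference_sign: int

    def __post_init__(self):
        if self.kind not in ("max", "min"):
            raise ValueError("kind must be 'max' or 'min'")
        if not (0 <= self.reference_time <= 100):
            raise ValueError("reference_time must lie in [0, 100]")


@dataclass
class ExtremeRecord:
    """Most extreme matched value for one PeakSpec, at 100 kg."""

    spec: PeakSpec
    value: float  # N or Nm
    source: tuple[str, int, int]  # subject, trial, cycle
    n_matched: int
    n_excluded_sign: int
    n_excluded_absent: int


@dataclass
class ExtremeTable:
    records: list[ExtremeRecord]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "activity": r.spec.activity,
                    "component": r.spec.component,
                    "peak_index": r.spec.peak_index,
                    "kind": r.spec.kind,
                    "reference_time_pct": r.spec.reference_time,
                    "value": r.value,
                    "subject": r.source[0],
                    "trial": r.source[1],
                    "cycle": r.source[2],
                    "n_matched": r.n_matched,
                    "n_excluded_sign": r.n_excluded_sign,
                    "n_excluded_absent": r.n_excluded_absent,
                }
            )
        return pd.DataFrame(rows)


def _default_prominence(component: str) -> float:
    return PROMINENCE_MOMENT if component in MOMENT_COMPONENTS else PROMINENCE_FORCE


def locate_reference_peaks(
    pattern: AveragedPattern,
    component: str,
    max_peaks: int = 3,
    prominence: Optional[float] = None,
    smooth_window: int = 5,
    activity: str = "",
) -> list[PeakSpec]:
    """Numbered relative extrema of a component on the average pattern.

    Maxima and minima of the lightly smoothed channel with prominence above
    the threshold are ranked by absolute value; the ``max_peaks`` largest
    are kept and numbered 1, 2, ... in time order.
    """
    x = np.asarray(pattern.get(component), float)
    if np.ptp(x) == 0:
        return []
    if prominence is None:
        prominence = _default_prominence(component)
    xs = _smooth(x, smooth_window)
    found: list[tuple[int, str]] = []
    hi, _ = find_peaks(xs, prominence=prominence)
    lo, _ = find_peaks(-xs, prominence=prominence)
    found += [(int(i), "max") for i in hi] + [(int(i), "min") for i in lo]
    if not found:
        return []
    found.sort(key=lambda p: abs(x[p[0]]), reverse=True)
    kept = sorted(found[:max_peaks])
    specs = []
    for rank, (i, kind) in enumerate(kept, start=1):
        val = float(x[i])
        specs.append(
            PeakSpec(
                activity=activity,
                component=component,
                peak_index=rank,
                kind=kind,
                reference_time=float(pattern.grid[i]),
                reference_value=val,
                reference_sign=1 if val >= 0 else -1,
            )
        )
    return specs


def match_peak_in_trial(
    trial_pattern: Union[NormalizedCycle, AveragedPattern],
    spec: PeakSpec,
    window: float = MATCH_WINDOW,
) -> tuple[str, Optional[float]]:
    """Find the spec's extremum in one trial; three outcomes are possible.

    Searches +/- ``window`` % cycle around the reference time for relative
    extrema of the spec's kind (a shoulder without a derivative sign change
    counts as missing).  Returns ``('matched', value)`` if the most extreme
    such extremum carries the reference sign, ``('sign-conflict', value)``
    if it carries the opposite sign, and ``('absent', None)`` if no
    extremum of that kind lies in the window.
    """
    if isinstance(trial_pattern, NormalizedCycle):
        grid = np.asarray(trial_pattern.grid, float)
        if spec.component == "Fres" and "Fres" not in trial_pattern.channels:
            f = trial_pattern.channels
            x = np.sqrt(f["Fx"] ** 2 + f["Fy"] ** 2 + f["Fz"] ** 2)
        elif spec.component == "-Fz":
            x = -np.asarray(trial_pattern.channels["Fz"], float)
        else:
            x = np.asarray(trial_pattern.channels[spec.component], float)
    else:
        grid = trial_pattern.grid
        x = np.asarray(trial_pattern.get(spec.component), float)

    mask = np.abs(grid - spec.reference_time) <= window
    idx = np.nonzero(mask)[0]
    seg = x[idx]
    sign = 1 if spec.kind == "max" else -1
    # interior relative extrema of the requested kind within the window
    rel = argrelextrema(sign * seg, np.greater)[0]
    # plateaus (equal neighbours) are handled by >= on one side
    if len(rel) == 0:
        rel = argrelextrema(sign * seg, np.greater_equal)[0]
        rel = rel[(rel > 0) & (rel < len(seg) - 1)]
        # drop plateau points that are not true extrema of the segment
        rel = np.array(
            [i for i in rel if sign * seg[i] > min(sign * seg[0], sign * seg[-1])],
            dtype=int,
        )
    if len(rel) == 0:
        return ABSENT, None
    values = seg[rel]
    best = float(values[np.argmax(sign * values)])
    sign_ok = best == 0 or (1 if best > 0 else -1) == spec.reference_sign
    if sign_ok:
        return MATCHED, best
    return SIGN_CONFLICT, best


def extreme_table(
    trial_cycles: Sequence[NormalizedCycle],
    specs: Sequence[PeakSpec],
    bw_high: float = 100.0,
    window: float = MATCH_WINDOW,
) -> ExtremeTable:
    """Most extreme matched value per spec over all trials, at ``bw_high`` kg.

    %BW values are converted with 9.81 * bw_high / 100 (= 9.81 at 100 kg).
    For every spec, matched + sign-excluded + absent counts add up to the
    number of trials; specs with no matching trial are omitted with a
    warning.
    """
    if not trial_cycles:
        raise ValueError("at least one trial is required")
    factor = GRAVITY * bw_high / 100.0
    records = []
    for spec in specs:
        sign = 1 if spec.kind == "max" else -1
        best_val, best_src = None, None
        n_match = n_sign = n_absent = 0
        for c in trial_cycles:
            outcome, value = match_peak_in_trial(c, spec, window=window)
            if outcome == MATCHED:
                n_match += 1
                if best_val is None or sign * value > sign * best_val:
                    best_val = value
                    best_src = (c.subject_id, c.trial_index, c.cycle_index)
            elif outcome == SIGN_CONFLICT:
                n_sign += 1
            else:
                n_absent += 1
        if best_val is None:
            log.warning(
                "no trial matched %s peak %d of %s; record omitted",
                spec.component,
                spec.peak_index,
                spec.activity,
            )
            continue
        records.append(
            ExtremeRecord(
                spec=spec,
                value=best_val * factor,
                source=best_src,
                n_matched=n_match,
                n_excluded_sign=n_sign,
                n_excluded_absent=n_absent,
            )
        )
    return ExtremeTable(records=records)


def standard_specs(
    pattern: AveragedPattern,
    components: Sequence[str] = FORCE_COMPONENTS + MOMENT_COMPONENTS,
    max_peaks: int = 3,
    activity: str = "",
) -> list[PeakSpec]:
    """Reference peaks of all components of an average pattern."""
    specs: list[PeakSpec] = []
    for comp in components:
        if comp in ("Fres", "-Fz") or comp in pattern.channels:
            specs.extend(
                locate_reference_peaks(
                    pattern, comp, max_peaks=max_peaks, activity=activity
                )
            )
    return specs
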