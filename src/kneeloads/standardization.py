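"""Standardized load levels AVER75, HIGH100, PEAK100 and their factors.

The standardization condenses multi-subject, multi-trial recordings into
three load levels per activity:

* **AVER75** — the inter-individual average pattern, scaled to a 75 kg
  (average) body weight; its F_res peak in %BW is P1.
* **HIGH100** — AVER75 multiplied by ``(100/75) * F_H``, where
  ``F_H = P2 / P1`` and P2 is the largest intra-individual average peak
  among the subjects; it represents the strongest subject at 100 kg.
* **PEAK100** — HIGH100 multiplied by ``C_peak = F_P / F_H``, where
  ``F_P = P3 / P1`` and P3 is the highest single-trial peak ever recorded,
  so the PEAK100 peak equals P3 scaled to 100 kg.

All factors are derived from F_res alone and applied identically to every
load component, so the three levels share their load *directions* and differ
only by the scalar factors ``C_aver = 1 / ((100/75) * F_H)`` and ``C_peak``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .load_model import LoadPattern, UNITS_PCT, to_physical_units
from .reference import BW_AVERAGE, BW_HIGH
from .segmentation import NormalizedCycle
from .warp_average import AveragedPattern, average_cycles, average_patterns


@dataclass
class PeakRegistry:
    """The six reference peaks of the standardization.

    P1-P3 are F_res peaks in %BW (inter-individual average, highest
    intra-individual average, highest single trial); P4-P6 are the peaks of
    AVER75 / HIGH100 / PEAK100 in newtons.
    """

    P1: float
    P2: float
    P3: float
    P2_source: str
    P3_source: tuple[str, int, int]
    P4: Optional[float] = None
    P5: Optional[float] = None
    P6: Optional[float] = None

    def __post_init__(self):
        if self.P1 <= 0:
            raise ValueError("P1 must be positive")
        if self.P2 < self.P1 * (1 - 1e-9) or self.P3 < self.P1 * (1 - 1e-9):
            raise ValueError("P2 and P3 cannot fall below the average peak P1")


@dataclass
class Factors:
    F_H: float
    F_P: float
    C_aver: float
    C_peak: float


@dataclass
class StandardizedLoadSet:
    """AVER75 / HIGH100 / PEAK100 patterns for one activity, plus factors."""

    activity: str
    AVER75: LoadPattern
    HIGH100: LoadPattern
    PEAK100: LoadPattern
    factors: Factors
    registry: PeakRegistry
    cycle_time: float
    n_cycles: int


def intra_subject_average(
    cycles_by_subject: Mapping[str, Sequence[NormalizedCycle]],
    tol: float = 1e-6,
    max_iter: int = 50,
) -> dict[str, AveragedPattern]:
    """Warp-average each subject's cycles (in %BW/%BWm)."""
    out = {}
    for subject, cycles in cycles_by_subject.items():
        if not cycles:
            raise ValueError(f"subject {subject!r} contributes no cycles")
        out[subject] = average_cycles(list(cycles), tol=tol, max_iter=max_iter)
    return out


def inter_subject_average(
    subject_patterns: Mapping[str, AveragedPattern],
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[AveragedPattern, float]:
    """Warp-average the subject patterns; returns (pattern, P1).

    P1 is the peak of the resulting inter-individual average F_res (%BW).
    """
    if not subject_patterns:
        raise ValueError("at least one subject pattern is required")
    pattern = average_patterns(list(subject_patterns.values()), tol=tol, max_iter=max_iter)
    p1 = float(np.max(pattern.channels["Fres"]))
    return pattern, p1


def _peak(curve: np.ndarray) -> float:
    return float(np.max(curve))


def compute_factors(
    population_pattern: AveragedPattern,
    subject_patterns: Mapping[str, AveragedPattern],
    trial_cycles: Sequence[NormalizedCycle],
    bw_avg: float = BW_AVERAGE,
    bw_high: float = BW_HIGH,
) -> tuple[Factors, PeakRegistry]:
    """Derive F_H, F_P, C_aver, C_peak from the F_res peak registry.

    ``trial_cycles`` are all individual normalized cycles (both measurement
    sessions may be pooled to broaden the search for the highest trial).
    """
    p1 = _peak(population_pattern.channels["Fres"])
    if p1 <= 0:
        raise ValueError("population pattern has a non-positive F_res peak")
    p2, p2_src = -np.inf, ""
    for subject, pat in subject_patterns.items():
        pk = _peak(pat.channels["Fres"])
        if pk <= 0:
            raise ValueError(f"subject {subject!r} pattern has non-positive peak")
        if pk > p2:
            p2, p2_src = pk, subject
    p3, p3_src = -np.inf, ("", 0, 0)
    for c in trial_cycles:
        f = c.channels
        fres = (
            np.asarray(f["Fres"], float)
            if "Fres" in f
            else np.sqrt(f["Fx"] ** 2 + f["Fy"] ** 2 + f["Fz"] ** 2)
        )
        pk = _peak(fres)
        if pk > p3:
            p3, p3_src = pk, (c.subject_id, c.trial_index, c.cycle_index)
    bw_ratio = bw_high / bw_avg
    f_h = p2 / p1
    f_p = p3 / p1
    factors = Factors(
        F_H=f_h, F_P=f_p, C_aver=1.0 / (bw_ratio * f_h), C_peak=f_p / f_h
    )
    registry = PeakRegistry(P1=p1, P2=p2, P3=p3, P2_source=p2_src, P3_source=p3_src)
    return factors, registry


def build_standardized_set(
    population_pattern: AveragedPattern,
    factors: Factors,
    registry: PeakRegistry,
    activity: str = "",
    bw_avg: float = BW_AVERAGE,
    bw_high: float = BW_HIGH,
    peak_shape: str = "average",
    peak_trial: Optional[NormalizedCycle] = None,
) -> StandardizedLoadSet:
    """Scale the population pattern to the three standardized levels.

    ``peak_shape='average'`` (default) builds PEAK100 = HIGH100 * C_peak, so
    all three levels share the average shape.  ``peak_shape='trial'``
    instead rescales the single highest trial's own components
    (``peak_trial``) so its peak reaches P3 at 100 kg, retaining that
    trial's load directions.
    """
    if bw_avg <= 0 or bw_high <= 0:
        raise ValueError("body weights must be positive")
    base = LoadPattern(
        grid=population_pattern.grid.copy(),
        channels={k: v.copy() for k, v in population_pattern.channels.items()},
        units=UNITS_PCT,
        cycle_time=population_pattern.cycle_time,
    )
    aver75 = to_physical_units(base, bw_avg)
    high100 = aver75.scaled((bw_high / bw_avg) * factors.F_H)
    high100.bw_reference = bw_high
    if peak_shape == "average":
        peak100 = high100.scaled(factors.C_peak)
    elif peak_shape == "trial":
        if peak_trial is None:
            raise ValueError("peak_shape='trial' requires the highest trial cycle")
        trial_channels = {
            k: np.asarray(v, float) for k, v in peak_trial.channels.items()
        }
        if "Fres" not in trial_channels:
            trial_channels["Fres"] = np.sqrt(
                trial_channels["Fx"] ** 2
                + trial_channels["Fy"] ** 2
                + trial_channels["Fz"] ** 2
            )
        trial_base = LoadPattern(
            grid=np.asarray(peak_trial.grid, float),
            channels=trial_channels,
            units=UNITS_PCT,
            cycle_time=peak_trial.duration,
        )
        peak100 = to_physical_units(trial_base, bw_high)
    else:
        raise ValueError(f"unknown peak_shape {peak_shape!r}")
    peak100.bw_reference = bw_high
    registry.P4 = float(np.max(aver75.channels["Fres"]))
    registry.P5 = float(np.max(high100.channels["Fres"]))
    registry.P6 = float(np.max(peak100.channels["Fres"]))
    return StandardizedLoadSet(
        activity=activity,
        AVER75=aver75,
        HIGH100=high100,
        PEAK100=peak100,
        factors=factors,
        registry=registry,
        cycle_time=population_pattern.cycle_time,
        n_cycles=population_pattern.n_cycles,
    )
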