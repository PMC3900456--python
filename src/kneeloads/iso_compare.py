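"""Peak-by-peak comparison with a wear-test reference waveform.

Knee wear simulators are driven by standardized walking waveforms (ISO
14243 style): axial force, anterior-posterior force, and internal-external
rotation torque over the cycle, plus the flexion angle.  Those channels map
onto the measured components -Fz, Fy, and Mz.  The reference waveform is
licensed content and therefore always a user-supplied input file, never
bundled.

``compare_peaks`` pairs each extremum of the reference waveform with the
nearest-in-time measured extremum of the same kind and reports signed
percent differences ``100 * (measured - reference) / |reference|``; a
reference peak with no measured counterpart within the pairing window is
flagged as lacking.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .load_model import TrialFormatError
from .standardization import StandardizedLoadSet

log = logging.getLogger(__name__)

#: reference channel -> measured component
CHANNEL_MAP = {
    "axial_force": "-Fz",
    "ap_force": "Fy",
    "rotation_torque": "Mz",
}

REFERENCE_COLUMNS = ("axial_force_N", "ap_force_N", "torque_Nm", "flexion_deg")

#: default pairing window, % cycle.
PAIRING_WINDOW = 20.0


@dataclass
class ReferenceProfile:
    """A wear-test drive waveform on the standard 0-100 % grid."""

    grid: np.ndarray
    channels: dict[str, np.ndarray]  # axial_force, ap_force, rotation_torque, flexion
    label: str = "reference"


@dataclass
class PeakComparison:
    channel: str
    label: str  # e.g. 'axial_force max 1'
    reference_time: float
    reference_value: float
    measured_time: Optional[float]
    measured_value: Optional[float]
    percent_difference: Optional[float]
    flexion_at_peak: Optional[float]
    lacking: bool = False


def load_reference_profile(path, n_grid: int = 201, label: str | None = None) -> ReferenceProfile:
    """Read a reference waveform from a TRIAL-TSV-like file.

    The file may carry ``#key\\tvalue`` header lines; the table needs a
    ``cycle_pct`` or ``time_s`` column plus axial_force_N, ap_force_N,
    torque_Nm, flexion_deg.  Channels are resampled onto the standard grid.
    """
    text = Path(path).read_text(encoding="utf-8")
    body = "\n".join(l for l in text.splitlines() if l.strip() and not l.startswith("#"))
    table = pd.read_csv(io.StringIO(body), sep="\t")
    for col in REFERENCE_COLUMNS:
        if col not in table.columns:
            raise TrialFormatError(f"reference profile missing channel '{col}'")
    if "cycle_pct" in table.columns:
        src = table["cycle_pct"].to_numpy(float)
    elif "time_s" in table.columns:
        t = table["time_s"].to_numpy(float)
        src = 100.0 * (t - t[0]) / (t[-1] - t[0])
    else:
        raise TrialFormatError("reference profile needs a cycle_pct or time_s column")
    grid = np.linspace(0.0, 100.0, n_grid)
    channels = {
        "axial_force": np.interp(grid, src, table["axial_force_N"].to_numpy(float)),
        "ap_force": np.interp(grid, src, table["ap_force_N"].to_numpy(float)),
        "rotation_torque": np.interp(grid, src, table["torque_Nm"].to_numpy(float)),
        "flexion": np.interp(grid, src, table["flexion_deg"].to_numpy(float)),
    }
    return ReferenceProfile(grid=grid, channels=channels, label=label or str(path))


def write_reference_profile(profile: ReferenceProfile, path) -> None:
    cols = {
        "cycle_pct": profile.grid,
        "axial_force_N": profile.channels["axial_force"],
        "ap_force_N": profile.channels["ap_force"],
        "torque_Nm": profile.channels["rotation_torque"],
        "flexion_deg": profile.channels["flexion"],
    }
    lines = ["\t".join(cols)]
    for row in zip(*cols.values()):
        lines.append("\t".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _extrema(x: np.ndarray, prominence: float) -> list[tuple[int, str]]:
    hi, _ = find_peaks(x, prominence=prominence)
    lo, _ = find_peaks(-x, prominence=prominence)
    out = [(int(i), "max") for i in hi] + [(int(i), "min") for i in lo]
    return sorted(out)


def compare_peaks(
    measured: StandardizedLoadSet,
    reference: ReferenceProfile,
    window: float = PAIRING_WINDOW,
    prominence_fraction: float = 0.05,
) -> list[PeakComparison]:
    """Pair reference-waveform extrema with measured HIGH100 extrema.

    For every relative extremum of each reference channel, the nearest
    measured extremum of the same channel and kind within ``window`` %
    cycle is selected; percent difference is
    ``100 * (measured - reference) / |reference|`` (positive = measured
    larger in the signed sense).  Prominence for extremum detection is
    ``prominence_fraction`` of each channel's range.
    """
    high = measured.HIGH100
    grid = high.grid
    flexion = high.channels.get("flexion")
    comparisons: list[PeakComparison] = []
    for ref_name, comp in CHANNEL_MAP.items():
        ref = np.asarray(reference.channels[ref_name], float)
        mea = np.asarray(high.get(comp), float)
        ref_peaks = _extrema(ref, prominence_fraction * np.ptp(ref)) if np.ptp(ref) else []
        mea_peaks = _extrema(mea, prominence_fraction * np.ptp(mea)) if np.ptp(mea) else []
        if not ref_peaks:
            log.warning("no extrema found in reference channel %s", ref_name)
        counter = {"max": 0, "min": 0}
        for i_ref, kind in ref_peaks:
            counter[kind] += 1
            label = f"{ref_name} {kind} {counter[kind]}"
            t_ref = float(reference.grid[i_ref])
            v_ref = float(ref[i_ref])
            candidates = [
                (abs(float(grid[i]) - t_ref), i)
                for i, k in mea_peaks
                if k == kind and abs(float(grid[i]) - t_ref) <= window
            ]
            if not candidates:
                comparisons.append(
                    PeakComparison(
                        channel=ref_name,
                        label=label,
                        reference_time=t_ref,
                        reference_value=v_ref,
                        measured_time=None,
                        measured_value=None,
                        percent_difference=None,
                        flexion_at_peak=None,
                        lacking=True,
                    )
                )
                continue
            _, i_mea = min(candidates)
            v_mea = float(mea[i_mea])
            pct = 100.0 * (v_mea - v_ref) / abs(v_ref) if v_ref != 0 else np.nan
            comparisons.append(
                PeakComparison(
                    channel=ref_name,
                    label=label,
                    reference_time=t_ref,
                    reference_value=v_ref,
                    measured_time=float(grid[i_mea]),
                    measured_value=v_mea,
                    percent_difference=pct,
                    flexion_at_peak=(
                        float(flexion[i_mea]) if flexion is not None else None
                    ),
                )
            )
    return comparisons


def comparison_table(comparisons: list[PeakComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": c.channel,
                "label": c.label,
                "reference_time_pct": c.reference_time,
                "reference_value": c.reference_value,
                "measured_time_pct": c.measured_time,
                "measured_value": c.measured_value,
                "percent_difference": c.percent_difference,
                "flexion_at_peak_deg": c.flexion_at_peak,
                "lacking": c.lacking,
            }
            for c in comparisons
        ]
    )
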