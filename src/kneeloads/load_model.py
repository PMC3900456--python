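"""Data model, coordinate conventions, unit conversion, and trial file I/O.

Six load components are measured in an implant-fixed coordinate system of a
right-sided tibial component: forces Fx (lateral +), Fy (anterior +), Fz
(axial; the physiological compressive load acts distally, so -Fz is the
positive axial contact force) and moments Mx, My, Mz (flexion, abduction,
outer tibial rotation positive).  Forces are stored in percent body weight
(%BW), moments in percent body weight times meter (%BWm); conversion to
newtons happens only at output, via ``to_physical_units``.

Trial files use a plain-text tab-separated dialect ("TRIAL-TSV"): ``#key\\tvalue``
header lines carrying subject metadata, then a column header and numeric rows.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

GRAVITY = 9.81  # m/s^2, used for %BW -> N conversion

FORCE_CHANNELS = ("Fx", "Fy", "Fz")
MOMENT_CHANNELS = ("Mx", "My", "Mz")
LOAD_CHANNELS = FORCE_CHANNELS + MOMENT_CHANNELS
#: channels scaled when converting between %BW and physical units; the
#: optional flexion channel is an angle in degrees and is never rescaled.
SCALABLE_CHANNELS = LOAD_CHANNELS + ("Fres", "Mres", "Fres_of_mean")

MANDATORY_HEADER_KEYS = (
    "subject_id",
    "sex",
    "age_years",
    "body_mass_kg",
    "height_cm",
    "side",
    "activity",
    "sample_rate_hz",
    "posterior_slope_deg",
    "tibiofemoral_angle_deg",
    "units",
)

UNITS_PCT = "pctBW_pctBWm"
UNITS_PHYS = "N_Nm"


class TrialFormatError(ValueError):
    """Raised when a TRIAL-TSV file violates the dialect."""


class FrameStateError(RuntimeError):
    """Raised when a frame/handedness transform is applied twice."""


@dataclass(frozen=True)
class SubjectMeta:
    """Subject metadata as recorded with each trial.

    ``tibiofemoral_angle`` is signed (varus positive, valgus negative);
    ``posterior_slope`` is the backward tilt of the tibial component about
    the medio-lateral (x) axis, positive backwards.
    """

    subject_id: str
    sex: str
    age: float
    body_mass: float
    height: float
    side: str
    tibiofemoral_angle: float
    posterior_slope: float

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be positive, got {self.body_mass}")
        if not (0 <= self.posterior_slope < 30):
            raise ValueError(
                f"posterior_slope must be in [0, 30) deg, got {self.posterior_slope}"
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sex not in ("m", "f"):
            raise ValueError(f"sex must be 'm' or 'f', got {self.sex!r}")


@dataclass
class Trial:
    """One recorded activity trial: synchronized load channels + metadata.

    ``channels`` maps channel name -> 1-D array; the six load components are
    mandatory, ``flexion`` (degrees) is optional.  ``frame`` is ``implant``
    or ``tibia``; ``handedness`` is ``raw`` (as recorded) or
    ``right-canonical`` (left-knee trials mirrored onto the right-side
    convention).
    """

    meta: SubjectMeta
    activity: str
    sample_rate: float
    time: np.ndarray
    channels: dict[str, np.ndarray]
    frame: str = "implant"
    handedness: str = "raw"
    trial_index: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = len(self.time)
        if n < 2:
            raise ValueError("trial must contain at least 2 samples")
        for name in LOAD_CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing mandatory channel {name}")
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValueError(
                    f"channel {name} has length {len(arr)} != time length {n}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def fres(self) -> np.ndarray:
        """Resultant contact force F_res, computed from the components."""
        return resultant(self.channels["Fx"], self.channels["Fy"], self.channels["Fz"])

    def mres(self) -> np.ndarray:
        """Resultant moment M_res."""
        return resultant(self.channels["Mx"], self.channels["My"], self.channels["Mz"])

    def neg_fz(self) -> np.ndarray:
        """Axial contact force -Fz (positive when directed distally)."""
        return -self.channels["Fz"]

    def copy(self) -> "Trial":
        return Trial(
            meta=self.meta,
            activity=self.activity,
            sample_rate=self.sample_rate,
            time=self.time.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            frame=self.frame,
            handedness=self.handedness,
            trial_index=self.trial_index,
        )


@dataclass
class LoadPattern:
    """Load channels on the standard 0-100 % cycle grid.

    Units are either %BW/%BWm (``bw_reference`` is None) or N/Nm (then
    ``bw_reference`` holds the body mass in kg the pattern was scaled to).
    """

    grid: np.ndarray
    channels: dict[str, np.ndarray]
    units: str = UNITS_PCT
    bw_reference: Optional[float] = None
    cycle_time: Optional[float] = None

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g[0] != 0 or g[-1] != 100 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must increase strictly from 0 to 100")
        if self.units == UNITS_PHYS and self.bw_reference is None:
            raise ValueError("physical-unit pattern requires bw_reference")
        n = len(g)
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValueError(f"channel {name} length {len(arr)} != grid {n}")

    def neg_fz(self) -> np.ndarray:
        return -self.channels["Fz"]

    def get(self, component: str) -> np.ndarray:
        """Channel accessor understanding the '-Fz' pseudo-component."""
        if component == "-Fz":
            return self.neg_fz()
        return self.channels[component]

    def scaled(self, factor: float) -> "LoadPattern":
        """Return a copy with every load channel multiplied by ``factor``."""
        channels = {
            k: (v * factor if k in SCALABLE_CHANNELS else v.copy())
            for k, v in self.channels.items()
        }
        return LoadPattern(
            grid=self.grid.copy(),
            channels=channels,
            units=self.units,
            bw_reference=self.bw_reference,
            cycle_time=self.cycle_time,
        )


def resultant(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Element-wise Euclidean norm of three component series."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError(
            f"component length mismatch: {x.shape}, {y.shape}, {z.shape}"
        )
    return np.sqrt(x * x + y * y + z * z)


def bw_to_newton_factor(body_mass_kg: float) -> float:
    """Factor converting %BW to N for the given body mass (7.36 at 75 kg)."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return GRAVITY * body_mass_kg / 100.0


def _rotation_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def to_tibia_frame(trial: Trial, slope_deg: Optional[float] = None) -> Trial:
    """Re-express loads in the tibia-based system.

    The implant sits rotated backwards (positively) about the x-axis by the
    posterior slope relative to the tibial long axis; force and moment
    vectors are rotated by ``-slope`` about x.  The same rotation is applied
    to forces and moments (orientation change only; the moment reference
    point is not moved), so F_res and M_res are invariant.
    """
    if trial.frame != "implant":
        raise FrameStateError("trial is already in the tibia frame")
    if slope_deg is None:
        slope_deg = trial.meta.posterior_slope
    rot = _rotation_x(-slope_deg)
    out = trial.copy()
    for triplet in (FORCE_CHANNELS, MOMENT_CHANNELS):
        vec = np.vstack([trial.channels[c] for c in triplet])
        rotated = rot @ vec
        for i, c in enumerate(triplet):
            out.channels[c] = rotated[i]
    out.frame = "tibia"
    return out


def mirror_to_right(trial: Trial) -> Trial:
    """Mirror a left-knee trial onto the right-sided coordinate convention.

    Reflection about the sagittal plane (x -> -x): Fx changes sign, and the
    pseudo-vector components about the in-plane axes (My, Mz) change sign;
    Fy, Fz, Mx are unchanged.  Applying the mirror twice is the identity.
    """
    if trial.handedness != "raw":
        raise FrameStateError("trial is already right-canonical")
    if trial.meta.side != "left":
        raise FrameStateError("mirror_to_right applies to left-side trials only")
    out = trial.copy()
    for c in ("Fx", "My", "Mz"):
        out.channels[c] = -out.channels[c]
    out.handedness = "right-canonical"
    return out


def ensure_right_canonical(trial: Trial) -> Trial:
    """Return a right-canonical view of the trial, mirroring if left-sided."""
    if trial.handedness == "right-canonical":
        return trial
    if trial.meta.side == "left":
        return mirror_to_right(trial)
    out = trial.copy()
    out.handedness = "right-canonical"
    return out


def to_physical_units(pattern: LoadPattern, target_bw: float) -> LoadPattern:
    """Convert a %BW/%BWm pattern to N/Nm for a subject of ``target_bw`` kg.

    Every load channel is multiplied by 9.81 * target_bw / 100 (7.36 at the
    average 75 kg, 9.81 at the high 100 kg).  Patterns already in N/Nm for
    body weight X can be rescaled to Y by multiplying with Y/X.
    """
    if pattern.units != UNITS_PCT:
        raise FrameStateError("pattern is already in physical units")
    if target_bw <= 0:
        raise ValueError("target body weight must be positive")
    out = pattern.scaled(bw_to_newton_factor(target_bw))
    out.units = UNITS_PHYS
    out.bw_reference = float(target_bw)
    return out


# ---------------------------------------------------------------------------
# TRIAL-TSV I/O

_COLUMNS = ("time_s", "Fx", "Fy", "Fz", "Mx", "My", "Mz")
_FLEX_COL = "flexion_deg"


def read_trial(path) -> Trial:
    """Read a TRIAL-TSV file into a :class:`Trial`."""
    text = Path(path).read_text(encoding="utf-8")
    header: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            parts = line[1:].split("\t", 1)
            if len(parts) != 2:
                raise TrialFormatError(f"malformed header line: {line!r}")
            header[parts[0].strip()] = parts[1].strip()
        elif line.strip():
            body_lines.append(line)
    for key in MANDATORY_HEADER_KEYS:
        if key not in header:
            raise TrialFormatError(f"missing mandatory header key '{key}'")
    if header["units"] != UNITS_PCT:
        raise TrialFormatError(
            f"unsupported units {header['units']!r}; expected {UNITS_PCT!r}"
        )
    table = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    for col in _COLUMNS:
        if col not in table.columns:
            raise TrialFormatError(f"missing column '{col}'")
    time = table["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise TrialFormatError("time column must be strictly increasing")
    meta = SubjectMeta(
        subject_id=header["subject_id"],
        sex=header["sex"],
        age=float(header["age_years"]),
        body_mass=float(header["body_mass_kg"]),
        height=float(header["height_cm"]),
        side=header["side"],
        tibiofemoral_angle=float(header["tibiofemoral_angle_deg"]),
        posterior_slope=float(header["posterior_slope_deg"]),
    )
    channels = {c: table[c].to_numpy(dtype=float) for c in LOAD_CHANNELS}
    if _FLEX_COL in table.columns:
        channels["flexion"] = table[_FLEX_COL].to_numpy(dtype=float)
    return Trial(
        meta=meta,
        activity=header["activity"],
        sample_rate=float(header["sample_rate_hz"]),
        time=time,
        channels=channels,
        frame=header.get("frame", "implant"),
        handedness=header.get("handedness", "raw"),
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_trial(trial: Trial, path) -> None:
    """Write a :class:`Trial` as TRIAL-TSV with 6 significant digits."""
    meta = trial.meta
    lines = [
        f"#subject_id\t{meta.subject_id}",
        f"#sex\t{meta.sex}",
        f"#age_years\t{_fmt(meta.age)}",
        f"#body_mass_kg\t{_fmt(meta.body_mass)}",
        f"#height_cm\t{_fmt(meta.height)}",
        f"#side\t{meta.side}",
        f"#activity\t{trial.activity}",
        f"#sample_rate_hz\t{_fmt(trial.sample_rate)}",
        f"#posterior_slope_deg\t{_fmt(meta.posterior_slope)}",
        f"#tibiofemoral_angle_deg\t{_fmt(meta.tibiofemoral_angle)}",
        f"#units\t{UNITS_PCT}",
        f"#frame\t{trial.frame}",
        f"#handedness\t{trial.handedness}",
    ]
    cols = list(_COLUMNS)
    arrays = [trial.time] + [trial.channels[c] for c in LOAD_CHANNELS]
    if "flexion" in trial.channels:
        cols.append(_FLEX_COL)
        arrays.append(trial.channels["flexion"])
    lines.append("\t".join(cols))
    for row in zip(*arrays):
        lines.append("\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pattern(pattern: LoadPattern, path, extra_header: dict | None = None) -> None:
    """Write a LoadPattern on the % cycle grid as a TSV table."""
    lines = [f"#units\t{pattern.units}"]
    if pattern.bw_reference is not None:
        lines.append(f"#bw_reference_kg\t{_fmt(pattern.bw_reference)}")
    if pattern.cycle_time is not None:
        lines.append(f"#cycle_time_s\t{_fmt(pattern.cycle_time)}")
    for k, v in (extra_header or {}).items():
        lines.append(f"#{k}\t{v}")
    names = sorted(pattern.channels)
    lines.append("\t".join(["cycle_pct"] + names))
    for i, g in enumerate(pattern.grid):
        lines.append(
            "\t".join([_fmt(g)] + [_fmt(pattern.channels[n][i]) for n in names])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
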