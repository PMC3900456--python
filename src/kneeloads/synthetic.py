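"""Synthetic multi-subject load recordings with known ground truth.

Real telemetry recordings from instrumented implants are not redistributable,
so every pipeline stage is exercised on generated data that emulates the
statistical structure the analysis assumes:

* an activity-specific *template* — smooth shape-preserving curves through
  planted control points (two-peaked walking stance, single-peaked jogging,
  min-to-min stair cycles, single-plateau non-cyclic exercises), with
  -Fz nearly identical to F_res;
* a multiplicative per-subject load scale (log-normal), the source of the
  inter-individual spread that the F_H / C_aver factors quantify;
* per-trial smooth monotone time distortions (random warps) and cycle
  duration jitter;
* additive Gaussian noise on the six components, with F_res always derived
  from the noisy components rather than noised independently;
* optional per-subject sign flips of transverse components, mimicking the
  observed inter-individual sign variability of e.g. Fx and My.

Everything is driven by one seed; the same seed reproduces byte-identical
trial files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .load_model import SubjectMeta, Trial, write_trial
from .reference import ACTIVITIES
from .segmentation import NONCYCLIC, STAIR_LIKE, WALKING_LIKE, detect_contacts
from .warp_average import WarpingPath

#: components eligible for per-subject sign flips (F_res is invariant to them).
FLIP_COMPONENTS = ("Fx", "My", "Mz")

_LOAD = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")


# ---------------------------------------------------------------------------
# Templates

#: control points per activity: channel -> [(phase %, value)], in %BW / %BWm /
#: degrees.  F_res and the in-plane forces are planted; Fz is derived so the
#: component resultant reproduces F_res exactly.
_CONTROL_POINTS: dict[str, dict[str, list[tuple[float, float]]]] = {
    "walking": {
        "Fres": [(0, 8), (2, 30), (8, 170), (15, 230), (31, 160), (48, 260),
                 (56, 150), (62, 30), (70, 10), (85, 8), (100, 8)],
        "Fx": [(0, 0), (10, -3), (15, -4.5), (30, 0), (48, 5), (60, 1),
               (70, 0), (100, 0)],
        "Fy": [(0, 0), (8, -20), (14, -32), (30, -5), (47, 15), (58, 3),
               (70, 0), (100, 0)],
        "Mx": [(0, 0), (10, 0.8), (30, 1.0), (45, 2.2), (60, 0.3), (70, 0),
               (100, 0)],
        "My": [(0, 0), (10, 0.8), (30, -1.5), (48, -3.4), (62, -0.5),
               (70, 0), (100, 0)],
        "Mz": [(0, 0), (15, 0.9), (30, 0.1), (48, -1.1), (62, -0.2),
               (70, 0), (100, 0)],
        "flexion": [(0, 5), (15, 18), (40, 8), (72, 62), (100, 6)],
    },
    "jogging": {
        "Fres": [(0, 10), (3, 60), (40, 420), (62, 40), (70, 12), (100, 10)],
        "Fx": [(0, 0), (40, 12), (70, 0), (100, 0)],
        "Fy": [(0, 0), (20, -40), (40, -62), (60, -5), (100, 0)],
        "Mx": [(0, 0), (40, 2.6), (70, 0), (100, 0)],
        "My": [(0, 0), (40, -4.2), (70, 0), (100, 0)],
        "Mz": [(0, 0), (40, -1.2), (70, 0), (100, 0)],
        "flexion": [(0, 12), (40, 42), (75, 80), (100, 12)],
    },
    "ascending_stairs": {
        "Fres": [(0, 20), (3, 60), (25, 310), (40, 190), (55, 300), (70, 110),
                 (94, 60), (100, 20)],
        "Fx": [(0, 0), (25, 8), (55, 4), (80, 0), (100, 0)],
        "Fy": [(0, 0), (12, 14), (30, 2), (55, -54), (78, -4), (100, 0)],
        "Mx": [(0, 0), (30, 1.6), (50, 2.6), (80, 0.2), (100, 0)],
        "My": [(0, 0), (25, -3.6), (55, -4.0), (85, -0.4), (100, 0)],
        "Mz": [(0, 0), (25, -0.4), (55, -1.0), (85, 0), (100, 0)],
        "flexion": [(0, 55), (25, 25), (60, 12), (80, 70), (100, 55)],
    },
    "descending_stairs": {
        "Fres": [(0, 20), (3, 60), (25, 305), (40, 180), (55, 315), (70, 110),
                 (94, 60), (100, 20)],
        "Fx": [(0, 0), (25, -6), (55, 6), (80, 0), (100, 0)],
        "Fy": [(0, 0), (12, 10), (30, 2), (55, -45), (78, -4), (100, 0)],
        "Mx": [(0, 0), (30, 2.2), (55, 3.4), (80, 0.2), (100, 0)],
        "My": [(0, 0), (25, -4.2), (55, -4.6), (85, -0.4), (100, 0)],
        "Mz": [(0, 0), (25, -0.8), (55, -1.3), (85, 0), (100, 0)],
        "flexion": [(0, 12), (30, 25), (70, 80), (100, 12)],
    },
    "knee_bend": {
        "Fres": [(0, 45), (15, 48), (50, 280), (85, 48), (100, 45)],
        "Fx": [(0, 0), (50, 4), (100, 0)],
        "Fy": [(0, 0), (30, -16), (50, -4), (70, 9), (100, 0)],
        "Mx": [(0, 0), (50, 3.2), (100, 0)],
        "My": [(0, 0), (35, 1.2), (50, -2.0), (65, 1.0), (100, 0)],
        "Mz": [(0, 0), (50, -1.2), (100, 0)],
        "flexion": [(0, 5), (50, 98), (100, 5)],
    },
    "standing_up": {
        "Fres": [(0, 45), (12, 50), (45, 285), (80, 50), (100, 45)],
        "Fx": [(0, 0), (45, 5), (100, 0)],
        "Fy": [(0, 0), (30, -19), (50, -5), (70, 10), (100, 0)],
        "Mx": [(0, 0), (45, 2.2), (100, 0)],
        "My": [(0, 0), (30, 1.5), (45, -2.2), (65, 0.8), (100, 0)],
        "Mz": [(0, 0), (45, -1.1), (100, 0)],
        "flexion": [(0, 94), (45, 40), (100, 6)],
    },
    "sitting_down": {
        "Fres": [(0, 45), (15, 50), (55, 275), (88, 50), (100, 45)],
        "Fx": [(0, 0), (55, 4), (100, 0)],
        "Fy": [(0, 0), (35, -15), (55, -4), (75, 8), (100, 0)],
        "Mx": [(0, 0), (55, 2.0), (100, 0)],
        "My": [(0, 0), (40, 1.0), (55, -1.4), (75, 0.6), (100, 0)],
        "Mz": [(0, 0), (55, -1.0), (100, 0)],
        "flexion": [(0, 6), (55, 40), (100, 94)],
    },
    "one_legged_stance": {
        "Fres": [(0, 45), (10, 50), (50, 265), (90, 50), (100, 45)],
        "Fx": [(0, 0), (50, 3), (100, 0)],
        "Fy": [(0, 0), (50, -25), (100, 0)],
        "Mx": [(0, 0), (50, 2.6), (100, 0)],
        "My": [(0, 0), (50, -4.2), (100, 0)],
        "Mz": [(0, 0), (50, -1.2), (100, 0)],
        "flexion": [(0, 5), (50, 10), (100, 5)],
    },
}


@dataclass
class Template:
    """Smooth activity template with planted peak locations."""

    activity: str
    cycle_time: float
    amplitude: float
    _interp: dict[str, PchipInterpolator]
    fres_peaks: list[tuple[float, float]]  # (phase %, value %BW)

    def eval(self, channel: str, phase: np.ndarray) -> np.ndarray:
        """Channel value at the given cycle phase(s), in % cycle."""
        phase = np.asarray(phase, float)
        if channel == "Fres":
            raw = self._interp["Fres"](phase)
        elif channel == "Fz":
            fres = self._interp["Fres"](phase)
            fx = self._interp["Fx"](phase)
            fy = self._interp["Fy"](phase)
            raw = -np.sqrt(np.maximum(fres**2 - fx**2 - fy**2, 0.0))
        else:
            raw = self._interp[channel](phase)
        if channel == "flexion":
            return raw
        return self.amplitude * raw

    def channels(self, n_grid: int = 201) -> dict[str, np.ndarray]:
        """All channels sampled on the standard 0-100 % grid."""
        grid = np.linspace(0.0, 100.0, n_grid)
        out = {c: self.eval(c, grid) for c in _LOAD + ("flexion", "Fres")}
        out["grid"] = grid
        return out


def make_template(activity: str, amplitude: float = 1.0) -> Template:
    """Build the parametric template of one activity.

    ``amplitude`` scales all load channels (0 gives a zero-load template);
    the flexion angle is not scaled.
    """
    if activity not in _CONTROL_POINTS:
        raise ValueError(
            f"unknown activity {activity!r}; supported: {sorted(_CONTROL_POINTS)}"
        )
    points = _CONTROL_POINTS[activity]
    interp = {
        name: PchipInterpolator(*map(np.array, zip(*pts)))
        for name, pts in points.items()
    }
    peaks = _planted_fres_peaks(points["Fres"], amplitude)
    t_c = float(ACTIVITIES.loc[activity, "cycle_time_s"])
    return Template(
        activity=activity,
        cycle_time=t_c,
        amplitude=amplitude,
        _interp=interp,
        fres_peaks=peaks,
    )


def _planted_fres_peaks(
    pts: list[tuple[float, float]], amplitude: float
) -> list[tuple[float, float]]:
    """Local maxima among the F_res control points (pchip peaks sit on knots)."""
    vals = [v for _, v in pts]
    peaks = []
    for i in range(1, len(pts) - 1):
        if vals[i] > vals[i - 1] and vals[i] > vals[i + 1]:
            peaks.append((pts[i][0], vals[i] * amplitude))
    return peaks


# ---------------------------------------------------------------------------
# Random warps

def random_warp(
    rng: np.random.Generator | int,
    strength: float,
    n_grid: int = 201,
    n_modes: int = 3,
) -> WarpingPath:
    """Smooth, monotone, endpoint-anchored random time distortion.

    ``strength`` in [0, 1) bounds the slope deviation of the warp (0 gives
    the identity).  The path is the normalized integral of positive weights
    ``exp(g)`` with ``g`` a random low-order sine series scaled so that
    ``max|g| = log(1 + strength)``.
    """
    if not (0 <= strength < 1):
        raise ValueError("strength must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    u = np.linspace(0.0, 1.0, n_grid)
    grid = 100.0 * u
    if strength == 0:
        return WarpingPath.identity(grid)
    coeffs = rng.standard_normal(n_modes)
    g = np.zeros(n_grid)
    for k, a in enumerate(coeffs, start=1):
        g += a * np.sin(np.pi * k * u)
    peak = np.max(np.abs(g))
    if peak > 0:
        g *= np.log1p(strength) / peak
    w = np.exp(g)
    v = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(u))])
    v /= v[-1]
    v[0], v[-1] = 0.0, 1.0
    return WarpingPath(grid=grid, mapped=100.0 * v)


def invert_warp(path: WarpingPath) -> WarpingPath:
    """Numerical inverse of a warping path (swap of axes + resampling)."""
    mapped = np.interp(path.grid, path.mapped, path.grid)
    mapped[0], mapped[-1] = path.grid[0], path.grid[-1]
    return WarpingPath(grid=path.grid.copy(), mapped=np.maximum.accumulate(mapped))


def warp_phase(path: WarpingPath, phase: np.ndarray) -> np.ndarray:
    """Evaluate the warp mapping at arbitrary phases (% cycle)."""
    return np.interp(phase, path.grid, path.mapped)


# ---------------------------------------------------------------------------
# Population sampling

@dataclass
class PopulationConfig:
    """Study conditions of one synthetic cohort.

    Defaults follow the published study's scale: 8 subjects, around 20
    cycles per subject for walking, cycle times from the activity table,
    log-normal subject load scales whose spread matches the observed
    inter-individual variation (C_aver around 0.53-0.60), modest timing
    jitter, and additive component noise within the implant's measurement
    accuracy (a few %BW against stance peaks of 230-420 %BW).
    """

    activity: str = "walking"
    n_subjects: int = 8
    cycles_per_subject: int = 20
    sample_rate: float = 100.0
    subject_scale_sigma: float = 0.18
    subject_scales: Optional[Sequence[float]] = None
    trial_scale_sigma: float = 0.05
    warp_strength: float = 0.15
    noise_sd: float = 3.0  # %BW, per force component
    moment_noise_sd: float = 0.3  # %BWm
    sign_flip_prob: float = 0.0
    flip_components: Sequence[str] = FLIP_COMPONENTS
    cycle_time: Optional[float] = None
    duration_jitter: float = 0.05
    amplitude: float = 1.0
    include_flexion: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.sign_flip_prob <= 1):
            raise ValueError("sign_flip_prob must lie in [0, 1]")
        if not (0 <= self.warp_strength < 1):
            raise ValueError("warp_strength must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Everything needed to recompute expected pipeline outputs."""

    template: Template
    config: PopulationConfig
    subject_scales: dict[str, float]
    sign_flips: dict[str, dict[str, int]]
    warps: dict[str, list[WarpingPath]]
    trial_factors: dict[str, list[float]]
    durations: dict[str, list[float]]
    boundaries: dict[str, np.ndarray]  # sample indices of cycle starts
    n_cycles: dict[str, int]

    def expected_subject_peak(self, subject: str) -> float:
        """Planted subject F_res peak.

        Template peak times the subject scale times the mean of the
        per-rendition trial factors that end up in the subject's cycles.
        """
        tpeak = max(v for _, v in self.template.fres_peaks)
        n = self.n_cycles[subject]
        factors = self.trial_factors[subject][:n] or [1.0]
        return tpeak * self.subject_scales[subject] * float(np.mean(factors))

    def expected_p1(self) -> float:
        tpeak = max(v for _, v in self.template.fres_peaks)
        return tpeak * float(np.mean(list(self.subject_scales.values())))

    def expected_f_h(self) -> float:
        scales = np.array(list(self.subject_scales.values()))
        return float(scales.max() / scales.mean())


def subject_scales_with_ratio(
    n: int, ratio: float, rng: np.random.Generator | int, sigma: float = 0.12
) -> np.ndarray:
    """Log-normal subject scales adjusted so max/mean equals ``ratio`` exactly.

    Used to plant a known F_H: the strongest subject's average peak exceeds
    the population average peak by exactly ``ratio``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    for _ in range(100):
        s = rng.lognormal(mean=0.0, sigma=sigma, size=n)
        m, mx = s.mean(), s.max()
        if mx == m:
            if ratio == 1:
                return s
            continue
        a = (ratio - 1) * m / (mx - m)
        s2 = m + a * (s - m)
        if np.all(s2 > 0.05):
            return s2 / s2.mean()  # normalize mean to 1; max/mean preserved
    raise RuntimeError("could not construct positive scales with requested ratio")


def _subject_meta(subject_id: str, k: int) -> SubjectMeta:
    side = "left" if k % 2 == 0 else "right"
    return SubjectMeta(
        subject_id=subject_id,
        sex="m" if k % 3 else "f",
        age=62 + (k * 5) % 15,
        body_mass=70 + 5 * k,
        height=165 + (k * 3) % 14,
        side=side,
        tibiofemoral_angle=float((-1) ** k * (2 + k % 4)),
        posterior_slope=float(5 + k % 6),
        )


def _render_cycle(
    template: Template,
    n_samples: int,
    warp: WarpingPath,
    scale: float,
    signs: dict[str, int],
    include_flexion: bool,
) -> dict[str, np.ndarray]:
    phase = 100.0 * np.arange(n_samples) / n_samples
    tpl_phase = warp_phase(warp, phase)
    out = {}
    for c in _LOAD:
        out[c] = template.eval(c, tpl_phase) * scale * signs.get(c, 1)
    if include_flexion:
        out["flexion"] = template.eval("flexion", tpl_phase)
    return out


def sample_population(
    config: PopulationConfig, out_dir: Optional[str | Path] = None
) -> tuple[list[Trial], GroundTruth]:
    """Generate a synthetic cohort; optionally write TRIAL-TSV files.

    Cyclic activities produce one continuous recording per subject holding
    ``cycles_per_subject`` complete cycles (one extra rendition is appended
    so the final cycle ends on a detected boundary); non-cyclic activities
    produce ``cycles_per_subject`` separate exercise recordings per subject.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    template = make_template(config.activity, amplitude=config.amplitude)
    t_c = config.cycle_time or template.cycle_time
    cyclic = config.activity in WALKING_LIKE + STAIR_LIKE

    if config.subject_scales is not None:
        scales = np.asarray(config.subject_scales, float)
        if len(scales) != config.n_subjects:
            raise ValueError("subject_scales length must equal n_subjects")
    else:
        scales = rng.lognormal(mean=0.0, sigma=config.subject_scale_sigma,
                               size=config.n_subjects)

    trials: list[Trial] = []
    truth = GroundTruth(
        template=template,
        config=config,
        subject_scales={},
        sign_flips={},
        warps={},
        trial_factors={},
        durations={},
        boundaries={},
        n_cycles={},
    )

    for k in range(config.n_subjects):
        sid = f"S{k + 1:02d}"
        meta = _subject_meta(sid, k)
        s_k = float(scales[k])
        signs = {
            c: (-1 if rng.random() < config.sign_flip_prob else 1)
            for c in config.flip_components
        }
        truth.subject_scales[sid] = s_k
        truth.sign_flips[sid] = signs
        truth.warps[sid] = []
        truth.trial_factors[sid] = []
        truth.durations[sid] = []

        # cyclic recordings need extra renditions so that cycles_per_subject
        # complete cycles survive boundary detection: walking cycles end at
        # the next contact (one extra), stair cycles live between interior
        # swing minima (two extra).
        if config.activity in WALKING_LIKE:
            n_render = config.cycles_per_subject + 1
        elif config.activity in STAIR_LIKE:
            n_render = config.cycles_per_subject + 2
        else:
            n_render = config.cycles_per_subject
        renditions = []
        for _ in range(n_render):
            warp = random_warp(rng, config.warp_strength)
            factor = float(rng.lognormal(0.0, config.trial_scale_sigma))
            duration = t_c * (1 + rng.uniform(-config.duration_jitter,
                                              config.duration_jitter))
            n = max(10, int(round(duration * config.sample_rate)))
            renditions.append(
                _render_cycle(template, n, warp, s_k * factor, signs,
                              config.include_flexion)
            )
            truth.warps[sid].append(warp)
            truth.trial_factors[sid].append(factor)
            truth.durations[sid].append(n / config.sample_rate)

        if cyclic:
            clean = {
                c: np.concatenate([r[c] for r in renditions])
                for c in renditions[0]
            }
            clean_fres = np.sqrt(
                clean["Fx"] ** 2 + clean["Fy"] ** 2 + clean["Fz"] ** 2
            )
            if config.activity in WALKING_LIKE:
                bounds = detect_contacts(clean_fres)
            else:  # stairs: cycles start at the planted swing minima
                lengths = [len(r["Fx"]) for r in renditions]
                bounds = list(np.cumsum(lengths)[:-1])
            truth.boundaries[sid] = np.asarray(bounds, dtype=int)
            truth.n_cycles[sid] = max(0, len(bounds) - 1)
            channels = _add_noise(clean, rng, config)
            n_total = len(channels["Fx"])
            trial = Trial(
                meta=meta,
                activity=config.activity,
                sample_rate=config.sample_rate,
                time=np.arange(n_total) / config.sample_rate,
                channels=channels,
            )
            trial.trial_index = 0
            trials.append(trial)
        else:
            truth.n_cycles[sid] = config.cycles_per_subject
            starts = []
            for j, r in enumerate(renditions):
                n_pad = int(round(0.2 * len(r["Fx"])))
                base = {
                    c: np.full(n_pad, template.eval(c, 0.0) * s_k
                               * signs.get(c, 1) if c != "flexion"
                               else template.eval("flexion", 0.0))
                    for c in r
                }
                channels = {
                    c: np.concatenate([base[c], r[c], base[c]]) for c in r
                }
                starts.append(n_pad)
                channels = _add_noise(channels, rng, config)
                n_total = len(channels["Fx"])
                trial = Trial(
                    meta=meta,
                    activity=config.activity,
                    sample_rate=config.sample_rate,
                    time=np.arange(n_total) / config.sample_rate,
                    channels=channels,
                )
                trial.trial_index = j
                trials.append(trial)
            truth.boundaries[sid] = np.asarray(starts, dtype=int)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, tr in enumerate(trials):
            write_trial(
                tr,
                out_dir
                / f"{tr.meta.subject_id}_{tr.activity}_{tr.trial_index:02d}.tsv",
            )
    return trials, truth


def _add_noise(
    channels: dict[str, np.ndarray],
    rng: np.random.Generator,
    config: PopulationConfig,
) -> dict[str, np.ndarray]:
    out = {}
    for c, arr in channels.items():
        if c in ("Fx", "Fy", "Fz"):
            sd = config.noise_sd
        elif c in ("Mx", "My", "Mz"):
            sd = config.moment_noise_sd
        else:  # flexion
            sd = 0.3
        out[c] = arr + (rng.standard_normal(len(arr)) * sd if sd > 0 else 0.0)
    return out
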