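"""End-to-end orchestration: trials in, standardized load sets out.

``run_standardization`` chains the whole analysis for one activity:
mirror left-knee trials onto the right-sided convention, optionally rotate
into the tibia frame, segment into loading cycles, resample to the % cycle
grid, warp-average within and then across subjects, derive the F_H / F_P
factors, scale to AVER75 / HIGH100 / PEAK100, and extract the EXTREME100
component table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .extremes import ExtremeTable, MATCH_WINDOW, extreme_table, standard_specs
from .load_model import (
    LoadPattern,
    Trial,
    ensure_right_canonical,
    read_trial,
    to_tibia_frame,
    write_pattern,
)
from .reference import BW_AVERAGE, BW_HIGH
from .segmentation import N_GRID, NormalizedCycle, normalize_cycle, segment_trial
from .standardization import (
    StandardizedLoadSet,
    build_standardized_set,
    compute_factors,
    inter_subject_average,
    intra_subject_average,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one standardization run; defaults are the study's."""

    inputs: Sequence[str | Path] = ()
    activity: Optional[str] = None
    bw_avg: float = BW_AVERAGE
    bw_high: float = BW_HIGH
    n_grid: int = N_GRID
    tol: float = 1e-6
    max_iter: int = 50
    window: float = MATCH_WINDOW
    tibia_frame: bool = False
    max_extreme_peaks: int = 3
    out_dir: Optional[str | Path] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class RunResult:
    loadset: StandardizedLoadSet
    extremes: ExtremeTable
    cycles_per_subject: dict[str, int]
    factor_table: pd.DataFrame


def load_trials(inputs: Sequence[str | Path]) -> list[Trial]:
    """Read trials from files and/or directories of TRIAL-TSV files."""
    trials = []
    for item in inputs:
        p = Path(item)
        paths = sorted(p.glob("*.tsv")) if p.is_dir() else [p]
        for i, path in enumerate(paths):
            t = read_trial(path)
            trials.append(t)
    return trials


def prepare_cycles(
    trials: Sequence[Trial],
    config: RunConfig,
) -> dict[str, list[NormalizedCycle]]:
    """Canonicalize, segment and normalize; returns cycles grouped by subject."""
    by_subject: dict[str, list[NormalizedCycle]] = {}
    for trial in trials:
        t = ensure_right_canonical(trial)
        if config.tibia_frame:
            t = to_tibia_frame(t)
        cycles = segment_trial(t)
        normed = [normalize_cycle(c, n_grid=config.n_grid) for c in cycles]
        by_subject.setdefault(t.meta.subject_id, []).extend(normed)
    for subject, cycles in sorted(by_subject.items()):
        log.info("subject %s: %d cycles", subject, len(cycles))
    return by_subject


def run_standardization(
    config: RunConfig, trials: Optional[Sequence[Trial]] = None
) -> RunResult:
    """Execute the full pipeline; optionally write report files.

    ``trials`` may be passed directly (e.g. from the synthetic generator);
    otherwise they are read from ``config.inputs``.
    """
    if trials is None:
        trials = load_trials(config.inputs)
    if not trials:
        raise ValueError("no readable trials")
    activity = config.activity or trials[0].activity
    trials = [t for t in trials if t.activity == activity]

    by_subject = prepare_cycles(trials, config)
    by_subject = {s: c for s, c in by_subject.items() if c}
    if not by_subject:
        raise ValueError(f"no cycles found for activity {activity!r}")
    all_cycles = [c for cycles in by_subject.values() for c in cycles]

    subject_patterns = intra_subject_average(
        by_subject, tol=config.tol, max_iter=config.max_iter
    )
    population, _ = inter_subject_average(
        subject_patterns, tol=config.tol, max_iter=config.max_iter
    )
    factors, registry = compute_factors(
        population,
        subject_patterns,
        all_cycles,
        bw_avg=config.bw_avg,
        bw_high=config.bw_high,
    )
    loadset = build_standardized_set(
        population,
        factors,
        registry,
        activity=activity,
        bw_avg=config.bw_avg,
        bw_high=config.bw_high,
    )
    loadset.n_cycles = len(all_cycles)

    specs = standard_specs(
        population, max_peaks=config.max_extreme_peaks, activity=activity
    )
    table = extreme_table(
        all_cycles, specs, bw_high=config.bw_high, window=config.window
    )

    factor_table = pd.DataFrame(
        [
            {
                "activity": activity,
                "n_cycles": len(all_cycles),
                "T_c_s": loadset.cycle_time,
                "C_aver": factors.C_aver,
                "C_peak": factors.C_peak,
                "F_H": factors.F_H,
                "F_P": factors.F_P,
            }
        ]
    )
    result = RunResult(
        loadset=loadset,
        extremes=table,
        cycles_per_subject={s: len(c) for s, c in by_subject.items()},
        factor_table=factor_table,
    )
    if config.out_dir is not None:
        _write_report(result, Path(config.out_dir))
    return result


def _float_fmt(x) -> str:
    return f"{x:.6g}" if isinstance(x, (int, float, np.floating)) else str(x)


def _write_report(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    ls = result.loadset
    for name in ("AVER75", "HIGH100", "PEAK100"):
        write_pattern(
            getattr(ls, name),
            out_dir / f"{ls.activity}_{name}.tsv",
            extra_header={"level": name, "activity": ls.activity},
        )
    result.factor_table.to_csv(
        out_dir / f"{ls.activity}_factors.tsv",
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    result.extremes.to_dataframe().to_csv(
        out_dir / f"{ls.activity}_extreme100.tsv",
        sep="\t",
        index=False,
        float_format="%.6g",
    )
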