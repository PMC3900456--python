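"""Time-warping average of loading cycles.

Cycle-to-cycle timing differences (a late second force peak, a stretched
swing phase) make the pointwise mean of time-normalized cycles smear out the
very extrema the average is supposed to represent.  The remedy is curve
registration: each cycle's time axis is deformed by a monotone, endpoint-
anchored *warping path* so that the summed squared difference of the
resultant force F_res between the deformed cycles becomes minimal; the
arithmetic mean of the deformed curves is the average pattern.  The path
fitted on F_res is then applied unchanged to all synchronized channels
(components, moments, flexion angle), preserving their mutual timing.

A desirable consequence of least-squares registration: a relative maximum
present in only half of the cycles, at varying times, survives averaging at
roughly half its height at an average time instead of being flattened.

The registration is an iterated template fit.  The template starts as the
pointwise mean; each iteration aligns every cycle to the template with a
constrained dynamic program (monotone lattice path, endpoints pinned, the
template index advancing by 0, 1, or 2 per grid step) and recomputes the
template as the mean of the warped curves, until the objective stops
decreasing.  The DP is exact for its step family — tests verify it against
exhaustive path enumeration on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segmentation import NormalizedCycle

#: convergence defaults: relative objective decrease below TOL stops.
TOL = 1e-6
MAX_ITER = 50


@dataclass
class WarpingPath:
    """Monotone map from a cycle's normalized time to template time.

    ``grid`` holds the input positions (0-100 %); ``mapped`` the template
    position of each input sample.  Endpoints are pinned (0 -> 0,
    100 -> 100) and the mapping is non-decreasing, so its total variation
    is exactly 100.
    """

    grid: np.ndarray
    mapped: np.ndarray

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        g, m = np.asarray(self.grid, float), np.asarray(self.mapped, float)
        if g.shape != m.shape:
            raise ValueError("grid and mapped must have equal length")
        if m[0] != g[0] or m[-1] != g[-1]:
            raise ValueError("warping path endpoints must be anchored")
        if np.any(np.diff(m) < 0):
            raise ValueError("warping path must be non-decreasing")

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.grid, self.mapped))

    @classmethod
    def identity(cls, grid: np.ndarray) -> "WarpingPath":
        return cls(grid=np.asarray(grid, float), mapped=np.asarray(grid, float))


@dataclass
class AveragedPattern:
    """Mean cycle of all channels on the standard grid.

    ``channels['Fres']`` is the mean of the warped F_res curves — the
    quantity the registration optimizes.  The resultant of the mean
    components (norm of a mean is <= mean of norms) is kept separately in
    ``channels['Fres_of_mean']``.
    """

    grid: np.ndarray
    channels: dict[str, np.ndarray]
    cycle_time: float
    n_cycles: int
    objective: float
    paths: list[WarpingPath] = field(default_factory=list)

    def get(self, component: str) -> np.ndarray:
        if component == "-Fz":
            return -self.channels["Fz"]
        return self.channels[component]


def _interp_monotone(xq: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp on a non-decreasing xp, averaging values at duplicated knots."""
    if np.all(np.diff(xp) > 0):
        return np.interp(xq, xp, fp)
    ux, inverse, counts = np.unique(xp, return_inverse=True, return_counts=True)
    sums = np.zeros(len(ux))
    np.add.at(sums, inverse, fp)
    return np.interp(xq, ux, sums / counts)


def apply_warp(path: WarpingPath, channel: np.ndarray) -> np.ndarray:
    """Resample ``channel`` along a warping path onto the template grid.

    The identity path returns the channel unchanged; warping a constant
    channel leaves it constant (time is deformed, amplitudes are not).
    """
    path.validate()
    channel = np.asarray(channel, float)
    if channel.shape != path.grid.shape:
        raise ValueError("channel must live on the path's grid")
    if path.is_identity:
        return channel.copy()
    return _interp_monotone(path.grid, path.mapped, channel)


#: template advance per layer: diagonal, 2-step skip, stand-still.  The
#: order encodes the tie-break preference (diagonal first).
_ADVANCES = (1, 2, 0)
#: allowed predecessor layers per layer: stand-still and skip steps may not
#: repeat (symmetric slope constraint: local warp slope stays in [1/2, 2]).
_ALLOWED_PRED = ((0, 1, 2), (0, 2), (0, 1))


def dp_align(x: np.ndarray, template: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal monotone alignment of cycle ``x`` to ``template``.

    Finds integer template indices j_0..j_{N-1} with j_0 = 0,
    j_{N-1} = N-1 and j_{i+1} - j_i in {0, 1, 2}, where neither a 0-step
    (template stands still) nor a 2-step (template skips) may immediately
    repeat — the symmetric slope constraint that keeps the local warp slope
    between 1/2 and 2 and prevents degenerate pinch alignments.  Minimizes
    ``sum_i (x[i] - template[j_i])**2``; ties prefer the diagonal step,
    then the template skip, then standing still, making the result
    reproducible.

    Returns (indices, cost).
    """
    x = np.asarray(x, float)
    y = np.asarray(template, float)
    n = len(x)
    if len(y) != n:
        raise ValueError("cycle and template must share the grid")
    if n == 1:
        return np.array([0]), float((x[0] - y[0]) ** 2)
    big = np.inf
    cost = (x[:, None] - y[None, :]) ** 2
    # acc[k, i, j]: best cost of reaching (i, j) with the step into i being
    # _ADVANCES[k]; pred[k, i, j]: layer of the chosen predecessor.
    acc = np.full((3, n, n), big)
    pred = np.full((3, n, n), -1, dtype=np.int8)
    acc[0, 0, 0] = cost[0, 0]  # virtual diagonal entry at the origin
    cols = np.arange(n)
    for i in range(1, n):
        prev = acc[:, i - 1, :]
        for k, adv in enumerate(_ADVANCES):
            cand = np.full((len(_ALLOWED_PRED[k]), n), big)
            for m, kp in enumerate(_ALLOWED_PRED[k]):
                if adv == 0:
                    cand[m] = prev[kp]
                else:
                    cand[m, adv:] = prev[kp, :-adv]
            choice = np.argmin(cand, axis=0)  # first on ties
            acc[k, i] = cand[choice, cols] + cost[i]
            pred[k, i] = np.asarray(_ALLOWED_PRED[k], dtype=np.int8)[choice]
    finals = acc[:, n - 1, n - 1]
    k = int(np.argmin(finals))
    if not np.isfinite(finals[k]):
        raise RuntimeError("no feasible alignment path")
    idx = np.empty(n, dtype=int)
    j = n - 1
    for i in range(n - 1, 0, -1):
        idx[i] = j
        kp = int(pred[k, i, j])
        j -= _ADVANCES[k]
        k = kp
    idx[0] = j
    if j != 0:
        raise RuntimeError("alignment backtrack did not reach the origin")
    return idx, float(finals[int(np.argmin(finals))])


def _warped_objective(
    curves: Sequence[np.ndarray], paths: Sequence[WarpingPath]
) -> tuple[np.ndarray, float]:
    warped = np.vstack([apply_warp(p, c) for p, c in zip(paths, curves)])
    template = warped.mean(axis=0)
    obj = float(np.sum((warped - template) ** 2))
    return template, obj


def fit_warps(
    fres_cycles: Sequence[np.ndarray],
    grid: Optional[np.ndarray] = None,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, list[WarpingPath], float]:
    """Register F_res cycles to their evolving mean template.

    Returns ``(template, paths, objective)`` where ``objective`` is the
    summed squared deviation of the warped curves from the template.  The
    objective never exceeds that of the unwarped pointwise mean (the
    starting point), and iterations stop once its relative decrease falls
    below ``tol`` or after ``max_iter`` rounds.
    """
    curves = [np.asarray(c, float) for c in fres_cycles]
    if not curves:
        raise ValueError("at least one cycle is required")
    n = len(curves[0])
    if any(len(c) != n for c in curves):
        raise ValueError("all cycles must share the grid")
    if grid is None:
        grid = np.linspace(0.0, 100.0, n)
    grid = np.asarray(grid, float)

    best_paths = [WarpingPath.identity(grid) for _ in curves]
    best_template, best_obj = _warped_objective(curves, best_paths)
    if len(curves) == 1:
        return curves[0].copy(), best_paths, 0.0

    # The alignment runs on amplitude-normalized curves: a purely scaled-up
    # cycle would otherwise minimize its squared difference by piling its
    # peak samples onto the template maximum (the classic DTW pinch),
    # distorting amplitudes.  Normalizing by each cycle's own peak makes the
    # DP compare shapes, so time is deformed and amplitudes are preserved;
    # the reported objective and template remain those of the raw curves.
    scales = [float(np.max(np.abs(c))) or 1.0 for c in curves]
    normed = [c / s for c, s in zip(curves, scales)]
    template_n = np.mean(np.vstack(normed), axis=0)

    for _ in range(max_iter):
        paths = []
        for c in normed:
            idx, _ = dp_align(c, template_n)
            paths.append(WarpingPath(grid=grid, mapped=grid[idx]))
        template_n = np.vstack(
            [apply_warp(p, c) for p, c in zip(paths, normed)]
        ).mean(axis=0)
        template, obj = _warped_objective(curves, paths)
        if obj >= best_obj:  # keep the monotone-objective guarantee
            break
        improved = (best_obj - obj) / best_obj if best_obj > 0 else 0.0
        best_paths, best_template, best_obj = paths, template, obj
        if improved < tol:
            break
    return best_template, best_paths, best_obj


def average_cycles(
    cycles: Sequence[NormalizedCycle],
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> AveragedPattern:
    """Warp-average a set of normalized cycles.

    Warping paths are fitted on F_res only and applied synchronously to all
    channels; the averaged cycle time T_c is the arithmetic mean of the
    cycle durations.
    """
    if not cycles:
        raise ValueError("at least one cycle is required")
    names = set(cycles[0].channels)
    for c in cycles[1:]:
        if set(c.channels) != names:
            raise ValueError(
                f"inconsistent channels in cycle {c.subject_id}/{c.cycle_index}: "
                f"{sorted(set(c.channels) ^ names)}"
            )
    grid = cycles[0].grid

    def _fres(c: NormalizedCycle) -> np.ndarray:
        if "Fres" in c.channels:
            return np.asarray(c.channels["Fres"], float)
        f = c.channels
        return np.sqrt(f["Fx"] ** 2 + f["Fy"] ** 2 + f["Fz"] ** 2)

    fres_curves = [_fres(c) for c in cycles]
    template, paths, obj = fit_warps(fres_curves, grid=grid, tol=tol, max_iter=max_iter)

    mean_channels: dict[str, np.ndarray] = {}
    for name in sorted(names):
        warped = np.vstack(
            [apply_warp(p, c.channels[name]) for p, c in zip(paths, cycles)]
        )
        mean_channels[name] = warped.mean(axis=0)
    mean_channels["Fres"] = np.vstack(
        [apply_warp(p, f) for p, f in zip(paths, fres_curves)]
    ).mean(axis=0)
    mean_channels["Fres_of_mean"] = np.sqrt(
        mean_channels["Fx"] ** 2 + mean_channels["Fy"] ** 2 + mean_channels["Fz"] ** 2
    )
    if {"Mx", "My", "Mz"} <= names:
        warped_m = np.vstack(
            [
                apply_warp(
                    p,
                    np.sqrt(
                        c.channels["Mx"] ** 2
                        + c.channels["My"] ** 2
                        + c.channels["Mz"] ** 2
                    ),
                )
                for p, c in zip(paths, cycles)
            ]
        )
        mean_channels["Mres"] = warped_m.mean(axis=0)

    return AveragedPattern(
        grid=grid,
        channels=mean_channels,
        cycle_time=float(np.mean([c.duration for c in cycles])),
        n_cycles=len(cycles),
        objective=obj,
        paths=paths,
    )


def average_patterns(
    patterns: Sequence[AveragedPattern],
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> AveragedPattern:
    """Warp-average already-averaged patterns (e.g. across subjects).

    Each pattern is treated as one pseudo-cycle whose duration is its T_c.
    """
    if not patterns:
        raise ValueError("at least one pattern is required")
    cycles = [
        NormalizedCycle(
            subject_id=f"pattern{i}",
            activity="",
            trial_index=0,
            cycle_index=i,
            grid=p.grid,
            channels={
                k: v
                for k, v in p.channels.items()
                if k not in ("Fres_of_mean",)
            },
            duration=p.cycle_time,
        )
        for i, p in enumerate(patterns)
    ]
    out = average_cycles(cycles, tol=tol, max_iter=max_iter)
    out.n_cycles = sum(p.n_cycles for p in patterns)
    return out
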