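"""Warping-path alignment, synchronized application, and cycle averaging."""

import numpy as np
import pytest

import kneeloads as kl
from kneeloads.segmentation import NormalizedCycle
from kneeloads.warp_average import (
    WarpingPath,
    apply_warp,
    average_cycles,
    dp_align,
    fit_warps,
)
from kneeloads.synthetic import warp_phase


def brute_force_align(x, y):
    """Exhaustive search over all feasible monotone step sequences.

    Independent of the DP: enumerates template advances in {0, 1, 2} with
    no immediate repetition of 0 or 2, endpoints pinned, and accumulates
    the squared-difference cost sample by sample.
    """
    n = len(x)
    best = [np.inf]

    def rec(i, j, last, cost):
        if cost >= best[0]:
            return
        if i == n - 1:
            if j == n - 1:
                best[0] = cost
            return
        remaining = n - 2 - i
        for d in (0, 1, 2):
            if d == last and d in (0, 2):
                continue
            jn = j + d
            if jn > n - 1 or jn + 2 * remaining < n - 1:
                continue
            rec(i + 1, jn, d, cost + (x[i + 1] - y[jn]) ** 2)

    rec(0, 0, 1, (x[0] - y[0]) ** 2)
    return best[0]


class TestWarpingPath:
    def test_endpoints_must_be_anchored(self, grid):
        with pytest.raises(ValueError, match="anchored"):
            WarpingPath(grid=grid, mapped=grid + 1.0)

    def test_must_be_monotone(self, grid):
        mapped = grid.copy()
        mapped[50], mapped[51] = mapped[51], mapped[50]
        with pytest.raises(ValueError, match="non-decreasing"):
            WarpingPath(grid=grid, mapped=mapped)

    def test_total_variation_is_hundred(self, grid):
        path = kl.random_warp(3, 0.4)
        assert np.sum(np.abs(np.diff(path.mapped))) == pytest.approx(100.0)


class TestApplyWarp:
    def test_identity_returns_channel_unchanged(self, grid):
        x = np.sin(grid / 10)
        out = apply_warp(WarpingPath.identity(grid), x)
        assert np.array_equal(out, x)

    def test_constant_channel_invariant_under_any_path(self, grid):
        path = kl.random_warp(9, 0.5)
        out = apply_warp(path, np.full(len(grid), 3.5))
        assert np.allclose(out, 3.5)

    def test_shift_warp_moves_pulse_apex(self, grid):
        # path sending input time 40 to template time 50: resampling along
        # it moves an apex at 40 to 50 on the template grid
        mapped = np.interp(grid, [0, 40, 100], [0, 50, 100])
        path = WarpingPath(grid=grid, mapped=mapped)
        pulse = np.maximum(0.0, 1 - np.abs(grid - 40) / 10)
        out = apply_warp(path, pulse)
        assert abs(grid[np.argmax(out)] - 50.0) <= 0.5
        assert out.max() == pytest.approx(1.0, abs=0.02)


class TestDPAlignment:
    @pytest.mark.parametrize("n,seed", [(9, 0), (11, 1), (13, 2), (15, 3)])
    def test_matches_exhaustive_search(self, n, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, n))
        idx, cost = dp_align(x, y)
        assert cost == pytest.approx(brute_force_align(x, y), rel=1e-10)

    def test_self_alignment_is_identity(self):
        x = np.sin(np.linspace(0, 3, 40))
        idx, cost = dp_align(x, x)
        assert cost == 0.0
        assert np.array_equal(idx, np.arange(40))

    def test_path_respects_step_constraints(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 60))
        idx, _ = dp_align(x, y)
        steps = np.diff(idx)
        assert set(steps) <= {0, 1, 2}
        for a, b in zip(steps[:-1], steps[1:]):
            assert not (a == b and a in (0, 2))


class TestFitWarps:
    def test_identical_cycles_identity_paths_zero_objective(self, grid):
        x = 100 * np.exp(-0.5 * ((grid - 40) / 10) ** 2) + 20
        template, paths, obj = fit_warps([x, x.copy(), x.copy()])
        assert obj == pytest.approx(0.0, abs=1e-18)
        assert all(p.is_identity for p in paths)
        assert np.allclose(template, x)

    def test_single_cycle_returns_identity(self, grid):
        x = np.cos(grid / 15)
        template, paths, obj = fit_warps([x])
        assert obj == 0.0 and paths[0].is_identity

    def test_recovers_known_time_distortion(self, grid):
        base = 100 * np.exp(-0.5 * ((grid - 30) / 10) ** 2) + 20
        c1 = base + 60 * np.exp(-0.5 * ((grid - 60) / 6) ** 2)
        warp = kl.random_warp(5, 0.25)
        c2 = np.interp(warp_phase(warp, grid), grid, c1)
        _, paths, _ = fit_warps([c1, c2])
        w1, w2 = apply_warp(paths[0], c1), apply_warp(paths[1], c2)
        # aligned curves agree; the relative warp is recovered within 2 grid
        # steps wherever the signal carries timing information (a warp is
        # unidentifiable on the flat tail of the cycle)
        assert np.max(np.abs(w1 - w2)) < 0.02 * c1.max()
        relative = np.interp(paths[1].mapped, paths[0].mapped, grid)
        slope = np.abs(np.gradient(c1, grid))
        informative = slope > 0.05 * slope.max()
        err = np.abs(relative - warp_phase(warp, grid))[informative]
        assert np.max(err) <= 1.0  # 2 steps of the 0.5 % grid

    def test_objective_never_worse_than_unwarped_mean(self, small_population):
        trials, _ = small_population
        cycles = [
            kl.normalize_cycle(c)
            for c in kl.segment_walking(trials[0])
        ]
        curves = [
            np.sqrt(c.channels["Fx"] ** 2 + c.channels["Fy"] ** 2
                    + c.channels["Fz"] ** 2)
            for c in cycles
        ]
        stack = np.vstack(curves)
        unwarped = float(np.sum((stack - stack.mean(0)) ** 2))
        _, paths, obj = fit_warps(curves)
        assert obj <= unwarped
        for p in paths:
            p.validate()

    def test_warping_preserves_extrema_amplitudes(self, small_population):
        trials, _ = small_population
        cycles = [kl.normalize_cycle(c) for c in kl.segment_walking(trials[0])]
        curves = [
            np.sqrt(c.channels["Fx"] ** 2 + c.channels["Fy"] ** 2
                    + c.channels["Fz"] ** 2)
            for c in cycles
        ]
        _, paths, _ = fit_warps(curves)
        for c, p in zip(curves, paths):
            w = apply_warp(p, c)
            span = np.ptp(c)
            assert abs(w.max() - c.max()) <= 0.01 * span
            assert abs(w.min() - c.min()) <= 0.01 * span

    def test_unshared_bump_survives_at_half_height(self, grid):
        base = 100 * np.exp(-0.5 * ((grid - 25) / 8) ** 2) + 20
        bump = 40 * np.exp(-0.5 * ((grid - 70) / 4) ** 2)
        template, _, _ = fit_warps([base, base + bump])
        height = (template - base)[(grid > 55) & (grid < 90)].max()
        assert height == pytest.approx(20.0, rel=0.10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_warps([])


def _make_cycles(channel_stacks, durations):
    grid = np.linspace(0, 100, channel_stacks[0]["Fz"].shape[0])
    return [
        NormalizedCycle(
            subject_id="S", activity="walking", trial_index=0, cycle_index=i,
            grid=grid, channels=ch, duration=d,
        )
        for i, (ch, d) in enumerate(zip(channel_stacks, durations))
    ]


class TestAverageCycles:
    def test_identical_cycles_reproduce_input(self, walking_template, grid):
        ch = {c: walking_template.eval(c, grid)
              for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
        cycles = _make_cycles([ch, dict(ch), dict(ch)], [1.0, 1.0, 1.0])
        pattern = average_cycles(cycles)
        assert np.allclose(pattern.channels["Fz"], ch["Fz"])
        assert pattern.cycle_time == pytest.approx(1.0)
        assert pattern.n_cycles == 3

    def test_cycle_time_is_mean_duration(self, grid):
        ch = {c: np.abs(np.sin(grid / 20)) * 100 if c == "Fz" else np.zeros(len(grid))
              for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
        # durations chosen to average exactly the walking cycle time 1.07 s
        cycles = _make_cycles([dict(ch) for _ in range(4)],
                              [1.00, 1.14, 1.04, 1.10])
        pattern = average_cycles(cycles)
        assert pattern.cycle_time == pytest.approx(1.07)

    def test_template_recovered_within_3pct_rms(self, walking_template):
        config = kl.PopulationConfig(
            n_subjects=1, cycles_per_subject=20, seed=99, subject_scales=[1.0],
        )
        trials, truth = kl.sample_population(config)
        cycles = [kl.normalize_cycle(c) for c in kl.segment_walking(trials[0])]
        pattern = average_cycles(cycles)
        # segmented cycles start at the foot-contact threshold crossing, a
        # known phase offset p0 into the template
        dense = np.linspace(0, 100, 10001)
        p0 = dense[np.argmax(walking_template.eval("Fres", dense) >= 20.0)]
        expected = walking_template.eval("Fres", (p0 + pattern.grid) % 100.0)
        rms = np.sqrt(np.mean((pattern.channels["Fres"] - expected) ** 2))
        assert rms <= 0.03 * expected.max()

    def test_inconsistent_channels_rejected(self, grid):
        ch = {c: np.zeros(len(grid)) for c in
              ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
        ch["Fz"] = -np.abs(np.sin(grid / 20)) * 100
        ch2 = dict(ch)
        ch2["flexion"] = np.zeros(len(grid))
        cycles = _make_cycles([ch, ch2], [1.0, 1.0])
        with pytest.raises(ValueError, match="inconsistent"):
            average_cycles(cycles)

    def test_fres_is_mean_of_warped_not_resultant_of_mean(self, grid):
        n = len(grid)
        a = {c: np.zeros(n) for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
        b = {c: np.zeros(n) for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
        bell = 100 * np.exp(-0.5 * ((grid - 50) / 10) ** 2) + 10
        a["Fx"], b["Fx"] = bell.copy(), -bell.copy()
        pattern = average_cycles(_make_cycles([a, b], [1.0, 1.0]))
        # components cancel, but the mean of warped resultants does not
        assert np.allclose(pattern.channels["Fres_of_mean"], 0.0, atol=1e-9)
        assert pattern.channels["Fres"].max() > 50
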