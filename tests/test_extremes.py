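"""Reference-peak location, per-trial matching, and the EXTREME100 table."""

import numpy as np
import pytest

import kneeloads as kl
from kneeloads.extremes import (
    locate_reference_peaks,
    match_peak_in_trial,
    extreme_table,
    standard_specs,
    MATCHED,
    SIGN_CONFLICT,
    ABSENT,
    PeakSpec,
)
from kneeloads.segmentation import NormalizedCycle
from kneeloads.warp_average import AveragedPattern


def _pattern(channels, grid):
    n = len(grid)
    full = {c: np.zeros(n) for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
    full.update({k: np.asarray(v, float) for k, v in channels.items()})
    if "Fres" not in full:
        full["Fres"] = np.sqrt(full["Fx"]**2 + full["Fy"]**2 + full["Fz"]**2)
    return AveragedPattern(grid=grid, channels=full, cycle_time=1.07,
                           n_cycles=1, objective=0.0)


def _cycle(channels, grid, subject="S01", cycle_index=0):
    n = len(grid)
    full = {c: np.zeros(n) for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
    full.update({k: np.asarray(v, float) for k, v in channels.items()})
    return NormalizedCycle(
        subject_id=subject, activity="walking", trial_index=0,
        cycle_index=cycle_index, grid=grid, channels=full, duration=1.07,
    )


def _spec(component="Fy", kind="max", time=30.0, value=20.0):
    return PeakSpec(
        activity="walking", component=component, peak_index=1, kind=kind,
        reference_time=time, reference_value=value,
        reference_sign=1 if value >= 0 else -1,
    )


class TestLocate:
    def test_walking_fres_has_two_planted_maxima(self, walking_template, grid):
        pattern = _pattern(
            {"Fres": walking_template.eval("Fres", grid)}, grid
        )
        specs = locate_reference_peaks(pattern, "Fres", max_peaks=3)
        maxima = [s for s in specs if s.kind == "max"]
        assert len(maxima) == 2
        planted = sorted(t for t, _ in walking_template.fres_peaks)
        for spec, t in zip(maxima, planted):
            assert abs(spec.reference_time - t) <= 1.0

    def test_monotone_ramp_has_no_interior_extrema(self, grid):
        pattern = _pattern({"Fy": np.linspace(-40, 40, len(grid))}, grid)
        assert locate_reference_peaks(pattern, "Fy") == []

    def test_flat_channel_gives_empty_list(self, grid):
        pattern = _pattern({"Mx": np.zeros(len(grid))}, grid)
        assert locate_reference_peaks(pattern, "Mx") == []

    def test_sinusoid_quarter_points(self, grid):
        pattern = _pattern({"Fy": 50 * np.sin(2 * np.pi * grid / 100)}, grid)
        specs = locate_reference_peaks(pattern, "Fy", max_peaks=3)
        kinds = {s.kind: s.reference_time for s in specs}
        assert kinds.keys() == {"max", "min"}
        assert abs(kinds["max"] - 25.0) <= 0.5
        assert abs(kinds["min"] - 75.0) <= 0.5

    def test_numbering_follows_time_order(self, walking_template, grid):
        pattern = _pattern({"Fres": walking_template.eval("Fres", grid)}, grid)
        specs = locate_reference_peaks(pattern, "Fres")
        times = [s.reference_time for s in specs]
        assert times == sorted(times)
        assert [s.peak_index for s in specs] == list(range(1, len(specs) + 1))


class TestMatch:
    def _bump(self, grid, height=20.0, at=30.0, width=4.0):
        return height * np.exp(-0.5 * ((grid - at) / width) ** 2)

    def test_trial_equal_to_average_returns_peak_value(self, grid):
        trial = _cycle({"Fy": self._bump(grid)}, grid)
        outcome, value = match_peak_in_trial(trial, _spec())
        assert outcome == MATCHED
        assert value == pytest.approx(20.0, rel=1e-6)

    def test_negated_component_is_sign_conflict(self, grid):
        trial = _cycle({"Fy": -self._bump(grid)}, grid)
        outcome, value = match_peak_in_trial(
            trial, _spec(kind="min", value=20.0)
        )
        # a minimum exists at the right time but with negative value while
        # the reference sign is positive
        assert outcome in (SIGN_CONFLICT, ABSENT)
        trial2 = _cycle({"Fy": -self._bump(grid)}, grid)
        out2, val2 = match_peak_in_trial(trial2, _spec(kind="max", value=20.0))
        assert out2 == ABSENT  # no maximum in the window at all

    def test_opposite_sign_extremum_of_same_kind(self, grid):
        # a maximum that pokes up to -5 from a deep valley: right kind,
        # wrong sign
        fy = -30 + 25 * np.exp(-0.5 * ((grid - 30) / 4) ** 2)
        trial = _cycle({"Fy": fy}, grid)
        outcome, value = match_peak_in_trial(trial, _spec())
        assert outcome == SIGN_CONFLICT
        assert value == pytest.approx(-5.0, abs=0.1)

    def test_jittered_peak_found_within_window(self, grid):
        rng = np.random.default_rng(8)
        for _ in range(5):
            shift = rng.uniform(-10, 10)
            v = rng.uniform(10, 40)
            trial = _cycle({"Fy": self._bump(grid, v, 30 + shift)}, grid)
            outcome, value = match_peak_in_trial(trial, _spec(), window=15.0)
            assert outcome == MATCHED
            assert value == pytest.approx(v, rel=0.01)

    def test_peak_outside_window_is_absent(self, grid):
        trial = _cycle({"Fy": self._bump(grid, at=70.0)}, grid)
        outcome, _ = match_peak_in_trial(trial, _spec(), window=15.0)
        assert outcome == ABSENT

    def test_shoulder_counts_as_absent(self, grid):
        trial = _cycle({"Fy": np.linspace(0, 40, len(grid))}, grid)
        outcome, _ = match_peak_in_trial(trial, _spec())
        assert outcome == ABSENT


class TestExtremeTable:
    def _bump(self, grid, height=20.0, at=30.0):
        return height * np.exp(-0.5 * ((grid - at) / 4.0) ** 2)

    def test_single_trial_equals_average_peaks_scaled(self, grid):
        fres = self._bump(grid, 250.0, 45.0)
        trial = _cycle({"Fz": -fres}, grid)
        spec = _spec(component="Fres", time=45.0, value=250.0)
        table = extreme_table([trial], [spec], bw_high=100.0)
        assert len(table.records) == 1
        assert table.records[0].value == pytest.approx(250.0 * 9.81, rel=1e-6)

    def test_planted_outlier_subject_is_reported(self, grid):
        trials = [
            _cycle({"Fy": self._bump(grid, 20.0)}, grid, subject=f"S{i}")
            for i in range(7)
        ] + [_cycle({"Fy": self._bump(grid, 100.0)}, grid, subject="S99")]
        table = extreme_table(trials, [_spec()], bw_high=100.0)
        rec = table.records[0]
        assert rec.source[0] == "S99"
        # an individual peak five times the average is faithfully reported
        assert rec.value == pytest.approx(100.0 * 9.81, rel=1e-6)

    def test_opposite_sign_trials_are_excluded(self, grid):
        pos = [_cycle({"Fy": self._bump(grid, 20 + i)}, grid, subject=f"P{i}")
               for i in range(4)]
        neg = [_cycle({"Fy": -30 + self._bump(grid, 25.0)}, grid,
                      subject=f"N{i}") for i in range(4)]
        table = extreme_table(pos + neg, [_spec()])
        rec = table.records[0]
        assert rec.n_matched == 4
        assert rec.n_excluded_sign == 4
        assert rec.value == pytest.approx(23.0 * 9.81, rel=1e-6)
        # brute-force filter oracle: max over the positive half only
        assert rec.value == pytest.approx(
            max(20 + i for i in range(4)) * 9.81, rel=1e-6
        )

    def test_counts_partition_all_trials(self, small_run):
        result, _ = small_run
        n_trials = result.loadset.n_cycles
        for rec in result.extremes.records:
            assert (rec.n_matched + rec.n_excluded_sign
                    + rec.n_excluded_absent) == n_trials

    def test_order_invariance(self, grid):
        trials = [
            _cycle({"Fy": self._bump(grid, h)}, grid, subject=f"S{h}")
            for h in (10.0, 35.0, 22.0)
        ]
        t1 = extreme_table(trials, [_spec()])
        t2 = extreme_table(trials[::-1], [_spec()])
        assert t1.records[0].value == t2.records[0].value
        assert t1.records[0].source == t2.records[0].source

    def test_extreme_bounds_average_when_average_included(self,
                                                          small_population):
        trials, _ = small_population
        cycles = [
            kl.normalize_cycle(c)
            for t in trials
            for c in kl.segment_walking(t)
        ]
        pattern = kl.average_cycles(cycles)
        specs = standard_specs(pattern, activity="walking")
        avg_as_trial = _cycle(
            {k: v for k, v in pattern.channels.items()
             if k in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")},
            pattern.grid, subject="AVG",
        )
        table = extreme_table(cycles + [avg_as_trial], specs)
        for rec in table.records:
            avg_scaled = rec.spec.reference_value * 9.81
            if rec.spec.kind == "max":
                assert rec.value >= avg_scaled - 1e-6
            else:
                assert rec.value <= avg_scaled + 1e-6

    def test_all_excluded_spec_is_omitted(self, grid):
        trials = [_cycle({"Fy": np.zeros(len(grid))}, grid)]
        table = extreme_table(trials, [_spec()])
        assert table.records == []
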