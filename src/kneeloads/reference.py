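"""Reference values from the in vivo instrumented-knee-implant study.

Eight subjects with telemetric tibial components performed eight activities;
the published study condensed those recordings into standardized load levels
(AVER75, HIGH100, PEAK100, EXTREME100).  The tables below carry the cohort
metadata, the per-activity cycle counts / cycle times / conversion factors,
the headline resultant-force peaks, and the extreme single-component values.
They serve two purposes here: the synthetic generator takes its study
conditions (cycle times, cycle counts, load magnitudes) from them, and the
consistency checks in the test suite recompute their internal arithmetic.
"""

from __future__ import annotations

import pandas as pd

#: Cohort of the eight instrumented-implant subjects.  Tibio-femoral angle is
#: signed (varus positive, valgus negative); postop_date1/2 are months after
#: surgery of the two measurement sessions.
SUBJECTS = pd.DataFrame(
    [
        # id,  sex, age, mass, height, side,  tf_angle, slope, d1, d2
        ("K1L", "m", 64, 105, 177, "left", 3.0, 5, 20, 27),
        ("K2L", "m", 74, 92, 171, "left", 5.0, 11, 46, 23),
        ("K3R", "m", 71, 98, 175, "right", 3.5, 10, 8, 16),
        ("K5R", "m", 62, 96, 175, "right", 1.0, 7, 30, 11),
        ("K6L", "f", 67, 83, 174, "left", -4.0, 7, 30, 12),
        ("K7L", "f", 76, 69, 166, "left", 6.5, 7, 21, 12),
        ("K8L", "m", 72, 79, 174, "left", 4.0, 11, 25, 13),
        ("K9L", "m", 76, 109, 166, "left", 7.0, 6, 15, 12),
    ],
    columns=[
        "subject_id",
        "sex",
        "age_years",
        "body_mass_kg",
        "height_cm",
        "side",
        "tibiofemoral_angle_deg",
        "posterior_slope_deg",
        "postop_date1_months",
        "postop_date2_months",
    ],
)

#: Per-activity cycle counts (min-max per subject and session), average cycle
#: time T_c (seconds, session 2) and conversion factors C_aver (HIGH100 ->
#: AVER75) and C_peak (HIGH100 -> PEAK100).
ACTIVITIES = pd.DataFrame(
    [
        ("walking", 12, 21, 18, 64, 1.07, 0.58, 1.06),
        ("ascending_stairs", 4, 7, 8, 17, 1.78, 0.53, 1.08),
        ("descending_stairs", 4, 9, 8, 17, 1.67, 0.60, 1.05),
        ("knee_bend", 3, 7, 4, 7, 7.61, 0.57, 1.04),
        ("standing_up", 4, 6, 4, 9, 2.68, 0.54, 1.02),
        ("sitting_down", 4, 6, 4, 8, 3.56, 0.54, 1.09),
        ("one_legged_stance", 3, 6, 4, 9, 8.45, 0.58, 1.04),
        ("jogging", 0, 0, 13, 20, 0.68, 0.57, 1.07),
    ],
    columns=[
        "activity",
        "cycles_d1_min",
        "cycles_d1_max",
        "cycles_d2_min",
        "cycles_d2_max",
        "cycle_time_s",
        "c_aver",
        "c_peak",
    ],
).set_index("activity")

#: Headline HIGH100 resultant-force peaks in newtons.
HIGH100_PEAKS_N = {
    "walking_peak1": 2848.0,  # contralateral toe off
    "walking_peak2": 3372.0,  # contralateral heel strike
    "ascending_stairs": 4218.0,
    "standing_up": 3792.0,
    "sitting_down": 3697.0,
    "knee_bend": 3407.0,
    "jogging": 5165.0,
}

#: AVER75 resultant-force peaks expressed in %BW.
AVER75_PEAKS_PCTBW = {
    "walking_peak1": 226.0,
    "walking_peak2": 267.0,
    "ascending_stairs_peak1": 311.0,
    "ascending_stairs_peak2": 305.0,
    "standing_up": 280.0,
}

#: EXTREME100 values: most extreme single-component peaks over all subjects
#: and trials, scaled to a 100 kg body weight.  Forces in N, moments in Nm;
#: peak numbering follows the time order of the marked extrema on the average
#: patterns.  None = no such numbered peak for that activity.
EXTREME100 = pd.DataFrame(
    [
        ("Fres", 1, 3110, 4209, 4787, 3676, 3870, 4036, 3608, 5551),
        ("Fres", 2, 3581, 4572, 4348, None, None, None, None, None),
        ("Fx", 1, -294, 307, -416, 222, 257, 301, 318, -423),
        ("Fx", 2, 292, -283, 308, None, None, None, None, 697),
        ("Fx", 3, -209, None, None, None, None, None, None, None),
        ("Fy", 1, -605, 220, -565, -557, -266, 392, 324, -1148),
        ("Fy", 2, 221, -679, 368, None, None, None, None, None),
        ("Fy", 3, None, -438, None, None, None, None, None, None),
        ("-Fz", 1, 3100, 4169, 4776, 3667, 3867, 4033, 3605, 5396),
        ("-Fz", 2, 3571, 4552, 4347, None, None, None, None, None),
        ("Mx", 1, 25.9, 30.5, 59.1, 38.7, 21.4, 28.6, 46.1, 39.8),
        ("Mx", 2, 32.2, 36.0, None, None, None, None, None, None),
        ("My", 1, -50.2, -48.8, -68.8, -57.3, 25.1, 22.8, 23.3, -57.1),
        ("My", 2, -53.2, -55.1, None, None, None, None, None, None),
        ("My", 3, 27.3, 37.2, None, None, None, None, None, None),
        ("Mz", 1, 12.0, 10.5, -18.5, -13.3, -11.4, -10.8, -13.9, -13.7),
        ("Mz", 2, -18.9, -13.9, None, None, None, None, None, None),
    ],
    columns=[
        "component",
        "peak_index",
        "walking",
        "ascending_stairs",
        "descending_stairs",
        "one_legged_stance",
        "standing_up",
        "sitting_down",
        "knee_bend",
        "jogging",
    ],
)

#: Defined body-weight levels of the standardization (kg).
BW_AVERAGE = 75.0
BW_HIGH = 100.0
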