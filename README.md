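# kneeloads

Standardized load profiles for knee implants from six-component contact
load recordings.

## The problem

Testing wear, fatigue, or fixation strength of a knee replacement — or
feeding a musculoskeletal or finite-element model — requires knowing the
forces and moments that actually act across the tibio-femoral joint during
daily activities. Instrumented tibial components measure all six load
components in vivo (three forces in percent body weight, %BW; three moments
in %BW·m), but raw multi-subject, multi-trial telemetry is not directly
usable as a test input: cycles differ in duration and timing, subjects
differ several-fold in load magnitude, and some components even flip sign
between subjects. This package condenses such recordings into standardized,
reproducible load-time profiles, for biomechanics researchers and implant
test engineers.

## Method

For each activity the pipeline:

1. **Segments** continuous recordings into loading cycles — foot contact to
   foot contact for walking and jogging (threshold crossing of the resultant
   force F_res = √(Fx² + Fy² + Fz²)), swing-phase force minima for stair
   climbing, baseline departure for non-cyclic exercises — and resamples
   each cycle onto a 0–100 % cycle grid.
2. **Averages by time warping.** Each cycle's time axis is deformed by a
   monotone, endpoint-anchored *warping path* chosen by a constrained
   dynamic program so that the squared differences of F_res between the
   deformed cycles, summed over the cycle, are minimal. The path fitted on
   F_res is applied unchanged to all six components (and the flexion angle),
   preserving their synchronization; the arithmetic mean of the deformed
   curves is the average pattern. Warping deforms time, not amplitude, so a
   relative maximum present in only half of the cycles survives at about
   half its height instead of being smeared away.
3. **Standardizes** the averages into three levels via the F_res peak
   registry P1–P3 (inter-individual average peak, highest intra-individual
   average peak, highest single-trial peak):
   - `AVER75` — the population average scaled to a 75 kg body weight
     (×9.81·75/100 = 7.36 N per %BW),
   - `HIGH100 = AVER75 × (100/75) × F_H` with `F_H = P2/P1` — the strongest
     subject at 100 kg,
   - `PEAK100 = HIGH100 × C_peak` with `C_peak = F_P/F_H`, `F_P = P3/P1` —
     the highest trial ever recorded, at 100 kg.
   The inverse factor `C_aver = 1/((100/75)·F_H)` recovers AVER75 from
   HIGH100. All factors derive from F_res and apply identically to every
   component.
4. **Extracts extremes** (`EXTREME100`): numbered relative extrema of each
   component are located on the average pattern and re-identified in every
   individual trial within a time window; trials where the peak carries the
   opposite sign or does not exist are excluded, and the most extreme
   matched value is reported at 100 kg.
5. **Compares** the standardized −Fz, Fy, Mz channels peak-by-peak against a
   user-supplied wear-simulator reference waveform (ISO 14243 style; the
   waveform itself is licensed content and must be provided as a file).

Because in vivo telemetry is not redistributable, the package ships a
first-class synthetic generator (`kneeloads.synthetic`) producing
multi-subject cohorts with known ground truth — activity templates,
log-normal subject scales, random monotone time distortions, component
noise, sign flips — against which every stage is tested.

## Worked example

Generate a small synthetic walking cohort and run the pipeline:

```
$ kneeloads simulate --subjects 4 --cycles 10 --seed 11 --out demo/trials
4 trial files in demo/trials; planted F_H = 1.15

$ kneeloads standardize demo/trials --out demo/report
activity  n_cycles  T_c_s   C_aver   C_peak      F_H      F_P
 walking        40  1.063 0.662932 1.131919 1.131338 1.280582
P1=287.358 %BW  F_H=1.13134  F_P=1.28058  C_aver=0.662932  C_peak=1.13192
report written to demo/report
```

Reading the output: 40 cycles were segmented (10 per subject) with an
average cycle time T_c of 1.063 s. The strongest subject's average F_res
peak exceeded the population average peak P1 = 287 %BW by the factor
F_H = 1.13, so the HIGH100 profile is (100/75)·1.13 ≈ 1.51 times the
AVER75 profile (equivalently, AVER75 = HIGH100 × C_aver with
C_aver = 0.66). The highest single cycle exceeded P1 by F_P = 1.28, giving
PEAK100 = HIGH100 × 1.13. The report directory holds the three standardized
patterns in N/N·m on the 0–100 % grid, the factor table, and the EXTREME100
component table with per-peak exclusion counts.

Python API equivalent:

```python
import kneeloads as kl

trials, truth = kl.sample_population(
    kl.PopulationConfig(n_subjects=4, cycles_per_subject=10, seed=11))
result = kl.run_standardization(kl.RunConfig(), trials=trials)
print(result.loadset.factors)       # F_H, F_P, C_aver, C_peak
print(result.extremes.to_dataframe())
```

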