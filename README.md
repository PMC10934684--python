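# gaitwave

Gait-phase-locked EEG amplitude analysis for mobile walking studies.

When people walk, cortical activity is modulated within each stride.
`gaitwave` implements the full analysis chain needed to measure that
modulation from a 32-electrode mobile EEG recording synchronized with a
thigh-worn IMU, and to compare it between walking groups and cueing
conditions:

1. **Band-specific filtering** — a 4th-order Butterworth band-pass
   (0.5–100 Hz for the delta chain) plus a 50 Hz notch before artifact
   removal, and a band-defining low-pass (4 Hz for delta) afterwards,
   applied forward–backward so gait-phase alignment is untouched.
2. **fastICA artifact removal** — the staged fixed-point procedure
   (centering → covariance eigendecomposition → PCA retention →
   whitening → symmetric tanh iteration), estimating five independent
   components and removing those whose topography and spectrum match
   ocular, glossokinetic or muscular activity.
3. **IMU gait segmentation** — initial contact at each maximum of the
   right-thigh flexion angle; each gait cycle is the interval between
   successive contacts, split into stance and swing at the angle
   minimum.
4. **Cycle matrices** — every cycle of cleaned EEG is
   amplitude-normalized to its local (per-electrode, per-cycle) peak,
   time-normalized to 100 points spanning 0–100 % of the gait cycle,
   and ensemble-averaged into one 30 × 100 matrix per subject and
   condition, then into mean/SD maps per group × condition cell.
5. **SnPM inference** — at each of the 100 gait-phase points a two-way
   mixed ANOVA (between-subject factor: overground **O** vs treadmill
   **T**; within-subject factor: self-selected **sSC** vs auditory-cued
   **SC** walking) yields F curves; the critical threshold **F\*** is
   the (1 − α) quantile of the permutation distribution of the maximum
   F over the curve, suprathreshold clusters get extent-based
   permutation p-values, and significant interactions trigger
   Bonferroni-corrected post hoc max-|t| comparisons between cells.

A first-class **synthetic-data module** generates complete EEG + IMU
walking cohorts — gait-locked delta-band sources, blink/eye-drift/
glossokinetic/EMG artifacts with their scalp topographies, 1/f
background noise, and injectable group × condition effects confined to
a chosen gait-phase window — so the whole chain is testable without any
recordings.

## Worked example

Simulate a 12-per-group cohort with an interaction effect injected at
electrode Fz over 3–8 % of the gait cycle, run the pipeline on that
electrode, and print the findings:

```python
import numpy as np
from gaitwave import (EffectSpec, PipelineConfig, generate_cohort,
                      process_recording, run_snpm)
from gaitwave.signal_io import DEFAULT_MONTAGE
from gaitwave.snpm_stats import build_designs

effect = EffectSpec(electrodes=("Fz",), phase_window=(3.0, 8.0),
                    amplitude_delta=8.0, factor="interaction",
                    affected_cells=frozenset({"TsSC"}))
cfg = PipelineConfig(n_per_group=12, duration=60.0, effect=effect, seed=7)
cohort = generate_cohort(cfg.n_per_group, effect, seed=cfg.seed,
                         duration=cfg.duration)
seqs = np.random.SeedSequence(cfg.seed).spawn(len(cohort.recordings))
mats = [process_recording(r, cfg,
                          ica_seed=int(q.generate_state(1)[0] % 2**31))["matrix"]
        for r, q in zip(cohort.recordings, seqs)]
design = build_designs(mats, DEFAULT_MONTAGE.active_labels)["Fz"]
res = run_snpm(design, n_perm=500, alpha=0.05, seed=11)
print("interaction p =", res.p_omnibus["interaction"],
      " F* =", round(res.F_star["interaction"], 2))
for c in res.clusters_for("interaction"):
    print(f"cluster {c.start_pct:.1f}-{c.end_pct:.1f}% of gait cycle, "
          f"p = {c.p_cluster}")
```

Output:

```
interaction p = 0.001996007984031936  F* = 11.43
cluster 1.5-10.0% of gait cycle, p = 0.001996007984031936
```

The omnibus interaction is significant (p ≈ 0.002 with 500
permutations) and the recovered cluster, 1.5–10.0 % of the gait cycle,
brackets the injected 3–8 % window — the pipeline detects *where in the
stride* the two groups diverge under self-selected walking.

The same analyses are available from the shell:

```bash
gaitwave steps                           # stride-count table summary
gaitwave simulate --n-per-group 12 --seed 1 --out-dir cohort/
gaitwave segment --imu cohort/O01_sSC_imu.csv --eeg-rate 512
gaitwave run-all --n-per-group 4 --duration 30 --seed 1 --out report.json
```

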