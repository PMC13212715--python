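# steadytorque

Analysis pipeline for fixed-end (isometric-joint) dorsiflexion tracking
contractions in which participants ramp torque up to a test plateau
(Hold 1), reduce it at a prescribed rate or by a prescribed amount, and
hold a matched lower plateau (Hold 2). The package covers the complete
offline analysis — signal conditioning, designed-trace generation, trial
validity gating, hold-phase torque/EMG/fascicle metrics, torque
steadiness, and repeated-measures statistics — plus a mechanistic
muscle-tendon-unit simulator that generates realistic multi-subject
datasets for testing every stage without access to human data.

## Modules

| module | contents |
| --- | --- |
| `steadytorque.signal_processing` | dual-pass Butterworth filters with corrected cut-offs (−3 dB lands on the desired frequency after both passes), active torque, EMG linear envelope (band-pass 20–400 Hz → mean-bias removal → rectification → 10 Hz smoothing), MVC normalization |
| `steadytorque.protocol` | desired-trace library for both experiments (5 + 6 conditions), contraction-onset detection, torque matching error, validity rules (10 % MVT matching limit; 0.8 / 2 Nm dip thresholds = pilot mean + 2 SD) |
| `steadytorque.kinematics` | Hold-1/Hold-2 means, fascicle shortening/lengthening amplitudes and maximum lengthening speed, torque-steadiness CV, condition averaging over valid trials |
| `steadytorque.stats` | repeated-measures correlation (ANCOVA; df = N − subjects − 1), one-/two-way within-subject ANOVA with Mauchly's test and Greenhouse–Geisser correction, Holm–Sidak step-down comparisons (pooled or per-pair variance), paired-design power via the noncentral t |
| `steadytorque.synthetic_data` | Hill-type contractile element + series-elastic element at fixed MTU length; a torque reduction causes tendon recoil and fascicle lengthening; PI tracking controller, signal-dependent torque noise, EMG interference synthesis, tracking drift, multi-subject dataset generator |
| `steadytorque.io_cli` | CSV + JSON-sidecar trial format, run configuration (YAML), the end-to-end pipeline with exclusion logging, and the `steadytorque` CLI |

## Command line

```bash
steadytorque protocol render --experiment 2 --condition 85-15   # desired trace as CSV
steadytorque simulate --experiment 1 --subjects 4 --seed 1 --out data/
steadytorque process  --data data/ --out results/
steadytorque stats rmcorr --input long.tsv --x torque --y emg
steadytorque stats anova  --input long.tsv --dv cv --within cond
steadytorque stats power  --dz 1 --target 0.9
```

`process` writes `trial_metrics.tsv` (one row per trial),
`condition_summary.tsv` (valid-trial means per subject × condition),
`exclusions.tsv` (machine-readable reason per excluded trial or cell),
and `provenance.json` (config hash + version; identical inputs give
byte-identical tables).

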