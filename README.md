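# reachcomp

Movement-component analysis of seated reaching trials recorded with a
simplified ten-marker motion-capture set (chin, C7, and bilateral acromion,
humeral epicondyle, index-finger MP joint, greater trochanter).

Two tasks are supported:

* **forward reach** — the MP joint's anterior (Y) transport is split into
  *shoulder/elbow*, *trunk rotation* and *trunk flexion* components;
* **hand-to-mouth reach** — the vertical (Z) hand–mouth gap closed is split
  into *shoulder/elbow flexion*, *shoulder abduction*, *girdle elevation*
  and *cervical flexion* components.

Every component is a telescoping start-to-end marker displacement
calibrated against the reaching-side greater trochanter, so components sum
to the total by construction and whole-body translation cancels exactly.
Percent contributions use the trial's own measured total by default
(`measured_total`), or a nominal limb-length-derived distance
(`arm_length`).

The package also ships:

* a seated **kinematic-chain simulator** (trunk–girdle–arm–head, seven
  degrees of freedom, minimum-jerk profiles, Gaussian marker noise at
  optical-device error magnitudes) plus an analytic decomposition oracle,
  so the whole pipeline is testable without recorded data;
* **cohort statistics** (pooled-variance Student *t* test by default, Welch
  and Holm options) and a stacked-contribution figure;
* readers/writers for a plain-text trial-table dialect and a minimal C3D
  ingest path;
* a `reachcomp` CLI.

## CLI walkthrough

```sh
# synthetic cohorts (trial tables + manifest.tsv per output directory)
reachcomp simulate --preset healthy --n 20 --seed 2 --out sim/healthy
reachcomp simulate --preset stroke  --n 10 --seed 1 --out sim/stroke

# decompose trials into a flat cohort table
cat sim/healthy/manifest.tsv <(tail -n +2 sim/stroke/manifest.tsv) > sim/manifest.tsv
reachcomp decompose sim/healthy/*.tsv sim/stroke/*.tsv \
    --manifest sim/manifest.tsv --out sim/table.tsv

# per-component group comparison and figure
reachcomp compare sim/table.tsv --task forward_reach --alpha 0.05
reachcomp plot sim/table.tsv --task forward_reach --out sim/forward.svg
```

`reachcomp --config analysis.yaml …` overrides thresholds (filter cutoff,
window threshold fraction, speed floor, gap-interpolation limit, …); see
`reachcomp.config.AnalysisConfig` for the keys and defaults.

## Python API sketch

```python
from reachcomp import (
    ChainConfig, JointProgram, Task, analyze_trial, read_trial_table,
    simulate_trial,
)

trial = read_trial_table("trial.tsv")            # or ingest_c3d(...)
window, dec = analyze_trial(trial)               # filter, window, decompose
print(dec.percent_trunk_flexion)

chain = ChainConfig.from_upper_extremity_length(717.0)
program = JointProgram.from_end_values({"shoulder_flexion": 70, "elbow_flexion": 10})
synthetic = simulate_trial(chain, program, Task.FORWARD_REACH, noise_sd=2.0, seed=0)
```

## Trial table format

UTF-8, tab-separated: `#key=value` metadata lines (`task`, `side`,
`sampling_rate` mandatory), then a header `time` + `<MARKER>_x|_y|_z`
triples, one row per frame, millimetres, `nan` for missing samples.  Axis
convention: X lateral, Y anterior (+forward), Z vertical (+up).

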