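# clockmaze

Analysis pipeline for circular-arena escape tasks in mice: per-trial
trajectory metrics from 3-point tracking, an escape-strategy classifier
(spatial / chain / futile), a from-scratch CART feature-ablation harness,
group-level summaries, and an agent-based simulator that generates the
synthetic cohorts the whole pipeline is tested against.

The reference arena is an 85 cm "clockmaze": a shallow-water pool whose
wall is pierced by 12 holes laid out like the hours of a clock face, one
of which leads to a dry escape pipe while the other 11 are decoys.  A
160 cm hidden-platform water-maze variant is also modelled.

## Modules

| module      | role |
|-------------|------|
| `arena`     | geometric model of the arena and its analysis zones (holes, decoys, exit, periphery band, quadrants, probe zones, platform) |
| `trackio`   | delimited track / metadata / metric-table I/O and trial-schedule generation (one-exit, three-exits, eight-exits protocols) |
| `metrics`   | per-trial features: latency, nose-based inspection errors, path length, rotations, meander, heading-to-exit, zone dwell, occupancy maps |
| `strategy`  | latency+errors strategy classifier and spatial-use trend analysis |
| `treeval`   | Gini-impurity CART learner and the feature-ablation study |
| `summaries` | learning scores, novelty differences, probe-zone preference, ensemble bands, EPM ratio, Spearman rho, temperature-latency fits |
| `simulate`  | seeded agent-based trajectory simulator with spatial / chain / futile policies and a logistic learning-curve mixture |
| `cli`       | `clockmaze` command-line driver tying the stages together |

## CLI

```sh
clockmaze simulate --subjects 10 --protocol one_exit --seed 1 --out run/sim
clockmaze metrics  --tracks run/sim/tracks --trials run/sim/trials.csv --out run/metrics.csv
clockmaze classify --metrics run/metrics.csv --out run/cls
clockmaze treeval  --metrics run/cls/labeled_metrics.csv --out run/ablation.csv
clockmaze summarize --metrics run/cls/labeled_metrics.csv --out run/sum
```

Every stage writes a `provenance.json` (command, seed, version) next to its
outputs; identical config + seed reproduce outputs bit-for-bit.

Track files are delimited text with header
`time_s,nose_x,nose_y,center_x,center_y,tail_x,tail_y` (comma or tab,
auto-detected); files lacking nose/tail columns are accepted as degraded
tracks, and nose-dependent operations refuse to run on them.

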