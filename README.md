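# myxodisp

Cell-tracking statistics and a data-driven agent-based model of *Myxococcus
xanthus* aggregate formation and dispersal.

Under starvation, *M. xanthus* cells aggregate into mounds; during the
subsequent *coarsening phase* some aggregates mature into fruiting bodies
while others — typically the smaller ones — disperse. `myxodisp` implements
the full analysis chain used to study which cell behaviors drive that
dispersal, for researchers working with time-lapse fluorescence data of
developing myxobacterial biofilms:

- **runs** — coarse-grains tracked-cell trajectories into behavioral *runs*
  (segments bounded by persistent/non-persistent state changes and reversals
  of gliding direction) and annotates each run with cue covariates: time,
  local density, local nematic alignment γ = cos 2(θᵢ − θ̄), and the
  distance, relative angle and area of the nearest aggregate.
- **aggregates** — segments and tracks aggregates in density movies (Otsu
  threshold on a normalized reference frame, rescaled to all frames),
  classifies motility and fates (stable / unstable / merged), and detects
  the start of the coarsening phase.
- **stats** — the *reversal bias*
  `bias = (t_toward − t_away) / t_all`
  (relative difference between mean run durations toward and away from the
  nearest aggregate, normalized by the mean duration of all persistent
  runs), traffic-jam metrics (speed, stopping probability, stop duration
  inside vs outside aggregates), cluster-bootstrap confidence intervals, and
  a logistic model of aggregate fate versus area whose 0.5-crossing defines
  the stable size threshold.
- **abm** — a closed-loop agent-based model whose agents resample their next
  state, reorientation, speed and run duration from a database of measured
  runs via cue-matched nearest-neighbor searches, with a kernel-density
  estimate of agent positions feeding back through in-simulation aggregate
  detection. Cue sets are switchable, so the area-dependent reversal bias
  and the area-dependent traffic jam can be enabled in isolation.
- **synthkit** — a synthetic-data generator (biased persistent random walks
  with a density-dependent traffic jam, Gaussian-blob density movies with
  growth and dispersal, and direct run databases) with known ground truth,
  so the whole chain is testable without microscopy data.

## Worked example

```python
import numpy as np
from myxodisp import presets, synthkit, stats
from myxodisp.runs import annotate_runs, extract_runs

cfg = presets.bias_recovery_world(seed=7)      # cells near small aggregates bias away
tracks = synthkit.gen_trajectories(cfg)
runs = extract_runs(tracks.table)
db = annotate_runs(runs, None, synthkit.ground_truth_aggregates(cfg),
                   tracks.table, fov_size=cfg.fov_size)
small = db.df[(db.df.nearest_aggregate_area > 0)
              & (db.df.nearest_aggregate_area < 4000)]
large = db.df[db.df.nearest_aggregate_area >= 4000]
print(f"bias near small aggregates: {stats.reversal_bias(small):+.3f}")
print(f"bias near large aggregates: {stats.reversal_bias(large):+.3f}")
```

prints

```
bias near small aggregates: -0.410
bias near large aggregates: +0.381
```

i.e. the pipeline recovers the generator's ±0.4 reversal bias per
aggregate-size stratum: cells drift toward large aggregates and away from
small ones — the behavioral signature of size-dependent dispersal.

A command-line interface mirrors the library
(`myxodisp synth|runs|aggregates|stats|abm|pipeline --help`); for example

```bash
myxodisp pipeline --seed 11 --out-prefix out/
```

runs segmentation → run extraction → statistics on a self-generated
synthetic world and writes `out/report.json` with the detected coarsening
start, bias and jam summaries, and the logistic stability threshold.

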