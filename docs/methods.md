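# Methods

This note documents the models, estimators, and numerical choices behind
`myxodisp`, and what the synthetic worlds do and do not establish about real
microscopy data.

## The behavioral model

Gliding *M. xanthus* cells are reduced to a two-state process. In the
**persistent** state a cell moves steadily along its long axis; runs end
either with a **reversal** (a ~180° polarity flip) or a **state change**
into the **non-persistent** (stopped) state, from which the cell later
resumes. Two couplings to the environment matter for aggregation:

- **Reversal bias.** The mean persistent run duration is longer when the
  cell's heading points within 90° of the nearest aggregate's centroid
  (τ_toward) than when it points away (τ_away). The summary statistic is

      bias = (t̄_toward − t̄_away) / t̄_all ,

  where t̄_all is the mean duration of *all* persistent runs in the subset,
  each run weighted equally. Under pure alternating reversals toward and
  away runs occur in equal numbers per track, so the run-level estimator
  converges to t̄_all = (τ_toward + τ_away)/2 (equal-count weighting), not
  the frequency-weighted harmonic mean; for τ = 6/4 min the statistic is
  0.4, which Monte-Carlo simulation confirms to two decimals. Positive bias
  produces net drift toward aggregates.
- **Traffic jam.** At high cell density the probability of ending a run
  with a stop (p_stop), the mean stop duration, and the run-speed reduction
  all increase, trapping cells inside aggregates.

Dispersal is modeled as a *sign flip of the bias* for cells whose nearest
aggregate is smaller than a threshold area A\* after the coarsening phase
begins, together with a weakening of the jam (lower p_stop, shorter stops)
near those aggregates.

## Synthetic-data generator (`synthkit`)

The generator stands in for the tdTomato trajectory channel (1-min cadence)
and the GFP density channel (15-min cadence).

- **Run durations** are shifted exponentials: a refractory floor
  (`min_run`, default 3 min for runs; `min_stop`, 2 min for stops) plus an
  exponential tail, with the mean equal to the configured τ. Reversal
  intervals of gliding bacteria are peaked rather than exponential near
  zero — the polarity oscillator has a refractory period — and the floor
  also keeps run durations resolvable at the 1-min tracking cadence.
  Setting the floors to zero recovers pure exponentials. All closed-form
  bias expectations depend only on the means and are unaffected.
- **Behavioral density** is, by default, a step field (1 inside the nearest
  aggregate disk, 0 outside) so that inside/outside jam parameters have an
  exact ground truth. The `smooth` profile (exponential falloff from the
  aggregate boundary, 20-µm decay, plus covariate noise) is used for
  agent-model databases, where continuous density variation is what lets
  density-driven stopping nucleate aggregates in the first place.
- **Aggregates** are disks that may grow linearly and, after `disperse_at`,
  shrink linearly to zero over a 60-min ramp; the movie renders each as an
  isotropic Gaussian blob (σ = radius/2) on a uniform background with
  optional pixel noise. The nearest aggregate is chosen by *boundary*
  distance (centroid distance minus radius), the same rule the annotation
  stage uses.
- **Boundaries** reflect. Reflection flips the heading mid-run, which
  corrupts net-displacement orientations near the walls in a way real data
  (where tracks simply leave the field) does not; the annotation stage
  therefore drops runs starting within `fov_margin` (40 µm) of the field
  edge when the field size is known.
- Defaults: speed 2.5 ± 0.5 µm/min; p_stop 0.1 outside → 0.4 inside; stop
  means 6 → 14 min; orientation noise 0.2 rad; position noise 0.05 µm.

What the generator does **not** emulate: tracking noise and identity
switches, streams and rippling, cell shape and steric interactions, uneven
illumination, or cell loss over time. Passing recovery tests therefore
demonstrates estimator correctness under the assumed statistical structure,
not robustness to every artifact of real microscopy.

## Trajectory coarse-graining (`runs`)

Frames are labeled persistent when, over a centered 5-min window, windowed
path speed ≥ 1 µm/min and windowed net displacement ≥ 2 µm (scaled for
truncated windows), with three refinements, each targeting a failure mode
of the windowed rule: frames whose adjacent raw steps are both below
0.6 µm are stopped regardless of the window (the window cannot resolve
stops much shorter than itself); labeled stops whose median raw step is
large are returned to the persistent state (the net-displacement criterion
dips around fast direction changes); and label runs shorter than 2 frames
merge into their flanks. These thresholds are calibration knobs
(`RunParams`), set against generator ground truth.

Reversals are detected at two scales: a fine test on raw single-frame steps
(turn > 120°, both steps above a 0.5-µm floor, with one sub-floor step
skippable on either side because an event between frames splits its
displacement), and a smoothed multi-frame fallback where the raw steps are
too small. Candidate frames form short clusters around each physical event;
a cluster is collapsed to its sharpest turn if the net turn across it is
reversal-like, or split into its first and last candidates if the direction
resumes (an out-and-back pair). Events separated by less than the 1-min
frame spacing are unresolvable in principle; accuracy tests therefore score
recall on events whose flanking runs last ≥ 3 min (observed recall ≈ 0.93,
false positives < 3%).

Runs tile each track exactly (shared boundary frames), and each run records
duration, mean speed (path/duration), net displacement, orientation (net
displacement direction; persistent only) and its end event. Annotation adds
the cue covariates; the change of orientation between consecutive runs has
π subtracted after reversal events so values are comparable across event
types. The alignment score uses the axial (period-π) nematic mean of
neighbor orientations within 12 µm and a 7-min backward window.

## Aggregate analysis (`aggregates`)

Frames are normalized by mean subtraction, a shift by the frame minimum,
and division by the total, making the total intensity exactly 1 per frame.
(Mean subtraction alone makes the total zero, so the shift is required for
the scaled-threshold formula to be well defined; the frame-to-frame
invariant total is preserved.) Otsu's threshold is computed on a 256-bin
histogram of the unit-rescaled reference frame — chosen midway between
aggregate initiation and coarsening — and mapped back with
`(a_max − a_min)·I_otsu + a_min`.

Connected components (8-connectivity, ≥ 100 µm²) are linked across frames
by maximal contour overlap, falling back to nearest centroid within a 20-µm
gate, with up to two missed frames tolerated (components near threshold
flicker). A track that disappears under the contour of a surviving neighbor
is **merged**, not dispersed, and is excluded from fate statistics; at
small agent numbers this distinction is essential or detection noise
dominates the dispersal counts. Motile aggregates move > 3 µm/min (median
smoothed centroid speed); short-lived ones are stationary and gone within
2 h of first detection, or disperse while motile; fates are unstable if the
track ends ≥ 30 min before the movie ends (the margin guards against
censoring at the final frames).

The coarsening start is the last time the 30-min running *median* of the
total area of candidate (stationary, long-lived, ultimately unstable)
aggregates stays within 95% of its global maximum — the end of the plateau.
A literal "last maximum with no later 95% recovery" is undefined for
gradual declines, since the frames right after the maximum still exceed the
band; the plateau-exit form is equivalent for sharp peaks and robust to
single-frame segmentation noise.

## Statistics (`stats`)

Windowed bias uses 60-min windows stepped at the 15-min density cadence,
with runs assigned by midpoint time. Confidence intervals are percentile
cluster bootstraps resampling whole cells (runs within a cell are
autocorrelated). The jam comparison conditions on the signed boundary
distance at run *start*; because stops occur at run end, boundary mixing
attenuates the inside/outside contrast relative to the generator's nominal
values, so recovery is validated against ground truth conditioned the same
way. The exit rate from the stopped state is the reciprocal mean stop
duration (a hazard-based estimate would differ for non-exponential
durations; the reciprocal mean is reported as such).

The stability model P(stable) = logistic(β₀ + β₁·area) is fit by IRLS with
a 10⁻⁸ ridge on standardized areas; the stable size threshold is −β₀/β₁.
Complete separation is detected and flagged, with the threshold reported as
the midpoint of the separating gap.

## Agent-based model (`abm`)

Agents move in straight lines between reversals and stops. When a run
expires, three sequential nearest-neighbor searches against the run
database decide (1) reverse vs stop, (2) the reorientation, and (3) jointly
the speed and duration of the next run — the third after reorienting,
because run statistics depend on the new angle to the nearest aggregate.
Cues are z-scored per (time-bin, state) stratum, weighting all cues equally
in the Euclidean metric; the simulated KDE density is standardized against
the simulation's own density statistics, reconciling the fluorescence and
KDE scales. Missing cue values are imputed with the stratum mean;
zero-variance cues are dropped with a warning. The database is binned in
time (100-min bins before the coarsening start, two equal bins after, with
the density cue active only before), and the coarsening start used for
binning comes from configuration, not self-detection. Behavior is drawn
uniformly from the k = 20 nearest rows (k = 1 reproduces strict
nearest-neighbor copying, which makes agents deterministic clones).

The density field is a Gaussian KDE of agent positions on the analysis
pixel grid, normalized to total 1; aggregates are supra-threshold connected
components, with components below 300 µm² (pinpoint artifacts of density
fluctuation) excluded from nearest-aggregate queries. Simulations start
from uniform random positions and run a 90-min spin-up restricted to the
density and alignment cues, sampling only from the first 20 min of the
database, before the main clock starts. Fates and dispersal statistics are
obtained by running the same imaging pipeline (segmentation, tracking,
fate labels) on the saved KDE field snapshots.

## Scaled-down agent-model study conditions (`presets`)

The dispersal-contrast study runs 2,000 agents in a 500 × 400 µm field for
a 450-min aggregation phase plus a 450-min coarsening phase (the extended
window lets mid-size aggregates destabilize fully), three replicates per
cue condition — sizes chosen so the full contrast completes in minutes on
one CPU. Reaching the regime the analysis assumes (stable aggregation when
no area cue is present) at this small scale required: a 5-µm KDE bandwidth
(small aggregates peak well above threshold; at 7 µm a 30-agent cluster is
barely detectable), a detection threshold of twice the uniform density
level, a strong bias (τ 12/6 min), the full traffic jam including a 60%
speed reduction at high density (without it aggregates wander, merge and
churn), area-weighted aggregate assignment in the database (cells
concentrate near large aggregates; uniform assignment cancels the mean
coarsening-phase bias), and no-aggregate sentinel rows before a 150-min
aggregate onset so density-driven nucleation can bootstrap. The dispersal
threshold is A\* = 4000 µm², inside the emergent aggregate size range.
These conditions are frozen in `presets.abm_world` / `abm_sim_config`.

Under them, simulations with the aggregate area in the duration search
disperse the large majority of sub-A\* aggregates and lose 30–70% of their
aggregate count over coarsening; simulations without area cues, or with
area-dependent jamming only, keep dispersal low — and the logistic
stability threshold of the area-cue runs falls within a factor of two of
A\*. Exact values for a given seed are produced by
`scripts/acceptance.py`.

## Known limitations

- Sub-frame reversal pairs are invisible at the 1-min cadence; the
  refractory floor makes them rare in synthetic data, but against real
  trajectories the same estimator will undercount the shortest runs.
- Aggregate identity through merges and splits is heuristic
  (largest-overlap parent); heavily merging fields will undercount
  unstable aggregates.
- The nearest-neighbor searches are sequential and independent; if the
  original behavioral correlations couple state, turn and duration beyond
  what the shared cue vector captures, resampling underestimates that
  coupling (only speed and duration are drawn jointly).
- At 2,000 agents, small-aggregate fates carry substantial demographic
  noise; contrast statistics are pooled over replicates, and conclusions
  at this scale are qualitative.
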