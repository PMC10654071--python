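"""Canonical synthetic study conditions.

These configurations define the fixed synthetic worlds used for validating
the pipeline end to end; tests and the reproduction script share them so the
conditions are stated once.  Rationale for the parameter values is in
docs/methods.md.
"""

from __future__ import annotations

from .abm import CueFlags, SimulationConfig, variant_flags
from .synthkit import AggregateSpec, SyntheticWorldConfig, linear_in_density

#: dispersal size threshold of the agent-model study world (µm²)
ABM_AREA_STAR = 4000.0
#: coarsening start of the agent-model study world (min)
ABM_T_COARSEN = 450.0


def run_set_world(seed: int = 0, n_runs: int = 10000) -> SyntheticWorldConfig:
    """Constant 6/4-min toward/away run-duration means, no stopping.

    The canonical configuration for validating the reversal-bias estimator
    against its closed-form expectation (bias 0.4).
    """
    return SyntheticWorldConfig(
        aggregates=[AggregateSpec((250.0, 200.0), 40.0)],
        tau_toward=6.0, tau_away=4.0, p_stop=0.0,
        n_runs=n_runs, seed=seed)


def bias_recovery_world(seed: int = 0) -> SyntheticWorldConfig:
    """Trajectory world with an area-dependent reversal-bias sign flip.

    Two large (stable-like) and two small aggregates; cells near the small
    ones bias away (toward/away means swapped below 4000 µm²), giving ±0.4
    expected bias in the large/small strata.
    """
    return SyntheticWorldConfig(
        fov_size=(600.0, 500.0),
        aggregates=[AggregateSpec((150.0, 150.0), 55.0),
                    AggregateSpec((450.0, 350.0), 55.0),
                    AggregateSpec((150.0, 380.0), 25.0),
                    AggregateSpec((450.0, 120.0), 25.0)],
        n_cells=200, duration=600.0,
        tau_toward=9.0, tau_away=6.0,
        p_stop=linear_in_density(0.1, 0.4),
        tau_stop=linear_in_density(6.0, 14.0),
        flip_time=0.0, flip_area=4000.0,
        seed=seed)


def jam_world(seed: int = 0) -> SyntheticWorldConfig:
    """Trajectory world isolating the traffic jam (no reversal bias).

    Equal 12-min toward/away means; stopping probability 0.1 outside vs 0.4
    inside aggregates, stop-duration means 6 vs 14 min.
    """
    return SyntheticWorldConfig(
        fov_size=(600.0, 500.0),
        aggregates=[AggregateSpec((160.0, 160.0), 55.0),
                    AggregateSpec((430.0, 330.0), 55.0),
                    AggregateSpec((160.0, 380.0), 55.0)],
        n_cells=200, duration=600.0,
        tau_toward=12.0, tau_away=12.0,
        p_stop=linear_in_density(0.1, 0.4),
        tau_stop=linear_in_density(6.0, 14.0),
        seed=seed)


def movie_world(seed: int = 0) -> SyntheticWorldConfig:
    """Density-movie world: one growing stable blob, one dispersing at 420 min."""
    return SyntheticWorldConfig(
        fov_size=(500.0, 400.0),
        aggregates=[AggregateSpec((150.0, 150.0), 35.0, growth_rate=0.01),
                    AggregateSpec((360.0, 260.0), 18.0, growth_rate=0.02,
                                  disperse_at=420.0)],
        duration=660.0, noise_sd=0.01, seed=seed)


def abm_world(seed: int = 42, n_runs: int = 30000) -> SyntheticWorldConfig:
    """Run-database world for the agent-model dispersal experiments.

    Six aggregate sizes spanning 300–10,000 µm²; strong toward bias
    (12/6 min); a full traffic jam (stopping, stop duration, and a 60% speed
    reduction at high density); behavior near sub-4000-µm² aggregates flips
    to a dispersing phenotype after the 450-min coarsening start.
    """
    return SyntheticWorldConfig(
        fov_size=(500.0, 400.0),
        aggregates=[AggregateSpec((100.0, 100.0), 10.0),
                    AggregateSpec((250.0, 300.0), 18.0),
                    AggregateSpec((400.0, 150.0), 25.0),
                    AggregateSpec((150.0, 320.0), 32.0),
                    AggregateSpec((380.0, 330.0), 40.0),
                    AggregateSpec((250.0, 100.0), 56.0)],
        duration=900.0,
        tau_toward=12.0, tau_away=6.0,
        density_profile="smooth", density_decay=20.0, density_noise=0.04,
        aggregate_onset=150.0, speed_jam=0.6,
        p_stop=linear_in_density(0.1, 0.55),
        tau_stop=linear_in_density(6.0, 20.0),
        flip_time=ABM_T_COARSEN, flip_area=ABM_AREA_STAR,
        n_runs=n_runs, seed=seed)


def abm_sim_config(variant: str = "bias-only", seed: int = 0,
                   **overrides) -> SimulationConfig:
    """Scaled-down simulation conditions paired with :func:`abm_world`.

    2,000 agents in a 500×400 µm field, 5-µm KDE bandwidth, detection
    threshold at twice the uniform density level, 300-µm² pinpoint filter,
    coarsening start 450 min, end 900 min.
    """
    kwargs = dict(
        fov=(500.0, 400.0), n_agents=2000,
        t_start=0.0, t_end=900.0, t_coarsen=ABM_T_COARSEN,
        kde_bandwidth=5.0, pixel_size=2.0,
        cue_flags=variant_flags(variant), seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
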