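"""Parameter-recovery study configurations.

Each published mixed-model coefficient table defines a generative truth:
the synthetic cohorts for a given recovery study are built from exactly
the fixed effects that the corresponding model carries, so that refitting
the model is a well-posed recovery problem.

- Open-field speed model (intercept, log2-speed slope, slope x darkness):
  truth -0.169 / 0.221 / 0.013, random intercepts and log-speed slopes
  for animal and session (the published formula lists random terms on all
  fixed effects).
- Stationary-subset speed model: truth 0.232 / 0.226 / 0.068 on cohorts
  dominated by stationary behaviour (> 2/3 of frames below 3 cm/s).
- Behaviour-community model (intercept, log2-speed, darkness, and
  exploratory-running / rearing / grooming offsets vs. walking): truth
  -0.240 / 0.200 / -0.029 / -0.001 / 0.277 / -0.211; the published
  formula lists random intercepts only, so the generative truth carries
  no random slopes.
"""

from __future__ import annotations

from achdyn import mixed_models as mm
from achdyn import simulate as sim

#: Occupancy profile for stationary-dominated sessions: ~72% of time in
#: sub-3 cm/s states, mirroring the stationary-session subset.
STATIONARY_OCCUPANCY = {
    "still": 0.50,
    "groom": 0.12,
    "rear": 0.10,
    "walk": 0.20,
    "run": 0.08,
}


def speed_model_config(session_duration: float = 300.0) -> sim.SynthConfig:
    """Generator truth for the open-field speed model."""
    return sim.SynthConfig(
        session_duration=session_duration,
        coeffs=sim.Coefficients(
            beta0=-0.169,
            beta_speed=0.221,
            beta_dark_slope=0.013,
            beta_rear=0.0,
            beta_groom=0.0,
            beta_er=0.0,
            beta_dark_main=0.0,
        ),
    )


def stationary_model_config(session_duration: float = 300.0) -> sim.SynthConfig:
    """Generator truth for the stationary-subset speed model."""
    return sim.SynthConfig(
        session_duration=session_duration,
        occupancy_targets=dict(STATIONARY_OCCUPANCY),
        coeffs=sim.Coefficients(
            beta0=0.232,
            beta_speed=0.226,
            beta_dark_slope=0.068,
            beta_rear=0.0,
            beta_groom=0.0,
            beta_er=0.0,
            beta_dark_main=0.0,
        ),
    )


def behavior_model_config(session_duration: float = 600.0) -> sim.SynthConfig:
    """Generator truth for the behaviour-community model (random
    intercepts only, as in its published formula)."""
    re = sim.RandomEffectParams(
        animal_intercept_sd=0.15,
        animal_slope_sd=0.0,
        session_intercept_sd=0.10,
        session_slope_sd=0.0,
    )
    return sim.SynthConfig(
        session_duration=session_duration,
        random_effects=re,
        coeffs=sim.Coefficients(
            beta0=-0.240,
            beta_speed=0.200,
            beta_dark_main=-0.029,
            beta_er=-0.001,
            beta_rear=0.277,
            beta_groom=-0.211,
            beta_dark_slope=0.0,
        ),
    )


def speed_recovery(
    n_replicates: int = 12,
    seed=0,
    n_animals: int = 5,
    sessions_per_animal: int = 10,
    session_duration: float = 300.0,
):
    return mm.recovery_study(
        speed_model_config(session_duration),
        "speed_dark",
        n_replicates,
        seed,
        n_animals=n_animals,
        sessions_per_animal=sessions_per_animal,
    )


def stationary_recovery(
    n_replicates: int = 12,
    seed=0,
    n_animals: int = 3,
    sessions_per_animal: int = 8,
    session_duration: float = 300.0,
):
    return mm.recovery_study(
        stationary_model_config(session_duration),
        "stationary_speed_dark",
        n_replicates,
        seed,
        n_animals=n_animals,
        sessions_per_animal=sessions_per_animal,
    )


def behavior_recovery(
    n_replicates: int = 24,
    seed=0,
    n_animals: int = 3,
    sessions_per_animal: int = 10,
    session_duration: float = 600.0,
):
    return mm.recovery_study(
        behavior_model_config(session_duration),
        "behavior_speed_dark",
        n_replicates,
        seed,
        n_animals=n_animals,
        sessions_per_animal=sessions_per_animal,
    )


def speed_coverage(
    n_replicates: int = 100,
    seed=0,
    n_animals: int = 5,
    sessions_per_animal: int = 4,
    session_duration: float = 120.0,
):
    """CI-coverage calibration of the log-speed slope on scaled cohorts."""
    return mm.recovery_study(
        speed_model_config(session_duration),
        "speed_dark",
        n_replicates,
        seed,
        n_animals=n_animals,
        sessions_per_animal=sessions_per_animal,
    )
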