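"""Synthetic predation trials and 7-day survival/defoliation trajectories.

The generator reproduces the statistical structure the analysis assumes, so
every downstream stage can be exercised without the original bench data.

Predation trials: for each density x replicate the expected consumption is
the random-predator prediction mu = predict_na(a(N0), th, n0, t) and the
observed count is Binomial(n0, mu/n0) — each prey independently consumed
with probability mu/n0 — or beta-binomial with intra-arena correlation rho
to stress-test interval coverage.  A type III mechanism is available through
a hyperbolic density-dependent attack rate a(N0) = b*N0 / (1 + c*N0), used
only to exercise the classifier.

Damage trajectories: a daily discrete-time thinning chain.  Each day, prey
on toxin-treated foliage die independently with a fixed probability; once
the predator has been released it removes up to its daily capacity of prey
(predation precedes feeding within a day); the survivors then feed, and
defoliation accumulates as survivors x per-larva daily consumption, capped
at 100%.

Every stochastic call takes a mandatory seed; per-replicate streams are
spawned from one SeedSequence so replicates are independent and the whole
dataset is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DamageSeries, ExperimentDesign, PredationTrial, ValidationError
from .rogers import predict_na

__all__ = [
    "SimulationParams",
    "DamageParams",
    "simulate_trials",
    "simulate_damage",
    "paper_presets",
    "FR_PRESETS",
    "DAMAGE_PRESETS",
    "TYPE3_PRESET",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one instar x treatment predation assay.

    Either a constant attack rate ``true_a`` (type II) or a hyperbolic
    density-dependent pair ``(type3_b, type3_c)`` (type III) must be given.
    """

    design: ExperimentDesign
    true_th: float
    true_a: float | None = None
    type3_b: float | None = None
    type3_c: float | None = None
    noise_model: str = "binomial"  # or "beta-binomial"
    rho: float = 0.0  # beta-binomial intra-arena correlation
    instar: int = 1
    treatment: str = "control"

    def __post_init__(self) -> None:
        if self.true_th < 0:
            raise ValidationError(f"true_th must be >= 0, got {self.true_th}")
        if self.true_a is not None:
            if self.true_a <= 0:
                raise ValidationError(f"true_a must be > 0, got {self.true_a}")
        elif self.type3_b is not None:
            if self.type3_b <= 0 or (self.type3_c or 0.0) < 0:
                raise ValidationError("type III requires b > 0 and c >= 0")
        else:
            raise ValidationError("either true_a or (type3_b, type3_c) must be set")
        if self.noise_model not in ("binomial", "beta-binomial"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "beta-binomial" and not 0.0 < self.rho < 1.0:
            raise ValidationError("beta-binomial requires 0 < rho < 1")

    def attack_rate(self, n0: float) -> float:
        if self.true_a is not None:
            return self.true_a
        return self.type3_b * n0 / (1.0 + (self.type3_c or 0.0) * n0)


@dataclass(frozen=True)
class DamageParams:
    """Generative parameters for one 7-day survival/defoliation treatment arm."""

    treatment: str
    bt_daily_mortality: float = 0.0  # per-prey, per-day kill probability from the toxin
    feeding_pct_per_larva_day: float = 100.0 / 70.0  # calibrated: 10 larvae x 7 d ~ 100%
    predator_release_day: int | None = None
    predator_daily_capacity: int = 10  # prey removed per day once released
    n_prey: int = 10
    days: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.bt_daily_mortality <= 1.0:
            raise ValidationError("bt_daily_mortality must lie in [0, 1]")
        if self.feeding_pct_per_larva_day < 0:
            raise ValidationError("feeding rate must be >= 0")
        if self.predator_daily_capacity < 0 or self.n_prey < 1 or self.days < 1:
            raise ValidationError("capacity >= 0, n_prey >= 1 and days >= 1 required")
        if self.predator_release_day is not None and self.predator_release_day < 0:
            raise ValidationError("predator_release_day must be >= 0")


def _draw_consumed(rng: np.random.Generator, n0: int, mu: float, params: SimulationParams) -> int:
    p = mu / n0
    if not 0.0 <= p <= 1.0:
        raise AssertionError(f"expected proportion {p} outside [0, 1]")  # impossible by construction
    if params.noise_model == "binomial":
        return int(rng.binomial(n0, p))
    # beta-binomial: p ~ Beta with mean p and pairwise correlation rho
    s = (1.0 - params.rho) / params.rho
    a, b = max(p * s, 1e-9), max((1.0 - p) * s, 1e-9)
    return int(rng.binomial(n0, rng.beta(a, b)))


def simulate_trials(params: SimulationParams, seed: int) -> list[PredationTrial]:
    """Draw one full density-ladder experiment; deterministic under ``seed``.

    Replicates get independent child streams of ``SeedSequence(seed)``, so a
    dataset is reproducible and replicate streams never overlap.
    """
    design = params.design
    children = np.random.SeedSequence(seed).spawn(design.n_trials)
    trials = []
    k = 0
    for n0 in design.densities:
        mu = predict_na(params.attack_rate(n0), params.true_th, n0, design.exposure_h)
        for rep in range(1, design.replicates + 1):
            rng = np.random.default_rng(children[k])
            k += 1
            trials.append(
                PredationTrial(
                    predator_instar=params.instar,
                    treatment=params.treatment,
                    n0=int(n0),
                    na=_draw_consumed(rng, int(n0), mu, params),
                    exposure_h=design.exposure_h,
                    replicate_id=rep,
                )
            )
    return trials


def simulate_damage(params: DamageParams, replicates: int, seed: int) -> list[DamageSeries]:
    """Draw per-arena 7-day trajectories from the daily thinning chain.

    Day order: toxin mortality (binomial thinning) -> predation (up to
    capacity prey removed, once past the release day) -> feeding by the
    remaining survivors.  All series invariants (survivors non-increasing,
    defoliation non-decreasing, bounded by 100%) hold by construction.
    """
    children = np.random.SeedSequence(seed).spawn(replicates)
    series = []
    for rep in range(1, replicates + 1):
        rng = np.random.default_rng(children[rep - 1])
        survivors = params.n_prey
        defol = 0.0
        days, surv_track, defol_track = [0], [survivors], [defol]
        for day in range(1, params.days + 1):
            if params.bt_daily_mortality > 0 and survivors > 0:
                survivors -= int(rng.binomial(survivors, params.bt_daily_mortality))
            if params.predator_release_day is not None and day > params.predator_release_day:
                survivors = max(0, survivors - params.predator_daily_capacity)
            defol = min(100.0, defol + survivors * params.feeding_pct_per_larva_day)
            days.append(day)
            surv_track.append(survivors)
            defol_track.append(defol)
        series.append(
            DamageSeries(
                treatment=params.treatment,
                replicate=rep,
                days=tuple(days),
                survivors=tuple(surv_track),
                defoliation_pct=tuple(defol_track),
                predator_release_day=params.predator_release_day,
            )
        )
    return series


# ---------------------------------------------------------------------------
# presets: the study conditions
# ---------------------------------------------------------------------------

_D1 = ExperimentDesign(densities=(2, 4, 8))
_D2 = ExperimentDesign(densities=(2, 4, 8, 16))
_D3 = ExperimentDesign(densities=(2, 4, 8, 16, 32, 64, 128))

#: Published point estimates (attack rate h^-1, handling time h) per
#: predator instar x prey treatment, with the matching density ladder.
FR_PRESETS: dict[str, SimulationParams] = {
    "instar1_control": SimulationParams(design=_D1, true_a=0.10, true_th=17.84, instar=1, treatment="control"),
    "instar1_cry3aa": SimulationParams(design=_D1, true_a=0.14, true_th=8.23, instar=1, treatment="cry3aa"),
    "instar2_control": SimulationParams(design=_D2, true_a=0.14, true_th=8.26, instar=2, treatment="control"),
    "instar2_cry3aa": SimulationParams(design=_D2, true_a=0.07, true_th=5.05, instar=2, treatment="cry3aa"),
    "instar3_control": SimulationParams(design=_D3, true_a=0.01, true_th=0.60, instar=3, treatment="control"),
    "instar3_cry3aa": SimulationParams(design=_D3, true_a=0.0087, true_th=0.57, instar=3, treatment="cry3aa"),
}

#: A synthetic sigmoid (type III) mechanism on the 4-density ladder:
#: hyperbolic density-dependent attack rate, used only to exercise the
#: classifier.  Proportion consumed rises from ~0.17 at N0=2 to ~0.53 at
#: N0=16 — an unambiguous type III signature.
TYPE3_PRESET = SimulationParams(
    design=_D2, true_th=1.0, type3_b=0.004, type3_c=0.02, instar=2, treatment="type3_synthetic"
)

# Cry3Aa at the prey's LC50: 50% cumulative mortality over the 7-day bioassay
# => daily probability 1 - 0.5**(1/7).  Intoxicated larvae also feed less;
# 0.52 %/larva-day makes the expected 7-day defoliation ~25%.
_BT_DAILY = 1.0 - 0.5 ** (1.0 / 7.0)

#: The four survival/damage treatment arms: water control, toxin alone,
#: predator alone (released at day 0), toxin + predator (released at day 3).
DAMAGE_PRESETS: dict[str, DamageParams] = {
    "t1_water": DamageParams(treatment="t1_water"),
    "t2_cry3aa": DamageParams(
        treatment="t2_cry3aa", bt_daily_mortality=_BT_DAILY, feeding_pct_per_larva_day=0.52
    ),
    "t3_water_predator": DamageParams(treatment="t3_water_predator", predator_release_day=0),
    "t4_cry3aa_predator": DamageParams(
        treatment="t4_cry3aa_predator",
        bt_daily_mortality=_BT_DAILY,
        feeding_pct_per_larva_day=0.52,
        predator_release_day=3,
    ),
}


def paper_presets() -> tuple[dict[str, SimulationParams], dict[str, DamageParams]]:
    """Named study-condition presets: six functional-response arms, four damage arms."""
    return dict(FR_PRESETS), dict(DAMAGE_PRESETS)


def get_preset(name: str):
    """Look up a preset by name across both families."""
    if name in FR_PRESETS:
        return FR_PRESETS[name]
    if name in DAMAGE_PRESETS:
        return DAMAGE_PRESETS[name]
    raise KeyError(f"unknown preset {name!r}; known: {sorted(FR_PRESETS) + sorted(DAMAGE_PRESETS)}")
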