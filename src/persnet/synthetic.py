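"""Seeded synthetic survey cohorts with known ground truth.

The study data behind this pipeline are confidential, so every stage is
exercised on generated cohorts that mimic the survey's record structure:
ego covariates, an ordered alter roster, and a tie section over the first
10 alters.  The generator is parameterized per group and is deterministic
given a seed.

Generative model (per participant)
----------------------------------
* ego covariates: age normal; race / education / employment categorical;
  income lognormal; domestic status and living situation Bernoulli;
  chronic conditions as four independent affliction flags (players) or a
  single indicator (controls), matching how the two cohorts are surveyed;
* roster size: negative binomial (zero-truncated), with a log-linear age
  link shared by both groups — older egos name slightly larger rosters;
* ties among the first 10 alters: independent presence at a per-ego
  density drawn from a Beta whose mean follows a logit-linear age link;
  present ties are "especially close" (strength 2) with fixed probability;
* alter attributes, conditionally independent given the ego: sex from a
  per-ego Beta-Bernoulli male share; race by a homophily mixture
  h * ego-race + (1 - h) * population; kin / distance / exercise /
  negative-influence flags Beta-Bernoulli; alter ages normal around the
  ego's age; football-affiliation flags (players only), with NFL contacts
  a sub-Bernoulli of organized-football contacts.

The age links on size and density are the mechanism by which the default
("paper-like") configuration reproduces raw group gaps in structure
medians while keeping the age-adjusted group effect on every structure
metric at zero; group differences in composition (male share, kin share,
race homophily) are planted directly.  An optional missingness injector
blanks attributes at configurable rates to exercise the non-missing
denominator logic downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import (
    CHRONIC_CONDITIONS,
    DOMESTIC_LEVELS,
    EDUCATION_LEVELS,
    EMPLOYMENT_LEVELS,
    AlterRecord,
    EgoRecord,
    LIVING_LEVELS,
    MAX_TIE_ALTERS,
    RACES,
    TieMatrix,
    records_to_table,
)

#: reference ego age (years) at which the size/density age links are anchored
REFERENCE_AGE = 48.0


def _check_prob(name: str, p: float | None) -> None:
    if p is not None and not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class GroupParams:
    """Generator parameters for one cohort."""

    n: int
    # ego covariates
    age_mean: float
    age_sd: float
    race_probs: tuple  # (White, Black, Other)
    education_probs: tuple  # 5 ordered levels
    employment_probs: tuple  # (employed, student, retired, unemployed)
    income_log_mean: float
    income_log_sd: float
    married_prob: float
    live_with_others_prob: float
    # chronic conditions: four-type flags (players) / single flag (controls)
    chronic_probs: dict | None = None
    chronic_present_prob: float | None = None
    # network size: zero-truncated negative binomial with log-linear age link
    size_mean: float = 7.8
    size_age_slope: float = 0.0066  # per year, on log(mean)
    size_dispersion: float = 8.0
    # tie density: Beta with logit-linear age link on the mean
    density_mean: float = 0.68
    density_concentration: float = 3.0
    density_age_slope: float = 0.0175  # per year, on logit(mean)
    strength2_given_tie: float = 0.5
    # alter attributes
    alter_male_mean: float = 0.5
    alter_male_concentration: float = 40.0
    homophily: dict = field(
        default_factory=lambda: {"White": 0.92, "Black": 0.55, "Other": 0.5}
    )
    kin_mean: float = 0.44
    kin_concentration: float = 8.0
    distant_mean: float = 0.35
    distant_concentration: float = 8.0
    non_exercise_mean: float = 0.33
    non_exercise_concentration: float = 8.0
    negative_mean: float = 0.05
    negative_concentration: float = 10.0
    alter_age_sd: float = 12.5
    football_prob: float | None = None
    nfl_given_football: float | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in (
            "married_prob",
            "live_with_others_prob",
            "chronic_present_prob",
            "strength2_given_tie",
            "alter_male_mean",
            "kin_mean",
            "distant_mean",
            "non_exercise_mean",
            "negative_mean",
            "density_mean",
            "football_prob",
            "nfl_given_football",
        ):
            _check_prob(name, getattr(self, name))
        for label, probs, k in (
            ("race_probs", self.race_probs, len(RACES)),
            ("education_probs", self.education_probs, len(EDUCATION_LEVELS)),
            ("employment_probs", self.employment_probs, len(EMPLOYMENT_LEVELS)),
        ):
            if len(probs) != k:
                raise ValueError(f"{label} must have {k} entries")
            for p in probs:
                _check_prob(label, p)
            if not math.isclose(sum(probs), 1.0, abs_tol=0.02):
                raise ValueError(f"{label} must sum to 1 (got {sum(probs)})")
        if self.chronic_probs is not None:
            for c, p in self.chronic_probs.items():
                if c not in CHRONIC_CONDITIONS:
                    raise ValueError(f"unknown chronic condition {c!r}")
                _check_prob(f"chronic_probs[{c}]", p)
        for h in self.homophily.values():
            _check_prob("homophily", h)
        if self.size_mean <= 0 or self.size_dispersion <= 0:
            raise ValueError("size_mean and size_dispersion must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Two-group synthetic cohort configuration."""

    players: GroupParams
    controls: GroupParams
    seed: int = 0
    #: optional missingness injector: rates keyed by "income", "age", "race",
    #: or "alter_<field>" (e.g. "alter_age"); items are blanked at that rate
    missing_rates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, r in self.missing_rates.items():
            _check_prob(f"missing_rates[{k}]", r)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The calibrated ("paper-like") default configuration.

    Targets: chronic-condition prevalence ~0.43 (players) vs ~0.23
    (controls); median roster size ~8 vs ~7 and density ~0.75 vs ~0.68 via
    the shared age links and the groups' different age distributions;
    planted composition contrasts (male share 0.68 vs 0.50, kin share 0.37
    vs 0.44, lower race homophily for Black egos).
    """
    controls = GroupParams(
        n=269,
        age_mean=39.5,
        age_sd=9.0,
        race_probs=(0.958, 0.008, 0.034),
        education_probs=(0.013, 0.109, 0.053, 0.432, 0.383),
        employment_probs=(0.925, 0.042, 0.008, 0.025),
        income_log_mean=math.log(65884.0),
        income_log_sd=0.36,
        married_prob=0.699,
        live_with_others_prob=0.86,
        chronic_present_prob=0.227,
        alter_male_mean=0.50,
        homophily={"White": 0.92, "Black": 0.55, "Other": 0.5},
        kin_mean=0.44,
        distant_mean=0.35,
        non_exercise_mean=0.33,
        negative_mean=0.05,
        alter_age_sd=12.5,
    )
    players = GroupParams(
        n=303,
        age_mean=58.5,
        age_sd=12.5,
        race_probs=(0.73, 0.25, 0.02),
        education_probs=(0.0, 0.064, 0.010, 0.613, 0.313),
        employment_probs=(0.623, 0.003, 0.294, 0.080),
        income_log_mean=math.log(68810.0),
        income_log_sd=0.36,
        married_prob=0.828,
        live_with_others_prob=0.868,
        chronic_probs={
            "sleep": 0.235,
            "pain": 0.085,
            "cardiometabolic": 0.16,
            "neurocognitive": 0.04,
        },
        alter_male_mean=0.68,
        homophily={"White": 0.92, "Black": 0.55, "Other": 0.5},
        kin_mean=0.37,
        distant_mean=0.38,
        non_exercise_mean=0.31,
        negative_mean=0.035,
        alter_age_sd=12.5,
        football_prob=0.42,
        nfl_given_football=0.12,
    )
    return SyntheticConfig(players=players, controls=controls, seed=seed)


def planted_effect_presets(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Named presets with known ground truth.

    * ``"null"`` — identical parameter blocks for both groups (no effect
      anywhere; for type-I error calibration), n = 300 per group;
    * ``"paper-like"`` — the calibrated default: composition differs
      (male share, kin share, race homophily by ego race) while the
      age-adjusted structure effect is zero;
    * ``"structure-shift"`` — composition identical but roster size and
      density genuinely shifted (positive control for structure tests).
    """
    base = default_config(seed)
    null_block = replace(
        base.controls,
        n=300,
        # same realized chronic prevalence under either cohort's encoding
        chronic_probs={"sleep": 0.15, "pain": 0.05, "cardiometabolic": 0.05, "neurocognitive": 0.01},
        chronic_present_prob=1 - (1 - 0.15) * (1 - 0.05) * (1 - 0.05) * (1 - 0.01),
    )
    null = SyntheticConfig(players=null_block, controls=null_block, seed=seed)
    structure = SyntheticConfig(
        players=replace(
            base.players,
            alter_male_mean=0.5,
            kin_mean=0.44,
            homophily=dict(base.controls.homophily),
            size_mean=10.5,
            density_mean=0.85,
        ),
        controls=replace(base.controls, size_mean=7.0, density_mean=0.62),
        seed=seed,
    )
    return {"null": null, "paper-like": base, "structure-shift": structure}


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _beta(rng: np.random.Generator, mean: float, concentration: float) -> float:
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))


def _trunc_nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    for _ in range(1000):
        k = int(rng.negative_binomial(dispersion, p))
        if k > 0:
            return k
    return 1


def _simulate_participant(
    rng: np.random.Generator, params: GroupParams, group: str, pid: str
) -> EgoRecord:
    age = float(rng.normal(params.age_mean, params.age_sd))
    age = float(np.clip(age, 21.0, 95.0))
    race = RACES[rng.choice(3, p=np.asarray(params.race_probs) / sum(params.race_probs))]
    education = EDUCATION_LEVELS[
        rng.choice(5, p=np.asarray(params.education_probs) / sum(params.education_probs))
    ]
    employment = EMPLOYMENT_LEVELS[
        rng.choice(4, p=np.asarray(params.employment_probs) / sum(params.employment_probs))
    ]
    income = float(np.exp(rng.normal(params.income_log_mean, params.income_log_sd)))
    domestic = DOMESTIC_LEVELS[0] if rng.random() < params.married_prob else DOMESTIC_LEVELS[1]
    living = LIVING_LEVELS[0] if rng.random() < params.live_with_others_prob else LIVING_LEVELS[1]

    if group == "player":
        probs = params.chronic_probs or {}
        chronic = frozenset(c for c in CHRONIC_CONDITIONS if rng.random() < probs.get(c, 0.0))
        chronic_present = None
    else:
        chronic = frozenset()
        p = params.chronic_present_prob
        chronic_present = bool(rng.random() < p) if p is not None else None

    # roster size with log-linear age link
    mu = params.size_mean * math.exp(params.size_age_slope * (age - REFERENCE_AGE))
    n = _trunc_nb(rng, mu, params.size_dispersion)

    # per-ego latent shares
    p_male = _beta(rng, params.alter_male_mean, params.alter_male_concentration)
    p_kin = _beta(rng, params.kin_mean, params.kin_concentration)
    p_dist = _beta(rng, params.distant_mean, params.distant_concentration)
    p_nonex = _beta(rng, params.non_exercise_mean, params.non_exercise_concentration)
    p_neg = _beta(rng, params.negative_mean, params.negative_concentration)
    h = params.homophily.get(race, 0.5)
    race_pop = np.asarray(params.race_probs) / sum(params.race_probs)

    alters = []
    for _ in range(n):
        if rng.random() < h:
            a_race = race
        else:
            a_race = RACES[rng.choice(3, p=race_pop)]
        a = AlterRecord(
            sex="male" if rng.random() < p_male else "female",
            race=a_race,
            age=float(np.clip(rng.normal(age, params.alter_age_sd), 18.0, 95.0)),
            kin=bool(rng.random() < p_kin),
            distant=bool(rng.random() < p_dist),
            non_exercising=bool(rng.random() < p_nonex),
            negative_influence=bool(rng.random() < p_neg),
        )
        if group == "player" and params.football_prob is not None:
            football = bool(rng.random() < params.football_prob)
            nfl = football and bool(rng.random() < (params.nfl_given_football or 0.0))
            a.played_organized_football = football
            a.played_nfl_with_participant = nfl
        alters.append(a)

    # ties among the first min(n, 10) alters at the ego's density draw
    k = min(n, MAX_TIE_ALTERS)
    logit = math.log(params.density_mean / (1 - params.density_mean))
    d_mean = 1.0 / (1.0 + math.exp(-(logit + params.density_age_slope * (age - REFERENCE_AGE))))
    d_i = _beta(rng, d_mean, params.density_concentration)
    strengths = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < d_i:
                strengths[i, j] = strengths[j, i] = (
                    2 if rng.random() < params.strength2_given_tie else 1
                )
    ties = TieMatrix(strengths) if k >= 1 else None

    return EgoRecord(
        participant_id=pid,
        group=group,
        age=age,
        race=race,
        education=education,
        employment=employment,
        income=income,
        domestic_status=domestic,
        living_situation=living,
        chronic_conditions=chronic,
        chronic_present=chronic_present,
        alters=alters,
        ties=ties,
    )


_ALTER_MISSING_FIELDS = (
    "sex",
    "race",
    "age",
    "kin",
    "distant",
    "non_exercising",
    "negative_influence",
)
_EGO_MISSING_FIELDS = ("age", "race", "income", "education", "employment")


def _inject_missingness(
    rng: np.random.Generator, records: Sequence[EgoRecord], rates: dict
) -> None:
    for rec in records:
        for f in _EGO_MISSING_FIELDS:
            r = rates.get(f, 0.0)
            if r and rng.random() < r:
                setattr(rec, f, None)
        for a in rec.alters:
            for f in _ALTER_MISSING_FIELDS:
                r = rates.get(f"alter_{f}", 0.0)
                if r and rng.random() < r:
                    setattr(a, f, None)


def simulate_records(config: SyntheticConfig, seed: int | None = None) -> list[EgoRecord]:
    """Generate the cohort as in-memory records (deterministic given seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = [
        _simulate_participant(rng, config.controls, "control", f"C{i+1:04d}")
        for i in range(config.controls.n)
    ]
    records += [
        _simulate_participant(rng, config.players, "player", f"P{i+1:04d}")
        for i in range(config.players.n)
    ]
    if config.missing_rates:
        _inject_missingness(rng, records, config.missing_rates)
    return records


def simulate_cohort(config: SyntheticConfig, seed: int | None = None):
    """Generate the cohort as a wide-CSV survey table (pandas DataFrame).

    The output flows through the identical pipeline entry point as a real
    survey export (:func:`persnet.io.parse_survey_table`).
    """
    return records_to_table(simulate_records(config, seed=seed))
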