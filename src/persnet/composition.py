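"""Per-ego network composition metrics and homogeneity scores.

Composition metrics summarize who the network members are, over the FULL
alter roster (the name-interpreter section covers all alters, unlike the
tie section).  Percentages and proportions use non-missing denominators:
alters with the relevant attribute blank simply drop out, and a metric is
missing when its denominator is zero.

Diversity indices are based on the index of qualitative variation

    IQV = (K / (K - 1)) * (1 - sum_k p_k^2)

over K categories: 0 when every member falls in one category, 1 at exact
uniformity.  Two homogeneity scores describe how much the network mirrors
the ego: the majority-male score (#men - #women) / #members in [-1, 1],
and the proportion of alters sharing the ego's race in [0, 1] (defined
only for networks of at least two members, matching how the montage
figures exclude tiny networks).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import stdev
from typing import Callable, Sequence

from .io import AlterRecord, EgoRecord, RACES, SEXES


@dataclass(frozen=True)
class CompositionMetrics:
    """Per-ego composition bundle (missing values are None).

    The two football-affiliation percentages are defined for the players
    cohort only and stay None for controls.
    """

    pct_kin: float | None
    diversity_sex: float | None
    diversity_race: float | None
    pct_distant: float | None
    sd_ages: float | None
    pct_non_exercising: float | None
    pct_negative: float | None
    pct_played_football: float | None
    pct_nfl_with_participant: float | None
    majority_male_score: float | None
    same_race_proportion: float | None

    def as_dict(self) -> dict:
        return {
            "pct_kin": self.pct_kin,
            "diversity_sex": self.diversity_sex,
            "diversity_race": self.diversity_race,
            "pct_distant": self.pct_distant,
            "sd_ages": self.sd_ages,
            "pct_non_exercising": self.pct_non_exercising,
            "pct_negative": self.pct_negative,
            "pct_played_football": self.pct_played_football,
            "pct_nfl_with_participant": self.pct_nfl_with_participant,
            "majority_male_score": self.majority_male_score,
            "same_race_proportion": self.same_race_proportion,
        }


def iqv(counts: Sequence[int], K: int) -> float | None:
    """Index of qualitative variation over per-category counts.

    ``K`` is the number of possible categories (not the number observed);
    zero-count categories still shape the 1 at exact uniformity.  Missing
    (None) when no members are counted.
    """
    if K < 2:
        raise ValueError("IQV needs at least two categories")
    total = sum(counts)
    if total == 0:
        return None
    p2 = sum((c / total) ** 2 for c in counts)
    return (K / (K - 1)) * (1.0 - p2)


def diversity_of_sex(alters: Sequence[AlterRecord]) -> float | None:
    """IQV of the male/female mix: 0 single-sex, 1 exactly balanced."""
    counts = [sum(1 for a in alters if a.sex == s) for s in SEXES]
    return iqv(counts, K=2)


def diversity_of_race(alters: Sequence[AlterRecord]) -> float | None:
    """IQV over {White, Black, Other}: 0 one race, 1 equal thirds."""
    counts = [sum(1 for a in alters if a.race == r) for r in RACES]
    return iqv(counts, K=3)


def percentage_metric(
    alters: Sequence[AlterRecord], predicate: Callable[[AlterRecord], bool | None]
) -> float | None:
    """100 * (#alters where predicate is True) / (#alters where it is known).

    Alters for which the predicate returns None (item left blank) drop out
    of the denominator; missing (None) when all are blank.
    """
    values = [predicate(a) for a in alters]
    known = [v for v in values if v is not None]
    if not known:
        return None
    return 100.0 * sum(known) / len(known)


def sd_of_ages(alters: Sequence[AlterRecord]) -> float | None:
    """Sample standard deviation (n-1) of known alter ages; None if < 2."""
    ages = [a.age for a in alters if a.age is not None]
    if len(ages) < 2:
        return None
    return stdev(ages)


def majority_male_score(alters: Sequence[AlterRecord]) -> float | None:
    """(#men - #women) / #members with known sex, in [-1, 1].

    -1 is an all-female network, +1 all-male.
    """
    m = sum(1 for a in alters if a.sex == "male")
    f = sum(1 for a in alters if a.sex == "female")
    if m + f == 0:
        return None
    return (m - f) / (m + f)


def same_race_proportion(record: EgoRecord) -> float | None:
    """Share of alters with the ego's race, in [0, 1] (1 = homogeneous).

    Requires a known ego race, at least one alter with known race, and a
    roster of at least two (smaller networks are excluded from homogeneity
    scoring).
    """
    if record.race is None or record.network_size < 2:
        return None
    races = [a.race for a in record.alters if a.race is not None]
    if not races:
        return None
    return sum(1 for r in races if r == record.race) / len(races)


def compute_composition(record: EgoRecord) -> CompositionMetrics:
    """Bundle all composition metrics for one record.

    Football-affiliation percentages are computed for players only (those
    survey items are not asked of controls).
    """
    alters = record.alters
    is_player = record.group == "player"
    return CompositionMetrics(
        pct_kin=percentage_metric(alters, lambda a: a.kin),
        diversity_sex=diversity_of_sex(alters),
        diversity_race=diversity_of_race(alters),
        pct_distant=percentage_metric(alters, lambda a: a.distant),
        sd_ages=sd_of_ages(alters),
        pct_non_exercising=percentage_metric(alters, lambda a: a.non_exercising),
        pct_negative=percentage_metric(alters, lambda a: a.negative_influence),
        pct_played_football=(
            percentage_metric(alters, lambda a: a.played_organized_football)
            if is_player
            else None
        ),
        pct_nfl_with_participant=(
            percentage_metric(alters, lambda a: a.played_nfl_with_participant)
            if is_player
            else None
        ),
        majority_male_score=majority_male_score(alters),
        same_race_proportion=same_race_proportion(record),
    )
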