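"""Cohort description and two-group comparison of network metrics.

The analysis contrasts per-ego network metrics between two cohorts (e.g.
former professional football players vs male US controls) in three layers:

1. a baseline descriptive table — median [IQR] for continuous ego
   covariates, count (%) for categoricals, with univariate p-values
   (Mann-Whitney / Pearson chi-squared);
2. per-metric comparisons: group medians and IQRs, a univariate
   Mann-Whitney p, and a covariate-adjusted p from an ordinary
   least-squares fit of ``metric ~ group + covariates`` (two-sided t-test
   on the group indicator), on complete cases;
3. stratified variants: players split by race (White vs Black/Other), by
   number of chronic illnesses (0/1/2/3+), or by illness type (none /
   sleep apnea / pain / cardiometabolic; overlapping membership), each
   stratum compared to its reference stratum and to controls.

The default covariate set is age, race, education, employment status,
median yearly income, and domestic status.  No multiplicity correction is
applied to the primary p-values; a Benjamini-Hochberg column (``q_bh``)
is emitted as supplementary output only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import (
    CHRONIC_CONDITIONS,
    DOMESTIC_LEVELS,
    EDUCATION_LEVELS,
    EMPLOYMENT_LEVELS,
    EgoRecord,
    LIVING_LEVELS,
    RACES,
    validate_record,
)
from .structure import compute_structure
from .composition import compute_composition

logger = logging.getLogger("persnet")

STRUCTURE_METRICS = (
    "network_size",
    "density",
    "constraint",
    "effective_size",
    "max_degree",
    "mean_degree",
)
COMPOSITION_METRICS = (
    "pct_kin",
    "diversity_sex",
    "diversity_race",
    "pct_distant",
    "sd_ages",
    "pct_non_exercising",
    "pct_negative",
    "pct_played_football",
    "pct_nfl_with_participant",
    "majority_male_score",
    "same_race_proportion",
)
ALL_METRICS = STRUCTURE_METRICS + COMPOSITION_METRICS

#: metrics defined for one cohort only; dropped from two-cohort contrasts
PLAYER_ONLY_METRICS = ("pct_played_football", "pct_nfl_with_participant")


# ---------------------------------------------------------------------------
# Metrics frame: records -> one row per participant
# ---------------------------------------------------------------------------


def metrics_frame(
    records: Sequence[EgoRecord], include_unusable: bool = False
) -> tuple[pd.DataFrame, list]:
    """Compute per-ego metrics for a cohort.

    Returns ``(frame, reports)``: one metrics row per participant that
    passes quality control (all participants when ``include_unusable``),
    plus the full list of :class:`~persnet.io.ValidationReport`.  The frame
    carries the ego covariates needed downstream (adjustment,
    stratification) alongside the structure and composition metrics.
    """
    rows = []
    reports = []
    for rec in records:
        report = validate_record(rec)
        reports.append(report)
        if not (report.usable or include_unusable):
            continue
        row = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "age": rec.age,
            "race": rec.race,
            "education": rec.education,
            "employment": rec.employment,
            "income": rec.income,
            "domestic_status": rec.domestic_status,
            "living_situation": rec.living_situation,
            "chronic_condition": rec.has_chronic_condition,
            "n_chronic_conditions": rec.n_chronic_conditions,
        }
        for c in CHRONIC_CONDITIONS:
            row[f"chronic_{c}"] = (
                (c in rec.chronic_conditions) if rec.group == "player" else None
            )
        row.update(compute_structure(rec).as_dict())
        row.update(compute_composition(rec).as_dict())
        rows.append(row)
    return pd.DataFrame(rows), reports


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both sides have <= 8 observations and there are
    no ties; otherwise the normal approximation with tie correction.
    NaNs are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney requires non-empty samples on both sides")
    pooled = np.concatenate([x, y])
    exact = max(len(x), len(y)) <= 8 and len(np.unique(pooled)) == len(pooled)
    res = scipy.stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.pvalue)


class ChiSquared(NamedTuple):
    statistic: float
    pvalue: float
    dof: int


def chi_square(table) -> ChiSquared:
    """Pearson chi-squared test on an r x c contingency table.

    No continuity (Yates) correction by default, matching the general
    r x c case; margins with a zero total are a degenerate input.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table: a margin is all zero")
    stat, p, dof, _ = scipy.stats.chi2_contingency(t, correction=False)
    return ChiSquared(statistic=float(stat), pvalue=float(p), dof=int(dof))


# ---------------------------------------------------------------------------
# Descriptive table (baseline characteristics)
# ---------------------------------------------------------------------------

_CONTINUOUS_VARS = ("age", "income")
_CATEGORICAL_VARS = {
    "race": RACES,
    "education": EDUCATION_LEVELS,
    "employment": EMPLOYMENT_LEVELS,
    "domestic_status": DOMESTIC_LEVELS,
    "living_situation": LIVING_LEVELS,
    "chronic_condition": (True, False),
}


def _median_iqr(values) -> tuple[float, float, float] | None:
    v = np.asarray([x for x in values if x is not None], dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return None
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def descriptive_table(
    records: Sequence[EgoRecord], groups: tuple[str, str] = ("control", "player")
) -> pd.DataFrame:
    """Baseline characteristics per group, Table-1 style.

    Continuous covariates yield one row with median and quartiles per
    group plus a Mann-Whitney p; categoricals yield one row per level with
    count and percentage of non-missing plus a single chi-squared p
    (repeated on each level row).  Raises on an empty group.
    """
    by_group = {g: [r for r in records if r.group == g] for g in groups}
    for g, recs in by_group.items():
        if not recs:
            raise ValueError(f"empty group {g!r} in descriptive table")
    g1, g2 = groups
    rows = []

    def getval(rec, var):
        if var == "chronic_condition":
            return rec.has_chronic_condition
        return getattr(rec, var)

    for var in _CONTINUOUS_VARS:
        row = {"variable": var, "level": "", "test": "mann_whitney"}
        vals = {}
        for g in groups:
            vals[g] = [getval(r, var) for r in by_group[g] if getval(r, var) is not None]
            mq = _median_iqr(vals[g])
            if mq is None:
                row[f"{g}_median"] = row[f"{g}_q1"] = row[f"{g}_q3"] = np.nan
            else:
                row[f"{g}_median"], row[f"{g}_q1"], row[f"{g}_q3"] = mq
        try:
            row["p_value"] = mann_whitney(vals[g1], vals[g2])
        except ValueError:
            row["p_value"] = np.nan
        rows.append(row)

    for var, levels in _CATEGORICAL_VARS.items():
        counts = {
            g: {lev: sum(1 for r in by_group[g] if getval(r, var) == lev) for lev in levels}
            for g in groups
        }
        totals = {g: sum(counts[g].values()) for g in groups}  # non-missing only
        table = [
            [counts[g][lev] for lev in levels if counts[g1][lev] + counts[g2][lev] > 0]
            for g in groups
        ]
        try:
            p = chi_square(table).pvalue if len(table[0]) >= 2 else np.nan
        except ValueError:
            p = np.nan
        for lev in levels:
            lev_name = {True: "present", False: "not_present"}.get(lev, str(lev))
            row = {"variable": var, "level": lev_name, "test": "chi_square", "p_value": p}
            for g in groups:
                row[f"{g}_n"] = counts[g][lev]
                row[f"{g}_pct"] = (
                    100.0 * counts[g][lev] / totals[g] if totals[g] else np.nan
                )
            rows.append(row)

    cols = ["variable", "level"]
    for g in groups:
        cols += [f"{g}_n", f"{g}_pct", f"{g}_median", f"{g}_q1", f"{g}_q3"]
    cols += ["p_value", "test"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def nfl_contact_distribution(records: Sequence[EgoRecord]) -> pd.Series:
    """Players by number of alters flagged as NFL teammates/coaches.

    Returns participant counts indexed by the per-ego number of alters
    with ``played_nfl_with_participant`` True (blank items count as no).
    """
    players = [r for r in records if r.group == "player"]
    if not players:
        raise ValueError("no players in cohort")
    counts = pd.Series(
        [sum(1 for a in r.alters if a.played_nfl_with_participant is True) for r in players]
    )
    return counts.value_counts().sort_index()


def nfl_contact_share(records: Sequence[EgoRecord], exactly: int = 1) -> float:
    """Percentage of players with exactly ``exactly`` NFL-contact alters."""
    dist = nfl_contact_distribution(records)
    total = int(dist.sum())
    return 100.0 * int(dist.get(exactly, 0)) / total


# ---------------------------------------------------------------------------
# Covariate-adjusted comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    """Covariates of the adjusted model and their codings.

    Default: the six-covariate set — age (years, continuous), race (binary
    White vs non-White), education (ordered 1-5), employment (dummies with
    employed as reference), income (continuous, $1000s), domestic status
    (binary married).
    """

    names: tuple = (
        "age",
        "race",
        "education",
        "employment",
        "income",
        "domestic_status",
    )

    def build_design(self, df: pd.DataFrame) -> pd.DataFrame:
        """Numeric design columns (no intercept) from raw covariates."""
        out = {}
        for name in self.names:
            col = df[name]
            if name == "age":
                out["age"] = pd.to_numeric(col, errors="coerce")
            elif name == "race":
                out["race_white"] = col.map(
                    lambda v: np.nan if v is None or (isinstance(v, float) and np.isnan(v))
                    else float(v == "White")
                )
            elif name == "education":
                order = {lev: i + 1 for i, lev in enumerate(EDUCATION_LEVELS)}
                out["education_ord"] = col.map(lambda v: order.get(v, np.nan))
            elif name == "employment":
                for lev in EMPLOYMENT_LEVELS[1:]:  # employed is the reference
                    out[f"employment_{lev}"] = col.map(
                        lambda v, lev=lev: np.nan
                        if v is None or (isinstance(v, float) and np.isnan(v))
                        else float(v == lev)
                    )
            elif name == "income":
                out["income_k"] = pd.to_numeric(col, errors="coerce") / 1000.0
            elif name == "domestic_status":
                out["married"] = col.map(
                    lambda v: np.nan if v is None or (isinstance(v, float) and np.isnan(v))
                    else float(v == "married")
                )
            else:
                out[name] = pd.to_numeric(df[name], errors="coerce")
        return pd.DataFrame(out, index=df.index)


@dataclass
class ComparisonResult:
    """Per-metric group contrast."""

    metric: str
    contrast: str
    group1: str
    group2: str
    median1: float | None
    q1_1: float | None
    q3_1: float | None
    median2: float | None
    q1_2: float | None
    q3_2: float | None
    n1: int = 0
    n2: int = 0
    p_univariate: float = np.nan
    coef_adjusted: float = np.nan
    p_adjusted: float = np.nan
    n_used: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns past the numerical rank, by pivoted QR."""
    _, _, piv = scipy.linalg.qr(X, pivoting=True)
    rank = np.linalg.matrix_rank(X)
    return [names[i] for i in sorted(piv[rank:])]


def adjusted_comparison(
    metric_values,
    group_labels,
    covariates: pd.DataFrame,
    spec: CovariateSpec | None = None,
    metric_name: str = "metric",
    groups: tuple[str, str] | None = None,
) -> ComparisonResult:
    """Compare a metric between two groups, raw and covariate-adjusted.

    Fits OLS of the metric on a group indicator (second group = 1) plus
    the coded covariates, on complete cases; ``p_adjusted`` is the
    two-sided t-test on the group coefficient.  ``p_univariate`` is the
    Mann-Whitney p over all non-missing metric values.

    Raises
    ------
    ValueError
        If fewer complete cases than parameters + 2, or if the design is
        rank deficient (the message names the collinear columns).
    """
    spec = spec or CovariateSpec()
    y = pd.Series(np.asarray(metric_values, dtype=float)).reset_index(drop=True)
    g = pd.Series(list(group_labels)).reset_index(drop=True)
    cov = covariates.reset_index(drop=True)
    if groups is None:
        uniq = sorted(g.dropna().unique())
        if len(uniq) != 2:
            raise ValueError(f"expected exactly two groups, got {uniq}")
        groups = (uniq[0], uniq[1])
    g1, g2 = groups
    mask_groups = g.isin(groups)

    y1 = y[(g == g1) & y.notna()]
    y2 = y[(g == g2) & y.notna()]
    med1 = _median_iqr(y1) or (np.nan,) * 3
    med2 = _median_iqr(y2) or (np.nan,) * 3
    p_uni = mann_whitney(y1, y2) if len(y1) and len(y2) else np.nan

    X = spec.build_design(cov)
    X.insert(0, "group", (g == g2).astype(float))
    complete = mask_groups & y.notna() & X.notna().all(axis=1)
    Xc = X[complete]
    yc = y[complete]
    # a covariate level absent from the complete cases yields a constant
    # column; drop it (it is inestimable) rather than fail the whole fit
    constant = [c for c in Xc.columns[1:] if Xc[c].nunique() <= 1]
    if constant:
        logger.info("%s: dropping constant covariate column(s) %s", metric_name, constant)
        Xc = Xc.drop(columns=constant)
    n_params = Xc.shape[1] + 1  # + intercept
    if len(yc) < n_params + 2:
        raise ValueError(
            f"{metric_name}: only {len(yc)} complete cases for {n_params} parameters"
        )
    Xmat = sm.add_constant(Xc, has_constant="add")
    if np.linalg.matrix_rank(Xmat.values) < Xmat.shape[1]:
        bad = _collinear_columns(Xmat.values, list(Xmat.columns))
        raise ValueError(f"{metric_name}: rank-deficient design, collinear columns {bad}")
    fit = sm.OLS(yc.values, Xmat).fit()

    return ComparisonResult(
        metric=metric_name,
        contrast=f"{g2} vs {g1}",
        group1=g1,
        group2=g2,
        median1=med1[0],
        q1_1=med1[1],
        q3_1=med1[2],
        median2=med2[0],
        q1_2=med2[1],
        q3_2=med2[2],
        n1=int(len(y1)),
        n2=int(len(y2)),
        p_univariate=p_uni,
        coef_adjusted=float(fit.params["group"]),
        p_adjusted=float(fit.pvalues["group"]),
        n_used=int(len(yc)),
    )


def compare_cohorts(
    frame: pd.DataFrame,
    spec: CovariateSpec | None = None,
    metrics: Sequence[str] | None = None,
    groups: tuple[str, str] = ("control", "player"),
    contrast_label: str | None = None,
) -> pd.DataFrame:
    """Per-metric two-group comparisons over a metrics frame.

    Skips metrics missing for a whole group (e.g. football percentages in
    a player-vs-control contrast) and appends a supplementary
    Benjamini-Hochberg ``q_bh`` column over the adjusted p-values; the
    primary p-values are uncorrected.
    """
    spec = spec or CovariateSpec()
    if metrics is None:
        metrics = [m for m in ALL_METRICS if m in frame.columns]
    rows = []
    for m in metrics:
        sub = frame[frame["group"].isin(groups)]
        per_group_n = sub.groupby("group")[m].apply(lambda s: s.notna().sum())
        if any(per_group_n.get(g, 0) == 0 for g in groups):
            logger.info("skipping metric %s: missing for an entire group", m)
            continue
        try:
            res = adjusted_comparison(
                sub[m],
                sub["group"],
                sub,
                spec=spec,
                metric_name=m,
                groups=groups,
            )
        except ValueError as exc:
            logger.warning("skipping metric %s: %s", m, exc)
            continue
        if contrast_label:
            res.contrast = contrast_label
        rows.append(res.as_dict())
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["p_adjusted"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.values] = multipletests(out.loc[ok, "p_adjusted"], method="fdr_bh")[1]
        out["q_bh"] = q
    return out


# ---------------------------------------------------------------------------
# Stratified comparisons
# ---------------------------------------------------------------------------

STRATA_RULES = ("race_2way", "illness_count", "illness_type")


def _race_stratum(race) -> str | None:
    if race is None or (isinstance(race, float) and np.isnan(race)):
        return None
    return "White" if race == "White" else "Black/Other"


def stratified_comparison(
    frame: pd.DataFrame,
    strata_rule: str,
    spec: CovariateSpec | None = None,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stratified contrasts within the players cohort (plus vs controls).

    * ``race_2way`` — players split White vs Black/Other; contrasts:
      Black/Other vs White players, and each player stratum vs controls;
    * ``illness_count`` — players with 1, 2, and 3+ chronic conditions,
      each vs players with none;
    * ``illness_type`` — players with sleep apnea, pain, cardiometabolic
      conditions (overlapping membership allowed), each vs players with no
      condition.

    Empty strata are skipped with a log entry.  Race is dropped from the
    adjustment covariates in ``race_2way`` (it defines the strata).
    """
    spec = spec or CovariateSpec()
    if strata_rule not in STRATA_RULES:
        raise ValueError(f"unknown strata rule {strata_rule!r} (use one of {STRATA_RULES})")
    players = frame[frame["group"] == "player"].copy()
    controls = frame[frame["group"] == "control"].copy()
    results = []

    def contrast(sub: pd.DataFrame, label_col: str, pair: tuple[str, str], name: str, cspec):
        counts = sub[label_col].value_counts()
        if any(counts.get(p, 0) == 0 for p in pair):
            logger.info("skipping stratified contrast %s: empty stratum", name)
            return None
        if label_col != "group":
            sub = sub.drop(columns=["group"]).rename(columns={label_col: "group"})
        try:
            return compare_cohorts(
                sub,
                spec=cspec,
                metrics=metrics,
                groups=pair,
                contrast_label=name,
            )
        except ValueError as exc:
            logger.warning("skipping stratified contrast %s: %s", name, exc)
            return None

    if strata_rule == "race_2way":
        cspec = CovariateSpec(tuple(n for n in spec.names if n != "race"))
        players["stratum"] = players["race"].map(_race_stratum)
        players = players[players["stratum"].notna()]
        results.append(
            contrast(players, "stratum", ("White", "Black/Other"), "Black/Other vs White players", cspec)
        )
        for s in ("White", "Black/Other"):
            sub = pd.concat(
                [controls.assign(stratum="control"), players[players["stratum"] == s]]
            )
            results.append(
                contrast(sub, "stratum", ("control", s), f"{s} players vs controls", cspec)
            )
    elif strata_rule == "illness_count":
        def bucket(n):
            if n is None or (isinstance(n, float) and np.isnan(n)):
                return None
            n = int(n)
            return "0" if n == 0 else "1" if n == 1 else "2" if n == 2 else "3+"

        players["stratum"] = players["n_chronic_conditions"].map(bucket)
        for s in ("1", "2", "3+"):
            sub = players[players["stratum"].isin(["0", s])]
            results.append(
                contrast(sub, "stratum", ("0", s), f"{s} conditions vs none", spec)
            )
    else:  # illness_type; membership may overlap across types
        none = players[players["n_chronic_conditions"] == 0].assign(stratum="none")
        for cond, label in (
            ("sleep", "sleep apnea"),
            ("pain", "pain"),
            ("cardiometabolic", "cardiometabolic"),
        ):
            has = players[players[f"chronic_{cond}"] == True].assign(stratum=label)  # noqa: E712
            sub = pd.concat([none, has])
            results.append(
                contrast(sub, "stratum", ("none", label), f"{label} vs no condition", spec)
            )

    results = [r for r in results if r is not None and len(r)]
    if not results:
        return pd.DataFrame()
    return pd.concat(results, ignore_index=True)
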