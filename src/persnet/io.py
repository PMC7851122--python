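"""Parsing, validation and serialization of PERSNET-style ego-network records.

A personal (egocentric) network survey record has three sections:

* ego covariates — demographics and health status of the participant;
* an ordered alter roster of unlimited length (the "name generator" plus
  "name interpreter" sections), one sub-record per named network member;
* a tie section (the "name inter-relater") giving presence/strength of the
  connections among the first 10 alters only.

This module defines the in-memory types (:class:`EgoRecord`,
:class:`AlterRecord`, :class:`TieMatrix`, :class:`ValidationReport`), a flat
wide-CSV dialect for survey exports, quality-control validation, per-ego graph
export (GraphML / edge list via networkx), and the metrics table writer.

Wide-CSV dialect
----------------
One row per participant.  Ego columns::

    participant_id, group, age, race, education, employment, income,
    domestic_status, living_situation, n_alters,
    chronic_neurocognitive, chronic_pain, chronic_cardiometabolic,
    chronic_sleep,            # players: 0/1 flags per affliction type
    chronic_present           # controls: single 0/1 flag

Alter columns, for i = 1..max roster length present in the header::

    alter{i}_sex, alter{i}_race, alter{i}_age, alter{i}_kin,
    alter{i}_distant, alter{i}_non_exercising, alter{i}_negative_influence,
    alter{i}_played_organized_football, alter{i}_played_nfl_with_participant

Tie columns ``tie_{i}_{j}`` for 1 <= i < j <= 10 with values in
{0 = no tie, 1 = tie, 2 = especially close}; blank cells in an otherwise
present tie section read as 0; a fully blank tie section reads as missing.
If both ``tie_i_j`` and ``tie_j_i`` appear and disagree, the maximum is kept
and the record is flagged ``asymmetric_ties_repaired`` (conservative
presence coding).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger("persnet")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

GROUPS = ("player", "control")
RACES = ("White", "Black", "Other")
SEXES = ("male", "female")
EDUCATION_LEVELS = (
    "high_school_or_less",
    "some_college",
    "associate_degree",
    "bachelors_degree",
    "graduate_degree",
)
EMPLOYMENT_LEVELS = ("employed", "student", "retired", "unemployed")
DOMESTIC_LEVELS = ("married", "not_married")
LIVING_LEVELS = ("with_others", "alone")
CHRONIC_CONDITIONS = ("neurocognitive", "pain", "cardiometabolic", "sleep")

#: the tie section covers only the first this-many alters
MAX_TIE_ALTERS = 10

#: declared mapping from finer free-text race codes to the three analysis
#: categories; matching is case-insensitive, unknown codes are a parse error
RACE_MAP = {
    "white": "White",
    "caucasian": "White",
    "black": "Black",
    "african american": "Black",
    "african-american": "Black",
    "asian": "Other",
    "hispanic": "Other",
    "latino": "Other",
    "native american": "Other",
    "pacific islander": "Other",
    "mixed": "Other",
    "other": "Other",
}

ALTER_FIELDS = (
    "sex",
    "race",
    "age",
    "kin",
    "distant",
    "non_exercising",
    "negative_influence",
    "played_organized_football",
    "played_nfl_with_participant",
)

_AGE_RANGE = (0.0, 120.0)  # ages outside are treated as inaccurate data


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AlterRecord:
    """One named network member (alter) and their interpreter attributes.

    Every attribute is tri-state: the surveyed value, or ``None`` when the
    participant left the item blank.  The two football-affiliation items are
    asked of the players cohort only and stay ``None`` for controls.
    """

    sex: str | None = None
    race: str | None = None
    age: float | None = None
    kin: bool | None = None
    distant: bool | None = None
    non_exercising: bool | None = None
    negative_influence: bool | None = None
    played_organized_football: bool | None = None
    played_nfl_with_participant: bool | None = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"bad alter sex {self.sex!r}")
        if self.race is not None and self.race not in RACES:
            raise ValueError(f"bad alter race {self.race!r}")


@dataclass(frozen=True)
class TieMatrix:
    """Symmetric alter-alter tie strengths over the first min(n, 10) alters.

    Entries take values 0 (no tie), 1 (tie) or 2 (especially close); the
    diagonal is undefined and stored as 0.  ``repaired`` records that an
    asymmetric input was symmetrized by keeping the pairwise maximum.
    """

    strengths: np.ndarray
    repaired: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.strengths, dtype=int)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("tie matrix must be square")
        if s.shape[0] > MAX_TIE_ALTERS:
            raise ValueError(f"tie matrix covers at most {MAX_TIE_ALTERS} alters")
        if not np.isin(s, (0, 1, 2)).all():
            raise ValueError("tie strengths must be in {0, 1, 2}")
        np.fill_diagonal(s, 0)
        if not (s == s.T).all():
            raise ValueError("tie matrix must be symmetric (use from_entries to repair)")
        object.__setattr__(self, "strengths", s)

    @property
    def k(self) -> int:
        return self.strengths.shape[0]

    @classmethod
    def from_entries(cls, k: int, entries: dict[tuple[int, int], int]) -> "TieMatrix":
        """Build from sparse 1-based ``(i, j) -> strength`` entries.

        Disagreeing ``(i, j)``/``(j, i)`` duplicates are resolved by the
        maximum and flagged via ``repaired``.
        """
        s = np.zeros((k, k), dtype=int)
        repaired = False
        seen: dict[tuple[int, int], int] = {}
        for (i, j), v in entries.items():
            if i == j:
                continue
            key = (min(i, j) - 1, max(i, j) - 1)
            if key in seen and seen[key] != v:
                repaired = True
            seen[key] = max(seen.get(key, 0), int(v))
        for (a, b), v in seen.items():
            s[a, b] = s[b, a] = v
        return cls(strengths=s, repaired=repaired)

    def dichotomized(self) -> np.ndarray:
        """Binary presence matrix: 1 iff strength >= 1."""
        return (self.strengths >= 1).astype(int)

    def tie_count(self) -> int:
        """Number of distinct alter-alter ties (presence-coded)."""
        return int(self.dichotomized().sum() // 2)


@dataclass
class EgoRecord:
    """One participant: ego covariates, alter roster and tie section."""

    participant_id: str
    group: str
    age: float | None = None
    race: str | None = None
    education: str | None = None
    employment: str | None = None
    income: float | None = None
    domestic_status: str | None = None
    living_situation: str | None = None
    #: players: set of affliction types drawn from CHRONIC_CONDITIONS
    chronic_conditions: frozenset = frozenset()
    #: controls: the single "any chronic condition" flag
    chronic_present: bool | None = None
    alters: list = field(default_factory=list)
    ties: TieMatrix | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"bad group {self.group!r}")
        bad = set(self.chronic_conditions) - set(CHRONIC_CONDITIONS)
        if bad:
            raise ValueError(f"unknown chronic condition(s) {sorted(bad)}")
        self.chronic_conditions = frozenset(self.chronic_conditions)

    @property
    def network_size(self) -> int:
        """Number of rostered alters — the full roster, no ceiling."""
        return len(self.alters)

    @property
    def tie_alter_count(self) -> int:
        """Number of alters covered by the tie section: min(n, 10)."""
        return min(self.network_size, MAX_TIE_ALTERS)

    @property
    def has_chronic_condition(self) -> bool | None:
        """Unified chronic-condition indicator across the two cohorts."""
        if self.group == "player":
            return len(self.chronic_conditions) > 0
        return self.chronic_present

    @property
    def n_chronic_conditions(self) -> int | None:
        if self.group == "player":
            return len(self.chronic_conditions)
        if self.chronic_present is None:
            return None
        return int(self.chronic_present)


@dataclass
class ValidationReport:
    """Quality-control outcome for one record.

    ``usable`` is False iff any of the disqualifying flags {incomplete,
    inaccurate, nonexistent_network} is present; ``size_lt_2`` and
    ``asymmetric_ties_repaired`` are informational only.
    """

    participant_id: str
    flags: frozenset = frozenset()

    VALID_FLAGS = frozenset(
        {
            "incomplete",
            "inaccurate",
            "nonexistent_network",
            "asymmetric_ties_repaired",
            "size_lt_2",
        }
    )
    _DISQUALIFYING = frozenset({"incomplete", "inaccurate", "nonexistent_network"})

    def __post_init__(self) -> None:
        self.flags = frozenset(self.flags)
        bad = self.flags - self.VALID_FLAGS
        if bad:
            raise ValueError(f"unknown validation flag(s) {sorted(bad)}")

    @property
    def usable(self) -> bool:
        return not (self.flags & self._DISQUALIFYING)


# ---------------------------------------------------------------------------
# Cell-level parsing helpers
# ---------------------------------------------------------------------------


def _is_blank(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


def _parse_bool(v, col: str) -> bool | None:
    if _is_blank(v):
        return None
    s = str(v).strip().lower()
    if s in {"1", "true", "yes", "1.0"}:
        return True
    if s in {"0", "false", "no", "0.0"}:
        return False
    raise ValueError(f"malformed boolean {v!r} in column {col}")


def _parse_float(v, col: str) -> float | None:
    if _is_blank(v):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ValueError(f"malformed number {v!r} in column {col}") from None


def _parse_cat(v, levels: Sequence[str], col: str) -> str | None:
    if _is_blank(v):
        return None
    s = str(v).strip()
    for lev in levels:
        if s.lower() == lev.lower():
            return lev
    raise ValueError(f"malformed code {v!r} in column {col} (expected one of {levels})")


def _parse_race(v, col: str) -> str | None:
    if _is_blank(v):
        return None
    s = str(v).strip().lower()
    if s in RACE_MAP:
        return RACE_MAP[s]
    raise ValueError(f"unknown race code {v!r} in column {col}")


# ---------------------------------------------------------------------------
# Survey table parsing
# ---------------------------------------------------------------------------


def _roster_length(row: pd.Series, alter_indices: Sequence[int]) -> int:
    if "n_alters" in row.index and not _is_blank(row["n_alters"]):
        n = int(float(row["n_alters"]))
        if n < 0:
            raise ValueError("n_alters must be >= 0")
        return n
    # fall back: largest alter index with any non-missing attribute
    n = 0
    for i in alter_indices:
        if any(not _is_blank(row.get(f"alter{i}_{f}")) for f in ALTER_FIELDS):
            n = max(n, i)
    return n


def _parse_alter(row: pd.Series, i: int) -> AlterRecord:
    def get(f):
        return row.get(f"alter{i}_{f}")

    return AlterRecord(
        sex=_parse_cat(get("sex"), SEXES, f"alter{i}_sex"),
        race=_parse_race(get("race"), f"alter{i}_race"),
        age=_parse_float(get("age"), f"alter{i}_age"),
        kin=_parse_bool(get("kin"), f"alter{i}_kin"),
        distant=_parse_bool(get("distant"), f"alter{i}_distant"),
        non_exercising=_parse_bool(get("non_exercising"), f"alter{i}_non_exercising"),
        negative_influence=_parse_bool(
            get("negative_influence"), f"alter{i}_negative_influence"
        ),
        played_organized_football=_parse_bool(
            get("played_organized_football"), f"alter{i}_played_organized_football"
        ),
        played_nfl_with_participant=_parse_bool(
            get("played_nfl_with_participant"), f"alter{i}_played_nfl_with_participant"
        ),
    )


def _parse_ties(row: pd.Series, k: int) -> TieMatrix | None:
    """Read the tie section over the first ``k`` (<=10) alters.

    Returns None when every relevant cell is blank (tie section missing);
    for k == 1 the tie section is trivially present (there are no pairs).
    """
    if k == 0:
        return None
    if k == 1:
        return TieMatrix(np.zeros((1, 1), dtype=int))
    entries: dict[tuple[int, int], int] = {}
    any_present = False
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            if i == j:
                continue
            col = f"tie_{i}_{j}"
            if col not in row.index or _is_blank(row[col]):
                continue
            v = int(float(row[col]))
            if v not in (0, 1, 2):
                raise ValueError(f"malformed tie strength {row[col]!r} in column {col}")
            any_present = True
            entries[(i, j)] = v
    if not any_present:
        return None
    return TieMatrix.from_entries(k, entries)


def _parse_row(row: pd.Series, alter_indices: Sequence[int]) -> EgoRecord:
    pid = str(row["participant_id"]).strip()
    if pid == "" or _is_blank(row["participant_id"]):
        raise ValueError("missing participant_id")
    group = _parse_cat(row.get("group"), GROUPS, "group")
    if group is None:
        raise ValueError("missing group")

    if group == "player":
        chronic = frozenset(
            c for c in CHRONIC_CONDITIONS if _parse_bool(row.get(f"chronic_{c}"), f"chronic_{c}")
        )
        chronic_present = None
    else:
        chronic = frozenset()
        chronic_present = _parse_bool(row.get("chronic_present"), "chronic_present")

    n = _roster_length(row, alter_indices)
    alters = [_parse_alter(row, i) for i in range(1, n + 1)]
    if group == "control":
        for a in alters:  # football items are not asked of controls
            a.played_organized_football = None
            a.played_nfl_with_participant = None
    ties = _parse_ties(row, min(n, MAX_TIE_ALTERS))

    return EgoRecord(
        participant_id=pid,
        group=group,
        age=_parse_float(row.get("age"), "age"),
        race=_parse_race(row.get("race"), "race"),
        education=_parse_cat(row.get("education"), EDUCATION_LEVELS, "education"),
        employment=_parse_cat(row.get("employment"), EMPLOYMENT_LEVELS, "employment"),
        income=_parse_float(row.get("income"), "income"),
        domestic_status=_parse_cat(row.get("domestic_status"), DOMESTIC_LEVELS, "domestic_status"),
        living_situation=_parse_cat(row.get("living_situation"), LIVING_LEVELS, "living_situation"),
        chronic_conditions=chronic,
        chronic_present=chronic_present,
        alters=alters,
        ties=ties,
    )


def parse_survey_table(table: pd.DataFrame, on_error: str = "log") -> list[EgoRecord]:
    """Parse a wide-CSV survey export into :class:`EgoRecord` objects.

    Parameters
    ----------
    table
        One row per participant, columns per the module-level dialect.
    on_error
        ``"log"`` (default): rows with malformed cells are skipped with a
        logged parse error; ``"raise"``: the first malformed row raises.

    Raises
    ------
    ValueError
        On duplicate ``participant_id`` (always), or on any malformed row
        when ``on_error="raise"``.
    """
    if "participant_id" not in table.columns or "group" not in table.columns:
        raise ValueError("survey table must have participant_id and group columns")
    alter_indices = sorted(
        {
            int(c.split("_")[0][5:])
            for c in table.columns
            if c.startswith("alter") and c.split("_")[0][5:].isdigit()
        }
    )
    records: list[EgoRecord] = []
    seen: set[str] = set()
    for idx, row in table.iterrows():
        try:
            rec = _parse_row(row, alter_indices)
        except ValueError as exc:
            if on_error == "raise":
                raise ValueError(f"row {idx}: {exc}") from exc
            logger.warning("skipping row %s: %s", idx, exc)
            continue
        if rec.participant_id in seen:
            raise ValueError(f"duplicate participant_id {rec.participant_id!r}")
        seen.add(rec.participant_id)
        records.append(rec)
    return records


def read_survey_csv(path, on_error: str = "log") -> list[EgoRecord]:
    """Read a wide-CSV survey file (UTF-8, header row) into records."""
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    return parse_survey_table(table, on_error=on_error)


# ---------------------------------------------------------------------------
# Serialization back to the wide dialect (round-trip support)
# ---------------------------------------------------------------------------


def _fmt_bool(v: bool | None) -> str:
    return "" if v is None else str(int(v))


def _fmt_num(v: float | None) -> str:
    if v is None:
        return ""
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def records_to_table(records: Sequence[EgoRecord]) -> pd.DataFrame:
    """Serialize records to the wide-CSV dialect (inverse of parsing).

    Column order is stable: ego block, alter blocks up to the longest
    roster, then tie columns ``tie_i_j`` (i < j) up to the largest tie
    section present.
    """
    max_alters = max((r.network_size for r in records), default=0)
    max_k = max((r.ties.k if r.ties is not None else 0 for r in records), default=0)
    cols = [
        "participant_id",
        "group",
        "age",
        "race",
        "education",
        "employment",
        "income",
        "domestic_status",
        "living_situation",
        "n_alters",
        *(f"chronic_{c}" for c in CHRONIC_CONDITIONS),
        "chronic_present",
    ]
    for i in range(1, max_alters + 1):
        cols.extend(f"alter{i}_{f}" for f in ALTER_FIELDS)
    for i in range(1, max_k + 1):
        for j in range(i + 1, max_k + 1):
            cols.append(f"tie_{i}_{j}")

    rows = []
    for r in records:
        d = {c: "" for c in cols}
        d["participant_id"] = r.participant_id
        d["group"] = r.group
        d["age"] = _fmt_num(r.age)
        d["race"] = r.race or ""
        d["education"] = r.education or ""
        d["employment"] = r.employment or ""
        d["income"] = _fmt_num(r.income)
        d["domestic_status"] = r.domestic_status or ""
        d["living_situation"] = r.living_situation or ""
        d["n_alters"] = str(r.network_size)
        if r.group == "player":
            for c in CHRONIC_CONDITIONS:
                d[f"chronic_{c}"] = str(int(c in r.chronic_conditions))
        else:
            d["chronic_present"] = _fmt_bool(r.chronic_present)
        for i, a in enumerate(r.alters, start=1):
            d[f"alter{i}_sex"] = a.sex or ""
            d[f"alter{i}_race"] = a.race or ""
            d[f"alter{i}_age"] = _fmt_num(a.age)
            for f in ALTER_FIELDS[3:]:
                d[f"alter{i}_{f}"] = _fmt_bool(getattr(a, f))
        if r.ties is not None:
            for i in range(1, r.ties.k + 1):
                for j in range(i + 1, r.ties.k + 1):
                    d[f"tie_{i}_{j}"] = str(int(r.ties.strengths[i - 1, j - 1]))
    # a k==1 tie section has no pair cells; roster length disambiguates
        rows.append(d)
    return pd.DataFrame(rows, columns=cols, dtype=str)


def write_survey_csv(records: Sequence[EgoRecord], path) -> None:
    records_to_table(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Quality-control validation
# ---------------------------------------------------------------------------


def validate_record(record: EgoRecord) -> ValidationReport:
    """Classify a record per the quality-control rules.

    Total: never raises.  Flags:

    * ``nonexistent_network`` — empty roster;
    * ``incomplete`` — some alter lacks sex AND race AND kin, or the tie
      section is missing while the roster has >= 2 members;
    * ``inaccurate`` — an ego or alter age outside the plausible [0, 120]
      range (the only inaccuracy detectable without re-contact);
    * ``size_lt_2`` — informational; such records are excluded from the
      homogeneity (majority-male / same-race) montage scores;
    * ``asymmetric_ties_repaired`` — informational, from tie symmetrization.
    """
    flags: set[str] = set()
    if record.network_size == 0:
        flags.add("nonexistent_network")
    else:
        if any(a.sex is None and a.race is None and a.kin is None for a in record.alters):
            flags.add("incomplete")
        if record.network_size >= 2 and record.ties is None:
            flags.add("incomplete")
        if record.network_size < 2:
            flags.add("size_lt_2")
    ages = [record.age] + [a.age for a in record.alters]
    if any(a is not None and not (_AGE_RANGE[0] <= a <= _AGE_RANGE[1]) for a in ages):
        flags.add("inaccurate")
    if record.ties is not None and record.ties.repaired:
        flags.add("asymmetric_ties_repaired")
    return ValidationReport(participant_id=record.participant_id, flags=frozenset(flags))


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------


def export_graph(record: EgoRecord, include_ego: bool = True) -> nx.Graph:
    """Build the per-ego graph: alter nodes with attributes, tie edges.

    Alter-alter edges exist among the first min(n, 10) alters wherever the
    (dichotomized) tie section records a tie, with the raw strength as an
    edge attribute.  With ``include_ego`` an ``"ego"`` node is added and
    connected to every rostered alter (the survey defines every named alter
    as an ego contact).

    Raises
    ------
    ValueError
        If the roster is empty.
    """
    if record.network_size == 0:
        raise ValueError("cannot export a graph for an empty roster")
    G = nx.Graph()
    for i, a in enumerate(record.alters, start=1):
        attrs = {f: getattr(a, f) for f in ALTER_FIELDS}
        attrs = {k: v for k, v in attrs.items() if v is not None}
        G.add_node(f"a{i}", **attrs)
    if record.ties is not None:
        s = record.ties.strengths
        for i in range(record.ties.k):
            for j in range(i + 1, record.ties.k):
                if s[i, j] >= 1:
                    G.add_edge(f"a{i+1}", f"a{j+1}", strength=int(s[i, j]))
    if include_ego:
        G.add_node("ego", role="ego")
        for i in range(1, record.network_size + 1):
            G.add_edge("ego", f"a{i}")
    return G


def write_graph(record: EgoRecord, path, include_ego: bool = True, fmt: str = "graphml") -> None:
    """Write the per-ego graph as GraphML or a 2-column TSV edge list."""
    G = export_graph(record, include_ego=include_ego)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for u, v in G.edges():
                w.writerow([u, v])
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


# ---------------------------------------------------------------------------
# Metrics table
# ---------------------------------------------------------------------------


def write_metrics_table(bundles: Iterable[dict], path) -> pd.DataFrame:
    """Write per-ego metric bundles as a CSV: one row per participant.

    All bundles must share the same key set (schema); the column order is
    the key order of the first bundle.  Missing metric values (``None`` /
    NaN) are encoded as empty cells.  Returns the DataFrame written.
    """
    bundles = list(bundles)
    if not bundles:
        raise ValueError("no metric bundles to write")
    schema = list(bundles[0].keys())
    for b in bundles:
        if list(b.keys()) != schema:
            raise ValueError(
                f"metric bundle schema mismatch: {sorted(set(schema) ^ set(b.keys()))}"
            )
    df = pd.DataFrame(bundles, columns=schema)
    df.to_csv(path, index=False, na_rep="")
    return df


def read_metrics_table(path) -> pd.DataFrame:
    """Read a metrics CSV written by :func:`write_metrics_table`."""
    return pd.read_csv(path)
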