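"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive, loop-level transcriptions of the
published formulas (Burt's constraint and effective size, the index of
qualitative variation, permutation enumeration for the rank-sum test) so
the package implementations can be checked against a fully independent
route.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from persnet import AlterRecord, EgoRecord, TieMatrix


# ---------------------------------------------------------------------------
# Record builders
# ---------------------------------------------------------------------------


def make_alter(**kw) -> AlterRecord:
    return AlterRecord(**kw)


def make_record(
    n_alters=4,
    strengths=None,
    group="player",
    pid="P0001",
    alter_kw=None,
    **ego_kw,
) -> EgoRecord:
    """A minimal well-formed record: n alters, optional tie matrix."""
    alters = [
        AlterRecord(sex="male", race="White", age=50.0, kin=(i % 2 == 0), **(alter_kw or {}))
        for i in range(n_alters)
    ]
    if strengths is None and n_alters >= 1:
        k = min(n_alters, 10)
        strengths = np.zeros((k, k), dtype=int)
    ties = TieMatrix(strengths) if strengths is not None else None
    return EgoRecord(
        participant_id=pid,
        group=group,
        age=ego_kw.pop("age", 55.0),
        race=ego_kw.pop("race", "White"),
        education=ego_kw.pop("education", "bachelors_degree"),
        employment=ego_kw.pop("employment", "employed"),
        income=ego_kw.pop("income", 70000.0),
        domestic_status=ego_kw.pop("domestic_status", "married"),
        living_situation=ego_kw.pop("living_situation", "with_others"),
        alters=alters,
        ties=ties,
        **ego_kw,
    )


def random_tie_matrix(rng: np.random.Generator, k: int) -> TieMatrix:
    s = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            s[i, j] = s[j, i] = rng.integers(0, 3)
    return TieMatrix(s)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def oracle_constraint(ties: TieMatrix, binary: bool = False) -> float:
    """Burt constraint of the ego, x100, by literal triple loop.

    Node 0 is the ego with unit weights to every alter; alter-alter weights
    are the raw strengths (or presence when ``binary``).
    """
    k = ties.k
    s = ties.dichotomized() if binary else ties.strengths
    n = k + 1
    z = np.zeros((n, n), dtype=float)
    for j in range(1, n):
        z[0][j] = z[j][0] = 1.0
    for i in range(1, n):
        for j in range(1, n):
            if i != j:
                z[i][j] = float(s[i - 1][j - 1])

    def p(i, j):
        denom = sum(z[i][q] + z[q][i] for q in range(n) if q != i)
        return (z[i][j] + z[j][i]) / denom

    total = 0.0
    for j in range(1, n):
        indirect = sum(p(0, q) * p(q, j) for q in range(1, n) if q != j)
        total += (p(0, j) + indirect) ** 2
    return 100.0 * total


def oracle_effective_size_binary(ties: TieMatrix) -> float:
    """Effective size as roster size minus mean alter-alter degree."""
    k = ties.k
    d = ties.dichotomized()
    degrees = [sum(d[i][j] for j in range(k)) for i in range(k)]
    return k - sum(degrees) / k


def oracle_iqv(labels, categories) -> float:
    K = len(categories)
    counted = [x for x in labels if x is not None]
    props = [sum(1 for x in counted if x == c) / len(counted) for c in categories]
    return (K / (K - 1)) * (1 - sum(p * p for p in props))


def oracle_mannwhitney_exact(x, y) -> float:
    """Two-sided exact p by enumerating all label assignments.

    Statistic: the min-side U; p = share of assignments with a U at least
    as extreme (as small) on either side.  Valid without ties.
    """
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_stat(xs, ys):
        u = sum(1 for a in xs for b in ys if a > b)
        return u

    u_obs = u_stat(x, y)
    u_min_obs = min(u_obs, nx * len(y) - u_obs)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        if min(u, nx * len(ys) - u) <= u_min_obs:
            count += 1
        total += 1
    return count / total
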