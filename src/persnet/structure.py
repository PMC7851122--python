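"""Per-ego network structure metrics.

Six quantities describe the arrangement of ties in a personal network:

* **network size** — number of rostered alters (full roster, no ceiling);
* **density** — realized fraction of the k(k-1)/2 possible alter-alter ties
  among the first k = min(n, 10) alters, presence-coded;
* **constraint** (Burt) — the extent to which the ego's contacts are
  invested in one another; high constraint means a closed, redundant
  network.  Reported on a x100 scale;
* **effective size** — number of non-redundant alters; the binary
  (Borgatti) simplification is k - 2t/k with t the alter-alter tie count;
* **maximum / mean degree** — over the alter-alter presence subgraph, with
  the ego excluded both as a node and from the counts.

Constraint is computed on the ego-plus-alters graph with unit ego-alter
weights and, by default, the raw {0,1,2} tie strengths between alters
(constraint is the one metric that uses strength of ties; everything else
is presence-coded).  With proportional investments

    p_ij = (z_ij + z_ji) / sum_q (z_iq + z_qi),      q over i's contacts,

the dyadic constraint of the ego e with respect to alter j is

    c_ej = (p_ej + sum_{q != e,j} p_eq * p_qj)^2

and the reported score is 100 * sum_j c_ej.  Closed forms used as test
anchors: a star egonet (no alter-alter ties) gives 100/k; a complete binary
egonet gives 100 * (2k-1)^2 / k^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EgoRecord, TieMatrix, MAX_TIE_ALTERS


@dataclass(frozen=True)
class StructureMetrics:
    """The six per-ego structural quantities (missing values are None)."""

    network_size: int
    density: float | None
    constraint: float | None
    effective_size: float | None
    max_degree: int | None
    mean_degree: float | None

    def as_dict(self) -> dict:
        return {
            "network_size": self.network_size,
            "density": self.density,
            "constraint": self.constraint,
            "effective_size": self.effective_size,
            "max_degree": self.max_degree,
            "mean_degree": self.mean_degree,
        }


def dichotomized_ties(ties: TieMatrix) -> np.ndarray:
    """Presence-coded tie matrix: entry 1 iff strength >= 1."""
    return ties.dichotomized()


def network_size(record: EgoRecord) -> int:
    """Number of individuals in the network, excluding the participant.

    Counts the full roster; the 10-alter cap applies only to the tie
    section, not to size.
    """
    return record.network_size


def density(ties: TieMatrix) -> float | None:
    """Actual / possible alter-alter connections, ego excluded.

    Presence-coded; undefined (None) for fewer than two alters.
    """
    k = ties.k
    if k < 2:
        return None
    return ties.tie_count() / (k * (k - 1) / 2)


def _weight_matrix(ties: TieMatrix, tie_weights: str) -> np.ndarray:
    """Symmetric (k+1)x(k+1) weights: node 0 = ego, unit ego-alter weights."""
    if tie_weights == "raw":
        s = ties.strengths.astype(float)
    elif tie_weights == "binary":
        s = ties.dichotomized().astype(float)
    else:
        raise ValueError(f"unknown tie_weights {tie_weights!r}")
    k = ties.k
    W = np.zeros((k + 1, k + 1))
    W[0, 1:] = W[1:, 0] = 1.0
    W[1:, 1:] = s
    return W


def burt_constraint(ties: TieMatrix, tie_weights: str = "raw") -> float | None:
    """Burt's constraint of the ego, x100.

    ``tie_weights="raw"`` (default) uses the {0,1,2} strengths between
    alters; ``"binary"`` uses presence coding.  Ego-alter weights are 1
    either way.  Undefined (None) for an empty network.
    """
    k = ties.k
    if k == 0:
        return None
    W = _weight_matrix(ties, tie_weights)
    M = W + W.T
    P = M / M.sum(axis=1, keepdims=True)  # rows: proportional investment
    p_e = P[0]  # ego's investments; p_e[0] == 0
    total = 0.0
    for j in range(1, k + 1):
        indirect = p_e @ P[:, j] - p_e[0] * P[0, j] - p_e[j] * P[j, j]
        total += (p_e[j] + indirect) ** 2
    return 100.0 * total


def effective_size(ties: TieMatrix, method: str = "borgatti") -> float | None:
    """Number of non-redundant network members.

    ``method="borgatti"`` (default): the binary simplification k - 2t/k on
    presence-coded ties.  ``method="burt"``: Burt's weighted redundancy sum
    sum_j (1 - sum_{q != e,j} p_eq * m_jq) with marginal tie strengths
    m_jq = (z_jq + z_qj) / max_l (z_jl + z_lj), using raw strengths.
    Undefined (None) for an empty network.
    """
    k = ties.k
    if k == 0:
        return None
    if method == "borgatti":
        return k - 2 * ties.tie_count() / k
    if method == "burt":
        W = _weight_matrix(ties, "raw")
        M = W + W.T
        P = M / M.sum(axis=1, keepdims=True)
        p_e = P[0]
        total = 0.0
        for j in range(1, k + 1):
            mx = M[j].max()
            m_j = M[:, j] / mx  # mx >= 2 always (ego tie)
            redundancy = p_e @ m_j - p_e[0] * m_j[0] - p_e[j] * m_j[j]
            total += 1.0 - redundancy
        return total
    raise ValueError(f"unknown effective-size method {method!r}")


def degree_stats(ties: TieMatrix) -> tuple[int, float] | None:
    """(max degree, mean degree) over the alter-alter presence subgraph.

    The ego is excluded as a node and from all counts.  Undefined (None)
    for an empty network; a single alter has degree 0.
    """
    k = ties.k
    if k == 0:
        return None
    deg = ties.dichotomized().sum(axis=1)
    return int(deg.max()), float(deg.mean())


def compute_structure(
    record: EgoRecord,
    tie_weights: str = "raw",
    effective_size_method: str = "borgatti",
) -> StructureMetrics:
    """Bundle all six structure metrics for one record.

    Size uses the full roster; all tie-based metrics use the first-10
    subnetwork (the only tie data collected) and are None when the tie
    section is missing.
    """
    n = record.network_size
    ties = record.ties
    if ties is None:
        return StructureMetrics(n, None, None, None, None, None)
    deg = degree_stats(ties)
    return StructureMetrics(
        network_size=n,
        density=density(ties),
        constraint=burt_constraint(ties, tie_weights=tie_weights),
        effective_size=effective_size(ties, method=effective_size_method),
        max_degree=deg[0] if deg else None,
        mean_degree=deg[1] if deg else None,
    )
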