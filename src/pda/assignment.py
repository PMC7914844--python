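"""Best-match assignment between electron configurations and the metric D.

Two configurations are compared by first finding the index permutation
that minimizes the summed per-electron spatial distance (a linear
assignment problem, solved by the Hungarian algorithm), and then taking
the maximal single-electron distance of that best match:

    D(A, B) = max_i d(a_{pi(i)}, b_i),   pi = argmin sum_i d(a_{pi(i)}, b_i).

The spinposition distance d ignores spin; D is therefore independent of
the electron number and discriminates a large displacement of a single
electron from small displacements of many.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .configurations import ElectronConfiguration, Spinposition
from .errors import ContractError

#: two assignments whose summed costs differ by less than this are ties
COST_TIE_TOL = 1e-10


@dataclass(frozen=True)
class AssignmentResult:
    """Best-match permutation of A onto B.

    ``permutation[i]`` is the index of the A electron matched to B's
    electron i, so ``A.permuted(permutation)`` is index-aligned to B.
    """

    permutation: np.ndarray
    distances: np.ndarray     # per-electron distances after matching, bohr
    D: float                  # max of distances (the metric)
    total_cost: float         # sum of distances (the assignment objective)
    spin_mismatches: int      # matched pairs with different ms


def spinposition_distance(a: Spinposition, b: Spinposition) -> float:
    """Euclidean distance of the position vectors; spin is ignored."""
    return float(np.linalg.norm(np.asarray(a[0], float) - np.asarray(b[0], float)))


def _cost_matrix(a: ElectronConfiguration, b: ElectronConfiguration) -> np.ndarray:
    return np.linalg.norm(a.positions[:, None, :] - b.positions[None, :, :], axis=-1)


def best_match(
    a: ElectronConfiguration,
    b: ElectronConfiguration,
    mode: str = "spatial",
) -> AssignmentResult:
    """Sum-cost-minimal permutation of A onto B.

    ``mode="spatial"`` uses the spin-free distance only. In
    ``mode="spin_aware"``, assignments whose summed cost ties with the
    optimum (within ``COST_TIE_TOL``) are disambiguated toward fewer
    spin-label mismatches, by adding a per-pair mismatch penalty small
    enough never to displace the spatial optimum by more than the tie
    tolerance. This preserves spin-correlation information for
    symmetric molecules where the spatial assignment is arbitrary.
    """
    if a.n != b.n:
        raise ContractError(f"electron count mismatch: {a.n} vs {b.n}")
    if mode not in ("spatial", "spin_aware"):
        raise ContractError(f"unknown assignment mode {mode!r}")
    cost = _cost_matrix(a, b)
    if mode == "spin_aware":
        mismatch = (a.spins[:, None] != b.spins[None, :]).astype(float)
        cost = cost + (COST_TIE_TOL / (2.0 * a.n)) * mismatch
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(a.n, dtype=int)
    perm[cols] = rows
    spatial = _cost_matrix(a, b)
    dists = spatial[perm, np.arange(a.n)]
    mismatches = int(np.sum(a.spins[perm] != b.spins))
    return AssignmentResult(
        permutation=perm,
        distances=dists,
        D=float(dists.max()) if a.n else 0.0,
        total_cost=float(dists.sum()),
        spin_mismatches=mismatches,
    )


def configuration_distance(
    a: ElectronConfiguration, b: ElectronConfiguration, mode: str = "spatial"
) -> float:
    """The metric D(A, B): maximal single-electron best-match distance."""
    return best_match(a, b, mode=mode).D


def best_match_bruteforce(
    a: ElectronConfiguration, b: ElectronConfiguration
) -> AssignmentResult:
    """Exhaustive-enumeration oracle for ``best_match`` (n <= ~8)."""
    if a.n != b.n:
        raise ContractError(f"electron count mismatch: {a.n} vs {b.n}")
    cost = _cost_matrix(a, b)
    best_perm, best_cost = None, np.inf
    for p in permutations(range(a.n)):
        c = cost[list(p), range(a.n)].sum()
        if c < best_cost - 1e-15:
            best_cost, best_perm = c, p
    perm = np.asarray(best_perm, dtype=int)
    dists = cost[perm, np.arange(a.n)]
    return AssignmentResult(
        permutation=perm,
        distances=dists,
        D=float(dists.max()),
        total_cost=float(dists.sum()),
        spin_mismatches=int(np.sum(a.spins[perm] != b.spins)),
    )


def subset_restrict(
    config: ElectronConfiguration, center: np.ndarray, k: int
) -> tuple[ElectronConfiguration, np.ndarray]:
    """The k electrons nearest to ``center``, with their original indices.

    Distance ties are broken toward the lower original index; the
    selected electrons keep their original relative order, so
    ``k = n`` returns the configuration unchanged.
    """
    if k > config.n:
        raise ContractError(f"cannot select {k} electrons out of {config.n}")
    if k < 1:
        raise ContractError("k must be >= 1")
    center = np.asarray(center, dtype=float)
    dists = np.linalg.norm(config.positions - center, axis=-1)
    chosen = np.sort(np.argsort(dists, kind="stable")[:k])
    return config.subset(chosen), chosen
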