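"""Grouping of maxima: greedy pre-clustering and single-linkage clusters.

Maxima are first reduced with a greedy spherical pre-clustering
(descending function value p, first-fit merge within a small sphere
radius in the metric D), then clustered by single linkage: two clusters
merge while their linkage distance

    D(A, B) = min_{A in A, B in B} D(A, B)

is at or below the similarity threshold ``d_sim``. This is equivalent
to DBSCAN with minPts = 1 and is implemented directly as connected
components of the D <= d_sim graph, so the best-match metric is used
verbatim.

Cluster probabilities are basin-count fractions, P_C = sum N_R* / N.
`local` clustering restricts every configuration to the k electrons
nearest a chosen center (e.g. a bond midpoint) before any distance is
evaluated, yielding marginal ("local") cluster probabilities.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .assignment import best_match, configuration_distance, subset_restrict
from .configurations import ElectronConfiguration
from .errors import ContractError
from .geometry import MoleculeGeometry
from .maximization import Maximum

_BRUTE_N = 4  # up to this electron count D is evaluated by enumeration


@dataclass
class ClusteringParams:
    """d_sim defaults to 0.2 a0; sensible range 0.1-0.4 a0.

    The guideline for choosing d_sim: maxima with different formal
    charges (different per-nucleus electron counts) should stay
    separated while structurally similar maxima that differ only by
    spin permutations should merge; the per-cluster
    ``nucleus_electron_counts`` diagnostic reports exactly this.
    """

    d_sim: float = 0.2
    precluster_radius: float = 0.01
    assignment_mode: str = "spatial"   # or "spin_aware"

    def __post_init__(self) -> None:
        if not (self.d_sim > self.precluster_radius > 0):
            raise ContractError("need d_sim > precluster_radius > 0")
        if self.assignment_mode not in ("spatial", "spin_aware"):
            raise ContractError(f"unknown assignment mode {self.assignment_mode!r}")


@dataclass
class Cluster:
    """A set of assigned (index-aligned) maxima.

    ``members`` are aligned copies: every member's electrons are
    permuted onto the index frame of the reference member (the one with
    the highest p). ``probability`` is P_C = sum of member basin counts
    over the total sample size. For local clusters the members hold the
    restricted configurations and ``full_members`` the originals.
    """

    members: list                     # list[Maximum], aligned to members[0]
    probability: float
    count: int                        # total attributed samples
    local: bool = False
    subset_indices: list = field(default_factory=list)  # per-member original indices
    full_members: list = field(default_factory=list)

    @property
    def reference(self) -> Maximum:
        return self.members[0]

    @property
    def n_members(self) -> int:
        return len(self.members)


# ------------------------------------------------------------------ distances
def _d_to_many(seed_pos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Metric D from configuration ``x`` (n,3) to every seed (k,n,3)."""
    k, n, _ = seed_pos.shape
    dist = np.linalg.norm(seed_pos[:, :, None, :] - x[None, None, :, :], axis=-1)
    if n <= _BRUTE_N:
        perms = np.array(list(_permutations(range(n))))       # (P, n)
        per = dist[:, perms, np.arange(n)[None, :]]           # (k, P, n)
        costs = per.sum(axis=-1)
        best = np.argmin(costs, axis=1)
        return per[np.arange(k), best].max(axis=-1)
    out = np.empty(k)
    for i in range(k):
        rows, cols = linear_sum_assignment(dist[i])
        out[i] = dist[i][rows, cols].max()
    return out


def _d_spin_to_many(
    seed_up: np.ndarray, seed_dn: np.ndarray, up: np.ndarray, dn: np.ndarray
) -> np.ndarray:
    """Spin-resolved D: best match restricted to spin-preserving
    permutations, i.e. independent assignment within each spin channel."""
    parts = []
    if up.shape[0]:
        parts.append(_d_to_many(seed_up, up))
    if dn.shape[0]:
        parts.append(_d_to_many(seed_dn, dn))
    return np.max(parts, axis=0) if parts else np.zeros(len(seed_up))


def pre_cluster(maxima: list[Maximum], radius: float) -> list[Maximum]:
    """Greedy spherical pre-clustering of maxima.

    Maxima are processed in order of decreasing p (increasing -ln p,
    stable for ties); each one merges into the first seed within
    ``radius`` (counts accumulate, the seed configuration is kept) or
    becomes a new seed. The total count is conserved exactly.

    Identity of maxima is spin-resolved: two maxima merge only when a
    spin-preserving relabelling brings them within ``radius`` (the
    assignment runs per spin channel). Maxima that differ only by an
    opposite-spin permutation - e.g. the two covalent maxima of H2 -
    therefore stay distinct here and are only unified later by the
    spin-free metric of the clustering stage.
    """
    if radius <= 0:
        raise ContractError("pre-clustering radius must be positive")
    if not maxima:
        return []
    values = np.array([m.value for m in maxima])
    counts = np.array([max(m.count, 1) for m in maxima])
    pos = np.stack([m.configuration.positions for m in maxima])
    spins = np.stack([m.configuration.spins for m in maxima])
    m_, n, _ = pos.shape
    order = np.argsort(values, kind="stable")

    # collapse bitwise-identical configurations first (cheap, exact)
    flat = np.concatenate([pos.reshape(m_, -1), spins], axis=1)
    _, uniq_idx, inverse = np.unique(
        flat, axis=0, return_index=True, return_inverse=True
    )
    group_count = np.zeros(len(uniq_idx), dtype=np.int64)
    np.add.at(group_count, inverse, counts)
    group_first = np.full(len(uniq_idx), m_, dtype=np.int64)
    for i in order:
        gi = inverse[i]
        if group_first[gi] == m_:
            group_first[gi] = i
    uniq_order = np.argsort(values[group_first], kind="stable")

    up_masks = spins > 0
    seeds: list[int] = []          # indices into the original list
    seed_counts: list[int] = []
    seed_up: list[np.ndarray] = []
    seed_dn: list[np.ndarray] = []
    seed_nup: list[int] = []
    for g in uniq_order:
        i = int(group_first[g])
        c = int(group_count[g])
        n_up = int(up_masks[i].sum())
        up = pos[i][up_masks[i]]
        dn = pos[i][~up_masks[i]]
        if seeds:
            same = np.array([nu == n_up for nu in seed_nup])
            if same.any():
                rows = np.flatnonzero(same)
                d = _d_spin_to_many(
                    np.stack([seed_up[r] for r in rows]),
                    np.stack([seed_dn[r] for r in rows]),
                    up,
                    dn,
                )
                hits = np.flatnonzero(d <= radius)
                if hits.size:
                    seed_counts[int(rows[hits[0]])] += c
                    continue
        seeds.append(i)
        seed_counts.append(c)
        seed_up.append(up)
        seed_dn.append(dn)
        seed_nup.append(n_up)
    out = []
    for i, c in zip(seeds, seed_counts):
        src = maxima[i]
        out.append(
            Maximum(
                configuration=src.configuration.copy(),
                value=src.value,
                count=c,
                frozen=src.frozen.copy(),
                converged=src.converged,
            )
        )
    return out


def linkage_distance(a: Cluster, b: Cluster, mode: str = "spatial") -> float:
    """Single-linkage distance: min of D over all cross-pairs of maxima."""
    if not a.members or not b.members:
        raise ContractError("linkage distance needs non-empty clusters")
    return min(
        configuration_distance(ma.configuration, mb.configuration, mode=mode)
        for ma in a.members
        for mb in b.members
    )


def _component_clusters(configs, maxima, params, n_total, local=False,
                        subset_indices=None, full_maxima=None):
    """Connected components of the D <= d_sim graph, built into Clusters."""
    m = len(maxima)
    pos = np.stack([c.positions for c in configs])
    rows, cols = [], []
    for i in range(m):
        if i + 1 < m:
            d = _d_to_many(pos[i + 1 :], pos[i])
            hits = np.flatnonzero(d <= params.d_sim) + i + 1
            rows.extend([i] * len(hits))
            cols.extend(hits.tolist())
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        idx = idx[np.argsort([maxima[i].value for i in idx], kind="stable")]
        ref_cfg = configs[idx[0]]
        members = []
        mem_subsets = []
        for i in idx:
            cfg = configs[i]
            res = best_match(cfg, ref_cfg, mode=params.assignment_mode)
            aligned = cfg.permuted(res.permutation)
            members.append(
                Maximum(
                    configuration=aligned,
                    value=maxima[i].value,
                    count=maxima[i].count,
                    frozen=maxima[i].frozen[
                        subset_indices[i][res.permutation]
                    ].copy()
                    if local
                    else maxima[i].frozen[res.permutation].copy(),
                    converged=maxima[i].converged,
                )
            )
            if local:
                mem_subsets.append(subset_indices[i][res.permutation].tolist())
        count = int(sum(maxima[i].count for i in idx))
        clusters.append(
            Cluster(
                members=members,
                probability=count / n_total,
                count=count,
                local=local,
                subset_indices=mem_subsets,
                full_members=[full_maxima[i] for i in idx] if local else [],
            )
        )
    clusters.sort(key=lambda c: (-c.probability, c.members[0].value))
    return clusters


def single_linkage(
    maxima: list[Maximum],
    params: ClusteringParams | None = None,
    n_total: int | None = None,
) -> list[Cluster]:
    """Single-linkage clustering of maxima at threshold d_sim.

    ``n_total`` is the total sample size behind the basin counts; it
    defaults to the summed counts (then the probabilities add to 1).
    Clusters come out sorted by decreasing probability.
    """
    if not maxima:
        raise ContractError("no maxima to cluster")
    params = params or ClusteringParams()
    if n_total is None:
        n_total = sum(max(m.count, 1) for m in maxima)
    configs = [m.configuration for m in maxima]
    return _component_clusters(configs, maxima, params, n_total)


def local_cluster(
    maxima: list[Maximum],
    center: np.ndarray,
    k: int,
    params: ClusteringParams | None = None,
    n_total: int | None = None,
) -> list[Cluster]:
    """Cluster with every configuration restricted to the k electrons
    nearest ``center`` (local clustering; yields marginal P_C)."""
    if k < 1:
        raise ContractError("k must be >= 1")
    if not maxima:
        raise ContractError("no maxima to cluster")
    params = params or ClusteringParams()
    if n_total is None:
        n_total = sum(max(m.count, 1) for m in maxima)
    restricted, subsets = [], []
    for m in maxima:
        cfg, idx = subset_restrict(m.configuration, center, k)
        restricted.append(cfg)
        subsets.append(idx)
    return _component_clusters(
        restricted,
        maxima,
        params,
        n_total,
        local=True,
        subset_indices=subsets,
        full_maxima=maxima,
    )


def nucleus_electron_counts(
    config: ElectronConfiguration, geometry: MoleculeGeometry
) -> list[int]:
    """Electrons assigned to each nucleus (nearest-nucleus partition).

    The diagnostic behind the d_sim guideline: members of one cluster
    should agree in these counts ("formal charges"), and clusters whose
    members disagree signal a d_sim chosen too large.
    """
    if len(geometry) == 0:
        return []
    d = np.linalg.norm(
        config.positions[:, None, :] - geometry.positions[None, :, :], axis=-1
    )
    nearest = np.argmin(d, axis=1)
    return [int(np.sum(nearest == i)) for i in range(len(geometry))]
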