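"""Spin correlation, electron motifs, and ab initio dot structures.

For a cluster C of index-aligned maxima, the spin correlation of the
electron pair (i, j) is the probability-weighted cluster average

    c_ij = 4 <ms_i ms_j>_C = (4 / P_C) sum_{R* in C} P_R* ms_i^{R*} ms_j^{R*},

normalized to [-1, +1] (the diagonal is +1 since 4 ms^2 = 1). Pairs
with c_ij = -1 always carry opposite spins and are called spin
coupled; the connected groups of spin-coupled electrons are electron
motifs, the generalization of the Lewis electron pair. Within a motif
of more than two electrons, next-neighbor pairs necessarily show
c_ij = +1: when one spin flips between two maxima of the cluster, the
whole motif flips.

A dot structure condenses a cluster into its representative maximum
(the member with the highest p), annotated with spins and with edges
between spin-coupled electrons.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .clustering import Cluster
from .configurations import ElectronConfiguration
from .errors import ContractError
from .geometry import MoleculeGeometry

#: default coupling tolerance: finite-sample weights make exact +-1
#: unreachable, but the empirical c_ij distribution is strongly
#: tri-modal at {-1, 0, +1} with a gap around the extremes, so a small
#: epsilon is safe. Intermediate values are reported, never coupled.
DEFAULT_EPSILON = 0.05


@dataclass(frozen=True)
class SpinCorrelationMatrix:
    """Symmetric n x n matrix of pair spin correlations, unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContractError("spin-correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ContractError("spin-correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-9):
            raise ContractError("spin correlations must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class MotifPartition:
    """Partition of electron indices into spin-coupled motifs.

    ``signs`` gives the relative spin pattern inside each motif
    (+1/-1, first member +1); ``inconsistent`` flags motifs whose
    correlation pattern is not two-colorable within tolerance.
    """

    motifs: list[list[int]]
    signs: list[list[int]]
    epsilon: float
    inconsistent: list[bool] = field(default_factory=list)

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)


@dataclass
class DotStructure:
    """Representative maximum of a cluster with spins and motif edges."""

    geometry: MoleculeGeometry
    positions: np.ndarray          # (n, 3) electron positions, bohr
    spins: np.ndarray              # canonicalized display spins
    motif_edges: list[tuple[int, int]]
    motifs: list[list[int]]
    probability: float


def spin_correlation(cluster: Cluster) -> SpinCorrelationMatrix:
    """Eq.-style cluster average c_ij = 4 <ms_i ms_j>_C over the members."""
    if not cluster.members:
        raise ContractError("empty cluster")
    n = cluster.members[0].configuration.n
    spins = np.stack([m.configuration.spins for m in cluster.members])
    weights = np.array([max(m.count, 1) for m in cluster.members], dtype=float)
    weights /= weights.sum()
    c = 4.0 * np.einsum("m,mi,mj->ij", weights, spins, spins)
    np.fill_diagonal(c, 1.0)
    return SpinCorrelationMatrix(values=np.clip(c, -1.0, 1.0))


def extract_motifs(
    matrix: SpinCorrelationMatrix, epsilon: float = DEFAULT_EPSILON
) -> MotifPartition:
    """Connected components of the c_ij <= -1 + eps graph.

    Within each component the implied sign pattern is checked: pairs of
    equal sign must satisfy c_ij >= 1 - eps, pairs of opposite sign
    c_ij <= -1 + eps. Components violating this (not two-colorable
    within tolerance) are flagged, not silently split.
    """
    if not (0.0 < epsilon < 1.0):
        raise ContractError("epsilon must lie in (0, 1)")
    c = matrix.values
    n = matrix.n
    coupled = (c <= -1.0 + epsilon) & ~np.eye(n, dtype=bool)
    adj = csr_matrix(coupled.astype(float))
    n_comp, labels = connected_components(adj, directed=False)
    motifs, signs, bad = [], [], []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp).tolist()
        motifs.append(idx)
        # two-coloring by BFS over coupled edges
        sign = {idx[0]: +1}
        queue = [idx[0]]
        while queue:
            i = queue.pop()
            for j in idx:
                if j not in sign and coupled[i, j]:
                    sign[j] = -sign[i]
                    queue.append(j)
        s = [sign[i] for i in idx]
        inconsistent = False
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                cij = c[idx[a], idx[b]]
                if s[a] == s[b] and cij < 1.0 - epsilon:
                    inconsistent = True
                if s[a] != s[b] and cij > -1.0 + epsilon:
                    inconsistent = True
        signs.append(s)
        bad.append(inconsistent)
    return MotifPartition(motifs=motifs, signs=signs, epsilon=epsilon, inconsistent=bad)


def select_representative(cluster: Cluster) -> ElectronConfiguration:
    """The member with the highest p (lowest -ln p); stable under ties."""
    if not cluster.members:
        raise ContractError("empty cluster")
    best = min(range(len(cluster.members)), key=lambda i: (cluster.members[i].value, i))
    return cluster.members[best].configuration


def correlation_histogram(
    clusters: list[Cluster],
    bins: int | np.ndarray = 41,
    value_range: tuple[float, float] = (-1.025, 1.025),
) -> tuple[np.ndarray, np.ndarray]:
    """P_C-weighted histogram of off-diagonal spin correlations.

    Pools c_ij (i < j) over all clusters, each pair weighted by its
    cluster probability. Empirically the distribution is tri-modal at
    {-1, 0, +1}.
    """
    vals, weights = [], []
    for cluster in clusters:
        c = spin_correlation(cluster).values
        iu = np.triu_indices(c.shape[0], k=1)
        vals.append(c[iu])
        weights.append(np.full(len(iu[0]), cluster.probability))
    if not vals:
        return np.histogram([], bins=bins, range=value_range)
    return np.histogram(
        np.concatenate(vals), bins=bins, range=value_range,
        weights=np.concatenate(weights),
    )


def build_dot_structure(
    cluster: Cluster,
    geometry: MoleculeGeometry,
    epsilon: float = DEFAULT_EPSILON,
) -> DotStructure:
    """Assemble the ab initio dot structure of a cluster.

    Edges connect spin-coupled pairs (c_ij <= -1 + eps) only; the
    derived +1 next-neighbor pairs get no edge. Spin colors carry
    meaning only within a motif, so each motif is canonicalized to have
    its first electron spin-up in the display copy.
    """
    matrix = spin_correlation(cluster)
    partition = extract_motifs(matrix, epsilon)
    rep = select_representative(cluster)
    spins = rep.spins.copy()
    for motif in partition.motifs:
        if spins[motif[0]] < 0:
            spins[motif] = -spins[motif]
    edges = [
        (i, j)
        for motif in partition.motifs
        for ai, i in enumerate(motif)
        for j in motif[ai + 1 :]
        if matrix.values[i, j] <= -1.0 + epsilon
    ]
    return DotStructure(
        geometry=geometry,
        positions=rep.positions.copy(),
        spins=spins,
        motif_edges=edges,
        motifs=partition.motifs,
        probability=cluster.probability,
    )
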