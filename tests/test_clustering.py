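"""Pre-clustering, single-linkage clustering, and local clustering."""
import numpy as np
import pytest

from pda import (
    Cluster,
    ClusteringParams,
    ContractError,
    ElectronConfiguration,
    Maximum,
    linkage_distance,
    local_cluster,
    nucleus_electron_counts,
    pre_cluster,
    single_linkage,
)
from pda.assignment import configuration_distance

from conftest import random_configuration


def _max(positions, spins=None, value=0.0, count=1):
    positions = np.asarray(positions, dtype=float)
    if spins is None:
        n = len(positions)
        spins = [0.5] * (n // 2 + n % 2) + [-0.5] * (n // 2)
    return Maximum(
        configuration=ElectronConfiguration(positions, spins),
        value=value,
        count=count,
    )


def h2_four_maxima(counts=(4860, 4860, 140, 140)):
    a, b = [0, 0, -0.7], [0, 0, 0.7]
    spins = [0.5, -0.5]
    return [
        _max([a, b], spins, value=1.13, count=counts[0]),
        _max([b, a], spins, value=1.13, count=counts[1]),
        _max([a, a], spins, value=2.32, count=counts[2]),
        _max([b, b], spins, value=2.32, count=counts[3]),
    ]


class TestPreCluster:
    def test_identical_maxima_collapse(self):
        maxima = [_max([[0, 0, 0.5]], [0.5], count=3) for _ in range(5)]
        out = pre_cluster(maxima, 0.01)
        assert len(out) == 1
        assert out[0].count == 15

    def test_distant_maxima_stay_separate(self):
        m1 = _max([[0, 0, 0]], [0.5])
        m2 = _max([[0, 0, 0.05]], [0.5])
        assert len(pre_cluster([m1, m2], 0.01)) == 2

    def test_jittered_h2_maxima_recover_four_seeds(self, rng):
        """1000 jittered copies of the 4 H2 maxima (jitter 0.001 a0,
        radius 0.01 a0) collapse to exactly 4 seeds, counts conserved."""
        base = h2_four_maxima()
        maxima = []
        for _ in range(1000):
            pick = base[int(rng.integers(4))]
            jitter = rng.normal(scale=0.001 / np.sqrt(3), size=(2, 3))
            jitter = np.clip(jitter, -0.001, 0.001)
            maxima.append(
                _max(
                    pick.configuration.positions + jitter,
                    pick.configuration.spins,
                    value=pick.value + rng.normal(scale=1e-4),
                    count=1,
                )
            )
        out = pre_cluster(maxima, 0.01)
        assert len(out) == 4
        assert sum(m.count for m in out) == 1000

    def test_spin_permuted_maxima_not_merged(self):
        """The two covalent H2 maxima coincide spatially but differ by an
        opposite-spin permutation; identity is spin-resolved, so they
        must survive pre-clustering as distinct maxima."""
        out = pre_cluster(h2_four_maxima(), 0.01)
        assert len(out) == 4

    def test_bad_radius_rejected(self):
        with pytest.raises(ContractError):
            pre_cluster(h2_four_maxima(), 0.0)


class TestLinkage:
    def test_singletons_equal_configuration_distance(self, rng):
        a = random_configuration(rng, 3)
        b = random_configuration(rng, 3)
        ca = Cluster(members=[_max(a.positions, a.spins)], probability=1, count=1)
        cb = Cluster(members=[_max(b.positions, b.spins)], probability=1, count=1)
        assert linkage_distance(ca, cb) == pytest.approx(
            configuration_distance(a, b), abs=1e-12
        )

    def test_shared_member_gives_zero(self, rng):
        a = random_configuration(rng, 3)
        b = random_configuration(rng, 3)
        ca = Cluster(
            members=[_max(a.positions, a.spins), _max(b.positions, b.spins)],
            probability=1,
            count=2,
        )
        cb = Cluster(members=[_max(b.positions, b.spins)], probability=1, count=1)
        assert linkage_distance(ca, cb) == 0.0

    def test_matches_bruteforce_min_over_cross_pairs(self, rng):
        mems_a = [random_configuration(rng, 4) for _ in range(3)]
        mems_b = [random_configuration(rng, 4) for _ in range(4)]
        ca = Cluster(members=[_max(c.positions, c.spins) for c in mems_a],
                     probability=1, count=3)
        cb = Cluster(members=[_max(c.positions, c.spins) for c in mems_b],
                     probability=1, count=4)
        oracle = min(
            configuration_distance(x, y) for x in mems_a for y in mems_b
        )
        assert linkage_distance(ca, cb) == pytest.approx(oracle, abs=1e-12)


class TestSingleLinkage:
    def test_h2_lewis_structures(self):
        """d_sim below the bond length merges the covalent pair and keeps
        the two ionic maxima separate: three Lewis structures."""
        clusters = single_linkage(
            h2_four_maxima(), ClusteringParams(d_sim=1.0), n_total=10000
        )
        assert len(clusters) == 3
        sizes = sorted(c.n_members for c in clusters)
        assert sizes == [1, 1, 2]
        covalent = max(clusters, key=lambda c: c.n_members)
        assert covalent.probability == pytest.approx(0.972)
        assert {c.count for c in clusters if c.n_members == 1} == {140}

    def test_small_dsim_isolates_every_maximum(self, rng):
        maxima = [_max(rng.normal(scale=2.0, size=(3, 3))) for _ in range(8)]
        min_d = min(
            configuration_distance(a.configuration, b.configuration)
            for i, a in enumerate(maxima)
            for b in maxima[i + 1 :]
        )
        clusters = single_linkage(
            maxima, ClusteringParams(d_sim=min_d / 2, precluster_radius=min_d / 20)
        )
        assert len(clusters) == len(maxima)

    def test_large_dsim_gives_single_cluster_with_unit_probability(self):
        clusters = single_linkage(h2_four_maxima(), ClusteringParams(d_sim=10.0))
        assert len(clusters) == 1
        assert clusters[0].probability == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, rng):
        maxima = [
            _max(rng.normal(size=(3, 3)), value=float(v), count=int(c))
            for v, c in zip(rng.normal(size=12), rng.integers(1, 50, size=12))
        ]
        clusters = single_linkage(maxima, ClusteringParams(d_sim=0.3))
        assert sum(c.probability for c in clusters) == pytest.approx(1.0)

    def test_cluster_count_monotone_in_dsim(self, rng):
        maxima = [_max(rng.normal(scale=1.5, size=(3, 3))) for _ in range(25)]
        counts = [
            len(single_linkage(maxima, ClusteringParams(d_sim=d, precluster_radius=1e-4)))
            for d in np.geomspace(0.02, 6.0, 12)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_preclustering_does_not_change_clusters(self, rng):
        """With jitter << radius << d_sim the final clusters agree with
        and without the pre-clustering reduction."""
        base = h2_four_maxima()
        jittered = []
        for _ in range(300):
            pick = base[int(rng.integers(4))]
            jittered.append(
                _max(
                    pick.configuration.positions
                    + rng.normal(scale=2e-4, size=(2, 3)),
                    pick.configuration.spins,
                    value=pick.value,
                    count=1,
                )
            )
        params = ClusteringParams(d_sim=1.0, precluster_radius=0.01)
        direct = single_linkage(jittered, params, n_total=300)
        reduced = single_linkage(
            pre_cluster(jittered, 0.01), params, n_total=300
        )
        assert len(direct) == len(reduced)
        for a, b in zip(direct, reduced):
            assert a.count == b.count
            assert a.probability == pytest.approx(b.probability, abs=1e-12)

    def test_member_alignment_to_reference(self):
        clusters = single_linkage(h2_four_maxima(), ClusteringParams(d_sim=1.0))
        covalent = max(clusters, key=lambda c: c.n_members)
        ref, other = covalent.members
        # after alignment both members share the reference's positions
        assert np.allclose(ref.configuration.positions, other.configuration.positions)
        # and the spin patterns are opposite (the spin-flip pair)
        assert np.allclose(
            ref.configuration.spins, -other.configuration.spins
        )


class TestLocalClustering:
    def _maxima_with_tail(self):
        """4-electron maxima: electrons 0,1 at a 'bond', electrons 2,3 in
        a remote 'environment' that differs between groups."""
        bond_cov = [[0, 0, -0.2], [0, 0, 0.2]]
        bond_ion = [[0, 0, -0.2], [0.05, 0, -0.2]]
        env_a = [[5, 0, 0], [0, 5, 0]]
        env_b = [[5, 5, 0], [0, 5, 5]]
        spins = [0.5, -0.5, 0.5, -0.5]
        return [
            _max(bond_cov + env_a, spins, value=1.0, count=30),
            _max(bond_cov + env_b, spins, value=1.1, count=23),
            _max(bond_ion + env_a, spins, value=1.2, count=27),
            _max(bond_ion + env_b, spins, value=1.3, count=20),
        ]

    def test_k_equals_n_reproduces_global(self, rng):
        maxima = [_max(rng.normal(size=(3, 3))) for _ in range(10)]
        params = ClusteringParams(d_sim=0.5, precluster_radius=1e-4)
        global_clusters = single_linkage(maxima, params)
        local_clusters = local_cluster(maxima, np.zeros(3), 3, params)
        assert len(global_clusters) == len(local_clusters)
        for a, b in zip(global_clusters, local_clusters):
            assert a.count == b.count
            assert a.probability == pytest.approx(b.probability)

    def test_marginalization_identity(self):
        """Local probabilities of merged clusters equal the sum of the
        global probabilities of their constituents."""
        maxima = self._maxima_with_tail()
        params = ClusteringParams(d_sim=0.3, precluster_radius=1e-3)
        global_clusters = single_linkage(maxima, params)
        assert len(global_clusters) == 4
        local_clusters = local_cluster(maxima, np.zeros(3), 2, params)
        assert len(local_clusters) == 2
        probs = sorted(c.probability for c in local_clusters)
        assert probs == pytest.approx([47 / 100, 53 / 100])
        total = sum(c.probability for c in global_clusters)
        assert sum(c.probability for c in local_clusters) == pytest.approx(total)

    def test_bond_difference_inside_subset_stays_split(self):
        """A covalent/ionic difference inside the restricted subset must
        not be marginalized away."""
        maxima = self._maxima_with_tail()
        local_clusters = local_cluster(
            maxima, np.zeros(3), 2, ClusteringParams(d_sim=0.3, precluster_radius=1e-3)
        )
        reps = [c.members[0].configuration.positions for c in local_clusters]
        assert not np.allclose(reps[0], reps[1])


def test_nucleus_electron_counts(h2_cas):
    cfg = ElectronConfiguration([[0, 0, -0.7], [0, 0, -0.6]], [0.5, -0.5])
    assert nucleus_electron_counts(cfg, h2_cas.geometry) == [2, 0]


def test_params_validation():
    with pytest.raises(ContractError):
        ClusteringParams(d_sim=0.005, precluster_radius=0.01)
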