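"""Density-model contracts: symmetry, gradients, and the H2 CI problem."""
import numpy as np
import pytest

import pda
from pda import ElectronConfiguration, finite_difference_grad
from pda.integrals import (
    _ContractedS,
    _eri,
    _kinetic,
    _nuclear,
    _overlap,
    h2_minimal_ci,
    sto_coulomb_two_center,
    sto_kinetic,
    sto_nuclear_attraction,
    sto_overlap,
)

from conftest import random_configuration


def _models(request):
    return [
        request.getfixturevalue(name)
        for name in ("h2_cas", "h2_rhf", "slater3", "gauss1", "two_mode")
    ]


class TestPermutationSymmetry:
    def test_same_spin_swap_is_exact(self, slater3, rng):
        """Swapping two same-spin electrons leaves ln p unchanged exactly."""
        for _ in range(100):
            cfg = random_configuration(rng, 3, n_alpha=2)
            swapped = cfg.permuted([1, 0, 2])  # both alpha
            assert pda.log_density(slater3, cfg) == pda.log_density(slater3, swapped)

    @pytest.mark.parametrize("model_name", ["h2_cas", "h2_rhf", "slater3"])
    def test_opposite_spin_swap_with_ms_swap(self, model_name, request, rng):
        """Exchanging positions and ms labels of an opposite-spin pair is a
        relabelling of identical particles and cannot change ln p."""
        model = request.getfixturevalue(model_name)
        n = model.n_electrons
        for _ in range(100):
            cfg = random_configuration(rng, n, n_alpha=model.n_alpha)
            # swap the last alpha with the first beta, labels included
            i, j = model.n_alpha - 1, model.n_alpha
            perm = list(range(n))
            perm[i], perm[j] = perm[j], perm[i]
            swapped = cfg.permuted(perm)  # permutes spins along with positions
            assert pda.log_density(model, cfg) == pytest.approx(
                pda.log_density(model, swapped), abs=1e-12
            )


class TestGradients:
    @pytest.mark.parametrize(
        "model_name", ["h2_cas", "h2_rhf", "slater3", "gauss1", "two_mode"]
    )
    def test_matches_central_finite_differences(self, model_name, request, rng):
        model = request.getfixturevalue(model_name)
        checked = 0
        while checked < 50:
            cfg = random_configuration(rng, model.n_electrons, n_alpha=model.n_alpha)
            if len(model.geometry) and np.min(
                np.linalg.norm(
                    cfg.positions[:, None] - model.geometry.positions[None], axis=-1
                )
            ) < 0.05:
                continue  # keep away from the cusp for the difference quotient
            analytic = pda.grad_log_density(model, cfg)
            numeric = finite_difference_grad(model, cfg, h=1e-5)
            scale = max(1.0, np.abs(numeric).max())
            assert np.allclose(analytic, numeric, atol=1e-5 * scale)
            checked += 1

    def test_zero_at_gaussian_center(self, gauss1):
        cfg = ElectronConfiguration([[0.0, 0.0, 0.0]], [0.5])
        assert np.allclose(pda.grad_log_density(gauss1, cfg), 0.0)

    def test_mirror_symmetry_of_h2_gradient(self, h2_cas, rng):
        """p is invariant under the z -> -z mirror of the molecule, so the
        gradient transforms with the mirror."""
        mirror = np.diag([1.0, 1.0, -1.0])
        for _ in range(10):
            cfg = random_configuration(rng, 2, n_alpha=1)
            mirrored = ElectronConfiguration(cfg.positions @ mirror, cfg.spins)
            g = pda.grad_log_density(h2_cas, cfg)
            gm = pda.grad_log_density(h2_cas, mirrored)
            assert np.allclose(gm, g @ mirror, atol=1e-12)

    def test_same_spin_coalescence_hits_node(self, slater3):
        """Two same-spin electrons at the same point annihilate the
        determinant: ln p is reported as (numerically) minus infinity."""
        cfg = ElectronConfiguration(
            [[0.3, 0.2, 0.1], [0.3, 0.2, 0.1], [0.0, 0.0, 0.5]], [0.5, 0.5, -0.5]
        )
        assert pda.log_density(slater3, cfg) <= -1e290


class TestGaussianFixture:
    def test_log_density_closed_form(self, gauss1, rng):
        origin = ElectronConfiguration([[0.0, 0.0, 0.0]], [0.5])
        lp0 = pda.log_density(gauss1, origin)
        for _ in range(20):
            r = rng.normal(size=3)
            cfg = ElectronConfiguration([r], [0.5])
            assert pda.log_density(gauss1, cfg) - lp0 == pytest.approx(
                -np.dot(r, r) / 2.0, abs=1e-12
            )

    def test_weights_must_normalize(self):
        with pytest.raises(pda.ContractError):
            pda.GaussianMixtureDensity(
                electrons=[([0.5, 0.2], [[0, 0, 0], [0, 0, 1]], [1.0, 1.0])]
            )


class TestH2Models:
    def test_variational_ci_coefficients(self, h2_cas):
        """Ground state mixes sigma_u^2 in with opposite sign; 2x2 oracle."""
        ci = h2_cas.ci_result
        assert abs(ci.c2) < abs(ci.c1)
        assert ci.c1 * ci.c2 < 0
        assert ci.c1 ** 2 + ci.c2 ** 2 == pytest.approx(1.0, abs=1e-12)
        # independent check: eigenvector of the stored 2x2 matrix
        h = np.array(ci.h_matrix)
        w, v = np.linalg.eigh(h)
        expect = v[:, 0] if v[0, 0] > 0 else -v[:, 0]
        assert np.allclose([ci.c1, ci.c2], expect, atol=1e-12)

    def test_cas_energy_below_rhf(self, h2_cas):
        assert h2_cas.ci_result.e_cas < h2_cas.ci_result.e_rhf

    def test_large_zeta_overlap_vanishes(self):
        assert h2_minimal_ci(1.4, 8.0).overlap < 1e-3

    def test_invalid_parameters_rejected(self):
        with pytest.raises(pda.ContractError):
            pda.build_h2_cas(-1.0, 1.0)
        with pytest.raises(pda.ContractError):
            pda.build_h2_cas(1.4, 0.0)

    def test_covalent_maximum_above_ionic(self, h2_cas):
        """Direct evaluation of the two-configuration wavefunction at the
        covalent and ionic points (independent of the model code)."""
        zeta, r = h2_cas.zeta, h2_cas.r_hh
        a = np.array([0, 0, -r / 2])
        b = np.array([0, 0, +r / 2])
        s = np.exp(-zeta * r) * (1 + zeta * r + (zeta * r) ** 2 / 3)

        def phi(x, c):
            return np.exp(-zeta * np.linalg.norm(x - c))

        def psi(r1, r2):
            g = lambda x: (phi(x, a) + phi(x, b)) / np.sqrt(2 * (1 + s))
            u = lambda x: (phi(x, a) - phi(x, b)) / np.sqrt(2 * (1 - s))
            return h2_cas.c1 * g(r1) * g(r2) + h2_cas.c2 * u(r1) * u(r2)

        assert psi(a, b) ** 2 > psi(a, a) ** 2
        spins = [0.5, -0.5]
        cov = ElectronConfiguration([a, b], spins)
        ion = ElectronConfiguration([a, a], spins)
        assert pda.log_density(h2_cas, cov) > pda.log_density(h2_cas, ion)
        # and the model value agrees with the direct evaluation
        assert pda.log_density(h2_cas, cov) == pytest.approx(
            2 * np.log(abs(psi(a, b))), abs=1e-12
        )

    def test_rhf_density_factorizes(self, h2_rhf, rng):
        """For the single determinant, ln p(r1,r2) + ln p(r1',r2') =
        ln p(r1,r2') + ln p(r1',r2) - the signature of a product density."""
        spins = [0.5, -0.5]
        for _ in range(20):
            r1, r2, r1p, r2p = rng.normal(scale=1.2, size=(4, 3))
            lp = lambda x, y: pda.log_density(
                h2_rhf, ElectronConfiguration([x, y], spins)
            )
            assert lp(r1, r2) + lp(r1p, r2p) == pytest.approx(
                lp(r1, r2p) + lp(r1p, r2), abs=1e-10
            )

    def test_spin_count_mismatch_rejected(self, h2_cas):
        with pytest.raises(pda.ContractError):
            pda.log_density(
                h2_cas, ElectronConfiguration([[0, 0, 0], [0, 0, 1]], [0.5, 0.5])
            )


class TestIntegralEngine:
    """The Gaussian-expansion engine against the closed Slater forms."""

    @pytest.mark.parametrize("zeta,r", [(1.0, 1.4), (1.2, 1.4), (0.8, 2.5)])
    def test_one_electron_integrals(self, zeta, r):
        a = _ContractedS.sto(zeta, [0, 0, 0])
        b = _ContractedS.sto(zeta, [0, 0, r])
        assert _overlap(a, a) == pytest.approx(1.0, abs=1e-8)
        assert _overlap(a, b) == pytest.approx(sto_overlap(zeta, r), abs=1e-6)
        assert _kinetic(a, a) == pytest.approx(sto_kinetic(zeta, 0.0), abs=1e-6)
        assert _kinetic(a, b) == pytest.approx(sto_kinetic(zeta, r), abs=1e-6)
        assert _nuclear(a, a, a.center) == pytest.approx(
            sto_nuclear_attraction(zeta, 0.0, True), abs=1e-6
        )
        assert _nuclear(a, a, b.center) == pytest.approx(
            sto_nuclear_attraction(zeta, r, False), abs=1e-6
        )

    @pytest.mark.parametrize("zeta,r", [(1.0, 1.4), (1.2, 1.4)])
    def test_two_electron_integrals(self, zeta, r):
        a = _ContractedS.sto(zeta, [0, 0, 0])
        b = _ContractedS.sto(zeta, [0, 0, r])
        assert _eri(a, a, a, a) == pytest.approx(5.0 * zeta / 8.0, abs=1e-7)
        assert _eri(a, a, b, b) == pytest.approx(
            sto_coulomb_two_center(zeta, r), abs=1e-7
        )
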