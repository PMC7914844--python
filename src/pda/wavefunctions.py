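"""Density models: |Psi|^2 evaluators with analytic gradients.

A density model provides ln p(R) up to an additive constant, together
with its gradient with respect to all electron positions. Only
differences of ln p enter the pipeline (Metropolis ratios, descent,
basin counting), so no normalization of |Psi|^2 is ever required.

Built-in models:

``H2CasDensity``
    Two-configuration CAS(2,2) wavefunction for H2 in the minimal basis
    of 1s Slater orbitals, Psi = c1 sigma_g^2 + c2 sigma_u^2 (singlet).
    With c = (1, 0) this degenerates to the restricted Hartree-Fock
    determinant, where p factorizes into independent one-electron
    densities for the two opposite-spin electrons.

``SlaterDeterminantDensity``
    Generic single determinant over user-supplied s-type Slater
    orbitals, p = det(Phi_alpha)^2 det(Phi_beta)^2.

``GaussianMixtureDensity``
    Analytic mixture fixtures with exactly known maxima, for tests.
"""
from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .configurations import SPIN_DOWN, SPIN_UP, ElectronConfiguration, spins_template
from .errors import ContractError
from .geometry import MoleculeGeometry
from .integrals import H2CIResult, h2_minimal_ci

_LOG_FLOOR = -1e300  # stands in for ln 0 at wavefunction nodes


class DensityModel(ABC):
    """Contract: ln p(R) up to a constant, and its position gradient."""

    geometry: MoleculeGeometry
    n_alpha: int
    n_beta: int
    model_id: str = "model"

    @property
    def n_electrons(self) -> int:
        return self.n_alpha + self.n_beta

    @property
    def spins(self) -> np.ndarray:
        """Canonical spin labelling: alpha electrons first."""
        return spins_template(self.n_alpha, self.n_beta)

    # -- batched core ------------------------------------------------------
    @abstractmethod
    def _log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        """ln p for positions of shape (m, n, 3); returns shape (m,)."""

    @abstractmethod
    def _grad_log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        """Gradient of ln p, shape (m, n, 3)."""

    def _log_density_and_grad(self, positions: np.ndarray, spins: np.ndarray):
        """Fused ln p and gradient; models may override to share work."""
        return self._log_density(positions, spins), self._grad_log_density(positions, spins)

    # -- public surface ----------------------------------------------------
    def validate_spins(self, spins: np.ndarray) -> None:
        spins = np.asarray(spins)
        n_up = int(np.sum(spins == SPIN_UP))
        n_down = int(np.sum(spins == SPIN_DOWN))
        if n_up != self.n_alpha or n_down != self.n_beta:
            raise ContractError(
                f"model expects ({self.n_alpha} up, {self.n_beta} down) electrons, "
                f"got ({n_up} up, {n_down} down)"
            )

    def log_density_batch(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        self.validate_spins(spins)
        return self._log_density(positions, np.asarray(spins, dtype=float))

    def grad_log_density_batch(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        self.validate_spins(spins)
        return self._grad_log_density(positions, np.asarray(spins, dtype=float))

    def log_density(self, config: ElectronConfiguration) -> float:
        return float(self.log_density_batch(config.positions[None], config.spins)[0])

    def grad_log_density(self, config: ElectronConfiguration) -> np.ndarray:
        """Gradient with respect to all 3n position coordinates, shape (n, 3)."""
        return self.grad_log_density_batch(config.positions[None], config.spins)[0]

    def initial_positions(self, rng: np.random.Generator) -> np.ndarray:
        """A starting point for a Metropolis chain: electrons spread
        round-robin over the nuclei with 0.5 a0 Gaussian displacement."""
        if len(self.geometry) == 0:
            raise ContractError(f"{self.model_id}: no nuclei; override initial_positions")
        nuclei = self.geometry.positions
        idx = np.arange(self.n_electrons) % len(nuclei)
        return nuclei[idx] + 0.5 * rng.normal(size=(self.n_electrons, 3))


def log_density(model: DensityModel, config: ElectronConfiguration) -> float:
    """ln p(R) up to a model constant; -inf where Psi = 0."""
    return model.log_density(config)


def grad_log_density(model: DensityModel, config: ElectronConfiguration) -> np.ndarray:
    """Gradient of ln p with respect to all position coordinates (n, 3)."""
    return model.grad_log_density(config)


# --------------------------------------------------------------------- H2 CAS
def _sto_values_and_grads(positions: np.ndarray, center: np.ndarray, zeta: float):
    """Un-normalized e^{-zeta r} values and gradients at (m, 3) points."""
    delta = positions - center
    r = np.linalg.norm(delta, axis=-1)
    val = np.exp(-zeta * r)
    safe_r = np.where(r > 1e-12, r, np.inf)  # cusp: gradient set to 0 exactly on the nucleus
    grad = -zeta * delta / safe_r[..., None] * val[..., None]
    return val, grad


class H2CasDensity(DensityModel):
    """H2 CAS(2,2) / RHF density in the minimal 1s Slater basis.

    The two protons sit at (0, 0, -R/2) and (0, 0, +R/2). The spatial
    wavefunction Psi(r1, r2) = c1 g(r1) g(r2) + c2 u(r1) u(r2) is
    symmetric in r1, r2 (singlet), so the density does not depend on
    which electron carries which spin label.
    """

    def __init__(
        self,
        r_hh: float,
        zeta: float,
        ci_coefficients: tuple[float, float],
        model_id: str = "h2_cas",
        ci_result: H2CIResult | None = None,
    ) -> None:
        if r_hh <= 0 or zeta <= 0:
            raise ContractError("r_hh and zeta must be positive")
        c1, c2 = ci_coefficients
        if not np.isclose(c1 * c1 + c2 * c2, 1.0, atol=1e-10):
            raise ContractError("CI coefficients must satisfy c1^2 + c2^2 = 1")
        self.r_hh = float(r_hh)
        self.zeta = float(zeta)
        self.c1 = float(c1)
        self.c2 = float(c2)
        self.ci_result = ci_result
        self.model_id = model_id
        self.n_alpha = 1
        self.n_beta = 1
        self.geometry = MoleculeGeometry(
            symbols=["H", "H"],
            positions=np.array([[0.0, 0.0, -r_hh / 2.0], [0.0, 0.0, +r_hh / 2.0]]),
        )
        s = np.exp(-zeta * r_hh) * (1 + zeta * r_hh + (zeta * r_hh) ** 2 / 3.0)
        self._ng = 1.0 / np.sqrt(2.0 * (1.0 + s))
        self._nu = 1.0 / np.sqrt(2.0 * (1.0 - s))
        self.overlap = float(s)

    # Psi and its per-electron gradient, vectorized over a batch.
    def _psi_parts(self, positions: np.ndarray):
        a, b = self.geometry.positions
        pa, ga = _sto_values_and_grads(positions, a, self.zeta)
        pb, gb = _sto_values_and_grads(positions, b, self.zeta)
        g = self._ng * (pa + pb)
        u = self._nu * (pa - pb)
        dg = self._ng * (ga + gb)
        du = self._nu * (ga - gb)
        return g, u, dg, du

    def _log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        g, u, _, _ = self._psi_parts(positions)
        psi = self.c1 * g[..., 0] * g[..., 1] + self.c2 * u[..., 0] * u[..., 1]
        with np.errstate(divide="ignore"):
            out = 2.0 * np.log(np.abs(psi))
        return np.where(np.isfinite(out), out, _LOG_FLOOR)

    def _grad_log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        g, u, dg, du = self._psi_parts(positions)
        psi = self.c1 * g[..., 0] * g[..., 1] + self.c2 * u[..., 0] * u[..., 1]
        d1 = self.c1 * g[..., 1, None] * dg[..., 0, :] + self.c2 * u[..., 1, None] * du[..., 0, :]
        d2 = self.c1 * g[..., 0, None] * dg[..., 1, :] + self.c2 * u[..., 0, None] * du[..., 1, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 2.0 * np.stack([d1, d2], axis=-2) / psi[..., None, None]
        return out

    def _log_density_and_grad(self, positions: np.ndarray, spins: np.ndarray):
        g, u, dg, du = self._psi_parts(positions)
        psi = self.c1 * g[..., 0] * g[..., 1] + self.c2 * u[..., 0] * u[..., 1]
        with np.errstate(divide="ignore"):
            val = 2.0 * np.log(np.abs(psi))
        val = np.where(np.isfinite(val), val, _LOG_FLOOR)
        d1 = self.c1 * g[..., 1, None] * dg[..., 0, :] + self.c2 * u[..., 1, None] * du[..., 0, :]
        d2 = self.c1 * g[..., 0, None] * dg[..., 1, :] + self.c2 * u[..., 0, None] * du[..., 1, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            grad = 2.0 * np.stack([d1, d2], axis=-2) / psi[..., None, None]
        return val, grad

    def known_maxima(self) -> list[ElectronConfiguration]:
        """The four local maxima: electrons on the nuclei.

        Order: two covalent (one electron at each proton, spin patterns
        swapped) then two ionic (both at the same proton).
        """
        a, b = self.geometry.positions
        spins = self.spins
        return [
            ElectronConfiguration(np.array([a, b]), spins),
            ElectronConfiguration(np.array([b, a]), spins),
            ElectronConfiguration(np.array([a, a]), spins),
            ElectronConfiguration(np.array([b, b]), spins),
        ]


def build_h2_cas(r_hh: float, zeta: float) -> H2CasDensity:
    """H2 CAS(2,2) density with variationally minimized CI coefficients."""
    ci = h2_minimal_ci(r_hh, zeta)
    return H2CasDensity(
        r_hh, zeta, (ci.c1, ci.c2), model_id="h2_cas", ci_result=ci
    )


def build_h2_hartree_fock(r_hh: float, zeta: float) -> H2CasDensity:
    """Single-determinant H2 density: Psi = sigma_g(r1) sigma_g(r2).

    The two opposite-spin electrons are statistically independent, so
    p(r1, r2) factorizes and ionic maxima (both electrons at the same
    proton) appear with the same weight as covalent ones.
    """
    ci = h2_minimal_ci(r_hh, zeta)
    return H2CasDensity(r_hh, zeta, (1.0, 0.0), model_id="h2_rhf", ci_result=ci)


# --------------------------------------------------- generic Slater determinant
@dataclass(frozen=True)
class STOrbital:
    """s-type molecular orbital: sum of 1s Slater primitives.

    ``primitives`` is a sequence of (center (3,), zeta, coefficient).
    """

    primitives: tuple

    def __post_init__(self):
        for center, zeta, _ in self.primitives:
            if zeta <= 0:
                raise ContractError("orbital exponents must be positive")

    def value_and_grad(self, positions: np.ndarray):
        val = np.zeros(positions.shape[:-1])
        grad = np.zeros(positions.shape)
        for center, zeta, coef in self.primitives:
            v, g = _sto_values_and_grads(positions, np.asarray(center, float), zeta)
            val += coef * v
            grad += coef * g
        return val, grad


class SlaterDeterminantDensity(DensityModel):
    """p = det(Phi_alpha)^2 det(Phi_beta)^2 over s-type Slater orbitals.

    ``orbitals`` are doubly used: the first ``n_alpha`` are occupied by
    alpha electrons, the first ``n_beta`` by beta electrons (restricted
    occupation). Separate lists can be given via ``beta_orbitals``.
    """

    def __init__(
        self,
        geometry: MoleculeGeometry,
        orbitals: Sequence[STOrbital],
        n_alpha: int,
        n_beta: int,
        beta_orbitals: Sequence[STOrbital] | None = None,
        model_id: str = "slater_determinant",
    ) -> None:
        if n_alpha < 0 or n_beta < 0 or n_alpha + n_beta == 0:
            raise ContractError("need at least one electron")
        if len(orbitals) < n_alpha:
            raise ContractError("not enough orbitals for alpha electrons")
        beta_orbitals = beta_orbitals if beta_orbitals is not None else orbitals
        if len(beta_orbitals) < n_beta:
            raise ContractError("not enough orbitals for beta electrons")
        self.geometry = geometry
        self.alpha_orbitals = list(orbitals[:n_alpha])
        self.beta_orbitals = list(beta_orbitals[:n_beta])
        self.n_alpha = n_alpha
        self.n_beta = n_beta
        self.model_id = model_id

    @staticmethod
    def _matrices(positions: np.ndarray, orbitals: list[STOrbital]):
        """Phi[m, i, j] = orbital_j(r_i) and its gradients (m, i, j, 3)."""
        vals, grads = [], []
        for orb in orbitals:
            v, g = orb.value_and_grad(positions)
            vals.append(v)
            grads.append(g)
        return np.stack(vals, axis=-1), np.stack(grads, axis=-2)

    def _split(self, positions: np.ndarray, spins: np.ndarray):
        up = np.flatnonzero(spins == SPIN_UP)
        down = np.flatnonzero(spins == SPIN_DOWN)
        return up, down

    def _log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        up, down = self._split(positions, spins)
        out = np.zeros(positions.shape[0])
        for idx, orbitals in ((up, self.alpha_orbitals), (down, self.beta_orbitals)):
            if len(idx) == 0:
                continue
            phi, _ = self._matrices(positions[:, idx], orbitals)
            _, logdet = np.linalg.slogdet(phi)
            out = out + 2.0 * logdet
        return np.where(np.isfinite(out), out, _LOG_FLOOR)

    def _grad_log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        up, down = self._split(positions, spins)
        out = np.zeros_like(positions)
        for idx, orbitals in ((up, self.alpha_orbitals), (down, self.beta_orbitals)):
            if len(idx) == 0:
                continue
            phi, dphi = self._matrices(positions[:, idx], orbitals)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                inv = np.linalg.inv(phi)
                # d ln|det Phi| / d r_i = sum_j inv[j, i] * grad orbital_j(r_i)
                out[:, idx] = 2.0 * np.einsum("mji,mijc->mic", inv, dphi)
        return out


# ------------------------------------------------------------ mixture fixtures
class GaussianMixtureDensity(DensityModel):
    """Analytic mixture density with exactly known maxima (test fixture).

    Two couplings:

    * product (independent electrons): ``p(R) = prod_i sum_k w_ik N(r_i; mu_ik, s_ik^2)``
    * joint (symmetrized sum): ``p(R) = sum_m w_m prod_i N(r_i; mu_mi, s_m^2)``

    Weights must be positive and sum to one (per electron / overall).
    """

    def __init__(self, *, electrons=None, joint=None, spins=None,
                 geometry: MoleculeGeometry | None = None,
                 model_id: str = "gaussian_mixture") -> None:
        if (electrons is None) == (joint is None):
            raise ContractError("give exactly one of electrons= or joint=")
        self.geometry = geometry if geometry is not None else MoleculeGeometry.empty()
        self.model_id = model_id
        if electrons is not None:
            self._mode = "product"
            self._electrons = []
            for weights, centers, sigmas in electrons:
                w = np.atleast_1d(np.asarray(weights, float))
                c = np.atleast_2d(np.asarray(centers, float))
                s = np.broadcast_to(np.asarray(sigmas, float), w.shape).astype(float)
                if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
                    raise ContractError("mixture weights must be positive and sum to 1")
                if np.any(s <= 0):
                    raise ContractError("mixture widths must be positive")
                self._electrons.append((w, c, s))
            n = len(self._electrons)
        else:
            self._mode = "joint"
            weights, centers, sigmas = joint
            w = np.atleast_1d(np.asarray(weights, float))
            c = np.asarray(centers, float)
            if c.ndim != 3:
                raise ContractError("joint centers must be (n_modes, n_electrons, 3)")
            s = np.broadcast_to(np.asarray(sigmas, float), w.shape).astype(float)
            if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
                raise ContractError("mixture weights must be positive and sum to 1")
            if np.any(s <= 0):
                raise ContractError("mixture widths must be positive")
            self._joint = (w, c, s)
            n = c.shape[1]
        if spins is None:
            spins = [SPIN_UP if i % 2 == 0 else SPIN_DOWN for i in range(n)]
        spins = np.asarray(spins, dtype=float)
        if len(spins) != n:
            raise ContractError("spins length mismatch")
        self.n_alpha = int(np.sum(spins == SPIN_UP))
        self.n_beta = int(np.sum(spins == SPIN_DOWN))
        self._spins = spins

    @property
    def spins(self) -> np.ndarray:
        return self._spins.copy()

    def _log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        from scipy.special import logsumexp

        if self._mode == "product":
            out = np.zeros(positions.shape[0])
            for i, (w, c, s) in enumerate(self._electrons):
                d2 = np.sum((positions[:, i, None, :] - c) ** 2, axis=-1)
                logs = np.log(w) - 3.0 * np.log(s) - d2 / (2.0 * s * s)
                out += logsumexp(logs, axis=-1)
            return out
        w, c, s = self._joint
        d2 = np.sum((positions[:, None, :, :] - c) ** 2, axis=(-1, -2))
        n = c.shape[1]
        logs = np.log(w) - 3.0 * n * np.log(s) - d2 / (2.0 * s * s)
        return logsumexp(logs, axis=-1)

    def _grad_log_density(self, positions: np.ndarray, spins: np.ndarray) -> np.ndarray:
        out = np.zeros_like(positions)
        if self._mode == "product":
            for i, (w, c, s) in enumerate(self._electrons):
                delta = positions[:, i, None, :] - c
                d2 = np.sum(delta ** 2, axis=-1)
                logs = np.log(w) - 3.0 * np.log(s) - d2 / (2.0 * s * s)
                logs -= logs.max(axis=-1, keepdims=True)
                resp = np.exp(logs)
                resp /= resp.sum(axis=-1, keepdims=True)
                out[:, i] = np.sum(resp[..., None] * (-delta / (s * s)[:, None]), axis=1)
            return out
        w, c, s = self._joint
        delta = positions[:, None, :, :] - c
        d2 = np.sum(delta ** 2, axis=(-1, -2))
        n = c.shape[1]
        logs = np.log(w) - 3.0 * n * np.log(s) - d2 / (2.0 * s * s)
        logs -= logs.max(axis=-1, keepdims=True)
        resp = np.exp(logs)
        resp /= resp.sum(axis=-1, keepdims=True)
        return np.sum(resp[:, :, None, None] * (-delta / (s * s)[:, None, None]), axis=1)

    def initial_positions(self, rng: np.random.Generator) -> np.ndarray:
        if self._mode == "product":
            pos = []
            for w, c, s in self._electrons:
                k = rng.choice(len(w), p=w)
                pos.append(c[k] + s[k] * rng.normal(size=3))
            return np.asarray(pos)
        w, c, s = self._joint
        m = rng.choice(len(w), p=w)
        return c[m] + s[m] * rng.normal(size=c.shape[1:])


# ------------------------------------------------------------------- utilities
def finite_difference_grad(
    model: DensityModel, config: ElectronConfiguration, h: float = 1e-5
) -> np.ndarray:
    """Central-difference gradient of ln p; oracle for analytic gradients."""
    base = config.positions
    out = np.zeros_like(base)
    for i in range(config.n):
        for c in range(3):
            plus = base.copy()
            minus = base.copy()
            plus[i, c] += h
            minus[i, c] -= h
            lp = model.log_density_batch(np.stack([plus, minus]), config.spins)
            out[i, c] = (lp[0] - lp[1]) / (2.0 * h)
    return out
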