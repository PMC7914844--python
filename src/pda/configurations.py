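"""Electron configurations: indexed sets of spinpositions.

A spinposition pairs a position vector r (bohr) with a magnetic spin
quantum number ms = +1/2 or -1/2. An electron configuration R = (x_i)
is one point of the 3n-dimensional configuration space; since electrons
are indistinguishable, any spin-preserving relabelling leaves the
probability density p(R) unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .errors import ContractError

SPIN_UP = +0.5
SPIN_DOWN = -0.5


class Spinposition(NamedTuple):
    position: np.ndarray  # (3,) bohr
    ms: float             # +0.5 or -0.5


@dataclass
class ElectronConfiguration:
    """Ordered spinpositions ``x_i = (r_i, ms_i)``, ``i = 0..n-1``."""

    positions: np.ndarray  # (n, 3) bohr
    spins: np.ndarray      # (n,) values in {+0.5, -0.5}

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.spins = np.atleast_1d(np.asarray(self.spins, dtype=float))
        if self.positions.shape != (len(self.spins), 3):
            raise ContractError(
                f"positions {self.positions.shape} inconsistent with "
                f"{len(self.spins)} spins"
            )
        if not np.all(np.isin(self.spins, (SPIN_UP, SPIN_DOWN))):
            raise ContractError("spins must be +1/2 or -1/2")

    @property
    def n(self) -> int:
        return len(self.spins)

    @property
    def n_alpha(self) -> int:
        return int(np.sum(self.spins == SPIN_UP))

    @property
    def n_beta(self) -> int:
        return int(np.sum(self.spins == SPIN_DOWN))

    def spinposition(self, i: int) -> Spinposition:
        return Spinposition(self.positions[i].copy(), float(self.spins[i]))

    def __iter__(self) -> Iterator[Spinposition]:
        return (self.spinposition(i) for i in range(self.n))

    def permuted(self, perm: np.ndarray) -> "ElectronConfiguration":
        """Relabelled copy: new index i holds old electron ``perm[i]``."""
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.n)):
            raise ContractError("perm must be a permutation of 0..n-1")
        return ElectronConfiguration(self.positions[perm].copy(), self.spins[perm].copy())

    def subset(self, indices: np.ndarray) -> "ElectronConfiguration":
        indices = np.asarray(indices, dtype=int)
        return ElectronConfiguration(
            self.positions[indices].copy(), self.spins[indices].copy()
        )

    def copy(self) -> "ElectronConfiguration":
        return ElectronConfiguration(self.positions.copy(), self.spins.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElectronConfiguration):
            return NotImplemented
        return np.array_equal(self.positions, other.positions) and np.array_equal(
            self.spins, other.spins
        )


def spins_template(n_alpha: int, n_beta: int) -> np.ndarray:
    """Canonical spin vector: alpha electrons first, then beta."""
    return np.concatenate(
        [np.full(n_alpha, SPIN_UP), np.full(n_beta, SPIN_DOWN)]
    )
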