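"""Molecular geometry and XYZ input.

All positions inside the package are in bohr (a0). XYZ files follow the
common convention of being in angstrom unless the comment line (or the
caller) declares bohr.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractError

BOHR_PER_ANGSTROM = 1.8897261258369282

#: Element symbol -> atomic number, H through Kr.
ELEMENTS = {
    s: i + 1
    for i, s in enumerate(
        "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar "
        "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr".split()
    )
}
_SYMBOLS = {z: s for s, z in ELEMENTS.items()}


@dataclass
class MoleculeGeometry:
    """Nuclear frame of a molecule.

    Parameters
    ----------
    symbols:
        Element symbols, one per nucleus.
    positions:
        Nuclear positions, shape ``(m, 3)``, in bohr.
    numbers:
        Atomic numbers; inferred from ``symbols`` when omitted.
    """

    symbols: list[str]
    positions: np.ndarray
    numbers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and self.positions.shape[1] != 3:
            raise ContractError("nuclear positions must be (m, 3)")
        if self.numbers is None:
            try:
                self.numbers = np.array([ELEMENTS[s] for s in self.symbols])
            except KeyError as exc:  # pragma: no cover - symbol table miss
                raise ContractError(f"unknown element symbol {exc}") from exc
        else:
            self.numbers = np.asarray(self.numbers, dtype=int)
        if len(self.symbols) != len(self.positions) or len(self.numbers) != len(
            self.positions
        ):
            raise ContractError("symbols, numbers, positions length mismatch")
        if np.any(self.numbers < 1):
            raise ContractError("atomic numbers must be >= 1")
        for i in range(len(self)):
            for j in range(i + 1, len(self)):
                if np.linalg.norm(self.positions[i] - self.positions[j]) == 0.0:
                    raise ContractError(f"nuclei {i} and {j} coincide")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def empty(cls) -> "MoleculeGeometry":
        """Nucleus-free frame (used by analytic test densities)."""
        return cls(symbols=[], positions=np.zeros((0, 3)))


def read_xyz(path: str | Path, units: str | None = None) -> MoleculeGeometry:
    """Read a standard XYZ file into a :class:`MoleculeGeometry`.

    The unit is taken from ``units`` ("bohr" or "angstrom") when given,
    else from a ``bohr`` / ``angstrom`` token in the comment line, else
    defaults to angstrom. Output is always bohr.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ContractError(f"empty XYZ file: {path}")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ContractError(f"bad XYZ atom count line in {path}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    if units is None:
        if re.search(r"\bbohr\b|\ba\.?u\.?\b", comment, re.IGNORECASE):
            units = "bohr"
        elif re.search(r"\bang(strom)?\b", comment, re.IGNORECASE):
            units = "angstrom"
        else:
            units = "angstrom"
    if units not in ("bohr", "angstrom"):
        raise ContractError(f"unknown unit declaration {units!r}")
    body = lines[2 : 2 + natoms]
    if len(body) < natoms:
        raise ContractError(f"XYZ file {path} truncated: expected {natoms} atoms")
    symbols, pos = [], []
    for line in body:
        parts = line.split()
        if len(parts) < 4:
            raise ContractError(f"bad XYZ atom line: {line!r}")
        symbols.append(parts[0])
        pos.append([float(x) for x in parts[1:4]])
    positions = np.asarray(pos)
    if units == "angstrom":
        positions = positions * BOHR_PER_ANGSTROM
    return MoleculeGeometry(symbols=symbols, positions=positions)


def symbol_for(z: int) -> str:
    return _SYMBOLS.get(int(z), f"Z{int(z)}")
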