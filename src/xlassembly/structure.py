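"""Lightweight coordinate container for Cα-trace and all-atom segment models.

Residue numbers are full-sequence (preproprotein) numbering, 1-based, and are
assumed unique across the whole molecule even when segments sit on different
chains; lookups are therefore keyed on ``(res_num, atom_name)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np


@dataclass(frozen=True)
class AtomRecord:
    """One atom: chain id, residue number/name, atom name, coordinates in Å."""

    chain: str
    res_num: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float
    element: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class Structure:
    """An ordered collection of :class:`AtomRecord` with fast atom lookup.

    Enforces uniqueness of ``(chain, res_num, atom_name)``. Instances are
    treated as immutable; geometric operations return new structures.
    """

    def __init__(self, atoms: Iterable[AtomRecord], name: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.name = name
        seen: set[tuple[str, int, str]] = set()
        self._index: dict[tuple[int, str], int] = {}
        for i, a in enumerate(self.atoms):
            full_key = (a.chain, a.res_num, a.atom_name)
            if full_key in seen:
                raise ValueError(f"duplicate atom {full_key!r} in structure")
            seen.add(full_key)
            self._index.setdefault((a.res_num, a.atom_name), i)
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        if self._coords is None:
            if self.atoms:
                self._coords = np.array([[a.x, a.y, a.z] for a in self.atoms])
            else:
                self._coords = np.empty((0, 3))
        return self._coords

    def coord(self, res_num: int, atom_name: str = "CA") -> np.ndarray | None:
        """Coordinates of one atom, or None if absent from the model."""
        i = self._index.get((res_num, atom_name))
        return None if i is None else self.coords[i]

    def has_atom(self, res_num: int, atom_name: str = "CA") -> bool:
        return (res_num, atom_name) in self._index

    def atom(self, res_num: int, atom_name: str = "CA") -> AtomRecord | None:
        i = self._index.get((res_num, atom_name))
        return None if i is None else self.atoms[i]

    def residues(self) -> list[int]:
        """Sorted distinct residue numbers present in the model."""
        return sorted({a.res_num for a in self.atoms})

    def residue_name(self, res_num: int) -> str | None:
        for a in self.atoms:
            if a.res_num == res_num:
                return a.res_name
        return None

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Same records, new coordinates (row-per-atom array)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"expected shape {(len(self.atoms), 3)}, got {xyz.shape}")
        new = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(new, name=self.name)

    def renamed_residues(self, names: dict[int, str]) -> "Structure":
        """Return a copy with residue names changed (e.g. to plant LYS/CYS)."""
        new = [
            replace(a, res_name=names[a.res_num]) if a.res_num in names else a
            for a in self.atoms
        ]
        return Structure(new, name=self.name)


def merge(structures: Iterable[Structure], name: str = "") -> Structure:
    """Concatenate several segment models into one structure."""
    atoms: list[AtomRecord] = []
    for s in structures:
        atoms.extend(s.atoms)
    return Structure(atoms, name=name)
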