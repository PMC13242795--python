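"""Molecular point clouds: coordinates plus categorical atom types.

The default type alphabet maps the K synthetic classes onto common organic
elements so that XYZ/SDF round-trips and covalent-radius bond perception work
out of the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Molecule", "DEFAULT_ALPHABET", "COVALENT_RADII", "element_for_type"]

# Cordero covalent radii (Å) for the elements the package touches.
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Se": 1.20,
}

DEFAULT_ALPHABET = ("C", "N", "O", "F")


@dataclass
class Molecule:
    """A point cloud of atoms: (N, 3) coordinates in Å and (N,) type indices."""

    coords: np.ndarray
    types: np.ndarray
    K: int = 4
    alphabet: tuple = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.types = np.asarray(self.types, dtype=int).reshape(-1)
        if self.coords.shape[0] != self.types.shape[0]:
            raise ValueError("coords and types must have equal atom counts")
        if self.types.size and (self.types.min() < 0 or self.types.max() >= self.K):
            raise ValueError("type index out of range")
        if len(self.alphabet) < self.K:
            raise ValueError("alphabet shorter than K")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def elements(self) -> list:
        return [self.alphabet[t] for t in self.types]

    def onehot_types(self) -> np.ndarray:
        out = np.zeros((self.n_atoms, self.K))
        out[np.arange(self.n_atoms), self.types] = 1.0
        return out

    def translated(self, offset) -> "Molecule":
        return Molecule(
            self.coords + np.asarray(offset, dtype=float),
            self.types.copy(),
            self.K,
            self.alphabet,
        )


def element_for_type(t: int, alphabet=DEFAULT_ALPHABET) -> str:
    return alphabet[t]
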