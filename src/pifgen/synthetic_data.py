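"""Seeded generators of toy distributions and ligand/pocket point clouds.

The ligand generator embeds simple topologies (chains, rings, one-branch
trees) in 3D with tightly distributed bond lengths and angles, mimicking the
local geometric regularities of small organic molecules: bonds 1.5 ± 0.03 Å,
tetrahedral chain angles 109.5 ± 3°, planar rings with the interior polygon
angle.  Atom types are drawn i.i.d. from a K-way alphabet (default K = 4,
mapped onto C/N/O/F).  Pockets are stubs: a fixed anchor scaffold whose
centroid (plus a template offset) determines where the paired ligand sits,
giving conditional generation a learnable, exactly invertible signal.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molecule import Molecule

__all__ = [
    "MoleculeTemplate",
    "PocketStub",
    "Instance",
    "make_toy_continuous",
    "make_toy_discrete",
    "make_ligand",
    "make_pocket_ligand_pair",
    "make_dataset",
]


@dataclass(frozen=True)
class MoleculeTemplate:
    """Generative recipe for a synthetic ligand."""

    topology: str = "chain"  # chain | ring | branched
    n_atoms_range: tuple = (5, 8)
    bond_length_mean: float = 1.5
    bond_length_sd: float = 0.03
    angle_mean: float | None = None  # None: 109.5 for chains, polygon angle for rings
    angle_sd: float = 3.0
    type_distribution: np.ndarray | None = None
    K: int = 4

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "ring", "branched"):
            raise ValueError(f"unknown topology {self.topology!r}")
        lo, hi = self.n_atoms_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid n_atoms_range")
        if self.topology == "ring" and lo < 3:
            raise ValueError("rings need at least 3 atoms")
        if self.topology == "branched" and lo < 4:
            raise ValueError("branched topology needs at least 4 atoms")
        if self.bond_length_mean <= 0 or self.bond_length_sd < 0 or self.angle_sd < 0:
            raise ValueError("lengths must be positive, sds nonnegative")
        td = self.type_distribution
        if td is None:
            td = np.full(self.K, 1.0 / self.K)
        td = np.asarray(td, dtype=float)
        if td.shape != (self.K,) or np.any(td < 0) or abs(td.sum() - 1.0) > 1e-9:
            raise ValueError("type_distribution must be a K-simplex point")
        object.__setattr__(self, "type_distribution", td)


@dataclass(frozen=True)
class PocketStub:
    """Fixed anchor point cloud standing in for a protein binding site."""

    coords: np.ndarray
    types: np.ndarray
    binding_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class Instance:
    """A training/evaluation instance: ligand plus optional pocket."""

    id: object
    molecule: Molecule
    pocket: PocketStub | None = None


# --- toy distributions ---------------------------------------------------------

_TOY_SPECS = {
    # name: (means, weights, sd)
    "two_gaussians": (np.array([[-2.0, 0.0], [2.0, 0.0]]), np.array([0.5, 0.5]), 0.5),
    "ring_mixture": (
        2.0
        * np.stack(
            [
                np.cos(2 * np.pi * np.arange(8) / 8),
                np.sin(2 * np.pi * np.arange(8) / 8),
            ],
            axis=1,
        ),
        np.full(8, 1.0 / 8),
        0.2,
    ),
    "grid_mixture": (
        np.array([[2.0 * i, 2.0 * j] for i in (-1, 0, 1) for j in (-1, 0, 1)]),
        np.full(9, 1.0 / 9),
        0.15,
    ),
}


def toy_mixture_mean(name: str) -> np.ndarray:
    """Closed-form mean of a named toy mixture (test oracle)."""
    means, weights, _ = _TOY_SPECS[name]
    return weights @ means


def make_toy_continuous(name: str, n: int, seed: int) -> np.ndarray:
    """n seeded 2D draws from a named Gaussian mixture."""
    if name not in _TOY_SPECS:
        raise ValueError(f"unknown toy dataset {name!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    means, weights, sd = _TOY_SPECS[name]
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    return means[comp] + rng.normal(0.0, sd, size=(n, 2))


def make_toy_discrete(K: int, probs, n: int, seed: int) -> np.ndarray:
    """n seeded category draws from a K-way categorical."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (K,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a K-simplex point")
    rng = np.random.default_rng(seed)
    return rng.choice(K, size=n, p=probs)


# --- ligand geometry -----------------------------------------------------------


def _chain_coords(
    n: int, lengths: np.ndarray, angles_deg: np.ndarray
) -> np.ndarray:
    """Planar zig-zag chain: bond i has given length, interior angles given."""
    coords = np.zeros((n, 3))
    coords[1] = [lengths[0], 0.0, 0.0]
    direction = 0.0  # heading angle in the xy-plane
    sign = 1.0
    for i in range(2, n):
        turn = np.deg2rad(180.0 - angles_deg[i - 2]) * sign
        direction += turn
        coords[i] = coords[i - 1] + lengths[i - 1] * np.array(
            [np.cos(direction), np.sin(direction), 0.0]
        )
        sign = -sign
    return coords


def _ring_coords(n: int, lengths: np.ndarray, angle_sd: float, rng) -> np.ndarray:
    """Planar n-ring built as an open chain then closed by a linear-ramp
    adjustment; closure residual must stay below 0.1 Å."""
    interior = 180.0 * (n - 2) / n
    angles = interior + rng.normal(0.0, angle_sd, size=n - 2)
    coords = np.zeros((n, 3))
    coords[1] = [lengths[0], 0.0, 0.0]
    direction = 0.0
    for i in range(2, n):
        direction += np.deg2rad(180.0 - angles[i - 2])
        coords[i] = coords[i - 1] + lengths[i - 1] * np.array(
            [np.cos(direction), np.sin(direction), 0.0]
        )
    # close the ring by constrained adjustment: alternately distribute the
    # closing-bond gap along the chain and re-enforce the drawn bond lengths
    ramp = (np.arange(n) / (n - 1))[:, None]
    for _ in range(8):
        gap_vec = coords[n - 1] - coords[0]
        gap = np.linalg.norm(gap_vec)
        target = coords[0] + lengths[n - 1] * gap_vec / gap
        coords = coords + ramp * (target - coords[n - 1])
        for i in range(n - 1):
            bond = coords[i + 1] - coords[i]
            coords[i + 1] = coords[i] + lengths[i] * bond / np.linalg.norm(bond)
    residual = abs(np.linalg.norm(coords[n - 1] - coords[0]) - lengths[n - 1])
    if residual > 0.1:
        raise ValueError("ring closure infeasible for the drawn geometry")
    return coords


def make_ligand(template: MoleculeTemplate, seed: int) -> Molecule:
    """Embed the template topology in 3D with noisy bond geometry."""
    rng = np.random.default_rng(seed)
    lo, hi = template.n_atoms_range
    n = int(rng.integers(lo, hi + 1))
    mean, sd = template.bond_length_mean, template.bond_length_sd
    if template.topology == "chain":
        angle = 109.5 if template.angle_mean is None else template.angle_mean
        lengths = rng.normal(mean, sd, size=n - 1)
        angles = angle + rng.normal(0.0, template.angle_sd, size=max(n - 2, 0))
        coords = _chain_coords(n, lengths, angles)
    elif template.topology == "ring":
        lengths = rng.normal(mean, sd, size=n)
        coords = _ring_coords(n, lengths, template.angle_sd, rng)
    else:  # branched: chain of n-1 atoms plus one substituent on a middle atom
        nb = n - 1
        lengths = rng.normal(mean, sd, size=nb - 1)
        angles = 109.5 + rng.normal(0.0, template.angle_sd, size=max(nb - 2, 0))
        backbone = _chain_coords(nb, lengths, angles)
        attach = nb // 2
        branch_dir = np.array([0.0, 0.0, 1.0])
        branch = backbone[attach] + rng.normal(mean, sd) * branch_dir
        coords = np.vstack([backbone, branch])
    types = rng.choice(template.K, size=n, p=template.type_distribution)
    coords = coords - coords.mean(axis=0)
    return Molecule(coords=coords, types=types, K=template.K)


# --- pocket pairing ------------------------------------------------------------


def _anchor_scaffold(m: int) -> np.ndarray:
    """Deterministic anchor ring of radius 4 Å in the xy-plane, centred at 0."""
    ang = 2.0 * np.pi * np.arange(m) / m
    return np.stack([4.0 * np.cos(ang), 4.0 * np.sin(ang), np.zeros(m)], axis=1)


def make_pocket_ligand_pair(
    template: MoleculeTemplate,
    pocket_size: int = 4,
    seed: int = 0,
    binding_offset=(0.0, 0.0, 0.0),
) -> tuple[PocketStub, Molecule]:
    """A pocket stub and a ligand whose centroid sits at
    anchor-centroid + binding_offset (the documented, invertible placement rule)."""
    if pocket_size < 2:
        raise ValueError("pocket needs at least 2 anchors")
    offset = np.asarray(binding_offset, dtype=float)
    anchors = _anchor_scaffold(pocket_size)
    types = np.arange(pocket_size) % 2  # alternating anchor types
    pocket = PocketStub(coords=anchors, types=types, binding_offset=offset)
    lig = make_ligand(template, seed)
    lig = lig.translated(pocket.centroid + offset - lig.coords.mean(axis=0))
    return pocket, lig


def make_dataset(
    template: MoleculeTemplate,
    n: int,
    seed: int,
    with_pocket: bool = True,
    pocket_size: int = 4,
) -> list:
    """n seeded instances; per-instance seeds are derived from the master seed."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for i, s in enumerate(sub_seeds):
        if with_pocket:
            pocket, lig = make_pocket_ligand_pair(template, pocket_size, int(s))
            out.append(Instance(id=i, molecule=lig, pocket=pocket))
        else:
            out.append(Instance(id=i, molecule=make_ligand(template, int(s))))
    return out
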