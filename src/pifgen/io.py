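"""XYZ/SDF readers and writers plus run-configuration handling.

XYZ is the primary interchange format (element symbol + coordinates is all
the model consumes); SDF (V2000) output is optional, with distance-rule
single-bond perception as a convenience.  Configurations are YAML with
per-section key validation: unknown keys are rejected and a content hash is
recorded so artifact directories are reproducible.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

from .evaluation import perceive_bonds
from .losses import LossWeights
from .molecule import DEFAULT_ALPHABET, Molecule
from .sampler import SamplerConfig
from .schedule_interp import PriorConfig, ScheduleConfig
from .training import MaskConfig, TrainConfig

__all__ = ["read_xyz", "write_xyz", "write_sdf", "load_config", "RunConfig"]


def write_xyz(path: str, mol: Molecule, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{mol.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(mol.elements, mol.coords):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str, alphabet=DEFAULT_ALPHABET, K: int | None = None) -> Molecule:
    sym_to_idx = {s: i for i, s in enumerate(alphabet)}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ValueError(f"{path}:1: malformed atom count") from exc
    coords, types = [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: malformed atom line")
        el = parts[0]
        if el not in sym_to_idx:
            raise ValueError(f"{path}:{ln}: unknown element symbol {el!r}")
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed coordinate") from exc
        types.append(sym_to_idx[el])
    if len(coords) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(coords)}")
    return Molecule(
        coords=np.asarray(coords).reshape(-1, 3),
        types=np.asarray(types, dtype=int),
        K=K or len(alphabet),
        alphabet=tuple(alphabet),
    )


def write_sdf(path: str, mol: Molecule, perceive: bool = True, name: str = "pifgen") -> None:
    """V2000 SDF; bonds (all single) come from distance-rule perception."""
    if mol.n_atoms > 999:
        raise ValueError("V2000 SDF is limited to 999 atoms")
    bonds = perceive_bonds(mol) if perceive else []
    lines = [name, "  pifgen", ""]
    lines.append(
        f"{mol.n_atoms:3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(
            f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i, j in bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}  1  0  0  0  0")
    lines += ["M  END", "$$$$", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


# --- configuration --------------------------------------------------------------

_SECTIONS = {
    "schedule": {"kind", "gamma"},
    "prior": {"family", "eps0", "beta0", "K"},
    "loss": {"lambda_x", "lambda_v", "dirichlet_form"},
    "mask": {"p_activate", "p_atom"},
    "model": {"hidden_dim", "layers", "knn_k"},
    "train": {"steps", "batch_size", "learning_rate", "seed", "log_interval",
              "checkpoint_interval", "t_max"},
    "sample": {"n_steps", "seed"},
    "data": {"template", "n", "seed", "with_pocket", "pocket_size"},
    "eval": {"bins"},
}


class RunConfig:
    """Validated nested configuration with paper-default hyperparameters."""

    def __init__(self, raw: dict | None = None):
        raw = raw or {}
        unknown_sections = set(raw) - set(_SECTIONS)
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        for section, allowed in _SECTIONS.items():
            given = raw.get(section, {}) or {}
            unknown = set(given) - allowed
            if unknown:
                raise ValueError(
                    f"unknown keys in [{section}]: {sorted(unknown)}"
                )
        self.raw = raw
        sched = raw.get("schedule", {}) or {}
        self.schedule = ScheduleConfig(
            kind=sched.get("kind", "exponential"), gamma=sched.get("gamma", 0.009)
        )
        pr = raw.get("prior", {}) or {}
        self.prior = PriorConfig(
            continuous_family=pr.get("family", "gaussian"),
            eps0=pr.get("eps0", 1.0),
            beta0=pr.get("beta0", 1.0),
            K=pr.get("K", 4),
        )
        lo = raw.get("loss", {}) or {}
        self.loss = LossWeights(
            lambda_x=lo.get("lambda_x", 1.0), lambda_v=lo.get("lambda_v", 1.0)
        )
        self.dirichlet_form = lo.get("dirichlet_form", "printed")
        mk = raw.get("mask", {}) or {}
        self.mask = MaskConfig(
            p_activate=mk.get("p_activate", 0.3), p_atom=mk.get("p_atom", 0.3)
        )
        mo = raw.get("model", {}) or {}
        self.model = {
            "hidden_dim": mo.get("hidden_dim", 64),
            "n_layers": mo.get("layers", 4),
            "knn_k": mo.get("knn_k", 8),
        }
        tr = raw.get("train", {}) or {}
        self.train = TrainConfig(
            steps=tr.get("steps", 2000),
            batch_size=tr.get("batch_size", 8),
            learning_rate=tr.get("learning_rate", 1e-3),
            seed=tr.get("seed", 0),
            schedule=self.schedule,
            prior=self.prior,
            loss=self.loss,
            mask=self.mask,
            t_max=tr.get("t_max", 0.99),
            log_interval=tr.get("log_interval", 50),
            checkpoint_interval=tr.get("checkpoint_interval", 0),
            dirichlet_form=self.dirichlet_form,
        )
        sa = raw.get("sample", {}) or {}
        self.sample = SamplerConfig(
            n_steps=sa.get("n_steps", 100),
            seed=sa.get("seed", 0),
            schedule=self.schedule,
            prior=self.prior,
        )
        self.data = {
            "template": (raw.get("data", {}) or {}).get("template", "chain"),
            "n": (raw.get("data", {}) or {}).get("n", 500),
            "seed": (raw.get("data", {}) or {}).get("seed", 0),
            "with_pocket": (raw.get("data", {}) or {}).get("with_pocket", True),
            "pocket_size": (raw.get("data", {}) or {}).get("pocket_size", 4),
        }
        self.eval_bins = (raw.get("eval", {}) or {}).get("bins", 64)

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(raw)
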