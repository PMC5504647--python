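"""Atomic containers: atom records, the rigid receptor, discrete ligand conformers, poses.

The receptor is held rigid throughout sampling; ligand flexibility is represented
by a discrete conformer library ("rotamers") plus a rigid-body transform. All
coordinates are Cartesian, in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "ROLE_BACKBONE",
    "ROLE_SIDECHAIN",
    "ROLE_LIGAND",
    "BACKBONE_ATOM_NAMES",
    "AtomRecord",
    "Receptor",
    "ConformerSet",
    "Pose",
]

ROLE_BACKBONE = "receptor-backbone"
ROLE_SIDECHAIN = "receptor-sidechain"
ROLE_LIGAND = "ligand"
_ROLES = (ROLE_BACKBONE, ROLE_SIDECHAIN, ROLE_LIGAND)

#: PDB atom names treated as protein backbone.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})

_POLAR_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, position and its role in the complex."""

    element: str
    coords: np.ndarray
    is_hydrogen: bool = False
    role: str = ROLE_LIGAND
    name: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError("atom coordinates must be finite")
        object.__setattr__(self, "coords", c)
        if self.role not in _ROLES:
            raise ValueError(f"unknown atom role: {self.role!r}")


def _infer_hydrogen(element: str) -> bool:
    return element.strip().upper() == "H"


class Receptor:
    """Rigid receptor stored as flat arrays for fast pairwise scoring.

    ``interaction_scale`` is a per-atom multiplier on the attractive surrogate
    well depth; the synthetic pocket fixture deepens it locally to plant a
    binding site, real receptors leave it at 1.
    """

    def __init__(
        self,
        coords: np.ndarray,
        elements: Sequence[str],
        names: Sequence[str] | None = None,
        is_hydrogen: Sequence[bool] | None = None,
        is_backbone: Sequence[bool] | None = None,
        interaction_scale: np.ndarray | None = None,
    ) -> None:
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.elements = np.asarray(elements, dtype=object)
        self.names = np.asarray(names if names is not None else [""] * n, dtype=object)
        if is_hydrogen is None:
            is_hydrogen = [_infer_hydrogen(e) for e in self.elements]
        self.is_hydrogen = np.asarray(is_hydrogen, dtype=bool)
        if is_backbone is None:
            is_backbone = [nm in BACKBONE_ATOM_NAMES for nm in self.names]
        self.is_backbone = np.asarray(is_backbone, dtype=bool)
        self.interaction_scale = (
            np.ones(n) if interaction_scale is None else np.asarray(interaction_scale, dtype=float)
        )
        if not (len(self.elements) == len(self.is_hydrogen) == len(self.is_backbone) == n):
            raise ValueError("receptor array lengths disagree")
        # clash set: backbone atoms plus C-beta
        self.clash_mask = self.is_backbone | (self.names == "CB")
        self.heavy_mask = ~self.is_hydrogen
        self.polar_mask = np.array([e.upper() in _POLAR_ELEMENTS for e in self.elements]) & self.heavy_mask

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_atom_records(cls, atoms: Iterable[AtomRecord]) -> "Receptor":
        atoms = list(atoms)
        if not atoms:
            raise ValueError("receptor needs at least one atom")
        if any(a.role == ROLE_LIGAND for a in atoms):
            raise ValueError("ligand atom passed to Receptor")
        return cls(
            coords=np.array([a.coords for a in atoms]),
            elements=[a.element for a in atoms],
            names=[a.name for a in atoms],
            is_hydrogen=[a.is_hydrogen for a in atoms],
            is_backbone=[a.role == ROLE_BACKBONE for a in atoms],
        )

    def to_atom_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                element=str(self.elements[i]),
                coords=self.coords[i],
                is_hydrogen=bool(self.is_hydrogen[i]),
                role=ROLE_BACKBONE if self.is_backbone[i] else ROLE_SIDECHAIN,
                name=str(self.names[i]),
            )
            for i in range(len(self))
        ]


class ConformerSet:
    """Ordered library of ligand conformations sharing atom identity and order."""

    def __init__(
        self,
        coords: np.ndarray,
        elements: Sequence[str],
        names: Sequence[str] | None = None,
        is_hydrogen: Sequence[bool] | None = None,
    ) -> None:
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("conformer coords must have shape (k, m, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one conformer")
        m = self.coords.shape[1]
        self.elements = np.asarray(elements, dtype=object)
        self.names = np.asarray(names if names is not None else [""] * m, dtype=object)
        if is_hydrogen is None:
            is_hydrogen = [_infer_hydrogen(e) for e in self.elements]
        self.is_hydrogen = np.asarray(is_hydrogen, dtype=bool)
        if len(self.elements) != m or len(self.is_hydrogen) != m:
            raise ValueError("conformer atom annotations disagree with coordinates")
        self.heavy_mask = ~self.is_hydrogen
        self.centroids = self.coords.mean(axis=1)

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_heavy(self) -> int:
        return int(self.heavy_mask.sum())


@dataclass(frozen=True)
class Pose:
    """Sampler state: receptor + one ligand conformer under a rigid transform."""

    receptor: Receptor
    conformers: ConformerSet
    conformer_index: int = 0
    transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if not (0 <= self.conformer_index < self.conformers.n_conformers):
            raise ValueError("conformer index out of range")

    def ligand_coords(self) -> np.ndarray:
        """Ligand atomic coordinates in the receptor frame, (m, 3)."""
        conf = self.conformers.coords[self.conformer_index]
        center = self.conformers.centroids[self.conformer_index]
        return self.transform.apply(conf, center)

    def ligand_heavy_coords(self) -> np.ndarray:
        return self.ligand_coords()[self.conformers.heavy_mask]

    def with_transform(self, transform: RigidTransform, conformer_index: int | None = None) -> "Pose":
        return Pose(
            receptor=self.receptor,
            conformers=self.conformers,
            conformer_index=self.conformer_index if conformer_index is None else conformer_index,
            transform=transform,
        )

    def translated(self, delta: np.ndarray) -> "Pose":
        """Rigidly translated copy (used by the interface-delta unbound reference)."""
        return self.with_transform(self.transform.translated(delta))

    def ligand_atom_records(self) -> list[AtomRecord]:
        coords = self.ligand_coords()
        cs = self.conformers
        return [
            AtomRecord(
                element=str(cs.elements[i]),
                coords=coords[i],
                is_hydrogen=bool(cs.is_hydrogen[i]),
                role=ROLE_LIGAND,
                name=str(cs.names[i]),
            )
            for i in range(cs.n_atoms)
        ]
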