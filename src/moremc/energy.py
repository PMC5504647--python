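"""Docking energy models.

Three scoring layers are provided:

* a coarse-grained contact score ``S_cg = R - min(A/N, 0.85)`` over ligand
  clash/contact counts, used for cheap pose filtering;
* a weighted full-atom score ``total = sum_i w_i * s_i`` over named score items,
  with the hard/soft weight presets used during repacking and rigid-body
  minimisation respectively;
* an interface-delta binding energy (bound score minus the score with the
  ligand rigidly pulled far away), used to rank decoys.

The individual full-atom score items are *surrogates*: a split 12-6
Lennard-Jones attractive/repulsive pair potential, a distance-Gaussian
hydrogen-bond well between ligand atoms and receptor N/O atoms, and a constant
per-atom reference energy. Terms with no meaningful analogue for a rigid
receptor and a chemically anonymous ligand (pair energy, backbone torsion
statistics, ...) are zero-valued stubs kept so the weighted-sum engine carries
the full set of item names. The surrogates make no claim to reproduce any
particular force field's magnitudes; only the weighted-combination semantics
and smoothness properties matter here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist

from .structure import AtomRecord, Pose, ROLE_LIGAND

logger = logging.getLogger(__name__)

__all__ = [
    "CLASH_RADIUS",
    "CONTACT_RADIUS",
    "CONTACT_SATURATION",
    "SCORE_ITEMS",
    "HARD_WEIGHTS",
    "SOFT_WEIGHTS",
    "CGCounts",
    "ScoreWeights",
    "ScoreBreakdown",
    "EnergyModel",
    "SurrogateParams",
    "coarse_grained_counts",
    "coarse_grained_counts_pose",
    "coarse_grained_score",
    "full_atom_score",
    "surrogate_terms",
    "interface_delta",
    "FullAtomModel",
    "CoarseGrainedModel",
]

#: Ligand atoms closer than this to a backbone/C-beta atom count as clashes (A).
CLASH_RADIUS = 2.25
#: Ligand atoms within (CLASH_RADIUS, CONTACT_RADIUS) of any protein atom count as contacts (A).
CONTACT_RADIUS = 4.75
#: The contact fraction A/N is rewarded only up to this saturation.
CONTACT_SATURATION = 0.85

#: Full-atom score items (Rosetta-style tags), in the canonical order of the
#: weight table: proline ring closure, LJ attractive/repulsive,
#: Lazaridis-Karplus solvation, residue pair energy, per-residue reference
#: energy, the four hydrogen-bond classes, backbone phi/psi statistics and the
#: omega dihedral restraint.
SCORE_ITEMS = (
    "pro_close",
    "fa_atr",
    "fa_rep",
    "fa_sol",
    "fa_pair",
    "ref",
    "hbond_lr_bb",
    "hbond_sr_bb",
    "hbond_bb_sc",
    "hbond_sc",
    "p_aa_pp",
    "omega",
)

#: Weights used during side-chain repacking.
HARD_WEIGHTS: Mapping[str, float] = {
    "pro_close": 1.00,
    "fa_atr": 0.80,
    "fa_rep": 0.40,
    "fa_sol": 0.60,
    "fa_pair": 0.80,
    "ref": 1.00,
    "hbond_lr_bb": 2.00,
    "hbond_sr_bb": 2.00,
    "hbond_bb_sc": 2.00,
    "hbond_sc": 2.00,
    "p_aa_pp": 0.50,
    "omega": 0.50,
}

#: Weights used during rigid-body minimisation.
SOFT_WEIGHTS: Mapping[str, float] = {
    "pro_close": 1.00,
    "fa_atr": 0.80,
    "fa_rep": 0.60,
    "fa_sol": 0.50,
    "fa_pair": 0.50,
    "ref": 1.00,
    "hbond_lr_bb": 1.20,
    "hbond_sr_bb": 1.20,
    "hbond_bb_sc": 1.20,
    "hbond_sc": 1.20,
    "p_aa_pp": 0.32,
    "omega": 0.50,
}


@dataclass(frozen=True)
class CGCounts:
    """Ligand clash/contact counts entering the coarse-grained score."""

    R: int
    A: int
    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("ligand must have at least one (non-hydrogen) atom")
        if not (0 <= self.R <= self.N and 0 <= self.A <= self.N):
            raise ValueError("counts must satisfy 0 <= R, A <= N")


@dataclass(frozen=True)
class ScoreWeights:
    """Named weights w_i for the full-atom weighted sum."""

    weights: Mapping[str, float]
    preset: str = "custom"

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @classmethod
    def hard(cls) -> "ScoreWeights":
        return cls(dict(HARD_WEIGHTS), preset="hard")

    @classmethod
    def soft(cls) -> "ScoreWeights":
        return cls(dict(SOFT_WEIGHTS), preset="soft")

    @classmethod
    def from_preset(cls, name: str) -> "ScoreWeights":
        try:
            return {"hard": cls.hard, "soft": cls.soft}[name]()
        except KeyError:
            raise ValueError(f"unknown weights preset: {name!r}") from None

    @classmethod
    def from_file(cls, path) -> "ScoreWeights":
        """Read ``item weight`` pairs (one per line, '#' comments) from a file."""
        weights: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                name, value = line.split()
                weights[name] = float(value)
        return cls(weights, preset="file")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, value in self.weights.items():
                fh.write(f"{name} {value}\n")

    def __getitem__(self, item: str) -> float:
        return self.weights[item]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Score-item values s_i plus their weighted total."""

    terms: Mapping[str, float]
    total: float

    @classmethod
    def from_terms(cls, terms: Mapping[str, float], weights: ScoreWeights) -> "ScoreBreakdown":
        return cls(terms=dict(terms), total=full_atom_score(terms, weights))


@runtime_checkable
class EnergyModel(Protocol):
    """Deterministic mapping from a sampler state to a scalar score (lower = better)."""

    def score(self, state) -> float: ...


def _split_atoms(atoms: Iterable[AtomRecord]):
    atoms = list(atoms)
    coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
    heavy = np.array([not a.is_hydrogen for a in atoms], dtype=bool)
    return atoms, coords, heavy


def coarse_grained_counts(
    receptor_atoms: Iterable[AtomRecord], ligand_atoms: Iterable[AtomRecord]
) -> CGCounts:
    """Count clashing (R) and contacting (A) ligand atoms out of N heavy ligand atoms.

    A ligand atom clashes when it sits within :data:`CLASH_RADIUS` of any
    receptor backbone or C-beta atom; a non-clashing ligand atom is a contact
    when its distance to *any* receptor atom falls in the open interval
    (:data:`CLASH_RADIUS`, :data:`CONTACT_RADIUS`). Clash takes precedence: no
    atom is counted twice. Hydrogens are excluded on both sides.
    """
    rec, rec_coords, rec_heavy = _split_atoms(receptor_atoms)
    lig, lig_coords, lig_heavy = _split_atoms(ligand_atoms)
    if any(a.role != ROLE_LIGAND for a in lig):
        raise ValueError("non-ligand atom in ligand_atoms")
    clash_set = np.array(
        [a.role == "receptor-backbone" or a.name == "CB" for a in rec], dtype=bool
    ) & rec_heavy
    return _counts_from_arrays(
        lig_coords[lig_heavy], rec_coords[rec_heavy], clash_set[rec_heavy]
    )


def _counts_from_arrays(
    lig_heavy_coords: np.ndarray, rec_heavy_coords: np.ndarray, clash_mask: np.ndarray
) -> CGCounts:
    n = len(lig_heavy_coords)
    if n == 0:
        raise ValueError("ligand has no non-hydrogen atoms")
    if len(rec_heavy_coords) == 0:
        return CGCounts(R=0, A=0, N=n)
    d = cdist(lig_heavy_coords, rec_heavy_coords)
    clashing = (
        (d[:, clash_mask] < CLASH_RADIUS).any(axis=1) if clash_mask.any() else np.zeros(n, bool)
    )
    in_band = ((d > CLASH_RADIUS) & (d < CONTACT_RADIUS)).any(axis=1)
    contacting = in_band & ~clashing
    return CGCounts(R=int(clashing.sum()), A=int(contacting.sum()), N=n)


def coarse_grained_counts_pose(pose: Pose) -> CGCounts:
    """Clash/contact counts straight from a :class:`Pose` (fast array path)."""
    rec = pose.receptor
    heavy = rec.heavy_mask
    return _counts_from_arrays(
        pose.ligand_heavy_coords(), rec.coords[heavy], rec.clash_mask[heavy]
    )


def coarse_grained_score(counts: CGCounts) -> float:
    """Contact score ``R - min(A/N, 0.85)``; lower is better, floor at -0.85."""
    return counts.R - min(counts.A / counts.N, CONTACT_SATURATION)


def full_atom_score(breakdown: Mapping[str, float] | ScoreBreakdown, weights: ScoreWeights) -> float:
    """Weighted sum ``sum_i w_i * s_i`` over the score items in ``breakdown``.

    Items with no weight contribute zero (logged once per call); NaN term
    values are rejected.
    """
    terms = breakdown.terms if isinstance(breakdown, ScoreBreakdown) else breakdown
    total = 0.0
    for name, value in terms.items():
        if math.isnan(value):
            raise ValueError(f"score item {name!r} is NaN")
        w = weights.weights.get(name)
        if w is None:
            logger.debug("score item %r has no weight; treated as 0", name)
            continue
        total += w * value
    return total


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate full-atom score items (all lengths in A).

    * Lennard-Jones: well depth ``lj_epsilon`` (scaled per receptor atom by the
      receptor's ``interaction_scale``), collision diameter ``lj_sigma``; the
      potential is split at the pair minimum r_min = 2^(1/6) sigma into a purely
      attractive branch (constant -epsilon inside r_min) and a purely repulsive
      branch (zero outside r_min), capped at ``repulsion_cap`` so overlapping
      atoms stay finite for Metropolis arithmetic.
    * Hydrogen bond: Gaussian well of depth ``hbond_depth`` and width
      ``hbond_width`` centred at ``hbond_r0`` between ligand heavy atoms and
      receptor N/O atoms.
    * Reference: constant ``ref_per_atom`` per heavy ligand atom.
    """

    lj_epsilon: float = 0.1
    lj_sigma: float = 3.4
    repulsion_cap: float = 1.0e4
    hbond_r0: float = 2.9
    hbond_width: float = 0.4
    hbond_depth: float = 0.5
    ref_per_atom: float = 0.25

    @property
    def lj_rmin(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.lj_sigma


def surrogate_terms(pose: Pose, params: SurrogateParams | None = None) -> ScoreBreakdown:
    """Evaluate every full-atom score item for a pose (unweighted values).

    Only ligand-receptor heavy-atom interactions are scored (the receptor is
    rigid, so its internal terms are constants and fixed to zero). The
    breakdown's ``total`` is the plain unweighted sum; combine with
    :func:`full_atom_score` for a weighted total.
    """
    params = params or SurrogateParams()
    rec = pose.receptor
    heavy = rec.heavy_mask
    rec_coords = rec.coords[heavy]
    scale = rec.interaction_scale[heavy]
    polar = rec.polar_mask[heavy]
    lig = pose.ligand_heavy_coords()
    if len(lig) == 0 or len(rec_coords) == 0:
        raise ValueError("surrogate terms need at least one heavy atom on each side")

    d = cdist(lig, rec_coords)
    np.clip(d, 1e-6, None, out=d)
    eps = params.lj_epsilon * scale[None, :]
    sr6 = (params.lj_sigma / d) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    inside = d < params.lj_rmin
    atr = np.where(inside, -eps, lj)
    rep = np.where(inside, np.minimum(lj + eps, params.repulsion_cap), 0.0)

    hb = 0.0
    if polar.any():
        dh = d[:, polar]
        hb = -params.hbond_depth * float(
            np.exp(-((dh - params.hbond_r0) ** 2) / (2.0 * params.hbond_width**2)).sum()
        )

    terms = {name: 0.0 for name in SCORE_ITEMS}
    terms["fa_atr"] = float(atr.sum())
    terms["fa_rep"] = float(rep.sum())
    terms["hbond_sc"] = hb
    terms["ref"] = params.ref_per_atom * len(lig)
    return ScoreBreakdown(terms=terms, total=float(sum(terms.values())))


#: Separation (A) treated as "unbound" when computing the interface delta.
UNBOUND_SEPARATION = 500.0


def interface_delta(pose: Pose, model: EnergyModel, separation: float = UNBOUND_SEPARATION) -> float:
    """Binding energy: score(bound) - score(ligand translated ``separation`` A away).

    Negative values indicate favourable binding. Any separation beyond every
    interaction range gives the same answer, so the default 500 A is safely
    "at infinity" for the shipped surrogates.
    """
    if separation < UNBOUND_SEPARATION:
        raise ValueError("separation must be at least 500 A")
    unbound = pose.translated(np.array([separation, 0.0, 0.0]))
    return model.score(pose) - model.score(unbound)


class FullAtomModel:
    """Full-atom energy model: weighted surrogate score items over a pose."""

    def __init__(
        self, weights: ScoreWeights | None = None, params: SurrogateParams | None = None
    ) -> None:
        self.weights = weights or ScoreWeights.hard()
        self.params = params or SurrogateParams()

    def breakdown(self, pose: Pose) -> ScoreBreakdown:
        return ScoreBreakdown.from_terms(surrogate_terms(pose, self.params).terms, self.weights)

    def score(self, pose: Pose) -> float:
        return full_atom_score(surrogate_terms(pose, self.params).terms, self.weights)

    def interface_delta(self, pose: Pose) -> float:
        return interface_delta(pose, self)


class CoarseGrainedModel:
    """Coarse-grained contact model over a pose (``S_cg`` as the score)."""

    def score(self, pose: Pose) -> float:
        return coarse_grained_score(coarse_grained_counts_pose(pose))
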