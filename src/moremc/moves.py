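"""Pose perturbation operators ("movers").

Two movers are provided: a small rigid-body trial move (with an occasional
ligand conformer swap) and a larger-amplitude "repack" surrogate that stands in
for periodic side-chain repacking — the receptor itself stays rigid, so the
repack surrogate instead shakes the ligand harder and always resamples its
conformer. :func:`propose` dispatches between them on the step index: every
``repackNth``-th step takes the repack path.

Movers are pure: they never mutate their input pose, and rigid moves preserve
all ligand intramolecular distances exactly (up to floating rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import random_rotation_matrix, rotation_about_axis
from .structure import Pose

__all__ = ["MoveConfig", "rotamer_trial_move", "repack_surrogate_move", "propose"]


@dataclass(frozen=True)
class MoveConfig:
    """Perturbation magnitudes (A / degrees) and the conformer-swap probability."""

    trial_translation_sd: float = 0.2
    trial_rotation_sd: float = 5.0
    repack_translation_sd: float = 1.0
    repack_rotation_sd: float = 30.0
    conformer_swap_prob: float = 0.2

    def __post_init__(self) -> None:
        if min(
            self.trial_translation_sd,
            self.trial_rotation_sd,
            self.repack_translation_sd,
            self.repack_rotation_sd,
        ) < 0:
            raise ValueError("move magnitudes must be non-negative")
        if not 0.0 <= self.conformer_swap_prob <= 1.0:
            raise ValueError("conformer_swap_prob must lie in [0, 1]")


def _perturb(
    pose: Pose,
    translation_sd: float,
    rotation_sd_deg: float,
    rng: np.random.Generator,
    conformer_index: int,
) -> Pose:
    """Gaussian translation + small rotation about a uniform random axis."""
    delta_t = (
        rng.normal(0.0, translation_sd, size=3) if translation_sd > 0 else np.zeros(3)
    )
    if rotation_sd_deg > 0:
        axis = random_rotation_matrix(rng)[:, 0]  # uniform direction on the sphere
        angle = math.radians(rng.normal(0.0, rotation_sd_deg))
        delta_r = rotation_about_axis(axis, angle)
    else:
        delta_r = np.eye(3)
    return pose.with_transform(
        pose.transform.then(delta_r, delta_t), conformer_index=conformer_index
    )


def rotamer_trial_move(pose: Pose, cfg: MoveConfig, rng: np.random.Generator) -> Pose:
    """Small rigid-body trial; with probability ``conformer_swap_prob`` also swap the conformer."""
    k = pose.conformers.n_conformers
    idx = pose.conformer_index
    if k > 1 and cfg.conformer_swap_prob > 0 and rng.uniform() < cfg.conformer_swap_prob:
        idx = int(rng.integers(k))
    return _perturb(pose, cfg.trial_translation_sd, cfg.trial_rotation_sd, rng, idx)


def repack_surrogate_move(pose: Pose, cfg: MoveConfig, rng: np.random.Generator) -> Pose:
    """Large-amplitude move with a forced uniform conformer resample."""
    k = pose.conformers.n_conformers
    idx = int(rng.integers(k)) if k > 1 else pose.conformer_index
    return _perturb(pose, cfg.repack_translation_sd, cfg.repack_rotation_sd, rng, idx)


def propose(
    pose: Pose,
    step_index: int,
    repackNth: int,
    cfg: MoveConfig,
    rng: np.random.Generator,
) -> Pose:
    """Dispatch: repack on every positive multiple of ``repackNth``, trial otherwise."""
    if repackNth < 1:
        raise ValueError("repackNth must be >= 1")
    if step_index > 0 and step_index % repackNth == 0:
        return repack_surrogate_move(pose, cfg, rng)
    return rotamer_trial_move(pose, cfg, rng)


class PoseProposer:
    """Callable proposer binding a :class:`MoveConfig` and repack cadence.

    Matches the ``proposer(state, step_index, rng)`` signature the samplers use,
    so docking poses and abstract test states share one sampler code path.
    """

    def __init__(self, cfg: MoveConfig | None = None, repackNth: int = 5) -> None:
        if repackNth < 1:
            raise ValueError("repackNth must be >= 1")
        self.cfg = cfg or MoveConfig()
        self.repackNth = repackNth

    def __call__(self, pose: Pose, step_index: int, rng: np.random.Generator) -> Pose:
        return propose(pose, step_index, self.repackNth, self.cfg, rng)
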