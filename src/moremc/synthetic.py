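"""Synthetic fixtures: analytic landscapes and toy docking complexes.

Everything the samplers and selectors need for testing is generated here, with
known ground truth:

* finite discrete systems whose Boltzmann distribution is available in closed
  form (Metropolis stationarity oracle);
* a 1-D quartic double well with a stated barrier, whose per-well occupancy at
  any temperature follows from numeric quadrature (barrier-crossing and
  replica-exchange convergence oracle);
* toy receptor-ligand complexes with a planted binding pocket whose native
  pose is the interface-delta minimum by construction (end-to-end docking
  oracle);
* archives with controllable Pareto-front structure (selector fixtures).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .geometry import RigidTransform, random_rotation_matrix
from .samplers import ArchiveEntry
from .structure import ConformerSet, Pose, Receptor

__all__ = [
    "DiscreteSystem",
    "make_discrete_system",
    "DoubleWell",
    "make_double_well",
    "GaussianProposer",
    "ToyComplexSpec",
    "ToyComplex",
    "make_toy_complex",
    "make_decoy_archive",
]


@dataclass(frozen=True)
class DiscreteSystem:
    """Finite state space with an energy table and symmetric uniform proposals.

    Doubles as its own energy model (``score``) and proposer (``propose``),
    so it plugs straight into the samplers. The exact Boltzmann distribution
    at any temperature is available for oracle tests.
    """

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if len(e) < 2:
            raise ValueError("need at least two states")
        if not np.all(np.isfinite(e)):
            raise ValueError("energies must be finite")

    @property
    def n_states(self) -> int:
        return len(self.energies)

    def score(self, state: int) -> float:
        return float(self.energies[state])

    def propose(self, state: int, step: int, rng: np.random.Generator) -> int:
        """Uniform proposal over the other states (symmetric by construction)."""
        other = int(rng.integers(self.n_states - 1))
        return other if other < state else other + 1

    def boltzmann(self, T: float) -> np.ndarray:
        """Exact stationary distribution proportional to exp(-E/T)."""
        if T <= 0:
            raise ValueError("temperature must be positive")
        w = np.exp(-(self.energies - self.energies.min()) / T)
        return w / w.sum()


def make_discrete_system(energies: Sequence[float]) -> DiscreteSystem:
    """Discrete system fixture; the returned object is both model and proposer."""
    return DiscreteSystem(np.asarray(energies, dtype=float))


class GaussianProposer:
    """Symmetric Gaussian random-walk proposal for scalar states."""

    def __init__(self, sd: float = 0.35) -> None:
        if sd <= 0:
            raise ValueError("proposal sd must be positive")
        self.sd = sd

    def __call__(self, state: float, step: int, rng: np.random.Generator) -> float:
        return state + rng.normal(0.0, self.sd)


@dataclass(frozen=True)
class DoubleWell:
    """Quartic double well E(x) = barrier*(x^2-1)^2 - asymmetry*(x+1)/2.

    With zero asymmetry the wells at x = +/-1 are symmetric and the barrier
    top at x = 0 sits exactly ``barrier`` above them; a positive asymmetry
    tilts the landscape so the right-hand well is deeper. Stationary
    quantities (per-well occupancy) are computed by numeric quadrature of the
    Boltzmann density, split at the barrier top.
    """

    barrier: float
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")

    def score(self, x: float) -> float:
        x2 = x * x
        return self.barrier * (x2 - 1.0) * (x2 - 1.0) - 0.5 * self.asymmetry * (x + 1.0)

    def stationary_points(self) -> np.ndarray:
        """Real roots of dE/dx, ascending: left minimum, barrier top, right minimum."""
        b, a = self.barrier, self.asymmetry
        roots = np.roots([4.0 * b, 0.0, -4.0 * b, -0.5 * a])
        real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
        if len(real) != 3:
            raise ValueError("asymmetry too large: the double well degenerated")
        return real

    @property
    def minima(self) -> tuple[float, float]:
        pts = self.stationary_points()
        return float(pts[0]), float(pts[2])

    @property
    def barrier_top(self) -> float:
        return float(self.stationary_points()[1])

    def well_of(self, x: float) -> int:
        """0 for the left well, 1 for the right, split at the barrier top."""
        return int(x > self.barrier_top)

    def well_probabilities(self, T: float, bound: float = 6.0) -> tuple[float, float]:
        """Boltzmann mass of each well at temperature T, by quadrature."""
        if T <= 0:
            raise ValueError("temperature must be positive")
        top = self.barrier_top
        e0 = min(self.score(m) for m in self.minima)
        dens = lambda x: math.exp(-(self.score(x) - e0) / T)  # noqa: E731
        left, _ = quad(dens, -bound, top, limit=200)
        right, _ = quad(dens, top, bound, limit=200)
        z = left + right
        return left / z, right / z

    def occupancy_ratio(self, T: float) -> float:
        """Right-to-left well occupancy ratio at temperature T."""
        left, right = self.well_probabilities(T)
        return right / left


def make_double_well(barrier: float, asymmetry: float = 0.0) -> DoubleWell:
    """1-D double-well energy model with known Boltzmann well occupancies."""
    return DoubleWell(barrier=barrier, asymmetry=asymmetry)


# ---------------------------------------------------------------------------
# toy docking complex
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of the planted-pocket toy complex.

    The receptor is a spherical-cap shell of pseudo-residue atoms (opening at
    the top); atoms within ``pocket_radius`` of the bottom pole have their
    attractive well depth multiplied by ``pocket_depth``, planting a single
    global binding-energy minimum there. The ligand is a compact ring of
    ``n_ligand`` heavy atoms with ``n_conformers`` discrete conformations; the
    randomized starting pose floats ``start_offset`` A above the native
    centroid near the cap opening.
    """

    n_receptor: int = 150
    n_ligand: int = 8
    n_conformers: int = 5
    pocket_depth: float = 8.0
    pocket_radius: float = 4.5
    shell_radius: float = 10.0
    start_offset: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligand < 2:
            raise ValueError("ligand needs at least two atoms")
        if self.n_conformers < 1 or self.n_receptor < 10:
            raise ValueError("invalid toy-complex size")


@dataclass(frozen=True)
class ToyComplex:
    """Generated fixture: receptor, conformer library, native and start poses."""

    spec: ToyComplexSpec
    receptor: Receptor
    conformers: ConformerSet
    native_pose: Pose
    start_pose: Pose


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistributed unit vectors (Fibonacci lattice)."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_RESIDUE_NAMES = ("N", "CA", "C", "O", "CB", "CG")


def make_toy_complex(spec: ToyComplexSpec | None = None) -> ToyComplex:
    """Build a toy complex whose interface-delta global minimum is the native pose."""
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)

    # receptor: the lowest-z cap of a Fibonacci sphere shell (bowl opening up)
    n_total = int(math.ceil(spec.n_receptor * 1.5))
    pts = _fibonacci_sphere(n_total) * spec.shell_radius
    order = np.argsort(pts[:, 2])
    coords = pts[order[: spec.n_receptor]]
    names = [_RESIDUE_NAMES[i % len(_RESIDUE_NAMES)] for i in range(spec.n_receptor)]
    elements = [nm[0] if nm[0] in ("N", "O") else "C" for nm in names]
    pole = np.array([0.0, 0.0, -spec.shell_radius])
    pocket = np.linalg.norm(coords - pole, axis=1) < spec.pocket_radius
    # per-atom pocket strengths vary (seeded), breaking the axial symmetry of
    # the cap so the planted orientation is a *unique* minimum, not one point
    # on a rotationally degenerate circle
    pocket_scale = spec.pocket_depth * (0.6 + 0.8 * rng.random(spec.n_receptor))
    scale = np.where(pocket, pocket_scale, 1.0)
    receptor = Receptor(
        coords=coords, elements=elements, names=names, interaction_scale=scale
    )

    # ligand: a compact *irregular* loop (varying radius and height, so no
    # rotation maps it onto itself), anchored just above the pocket
    from .energy import SurrogateParams

    anchor = pole + np.array([0.0, 0.0, SurrogateParams().lj_rmin])
    i = np.arange(spec.n_ligand)
    theta = 2.0 * math.pi * i / spec.n_ligand
    radius = 1.1 + 0.5 * i / spec.n_ligand
    ring = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), 0.15 * np.sin(2.0 * theta)]
    )
    native_conf = anchor + ring + rng.normal(0.0, 0.05, size=ring.shape)
    # alternative conformers differ in *internal* geometry only (rigid
    # rotations are already covered by the pose transform)
    confs = [native_conf]
    for _ in range(spec.n_conformers - 1):
        confs.append(native_conf + rng.normal(0.0, 0.25, size=ring.shape))
    lig_elements = ["C"] * spec.n_ligand
    if spec.n_ligand >= 3:
        lig_elements[0], lig_elements[1] = "O", "N"
    conformers = ConformerSet(
        coords=np.array(confs),
        elements=lig_elements,
        names=[f"L{i + 1}" for i in range(spec.n_ligand)],
    )

    native_pose = Pose(receptor=receptor, conformers=conformers, conformer_index=0)
    lateral = rng.normal(0.0, 1.0, size=2)
    start_t = np.array([lateral[0], lateral[1], spec.start_offset])
    start_pose = Pose(
        receptor=receptor,
        conformers=conformers,
        conformer_index=int(rng.integers(spec.n_conformers)),
        transform=RigidTransform(rotation=random_rotation_matrix(rng), translation=start_t),
    )
    return ToyComplex(
        spec=spec,
        receptor=receptor,
        conformers=conformers,
        native_pose=native_pose,
        start_pose=start_pose,
    )


# ---------------------------------------------------------------------------
# selector fixtures
# ---------------------------------------------------------------------------


def make_decoy_archive(
    n: int,
    seed: int = 0,
    front_size: int | None = None,
    n_duplicates: int = 0,
) -> list[ArchiveEntry]:
    """Archive of n entries whose min-min Pareto front has exactly ``front_size`` members.

    Front members carry strictly decreasing TScore at increasing step (hence
    mutually non-dominated); every other entry copies a preceding front
    member's TScore plus a positive offset, so it is dominated by that member.
    ``n_duplicates`` appends exact (step, tscore) copies of random earlier
    entries (push order later), exercising the duplicate-collapse rule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_duplicates < 0 or n_duplicates >= n:
        raise ValueError("need 0 <= n_duplicates < n")
    n_base = n - n_duplicates
    if front_size is None:
        front_size = max(1, n_base // 5)
    if not 1 <= front_size <= n_base:
        raise ValueError("front_size must lie in [1, n - n_duplicates]")
    rng = np.random.default_rng(seed)

    front_steps = np.sort(rng.choice(np.arange(2, n_base + 1), size=front_size - 1, replace=False))
    front_steps = np.concatenate([[1], front_steps])  # a front member leads the archive
    front_tscores = np.sort(rng.uniform(-10.0, 10.0, size=front_size))[::-1]
    front_by_step = dict(zip(front_steps.tolist(), front_tscores.tolist()))

    entries: list[ArchiveEntry] = []
    last_front_tscore = math.inf
    for step in range(1, n_base + 1):
        if step in front_by_step:
            tscore = front_by_step[step]
            last_front_tscore = tscore
        else:
            tscore = last_front_tscore + float(rng.uniform(0.1, 2.0))
        entries.append(
            ArchiveEntry(
                step=step, tscore=tscore, state=None, label=0,
                temperature=float("nan"), accepted=True,
            )
        )
    for _ in range(n_duplicates):
        src = entries[int(rng.integers(n_base))]
        entries.append(
            ArchiveEntry(
                step=src.step, tscore=src.tscore, state=None, label=0,
                temperature=float("nan"), accepted=True,
            )
        )
    return entries
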