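"""Binary-objective Pareto fronts and replica-selection strategies.

The replica-exchange variants differ only in how they re-seed the replica
ensemble from the history archive each cycle:

* plain REMC takes the last ``numR`` entries pushed to the archive;
* MO-REMC takes the min-min Pareto front over (MC step, TScore) — the
  non-dominated trade-off between search time and energy — topping up with the
  most recent entries when the front is short;
* hybrid MO-REMC (HMO-REMC) additionally mixes in the max-min front
  (maximise step, minimise TScore), i.e. the most *recent* low-energy
  envelope, favouring the lowest-TScore members of the combined set.

Selectors operate on any objects exposing ``step`` and ``tscore`` attributes
(archive entries) and always return exactly ``numR`` of them, never inventing
new entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

__all__ = [
    "ObjectivePoint",
    "ScenarioFlags",
    "MIN_MIN",
    "MAX_MIN",
    "MIN_MAX",
    "MAX_MAX",
    "ParetoFront",
    "dominates",
    "pareto_front",
    "select_remc_replicas",
    "select_mo_remc_replicas",
    "select_hmo_remc_replicas",
    "mo_selection_from_front",
    "hmo_selection_from_fronts",
    "SELECTORS",
]


@dataclass(frozen=True)
class ScenarioFlags:
    """Orientation of the two objectives: maximise (True) or minimise (False)."""

    maxX: bool = False
    maxY: bool = False


MIN_MIN = ScenarioFlags(False, False)
MAX_MIN = ScenarioFlags(True, False)
MIN_MAX = ScenarioFlags(False, True)
MAX_MAX = ScenarioFlags(True, True)


@dataclass(frozen=True)
class ObjectivePoint:
    """A point in objective space, optionally carrying its source entry."""

    x: float
    y: float
    payload: Any = None


def _xy(p) -> tuple[float, float]:
    if isinstance(p, ObjectivePoint):
        return p.x, p.y
    return float(p[0]), float(p[1])


def dominates(p, q, flags: ScenarioFlags = MIN_MIN) -> bool:
    """True iff ``p`` is at least as good as ``q`` in both objectives, strictly better in one."""
    px, py = _xy(p)
    qx, qy = _xy(q)
    bx = (px > qx) if flags.maxX else (px < qx)
    by = (py > qy) if flags.maxY else (py < qy)
    return (bx or px == qx) and (by or py == qy) and (bx or by)


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated points, ordered by objective X in the sweep direction."""

    points: tuple[ObjectivePoint, ...]
    flags: ScenarioFlags

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def payloads(self) -> list:
        return [p.payload for p in self.points]


def pareto_front(points: Sequence, flags: ScenarioFlags = MIN_MIN) -> ParetoFront:
    """Exact non-dominated set of ``points`` under ``flags`` by a single sorted sweep.

    Points are accepted as ``ObjectivePoint`` instances or (x, y) pairs. Exact
    (x, y) duplicates are collapsed to the first-pushed occurrence before the
    sweep; ties on objective X are ordered best-Y-first so the sweep yields the
    exact non-dominated set even on degenerate inputs. The result preserves the
    sorted-by-X sweep order.
    """
    if len(points) == 0:
        raise ValueError("pareto_front needs at least one point")
    pts: list[ObjectivePoint] = []
    seen: set[tuple[float, float]] = set()
    for p in points:
        op = p if isinstance(p, ObjectivePoint) else ObjectivePoint(*_xy(p), payload=None)
        key = (op.x, op.y)
        if key in seen:
            continue
        seen.add(key)
        pts.append(op)

    sx = -1.0 if flags.maxX else 1.0
    sy = -1.0 if flags.maxY else 1.0
    pts.sort(key=lambda p: (sx * p.x, sy * p.y))

    front = [pts[0]]
    best_y = sy * pts[0].y
    for p in pts[1:]:
        yk = sy * p.y
        if yk < best_y:  # strictly better in Y than everything already on the front
            front.append(p)
            best_y = yk
    return ParetoFront(points=tuple(front), flags=flags)


def _require(archive: Sequence, numR: int) -> None:
    if numR < 1:
        raise ValueError("numR must be >= 1")
    if len(archive) < numR:
        raise ValueError(f"archive has {len(archive)} entries, need at least numR={numR}")


def _entry_points(archive: Sequence) -> list[ObjectivePoint]:
    return [ObjectivePoint(e.step, e.tscore, payload=e) for e in archive]


def _by_tscore(entries: Sequence) -> list:
    # lowest TScore first; ties broken toward the more recent (larger step) entry
    return sorted(entries, key=lambda e: (e.tscore, -e.step))


def _fill_recent(selected: list, archive: Sequence, numR: int) -> list:
    chosen = {id(e) for e in selected}
    for e in reversed(archive):
        if len(selected) >= numR:
            break
        if id(e) not in chosen:
            selected.append(e)
            chosen.add(id(e))
    return selected


def select_remc_replicas(archive: Sequence, numR: int) -> list:
    """The last ``numR`` entries pushed to the archive, in push order."""
    _require(archive, numR)
    return list(archive[-numR:])


def mo_selection_from_front(front: Sequence, archive: Sequence, numR: int) -> list:
    """Front-then-fill: lowest-TScore front members, topped up with recent entries.

    Shared by :func:`select_mo_remc_replicas` and the sampler's incremental
    front maintenance, so both produce identical ensembles.
    """
    front = _by_tscore(front)
    if len(front) >= numR:
        return front[:numR]
    return _fill_recent(front, archive, numR)


def hmo_selection_from_fronts(
    minmin_front: Sequence, maxmin_front: Sequence, archive: Sequence, numR: int
) -> list:
    """Hybrid fill from the deduplicated union of the two fronts, lowest TScore first."""
    union: list = []
    seen: set[int] = set()
    for front in (minmin_front, maxmin_front):
        for e in front:
            if id(e) not in seen:
                seen.add(id(e))
                union.append(e)
    union = _by_tscore(union)
    if len(union) >= numR:
        return union[:numR]
    return _fill_recent(union, archive, numR)


def select_mo_remc_replicas(archive: Sequence, numR: int) -> list:
    """Min-min Pareto-front entries, lowest TScore first, topped up with recent entries."""
    _require(archive, numR)
    front = pareto_front(_entry_points(archive), MIN_MIN).payloads()
    return mo_selection_from_front(front, archive, numR)


def select_hmo_remc_replicas(archive: Sequence, numR: int) -> list:
    """Union of the min-min and max-min fronts, preferring the lowest-TScore members.

    Both fronts are used "iteratively, in TScore order": their union is ranked
    by ascending TScore; if the union exceeds ``numR`` the lowest-TScore
    members win, if it falls short the most recent archive entries fill the
    remainder.
    """
    _require(archive, numR)
    points = _entry_points(archive)
    return hmo_selection_from_fronts(
        pareto_front(points, MIN_MIN).payloads(),
        pareto_front(points, MAX_MIN).payloads(),
        archive,
        numR,
    )


SELECTORS = {
    "last": select_remc_replicas,
    "mo": select_mo_remc_replicas,
    "hmo": select_hmo_remc_replicas,
}
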