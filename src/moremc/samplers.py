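"""The sampling engines: Metropolis MC and the replica-exchange family.

Four methods share one machinery:

* **MC** — a single Metropolis chain at fixed temperature, sampling the
  Boltzmann distribution exp(-E/T) (k_B = 1);
* **REMC** — ``numR`` chains on a temperature ladder; after every ``numC``
  local steps, neighbouring rungs attempt a temperature swap (even rung pairs
  (0,1), (2,3), ... only) and the replica ensemble is re-seeded with the last
  ``numR`` archive entries;
* **MO-REMC / HMO-REMC** — identical loop, but re-seeding draws from the
  Pareto front(s) of the history archive over the binary objectives
  (MC step, TScore); see :mod:`moremc.pareto`.

The Metropolis acceptance uses the clamped Boltzmann probability
``exp(clip((E_last - E_new)/T, -40, 40))``, with a fast path that accepts
downhill/flat moves without touching the exponential. Replica swaps accept
with probability ``min(1, exp(-Delta))`` where
``Delta = (beta_j - beta_i)(E_i - E_j)``, rejecting outright when
``Delta > 75`` (e^-75 is far below any uniform draw).

All samplers are generic over the state type: any ``model.score(state)`` and
``proposer(state, step_index, rng)`` pair works, so docking poses and the
analytic test landscapes run through the same code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .pareto import (
    SELECTORS,
    hmo_selection_from_fronts,
    mo_selection_from_front,
    select_remc_replicas,
)

__all__ = [
    "BOLTZ_CLAMP",
    "EXCHANGE_REJECT_THRESHOLD",
    "MC_TEMPERATURE",
    "TemperatureLadder",
    "ReplicaState",
    "ArchiveEntry",
    "SamplerConfig",
    "RunResult",
    "boltz_acceptance_prob",
    "metropolis_accept",
    "mc_boltzmann",
    "exchange_delta",
    "attempt_exchange",
    "remc_run",
    "mc_run",
    "run_method",
    "METHODS",
]

#: Exponent clamp in the Metropolis acceptance probability.
BOLTZ_CLAMP = 40.0
#: Replica swaps with Delta above this are rejected without a uniform draw.
EXCHANGE_REJECT_THRESHOLD = 75.0
#: Fixed temperature of the plain-MC reference method.
MC_TEMPERATURE = 2.0


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly increasing temperatures T_1..T_numR spanning [minT, maxT]."""

    temperatures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", t)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("ladder needs at least one temperature")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def geometric(cls, minT: float, maxT: float, numR: int) -> "TemperatureLadder":
        """Geometric spacing between minT and maxT (uniform in log-temperature)."""
        if numR == 1:
            return cls(np.array([float(minT)]))
        if not minT < maxT:
            raise ValueError("need minT < maxT for numR >= 2")
        return cls(np.geomspace(minT, maxT, numR))

    @property
    def betas(self) -> np.ndarray:
        return 1.0 / self.temperatures

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class ReplicaState:
    """One chain: its label, current state/energy and ladder rung."""

    label: int
    state: Any
    energy: float
    temp_index: int


@dataclass(slots=True)
class ArchiveEntry:
    """One retained MC sample: (step, TScore) objectives plus its snapshot.

    ``step`` is the global push index into the shared archive (objective X);
    ``tscore`` is the energy of the retained sample (objective Y). On
    rejection the previous accepted conformation is retained as a duplicate
    sample, flagged by ``accepted=False``.
    """

    step: int
    tscore: float
    state: Any
    label: int
    temperature: float
    accepted: bool


@dataclass(frozen=True)
class SamplerConfig:
    """Run parameters; the fixed benchmark configuration is (16, 16, 5, 2, 4)."""

    numR: int = 16
    numC: int = 16
    repackNth: int = 5
    minT: float = 2.0
    maxT: float = 4.0
    seed: int = 0
    selector: str = "last"
    n_cycles: int = 100
    exchange_odd_pairs: bool = False
    archive_per_cycle: bool = False

    def __post_init__(self) -> None:
        if self.numR < 1 or self.numC < 1 or self.n_cycles < 1:
            raise ValueError("numR, numC and n_cycles must be >= 1")
        if self.repackNth < 1:
            raise ValueError("repackNth must be >= 1")
        if self.minT <= 0:
            raise ValueError("minT must be positive")
        if self.numR >= 2 and not self.minT < self.maxT:
            raise ValueError("exchange runs need minT < maxT")
        if isinstance(self.selector, str) and self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")

    @property
    def total_steps(self) -> int:
        return self.numR * self.numC * self.n_cycles


def boltz_acceptance_prob(last_accepted_score: float, score: float, T: float) -> float:
    """Clamped Boltzmann acceptance probability exp(clip((last-score)/T, -40, 40)).

    May exceed 1; callers treat values >= 1 as certain acceptance.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    bf = (last_accepted_score - score) / T
    return math.exp(min(BOLTZ_CLAMP, max(-BOLTZ_CLAMP, bf)))


def metropolis_accept(
    last_accepted_score: float, score: float, T: float, u: float, *, fast: bool = True
) -> bool:
    """Metropolis decision given a uniform draw ``u``.

    The fast path accepts immediately when the Boltzmann factor is
    non-negative (probability >= 1), skipping the exponential; it is decision-
    identical to evaluating :func:`boltz_acceptance_prob` directly.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    if fast:
        if T <= 0:
            raise ValueError("temperature must be positive")
        if last_accepted_score - score >= 0.0:
            return True
    prob = boltz_acceptance_prob(last_accepted_score, score, T)
    return prob >= 1.0 or u < prob


def mc_boltzmann(
    initial: Any,
    T: float,
    n_steps: int,
    model,
    proposer: Callable[[Any, int, np.random.Generator], Any],
    rng: np.random.Generator,
    *,
    start_step: int = 0,
    label: int = 0,
    temp_index: int = 0,
    initial_energy: float | None = None,
) -> tuple[ReplicaState, list[ArchiveEntry]]:
    """Metropolis MC chain at temperature ``T`` for ``n_steps`` steps.

    Each step proposes a perturbed state, scores it and applies the Metropolis
    rule; on rejection the previous accepted state is retained as the step's
    sample (a duplicate). Every retained sample is pushed to the returned
    archive with its step index and energy. The uniform draw is consumed only
    for uphill proposals (the fast path needs no randomness).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if T <= 0:
        raise ValueError("temperature must be positive")
    state = initial
    energy = float(model.score(state)) if initial_energy is None else float(initial_energy)
    entries: list[ArchiveEntry] = []
    append = entries.append
    score = model.score
    uniform = rng.uniform
    exp = math.exp
    clamp = BOLTZ_CLAMP
    for k in range(1, n_steps + 1):
        step = start_step + k
        prop = proposer(state, step, rng)
        pe = float(score(prop))
        bf = (energy - pe) / T
        if bf >= 0.0:
            accepted = True
        else:
            accepted = uniform() < exp(max(-clamp, bf))
        if accepted:
            state = prop
            energy = pe
        append(ArchiveEntry(step, energy, state, label, T, accepted))
    return ReplicaState(label=label, state=state, energy=energy, temp_index=temp_index), entries


def exchange_delta(E_i: float, E_j: float, T_i: float, T_j: float) -> float:
    """Replica-swap exponent Delta = (beta_j - beta_i)(E_i - E_j), beta = 1/T."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    return (1.0 / T_j - 1.0 / T_i) * (E_i - E_j)


def attempt_exchange(
    rep_i: ReplicaState, rep_j: ReplicaState, u: float, ladder: TemperatureLadder
) -> bool:
    """Attempt a temperature swap between replicas on adjacent rungs.

    Accepts with probability 1 when Delta <= 0, rejects outright when
    Delta > 75 (no point comparing e^-Delta against a uniform draw), otherwise
    accepts iff ``u < exp(-Delta)``. On acceptance the two replicas' rung
    assignments are swapped in place — labels travel with their poses.
    """
    if abs(rep_i.temp_index - rep_j.temp_index) != 1:
        raise ValueError("exchanges are only attempted between neighbouring rungs")
    T_i = float(ladder.temperatures[rep_i.temp_index])
    T_j = float(ladder.temperatures[rep_j.temp_index])
    delta = exchange_delta(rep_i.energy, rep_j.energy, T_i, T_j)
    if delta <= 0.0:
        accept = True
    elif delta > EXCHANGE_REJECT_THRESHOLD:
        accept = False
    else:
        accept = u < math.exp(-delta)
    if accept:
        rep_i.temp_index, rep_j.temp_index = rep_j.temp_index, rep_i.temp_index
    return accept


class _IncrementalFronts:
    """Min-min and max-min Pareto fronts maintained online over archive pushes.

    Valid because pushes arrive with strictly increasing step (objective X):
    the min-min front is the running strict-minima sequence of TScore, and the
    max-min front is a monotonic stack (pop members whose TScore is >= the
    newcomer's). Both reproduce :func:`moremc.pareto.pareto_front` exactly on
    this input class.
    """

    def __init__(self) -> None:
        self.min_min: list[ArchiveEntry] = []
        self.max_min: list[ArchiveEntry] = []

    def push(self, entry: ArchiveEntry) -> None:
        if not self.min_min or entry.tscore < self.min_min[-1].tscore:
            self.min_min.append(entry)
        stack = self.max_min
        while stack and stack[-1].tscore >= entry.tscore:
            stack.pop()
        stack.append(entry)

    def clear(self) -> None:
        self.min_min.clear()
        self.max_min.clear()


@dataclass
class RunResult:
    """Everything a sampling run produced."""

    method: str
    config: SamplerConfig
    ladder: TemperatureLadder
    archive: list[ArchiveEntry]
    #: (n_cycles, numR) array: rung occupied by each replica label after each cycle's exchanges.
    trajectory: np.ndarray
    replicas: list[ReplicaState]
    exchange_attempts: int = 0
    exchange_accepts: int = 0
    per_cycle_accepts: list[int] = field(default_factory=list)

    @property
    def exchange_acceptance_rate(self) -> float:
        return self.exchange_accepts / self.exchange_attempts if self.exchange_attempts else float("nan")

    def best_entry(self) -> ArchiveEntry:
        return min(self.archive, key=lambda e: (e.tscore, -e.step))


def _spawn_rngs(seed: int, numR: int) -> tuple[list[np.random.Generator], np.random.Generator]:
    """Deterministic independent streams: one child per replica plus one for exchanges."""
    children = np.random.SeedSequence(seed).spawn(numR + 1)
    return [np.random.default_rng(c) for c in children[:numR]], np.random.default_rng(children[numR])


def _resolve_selector(selector):
    if callable(selector):
        return selector, None
    return None, selector  # built-in name, handled incrementally


def remc_run(
    initial: Any,
    config: SamplerConfig,
    model,
    proposer: Callable[[Any, int, np.random.Generator], Any],
    *,
    method_name: str | None = None,
) -> RunResult:
    """Replica-exchange main loop.

    Per outer cycle: (1) every replica runs ``numC`` Metropolis steps at its
    current rung temperature, and the retained samples are pushed to the
    shared history archive in interleaved order (local step major, replica
    label minor) so "the last numR entries" is one per replica; (2) temperature
    swaps are attempted for the even rung pairs (0,1), (2,3), ...;
    (3) the configured selector re-seeds the replica ensemble from the
    archive, assigning selected snapshots to rungs in order of increasing
    TScore (lowest energy to the coldest rung). Selected energies are reused
    from the archive rather than re-scored.

    ``initial`` may be a single state (replicated across replicas) or a
    sequence of ``numR`` states. Reproducible regardless of replica execution
    order: every replica owns an independent RNG stream spawned from the seed.
    """
    numR = config.numR
    ladder = TemperatureLadder.geometric(config.minT, config.maxT, numR)
    rngs, ex_rng = _spawn_rngs(config.seed, numR)
    custom_selector, builtin = _resolve_selector(config.selector)

    if isinstance(initial, (list, tuple)):
        if len(initial) != numR:
            raise ValueError("need one initial state per replica")
        states = list(initial)
    else:
        states = [initial] * numR
    replicas = [
        ReplicaState(label=i, state=s, energy=float(model.score(s)), temp_index=i)
        for i, s in enumerate(states)
    ]

    archive: list[ArchiveEntry] = []
    fronts = _IncrementalFronts() if builtin in ("mo", "hmo") else None
    trajectory = np.empty((config.n_cycles, numR), dtype=np.int64)
    local_steps = [0] * numR
    attempts = accepts = 0
    per_cycle_accepts: list[int] = []
    global_step = 0

    for cycle in range(config.n_cycles):
        # (1) local Metropolis steps, one independent stream per replica
        per_replica: list[list[ArchiveEntry]] = [None] * numR  # type: ignore[list-item]
        for rep in replicas:
            lab = rep.label
            new_state, entries = mc_boltzmann(
                rep.state,
                float(ladder.temperatures[rep.temp_index]),
                config.numC,
                model,
                proposer,
                rngs[lab],
                start_step=local_steps[lab],
                label=lab,
                temp_index=rep.temp_index,
                initial_energy=rep.energy,
            )
            local_steps[lab] += config.numC
            rep.state, rep.energy = new_state.state, new_state.energy
            per_replica[lab] = entries
        # merge interleaved (local step major, label minor) with global step ids
        for k in range(config.numC):
            for lab in range(numR):
                e = per_replica[lab][k]
                global_step += 1
                e.step = global_step
                archive.append(e)
                if fronts is not None:
                    fronts.push(e)

        # (2) even-pair exchange sweep over rungs
        label_at = [0] * numR
        for rep in replicas:
            label_at[rep.temp_index] = rep.label
        start = 1 if (config.exchange_odd_pairs and cycle % 2 == 1) else 0
        cycle_accepts = 0
        for r in range(start, numR - 1, 2):
            u = float(ex_rng.uniform())
            ok = attempt_exchange(replicas[label_at[r]], replicas[label_at[r + 1]], u, ladder)
            attempts += 1
            cycle_accepts += ok
        accepts += cycle_accepts
        per_cycle_accepts.append(cycle_accepts)
        trajectory[cycle] = [rep.temp_index for rep in replicas]

        # (3) selector re-seeds the ensemble from the archive
        if len(archive) >= numR:
            if custom_selector is not None:
                selected = custom_selector(archive, numR)
            elif builtin == "last":
                selected = select_remc_replicas(archive, numR)
            elif builtin == "mo":
                selected = mo_selection_from_front(list(fronts.min_min), archive, numR)
            else:  # hmo
                selected = hmo_selection_from_fronts(
                    list(fronts.min_min), list(fronts.max_min), archive, numR
                )
            if len(selected) != numR:
                raise RuntimeError("selector returned wrong cardinality")
            ordered = sorted(selected, key=lambda e: (e.tscore, -e.step))
            label_at = [0] * numR
            for rep in replicas:
                label_at[rep.temp_index] = rep.label
            for r in range(numR):
                rep = replicas[label_at[r]]
                rep.state = ordered[r].state
                rep.energy = ordered[r].tscore
        if config.archive_per_cycle:
            archive = []
            if fronts is not None:
                fronts.clear()

    return RunResult(
        method=method_name or f"remc[{builtin or 'custom'}]",
        config=config,
        ladder=ladder,
        archive=archive,
        trajectory=trajectory,
        replicas=replicas,
        exchange_attempts=attempts,
        exchange_accepts=accepts,
        per_cycle_accepts=per_cycle_accepts,
    )


def mc_run(
    initial: Any,
    config: SamplerConfig,
    model,
    proposer: Callable[[Any, int, np.random.Generator], Any],
    *,
    temperature: float | None = None,
) -> RunResult:
    """Plain MC reference: one chain at ``minT`` for numR*numC*n_cycles steps.

    Uses the same stream-spawning scheme as a one-replica exchange run, so a
    ``numR=1`` REMC run with the ``last`` selector reproduces it bit-exactly.
    """
    T = config.minT if temperature is None else temperature
    rngs, _ = _spawn_rngs(config.seed, 1)
    final, archive = mc_boltzmann(
        initial, T, config.total_steps, model, proposer, rngs[0]
    )
    return RunResult(
        method="mc",
        config=config,
        ladder=TemperatureLadder(np.array([T])),
        archive=archive,
        trajectory=np.zeros((config.n_cycles, 1), dtype=np.int64),
        replicas=[final],
    )


METHODS = ("mc", "remc", "mo-remc", "hmo-remc")


def run_method(
    method: str,
    initial: Any,
    config: SamplerConfig,
    model,
    proposer: Callable[[Any, int, np.random.Generator], Any],
) -> RunResult:
    """Dispatch one of the four sampling methods by name."""
    if method == "mc":
        return mc_run(initial, config, model, proposer)
    selector = {"remc": "last", "mo-remc": "mo", "hmo-remc": "hmo"}.get(method)
    if selector is None:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    cfg = config if config.selector == selector else _with_selector(config, selector)
    return remc_run(initial, cfg, model, proposer, method_name=method)


def _with_selector(config: SamplerConfig, selector: str) -> SamplerConfig:
    from dataclasses import replace

    return replace(config, selector=selector)
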