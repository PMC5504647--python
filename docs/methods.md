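# Methods

This note records the models, algorithms, numerical choices and known
limitations of `moremc`. It complements the README (which shows what the
package does) by explaining *why* each piece is built the way it is.

## Sampling model

The sampler state is a docking pose: a rigid receptor, one member of a
discrete ligand conformer library, and a rigid-body transform (proper
rotation about the instantaneous ligand centroid, plus a translation).
Receptor flexibility is out of scope; the conformer library stands in for
ligand torsional flexibility, treated like a rotamer set.

**Metropolis kernel.** One MC step proposes a perturbed state, scores it and
accepts with probability `exp(clip((E_last − E_new)/T, −40, +40))`, treating
values ≥ 1 as certain acceptance (k_B = 1 throughout). The clamp keeps the
arithmetic finite for arbitrarily bad clashes. A fast path accepts
non-negative Boltzmann factors without evaluating the exponential or drawing
a uniform variate; it is decision-identical to the direct evaluation (tested
exhaustively on random tuples). On rejection the previous conformation is
retained as the step's sample — the archive therefore traces the accepted
trajectory, with duplicates marking rejections.

**Movers.** Two proposal operators: a small rigid-body trial
(Gaussian translation, default σ = 0.2 Å; rotation about a uniformly random
axis with Gaussian angle, default σ = 5°; conformer swap with probability
0.2) and a larger "repack" surrogate (1.0 Å / 30°, forced uniform conformer
resample) fired on every `repackNth`-th step. True side-chain repacking is
external machinery this package does not model; what the sampling loop needs
from it — a periodic large-amplitude move — is preserved. Magnitudes are
configurable; the defaults were chosen to give reasonable acceptance rates
(~0.5) on the toy fixtures at T = 2 and are stated here because no canonical
values exist for them.

**Replica exchange.** `numR` chains sit on a temperature ladder spanning
[minT, maxT]; geometric spacing is used, the standard choice for roughly
uniform acceptance across rungs when only the endpoints are specified.
Each outer cycle: every replica runs `numC` local Metropolis steps at its
rung's temperature; swaps are then attempted for the even rung pairs (0,1),
(2,3), … — never the odd pairs — with probability `min(1, exp(−Δ))`,
`Δ = (β_j − β_i)(E_i − E_j)`, rejecting outright when Δ > 75 (e^−75 cannot
beat any uniform draw, so the draw is not even needed). The even-pair-only
scheme does not satisfy detailed balance; it is implemented as specified
because fidelity to the method matters more here than MCMC orthodoxy, and an
`exchange_odd_pairs` flag adds the alternating odd sweep as a documented
extension (off by default). One exchange sweep runs per cycle, after the
local steps. Exchanges swap rung assignments; replica labels travel with
their poses.

**Archive and selection.** Every retained sample is pushed to a shared
history archive. Entries from a cycle are merged in interleaved order
(local step major, replica label minor) so the archive tail always holds one
recent sample per replica — the behaviour a parallel implementation would
produce, and what makes "the last `numR` entries" a meaningful ensemble.
After the exchange sweep a selector re-seeds the replica ensemble from the
archive:

* `last` (REMC): the last `numR` entries in push order;
* `mo` (MO-REMC): the min-min Pareto front over (step, score) — the
  non-dominated trade-off between search time and energy — taking the
  lowest-score members first and topping up with the most recent entries
  when the front is short;
* `hmo` (HMO-REMC): the deduplicated union of the min-min and max-min
  fronts (max-min = maximize step, minimize score: the recent low envelope),
  ranked by ascending score, truncated or topped up to exactly `numR`.

Selected snapshots are assigned to rungs in order of increasing score —
lowest energy to the coldest rung — matching the principle that cold
replicas exploit minima while hot ones explore. (How selected replicas map
back onto rungs is not otherwise specified; this ordering is our documented
choice.) Selected energies are reused from the archive rather than
re-scored: scoring is deterministic. The archive is global across cycles
("history-dependent" selection); an `archive_per_cycle` flag provides the
per-cycle alternative.

Because archive steps increase strictly, both fronts are maintained
incrementally — the min-min front is the running strict-minima sequence of
the score, and the max-min front is a monotonic stack — in amortized O(1)
per push, bit-identical to recomputing the fronts from scratch (tested).
The general `pareto_front` routine (any min/max orientation per axis,
single sorted sweep with best-second-objective tie-breaking, exact
duplicates collapsed to the first pushed) is verified exactly against an
O(n²) brute-force scan.

**Reproducibility.** One master seed spawns one independent RNG stream per
replica plus one for exchange draws (`numpy.random.SeedSequence.spawn`).
Results are therefore independent of replica execution order: a concurrent
implementation would be bit-identical to the serial one. One uniform is
drawn per attempted swap, whether or not the decision needs it, to keep
stream consumption deterministic. With `numR = 1` and the `last` selector
the exchange run degenerates bit-exactly to the plain MC chain. Plain MC
runs at `minT` (the benchmark fixes T = 2) for the same total budget
`numR · numC · n_cycles`.

## Scoring model

**Coarse-grained.** `S_cg = R − min(A/N, 0.85)` where, over non-hydrogen
atoms only, R counts ligand atoms within 2.25 Å of any receptor backbone or
Cβ atom (strict `<`), A counts remaining ligand atoms with any receptor atom
in the open interval (2.25, 4.75) Å, and N is the heavy ligand atom count.
Clash takes precedence — no atom is counted in both R and A; boundary
inclusivity is not canonically defined, so the clash band is closed toward
precedence and both bands exclude their endpoints.

**Weighted full-atom score.** `total = Σ w_i s_i` over named score items.
The hard preset (used during repacking) and soft preset (rigid-body
minimisation) ship the published weight table under Rosetta-style item tags
(`fa_atr` 0.80/0.80, `fa_rep` 0.40/0.60, `fa_sol` 0.60/0.50, `fa_pair`
0.80/0.50, `ref` 1.00/1.00, the four hydrogen-bond classes 2.00/1.20,
`p_aa_pp` 0.50/0.32, `omega` 0.50/0.50, `pro_close` 1.00/1.00) and
round-trip bit-exactly against the table stored in the tests. Items with no
weight contribute zero (logged); NaN terms are errors.

**Surrogate terms.** The term *values* are simplified surrogates — this
package makes no claim to reproduce any production force field's
magnitudes, only the weighted-combination semantics:

* `fa_atr` / `fa_rep`: a 12-6 Lennard-Jones pair potential
  (σ = 3.4 Å, base well depth ε = 0.1, scaled per receptor atom by its
  `interaction_scale`) split at the pair minimum r_min = 2^{1/6}σ into a
  purely attractive branch (constant −ε inside r_min) and a purely
  repulsive branch (zero outside r_min), the split used by soft-core
  docking scores. The repulsive branch is capped at 10⁴ per pair so
  coincident atoms stay finite for Metropolis arithmetic.
* `hbond_sc`: a distance Gaussian, depth 0.5 at r₀ = 2.9 Å, width 0.4 Å,
  between ligand heavy atoms and receptor N/O atoms.
* `ref`: a constant 0.25 per heavy ligand atom.
* `pro_close`, `fa_sol`, `fa_pair`, the backbone hydrogen-bond classes,
  `p_aa_pp`, `omega`: zero-valued stubs. They are receptor-internal or
  sequence-statistics terms that are constant for a rigid receptor and a
  chemically anonymous ligand; they remain in the breakdown so the
  weighted-sum engine always carries the full item set.

**Interface delta.** `IFDelta = score(bound) − score(ligand translated
500 Å away)`; negative favours binding. All shipped interaction terms decay
far below 10⁻⁶ by 500 Å, so the separation choice is immaterial (tested at
500 vs 1000 Å).

## Analysis

Lrmsd is computed over non-hydrogen ligand atoms in the fixed receptor
frame, without superposition — the standard docking measure; ≤ 2 Å is a
success. (Small-molecule ligands have no Cα; "ligand RMSD" here always
means all heavy atoms.) Near-duplicate filtering visits decoys in a seeded
random order and drops any decoy whose ligand RMSD to an already-kept decoy
is below 0.65·√N Å — "stochastic elimination" with the iteration order as
the only stochastic element. Ranking: drop decoys whose ligand touches no
receptor atom within 4.75 Å (the coarse score's outer contact radius; the
touching flag has no canonical definition), keep the `max(1, floor(0.05·m))`
lowest-total-score survivors (the minimum of one avoids returning nothing
from a non-empty pool), sort ascending by interface delta.
Temperature-occupancy reports each replica's rung-visit frequencies (rows
normalised to 1) plus the mean and variance of its rung trajectory; a
flattening matrix with shrinking variance is the signature of good
temperature mixing. Published occupancy "averages" above 1 for plain MC
correspond to an unnormalised statistic that is not defined anywhere we can
implement from; the normalised occupancy is reported instead.

## Synthetic fixtures and what they do (not) show

* **Discrete systems**: finite energy tables with uniform symmetric
  proposals; the exact Boltzmann distribution is closed-form, giving a
  stationarity oracle (10⁶-step occupancy within total variation 0.01).
* **Double well**: `E(x) = b(x²−1)² − a(x+1)/2` with barrier b and tilt a;
  stationary points from the cubic derivative roots, per-well Boltzmann
  mass by quadrature. With a = 0 the wells are exactly symmetric, so any
  deviation of the cold rung's well ratio from 1 is a mixing failure, not a
  statistical accident. Used for the barrier-crossing comparison (barrier 6,
  ladder 2…4): the ladder methods first sample the far well in ~2.5× fewer
  total steps than single-chain MC at T = 2, and the REMC cold rung's
  occupancy matches quadrature within a few percent. HMO-REMC's cold rung
  instead pins to the best-found basin — expected: the Pareto selectors are
  greedy optimizers, not canonical samplers.
* **Toy complexes**: a Fibonacci-lattice spherical-cap shell (150 pseudo
  atoms, radius 10 Å, opening upward) with backbone-patterned atom names;
  atoms within 4.5 Å of the bottom pole have their attractive well depths
  multiplied by ~`pocket_depth` (8, with seeded per-atom variation to break
  the cap's axial symmetry). The ligand is an irregular 8-atom loop
  (varying radius and height, so no rotation maps it onto itself) anchored
  at LJ-contact distance above the pole; alternative conformers perturb its
  internal geometry only (σ = 0.25 Å). The planted pose is a strict minimum
  under coarse translation/rotation scans (tested), and the surrogate's
  true global minimum lies within the 2 Å success radius of it — not
  exactly on it, since jittered conformers and sub-Ångström relaxation can
  score marginally better, just as force-field minima rarely coincide with
  crystal poses. Defaults (150 receptor atoms, 8 ligand atoms, 5
  conformers) keep a full exchange run in seconds.

What passing these tests shows: the samplers target the right stationary
distributions, the exchange and selection machinery behaves as specified,
and the end-to-end pipeline finds a planted pocket from a randomized start.
What they do not show: performance on real receptors with thousands of
atoms, real chemistry (protonation, solvation, torsional strain), or any
particular production energy function — those are explicit non-goals.

## Problem sizes and numerical choices

The statistical suite uses 10⁶-step stationarity runs, 10⁵ draws for the
acceptance-law checks, 20 seeds × 2·10⁵ total steps for the double-well
comparison, and 20 seeds × 12 800 steps for toy docking — sizes at which
each check has clear statistical power (3-standard-error bands, total
variation 0.01) while the whole suite runs in about two minutes. Ties in
the selectors break toward the more recent entry (larger step); ties on
objective X in the Pareto sweep sort best-Y-first, which makes the sweep
return the exact non-dominated set even on degenerate inputs. Empty
archives, empty decoy pools and degenerate ladders raise explicit errors.

## Known limitations

* Receptor rigidity: the "repack" mover perturbs only the ligand.
* The even-pair swap scheme and the Pareto selectors break detailed
  balance by design; only plain MC and the local chains within REMC are
  canonical samplers.
* The conformer library is fixed at input; no on-the-fly torsion sampling.
* Surrogate score terms are not calibrated against any physical data.
* PDB support covers minimal ATOM/HETATM complexes (waters skipped); no
  mmCIF, MOL2/SDF, or chemistry-aware typing.
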