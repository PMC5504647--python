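"""Pareto fronts over a sampling archive and the three replica selectors.

Builds a synthetic archive with a known min-min front, computes the min-min
(minimise step, minimise score) and max-min (maximise step, minimise score)
fronts, and shows which entries each replica-selection strategy would hand
back to the exchange loop.
"""

from moremc import (
    MAX_MIN,
    MIN_MIN,
    make_decoy_archive,
    pareto_front,
    select_hmo_remc_replicas,
    select_mo_remc_replicas,
    select_remc_replicas,
)

archive = make_decoy_archive(n=40, seed=1, front_size=5)
points = [(e.step, e.tscore) for e in archive]

minmin = pareto_front(points, MIN_MIN)
maxmin = pareto_front(points, MAX_MIN)
print(f"archive of {len(archive)} entries")
print("min-min front (historic best trade-off):",
      [(p.x, round(p.y, 2)) for p in minmin])
print("max-min front (recent low envelope):  ",
      [(p.x, round(p.y, 2)) for p in maxmin])

numR = 6
for name, selector in [("REMC  (last numR)", select_remc_replicas),
                       ("MO    (min-min front)", select_mo_remc_replicas),
                       ("HMO   (hybrid fronts)", select_hmo_remc_replicas)]:
    sel = selector(archive, numR)
    print(f"{name}: steps {[e.step for e in sel]}")
# REMC keeps whatever was sampled last; MO pulls the ensemble back to the
# lowest-score non-dominated history; HMO mixes in the recent low envelope so
# the ensemble stays greedy *and* diverse. Both Pareto selectors always
# include the archive's global score minimizer.
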