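import math

import numpy as np
import pytest

from moremc import (
    ArchiveEntry,
    ReplicaState,
    SamplerConfig,
    TemperatureLadder,
    attempt_exchange,
    boltz_acceptance_prob,
    exchange_delta,
    make_discrete_system,
    make_double_well,
    mc_boltzmann,
    mc_run,
    metropolis_accept,
    remc_run,
    run_method,
)
from moremc.synthetic import GaussianProposer


class TestBoltzAcceptanceProb:
    def test_equal_scores_give_unity(self):
        assert boltz_acceptance_prob(5.0, 5.0, 2.0) == 1.0

    def test_clamp_at_minus_forty(self):
        assert boltz_acceptance_prob(0.0, 200.0, 1.0) == pytest.approx(math.exp(-40.0))

    def test_clamp_at_plus_forty(self):
        assert boltz_acceptance_prob(200.0, 0.0, 1.0) == pytest.approx(math.exp(40.0))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            boltz_acceptance_prob(0.0, 1.0, 0.0)


class TestMetropolisAccept:
    def test_downhill_always_accepted(self):
        for u in (0.0, 0.5, 1.0):
            assert metropolis_accept(1.0, 0.5, 2.0, u)

    def test_uphill_hand_value(self):
        # boltz factor -1: e^-1 ~ 0.368 < 0.5 -> reject
        assert not metropolis_accept(0.0, 2.0, 2.0, 0.5)
        assert metropolis_accept(0.0, 2.0, 2.0, 0.3)

    def test_fast_and_exponential_paths_agree(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            last, score = rng.normal(scale=20, size=2)
            T = rng.uniform(0.1, 10)
            u = rng.uniform()
            assert metropolis_accept(last, score, T, u, fast=True) == metropolis_accept(
                last, score, T, u, fast=False
            )


class TestMcBoltzmann:
    def test_flat_landscape_accepts_everything(self):
        sysd = make_discrete_system([1.0, 1.0, 1.0])
        _, entries = mc_boltzmann(0, 2.0, 500, sysd, sysd.propose, np.random.default_rng(0))
        assert all(e.accepted for e in entries)

    def test_rejection_retains_previous_sample(self):
        sysd = make_discrete_system([0.0, 100.0])
        final, entries = mc_boltzmann(0, 0.5, 200, sysd, sysd.propose, np.random.default_rng(0))
        rejected = [e for e in entries if not e.accepted]
        assert rejected, "expected rejections on a 200 k_BT step"
        assert all(e.state == 0 and e.tscore == 0.0 for e in rejected)
        assert final.state == 0

    def test_bit_identical_under_same_seed(self):
        sysd = make_discrete_system([0.0, 1.0, 2.0])
        _, a = mc_boltzmann(0, 2.0, 300, sysd, sysd.propose, np.random.default_rng(9))
        _, b = mc_boltzmann(0, 2.0, 300, sysd, sysd.propose, np.random.default_rng(9))
        assert [(e.step, e.state, e.tscore, e.accepted) for e in a] == [
            (e.step, e.state, e.tscore, e.accepted) for e in b
        ]

    def test_three_state_occupancy_near_boltzmann(self):
        sysd = make_discrete_system([0.0, 1.0, 2.0])
        _, entries = mc_boltzmann(0, 2.0, 100_000, sysd, sysd.propose, np.random.default_rng(3))
        occ = np.bincount([e.state for e in entries], minlength=3) / len(entries)
        tv = 0.5 * np.abs(occ - sysd.boltzmann(2.0)).sum()
        assert tv < 0.02


class TestExchange:
    def test_delta_zero_cases(self):
        assert exchange_delta(3.0, 3.0, 2.0, 4.0) == 0.0
        assert exchange_delta(-1.0, 5.0, 2.0, 2.0) == 0.0

    def test_delta_hand_value(self):
        assert exchange_delta(-10.0, -5.0, 2.0, 4.0) == pytest.approx(1.25)

    def test_delta_antisymmetry_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            Ei, Ej = rng.normal(scale=10, size=2)
            Ti, Tj = rng.uniform(0.5, 5, size=2)
            assert exchange_delta(Ei, Ej, Ti, Tj) == pytest.approx(
                exchange_delta(Ej, Ei, Tj, Ti)
            )

    def test_delta_requires_positive_temperatures(self):
        with pytest.raises(ValueError):
            exchange_delta(0.0, 1.0, -1.0, 2.0)

    def _pair(self, E_i=-10.0, E_j=-5.0):
        ladder = TemperatureLadder.geometric(2.0, 4.0, 2)
        ri = ReplicaState(label=0, state=None, energy=E_i, temp_index=0)
        rj = ReplicaState(label=1, state=None, energy=E_j, temp_index=1)
        return ri, rj, ladder

    def test_nonpositive_delta_always_accepts(self):
        ri, rj, ladder = self._pair(E_i=5.0, E_j=-5.0)  # Delta < 0
        assert attempt_exchange(ri, rj, u=1.0, ladder=ladder)

    def test_huge_delta_rejected_outright(self):
        ri, rj, ladder = self._pair(E_i=-500.0, E_j=0.0)  # Delta = 125
        assert not attempt_exchange(ri, rj, u=0.0, ladder=ladder)

    def test_acceptance_swaps_rungs_and_labels_travel_with_poses(self):
        ri, rj, ladder = self._pair(E_i=5.0, E_j=-5.0)  # Delta < 0: certain accept
        assert attempt_exchange(ri, rj, 0.5, ladder)
        assert (ri.temp_index, rj.temp_index) == (1, 0)
        assert (ri.label, ri.energy) == (0, 5.0)  # only the rung moved

    def test_double_swap_restores_original_rungs(self):
        ri, rj, ladder = self._pair(E_i=3.0, E_j=3.0)  # Delta = 0 both ways
        assert attempt_exchange(ri, rj, 0.5, ladder)
        assert attempt_exchange(ri, rj, 0.5, ladder)
        assert (ri.temp_index, rj.temp_index) == (0, 1)

    def test_non_adjacent_rungs_are_a_contract_violation(self):
        ladder = TemperatureLadder.geometric(2.0, 4.0, 3)
        ri = ReplicaState(0, None, 0.0, 0)
        rj = ReplicaState(1, None, 0.0, 2)
        with pytest.raises(ValueError):
            attempt_exchange(ri, rj, 0.5, ladder)

    def test_empirical_acceptance_matches_closed_form(self):
        rng = np.random.default_rng(17)
        n = 20_000
        hits = 0
        for _ in range(n):
            ri, rj, ladder = self._pair()  # Delta = 1.25
            hits += attempt_exchange(ri, rj, rng.uniform(), ladder)
        p = math.exp(-1.25)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestTemperatureLadder:
    def test_geometric_endpoints_and_monotonicity(self):
        ladder = TemperatureLadder.geometric(2.0, 4.0, 16)
        assert ladder.temperatures[0] == pytest.approx(2.0)
        assert ladder.temperatures[-1] == pytest.approx(4.0)
        assert np.all(np.diff(ladder.temperatures) > 0)
        np.testing.assert_allclose(ladder.betas, 1.0 / ladder.temperatures)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            TemperatureLadder.geometric(2.0, 2.0, 4)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(numR=2, minT=2.0, maxT=2.0)
        with pytest.raises(ValueError):
            SamplerConfig(repackNth=0)
        with pytest.raises(ValueError):
            SamplerConfig(selector="nope")


class TestRemcRun:
    def setup_method(self):
        self.dw = make_double_well(6.0)
        self.prop = GaussianProposer(0.35)

    def test_archive_length(self):
        cfg = SamplerConfig(numR=4, numC=8, seed=0, n_cycles=10)
        res = remc_run(-1.0, cfg, self.dw, self.prop)
        assert len(res.archive) == 4 * 8 * 10
        assert [e.step for e in res.archive] == list(range(1, 321))

    def test_temperature_multiset_invariant(self):
        cfg = SamplerConfig(numR=4, numC=8, seed=1, n_cycles=25)
        res = remc_run(-1.0, cfg, self.dw, self.prop)
        for row in res.trajectory:
            assert sorted(row) == [0, 1, 2, 3]

    def test_constant_energy_accepts_every_exchange(self):
        sysd = make_discrete_system([2.0, 2.0, 2.0])
        cfg = SamplerConfig(numR=4, numC=4, seed=2, n_cycles=10)
        res = remc_run(0, cfg, sysd, sysd.propose)
        assert res.exchange_attempts == 2 * 10
        assert res.exchange_accepts == res.exchange_attempts

    def test_single_replica_degenerates_to_plain_mc(self):
        cfg = SamplerConfig(numR=1, numC=16, seed=5, selector="last", n_cycles=30)
        a = remc_run(-1.0, cfg, self.dw, self.prop).archive
        b = mc_run(-1.0, cfg, self.dw, self.prop).archive
        assert [(e.step, e.state, e.tscore, e.accepted) for e in a] == [
            (e.step, e.state, e.tscore, e.accepted) for e in b
        ]

    def test_deterministic_across_runs(self):
        cfg = SamplerConfig(numR=4, numC=8, seed=3, selector="hmo", n_cycles=15)
        a = remc_run(-1.0, cfg, self.dw, self.prop)
        b = remc_run(-1.0, cfg, self.dw, self.prop)
        assert [(e.step, e.state, e.tscore) for e in a.archive] == [
            (e.step, e.state, e.tscore) for e in b.archive
        ]
        np.testing.assert_array_equal(a.trajectory, b.trajectory)

    def test_selector_cardinality_enforced(self):
        cfg = SamplerConfig(numR=4, numC=4, seed=0, selector=lambda arc, k: arc[-2:], n_cycles=2)
        with pytest.raises(RuntimeError):
            remc_run(-1.0, cfg, self.dw, self.prop)

    def test_builtin_selectors_match_public_functions(self):
        # the incremental front path must reproduce the direct selector outputs
        from moremc.pareto import select_hmo_remc_replicas, select_mo_remc_replicas

        for name, fn in [("mo", select_mo_remc_replicas), ("hmo", select_hmo_remc_replicas)]:
            cfg = SamplerConfig(numR=4, numC=8, seed=11, selector=name, n_cycles=12)
            fast = remc_run(-1.0, cfg, self.dw, self.prop)
            cfg_slow = SamplerConfig(numR=4, numC=8, seed=11, selector=fn, n_cycles=12)
            slow = remc_run(-1.0, cfg_slow, self.dw, self.prop)
            assert [(e.step, e.state) for e in fast.archive] == [
                (e.step, e.state) for e in slow.archive
            ]

    def test_interleaved_push_order_is_one_entry_per_replica_at_the_tail(self):
        cfg = SamplerConfig(numR=4, numC=8, seed=4, n_cycles=3)
        res = remc_run(-1.0, cfg, self.dw, self.prop)
        tail = res.archive[-4:]
        assert sorted(e.label for e in tail) == [0, 1, 2, 3]

    def test_run_method_dispatch(self):
        cfg = SamplerConfig(numR=2, numC=4, seed=0, n_cycles=3)
        assert run_method("mc", -1.0, cfg, self.dw, self.prop).method == "mc"
        assert run_method("hmo-remc", -1.0, cfg, self.dw, self.prop).method == "hmo-remc"
        with pytest.raises(ValueError):
            run_method("annealing", -1.0, cfg, self.dw, self.prop)
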