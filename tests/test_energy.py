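import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from moremc import (
    AtomRecord,
    CGCounts,
    FullAtomModel,
    Pose,
    ScoreWeights,
    SurrogateParams,
    coarse_grained_counts,
    coarse_grained_score,
    full_atom_score,
    interface_delta,
    surrogate_terms,
)
from moremc.energy import HARD_WEIGHTS, SOFT_WEIGHTS, SCORE_ITEMS
from moremc.structure import ROLE_BACKBONE, ROLE_LIGAND, ROLE_SIDECHAIN

# Independent copy of the published weight table (hard, soft), asserted
# bit-exactly against the shipped presets.
WEIGHT_TABLE = {
    "pro_close": (1.00, 1.00),
    "fa_atr": (0.80, 0.80),
    "fa_rep": (0.40, 0.60),
    "fa_sol": (0.60, 0.50),
    "fa_pair": (0.80, 0.50),
    "ref": (1.00, 1.00),
    "hbond_lr_bb": (2.00, 1.20),
    "hbond_sr_bb": (2.00, 1.20),
    "hbond_bb_sc": (2.00, 1.20),
    "hbond_sc": (2.00, 1.20),
    "p_aa_pp": (0.50, 0.32),
    "omega": (0.50, 0.50),
}


def _rec(xyz, role=ROLE_SIDECHAIN, name="CG", element="C"):
    return AtomRecord(element=element, coords=np.array(xyz), role=role, name=name)


def _lig(xyz, element="C"):
    return AtomRecord(element=element, coords=np.array(xyz), role=ROLE_LIGAND, name="L1")


class TestCoarseGrainedCounts:
    def test_far_ligand_has_no_contacts(self):
        counts = coarse_grained_counts([_rec([0, 0, 0])], [_lig([10, 0, 0])])
        assert (counts.R, counts.A, counts.N) == (0, 0, 1)

    def test_contact_band_is_open_interval(self):
        counts = coarse_grained_counts([_rec([0, 0, 0])], [_lig([3.0, 0, 0])])
        assert (counts.R, counts.A, counts.N) == (0, 1, 1)

    def test_clash_against_backbone(self):
        counts = coarse_grained_counts(
            [_rec([0, 0, 0], role=ROLE_BACKBONE, name="CA")], [_lig([1.0, 0, 0])]
        )
        assert (counts.R, counts.A, counts.N) == (1, 0, 1)

    def test_sidechain_cannot_clash_but_cbeta_can(self):
        sidechain = coarse_grained_counts([_rec([0, 0, 0], name="CG")], [_lig([1.0, 0, 0])])
        assert sidechain.R == 0
        cbeta = coarse_grained_counts([_rec([0, 0, 0], name="CB")], [_lig([1.0, 0, 0])])
        assert cbeta.R == 1

    def test_clash_takes_precedence_over_contact(self):
        # within 2.25 of a backbone atom *and* within the contact band of another
        receptor = [_rec([0, 0, 0], role=ROLE_BACKBONE, name="N"), _rec([4.0, 0, 0])]
        counts = coarse_grained_counts(receptor, [_lig([1.0, 0, 0])])
        assert (counts.R, counts.A) == (1, 0)

    def test_hydrogens_excluded_from_all_counts(self):
        lig = [_lig([3.0, 0, 0]), AtomRecord("H", np.array([3.0, 0.5, 0]), True, ROLE_LIGAND)]
        counts = coarse_grained_counts([_rec([0, 0, 0])], lig)
        assert counts.N == 1

    def test_empty_ligand_is_an_error(self):
        with pytest.raises(ValueError):
            coarse_grained_counts([_rec([0, 0, 0])], [])


class TestCoarseGrainedScore:
    @pytest.mark.parametrize(
        "R, A, N, expected",
        [(0, 10, 10, -0.85), (2, 5, 10, 1.5), (0, 0, 5, 0.0), (0, 9, 10, -0.85)],
    )
    def test_hand_values(self, R, A, N, expected):
        assert coarse_grained_score(CGCounts(R, A, N)) == pytest.approx(expected)

    @given(st.integers(1, 50), st.data())
    def test_floor_and_monotonicity(self, N, data):
        R = data.draw(st.integers(0, N))
        A = data.draw(st.integers(0, N))
        s = coarse_grained_score(CGCounts(R, A, N))
        assert s >= -0.85
        if R < N:
            assert coarse_grained_score(CGCounts(R + 1, A, N)) >= s
        if A < N:
            assert coarse_grained_score(CGCounts(R, A + 1, N)) <= s


class TestFullAtomScore:
    def test_zero_terms_zero_total(self):
        assert full_atom_score({k: 0.0 for k in SCORE_ITEMS}, ScoreWeights.hard()) == 0.0

    def test_single_term_hand_product(self):
        assert full_atom_score({"fa_atr": 2.0}, ScoreWeights.hard()) == pytest.approx(1.6)

    @given(
        st.dictionaries(st.sampled_from(SCORE_ITEMS), st.floats(-50, 50), min_size=1),
        st.floats(0.1, 4.0),
    )
    def test_linearity(self, terms, factor):
        w = ScoreWeights.hard()
        base = full_atom_score(terms, w)
        scaled = full_atom_score({k: factor * v for k, v in terms.items()}, w)
        assert scaled == pytest.approx(factor * base, rel=1e-12, abs=1e-9)

    def test_missing_weight_contributes_zero(self):
        assert full_atom_score({"not_a_term": 5.0}, ScoreWeights.hard()) == 0.0

    def test_nan_term_rejected(self):
        with pytest.raises(ValueError):
            full_atom_score({"fa_atr": float("nan")}, ScoreWeights.hard())

    def test_presets_match_published_table_bit_exactly(self):
        for name, (hard, soft) in WEIGHT_TABLE.items():
            assert HARD_WEIGHTS[name] == hard
            assert SOFT_WEIGHTS[name] == soft
        assert set(HARD_WEIGHTS) == set(WEIGHT_TABLE) == set(SCORE_ITEMS)
        assert ScoreWeights.hard().weights == dict(HARD_WEIGHTS)
        assert ScoreWeights.soft().weights == dict(SOFT_WEIGHTS)

    def test_weights_file_round_trip(self, tmp_path):
        path = tmp_path / "weights.txt"
        ScoreWeights.soft().to_file(path)
        assert ScoreWeights.from_file(path).weights == ScoreWeights.soft().weights


class TestSurrogateTerms:
    def test_all_items_present_and_finite(self, toy):
        bd = surrogate_terms(toy.native_pose)
        assert set(bd.terms) == set(SCORE_ITEMS)
        assert all(math.isfinite(v) for v in bd.terms.values())

    def test_infinite_separation_leaves_only_reference(self, toy):
        params = SurrogateParams()
        far = toy.native_pose.translated(np.array([1e4, 0, 0]))
        bd = surrogate_terms(far, params)
        ref = params.ref_per_atom * toy.conformers.n_heavy
        assert bd.terms["ref"] == pytest.approx(ref)
        assert bd.total == pytest.approx(ref, abs=1e-8)

    def test_deterministic(self, toy):
        a = surrogate_terms(toy.start_pose)
        b = surrogate_terms(toy.start_pose)
        assert a.terms == b.terms

    def test_attractive_well_depth_at_pair_minimum(self):
        # one receptor atom, one ligand atom exactly at r_min: fa_atr = -epsilon
        params = SurrogateParams()
        from moremc import ConformerSet, Receptor

        rec = Receptor(coords=[[0.0, 0.0, 0.0]], elements=["C"], names=["CG"])
        conf = ConformerSet(coords=[[[params.lj_rmin, 0.0, 0.0]]], elements=["C"])
        bd = surrogate_terms(Pose(receptor=rec, conformers=conf), params)
        assert bd.terms["fa_atr"] == pytest.approx(-params.lj_epsilon)
        assert bd.terms["fa_rep"] == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_atoms_hit_the_repulsion_cap(self):
        params = SurrogateParams()
        from moremc import ConformerSet, Receptor

        rec = Receptor(coords=[[0.0, 0.0, 0.0]], elements=["C"], names=["CG"])
        conf = ConformerSet(coords=[[[0.0, 0.0, 0.0]]], elements=["C"])
        bd = surrogate_terms(Pose(receptor=rec, conformers=conf), params)
        assert bd.terms["fa_rep"] == pytest.approx(params.repulsion_cap)
        assert math.isfinite(bd.total)


class TestInterfaceDelta:
    def test_zero_interaction_model_gives_zero(self, toy):
        class RefOnly:
            def score(self, pose):
                return 42.0  # constant: no interaction terms at all

        assert interface_delta(toy.native_pose, RefOnly()) == 0.0

    def test_native_pose_binds_favourably(self, toy, model):
        assert interface_delta(toy.native_pose, model) < 0

    def test_separation_choice_is_irrelevant(self, toy, model):
        d500 = interface_delta(toy.native_pose, model, separation=500.0)
        d1000 = interface_delta(toy.native_pose, model, separation=1000.0)
        assert abs(d500 - d1000) < 1e-6

    def test_model_convenience_agrees(self, toy, model):
        assert model.interface_delta(toy.start_pose) == pytest.approx(
            interface_delta(toy.start_pose, model)
        )
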