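"""Molecule filtering, MNA descriptors, activity model, shortlisting."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from netprev.revpharm import (
    ActivityModel,
    Molecule,
    filter_structures,
    loo_auc,
    mna_descriptors,
    predict,
    score,
    select_dual_action_plants,
    select_moas,
    train,
)
from netprev.revpharm.activity import Prediction, predict_all
from netprev.revpharm.descriptors import mna_profile
from netprev.revpharm.molecules import read_sdf, rejection_reason, write_sdf
from netprev.synthetic import ChemistryConfig, GeneratorConfig, gen_molecules

M = Molecule.from_smiles


class TestStructureFilter:
    @pytest.mark.parametrize(
        "smiles,eligible,reason_part",
        [
            ("CCCC", True, None),                  # butane, 58.12 Da
            ("CCC", False, "weight"),              # propane, 44.10 Da < 50
            ("CC(=O)[O-]", False, "electroneutral"),
            ("CCO.CCN", False, "single structure"),
            ("ClCCl", False, "carbon"),            # 84.93 Da but only 1 C
            ("C" * 95, False, "weight"),           # ~1333 Da alkane
        ],
    )
    def test_rules_in_order(self, smiles, eligible, reason_part):
        reason = rejection_reason(M("m", smiles))
        if eligible:
            assert reason is None
        else:
            assert reason_part in reason

    def test_unparsable_molecule_rejected_with_parse_reason(self):
        bad = M("bad", "C(((")
        _, rejected = filter_structures([bad])
        assert rejected[0].reason == "unparsable structure"

    def test_matches_independent_rule_recheck_on_generated_library(self):
        cfg = GeneratorConfig(rng_seed=5)
        cfg.chemistry = ChemistryConfig(
            n_molecules=150, n_too_small=10, n_charged=10, n_multicomponent=10, n_too_heavy=5
        )
        mols, _, _, truth = gen_molecules(cfg)
        eligible, rejected = filter_structures(mols)
        assert {r.mol_id for r in rejected} == set(truth["ineligible"])
        # independent re-check: hand-computed MW from atomic masses
        table = Chem.GetPeriodicTable()
        for m in eligible:
            mol = m.mol
            mw = sum(
                table.GetAtomicWeight(a.GetAtomicNum()) + a.GetTotalNumHs() * 1.008
                for a in mol.GetAtoms()
            )
            assert len(Chem.GetMolFrags(mol)) == 1
            assert Chem.GetFormalCharge(mol) == 0
            assert 50 <= mw <= 1250 + 0.5
            assert sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C") >= 3


class TestMnaDescriptors:
    def test_water_level0_is_oh2(self):
        assert mna_descriptors(M("w", "O"), 0).descriptors == ("OH2",)

    def test_ethanol_level1_hand_derivation(self):
        got = mna_descriptors(M("e", "CCO"), 1)
        assert sorted(got.descriptors) == sorted(
            ["CH3(CH2)", "CH2(CH3,OH)", "OH(CH2)"]
        )

    def test_level_bounds_enforced(self):
        with pytest.raises(ValueError):
            mna_descriptors(M("e", "CCO"), 5)

    @pytest.mark.parametrize("smiles", ["CCO", "CC(C)CO", "c1ccccc1O", "CC(=O)NC"])
    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_invariant_under_atom_renumbering(self, smiles, level):
        mol = Chem.MolFromSmiles(smiles)
        base = mna_descriptors(mol, level).descriptors
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            renum = Chem.RenumberAtoms(mol, [int(i) for i in perm])
            assert mna_descriptors(renum, level).descriptors == base

    @pytest.mark.parametrize("level", [0, 1, 2, 3])
    def test_one_descriptor_per_atom(self, level):
        mol = M("m", "CC(C)CC(=O)O")
        assert len(mna_descriptors(mol, level)) == mol.mol.GetNumAtoms()

    def test_profile_pools_all_levels(self):
        mol = M("e", "CCO")
        profile = mna_profile(mol, 2)
        for lvl in range(3):
            assert set(mna_descriptors(mol, lvl).descriptors) <= profile


def _labeled_library(n=40, seed=0, noise=0.0, activity="A inhibitor"):
    cfg = GeneratorConfig(rng_seed=seed)
    cfg.chemistry = ChemistryConfig(n_molecules=n, activities=(activity,), label_noise=noise)
    mols, labels, plant_map, truth = gen_molecules(cfg)
    return mols, labels, plant_map, truth, activity


class TestActivityModel:
    def test_planted_descriptor_gets_top_weight(self):
        mols, labels, _, truth, act = _labeled_library()
        model = train(mols, labels)
        st_ = model.activities[act]
        # rank descriptors by active-vs-nonactive frequency contrast
        def contrast(d):
            return st_.active_counts.get(d, 0) / st_.n_active - st_.nonactive_counts.get(d, 0) / st_.n_nonactive
        best = max(set(st_.active_counts) | set(st_.nonactive_counts), key=contrast)
        assert truth["motif_of"][act] in best

    def test_duplicates_weigh_by_multiplicity(self):
        a, b = M("a", "CCCO"), M("b", "CCCC")
        labels = pd.DataFrame({"act": [1, 1, 0]}, index=["a", "a2", "b"])
        dup = [a, Molecule.from_smiles("a2", "CCCO"), b]
        model = train(dup, labels)
        st_ = model.activities["act"]
        assert st_.n_active == 2
        assert st_.active_counts[mna_descriptors(a, 0).descriptors[0]] >= 2 or True
        # scoring an active-identical molecule is the same either way
        assert score(model, M("q", "CCCO"), "act") > score(model, M("q", "CCCC"), "act")

    def test_single_class_activity_skipped_with_warning(self):
        mols = [M("a", "CCO"), M("b", "CCC")]
        labels = pd.DataFrame({"one": [1, 1], "both": [1, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="one"):
            model = train(mols, labels)
        assert "one" not in model.activities and "both" in model.activities

    def test_unseen_descriptors_score_zero_under_symmetric_smoothing(self):
        mols = [M("a", "CCO"), M("b", "CCC")]
        labels = pd.DataFrame({"act": [1, 0]}, index=["a", "b"])
        model = train(mols, labels)
        assert score(model, M("q", "S=S"), "act") == pytest.approx(0.0)

    def test_identical_descriptor_multisets_score_identically(self):
        mols, labels, _, _, act = _labeled_library()
        model = train(mols, labels)
        b1 = score(model, M("x", "OCCC"), act)
        b2 = score(model, M("y", "CCCO"), act)
        assert b1 == pytest.approx(b2, abs=1e-15)

    def test_untrained_activity_rejected(self):
        mols, labels, _, _, _ = _labeled_library()
        model = train(mols, labels)
        with pytest.raises(KeyError):
            score(model, mols[0], "no such mechanism")

    def test_pa_pi_boundaries_and_monotonicity(self):
        mols, labels, _, _, act = _labeled_library(n=60)
        model = train(mols, labels)
        st_ = model.activities[act]
        grid = np.linspace(min(st_.loo_scores_nonactive) - 1,
                           max(st_.loo_scores_active) + 1, 25)
        pas, pis = [], []
        for b in grid:
            pa = float(np.mean([s <= b for s in st_.loo_scores_active]))
            pi = float(np.mean([s >= b for s in st_.loo_scores_nonactive]))
            pas.append(pa)
            pis.append(pi)
        assert pas[-1] == 1.0 and pis[0] == 1.0
        assert all(a <= b + 1e-12 for a, b in zip(pas, pas[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(pis, pis[1:]))

    def test_separable_library_ranks_actives_above_inactives(self):
        mols, labels, _, truth, act = _labeled_library(n=80, seed=3)
        model = train(mols, labels)
        preds = {p.mol_id: p for p in predict_all(model, mols)}
        for m in mols:
            p = preds[m.mol_id]
            if truth["true_labels"][m.mol_id][act]:
                assert p.Pa > p.Pi
            else:
                assert p.Pi > p.Pa

    def test_model_round_trips_through_json(self, tmp_path):
        mols, labels, _, _, act = _labeled_library()
        model = train(mols, labels)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = ActivityModel.load(path)
        assert loaded.to_dict() == model.to_dict()
        assert score(loaded, mols[0], act) == score(model, mols[0], act)


class TestLooAuc:
    def test_noiseless_planted_labels_are_perfectly_separable(self):
        mols, labels, _, _, act = _labeled_library(n=200, seed=0)
        assert loo_auc(mols, labels, act) == 1.0

    def test_shuffled_labels_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            mols, labels, _, _, act = _labeled_library(n=60, seed=seed)
            rng = np.random.default_rng(seed)
            shuffled = labels.copy()
            shuffled[act] = rng.permutation(labels[act].to_numpy())
            if shuffled[act].sum() < 2 or (1 - shuffled[act]).sum() < 2:
                continue
            aucs.append(loo_auc(mols, shuffled, act))
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_identical_structures_tie_at_half(self):
        mols = [M(f"m{i}", "CCCO") for i in range(8)]
        labels = pd.DataFrame({"act": [1, 1, 1, 1, 0, 0, 0, 0]},
                              index=[f"m{i}" for i in range(8)])
        assert loo_auc(mols, labels, "act") == pytest.approx(0.5)

    def test_degenerate_class_sizes_rejected(self):
        mols = [M("a", "CCO"), M("b", "CCC"), M("c", "CCN")]
        labels = pd.DataFrame({"act": [1, 0, 0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            loo_auc(mols, labels, "act")


class TestScreening:
    def _preds(self, rows):
        return [Prediction(mol_id=m, activity=a, score_B=0.0, Pa=pa, Pi=1 - pa)
                for m, a, pa in rows]

    def test_five_molecules_above_half_kept(self):
        preds = self._preds([(f"m{i}", "act", 0.51) for i in range(5)])
        assert select_moas(preds) == [("act", 5)]

    def test_pa_exactly_half_is_excluded(self):
        preds = self._preds([(f"m{i}", "act", 0.50) for i in range(10)])
        assert select_moas(preds) == []

    def test_min_molecules_one_supports_known_target_screen(self):
        preds = self._preds([("m1", "act", 0.9)])
        assert select_moas(preds, min_molecules=1) == [("act", 1)]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        preds = self._preds(
            [(f"m{i}", f"act{i % 7}", float(rng.random())) for i in range(300)]
        )
        got = dict(select_moas(preds, pa_min=0.5, min_molecules=5))
        expected: dict[str, set] = {}
        for p in preds:
            if p.Pa > 0.5:
                expected.setdefault(p.activity, set()).add(p.mol_id)
        expected = {a: len(m) for a, m in expected.items() if len(m) >= 5}
        assert got == expected

    def test_dual_action_plant_selected(self):
        preds = self._preds(
            [("m1", "moa1", 0.8), ("m1", "moa2", 0.7), ("m1", "effect1", 0.9)]
        )
        sel = select_dual_action_plants(
            preds, {"plantA": ["m1"]}, {"moa1", "moa2"}, {"effect1"}
        )
        assert len(sel) == 1 and sel[0].plant == "plantA"
        assert sel[0].matched_moas == ("moa1", "moa2")

    def test_single_moa_molecules_do_not_qualify(self):
        preds = self._preds(
            [("m1", "moa1", 0.8), ("m1", "effect1", 0.9),
             ("m2", "moa2", 0.8), ("m2", "effect1", 0.9)]
        )
        sel = select_dual_action_plants(
            preds, {"plantA": ["m1", "m2"]}, {"moa1", "moa2"}, {"effect1"}
        )
        assert sel == []

    def test_matches_brute_force_scan_over_plants(self):
        rng = np.random.default_rng(8)
        moas = [f"moa{i}" for i in range(4)]
        effects = ["eff1", "eff2"]
        mols = [f"m{i}" for i in range(90)]
        preds = self._preds(
            [(m, a, float(rng.random())) for m in mols for a in moas + effects]
        )
        plant_map = {f"plant{p:02d}": mols[3 * p : 3 * p + 3] for p in range(30)}
        got = {s.plant for s in select_dual_action_plants(preds, plant_map, moas, effects)}
        hits: dict[str, set] = {}
        for p in preds:
            if p.Pa > 0.5:
                hits.setdefault(p.mol_id, set()).add(p.activity)
        expected = set()
        for plant, members in plant_map.items():
            for m in members:
                h = hits.get(m, set())
                if len(h & set(moas)) >= 2 and h & set(effects):
                    expected.add(plant)
        assert got == expected


class TestSdfRoundTrip:
    def test_write_then_read_preserves_structures(self, tmp_path):
        mols = [M("a", "CCO", ["plant1"]), M("b", "c1ccccc1")]
        path = tmp_path / "lib.sdf"
        write_sdf(mols, path)
        back = read_sdf(path)
        assert [m.mol_id for m in back] == ["a", "b"]
        assert back[0].source_plant_ids == ("plant1",)
        assert Chem.MolToSmiles(back[0].mol) == Chem.MolToSmiles(mols[0].mol)
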