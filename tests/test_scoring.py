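"""Crisp and fuzzy confusion, INF/F1 and ranking behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnaconsensus.annotation import Interaction, ModelInteractionSet
from rnaconsensus.consensus import (
    AnalysisConfig,
    apply_constraints,
    build_frequency_multiset,
    parse_constraints,
    threshold_consensus,
)
from rnaconsensus.robustness import synth_ensemble
from rnaconsensus.scoring import (
    ConfusionCounts,
    ConfusionSums,
    crisp_confusion,
    f1_score,
    fuzzy_confusion,
    inf_score,
    rank_models,
)
from tests.conftest import make_residues


class TestCrispConfusion:
    def test_set_definitions(self, residues8):
        a = Interaction("stacking", residues8[0], residues8[1])
        b = Interaction("stacking", residues8[1], residues8[2])
        c = Interaction("stacking", residues8[2], residues8[3])
        model = ModelInteractionSet("m", [a, b])
        conf = crisp_confusion(model, {a.key(), c.key()})
        assert (conf.tp, conf.fp, conf.fn) == (1, 1, 1)

    def test_perfect_match(self, residues8):
        a = Interaction("stacking", residues8[0], residues8[1])
        model = ModelInteractionSet("m", [a])
        conf = crisp_confusion(model, {a.key()})
        assert (conf.fp, conf.fn) == (0, 0)

    def test_empty_model(self, residues8):
        keys = {
            Interaction("stacking", residues8[k], residues8[k + 1]).key()
            for k in range(3)
        }
        conf = crisp_confusion(ModelInteractionSet("m"), keys)
        assert (conf.tp, conf.fp, conf.fn) == (0, 0, 3)


class TestFuzzyConfusion:
    def test_worked_example(self, abc_ensemble):
        sets, _ = abc_ensemble
        cm = build_frequency_multiset(sets)
        conf = fuzzy_confusion(sets[0], cm)  # model A = {x, y}
        assert conf.tp == pytest.approx(4 / 3, abs=1e-12)
        assert conf.fp == pytest.approx(2 / 3, abs=1e-12)
        assert conf.fn == pytest.approx(1 / 3, abs=1e-12)

    def test_unanimous_consensus_gives_zero_error(self, abc_ensemble):
        sets, _ = abc_ensemble
        cm = build_frequency_multiset([sets[1], sets[1]])
        conf = fuzzy_confusion(sets[1], cm)
        assert (conf.fp, conf.fn) == (0.0, 0.0)

    def test_brute_force_per_entry_oracle(self):
        """TPsum/FPsum/FNsum equal a naive per-entry accumulation."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            sets, _ = synth_ensemble(
                int(rng.integers(2, 6)), 8, int(rng.integers(1, 10)),
                2.0, int(rng.integers(1e6)),
            )
            cm = build_frequency_multiset(sets)
            for model in sets:
                tp = fp = fn = 0.0
                for k, e in cm.entries.items():
                    if k in model:
                        tp += e.membership
                        fp += 1 - e.membership
                    else:
                        fn += e.membership
                conf = fuzzy_confusion(model, cm)
                assert conf.tp == pytest.approx(tp)
                assert conf.fp == pytest.approx(fp)
                assert conf.fn == pytest.approx(fn)

    def test_required_entry_absent_costs_full_fn(self, abc_ensemble):
        sets, _ = abc_ensemble
        cm = build_frequency_multiset(sets)
        residues = make_residues(8, bases="GCAU")
        apply_constraints(cm, parse_constraints("..(..)..", 8), residues)
        conf = fuzzy_confusion(sets[1], cm)  # B = {x} lacks the required pair
        assert conf.fn == pytest.approx(2 / 3 + 1.0)

    def test_forbidden_entry_present_costs_full_fp(self, abc_ensemble):
        sets, named = abc_ensemble
        cm = build_frequency_multiset(sets)
        residues = make_residues(8, bases="GCAU")
        # y = (2,7) appears only in model A; forbid position 2
        apply_constraints(cm, parse_constraints(".x......", 8), residues)
        conf_a = fuzzy_confusion(sets[0], cm)
        # x: p=1 -> TP 1; y forbidden & present -> FP 1; z absent -> FN 1/3
        assert conf_a.tp == pytest.approx(1.0)
        assert conf_a.fp == pytest.approx(1.0)
        assert conf_a.fn == pytest.approx(1 / 3)

    def test_interaction_unknown_to_consensus_is_full_fp(self, residues8):
        a = Interaction("stacking", residues8[0], residues8[1])
        b = Interaction("stacking", residues8[1], residues8[2])
        cm = build_frequency_multiset(
            [ModelInteractionSet("m1", [a]), ModelInteractionSet("m2", [a])]
        )
        outsider = ModelInteractionSet("ext", [a, b])
        conf = fuzzy_confusion(outsider, cm)
        assert conf.fp == pytest.approx(1.0)


class TestScores:
    @pytest.mark.parametrize(
        "conf, expected_inf, expected_f1",
        [
            (ConfusionCounts(1, 1, 1), 0.5, 0.5),
            (ConfusionCounts(5, 0, 0), 1.0, 1.0),
            (ConfusionCounts(0, 0, 0), 1.0, 1.0),
            (ConfusionCounts(0, 2, 0), 0.0, 0.0),
            (ConfusionCounts(0, 0, 3), 0.0, 0.0),
            (
                ConfusionSums(4 / 3, 2 / 3, 1 / 3),
                math.sqrt(8 / 15),
                8 / 11,
            ),
        ],
    )
    def test_formula_values(self, conf, expected_inf, expected_f1):
        assert inf_score(conf) == pytest.approx(expected_inf, abs=1e-12)
        assert f1_score(conf) == pytest.approx(expected_f1, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        tp=st.floats(0, 50), fp=st.floats(0, 50), fn=st.floats(0, 50)
    )
    def test_scores_bounded(self, tp, fp, fn):
        conf = ConfusionSums(tp, fp, fn)
        for score in (inf_score(conf), f1_score(conf)):
            assert 0.0 <= score <= 1.0

    def test_perfect_iff_no_errors(self):
        assert inf_score(ConfusionSums(2.0, 0.0, 0.0)) == 1.0
        assert inf_score(ConfusionSums(2.0, 0.1, 0.0)) < 1.0
        assert f1_score(ConfusionSums(2.0, 0.0, 0.1)) < 1.0


class TestRanking:
    def test_weighted_f1_ranking_of_worked_example(self, abc_ensemble):
        sets, _ = abc_ensemble
        cm = build_frequency_multiset(sets)
        cfg = AnalysisConfig(mode="weighted", metric="F1")
        ranking, reports = rank_models(sets, cm, cfg)
        assert [mid for mid, _ in ranking.order] == ["B", "A", "C"]
        scores = dict(ranking.order)
        assert scores["B"] == pytest.approx(3 / 4, abs=1e-12)
        assert scores["A"] == pytest.approx(8 / 11, abs=1e-12)
        assert scores["C"] == pytest.approx(8 / 11, abs=1e-12)
        by_id = {r.model_id: r for r in reports}
        assert by_id["A"].inf == pytest.approx(math.sqrt(8 / 15), abs=1e-12)
        assert by_id["B"].inf == pytest.approx(math.sqrt(3 / 5), abs=1e-12)

    def test_identical_models_all_score_one_lexicographic(self, abc_ensemble):
        sets, _ = abc_ensemble
        clones = [
            ModelInteractionSet(mid, list(sets[0]))
            for mid in ("zeta", "alpha", "mid")
        ]
        cm = build_frequency_multiset(clones)
        ranking, _ = rank_models(clones, cm, AnalysisConfig())
        assert ranking.order == [
            ("alpha", 1.0), ("mid", 1.0), ("zeta", 1.0),
        ]

    def test_threshold_mode_unanimous_consensus(self, abc_ensemble):
        sets, named = abc_ensemble
        cm = build_frequency_multiset(sets)
        cfg = AnalysisConfig(mode="threshold", confidence_level=3)
        ranking, reports = rank_models(sets, cm, cfg)
        by_id = {r.model_id: r for r in reports}
        assert by_id["B"].inf == 1.0 and by_id["B"].f1 == 1.0
        assert by_id["B"].confusion == ConfusionCounts(1, 0, 0)
        assert ranking.order[0][0] == "B"

    def test_empty_ensemble_rejected(self, abc_ensemble):
        sets, _ = abc_ensemble
        cm = build_frequency_multiset(sets)
        with pytest.raises(ValueError):
            rank_models([], cm, AnalysisConfig())

    def test_scope_canonical_only_ignores_stacking(self, abc_ensemble):
        sets, _ = abc_ensemble
        cm = build_frequency_multiset(sets)
        cfg = AnalysisConfig(scope="canonical_only", metric="F1")
        _, reports = rank_models(sets, cm, cfg)
        by_id = {r.model_id: r for r in reports}
        # without z (stacking), models B and C are identical
        assert by_id["B"].f1 == pytest.approx(by_id["C"].f1)

    def test_permuting_model_order_changes_no_score(self, abc_ensemble):
        sets, _ = abc_ensemble
        cm = build_frequency_multiset(sets)
        cfg = AnalysisConfig(metric="F1")
        _, r1 = rank_models(sets, cm, cfg)
        _, r2 = rank_models(sets[::-1], cm, cfg)
        assert {r.model_id: r.f1 for r in r1} == {
            r.model_id: r.f1 for r in r2
        }


class TestCrossModeProperties:
    def test_fuzzy_reduces_to_crisp_at_unit_membership(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            sets, _ = synth_ensemble(3, 8, int(rng.integers(2, 12)), 0.0,
                                     int(rng.integers(1e6)))
            cm = build_frequency_multiset(sets)
            consensus = threshold_consensus(cm, cm.n_models)
            for model in sets:
                fz = fuzzy_confusion(model, cm)
                cr = crisp_confusion(model, consensus)
                assert fz.tp == pytest.approx(cr.tp)
                assert fz.fp == pytest.approx(cr.fp)
                assert fz.fn == pytest.approx(cr.fn)
                assert inf_score(fz) == pytest.approx(inf_score(cr))

    def test_crisp_scores_match_set_algebra_oracle(self):
        rng = np.random.default_rng(23)
        for trial in range(200):
            n_models = int(rng.integers(2, 7))
            sets, _ = synth_ensemble(
                n_models, 10, int(rng.integers(1, 20)), 3.0,
                int(rng.integers(1e6)),
            )
            cm = build_frequency_multiset(sets)
            n = int(rng.integers(1, n_models + 1))
            consensus = threshold_consensus(cm, n)
            for model in sets:
                conf = crisp_confusion(model, consensus)
                mk, ck = model.keys(), set(consensus)
                assert conf.tp == len(mk & ck)
                assert conf.fp == len(mk - ck)
                assert conf.fn == len(ck - mk)
                assert conf.tp + conf.fn == len(ck)
                assert conf.tp + conf.fp == len(mk)

    def test_adding_common_interaction_never_hurts_f1(self):
        """Weighted mode: adding an interaction with membership > 0.5
        cannot decrease a model's F1."""
        rng = np.random.default_rng(31)
        checked = 0
        for trial in range(300):
            sets, _ = synth_ensemble(
                4, 8, int(rng.integers(2, 12)), 2.0, int(rng.integers(1e6))
            )
            cm = build_frequency_multiset(sets)
            common = [
                e for e in cm.entries.values() if e.membership > 0.5
            ]
            if not common:
                continue
            entry = common[int(rng.integers(len(common)))]
            victims = [s for s in sets if entry.interaction.key() not in s]
            if not victims:
                continue
            model = victims[0]
            before = f1_score(fuzzy_confusion(model, cm))
            grown = model.copy()
            grown.add(entry.interaction)
            after = f1_score(fuzzy_confusion(grown, cm))
            assert after >= before - 1e-12
            checked += 1
        assert checked >= 50
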