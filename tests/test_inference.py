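"""Posterior updates, ranking, evidence classification, and stopping."""

import numpy as np
import pytest

from redeye import (
    AnswerValue,
    Belief,
    ContradictionError,
    SessionState,
    apply_answer,
    check_stop,
    displayed_differential,
    evidence_for,
    init_belief,
    rank_differential,
    update_posterior,
)

from conftest import (
    NO,
    UNKNOWN,
    YES,
    brute_force_posterior,
    make_kb,
    q,
    random_answers,
    random_kb,
)


class TestAnswerParsing:
    @pytest.mark.parametrize("raw,expected", [
        ("yes", YES), ("YES", YES), ("y", YES),
        ("No", NO), ("n", NO),
        ("i don't know", UNKNOWN), ("unknown", UNKNOWN), ("", UNKNOWN),
        (None, UNKNOWN),
    ])
    def test_parse(self, raw, expected):
        assert AnswerValue.parse(raw) is expected

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            AnswerValue.parse("maybe")


class TestUpdate:
    def test_prior_initialization(self):
        kb = make_kb({"a": 3.0, "b": 1.0}, [q("q1", {}, default=0.5)])
        belief = init_belief(kb)
        assert belief["a"] == pytest.approx(0.75)
        assert belief["b"] == pytest.approx(0.25)

    def test_yes_reweights_by_likelihood_ratio(self, two_dx_kb):
        belief = init_belief(two_dx_kb)
        post = update_posterior(belief, two_dx_kb.questions[0], YES)
        assert post["a"] == pytest.approx(2 / 3)
        assert post["b"] == pytest.approx(1 / 3)

    def test_unknown_is_identity(self, two_dx_kb):
        belief = init_belief(two_dx_kb)
        assert update_posterior(belief, two_dx_kb.questions[0],
                                UNKNOWN) is belief

    def test_zero_probability_is_hard_rule_out(self):
        kb = make_kb({"a": 0.3, "b": 0.7}, [q("q1", {"a": 0.0, "b": 0.5})])
        post = update_posterior(init_belief(kb), kb.questions[0], YES)
        assert post["a"] == 0.0
        assert post["b"] == pytest.approx(1.0)

    def test_contradiction_identifies_question(self):
        kb = make_kb({"a": 1.0}, [q("qz", {"a": 0.0})])
        with pytest.raises(ContradictionError, match="qz"):
            update_posterior(init_belief(kb), kb.questions[0], YES)

    def test_five_step_sequence_matches_product_oracle(self):
        rng = np.random.default_rng(20240615)
        kb = random_kb(rng, n_dx=15, n_q=8)
        answers = random_answers(rng, kb, n=5, p_unknown=0.0)
        belief = init_belief(kb)
        for qid, ans in answers:
            belief = update_posterior(belief, kb.question_index[qid], ans)
        oracle = brute_force_posterior(kb, answers)
        for d in oracle:
            assert belief[d] == pytest.approx(oracle[d], abs=1e-12)


class TestInvariants:
    """Core algebraic properties of the sequential Bayes update."""

    @pytest.mark.parametrize("seed", range(20))
    def test_normalization_and_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        kb = random_kb(rng)
        answers = random_answers(rng, kb)
        belief = init_belief(kb)
        for qid, ans in answers:
            belief = update_posterior(belief, kb.question_index[qid], ans)
            assert abs(sum(p for _, p in belief.items()) - 1.0) < 1e-9
        oracle = brute_force_posterior(kb, answers)
        for d in oracle:
            assert belief[d] == pytest.approx(oracle[d], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_commutativity(self, seed):
        rng = np.random.default_rng(1000 + seed)
        kb = random_kb(rng)
        answers = random_answers(rng, kb)

        def run(seq):
            b = init_belief(kb)
            for qid, ans in seq:
                b = update_posterior(b, kb.question_index[qid], ans)
            return b

        forward = run(answers)
        shuffled = list(answers)
        rng.shuffle(shuffled)
        assert forward.tv_distance(run(shuffled)) < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_unknown_neutrality(self, seed):
        rng = np.random.default_rng(2000 + seed)
        kb = random_kb(rng)
        answers = random_answers(rng, kb, p_unknown=0.0)
        with_unknowns = []
        for item in answers:
            with_unknowns.append(item)
        unanswered = [qq.id for qq in kb.questions
                      if qq.id not in {a for a, _ in answers}]
        for qid in unanswered:
            with_unknowns.append((qid, UNKNOWN))

        def run(seq):
            b = init_belief(kb)
            for qid, ans in seq:
                b = update_posterior(b, kb.question_index[qid], ans)
            return b

        assert run(answers).tv_distance(run(with_unknowns)) < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_evidence(self, seed):
        """YES to a question with P(YES|d1) > P(YES|d2) never lowers the
        posterior ratio d1:d2."""
        rng = np.random.default_rng(3000 + seed)
        kb = random_kb(rng, n_dx=5, n_q=6)
        belief = init_belief(kb)
        question = kb.questions[int(rng.integers(len(kb.questions)))]
        d1, d2 = "d0", "d1"
        if question.p_yes(d1) < question.p_yes(d2):
            d1, d2 = d2, d1
        before = belief[d1] / belief[d2]
        post = update_posterior(belief, question, YES)
        after = post[d1] / post[d2]
        assert after >= before - 1e-12


class TestRanking:
    def test_sorted_with_consecutive_ranks(self):
        kb = make_kb({"a": 0.5, "b": 0.3, "c": 0.2},
                     [q("q1", {}, default=0.5)])
        entries = rank_differential(init_belief(kb), kb)
        assert [e.diagnosis_id for e in entries] == ["a", "b", "c"]
        assert [e.rank for e in entries] == [1, 2, 3]
        assert entries[0].numeric_score == 50.0
        assert entries[0].visual_score == 5

    def test_ties_break_by_kb_order(self):
        kb = make_kb({"x": 0.4, "y": 0.4, "z": 0.2},
                     [q("q1", {}, default=0.5)])
        entries = rank_differential(init_belief(kb), kb)
        assert [e.diagnosis_id for e in entries][:2] == ["x", "y"]

    def test_low_posterior_urgent_diagnosis_still_displayed(self):
        kb = make_kb({"benign": 0.99, "grave": 0.01},
                     [q("q1", {}, default=0.5)], urgent=("grave",))
        entries = rank_differential(init_belief(kb), kb)
        shown = displayed_differential(entries, kb, top_n=1)
        assert "grave" in [e.diagnosis_id for e in shown]

    def test_zero_posterior_nonurgent_omitted_from_display_only(self):
        kb = make_kb({"a": 0.5, "b": 0.5},
                     [q("q1", {"a": 0.0, "b": 0.5})])
        belief = update_posterior(init_belief(kb), kb.questions[0], YES)
        entries = rank_differential(belief, kb)
        assert len(entries) == 2  # belief keeps every diagnosis
        shown = displayed_differential(entries, kb)
        assert [e.diagnosis_id for e in shown] == ["b"]


class TestEvidence:
    def test_no_answers_yields_empty_lists(self, two_dx_kb):
        state = SessionState(kb=two_dx_kb, belief=init_belief(two_dx_kb))
        assert evidence_for("a", state) == ([], [])

    def test_unknown_diagnosis_raises(self, two_dx_kb):
        state = SessionState(kb=two_dx_kb, belief=init_belief(two_dx_kb))
        with pytest.raises(KeyError):
            evidence_for("nope", state)

    def test_classification_matches_relative_shift_oracle(self):
        """An answer supports a diagnosis iff it raised that diagnosis's
        posterior share from a flat belief (recomputed by hand)."""
        kb = make_kb({"ulcer": 1.0, "conj": 1.0},
                     [q("opacity", {"ulcer": 0.9, "conj": 0.05}),
                      q("pain", {"ulcer": 0.7, "conj": 0.1})])
        state = SessionState(kb=kb, belief=init_belief(kb))
        apply_answer(state, kb.question_index["opacity"], YES)
        apply_answer(state, kb.question_index["pain"], NO)
        supporting, refuting = evidence_for("ulcer", state)
        assert [text for text, _ in supporting] == ["opacity?"]
        assert [text for text, _ in refuting] == ["pain?"]
        # oracle: flat belief, single update, compare shares
        flat = Belief({"ulcer": 0.5, "conj": 0.5})
        after = update_posterior(flat, kb.question_index["opacity"], YES)
        assert after["ulcer"] > 0.5  # supports
        after = update_posterior(flat, kb.question_index["pain"], NO)
        assert after["ulcer"] < 0.5  # refutes


class TestStopping:
    def test_dominant_top_posterior_stops(self):
        kb = make_kb({"a": 0.90, "b": 0.05, "c": 0.05},
                     [q("q1", {}, default=0.5)])
        state = SessionState(kb=kb, belief=init_belief(kb))
        decision = check_stop(state)
        assert decision.stop and decision.reason == "dominance"

    def test_continue_while_undecided_and_questions_remain(self):
        kb = make_kb({"a": 0.4, "b": 0.35, "c": 0.25},
                     [q("q1", {"a": 0.9, "b": 0.1, "c": 0.5})])
        state = SessionState(kb=kb, belief=init_belief(kb))
        assert not check_stop(state).stop

    def test_exhausted_bank_with_no_information_flags_low_confidence(self):
        kb = make_kb({"a": 0.4, "b": 0.35, "c": 0.25},
                     [q("q1", {}, default=0.5)])
        state = SessionState(kb=kb, belief=init_belief(kb))
        apply_answer(state, kb.questions[0], UNKNOWN)
        decision = check_stop(state)
        assert decision.stop and decision.reason == "exhausted"
        assert decision.low_confidence
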