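"""Dynamic question selection by value of information.

After the fixed opening questions, the next question is the eligible one
whose answer could move the belief the most: for each candidate we compute
the total-variation distance between the current belief and the belief
updated by a YES and by a NO, and score the question either by the larger
of the two shifts ("max", the default — best-case discrimination) or by the
answer-probability-weighted average ("expected").  UNKNOWN never changes the
belief, so it is excluded from scoring.

Eligibility enforces the KB's ordering constraints: a question with unmet
prerequisites is withheld, and a question whose redundancy trigger has fired
is permanently eliminated from the bank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, List, Optional

from .inference import (
    AnswerValue,
    Belief,
    ContradictionError,
    SessionState,
    update_posterior,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .knowledge_base import Question


@dataclass(frozen=True)
class VOIScore:
    """Value-of-information score for one candidate question."""

    question_id: str
    score: float
    per_answer: Dict[AnswerValue, float]  # YES/NO -> TV shift


def eligible_questions(state: SessionState) -> List["Question"]:
    """Questions that may still be asked, in KB declaration order.

    Excludes answered and eliminated questions and those with unsatisfied
    prerequisites.  Redundancy triggers are evaluated against the answered
    pairs first and fired questions are moved to ``state.eliminated``
    (idempotent), so elimination is permanent even if the triggering answer
    is later contradicted.
    """
    answered_pairs = set(state.answered)
    answered_ids = state.answered_ids
    for q in state.kb.questions:
        if q.id in state.eliminated or q.id in answered_ids:
            continue
        if any(pair in answered_pairs for pair in q.redundancy_triggers):
            state.eliminated.add(q.id)
    out = []
    for q in state.kb.questions:
        if q.id in answered_ids or q.id in state.eliminated:
            continue
        if all(pair in answered_pairs for pair in q.prerequisites):
            out.append(q)
    return out


def voi_score(belief: Belief, question: "Question",
              mode: str = "max") -> VOIScore:
    """Score a question by how far its answer could shift the belief.

    For each informative answer a ∈ {YES, NO}, d_a is the total-variation
    distance between the current belief and the Bayes-updated belief.  A
    contradictory branch (the answer would zero the whole belief)
    contributes d_a = 0 — it can never be observed under the model.

    mode="max":      score = max(d_YES, d_NO)
    mode="expected": score = Σ_a P(a) · d_a with P(a) = Σ_j pre_j P(a|j)
    """
    if mode not in ("max", "expected"):
        raise ValueError(f"unknown VOI mode: {mode!r}")
    detail: Dict[AnswerValue, float] = {}
    p_answer: Dict[AnswerValue, float] = {}
    for ans in (AnswerValue.YES, AnswerValue.NO):
        try:
            post = update_posterior(belief, question, ans)
            detail[ans] = belief.tv_distance(post)
        except ContradictionError:
            detail[ans] = 0.0
        p_yes = sum(p * question.p_yes(d) for d, p in belief.items())
        p_answer[ans] = p_yes if ans is AnswerValue.YES else 1.0 - p_yes
    if mode == "max":
        score = max(detail.values())
    else:
        score = sum(p_answer[a] * detail[a] for a in detail)
    return VOIScore(question_id=question.id, score=score, per_answer=detail)


def select_next_question(state: SessionState) -> Optional["Question"]:
    """Pick the next question, or None when the bank is spent.

    Unanswered opening questions come first, in KB order.  Afterwards the
    eligible question with the highest VOI score wins; ties break by KB
    declaration order, so selection is deterministic.
    """
    eligible = eligible_questions(state)
    if not eligible:
        return None
    for q in eligible:
        if q.opening:
            return q
    mode = state.kb.settings.voi_mode
    best = None
    best_score = -1.0
    for q in eligible:  # KB order; strict > keeps the earliest on ties
        s = voi_score(state.belief, q, mode=mode).score
        if s > best_score:
            best, best_score = q, s
    return best
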