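"""Interactive and batch front-ends over the inference engine.

``run_interview`` drives the ask → answer → update → re-rank → advise →
stop-check loop against any IO channel (the CLI passes real terminal IO,
tests pass scripted functions).  ``batch_diagnose`` replays recorded
questionnaire answer vectors; because the posterior is a product of
per-answer likelihoods, feeding answers in KB order yields exactly the
belief an interactive session with the same answers would reach, whatever
order the questions were asked in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from .inference import (
    AnswerValue,
    ContradictionError,
    DifferentialEntry,
    SessionState,
    apply_answer,
    check_stop,
    displayed_differential,
    init_belief,
    rank_differential,
)
from .knowledge_base import AdviceRule, KnowledgeBase
from .question_policy import select_next_question

logger = logging.getLogger("redeye")

QUIT_WORDS = frozenset({"quit", "exit", "stop", "q"})
#: unparseable replies tolerated before an answer is scored UNKNOWN
MAX_STRIKES = 3


@dataclass(frozen=True)
class BatchResult:
    """Outcome of one replayed case."""

    case_id: str
    differential: Tuple[DifferentialEntry, ...]
    advice: Tuple[str, ...]
    stopped_reason: str
    low_confidence: bool

    @property
    def top3(self) -> Tuple[str, ...]:
        return tuple(e.diagnosis_id for e in self.differential[:3])

    @property
    def top1(self) -> str:
        return self.differential[0].diagnosis_id


def advice_due(state: SessionState) -> List[AdviceRule]:
    """Advice rules whose condition holds now and have not yet fired."""
    answered = set(state.answered)
    due = []
    for rule in state.kb.advice:
        if rule.id in state.advice_emitted:
            continue
        if not all(pair in answered for pair in rule.answers):
            continue
        if rule.min_posterior is not None:
            dx, threshold = rule.min_posterior
            if state.belief[dx] < threshold:
                continue
        due.append(rule)
    return due


def _emit_advice(state: SessionState,
                 sink: Optional[Callable[[str], None]]) -> List[str]:
    messages = []
    for rule in advice_due(state):
        state.advice_emitted.append(rule.id)
        messages.append(rule.message)
        if sink is not None:
            sink(f"ADVICE: {rule.message}")
    return messages


def render_differential(entries: Sequence[DifferentialEntry],
                        kb: KnowledgeBase,
                        top_n: Optional[int] = None) -> str:
    """Plain-text differential: rank, name, numeric score, bar, urgency."""
    shown = displayed_differential(entries, kb, top_n=top_n)
    names = {d.id: d.name for d in kb.diagnoses}
    urgent = kb.urgent_ids
    width = max((len(names[e.diagnosis_id]) for e in shown), default=0)
    lines = []
    for e in shown:
        bar = "#" * e.visual_score + "." * (10 - e.visual_score)
        flag = "  [URGENT]" if e.diagnosis_id in urgent else ""
        lines.append(
            f"{e.rank:2d}. {names[e.diagnosis_id]:<{width}}  "
            f"{e.numeric_score:5.1f}  [{bar}]{flag}"
        )
    return "\n".join(lines)


def run_interview(
    kb: KnowledgeBase,
    input_fn: Callable[[str], str] = input,
    print_fn: Callable[[str], None] = print,
    top_n: Optional[int] = 5,
) -> SessionState:
    """Run one interactive workup and return the finished session.

    The differential (numeric + visual scores) is printed after every
    answer; advice is printed the moment its rule first fires.  The loop
    ends when the user quits, the top diagnosis dominates, or the question
    bank is exhausted.  Unparseable input re-prompts; after
    :data:`MAX_STRIKES` failures the answer is recorded as UNKNOWN.  A
    contradictory answer (one that would rule out every remaining
    diagnosis) is skipped with a warning rather than aborting the session.
    """
    state = SessionState(kb=kb, belief=init_belief(kb))
    while True:
        question = select_next_question(state)
        if question is None:
            decision = check_stop(state)
            state.stopped, state.stop_reason = True, "exhausted"
            state.low_confidence = decision.low_confidence
            break
        answer = None
        strikes = 0
        while answer is None:
            raw = input_fn(f"{question.text} [yes/no/unknown] ")
            if raw is not None and str(raw).strip().lower() in QUIT_WORDS:
                decision = check_stop(state)
                state.stopped, state.stop_reason = True, "user"
                state.low_confidence = decision.low_confidence
                return state
            try:
                answer = AnswerValue.parse(raw)
            except ValueError:
                strikes += 1
                if strikes >= MAX_STRIKES:
                    logger.warning(
                        "unparseable answer to %r three times; "
                        "recording UNKNOWN", question.id)
                    answer = AnswerValue.UNKNOWN
                else:
                    print_fn("Please answer yes, no, or unknown.")
        try:
            apply_answer(state, question, answer)
        except ContradictionError:
            logger.warning(
                "answer %s to %r contradicts every remaining diagnosis; "
                "skipped", answer.value, question.id)
            print_fn(
                f"(That answer is inconsistent with every remaining "
                f"diagnosis; skipping {question.id}.)"
            )
            state.answered.append((question.id, AnswerValue.UNKNOWN))
            continue
        print_fn(render_differential(rank_differential(state.belief, kb),
                                     kb, top_n=top_n))
        _emit_advice(state, print_fn)
        decision = check_stop(state)
        if decision.stop:
            state.stopped, state.stop_reason = True, decision.reason
            state.low_confidence = decision.low_confidence
            break
    return state


def replay_answers(
    kb: KnowledgeBase,
    answers: Dict[str, AnswerValue],
) -> SessionState:
    """Feed a recorded answer vector through the engine in KB order.

    Unknown question ids raise a KeyError listing the offenders.  Advice
    rules are evaluated after every update, as in an interview.
    Contradictory answers are skipped with a warning (recorded as UNKNOWN),
    matching interactive behavior.
    """
    unknown = sorted(set(answers) - set(kb.question_index))
    if unknown:
        raise KeyError(
            f"answer columns do not map onto KB questions: {unknown}"
        )
    state = SessionState(kb=kb, belief=init_belief(kb))
    for q in kb.questions:
        ans = answers.get(q.id, AnswerValue.UNKNOWN)
        try:
            apply_answer(state, q, ans)
        except ContradictionError:
            logger.warning(
                "case answer %s to %r contradicts every remaining "
                "diagnosis; skipped", ans.value, q.id)
            state.answered.append((q.id, AnswerValue.UNKNOWN))
        _emit_advice(state, None)
    state.stopped, state.stop_reason = True, "exhausted"
    prior = init_belief(kb)
    from .inference import LOW_CONFIDENCE_TV
    state.low_confidence = (
        state.belief.tv_distance(prior) <= LOW_CONFIDENCE_TV
    )
    return state


def batch_diagnose(kb: KnowledgeBase, cases: Iterable) -> List[BatchResult]:
    """Diagnose a batch of recorded cases; deterministic.

    Each case needs ``case_id`` and ``answers`` attributes (see
    ``evaluation.CaseRecord``).  Every provided answer is consumed; order
    is irrelevant because the update is commutative.
    """
    results = []
    for case in cases:
        state = replay_answers(kb, case.answers)
        advice = tuple(
            next(r.message for r in kb.advice if r.id == rid)
            for rid in state.advice_emitted
        )
        results.append(BatchResult(
            case_id=case.case_id,
            differential=tuple(rank_differential(state.belief, kb)),
            advice=advice,
            stopped_reason=state.stop_reason or "exhausted",
            low_confidence=state.low_confidence,
        ))
    return results
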