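"""Belief maintenance over the differential diagnosis.

The engine models a patient as having exactly one of the diagnoses in the
knowledge base and treats every questionnaire item as a binary finding whose
YES-probability is specified per diagnosis.  Under conditional independence
of findings given the diagnosis, the posterior after any set of answers is
the normalized product of the prior and the per-answer likelihoods — a naive
Bayes update applied one answer at a time.

"I don't know" carries likelihood 1 for every diagnosis and therefore never
moves the belief; this mirrors how undocumented questionnaire responses are
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence, Tuple

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .knowledge_base import KnowledgeBase, Question

#: Tolerance for normalization and probability comparisons.
TOL = 1e-9

#: Total-variation radius around the prior below which a finished session is
#: flagged as low-confidence (no discrimination achieved).
LOW_CONFIDENCE_TV = 0.05


class AnswerValue(Enum):
    """A questionnaire response: YES, NO, or UNKNOWN ("I don't know")."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: object) -> "AnswerValue":
        """Parse a free-text answer, case-insensitively.

        Blank strings and None map to UNKNOWN, as do "i don't know" and
        common abbreviations.  Raises ``ValueError`` for anything else.
        """
        if text is None:
            return cls.UNKNOWN
        if isinstance(text, AnswerValue):
            return text
        s = str(text).strip().lower()
        if s in ("", "unknown", "u", "i don't know", "i dont know", "idk",
                 "dk", "?", "na", "n/a"):
            return cls.UNKNOWN
        if s in ("yes", "y", "true", "1"):
            return cls.YES
        if s in ("no", "n", "false", "0"):
            return cls.NO
        raise ValueError(f"unparseable answer: {text!r}")


class ContradictionError(ValueError):
    """An answer assigned zero likelihood to every remaining diagnosis."""

    def __init__(self, question_id: str):
        self.question_id = question_id
        super().__init__(
            f"answer to question {question_id!r} rules out every diagnosis "
            "with remaining probability mass"
        )


@dataclass(frozen=True)
class Belief:
    """A normalized probability distribution over diagnosis ids."""

    probabilities: Dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"belief does not sum to 1 (sum={total!r})")
        if any(p < -TOL for p in self.probabilities.values()):
            raise ValueError("belief contains negative probability")

    def __getitem__(self, diagnosis_id: str) -> float:
        return self.probabilities[diagnosis_id]

    def items(self):
        return self.probabilities.items()

    def tv_distance(self, other: "Belief") -> float:
        """Total-variation distance ½ Σ|p_i − q_i| to another belief."""
        keys = self.probabilities.keys()
        return 0.5 * sum(
            abs(self.probabilities[k] - other.probabilities[k]) for k in keys
        )


@dataclass(frozen=True)
class DifferentialEntry:
    """One row of the ranked differential.

    ``numeric_score`` is the posterior as a percentage rounded to 1 decimal;
    ``visual_score`` is a 0-10 bar length.
    """

    diagnosis_id: str
    posterior: float
    numeric_score: float
    visual_score: int
    rank: int


@dataclass(frozen=True)
class StopDecision:
    stop: bool
    reason: Optional[str]  # "user" | "dominance" | "exhausted" | None
    low_confidence: bool


@dataclass
class SessionState:
    """Mutable state of one diagnostic session (interactive or batch)."""

    kb: "KnowledgeBase"
    belief: Belief
    answered: List[Tuple[str, AnswerValue]] = field(default_factory=list)
    eliminated: set = field(default_factory=set)
    advice_emitted: List[str] = field(default_factory=list)
    stopped: bool = False
    stop_reason: Optional[str] = None
    low_confidence: bool = False
    #: belief snapshot after each answer, for audit export
    trajectory: List[Tuple[str, AnswerValue, Belief]] = field(
        default_factory=list
    )

    @property
    def answered_ids(self) -> set:
        return {qid for qid, _ in self.answered}

    def trajectory_rows(self) -> List[Dict[str, object]]:
        """Belief trajectory as flat rows (question, answer, posteriors)."""
        rows: List[Dict[str, object]] = []
        for step, (qid, ans, belief) in enumerate(self.trajectory, start=1):
            row: Dict[str, object] = {
                "step": step, "question_id": qid, "answer": ans.value,
            }
            row.update(belief.probabilities)
            rows.append(row)
        return rows


def init_belief(kb: "KnowledgeBase") -> Belief:
    """Initialize the belief to the KB's normalized priors."""
    total = sum(d.prior for d in kb.diagnoses)
    if total <= 0:
        raise ValueError("cannot initialize belief: all priors are zero")
    return Belief({d.id: d.prior / total for d in kb.diagnoses})


def answer_likelihood(question: "Question", diagnosis_id: str,
                      answer: AnswerValue) -> float:
    """Likelihood of ``answer`` to ``question`` given ``diagnosis_id``.

    UNKNOWN has likelihood 1 for every diagnosis (no information).
    """
    if answer is AnswerValue.UNKNOWN:
        return 1.0
    p_yes = question.p_yes(diagnosis_id)
    return p_yes if answer is AnswerValue.YES else 1.0 - p_yes


def update_posterior(belief: Belief, question: "Question",
                     answer: AnswerValue) -> Belief:
    """One Bayes step: reweight the belief by the answer's likelihood.

    A conditional probability of 0 (or 1) acts as a hard rule-out: the
    corresponding diagnoses drop to exactly zero posterior.  If the answer
    rules out *every* diagnosis still carrying mass, a
    :class:`ContradictionError` is raised; interactive callers may downgrade
    this to a logged skip.
    """
    if answer is AnswerValue.UNKNOWN:
        return belief
    weighted = {
        d: p * answer_likelihood(question, d, answer)
        for d, p in belief.items()
    }
    total = sum(weighted.values())
    if total <= 0.0:
        raise ContradictionError(question.id)
    return Belief({d: w / total for d, w in weighted.items()})


def apply_answer(state: SessionState, question: "Question",
                 answer: AnswerValue) -> None:
    """Record an answer in the session and update the belief.

    Raises :class:`ContradictionError` without recording the answer if the
    update would zero out the whole belief.
    """
    new_belief = update_posterior(state.belief, question, answer)
    state.belief = new_belief
    state.answered.append((question.id, answer))
    state.trajectory.append((question.id, answer, new_belief))


def rank_differential(belief: Belief, kb: "KnowledgeBase"
                      ) -> List[DifferentialEntry]:
    """Full ranked differential, ties broken by KB declaration order."""
    order = {d.id: i for i, d in enumerate(kb.diagnoses)}
    ids = sorted(belief.probabilities,
                 key=lambda d: (-belief[d], order[d]))
    entries = []
    for rank, d in enumerate(ids, start=1):
        p = belief[d]
        entries.append(DifferentialEntry(
            diagnosis_id=d,
            posterior=p,
            numeric_score=round(p * 100, 1),
            visual_score=int(round(p * 10)),
            rank=rank,
        ))
    return entries


def displayed_differential(entries: Sequence[DifferentialEntry],
                           kb: "KnowledgeBase",
                           top_n: Optional[int] = None
                           ) -> List[DifferentialEntry]:
    """Entries to render: the top ``top_n`` plus every urgent diagnosis with
    nonzero posterior, regardless of rank, so critical diagnoses stay in
    view.  Zero-posterior non-urgent entries are dropped from display only.
    """
    urgent = {d.id for d in kb.diagnoses if d.urgent}
    shown = []
    for e in entries:
        in_cut = top_n is None or e.rank <= top_n
        if e.diagnosis_id in urgent and e.posterior > 0.0:
            shown.append(e)
        elif in_cut and e.posterior > 0.0:
            shown.append(e)
    return shown


def evidence_for(diagnosis_id: str, state: SessionState
                 ) -> Tuple[List[Tuple[str, AnswerValue]],
                            List[Tuple[str, AnswerValue]]]:
    """Split answered questions into supporting vs refuting evidence.

    An answered (non-UNKNOWN) question supports the diagnosis when its
    likelihood under that diagnosis exceeds the unweighted average
    likelihood across all diagnoses — i.e. the answer raised this
    diagnosis's share of the posterior relative to a flat belief — and
    refutes it when below; neutral answers are omitted.  Each item carries
    the question text and the given answer.
    """
    kb = state.kb
    if diagnosis_id not in kb.diagnosis_index:
        raise KeyError(f"unknown diagnosis id: {diagnosis_id!r}")
    supporting: List[Tuple[str, AnswerValue]] = []
    refuting: List[Tuple[str, AnswerValue]] = []
    n = len(kb.diagnoses)
    for qid, ans in state.answered:
        if ans is AnswerValue.UNKNOWN:
            continue
        q = kb.question_index[qid]
        lik = answer_likelihood(q, diagnosis_id, ans)
        avg = sum(answer_likelihood(q, d.id, ans) for d in kb.diagnoses) / n
        if lik > avg + TOL:
            supporting.append((q.text, ans))
        elif lik < avg - TOL:
            refuting.append((q.text, ans))
    return supporting, refuting


def check_stop(state: SessionState) -> StopDecision:
    """Decide whether the workup should stop.

    Stops when the top posterior dominates the runner-up by the configured
    factor θ while clearing the posterior floor, or when no eligible
    question remains.  On stopping, the session is additionally flagged
    ``low_confidence`` when the belief sits within total variation
    :data:`LOW_CONFIDENCE_TV` of the prior — the answers discriminated
    nothing, so the top diagnosis is essentially the prior's.
    """
    from .question_policy import eligible_questions  # avoid import cycle

    kb = state.kb
    probs = sorted(state.belief.probabilities.values(), reverse=True)
    top = probs[0]
    second = probs[1] if len(probs) > 1 else 0.0
    settings = kb.settings

    reason: Optional[str] = None
    if top >= settings.theta * second and top >= settings.posterior_stop:
        reason = "dominance"
    elif not eligible_questions(state):
        reason = "exhausted"

    if reason is None:
        return StopDecision(stop=False, reason=None, low_confidence=False)
    low = state.belief.tv_distance(init_belief(kb)) <= LOW_CONFIDENCE_TV
    return StopDecision(stop=True, reason=reason, low_confidence=low)
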