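"""Shared fixtures: the shipped KB, tiny hand-built KBs, random KBs, and
the independent brute-force Bayes oracle used to cross-check the engine."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from redeye import (
    AnswerValue,
    Diagnosis,
    KnowledgeBase,
    Question,
    Settings,
    load_default_kb,
)

YES, NO, UNKNOWN = AnswerValue.YES, AnswerValue.NO, AnswerValue.UNKNOWN


@pytest.fixture(scope="session")
def default_kb() -> KnowledgeBase:
    return load_default_kb()


def make_kb(priors: Dict[str, float],
            questions: List[Question],
            urgent: Tuple[str, ...] = (),
            settings: Optional[Settings] = None) -> KnowledgeBase:
    """Small hand-built KB with normalized priors."""
    total = sum(priors.values())
    diagnoses = tuple(
        Diagnosis(id=d, name=d.title(), urgent=d in urgent, prior=p / total)
        for d, p in priors.items()
    )
    return KnowledgeBase(
        diagnoses=diagnoses,
        questions=tuple(questions),
        settings=settings or Settings(),
    )


def q(qid: str, model: Dict[str, float], default: Optional[float] = None,
      **kwargs) -> Question:
    return Question(id=qid, text=f"{qid}?", answer_model=model,
                    default=default, **kwargs)


@pytest.fixture
def two_dx_kb() -> KnowledgeBase:
    """Two diagnoses, one separating question: P(YES|a)=0.8, P(YES|b)=0.4."""
    return make_kb(
        {"a": 1.0, "b": 1.0},
        [q("sep", {"a": 0.8, "b": 0.4})],
    )


def random_kb(rng: np.random.Generator,
              n_dx: Optional[int] = None,
              n_q: Optional[int] = None) -> KnowledgeBase:
    """Random KB (up to 15 diagnoses x 30 questions) with probabilities in
    (0, 1), so no answer sequence is contradictory."""
    n_dx = n_dx or int(rng.integers(2, 16))
    n_q = n_q or int(rng.integers(1, 31))
    priors = {f"d{i}": float(rng.uniform(0.1, 1.0)) for i in range(n_dx)}
    questions = [
        q(f"q{j}", {f"d{i}": float(rng.uniform(0.02, 0.98))
                    for i in range(n_dx)})
        for j in range(n_q)
    ]
    return make_kb(priors, questions)


def random_answers(rng: np.random.Generator, kb: KnowledgeBase,
                   n: Optional[int] = None,
                   p_unknown: float = 0.2
                   ) -> List[Tuple[str, AnswerValue]]:
    """Random (question, answer) sequence over distinct KB questions."""
    n = n if n is not None else int(rng.integers(0, len(kb.questions) + 1))
    picks = rng.choice(len(kb.questions), size=n, replace=False)
    out = []
    for j in picks:
        u = rng.random()
        ans = UNKNOWN if u < p_unknown else (YES if u < 0.6 else NO)
        out.append((kb.questions[int(j)].id, ans))
    return out


def brute_force_posterior(kb: KnowledgeBase,
                          answers: List[Tuple[str, AnswerValue]]
                          ) -> Dict[str, float]:
    """Independent oracle: single normalized product of likelihoods.

    Deliberately computed in one pass (no incremental renormalization) so
    it exercises a different code path than the engine.
    """
    weights = {}
    for d in kb.diagnoses:
        w = d.prior
        for qid, ans in answers:
            if ans is UNKNOWN:
                continue
            p_yes = kb.question_index[qid].p_yes(d.id)
            w *= p_yes if ans is YES else 1.0 - p_yes
        weights[d.id] = w
    total = sum(weights.values())
    return {d: w / total for d, w in weights.items()}
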