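"""Synthetic patient questionnaires.

The generator draws cases from the same statistical model the engine
assumes: a gold diagnosis sampled from a prevalence distribution, then each
question answered YES with its KB-declared conditional probability,
independently given the diagnosis.  Two corruption knobs emulate real
questionnaires: ``noise_rate`` flips a YES/NO answer (a referrer recording
a finding the gold-standard clinician disputes), and ``unknown_rate``
blanks it to "I don't know" (an undocumented response).  Because answers
are conditionally independent given diagnosis — exactly the engine's
assumption — recovery accuracy on these cases measures engine correctness
and KB separability, not clinical validity.

The "ed-mix" prevalence option mirrors the emergency-department case mix of
the 57-patient validation study (16 keratitis/abrasion, 13 iritis, 11
corneal ulcer, 4 conjunctivitis, 4 scleritis, 2 dry eye, 1 each of eczema,
subconjunctival blood, acute angle closure and endophthalmitis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .evaluation import CaseRecord
from .inference import AnswerValue
from .knowledge_base import KnowledgeBase

#: per-diagnosis case counts of the validation study's gold standard
ED_MIX_COUNTS: Dict[str, int] = {
    "eczema": 1,
    "dry_eye": 2,
    "subconj_blood": 1,
    "conjunctivitis": 4,
    "scleritis": 4,
    "keratitis": 16,
    "corneal_ulcer": 11,
    "acute_acg": 1,
    "iritis": 13,
    "endophthalmitis": 1,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic batch.

    prevalence: sampling weights per diagnosis id; defaults to the KB
        priors.  Pass :func:`ed_mix_prevalence` to emulate the study's
        emergency-department case mix.
    unknown_rate: probability an answer is blanked to UNKNOWN (default 0 —
        fully documented questionnaires).
    noise_rate: probability a YES/NO answer is flipped (default 0 —
        answers agree with the gold-standard clinician).
    """

    kb: KnowledgeBase
    n_cases: int
    prevalence: Optional[Mapping[str, float]] = None
    unknown_rate: float = 0.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.unknown_rate <= 1.0:
            raise ValueError("unknown_rate must be in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.n_cases < 0:
            raise ValueError("n_cases must be nonnegative")


def ed_mix_prevalence(kb: KnowledgeBase) -> Dict[str, float]:
    """Emergency-department case-mix weights over the KB's diagnoses.

    Diagnoses absent from the study's gold standard get weight 0.
    """
    return {d.id: float(ED_MIX_COUNTS.get(d.id, 0)) for d in kb.diagnoses}


def _weights(config: SimulationConfig) -> Tuple[List[str], np.ndarray]:
    kb = config.kb
    if config.prevalence is None:
        prev = {d.id: d.prior for d in kb.diagnoses}
    else:
        prev = dict(config.prevalence)
        unknown = sorted(set(prev) - set(kb.diagnosis_index))
        if unknown:
            raise ValueError(f"prevalence names unknown diagnoses: {unknown}")
    ids = [d.id for d in kb.diagnoses]
    w = np.array([max(prev.get(d, 0.0), 0.0) for d in ids], dtype=float)
    if w.sum() <= 0:
        raise ValueError("prevalence weights are all zero")
    return ids, w / w.sum()


def simulate_cases(config: SimulationConfig) -> List[CaseRecord]:
    """Draw a deterministic batch of synthetic cases.

    Per case: sample gold_dx from the prevalence; answer each question as
    Bernoulli(P(YES | gold_dx)); flip with ``noise_rate``; blank to UNKNOWN
    with ``unknown_rate``.  The referrer diagnosis is left unattempted —
    synthetic cases exercise the algorithm, not referrers.  Identical
    config and seed give identical output.
    """
    kb = config.kb
    ids, weights = _weights(config)
    rng = np.random.default_rng(config.seed)
    cases = []
    for i in range(config.n_cases):
        gold = ids[rng.choice(len(ids), p=weights)]
        answers: Dict[str, AnswerValue] = {}
        for q in kb.questions:
            yes = rng.random() < q.p_yes(gold)
            if rng.random() < config.noise_rate:
                yes = not yes
            if rng.random() < config.unknown_rate:
                answers[q.id] = AnswerValue.UNKNOWN
            else:
                answers[q.id] = AnswerValue.YES if yes else AnswerValue.NO
        cases.append(CaseRecord(
            case_id=f"sim{i + 1:05d}",
            answers=answers,
            referrer_dx=None,
            gold_dx=gold,
        ))
    return cases


def perturb_answers(case: CaseRecord,
                    edits: Sequence[Tuple[str, AnswerValue]],
                    kb: Optional[KnowledgeBase] = None) -> CaseRecord:
    """Copy a case with some answers changed (the original is untouched).

    Used for re-run analyses: change the findings in dispute and see how
    the differential moves.  With a KB given, edit targets are checked
    against the question bank.
    """
    if kb is not None:
        unknown = sorted({qid for qid, _ in edits}
                         - set(kb.question_index))
        if unknown:
            raise KeyError(f"edits reference unknown questions: {unknown}")
    answers = dict(case.answers)
    for qid, ans in edits:
        answers[qid] = AnswerValue.parse(ans)
    return replace(case, answers=answers)
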