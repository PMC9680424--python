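"""Knowledge base: the diagnosis ontology and question bank.

A knowledge base bundles everything the engine needs to run a workup for one
complaint: the candidate diagnoses with relative pre-test prevalences and
urgency flags, the Yes/No/I-don't-know question bank with per-diagnosis
answer models and ordering constraints, management-advice rules, and engine
settings.  The file format is a single human-editable YAML document (JSON is
a YAML subset and also accepted); the schema is documented field-by-field in
``docs/kb-schema.md`` and machine-validated by ``data/kb_schema.json``.

The shipped default KB covers the 15 red-eye diagnoses the engine
distinguishes, four of which (corneal ulcer, acute angle-closure glaucoma,
iritis, endophthalmitis/severe inflammation) are flagged urgent.  Its
conditional probabilities are authored from standard clinical cues —
fluorescein staining, whitish corneal opacity, contact lens use, foreign
body sensation, pain, pupil and corneal findings, redness pattern, lid
signs, discharge, tearing, trauma, vision loss, recent surgery — and are
editable; the engine itself is KB-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

from .inference import AnswerValue

PathLike = Union[str, Path]

#: Name of the catch-all evaluation bucket for gold diagnoses the KB does
#: not model (always scored algorithm-incorrect).
OTHER = "other"


class KBSchemaError(ValueError):
    """The file does not parse as the documented KB schema."""


class KBValidationError(ValueError):
    """A structurally parsed KB violates one or more invariants."""

    def __init__(self, violations: List[str]):
        self.violations = violations
        super().__init__(
            "knowledge base failed validation:\n  - "
            + "\n  - ".join(violations)
        )


@dataclass(frozen=True)
class Diagnosis:
    id: str
    name: str
    urgent: bool = False
    prior: float = 1.0


@dataclass(frozen=True)
class Question:
    """One questionnaire item with its disease-stratification table.

    ``answer_model`` maps diagnosis id -> P(YES | diagnosis); ``default``
    fills in any diagnosis not listed explicitly.  A value of 0 is a hard
    rule-out on YES and 1 a hard rule-out on NO.  ``prerequisites`` are
    (question-id, answer) pairs that must already hold before this question
    becomes eligible; ``redundancy_triggers`` are pairs whose occurrence
    permanently eliminates this question from the bank.  ``opening``
    questions form the fixed opening set asked before dynamic ordering
    begins.
    """

    id: str
    text: str
    answer_model: Dict[str, float]
    default: Optional[float] = None
    prerequisites: Tuple[Tuple[str, AnswerValue], ...] = ()
    redundancy_triggers: Tuple[Tuple[str, AnswerValue], ...] = ()
    opening: bool = False

    def p_yes(self, diagnosis_id: str) -> float:
        if diagnosis_id in self.answer_model:
            return self.answer_model[diagnosis_id]
        if self.default is not None:
            return self.default
        raise KeyError(
            f"question {self.id!r} has no answer model for diagnosis "
            f"{diagnosis_id!r} and no default"
        )


@dataclass(frozen=True)
class AdviceRule:
    """Fires a management message when its condition first holds.

    The condition is a conjunction of (question-id, answer) pairs over the
    answered set, optionally strengthened by a minimum posterior for a named
    diagnosis.  A rule fires at most once per session.
    """

    id: str
    message: str
    answers: Tuple[Tuple[str, AnswerValue], ...] = ()
    min_posterior: Optional[Tuple[str, float]] = None


@dataclass(frozen=True)
class Settings:
    """Engine settings stored with the KB.

    theta: dominance factor — stop once the top posterior is at least
        theta times the runner-up (and clears ``posterior_stop``).
    posterior_stop: absolute posterior floor for the dominance stop.
    voi_mode: "max" (best-case belief shift over the two informative
        answers) or "expected" (answer-probability-weighted shift).
    """

    theta: float = 5.0
    posterior_stop: float = 0.5
    voi_mode: str = "max"


@dataclass(frozen=True)
class KnowledgeBase:
    diagnoses: Tuple[Diagnosis, ...]
    questions: Tuple[Question, ...]
    advice: Tuple[AdviceRule, ...] = ()
    settings: Settings = Settings()

    @property
    def diagnosis_index(self) -> Dict[str, Diagnosis]:
        return {d.id: d for d in self.diagnoses}

    @property
    def question_index(self) -> Dict[str, Question]:
        return {q.id: q for q in self.questions}

    @property
    def urgent_ids(self) -> frozenset:
        return frozenset(d.id for d in self.diagnoses if d.urgent)


# ---------------------------------------------------------------------------
# parsing

def _parse_answer_pair(raw: object, where: str) -> Tuple[str, AnswerValue]:
    if not isinstance(raw, (list, tuple)) or len(raw) != 2:
        raise KBSchemaError(
            f"{where}: expected a [question-id, answer] pair, got {raw!r}"
        )
    qid, ans = raw
    try:
        return str(qid), AnswerValue.parse(ans)
    except ValueError as exc:
        raise KBSchemaError(f"{where}: {exc}") from exc


def _parse_question(raw: dict, idx: int) -> Question:
    where = f"questions[{idx}]"
    if not isinstance(raw, dict) or "id" not in raw:
        raise KBSchemaError(f"{where}: missing 'id'")
    qid = str(raw["id"])
    if "text" not in raw:
        raise KBSchemaError(f"{where} ({qid}): missing 'text'")
    model_raw = raw.get("answer_model")
    if not isinstance(model_raw, dict):
        raise KBSchemaError(f"{where} ({qid}): missing 'answer_model' table")
    model = {}
    default = None
    for key, val in model_raw.items():
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise KBSchemaError(
                f"{where} ({qid}): answer_model[{key!r}] is not a number"
            )
        if key == "default":
            default = float(val)
        else:
            model[str(key)] = float(val)
    prereqs = tuple(
        _parse_answer_pair(p, f"{where} ({qid}).prerequisites[{i}]")
        for i, p in enumerate(raw.get("prerequisites", []) or [])
    )
    triggers = tuple(
        _parse_answer_pair(p, f"{where} ({qid}).redundancy_triggers[{i}]")
        for i, p in enumerate(raw.get("redundancy_triggers", []) or [])
    )
    return Question(
        id=qid,
        text=str(raw["text"]),
        answer_model=model,
        default=default,
        prerequisites=prereqs,
        redundancy_triggers=triggers,
        opening=bool(raw.get("opening", False)),
    )


def _parse_advice(raw: dict, idx: int) -> AdviceRule:
    where = f"advice[{idx}]"
    if not isinstance(raw, dict) or "id" not in raw:
        raise KBSchemaError(f"{where}: missing 'id'")
    rid = str(raw["id"])
    cond = raw.get("when", {}) or {}
    answers = tuple(
        _parse_answer_pair(p, f"{where} ({rid}).when.answers[{i}]")
        for i, p in enumerate(cond.get("answers", []) or [])
    )
    min_post = None
    if "min_posterior" in cond and cond["min_posterior"] is not None:
        mp = cond["min_posterior"]
        if not isinstance(mp, dict) or len(mp) != 1:
            raise KBSchemaError(
                f"{where} ({rid}): min_posterior must map one diagnosis id "
                "to a probability"
            )
        (dx, p), = mp.items()
        min_post = (str(dx), float(p))
    return AdviceRule(
        id=rid,
        message=str(raw.get("message", "")),
        answers=answers,
        min_posterior=min_post,
    )


def parse_kb(doc: dict) -> KnowledgeBase:
    """Build an (unvalidated, unnormalized) KnowledgeBase from a mapping."""
    if not isinstance(doc, dict):
        raise KBSchemaError("top level of KB document must be a mapping")
    diagnoses = []
    for i, raw in enumerate(doc.get("diagnoses", []) or []):
        if not isinstance(raw, dict) or "id" not in raw:
            raise KBSchemaError(f"diagnoses[{i}]: missing 'id'")
        prior = raw.get("prior", 1.0)
        if not isinstance(prior, (int, float)) or isinstance(prior, bool):
            raise KBSchemaError(
                f"diagnoses[{i}] ({raw['id']}): 'prior' is not a number"
            )
        diagnoses.append(Diagnosis(
            id=str(raw["id"]),
            name=str(raw.get("name", raw["id"])),
            urgent=bool(raw.get("urgent", False)),
            prior=float(prior),
        ))
    questions = tuple(
        _parse_question(raw, i)
        for i, raw in enumerate(doc.get("questions", []) or [])
    )
    advice = tuple(
        _parse_advice(raw, i)
        for i, raw in enumerate(doc.get("advice", []) or [])
    )
    sraw = doc.get("settings", {}) or {}
    settings = Settings(
        theta=float(sraw.get("theta", 5.0)),
        posterior_stop=float(sraw.get("posterior_stop", 0.5)),
        voi_mode=str(sraw.get("voi_mode", "max")),
    )
    return KnowledgeBase(
        diagnoses=tuple(diagnoses), questions=questions,
        advice=advice, settings=settings,
    )


# ---------------------------------------------------------------------------
# validation

def _prerequisite_cycle(kb: KnowledgeBase) -> Optional[List[str]]:
    """Return a question-id cycle in the prerequisite graph, if any."""
    graph = {q.id: [qid for qid, _ in q.prerequisites
                    if qid in kb.question_index]
             for q in kb.questions}
    WHITE, GREY, BLACK = 0, 1, 2
    color = {q: WHITE for q in graph}
    stack: List[str] = []

    def visit(node: str) -> Optional[List[str]]:
        color[node] = GREY
        stack.append(node)
        for dep in graph[node]:
            if color[dep] == GREY:
                return stack[stack.index(dep):] + [dep]
            if color[dep] == WHITE:
                found = visit(dep)
                if found:
                    return found
        stack.pop()
        color[node] = BLACK
        return None

    for node in graph:
        if color[node] == WHITE:
            found = visit(node)
            if found:
                return found
    return None


def validate_kb(kb: KnowledgeBase) -> List[str]:
    """Check every structural invariant; return an itemized report.

    An empty list means the KB is valid.  Each entry names the offending
    component, so a KB author can fix the file without reading code.
    """
    report: List[str] = []
    dx_ids = [d.id for d in kb.diagnoses]
    if len(set(dx_ids)) != len(dx_ids):
        dupes = sorted({d for d in dx_ids if dx_ids.count(d) > 1})
        report.append(f"duplicate diagnosis ids: {dupes}")
    if not kb.diagnoses:
        report.append("KB declares no diagnoses")
    for d in kb.diagnoses:
        if d.prior < 0:
            report.append(f"diagnosis {d.id!r}: negative prior {d.prior}")
    if kb.diagnoses and all(d.prior <= 0 for d in kb.diagnoses):
        report.append("no diagnosis has prior > 0")

    q_ids = [q.id for q in kb.questions]
    if len(set(q_ids)) != len(q_ids):
        dupes = sorted({q for q in q_ids if q_ids.count(q) > 1})
        report.append(f"duplicate question ids: {dupes}")
    known_q = set(q_ids)
    dx_set = set(dx_ids)
    for q in kb.questions:
        for dx, p in q.answer_model.items():
            if dx not in dx_set:
                report.append(
                    f"question {q.id!r}: answer_model references unknown "
                    f"diagnosis {dx!r}"
                )
            if not 0.0 <= p <= 1.0:
                report.append(
                    f"question {q.id!r}: answer_model[{dx!r}] = {p} is "
                    "outside [0, 1]"
                )
        if q.default is not None and not 0.0 <= q.default <= 1.0:
            report.append(
                f"question {q.id!r}: default = {q.default} is outside [0, 1]"
            )
        if q.default is None:
            missing = sorted(dx_set - set(q.answer_model))
            if missing:
                report.append(
                    f"question {q.id!r}: answer_model omits diagnoses "
                    f"{missing} and declares no default"
                )
        for qid, _ in q.prerequisites:
            if qid not in known_q:
                report.append(
                    f"question {q.id!r}: prerequisite references unknown "
                    f"question {qid!r}"
                )
        for qid, _ in q.redundancy_triggers:
            if qid not in known_q:
                report.append(
                    f"question {q.id!r}: redundancy trigger references "
                    f"unknown question {qid!r}"
                )
    cycle = _prerequisite_cycle(kb)
    if cycle:
        report.append("prerequisite cycle: " + " -> ".join(cycle))

    for rule in kb.advice:
        if not rule.message:
            report.append(f"advice rule {rule.id!r}: empty message")
        for qid, _ in rule.answers:
            if qid not in known_q:
                report.append(
                    f"advice rule {rule.id!r}: condition references unknown "
                    f"question {qid!r}"
                )
        if rule.min_posterior is not None:
            dx, p = rule.min_posterior
            if dx not in dx_set:
                report.append(
                    f"advice rule {rule.id!r}: min_posterior references "
                    f"unknown diagnosis {dx!r}"
                )
            if not 0.0 <= p <= 1.0:
                report.append(
                    f"advice rule {rule.id!r}: min_posterior {p} outside "
                    "[0, 1]"
                )

    if kb.settings.theta < 1.0:
        report.append(f"settings.theta = {kb.settings.theta} must be >= 1")
    if not 0.0 <= kb.settings.posterior_stop <= 1.0:
        report.append(
            f"settings.posterior_stop = {kb.settings.posterior_stop} "
            "outside [0, 1]"
        )
    if kb.settings.voi_mode not in ("max", "expected"):
        report.append(
            f"settings.voi_mode = {kb.settings.voi_mode!r} is not one of "
            "'max' or 'expected'"
        )
    return report


def _normalize_priors(kb: KnowledgeBase) -> KnowledgeBase:
    total = sum(d.prior for d in kb.diagnoses)
    diagnoses = tuple(
        Diagnosis(d.id, d.name, d.urgent, d.prior / total)
        for d in kb.diagnoses
    )
    return KnowledgeBase(diagnoses, kb.questions, kb.advice, kb.settings)


def load_kb(path: PathLike) -> KnowledgeBase:
    """Load, validate and normalize a KB file.

    Raises :class:`KBSchemaError` on parse failure and
    :class:`KBValidationError` (with the itemized report) on invariant
    violations.  Priors are renormalized to sum to 1.
    """
    text = Path(path).read_text()
    return loads_kb(text)


def loads_kb(text: str) -> KnowledgeBase:
    """Like :func:`load_kb`, from a string."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise KBSchemaError(f"KB file is not valid YAML: {exc}") from exc
    kb = parse_kb(doc)
    violations = validate_kb(kb)
    if violations:
        raise KBValidationError(violations)
    return _normalize_priors(kb)


# ---------------------------------------------------------------------------
# serialization

def kb_to_dict(kb: KnowledgeBase) -> dict:
    doc: Dict[str, object] = {
        "settings": {
            "theta": kb.settings.theta,
            "posterior_stop": kb.settings.posterior_stop,
            "voi_mode": kb.settings.voi_mode,
        },
        "diagnoses": [
            {"id": d.id, "name": d.name, "urgent": d.urgent,
             "prior": d.prior}
            for d in kb.diagnoses
        ],
        "questions": [],
        "advice": [],
    }
    for q in kb.questions:
        model: Dict[str, float] = {}
        if q.default is not None:
            model["default"] = q.default
        model.update(q.answer_model)
        qd: Dict[str, object] = {
            "id": q.id, "text": q.text, "answer_model": model,
        }
        if q.opening:
            qd["opening"] = True
        if q.prerequisites:
            qd["prerequisites"] = [[qid, a.value]
                                   for qid, a in q.prerequisites]
        if q.redundancy_triggers:
            qd["redundancy_triggers"] = [[qid, a.value]
                                         for qid, a in q.redundancy_triggers]
        doc["questions"].append(qd)
    for r in kb.advice:
        rd: Dict[str, object] = {"id": r.id, "message": r.message, "when": {}}
        if r.answers:
            rd["when"]["answers"] = [[qid, a.value] for qid, a in r.answers]
        if r.min_posterior is not None:
            rd["when"]["min_posterior"] = {r.min_posterior[0]:
                                           r.min_posterior[1]}
        doc["advice"].append(rd)
    return doc


def save_kb(kb: KnowledgeBase, path: PathLike) -> None:
    """Serialize a KB back to YAML (lossless round-trip with load)."""
    Path(path).write_text(
        yaml.safe_dump(kb_to_dict(kb), sort_keys=False,
                       allow_unicode=True)
    )


def default_kb_path() -> Path:
    """Path of the shipped red-eye KB inside the installed package."""
    return Path(resources.files("redeye").joinpath("data/red_eye_kb.yaml"))


def load_default_kb() -> KnowledgeBase:
    """Load the shipped red-eye knowledge base."""
    return load_kb(default_kb_path())
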