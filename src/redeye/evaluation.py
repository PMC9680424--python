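"""Study-style evaluation: concordance, top-k accuracy, urgency metrics.

Scoring conventions follow the validation study this evaluation layer
reproduces: a referrer who attempted no diagnosis is scored incorrect; a
gold-standard diagnosis outside the KB's ontology is bucketed as "other"
and is always algorithm-incorrect; blank questionnaire cells are read as
"I don't know"; a case is *classified* urgent iff the algorithm's top-1
diagnosis carries the urgent flag, and *truly* urgent iff its gold
diagnosis does ("other" counts as non-urgent).  Confidence intervals are
exact (Clopper–Pearson) binomial intervals from beta quantiles.

Percentages are rounded half-up to one decimal; CI bounds half-up to whole
percent, matching the usual print style of clinical accuracy tables.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from scipy.stats import beta as beta_dist

from .inference import AnswerValue
from .knowledge_base import OTHER, KnowledgeBase, PathLike
from .session import BatchResult

#: referrer_dx sentinel for "no diagnosis attempted" (scored incorrect)
NONE_ATTEMPTED = None

RESERVED_COLUMNS = ("case_id", "referrer_dx", "gold_dx")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3), unlike banker's ``round``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CaseRecord:
    """One patient: answer vector plus referrer and gold diagnoses."""

    case_id: str
    answers: Dict[str, AnswerValue]
    referrer_dx: Optional[str] = NONE_ATTEMPTED
    gold_dx: str = OTHER


@dataclass(frozen=True)
class Fraction:
    """A correct/total count that knows its percentage."""

    correct: int
    total: int

    @property
    def percentage(self) -> float:
        return round_half_up(100.0 * self.correct / self.total, 1)

    def __str__(self) -> str:
        return f"{self.correct}/{self.total}"


@dataclass(frozen=True)
class ClusterRow:
    """Per gold-diagnosis cluster concordance counts."""

    cluster: str
    n: int
    referrer: int
    top1: int
    top2: int
    top3: int


@dataclass(frozen=True)
class ConcordanceTable:
    rows: Tuple[ClusterRow, ...]

    def total(self, column: str) -> Fraction:
        return Fraction(sum(getattr(r, column) for r in self.rows),
                        sum(r.n for r in self.rows))

    def subset(self, clusters: Iterable[str]) -> "ConcordanceTable":
        wanted = set(clusters)
        return ConcordanceTable(tuple(r for r in self.rows
                                      if r.cluster in wanted))

    def complement(self, clusters: Iterable[str]) -> "ConcordanceTable":
        unwanted = set(clusters)
        return ConcordanceTable(tuple(r for r in self.rows
                                      if r.cluster not in unwanted))


@dataclass(frozen=True)
class RateWithCI:
    """A proportion with its exact 95% CI (bounds as whole percents)."""

    fraction: Fraction
    ci_lower_pct: int
    ci_upper_pct: int


@dataclass(frozen=True)
class UrgencyReport:
    """Urgency confusion matrix (top-1 classification) and derived rates."""

    true_urgent_classified_urgent: int      # TP
    true_urgent_classified_nonurgent: int   # FN
    true_nonurgent_classified_nonurgent: int  # TN
    true_nonurgent_classified_urgent: int   # FP
    sensitivity: Optional[RateWithCI]
    specificity: Optional[RateWithCI]


@dataclass(frozen=True)
class EvalReport:
    table: ConcordanceTable
    overall: Dict[str, Fraction]          # referrer/top1/top2/top3
    urgent_subset: Dict[str, Fraction]
    nonurgent_subset: Dict[str, Fraction]
    urgency: Optional[UrgencyReport]      # None for fixture-only evaluation


# ---------------------------------------------------------------------------
# case IO

def read_cases(path: PathLike,
               kb: Optional[KnowledgeBase] = None) -> List[CaseRecord]:
    """Read a case CSV: header of question ids plus case_id/referrer_dx/
    gold_dx; cells yes/no/unknown or blank (blank -> UNKNOWN).

    Diagnosis labels not in the KB map to the "other" bucket with a
    warning.  A missing gold_dx is a row error; an empty referrer_dx means
    no diagnosis was attempted.
    """
    known_dx = set(kb.diagnosis_index) if kb is not None else None
    cases = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        for required in ("case_id", "gold_dx"):
            if required not in fields:
                raise ValueError(f"case CSV lacks a {required!r} column")
        question_cols = [c for c in fields if c not in RESERVED_COLUMNS]
        for i, row in enumerate(reader, start=2):
            case_id = (row.get("case_id") or "").strip() or f"row{i}"
            gold = (row.get("gold_dx") or "").strip()
            if not gold:
                raise ValueError(f"case {case_id!r} (line {i}): missing "
                                 "gold_dx")
            gold = _map_dx(gold, known_dx, case_id, "gold_dx")
            ref_raw = (row.get("referrer_dx") or "").strip()
            referrer = (_map_dx(ref_raw, known_dx, case_id, "referrer_dx")
                        if ref_raw else NONE_ATTEMPTED)
            answers = {col: AnswerValue.parse(row.get(col))
                       for col in question_cols}
            cases.append(CaseRecord(case_id=case_id, answers=answers,
                                    referrer_dx=referrer, gold_dx=gold))
    return cases


def _map_dx(label: str, known: Optional[set], case_id: str,
            column: str) -> str:
    label = label.strip().lower()
    if label == OTHER or known is None or label in known:
        return label
    warnings.warn(
        f"case {case_id!r}: {column} {label!r} is not a KB diagnosis; "
        f"mapped to '{OTHER}'",
        stacklevel=2,
    )
    return OTHER


def write_cases(cases: Sequence[CaseRecord], path: PathLike,
                question_ids: Sequence[str]) -> None:
    """Write cases in the same CSV dialect ``read_cases`` consumes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", *question_ids,
                         "referrer_dx", "gold_dx"])
        for c in cases:
            row = [c.case_id]
            for qid in question_ids:
                ans = c.answers.get(qid, AnswerValue.UNKNOWN)
                row.append("" if ans is AnswerValue.UNKNOWN else ans.value)
            row.append(c.referrer_dx or "")
            row.append(c.gold_dx)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# accuracies

def _aligned(results: Sequence[BatchResult],
             cases: Sequence[CaseRecord]
             ) -> List[Tuple[BatchResult, CaseRecord]]:
    if len(results) != len(cases):
        raise ValueError("results and cases differ in length")
    pairs = []
    for res, case in zip(results, cases):
        if res.case_id != case.case_id:
            raise ValueError(
                f"result/case id mismatch: {res.case_id!r} vs "
                f"{case.case_id!r}"
            )
        pairs.append((res, case))
    return pairs


def _hit(result: BatchResult, case: CaseRecord, k: int) -> bool:
    if case.gold_dx == OTHER:
        return False
    return case.gold_dx in [e.diagnosis_id for e in result.differential[:k]]


def topk_accuracy(results: Sequence[BatchResult],
                  cases: Sequence[CaseRecord], k: int) -> Fraction:
    """Fraction of cases whose gold diagnosis is in the top-k ranks.

    Gold labels in the "other" bucket are always incorrect (the engine
    cannot name them).
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    pairs = _aligned(results, cases)
    correct = sum(_hit(res, case, k) for res, case in pairs)
    return Fraction(correct, len(pairs))


def referrer_accuracy(cases: Sequence[CaseRecord]) -> Fraction:
    """Concordance of the referrer diagnosis with gold; none-attempted and
    "other" gold labels score incorrect."""
    correct = sum(
        c.referrer_dx is not NONE_ATTEMPTED
        and c.gold_dx != OTHER
        and c.referrer_dx == c.gold_dx
        for c in cases
    )
    return Fraction(correct, len(cases))


def clopper_pearson(x: int, n: int, alpha: float = 0.05
                    ) -> Tuple[float, float]:
    """Exact two-sided binomial CI via beta quantiles.

    lower = Beta^{-1}(alpha/2; x, n-x+1) (0 when x = 0);
    upper = Beta^{-1}(1-alpha/2; x+1, n-x) (1 when x = n).
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, n >= 1; got x={x}, n={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(
        beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def rate_with_ci(x: int, n: int, alpha: float = 0.05) -> RateWithCI:
    lo, hi = clopper_pearson(x, n, alpha)
    return RateWithCI(
        fraction=Fraction(x, n),
        ci_lower_pct=int(round_half_up(lo * 100)),
        ci_upper_pct=int(round_half_up(hi * 100)),
    )


def urgency_metrics(results: Sequence[BatchResult],
                    cases: Sequence[CaseRecord],
                    kb: KnowledgeBase) -> UrgencyReport:
    """Urgency confusion matrix using the top-1 diagnosis as classifier.

    Sensitivity = classified-urgent among gold-urgent; specificity =
    classified-non-urgent among gold-non-urgent.  A zero denominator makes
    the corresponding rate undefined (None), never 0.
    """
    urgent = kb.urgent_ids
    tp = fn = tn = fp = 0
    for res, case in _aligned(results, cases):
        truly = case.gold_dx in urgent  # "other" is non-urgent
        classified = res.top1 in urgent
        if truly and classified:
            tp += 1
        elif truly:
            fn += 1
        elif classified:
            fp += 1
        else:
            tn += 1
    sens = rate_with_ci(tp, tp + fn) if tp + fn > 0 else None
    spec = rate_with_ci(tn, tn + fp) if tn + fp > 0 else None
    return UrgencyReport(
        true_urgent_classified_urgent=tp,
        true_urgent_classified_nonurgent=fn,
        true_nonurgent_classified_nonurgent=tn,
        true_nonurgent_classified_urgent=fp,
        sensitivity=sens,
        specificity=spec,
    )


# ---------------------------------------------------------------------------
# reports

def concordance_table(results: Sequence[BatchResult],
                      cases: Sequence[CaseRecord]) -> ConcordanceTable:
    """Cluster cases by gold diagnosis and count concordances."""
    clusters: Dict[str, Dict[str, int]] = {}
    for res, case in _aligned(results, cases):
        c = clusters.setdefault(
            case.gold_dx,
            {"n": 0, "referrer": 0, "top1": 0, "top2": 0, "top3": 0},
        )
        c["n"] += 1
        c["referrer"] += (case.referrer_dx is not NONE_ATTEMPTED
                          and case.gold_dx != OTHER
                          and case.referrer_dx == case.gold_dx)
        for k in (1, 2, 3):
            c[f"top{k}"] += _hit(res, case, k)
    rows = tuple(
        ClusterRow(cluster=name, **counts)
        for name, counts in clusters.items()
    )
    return ConcordanceTable(rows)


def counts_to_table(counts: Mapping[str, Mapping[str, int]]
                    ) -> ConcordanceTable:
    """Build a ConcordanceTable from per-cluster count mappings.

    This is the fixture entry point: published concordance counts can be
    evaluated directly, without the raw per-patient questionnaires.
    """
    rows = []
    for cluster, c in counts.items():
        row = ClusterRow(cluster=cluster, n=int(c["n"]),
                         referrer=int(c["referrer"]), top1=int(c["top1"]),
                         top2=int(c["top2"]), top3=int(c["top3"]))
        if not (row.top1 <= row.top2 <= row.top3 <= row.n
                and row.referrer <= row.n):
            raise ValueError(
                f"cluster {cluster!r}: counts must satisfy "
                "top1 <= top2 <= top3 <= n and referrer <= n"
            )
        rows.append(row)
    return ConcordanceTable(tuple(rows))


def read_counts_csv(path: PathLike) -> ConcordanceTable:
    """Read a concordance-count fixture CSV
    (columns cluster,n,referrer,top1,top2,top3)."""
    counts: Dict[str, Dict[str, int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            counts[row["cluster"]] = {
                k: int(row[k]) for k in ("n", "referrer",
                                         "top1", "top2", "top3")
            }
    return counts_to_table(counts)


def report_from_table(table: ConcordanceTable,
                      urgent_clusters: Iterable[str]) -> EvalReport:
    """Accuracy report from concordance counts alone (no raw cases)."""
    urgent = list(urgent_clusters)
    cols = ("referrer", "top1", "top2", "top3")
    return EvalReport(
        table=table,
        overall={c: table.total(c) for c in cols},
        urgent_subset={c: table.subset(urgent).total(c) for c in cols},
        nonurgent_subset={c: table.complement(urgent).total(c)
                          for c in cols},
        urgency=None,
    )


def evaluate_cases(kb: KnowledgeBase, cases: Sequence[CaseRecord],
                   results: Optional[Sequence[BatchResult]] = None
                   ) -> EvalReport:
    """Full evaluation of raw cases: run the engine, tabulate, score."""
    from .session import batch_diagnose

    if not cases:
        raise ValueError("no cases to evaluate")
    if results is None:
        results = batch_diagnose(kb, cases)
    table = concordance_table(results, cases)
    report = report_from_table(table, kb.urgent_ids)
    return EvalReport(
        table=report.table,
        overall=report.overall,
        urgent_subset=report.urgent_subset,
        nonurgent_subset=report.nonurgent_subset,
        urgency=urgency_metrics(results, cases, kb),
    )


def summarize(report: EvalReport,
              names: Optional[Mapping[str, str]] = None) -> str:
    """Render the concordance table plus headline rates as text."""
    if not report.table.rows:
        raise ValueError("empty report: no clusters to summarize")
    names = dict(names or {})
    lines = ["cluster | n | referrer | top1 | top2 | top3"]
    for r in report.table.rows:
        label = names.get(r.cluster, r.cluster)
        lines.append(
            f"{label} | {r.n} | {r.referrer}/{r.n} | {r.top1}/{r.n} | "
            f"{r.top2}/{r.n} | {r.top3}/{r.n}"
        )
    o = report.overall
    n_total = sum(r.n for r in report.table.rows)
    lines.append(
        f"Total | {n_total} | "
        f"{o['referrer']} | {o['top1']} | {o['top2']} | {o['top3']}"
    )
    lines.append(
        "overall%: referrer "
        f"{o['referrer'].percentage} | top1 {o['top1'].percentage} | "
        f"top2 {o['top2'].percentage} | top3 {o['top3'].percentage}"
    )
    if report.urgency is not None:
        u = report.urgency
        if u.sensitivity is not None:
            s = u.sensitivity
            lines.append(
                f"urgency sensitivity: {s.fraction.percentage}% "
                f"(95% CI: {s.ci_lower_pct}-{s.ci_upper_pct}%)"
            )
        if u.specificity is not None:
            s = u.specificity
            lines.append(
                f"urgency specificity: {s.fraction.percentage}% "
                f"(95% CI: {s.ci_lower_pct}-{s.ci_upper_pct}%)"
            )
    return "\n".join(lines)


def report_to_dict(report: EvalReport) -> dict:
    """Machine-readable JSON form of an EvalReport (lossless counts)."""
    out: dict = {
        "clusters": [
            {"cluster": r.cluster, "n": r.n, "referrer": r.referrer,
             "top1": r.top1, "top2": r.top2, "top3": r.top3}
            for r in report.table.rows
        ],
    }
    for key, block in (("overall", report.overall),
                       ("urgent_subset", report.urgent_subset),
                       ("nonurgent_subset", report.nonurgent_subset)):
        out[key] = {
            c: {"correct": f.correct, "total": f.total,
                "percentage": f.percentage}
            for c, f in block.items()
        }
    if report.urgency is not None:
        u = report.urgency
        out["urgency"] = {
            "confusion": {
                "tp": u.true_urgent_classified_urgent,
                "fn": u.true_urgent_classified_nonurgent,
                "tn": u.true_nonurgent_classified_nonurgent,
                "fp": u.true_nonurgent_classified_urgent,
            },
        }
        for label, rate in (("sensitivity", u.sensitivity),
                            ("specificity", u.specificity)):
            out["urgency"][label] = None if rate is None else {
                "correct": rate.fraction.correct,
                "total": rate.fraction.total,
                "percentage": rate.fraction.percentage,
                "ci_lower_pct": rate.ci_lower_pct,
                "ci_upper_pct": rate.ci_upper_pct,
            }
    return out


def report_to_json(report: EvalReport, path: Optional[PathLike] = None
                   ) -> str:
    text = json.dumps(report_to_dict(report), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# shipped study fixture

def load_study_counts() -> ConcordanceTable:
    """The published per-cluster concordance counts of the 57-patient
    red-eye validation study (the shipped fixture the evaluation layer is
    checked against)."""
    from importlib import resources

    path = resources.files("redeye").joinpath("data/study_concordance.csv")
    return read_counts_csv(str(path))


#: gold-diagnosis clusters counted as urgent in the study fixture
STUDY_URGENT_CLUSTERS = ("corneal_ulcer", "acute_acg", "iritis",
                         "endophthalmitis")
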