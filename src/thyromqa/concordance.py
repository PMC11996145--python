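"""Pairwise concordance evaluation between answer sources.

For each question, the concordance rate of a pair of answer sources
(reviewer, backend, or ground truth) is the number of concordant answers
divided by the number of answers, in percent. Rates are averaged across
questions (mean with SD) and also pooled over raw counts; the two
framings differ slightly whenever per-question totals are unequal weights
of disagreement, so both are always reported. Pairings are compared with
two-sided t tests over the per-question rate vectors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import IncompleteGridError
from .models import (
    NOT_STATED,
    SENTINELS,
    AnswerSet,
    AnswerType,
    CanonicalAnswer,
    ConcordanceTable,
    Question,
    QuestionConcordance,
)


@dataclass(frozen=True)
class ConcordancePolicy:
    """Adjudication policy for typed answer comparison.

    ``equate_not_stated_false`` treats a not-stated answer to a boolean
    absence-type question ("Is vascular invasion present?") as equivalent
    to "no": pathology reports routinely omit pertinent negatives, and a
    reviewer reading silence as absence is judging the same fact.
    ``size_decimals`` rounds sizes before comparison (0.1 cm).
    """

    equate_not_stated_false: bool = True
    size_decimals: int = 1


DEFAULT_POLICY = ConcordancePolicy()


def _t_token(value: str) -> str:
    v = value.strip().upper()
    return v[1:] if v.startswith("PT") else v


def is_concordant(a: CanonicalAnswer, b: CanonicalAnswer, question: Question,
                  policy: ConcordancePolicy = DEFAULT_POLICY) -> bool:
    """Type-aware equality of two canonical answers to the same cell."""
    if (a.report_id, a.question_id) != (b.report_id, b.question_id):
        raise ValueError(
            f"answers address different cells: {(a.report_id, a.question_id)} "
            f"vs {(b.report_id, b.question_id)}")
    va, vb = a.value, b.value

    if question.answer_type is AnswerType.boolean and policy.equate_not_stated_false:
        va = False if va == NOT_STATED else va
        vb = False if vb == NOT_STATED else vb

    if va in SENTINELS or vb in SENTINELS:
        return va == vb
    if question.answer_type is AnswerType.size_cm:
        return round(float(va), policy.size_decimals) == round(float(vb), policy.size_decimals)
    if question.answer_type is AnswerType.boolean:
        return bool(va) == bool(vb)
    if question.answer_type is AnswerType.count:
        return int(va) == int(vb)
    if question.answer_type is AnswerType.tnm_stage:
        return _t_token(str(va)) == _t_token(str(vb))
    return str(va) == str(vb)


def _check_grid(answer_set: AnswerSet, report_ids: Sequence[str],
                questions: Sequence[Question]) -> None:
    missing = [(r, q.question_id) for r in report_ids for q in questions
               if (r, q.question_id) not in answer_set.answers]
    if missing:
        raise IncompleteGridError(
            f"answer set {answer_set.source_id} is missing {len(missing)} cells "
            f"(first: {missing[:5]})", missing=missing)


def summarize(rates: Sequence[float], sample: bool = True) -> Tuple[float, float]:
    """Mean and SD of per-question rates; sample (n-1) convention by
    default, population (n) convention with ``sample=False``. A single
    rate has SD 0 under the population convention."""
    if len(rates) == 0:
        raise ValueError("rates must be nonempty")
    arr = np.asarray(rates, dtype=float)
    mean = float(arr.mean())
    if len(arr) == 1:
        sd = float("nan") if sample else 0.0
    else:
        sd = float(arr.std(ddof=1 if sample else 0))
    return mean, sd


def per_question_rates(set_a: AnswerSet, set_b: AnswerSet,
                       questions: Sequence[Question],
                       policy: ConcordancePolicy = DEFAULT_POLICY) -> ConcordanceTable:
    """Per-question pairwise concordance with mean/SD and pooled summaries.

    Both sets must be complete over the same report x question grid.
    """
    reports_a = set_a.report_ids()
    reports_b = set_b.report_ids()
    if set(reports_a) != set(reports_b):
        raise IncompleteGridError(
            f"answer sets cover different reports: {set_a.source_id} has "
            f"{len(reports_a)}, {set_b.source_id} has {len(reports_b)}")
    _check_grid(set_a, reports_a, questions)
    _check_grid(set_b, reports_a, questions)

    pair = f"{set_a.source_id}-{set_b.source_id}"
    entries = []
    for question in questions:
        concordant = sum(
            is_concordant(set_a.get(r, question.question_id),
                          set_b.get(r, question.question_id), question, policy)
            for r in reports_a)
        entries.append(QuestionConcordance(question_id=question.question_id, pair=pair,
                                           concordant=concordant, total=len(reports_a)))
    rates = [e.rate for e in entries]
    mean, sd = summarize(rates, sample=True)
    _, sd_pop = summarize(rates, sample=False)
    return ConcordanceTable(
        pair=pair,
        entries=entries,
        mean_rate=mean,
        sd_rate=sd,
        sd_rate_population=sd_pop,
        pooled_concordant=sum(e.concordant for e in entries),
        pooled_total=sum(e.total for e in entries),
    )


def compare_pairings(rates_a: Sequence[float], rates_b: Sequence[float],
                     mode: str = "paired") -> Tuple[float, float, str]:
    """Two-sided t test between two question-aligned rate vectors.

    ``paired`` (default) treats the shared questions as matched units;
    ``welch`` runs an unpaired unequal-variance test. Identical vectors
    give (0.0, 1.0) rather than the indeterminate 0/0 statistic.
    """
    if len(rates_a) != len(rates_b):
        raise ValueError(f"rate vectors differ in length: {len(rates_a)} vs {len(rates_b)}")
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if mode == "paired":
        if np.allclose(a - b, (a - b)[0]) and math.isclose((a - b).std(), 0.0):
            # zero-variance differences: no evidence against equality unless
            # the constant shift itself is nonzero, which t cannot assess
            return (0.0, 1.0, mode) if np.allclose(a, b) else (float("inf"), 0.0, mode)
        t_stat, p = stats.ttest_rel(a, b)
    elif mode == "welch":
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'paired' or 'welch'")
    return float(t_stat), float(p), mode
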