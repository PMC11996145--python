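"""End-to-end MQA runs: retrieval, backend answering, normalization, and
truth-derived answer sets for evaluation."""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml
from pydantic import BaseModel, Field

from .backends import Backend, answer, normalize
from .models import (
    NOT_APPLICABLE,
    AnswerSet,
    CanonicalAnswer,
    Question,
    RawAnswer,
    ReportTruth,
    RetrievalContext,
    SyntheticReport,
)
from .retrieval import (
    DEFAULT_EMBED_DIMENSION,
    DEFAULT_SEGMENT_LENGTH,
    DEFAULT_TOKEN_LIMIT,
    DEFAULT_TOP_K,
    Embedder,
    HashedTfEmbedder,
    select_context,
)


class PipelineConfig(BaseModel):
    """Retrieval settings for a run (YAML-loadable)."""

    segment_length: int = Field(default=DEFAULT_SEGMENT_LENGTH, ge=1)
    top_k: int = Field(default=DEFAULT_TOP_K, ge=1)
    token_limit: int = Field(default=DEFAULT_TOKEN_LIMIT, ge=1)
    embedder: str = "hashed-tf"
    embed_dimension: int = Field(default=DEFAULT_EMBED_DIMENSION, ge=1)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def make_embedder(self) -> Embedder:
        if self.embedder != "hashed-tf":
            raise ValueError(f"unknown embedder {self.embedder!r}")
        return HashedTfEmbedder(dimension=self.embed_dimension)


@dataclass
class RunResult:
    """All artifacts of one MQA run over a corpus."""

    answers: AnswerSet
    raw: List[RawAnswer] = field(default_factory=list)
    contexts: List[RetrievalContext] = field(default_factory=list)


def truth_answer(truth: ReportTruth, question: Question) -> CanonicalAnswer:
    """The ground-truth canonical answer for one question.

    Conditional questions resolve to ``not_applicable`` when their trigger
    is false (no nodes examined; no second cancer).
    """
    qid = question.question_id
    mapping = {
        "q1": lambda t: t.tumor_size_cm,
        "q2": lambda t: t.gross_ete,
        "q3": lambda t: t.location.value,
        "q4": lambda t: t.nodes_examined > 0,
        "q5": lambda t: t.nodes_positive if t.nodes_examined > 0 else NOT_APPLICABLE,
        "q6": lambda t: t.t_category.value,
        "q7": lambda t: t.vascular_invasion,
        "q8": lambda t: t.lymphatic_invasion,
        "q9": lambda t: t.histology.value,
        "q10": lambda t: t.aggressive_variant.value,
        "q11": lambda t: t.second_cancer,
        "q12": lambda t: (t.second_cancer_histology.value if t.second_cancer
                          else NOT_APPLICABLE),
    }
    if qid not in mapping:
        raise ValueError(f"no ground-truth mapping for question {qid}")
    return CanonicalAnswer(report_id=truth.report_id, question_id=qid,
                           value=mapping[qid](truth))


def truth_answer_set(truths: Sequence[ReportTruth],
                     questions: Sequence[Question]) -> AnswerSet:
    """Ground-truth answers over the full report x question grid."""
    answer_set = AnswerSet(source_id="TRUTH")
    for truth in truths:
        for question in questions:
            answer_set.add(truth_answer(truth, question))
    return answer_set


def run_mqa(
    reports: Sequence[Tuple[str, str]],
    questions: Sequence[Question],
    backend: Backend,
    config: Optional[PipelineConfig] = None,
    use_retrieval: bool = True,
) -> RunResult:
    """Answer every question for every report.

    ``reports`` are (report_id, text) pairs. With ``use_retrieval`` the
    context is built by token-budget check + segmentation + top-k cosine
    retrieval; otherwise the full text is always used.
    """
    config = config or PipelineConfig()
    embedder = config.make_embedder()
    result = RunResult(answers=AnswerSet(source_id=backend.backend_id))
    for report_id, text in reports:
        for question in questions:
            if use_retrieval:
                ctx = select_context(
                    question.text, text,
                    report_id=report_id, question_id=question.question_id,
                    k=config.top_k, embedder=embedder,
                    token_limit=config.token_limit,
                    segment_length=config.segment_length)
            else:
                ctx = RetrievalContext(report_id=report_id,
                                       question_id=question.question_id,
                                       context_text=text, used_full_text=True)
            t0 = time.perf_counter()
            raw = answer(ctx.context_text, question, backend)
            raw = raw.model_copy(update={"report_id": report_id,
                                         "elapsed_s": time.perf_counter() - t0})
            result.raw.append(raw)
            result.contexts.append(ctx)
            result.answers.add(normalize(raw, question))
    return result


def retrieval_hit_rate(reports: Sequence[SyntheticReport],
                       contexts: Sequence[RetrievalContext]) -> float:
    """Fraction of (report, question) cells whose answer-bearing sentence
    is fully contained in the assembled context.

    A full-text context always hits; a retrieved context hits when the
    evidence sentence's character span is covered by the union of the
    selected segment spans (adjacent selected segments are spliced back
    seamlessly at assembly, so span coverage equals textual presence).
    """
    by_id: Dict[str, SyntheticReport] = {r.report_id: r for r in reports}
    hits = 0
    total = 0
    for ctx in contexts:
        report = by_id[ctx.report_id]
        evidence = report.evidence.get(ctx.question_id)
        if evidence is None:
            continue
        total += 1
        if ctx.used_full_text:
            hits += 1
            continue
        start = report.text.find(evidence)
        if start < 0:
            continue
        end = start + len(evidence)
        covered = _merge_spans(ctx.segment_spans)
        if any(a <= start and end <= b for a, b in covered):
            hits += 1
    if total == 0:
        raise ValueError("no evidence-bearing cells to score")
    return hits / total


def _merge_spans(spans: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged
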