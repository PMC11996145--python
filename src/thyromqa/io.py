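"""JSONL readers and writers for corpora, ground truth and answers.

Corpus text and ground truth are written to separate files (keyed by
report id), simulating the blinded setting in which the extraction
pipeline never sees labels.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

from .models import AnswerSet, CanonicalAnswer, RawAnswer, ReportTruth, SyntheticReport

PathLike = Union[str, Path]


def _write_jsonl(records: Iterable[dict], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def _read_jsonl(path: PathLike) -> List[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_corpus(reports: Iterable[SyntheticReport], path: PathLike) -> None:
    """One object per report: {report_id, text, category}."""
    _write_jsonl(({"report_id": r.report_id, "text": r.text,
                   "category": r.truth.category.value} for r in reports), path)


def read_corpus(path: PathLike) -> List[dict]:
    return _read_jsonl(path)


def write_truth(reports: Iterable[SyntheticReport], path: PathLike) -> None:
    """Ground truth keyed by report_id, one record per report."""
    _write_jsonl((r.truth.model_dump(mode="json") for r in reports), path)


def read_truth(path: PathLike) -> List[ReportTruth]:
    return [ReportTruth.model_validate(rec) for rec in _read_jsonl(path)]


def write_answers(raw: Iterable[RawAnswer], canonical: AnswerSet, path: PathLike) -> None:
    """One record per cell: raw backend text plus its canonical value."""
    records = []
    for r in raw:
        canon = canonical.get(r.report_id, r.question_id)
        records.append({
            "report_id": r.report_id,
            "question_id": r.question_id,
            "backend_id": r.backend_id,
            "raw_text": r.text,
            "canonical_value": canon.value,
            "elapsed_s": r.elapsed_s,
        })
    _write_jsonl(records, path)


def read_answers(path: PathLike, source_id: str) -> AnswerSet:
    answer_set = AnswerSet(source_id=source_id)
    for rec in _read_jsonl(path):
        answer_set.add(CanonicalAnswer(report_id=rec["report_id"],
                                       question_id=rec["question_id"],
                                       value=rec["canonical_value"]))
    return answer_set
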