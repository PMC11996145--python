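"""Core domain records for the thyroid pathology MQA pipeline.

The records mirror the artifacts that flow through the pipeline: the
ground truth behind a synthetic report, the report itself, retrieval
segments and assembled contexts, questions, raw backend answers and
their typed canonical forms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Dict, List, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

#: Sentinel canonical values. ``NOT_STATED`` means the source text does not
#: answer the question; ``NOT_APPLICABLE`` means the question's trigger
#: condition is false (e.g. "how many positive nodes" when none were examined).
NOT_STATED = "not_stated"
NOT_APPLICABLE = "not_applicable"

SENTINELS = frozenset({NOT_STATED, NOT_APPLICABLE})


class Category(str, Enum):
    """Report category; only ``thyroid_malignant`` reports enter analysis."""

    thyroid_malignant = "thyroid_malignant"
    other_organ = "other_organ"
    benign = "benign"
    cytopathology = "cytopathology"
    outside_review = "outside_review"


class Location(str, Enum):
    right_lobe = "right_lobe"
    left_lobe = "left_lobe"
    isthmus = "isthmus"


class Histology(str, Enum):
    papillary = "papillary"
    follicular = "follicular"
    medullary = "medullary"


class Variant(str, Enum):
    """Aggressive histologic variants of papillary carcinoma."""

    none = "none"
    tall_cell = "tall_cell"
    hobnail = "hobnail"
    columnar = "columnar"


class TCategory(str, Enum):
    T1a = "T1a"
    T1b = "T1b"
    T2 = "T2"
    T3a = "T3a"
    T3b = "T3b"


class NCategory(str, Enum):
    N0 = "N0"
    N1 = "N1"


class RiskTier(str, Enum):
    low = "low"
    intermediate = "intermediate"
    high = "high"


class Style(str, Enum):
    """Narrative style of a rendered report."""

    prose = "prose"
    synoptic = "synoptic"
    mixed = "mixed"


class AnswerType(str, Enum):
    size_cm = "size_cm"
    boolean = "boolean"
    location = "location"
    count = "count"
    tnm_stage = "tnm_stage"
    histology = "histology"
    variant = "variant"


class QuestionGroup(str, Enum):
    T = "T"
    N = "N"
    TNM = "TNM"
    recurrence_risk = "recurrence_risk"


class ReportTruth(BaseModel):
    """Canonical ground-truth fields for one surgical pathology report.

    Tumor fields are populated only for ``thyroid_malignant`` reports;
    excluded categories (other organ, benign, cytopathology, outside
    review) carry boilerplate text and no tumor facts.
    """

    report_id: str
    category: Category
    tumor_size_cm: Optional[float] = Field(default=None, gt=0)
    location: Optional[Location] = None
    gross_ete: Optional[bool] = None
    nodes_examined: Optional[int] = Field(default=None, ge=0)
    nodes_positive: Optional[int] = Field(default=None, ge=0)
    vascular_invasion: Optional[bool] = None
    lymphatic_invasion: Optional[bool] = None
    histology: Optional[Histology] = None
    aggressive_variant: Optional[Variant] = None
    second_cancer: Optional[bool] = None
    second_cancer_histology: Optional[Histology] = None
    t_category: Optional[TCategory] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "ReportTruth":
        tumor_fields = (
            self.tumor_size_cm, self.location, self.gross_ete,
            self.nodes_examined, self.nodes_positive, self.vascular_invasion,
            self.lymphatic_invasion, self.histology, self.aggressive_variant,
            self.second_cancer, self.t_category,
        )
        if self.category is Category.thyroid_malignant:
            if any(f is None for f in tumor_fields):
                raise ValueError("thyroid_malignant reports require all tumor fields")
            if self.nodes_positive > self.nodes_examined:
                raise ValueError("nodes_positive exceeds nodes_examined")
            if self.aggressive_variant is not Variant.none and self.histology is not Histology.papillary:
                raise ValueError("aggressive variants occur only in papillary carcinoma")
            if self.second_cancer != (self.second_cancer_histology is not None):
                raise ValueError("second_cancer_histology must be set iff second_cancer")
            from .staging import derive_t_category

            expected = derive_t_category(self.tumor_size_cm, self.gross_ete)
            if self.t_category is not expected:
                raise ValueError(
                    f"t_category {self.t_category} inconsistent with size/ETE (expected {expected})"
                )
        else:
            if any(f is not None for f in tumor_fields) or self.second_cancer_histology is not None:
                raise ValueError("only thyroid_malignant reports carry tumor fields")
        return self


class SyntheticReport(BaseModel):
    """A rendered report narrative together with its generating truth.

    ``evidence`` maps each default question id to the sentence in ``text``
    that states the answer (present only for thyroid_malignant reports);
    ``distractor_dims_cm`` lists specimen dimensions that are NOT the
    tumor size (whole-lobe measurements etc.).
    """

    truth: ReportTruth
    text: str
    style: Style
    distractor_dims_cm: List[float] = Field(default_factory=list)
    evidence: Dict[str, str] = Field(default_factory=dict)

    @property
    def report_id(self) -> str:
        return self.truth.report_id


class Question(BaseModel):
    """One item of the MQA schema.

    ``depends_on`` marks conditional items: ``(question_id, value)`` means
    the question applies only when that other question's answer equals
    ``value``; otherwise its canonical answer is ``not_applicable``.
    """

    question_id: str
    text: str
    answer_type: AnswerType
    group: QuestionGroup
    depends_on: Optional[Tuple[str, bool]] = None


class RawAnswer(BaseModel):
    """Free-text backend output for one (report, question) cell."""

    report_id: str
    question_id: str
    text: str = Field(min_length=1)
    backend_id: str
    elapsed_s: float = Field(default=0.0, ge=0)


class CanonicalAnswer(BaseModel):
    """Typed, normalized answer used for concordance.

    ``value`` holds a float (cm) for sizes, bool, int, an enum value string
    (location/histology/variant), a TNM T token such as ``"T3a"``, or one of
    the sentinels ``not_stated`` / ``not_applicable``.
    """

    report_id: str
    question_id: str
    value: Any


@dataclass(frozen=True)
class Segment:
    """A fixed-length character chunk of a report (0-based, half-open)."""

    report_id: str
    index: int
    start: int
    end: int
    text: str

    def __post_init__(self):
        if self.end - self.start != len(self.text):
            raise ValueError("segment offsets inconsistent with text length")


@dataclass
class RetrievalContext:
    """The assembled context for one (report, question) pair.

    ``selected`` holds up to k segment indices in document order with
    ``scores`` aligned 1:1; ``score_order`` records the same indices ranked
    by descending similarity. ``used_full_text`` is set when the report fits
    the token budget and no retrieval was needed.
    """

    report_id: str
    question_id: str
    selected: List[int] = field(default_factory=list)
    scores: List[float] = field(default_factory=list)
    score_order: List[int] = field(default_factory=list)
    context_text: str = ""
    used_full_text: bool = False
    segment_spans: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class AnswerSet:
    """All canonical answers of one source (reviewer, backend, or truth)
    over a report x question grid, keyed by (report_id, question_id)."""

    source_id: str
    answers: Dict[Tuple[str, str], CanonicalAnswer] = field(default_factory=dict)

    def add(self, answer: CanonicalAnswer) -> None:
        self.answers[(answer.report_id, answer.question_id)] = answer

    def get(self, report_id: str, question_id: str) -> CanonicalAnswer:
        return self.answers[(report_id, question_id)]

    def report_ids(self) -> List[str]:
        return sorted({r for r, _ in self.answers})


@dataclass(frozen=True)
class QuestionConcordance:
    """Concordance of one question under one pairwise comparison."""

    question_id: str
    pair: str
    concordant: int
    total: int

    @property
    def rate(self) -> float:
        """Concordance rate in percent."""
        return 100.0 * self.concordant / self.total if self.total else float("nan")


@dataclass
class ConcordanceTable:
    """Per-question pairwise concordance with pooled and averaged summaries.

    ``mean_rate``/``sd_rate`` average the per-question percentage rates
    (sample SD, n-1); ``sd_rate_population`` is the n-convention SD.
    ``pooled_*`` sum raw counts over questions.
    """

    pair: str
    entries: List[QuestionConcordance]
    mean_rate: float
    sd_rate: float
    sd_rate_population: float
    pooled_concordant: int
    pooled_total: int

    @property
    def pooled_rate(self) -> float:
        return 100.0 * self.pooled_concordant / self.pooled_total if self.pooled_total else float("nan")
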