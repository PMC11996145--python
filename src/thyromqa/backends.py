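"""Answer backends and answer normalization.

A backend maps (context text, question) to one free-text answer. The
deterministic rule-based reference backend stands in for a generative
model: per-question pattern logic with negation handling, designed around
the known failure modes of pathology narratives — specimen dimensions that
are not the tumor size, node sections labeled by neck level rather than
"cervical", and conditional questions whose trigger is absent from the
retrieved context.

``normalize`` turns free text into typed canonical values (cm floats,
booleans, enum strings, TNM T tokens, counts) so concordance judgment is
explicit and testable rather than an eyeballed string match.
"""
from __future__ import annotations

import logging
import re
from typing import List, Optional, Protocol, Tuple

from .models import (
    NOT_APPLICABLE,
    NOT_STATED,
    AnswerType,
    CanonicalAnswer,
    Histology,
    Location,
    Question,
    RawAnswer,
    Variant,
)

log = logging.getLogger(__name__)

NOT_STATED_TEXT = "The report does not state this."

_WORD_NUMBERS = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
    "twenty": 20,
}
_NUM = r"(?:\d+|" + "|".join(_WORD_NUMBERS) + r")"

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+|\n+")
_DIM_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(cm|mm|centimeters?|millimeters?)\b")
_MULTI_DIM_RE = re.compile(r"\d+(?:\.\d+)?\s*x\s*\d")
_TNM_RE = re.compile(r"\bp?t\s?([0-4][ab]?)\b")
_NODE_COUNT_RE = re.compile(rf"\b({_NUM})\s+of\s+(?:the\s+)?({_NUM})\b")

_TUMOR_TOKENS = ("tumor", "carcinoma", "cancer", "lesion", "neoplasm")
_NEGATION_TOKENS = ("not ", "no ", "without", "absent", "negative for", "free of")
_LOCATION_KEYWORDS = ("located", "location", "site", "arises", "arising", "centered", "involv")


def split_sentences(text: str) -> List[str]:
    """Split on sentence punctuation and newlines; synoptic field lines
    come out as individual sentences."""
    return [s.strip() for s in _SENTENCE_SPLIT.split(text) if s and s.strip()]


def is_negated(sentence: str) -> bool:
    low = " " + sentence.lower()
    return any(tok in low for tok in _NEGATION_TOKENS)


def _has_tumor_token(sentence: str) -> bool:
    low = sentence.lower()
    return any(tok in low for tok in _TUMOR_TOKENS)


def parse_number(token: str) -> int:
    token = token.lower()
    return int(token) if token.isdigit() else _WORD_NUMBERS[token]


class Backend(Protocol):
    """The backend contract: one free-text answer per (context, question)."""

    backend_id: str

    def generate(self, context_text: str, question: Question) -> str: ...


def answer(context_text: str, question: Question, backend: "Backend") -> RawAnswer:
    """Run one backend call; failures degrade to a not-stated answer."""
    if not context_text:
        raise ValueError("context_text must be nonempty")
    try:
        text = backend.generate(context_text, question)
    except Exception:
        log.exception("backend %s failed on %s; recording not stated",
                      backend.backend_id, question.question_id)
        text = NOT_STATED_TEXT
    return RawAnswer(report_id="", question_id=question.question_id,
                     text=text or NOT_STATED_TEXT, backend_id=backend.backend_id)


# ---------------------------------------------------------------------------
# Reference rule-based backend


def _question_slot(question: Question) -> str:
    """Map a question to an extraction slot by its phrasing.

    Keyed on wording rather than id so custom question sets that rephrase
    an item still dispatch to sensible pattern logic.
    """
    low = question.text.lower()
    if "second" in low and "histology" in low:
        return "second_histology"
    if "second" in low:
        return "second_cancer"
    if "size" in low:
        return "size"
    if "extend beyond" in low or "extrathyroidal" in low or "capsule" in low:
        return "ete"
    if "locat" in low or "where" in low:
        return "location"
    if "how many" in low and "lymph node" in low:
        return "nodes_positive"
    if "lymph node" in low:
        return "nodes_present"
    if "tnm" in low or "stage" in low:
        return "tnm"
    if "vascular invasion" in low:
        return "vascular"
    if "lymphatic invasion" in low:
        return "lymphatic"
    if "variant" in low:
        return "variant"
    if "histology" in low:
        return "histology"
    raise ValueError(f"no extraction slot matches question: {question.text!r}")


def _find_node_counts(sentences: List[str]) -> Tuple[Optional[int], Optional[int], bool]:
    """Return (positive, examined, explicit_none) from node sentences.

    ``explicit_none`` is set when the context states that no lymph nodes
    were identified.
    """
    for sent in sentences:
        low = sent.lower()
        if "lymph node" not in low:
            continue
        m = _NODE_COUNT_RE.search(low)
        if m:
            return parse_number(m.group(1)), parse_number(m.group(2)), False
        if is_negated(sent):
            return None, None, True
    return None, None, False


def _extract_size(sentences: List[str]) -> Optional[str]:
    """Tumor size with unit, rejecting specimen-dimension distractors.

    Only sentences that mention the tumor itself qualify; three-dimensional
    specimen measurements (e.g. a whole lobe, "4.2 x 3.0 x 2.1 cm") never
    yield a size even when no tumor dimension exists.
    """
    for sent in sentences:
        if not _has_tumor_token(sent):
            continue
        if _MULTI_DIM_RE.search(sent):
            continue
        m = _DIM_RE.search(sent.lower())
        if m:
            unit = "mm" if m.group(2).startswith("m") else "cm"
            return f"The size of the primary tumor was {m.group(1)} {unit}."
    return None


def _extract_boolean_topic(sentences: List[str], topic_patterns: Tuple[str, ...],
                           yes_text: str, no_text: str) -> Optional[str]:
    for sent in sentences:
        low = sent.lower()
        if any(pat in low for pat in topic_patterns):
            return no_text if is_negated(sent) else yes_text
    return None


def reference_extract(context_text: str, question: Question) -> str:
    """Deterministic per-question pattern extraction over the context."""
    sentences = split_sentences(context_text)
    slot = _question_slot(question)

    if slot == "size":
        return _extract_size(sentences) or NOT_STATED_TEXT

    if slot == "ete":
        out = _extract_boolean_topic(
            sentences,
            ("extrathyroidal extension", "beyond the capsule", "extends beyond"),
            "Yes, the tumor extends beyond the capsule of the thyroid.",
            "No, the tumor does not extend beyond the capsule of the thyroid.")
        return out or NOT_STATED_TEXT

    if slot == "location":
        for sent in sentences:
            low = sent.lower()
            if not _has_tumor_token(sent):
                continue
            if not any(k in low for k in _LOCATION_KEYWORDS):
                continue
            if "right" in low:
                return "The primary cancer is located in the right thyroid lobe."
            if "left" in low:
                return "The primary cancer is located in the left thyroid lobe."
            if "isthmus" in low:
                return "The primary cancer is located in the isthmus."
        return NOT_STATED_TEXT

    if slot in ("nodes_present", "nodes_positive"):
        positive, examined, explicit_none = _find_node_counts(sentences)
        if slot == "nodes_present":
            if examined is not None:
                return ("Yes, cervical lymph nodes were present."
                        if examined > 0 else "No, cervical lymph nodes were not present.")
            if explicit_none:
                return "No, cervical lymph nodes were not present."
            return NOT_STATED_TEXT
        if positive is not None:
            return f"{positive} lymph nodes were positive for malignancy."
        if explicit_none:
            return "Not applicable; no cervical lymph nodes were present."
        return NOT_STATED_TEXT

    if slot == "tnm":
        for sent in sentences:
            m = _TNM_RE.search(sent.lower())
            if m:
                token = "pT" + m.group(1).upper().replace("A", "a").replace("B", "b")
                return f"The final pathology TNM stage of the thyroid cancer is {token}."
        return NOT_STATED_TEXT

    if slot == "vascular":
        out = _extract_boolean_topic(
            sentences, ("vascular invasion",),
            "Yes, vascular invasion is present.",
            "No, vascular invasion is not present.")
        return out or NOT_STATED_TEXT

    if slot == "lymphatic":
        out = _extract_boolean_topic(
            sentences, ("lymphatic invasion",),
            "Yes, lymphatic invasion is present.",
            "No, lymphatic invasion is not present.")
        return out or NOT_STATED_TEXT

    if slot == "histology":
        for sent in sentences:
            low = sent.lower()
            if "second" in low or "incidental" in low:
                continue
            if not any(t in low for t in ("carcinoma", "cancer", "histologic type", "histology")):
                continue
            for name in ("papillary", "follicular", "medullary"):
                if name in low:
                    return f"The histology of the primary thyroid cancer was {name} carcinoma."
        return NOT_STATED_TEXT

    if slot == "variant":
        for sent in sentences:
            low = sent.lower()
            hit = next((v for v in ("tall cell", "hobnail", "columnar") if v in low), None)
            if hit is None:
                continue
            if is_negated(sent):
                return ("No, a variant of thyroid cancer such as tall cell, hobnail "
                        "variant, or columnar cell variant was not present.")
            return f"Yes, a {hit} variant of thyroid cancer was present."
        return NOT_STATED_TEXT

    if slot in ("second_cancer", "second_histology"):
        second_sentences = [s for s in sentences
                            if "second" in s.lower()
                            and any(t in s.lower() for t in ("cancer", "carcinoma", "focus", "malignan"))]
        if not second_sentences:
            return NOT_STATED_TEXT
        negated = all(is_negated(s) for s in second_sentences)
        if slot == "second_cancer":
            return ("No, there was no second thyroid cancer present."
                    if negated else "Yes, there was a second thyroid cancer present.")
        if negated:
            return "Not applicable; there was no second thyroid cancer present."
        for sent in second_sentences:
            low = sent.lower()
            for name in ("papillary", "follicular", "medullary"):
                if name in low:
                    return f"The histology of the second thyroid cancer was {name} carcinoma."
        return NOT_STATED_TEXT

    raise AssertionError(f"unhandled slot {slot}")  # pragma: no cover


class ReferenceBackend:
    """The built-in deterministic rule-based backend."""

    backend_id = "reference"

    def generate(self, context_text: str, question: Question) -> str:
        return reference_extract(context_text, question)


# ---------------------------------------------------------------------------
# Normalization to canonical typed values


def _normalize_boolean(low: str):
    stripped = low.lstrip(" \"'")
    if stripped.startswith("yes"):
        return True
    if stripped.startswith("no"):
        return False
    if any(tok in " " + low for tok in _NEGATION_TOKENS):
        return False
    if any(tok in low for tok in ("present", "identified", "positive", "seen")):
        return True
    return NOT_STATED


def normalize(raw: RawAnswer, question: Question) -> CanonicalAnswer:
    """Parse a free-text answer into its typed canonical value.

    Total: anything unparseable becomes ``not_stated``. Unit-aware for
    sizes (mm are converted to cm); negation-aware for booleans; TNM
    tokens reduce to the uppercase T token (``pT3a`` -> ``T3a``).
    """
    low = raw.text.lower()
    value = None

    if "not applicable" in low:
        value = NOT_APPLICABLE
    elif any(p in low for p in ("not stated", "does not state", "not specified",
                                "cannot be determined", "no information")):
        value = NOT_STATED
    elif question.answer_type is AnswerType.size_cm:
        m = _DIM_RE.search(low)
        if m:
            size = float(m.group(1))
            if m.group(2).startswith("m"):
                size /= 10.0
            value = size
        else:
            value = NOT_STATED
    elif question.answer_type is AnswerType.boolean:
        value = _normalize_boolean(low)
    elif question.answer_type is AnswerType.location:
        if "isthmus" in low and "right" not in low and "left" not in low:
            value = Location.isthmus.value
        elif "right" in low:
            value = Location.right_lobe.value
        elif "left" in low:
            value = Location.left_lobe.value
        else:
            value = NOT_STATED
    elif question.answer_type is AnswerType.count:
        m = re.search(rf"\b({_NUM})\b", low)
        value = parse_number(m.group(1)) if m else NOT_STATED
    elif question.answer_type is AnswerType.tnm_stage:
        m = _TNM_RE.search(low)
        value = ("T" + m.group(1)[0] + m.group(1)[1:].lower()) if m else NOT_STATED
    elif question.answer_type is AnswerType.histology:
        value = next((h.value for h in Histology if h.value in low), NOT_STATED)
    elif question.answer_type is AnswerType.variant:
        bool_read = _normalize_boolean(low)
        hit = next((v for v, pat in ((Variant.tall_cell, "tall cell"),
                                     (Variant.hobnail, "hobnail"),
                                     (Variant.columnar, "columnar")) if pat in low), None)
        if bool_read is False:
            value = Variant.none.value
        elif hit is not None:
            value = hit.value
        else:
            value = NOT_STATED
    else:  # pragma: no cover
        value = NOT_STATED

    return CanonicalAnswer(report_id=raw.report_id, question_id=raw.question_id, value=value)
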