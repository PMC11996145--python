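"""Context construction for token-limited QA backends.

A report that fits the backend's token budget is passed whole. Longer
reports are split into fixed-length 1200-character segments, each segment
and the posed question are embedded, and the top-3 segments by cosine
similarity are assembled (in document order) into the final context.

The embedder is pluggable; the built-in default hashes lowercase word
tokens into a fixed-dimension term-frequency vector with sublinear
(1 + log) weighting and unit normalization. It is fully deterministic,
which keeps the pipeline reproducible without any model download. Real
sentence-embedding backends can be attached through the same contract.
"""
from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass
from typing import Callable, List, Optional, Protocol, Sequence

import numpy as np

from .errors import DimensionMismatchError
from .models import RetrievalContext, Segment

DEFAULT_SEGMENT_LENGTH = 1200
DEFAULT_TOKEN_LIMIT = 2048
DEFAULT_TOP_K = 3
DEFAULT_EMBED_DIMENSION = 32768

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def whitespace_token_count(text: str) -> int:
    """Default token counter: whitespace-delimited tokens.

    Backend tokenizers vary; a whitespace count is deterministic and
    backend-agnostic, and slightly undercounts subword tokenizers, so the
    budget check stays conservative for typical clinical prose.
    """
    return len(text.split())


def needs_splitting(
    text: str,
    token_limit: int = DEFAULT_TOKEN_LIMIT,
    token_counter: Callable[[str], int] = whitespace_token_count,
) -> bool:
    """True iff the text exceeds the backend's context budget."""
    if token_limit < 1:
        raise ValueError("token_limit must be >= 1")
    return token_counter(text) > token_limit


def segment_text(
    text: str,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    report_id: str = "",
) -> List[Segment]:
    """Split text into consecutive fixed-length character segments.

    Segments tile the input exactly (no overlap, no gap); all but the last
    have length ``segment_length``. Splits fall at raw character offsets
    and may cut through words. Empty text yields an empty list.
    """
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    segments = []
    for index, start in enumerate(range(0, len(text), segment_length)):
        end = min(start + segment_length, len(text))
        segments.append(Segment(report_id=report_id, index=index, start=start,
                                end=end, text=text[start:end]))
    return segments


@dataclass(frozen=True)
class EmbeddingVector:
    """A fixed-dimension embedding; ``is_empty`` flags the designated
    empty-text vector, whose similarity against anything is defined as 0."""

    values: np.ndarray
    is_empty: bool = False

    @property
    def dimension(self) -> int:
        return int(self.values.shape[0])


class Embedder(Protocol):
    """Deterministic text -> fixed-dimension vector contract."""

    embedder_id: str
    dimension: int

    def embed(self, text: str) -> EmbeddingVector: ...


class HashedTfEmbedder:
    """Hashing term-frequency embedder.

    Lowercase word tokens are hashed (CRC32, stable across processes) into
    ``dimension`` buckets; bucket weights are sublinear term frequencies
    ``1 + ln(count)``; the vector is unit-normalized. Distinct runs over
    identical text give identical vectors.
    """

    embedder_id = "hashed-tf"

    def __init__(self, dimension: int = DEFAULT_EMBED_DIMENSION):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.dimension = dimension

    def bucket(self, token: str) -> int:
        return zlib.crc32(token.encode("utf-8")) % self.dimension

    def embed(self, text: str) -> EmbeddingVector:
        tokens = _TOKEN_RE.findall(text.lower())
        vec = np.zeros(self.dimension, dtype=np.float64)
        if not tokens:
            return EmbeddingVector(values=vec, is_empty=True)
        counts: dict[int, int] = {}
        for tok in tokens:
            b = self.bucket(tok)
            counts[b] = counts.get(b, 0) + 1
        for b, c in counts.items():
            vec[b] = 1.0 + math.log(c)
        norm = np.linalg.norm(vec)
        vec /= norm
        return EmbeddingVector(values=vec)


def embed(text: str, embedder: Optional[Embedder] = None) -> EmbeddingVector:
    """Embed text with the given (default: hashed-tf) embedder."""
    return (embedder or HashedTfEmbedder()).embed(text)


def similarity(a: EmbeddingVector, b: EmbeddingVector) -> float:
    """Cosine similarity in [-1, 1]; 0 by definition against an empty-text
    vector. Raises DimensionMismatchError on unequal dimensions."""
    if a.dimension != b.dimension:
        raise DimensionMismatchError(
            f"embedding dimensions differ: {a.dimension} != {b.dimension}")
    if a.is_empty or b.is_empty:
        return 0.0
    na = np.linalg.norm(a.values)
    nb = np.linalg.norm(b.values)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a.values, b.values) / (na * nb))


def rank_segments(scores: Sequence[float], k: int) -> List[int]:
    """Indices of the k highest scores, ties broken toward the lower index."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return order[:k]


def assemble_context(text: str, segments: Sequence[Segment], selected: Sequence[int]) -> str:
    """Join the selected segments in document order.

    Runs of consecutive segments are spliced back seamlessly from the
    original text (so a word cut by a segment boundary is restored); a
    single newline separates non-contiguous runs.
    """
    if not selected:
        return ""
    chosen = sorted(selected)
    runs: List[tuple[int, int]] = []
    run_start = chosen[0]
    prev = chosen[0]
    for idx in chosen[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        runs.append((run_start, prev))
        run_start = prev = idx
    runs.append((run_start, prev))
    pieces = [text[segments[a].start:segments[b].end] for a, b in runs]
    return "\n".join(pieces)


def select_context(
    question_text: str,
    report_text: str,
    *,
    report_id: str = "",
    question_id: str = "",
    k: int = DEFAULT_TOP_K,
    embedder: Optional[Embedder] = None,
    token_limit: int = DEFAULT_TOKEN_LIMIT,
    token_counter: Callable[[str], int] = whitespace_token_count,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> RetrievalContext:
    """Build the QA context for one (report, question) pair.

    Short reports (within the token budget) are used whole. Otherwise the
    report is segmented, segments are scored against the embedded question,
    and the k best are assembled in document order.
    """
    if not report_text:
        raise ValueError("report_text must be nonempty")
    if not needs_splitting(report_text, token_limit, token_counter):
        return RetrievalContext(report_id=report_id, question_id=question_id,
                                context_text=report_text, used_full_text=True)
    emb = embedder or HashedTfEmbedder()
    segments = segment_text(report_text, segment_length, report_id=report_id)
    qvec = emb.embed(question_text)
    scores = [similarity(emb.embed(seg.text), qvec) for seg in segments]
    score_order = rank_segments(scores, k)
    selected = sorted(score_order)
    return RetrievalContext(
        report_id=report_id,
        question_id=question_id,
        selected=selected,
        scores=[scores[i] for i in selected],
        score_order=score_order,
        context_text=assemble_context(report_text, segments, selected),
        used_full_text=False,
        segment_spans=[(segments[i].start, segments[i].end) for i in selected],
    )
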