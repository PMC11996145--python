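"""Segmentation, embedding, cosine similarity and top-k context selection."""
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyromqa.errors import DimensionMismatchError
from thyromqa.retrieval import (
    EmbeddingVector,
    HashedTfEmbedder,
    assemble_context,
    embed,
    needs_splitting,
    rank_segments,
    segment_text,
    select_context,
    similarity,
    whitespace_token_count,
)


class TestNeedsSplitting:
    def test_boundary(self):
        assert not needs_splitting("tok " * 2048, token_limit=2048)
        assert needs_splitting("tok " * 2049, token_limit=2048)

    def test_short_and_empty(self):
        assert not needs_splitting("ten short whitespace tokens " * 2)
        assert not needs_splitting("")

    def test_custom_counter(self):
        assert needs_splitting("abcd", token_limit=3, token_counter=len)


class TestSegmentation:
    @pytest.mark.parametrize("n, expected_lengths", [
        (3000, [1200, 1200, 600]),
        (1200, [1200]),
        (2400, [1200, 1200]),
        (1, [1]),
        (0, []),
    ])
    def test_lengths(self, n, expected_lengths):
        segs = segment_text("a" * n)
        assert [len(s.text) for s in segs] == expected_lengths

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(text=st.text(max_size=5000), length=st.integers(1, 1500))
    def test_tiling_and_reconstruction(self, text, length):
        segs = segment_text(text, segment_length=length)
        assert "".join(s.text for s in segs) == text
        prev_end = 0
        for i, seg in enumerate(segs):
            assert seg.index == i
            assert seg.start == prev_end
            assert seg.end - seg.start == len(seg.text)
            prev_end = seg.end
        assert all(len(s.text) == length for s in segs[:-1])


class TestEmbedder:
    def test_deterministic_and_unit_norm(self):
        emb = HashedTfEmbedder()
        a = emb.embed("papillary carcinoma of the right lobe")
        b = emb.embed("papillary carcinoma of the right lobe")
        assert np.array_equal(a.values, b.values)
        assert abs(np.linalg.norm(a.values) - 1.0) < 1e-9

    def test_disjoint_vocabularies_orthogonal(self):
        """Texts sharing no terms embed orthogonally (no hash collisions
        among these tokens, verified by brute-force bucket comparison)."""
        emb = HashedTfEmbedder(dimension=4096)
        ta = "papillary carcinoma thyroid lobe"
        tb = "cassette formalin stains reviewed"
        buckets_a = {emb.bucket(w) for w in ta.split()}
        buckets_b = {emb.bucket(w) for w in tb.split()}
        assert not buckets_a & buckets_b, "chosen test tokens collide; pick others"
        assert similarity(emb.embed(ta), emb.embed(tb)) == pytest.approx(0.0)

    def test_empty_text_flagged_and_similarity_zero(self):
        emb = HashedTfEmbedder()
        empty = emb.embed("")
        assert empty.is_empty
        assert similarity(empty, emb.embed("tumor")) == 0.0


class TestSimilarity:
    def test_closed_forms(self):
        v = EmbeddingVector(np.array([3.0, 4.0]))
        assert similarity(v, v) == pytest.approx(1.0)
        e1 = EmbeddingVector(np.array([1.0, 0.0]))
        e2 = EmbeddingVector(np.array([0.0, 1.0]))
        diag = EmbeddingVector(np.array([1.0, 1.0]))
        assert similarity(e1, e2) == pytest.approx(0.0)
        assert similarity(e1, diag) == pytest.approx(math.sqrt(2) / 2)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            similarity(EmbeddingVector(np.ones(3)), EmbeddingVector(np.ones(4)))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3),
           st.lists(st.floats(-5, 5), min_size=3, max_size=3),
           st.floats(0.01, 100))
    def test_symmetry_and_scale_invariance(self, xs, ys, c):
        a = EmbeddingVector(np.array(xs))
        b = EmbeddingVector(np.array(ys))
        if np.linalg.norm(a.values) == 0 or np.linalg.norm(b.values) == 0:
            return
        s = similarity(a, b)
        assert -1 - 1e-9 <= s <= 1 + 1e-9
        assert similarity(b, a) == pytest.approx(s, abs=1e-12)
        scaled = EmbeddingVector(c * a.values)
        assert similarity(scaled, b) == pytest.approx(s, abs=1e-12)


class TestSelectContext:
    def test_short_report_used_whole(self):
        ctx = select_context("Is vascular invasion present?", "A short report.")
        assert ctx.used_full_text
        assert ctx.selected == []
        assert ctx.context_text == "A short report."

    def test_exactly_k_segments_all_selected(self):
        text = ("word " * 720)[:3600]  # exactly 3 segments of 1200 chars
        ctx = select_context("anything at all", text,
                             segment_length=1200, token_limit=100)
        assert not ctx.used_full_text
        assert ctx.selected == [0, 1, 2]
        assert ctx.context_text == text  # contiguous run splices seamlessly

    def test_keyword_segment_retrieved(self):
        """A segment holding the question's key terms verbatim ranks in the
        top 3 (confirmed against brute-force cosine over all segments)."""
        rng = random.Random(0)
        filler_words = ["colloid", "parenchyma", "fibrosis", "cassette", "stroma"]
        blocks = [" ".join(rng.choice(filler_words) for _ in range(200)) for _ in range(10)]
        blocks[6] = "lymphatic invasion is present " * 40
        text = " ".join(blocks)
        question = "Is lymphatic invasion present?"
        emb = HashedTfEmbedder()
        ctx = select_context(question, text, token_limit=100, embedder=emb)
        from thyromqa.retrieval import segment_text as st_
        segs = segment_text(text)
        qv = emb.embed(question)
        brute = sorted(range(len(segs)),
                       key=lambda i: (-similarity(emb.embed(segs[i].text), qv), i))[:3]
        assert ctx.score_order == brute
        assert any("lymphatic invasion" in segs[i].text for i in ctx.selected)

    def test_oracle_equivalence_random_instances(self):
        """Selected indices match brute-force score-sort-take-k, including
        tie-breaking toward the lower index."""
        rng = random.Random(2024)
        emb = HashedTfEmbedder(dimension=512)
        vocab = [f"w{i}" for i in range(30)]
        for trial in range(200):
            n_words = rng.randint(30, 400)
            text = " ".join(rng.choice(vocab) for _ in range(n_words))
            question = " ".join(rng.choice(vocab) for _ in range(rng.randint(1, 6)))
            k = rng.randint(1, 4)
            seg_len = rng.randint(20, 120)
            ctx = select_context(question, text, k=k, embedder=emb,
                                 token_limit=5, segment_length=seg_len)
            segs = segment_text(text, segment_length=seg_len)
            qv = emb.embed(question)
            scores = [similarity(emb.embed(s.text), qv) for s in segs]
            brute = sorted(range(len(segs)), key=lambda i: (-scores[i], i))[:k]
            assert sorted(brute) == ctx.selected, f"trial {trial}"
            assert ctx.score_order == brute, f"trial {trial}"

    def test_nonadjacent_segments_joined_with_newline(self):
        text = "a" * 100
        segs = segment_text(text, segment_length=10)
        assert assemble_context(text, segs, [0, 5]) == text[0:10] + "\n" + text[50:60]
        assert assemble_context(text, segs, [3, 4, 5]) == text[30:60]
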