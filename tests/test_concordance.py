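"""Concordance arithmetic: typed agreement, per-question rates, summaries
and pairwise t tests."""
import math
import random

import numpy as np
import pytest
from scipy import special

import thyromqa as t
from thyromqa.concordance import (
    ConcordancePolicy,
    compare_pairings,
    is_concordant,
    per_question_rates,
    summarize,
)
from thyromqa.errors import IncompleteGridError
from thyromqa.models import NOT_APPLICABLE, NOT_STATED, AnswerSet, CanonicalAnswer


def _ans(value, qid="q1", rid="r1"):
    return CanonicalAnswer(report_id=rid, question_id=qid, value=value)


class TestIsConcordant:
    def test_sizes_rounded_to_tenth_cm(self, question_map):
        q = question_map["q1"]
        assert is_concordant(_ans(5.5), _ans(5.5), q)
        assert is_concordant(_ans(5.50), _ans(5.549), q)
        assert not is_concordant(_ans(5.5), _ans(4.2), q)

    def test_not_applicable_matches_itself(self, question_map):
        q = question_map["q12"]
        assert is_concordant(_ans(NOT_APPLICABLE, "q12"), _ans(NOT_APPLICABLE, "q12"), q)
        assert not is_concordant(_ans(NOT_APPLICABLE, "q12"), _ans("papillary", "q12"), q)

    def test_not_stated_equates_false_for_booleans_by_policy(self, question_map):
        q = question_map["q7"]
        assert is_concordant(_ans(NOT_STATED, "q7"), _ans(False, "q7"), q)
        assert not is_concordant(_ans(NOT_STATED, "q7"), _ans(True, "q7"), q)
        strict = ConcordancePolicy(equate_not_stated_false=False)
        assert not is_concordant(_ans(NOT_STATED, "q7"), _ans(False, "q7"), q, strict)

    def test_tnm_case_and_prefix_insensitive(self, question_map):
        q = question_map["q6"]
        assert is_concordant(_ans("pT3a", "q6"), _ans("T3A", "q6"), q)
        assert not is_concordant(_ans("T3a", "q6"), _ans("T3b", "q6"), q)

    def test_mismatched_cells_rejected(self, question_map):
        with pytest.raises(ValueError):
            is_concordant(_ans(1.0, rid="r1"), _ans(1.0, rid="r2"), question_map["q1"])


def _grid_sets(questions, n_reports=84, flips=()):
    """Two complete answer sets over n_reports x 12, differing on `flips`."""
    a = AnswerSet(source_id="A")
    b = AnswerSet(source_id="B")
    for i in range(n_reports):
        rid = f"r{i}"
        for q in questions:
            a.add(_ans(1.0, q.question_id, rid) if q.answer_type.value == "size_cm"
                  else _ans(True, q.question_id, rid) if q.answer_type.value == "boolean"
                  else _ans("right_lobe", q.question_id, rid) if q.answer_type.value == "location"
                  else _ans(2, q.question_id, rid) if q.answer_type.value == "count"
                  else _ans("T1b", q.question_id, rid) if q.answer_type.value == "tnm_stage"
                  else _ans("papillary", q.question_id, rid) if q.answer_type.value == "histology"
                  else _ans("none", q.question_id, rid))
            cell = (rid, q.question_id)
            if cell in flips:
                flipped = {"size_cm": 2.0, "boolean": False, "location": "left_lobe",
                           "count": 5, "tnm_stage": "T2", "histology": "medullary",
                           "variant": "hobnail"}[q.answer_type.value]
                b.add(_ans(flipped, q.question_id, rid))
            else:
                b.add(a.get(rid, q.question_id))
    return a, b


class TestPerQuestionRates:
    def test_identical_sets_are_fully_concordant(self, questions):
        a, b = _grid_sets(questions, n_reports=10)
        table = per_question_rates(a, b, questions)
        assert all(e.rate == 100.0 for e in table.entries)
        assert table.mean_rate == 100.0 and table.sd_rate == 0.0
        assert table.pooled_concordant == table.pooled_total == 120

    def test_nine_disagreements_on_default_grid(self, questions):
        """9 discordant cells out of 84x12 pool to 999/1008 = 99.1%."""
        rng = random.Random(5)
        cells = [(f"r{rng.randrange(84)}", f"q{rng.randrange(1, 13)}") for _ in range(30)]
        flips = set()
        for cell in cells:
            if len(flips) < 9:
                flips.add(cell)
        assert len(flips) == 9
        a, b = _grid_sets(questions, n_reports=84, flips=flips)
        table = per_question_rates(a, b, questions)
        assert table.pooled_total == 1008
        assert table.pooled_concordant == 999
        assert table.pooled_rate == pytest.approx(100 * 999 / 1008)
        assert round(table.pooled_rate, 1) == 99.1

    def test_symmetry_and_conservation(self, questions):
        rng = random.Random(3)
        flips = {(f"r{rng.randrange(20)}", f"q{rng.randrange(1, 13)}") for _ in range(12)}
        a, b = _grid_sets(questions, n_reports=20, flips=flips)
        tab_ab = per_question_rates(a, b, questions)
        tab_ba = per_question_rates(b, a, questions)
        assert [e.concordant for e in tab_ab.entries] == [e.concordant for e in tab_ba.entries]
        assert tab_ab.pooled_total == 20 * 12
        assert tab_ab.pooled_concordant == sum(e.concordant for e in tab_ab.entries)

    def test_incomplete_grid_rejected(self, questions):
        a, b = _grid_sets(questions, n_reports=3)
        removed = ("r1", "q5")
        del b.answers[removed]
        with pytest.raises(IncompleteGridError) as exc:
            per_question_rates(a, b, questions)
        assert removed in exc.value.missing


class TestSummarize:
    def test_reviewer_column_mean_and_sd(self):
        """The canonical 12-question rate column averaging to 99 with SD
        rounding to 1 under both conventions."""
        rates = [98, 97, 99, 99, 100, 100, 100, 100, 100, 97, 99, 99]
        mean, sd = summarize(rates)
        assert mean == pytest.approx(99.0)
        assert round(sd) == 1
        _, sd_pop = summarize(rates, sample=False)
        assert round(sd_pop) == 1

    def test_single_value(self):
        mean, sd = summarize([88.0], sample=False)
        assert mean == 88.0 and sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestComparePairings:
    def test_identical_vectors_give_p_one(self):
        rates = [99.0, 98.0, 100.0]
        t_stat, p, mode = compare_pairings(rates, rates)
        assert (t_stat, p, mode) == (0.0, 1.0, "paired")

    def test_agrees_with_t_distribution_closed_form(self):
        """p matches the incomplete-beta form of the t CDF to 1e-9."""
        rng = random.Random(17)
        for _ in range(20):
            n = rng.randint(3, 12)
            a = [rng.uniform(80, 100) for _ in range(n)]
            b = [rng.uniform(80, 100) for _ in range(n)]
            t_stat, p, _ = compare_pairings(a, b, mode="paired")
            d = np.array(a) - np.array(b)
            df = n - 1
            t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            p_expected = special.betainc(df / 2, 0.5, df / (df + t_expected ** 2))
            assert t_stat == pytest.approx(t_expected, abs=1e-9)
            assert p == pytest.approx(p_expected, abs=1e-9)

    def test_hand_computed_toy(self):
        """Three questions, one discordant pair: t = mean(d)/(sd(d)/sqrt(n))."""
        a = [100.0, 100.0, 100.0]
        b = [100.0, 100.0, 97.0]
        t_stat, p, _ = compare_pairings(a, b)
        # d = (0, 0, 3): mean 1, sd sqrt(3), t = 1/(sqrt(3)/sqrt(3)) = 1
        assert t_stat == pytest.approx(1.0)
        assert 0.0 <= p <= 1.0

    def test_welch_mode_and_length_check(self):
        t_stat, p, mode = compare_pairings([99, 98, 97], [90, 89, 88], mode="welch")
        assert mode == "welch" and p < 0.05
        with pytest.raises(ValueError):
            compare_pairings([1.0], [1.0, 2.0])
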