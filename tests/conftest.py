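import pytest

import thyromqa as t


@pytest.fixture(scope="session")
def questions():
    return t.load_questions()


@pytest.fixture(scope="session")
def question_map(questions):
    return {q.question_id: q for q in questions}


@pytest.fixture(scope="session")
def corpus_102():
    """The default study-sized corpus: 102 reports, 84 malignant."""
    return t.generate_corpus(102, seed=42)


@pytest.fixture(scope="session")
def included_84(corpus_102):
    included, _ = t.filter_corpus(corpus_102)
    return included


@pytest.fixture(scope="session")
def truth_set(included_84, questions):
    return t.truth_answer_set([r.truth for r in included_84], questions)


@pytest.fixture(scope="session")
def full_text_run(included_84, questions):
    """Reference backend over full report text (no retrieval)."""
    return t.run_mqa([(r.report_id, r.text) for r in included_84],
                     questions, t.ReferenceBackend(), use_retrieval=False)


@pytest.fixture(scope="session")
def retrieval_run(included_84, questions):
    """Reference backend over top-3 retrieved contexts."""
    return t.run_mqa([(r.report_id, r.text) for r in included_84],
                     questions, t.ReferenceBackend(), use_retrieval=True)
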