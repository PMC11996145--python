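"""The 12-question thyroid MQA schema and prompt construction.

The default question set extracts the fields needed for AJCC-TNM staging
and ATA recurrence-risk assessment; custom sets load from YAML with the
same structure. Prompt building is pure placeholder substitution into a
configurable template.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .errors import ConfigurationError
from .models import Question

CONTEXT_PLACEHOLDER = "{context}"
QUESTION_PLACEHOLDER = "{question}"

DEFAULT_TEMPLATE_TEXT = (
    "Use only the following pathology report excerpt to answer the question.\n"
    "\n"
    "Report excerpt:\n"
    "{context}\n"
    "\n"
    "Question: {question}\n"
    "Answer in one short sentence."
)


@dataclass(frozen=True)
class PromptTemplate:
    """A prompt template with exactly one context and one question slot."""

    template: str = DEFAULT_TEMPLATE_TEXT

    def __post_init__(self):
        for placeholder in (CONTEXT_PLACEHOLDER, QUESTION_PLACEHOLDER):
            n = self.template.count(placeholder)
            if n != 1:
                raise ConfigurationError(
                    f"template must contain {placeholder} exactly once (found {n})")


def _parse_questions(payload: dict) -> List[Question]:
    items = payload.get("questions")
    if not items:
        raise ConfigurationError("question set defines no questions")
    questions = []
    for item in items:
        dep = item.get("depends_on")
        questions.append(Question(
            question_id=item["question_id"],
            text=item["text"],
            answer_type=item["answer_type"],
            group=item["group"],
            depends_on=tuple(dep) if dep else None,
        ))
    ids = [q.question_id for q in questions]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate question ids in {ids}")
    known = set(ids)
    for q in questions:
        if q.depends_on and q.depends_on[0] not in known:
            raise ConfigurationError(
                f"{q.question_id} depends on unknown question {q.depends_on[0]}")
    return questions


def load_questions(path: Optional[Union[str, Path]] = None) -> List[Question]:
    """Load a question set from YAML; with no path, the default 12-item set."""
    if path is None:
        text = resources.files("thyromqa.data").joinpath("questions.yaml").read_text()
    else:
        text = Path(path).read_text()
    return _parse_questions(yaml.safe_load(text))


def build_prompt(template: PromptTemplate, context_text: str, question: Question) -> str:
    """Substitute context and question into the template."""
    if not context_text:
        raise ValueError("context_text must be nonempty")
    out = template.template.replace(CONTEXT_PLACEHOLDER, context_text)
    return out.replace(QUESTION_PLACEHOLDER, question.text)
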