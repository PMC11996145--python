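"""Simplified AJCC 8th-edition T/N categories and ATA recurrence-risk tiers
for differentiated thyroid carcinoma.

These rules serve two purposes: they are the consistency oracle for the
synthetic report generator (the rendered TNM token must agree with the
generated size/ETE fields), and a cross-check on extracted answers. The
implementation covers only the subset of the guidelines reachable by the
12-question schema: T1a-T3b by size and gross extrathyroidal extension
(ETE), a binary N0/N1 node category, and a low/intermediate/high recurrence
tier driven by gross ETE, vascular invasion, aggressive variants and nodal
disease. T4, the N1a/N1b split, M staging, age-dependent stage groups and
microscopic-ETE nuance are out of scope, and the generator never emits
cases that would need them.

Thresholds live in ``data/staging_rules.yaml`` so they are auditable.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from .errors import StagingError
from .models import NCategory, RiskTier, TCategory, Variant


@lru_cache(maxsize=1)
def load_rules() -> dict:
    """Load the staging threshold table shipped with the package."""
    text = resources.files("thyromqa.data").joinpath("staging_rules.yaml").read_text()
    return yaml.safe_load(text)


class StagingInput(BaseModel):
    """Pathology fields relevant to staging and recurrence risk."""

    tumor_size_cm: float = Field(gt=0)
    gross_ete: bool
    nodes_positive: int = Field(ge=0)
    vascular_invasion: bool
    lymphatic_invasion: bool = False
    aggressive_variant: Variant = Variant.none


def derive_t_category(size_cm: float, gross_ete: bool) -> TCategory:
    """T category from tumor size (cm) and gross extrathyroidal extension.

    Gross ETE into the strap muscles gives T3b regardless of size; otherwise
    size bins with inclusive upper bounds: <=1 cm T1a, <=2 cm T1b, <=4 cm T2,
    >4 cm T3a.
    """
    if size_cm is None or not size_cm > 0:
        raise StagingError(f"tumor size must be positive, got {size_cm!r}")
    rules = load_rules()["t_category"]
    if gross_ete:
        return TCategory(rules["gross_ete_category"])
    if size_cm <= rules["t1a_max_cm"]:
        return TCategory.T1a
    if size_cm <= rules["t1b_max_cm"]:
        return TCategory.T1b
    if size_cm <= rules["t2_max_cm"]:
        return TCategory.T2
    return TCategory.T3a


def derive_n_category(nodes_positive: int) -> NCategory:
    """Binary node category: any positive node is N1."""
    if nodes_positive < 0:
        raise StagingError(f"nodes_positive must be >= 0, got {nodes_positive}")
    threshold = load_rules()["n_category"]["n1_min_positive"]
    return NCategory.N1 if nodes_positive >= threshold else NCategory.N0


def recurrence_risk_tier(inp: StagingInput) -> RiskTier:
    """ATA-style structural recurrence risk tier.

    Gross ETE dominates (high); otherwise vascular invasion, any aggressive
    variant, or nodal disease gives intermediate; else low.
    """
    if inp.gross_ete:
        return RiskTier.high
    if inp.vascular_invasion or inp.aggressive_variant is not Variant.none or inp.nodes_positive > 0:
        return RiskTier.intermediate
    return RiskTier.low
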