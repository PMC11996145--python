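"""Seeded synthetic thyroid surgical pathology reports with ground truth.

The generator emulates the narrative structure of real surgical pathology
reports — specimen list, gross description, microscopic/diagnosis sections,
prose and synoptic styles — together with the features that make automated
extraction nontrivial in practice:

* whole-specimen dimensions (lobe measurements) that are NOT the tumor
  size, the classic distractor for "what is the size of the primary tumor";
* lymph-node sections labeled by neck level or compartment ("level VI",
  "central compartment"), with the word "cervical" appearing only with a
  configurable probability;
* tumor sizes occasionally reported in mm, exercising unit normalization;
* a configurable fraction of reports padded past the QA backend's token
  budget, forcing the segmentation/retrieval path;
* excluded report categories (other organ sites, benign, cytopathology,
  outside review) mirroring real corpus composition.

Every ground-truth fact of a malignant report is stated by at least one
sentence literally present in the text, recorded in ``evidence`` keyed by
default question id. Generation is fully deterministic per (n, seed,
config).
"""
from __future__ import annotations

import random
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, Field

from .errors import ConfigurationError
from .models import (
    Category,
    Histology,
    Location,
    NCategory,
    ReportTruth,
    Style,
    SyntheticReport,
    Variant,
)
from .retrieval import DEFAULT_TOKEN_LIMIT, whitespace_token_count
from .staging import derive_n_category, derive_t_category

#: Corpus composition mirroring a realistic institutional query: most
#: reports are malignant thyroid resections, with a tail of other organ
#: sites, benign resections, cytopathology and outside reviews.
DEFAULT_CATEGORY_PROPORTIONS = {
    Category.thyroid_malignant: 84 / 102,
    Category.other_organ: 10 / 102,
    Category.benign: 2 / 102,
    Category.cytopathology: 5 / 102,
    Category.outside_review: 1 / 102,
}


class StyleConfig(BaseModel):
    """Generator settings controlling corpus composition and narration."""

    category_proportions: Dict[Category, float] = Field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS))
    style_weights: Dict[Style, float] = Field(
        default_factory=lambda: {Style.prose: 0.5, Style.synoptic: 0.3, Style.mixed: 0.2})
    #: fraction of reports padded beyond the token budget
    long_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    #: fraction of malignant reports whose tumor size is written in mm
    mm_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    #: probability that node sections use the word "cervical" verbatim
    cervical_probability: float = Field(default=0.2, ge=0.0, le=1.0)
    distractor_dimensions: bool = True
    token_limit: int = DEFAULT_TOKEN_LIMIT

    def __init__(self, **data):
        super().__init__(**data)
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.category_proportions.values()):
            raise ConfigurationError(
                f"category proportions must be nonnegative and sum to 1, got {total}")
        if not self.style_weights or any(v < 0 for v in self.style_weights.values()):
            raise ConfigurationError("style weights must be nonnegative")


def _largest_remainder_counts(proportions: Dict[Category, float], n: int) -> Dict[Category, int]:
    """Integer category counts summing to n, by largest-remainder rounding."""
    quotas = {c: p * n for c, p in proportions.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda c: (-(quotas[c] - counts[c]), c.value))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _sample_truth(report_id: str, category: Category, rng: random.Random) -> ReportTruth:
    if category is not Category.thyroid_malignant:
        return ReportTruth(report_id=report_id, category=category)
    size = round(rng.uniform(0.3, 6.5), 1)
    gross_ete = rng.random() < 0.10
    location = rng.choices(
        [Location.right_lobe, Location.left_lobe, Location.isthmus],
        weights=[0.45, 0.45, 0.10])[0]
    nodes_examined = 0 if rng.random() < 0.35 else rng.randint(1, 12)
    if nodes_examined == 0 or rng.random() < 0.4:
        nodes_positive = 0
    else:
        nodes_positive = rng.randint(0, nodes_examined)
    vascular = rng.random() < 0.20
    lymphatic = rng.random() < 0.15
    histology = rng.choices(
        [Histology.papillary, Histology.follicular, Histology.medullary],
        weights=[0.80, 0.12, 0.08])[0]
    if histology is Histology.papillary:
        variant = rng.choices(
            [Variant.none, Variant.tall_cell, Variant.hobnail, Variant.columnar],
            weights=[0.80, 0.10, 0.05, 0.05])[0]
    else:
        variant = Variant.none
    second = rng.random() < 0.15
    second_hist = rng.choice([Histology.papillary, Histology.follicular]) if second else None
    return ReportTruth(
        report_id=report_id,
        category=category,
        tumor_size_cm=size,
        location=location,
        gross_ete=gross_ete,
        nodes_examined=nodes_examined,
        nodes_positive=nodes_positive,
        vascular_invasion=vascular,
        lymphatic_invasion=lymphatic,
        histology=histology,
        aggressive_variant=variant,
        second_cancer=second,
        second_cancer_histology=second_hist,
        t_category=derive_t_category(size, gross_ete),
    )


_HISTOLOGY_PHRASE = {
    Histology.papillary: "papillary thyroid carcinoma",
    Histology.follicular: "follicular thyroid carcinoma",
    Histology.medullary: "medullary thyroid carcinoma",
}
_LOCATION_PHRASE = {
    Location.right_lobe: "right thyroid lobe",
    Location.left_lobe: "left thyroid lobe",
    Location.isthmus: "isthmus",
}
_VARIANT_PHRASE = {
    Variant.tall_cell: "Tall cell",
    Variant.hobnail: "Hobnail",
    Variant.columnar: "Columnar cell",
}

_CLINICAL_HISTORY = [
    "Thyroid nodule, status post fine needle aspiration.",
    "Enlarging thyroid nodule with compressive symptoms.",
    "Thyroid nodule discovered incidentally on imaging.",
    "Multinodular goiter with a dominant nodule.",
]

#: Padding sentences free of any extraction keyword; used to push a report
#: past the token budget without adding answer-bearing or confounding text.
_FILLER_TEMPLATES = [
    "Cassette {label} contains a representative section of unremarkable thyroid parenchyma with abundant colloid.",
    "Cassette {label} demonstrates preserved follicular architecture without significant cytologic atypia.",
    "The tissue was fixed in neutral buffered formalin and processed routinely for histologic examination.",
    "Hematoxylin and eosin stained slides from cassette {label} were reviewed in their entirety.",
    "Scattered foci of stromal fibrosis and chronic inflammation are noted in the background parenchyma.",
    "Cassette {label} shows areas of cystic degeneration and dense hyalinized stroma.",
    "All controls stained appropriately and were reviewed alongside the diagnostic material.",
    "Gross photographs were obtained and retained in the departmental archive.",
]

_EXCLUDED_TEXTS = {
    Category.other_organ: (
        "SURGICAL PATHOLOGY REPORT\n\nSPECIMEN: Parathyroid gland, excision.\n\n"
        "DIAGNOSIS: Hypercellular parathyroid tissue, consistent with parathyroid adenoma. "
        "The specimen weighs 450 mg and measures 1.4 x 0.9 x 0.6 cm."),
    Category.benign: (
        "SURGICAL PATHOLOGY REPORT\n\nSPECIMEN: Thyroid, right lobectomy.\n\n"
        "DIAGNOSIS: Multinodular goiter with adenomatoid change. Negative for malignancy."),
    Category.cytopathology: (
        "CYTOPATHOLOGY REPORT\n\nSPECIMEN: Thyroid, fine needle aspiration.\n\n"
        "INTERPRETATION: Benign-appearing follicular cells and colloid. "
        "Bethesda category II, benign."),
    Category.outside_review: (
        "SURGICAL PATHOLOGY REPORT\n\nSPECIMEN: Outside slides received for review.\n\n"
        "COMMENT: Outside material reviewed for treatment planning; "
        "refer to the originating institution's report for the complete diagnosis."),
}


def _fact_sentences(truth: ReportTruth, style: Style, rng: random.Random,
                    config: StyleConfig) -> Dict[str, str]:
    """One answer-bearing sentence per default question id."""
    ev: Dict[str, str] = {}
    size = truth.tumor_size_cm
    in_mm = rng.random() < config.mm_fraction
    size_str = f"{round(size * 10):d} mm" if in_mm else f"{size:.1f} cm"
    loc = _LOCATION_PHRASE[truth.location]
    hist = _HISTOLOGY_PHRASE[truth.histology]
    node_label = "cervical" if rng.random() < config.cervical_probability else rng.choice(
        ["level VI", "central compartment", "perithyroidal"])
    n_token = derive_n_category(truth.nodes_positive).value

    if style is Style.synoptic:
        ev["q9"] = f"Histologic type: {hist.capitalize()}."
        ev["q1"] = f"Tumor size: {size_str}."
        ev["q3"] = f"Tumor site: {loc.capitalize()}."
        ev["q2"] = ("Extrathyroidal extension: Present, gross extension into the strap muscles."
                    if truth.gross_ete else "Extrathyroidal extension: Not identified.")
        ev["q7"] = ("Vascular invasion: Present." if truth.vascular_invasion
                    else "Vascular invasion: Not identified.")
        ev["q8"] = ("Lymphatic invasion: Present." if truth.lymphatic_invasion
                    else "Lymphatic invasion: Not identified.")
        if truth.nodes_examined > 0:
            ev["q4"] = (f"Lymph nodes: {truth.nodes_positive} of {truth.nodes_examined} "
                        f"{node_label} lymph nodes positive for malignancy.")
        else:
            ev["q4"] = "Lymph nodes: No lymph nodes identified."
        ev["q5"] = ev["q4"]
        if truth.aggressive_variant is not Variant.none:
            ev["q10"] = (f"Aggressive histologic variant: "
                         f"{_VARIANT_PHRASE[truth.aggressive_variant]} variant.")
        else:
            ev["q10"] = "Aggressive histologic variant (tall cell, hobnail, or columnar cell): Not identified."
        if truth.second_cancer:
            ev["q11"] = (f"Second thyroid cancer: Present, "
                         f"{_HISTOLOGY_PHRASE[truth.second_cancer_histology]}.")
        else:
            ev["q11"] = "Second thyroid cancer: Not identified."
        ev["q12"] = ev["q11"]
        ev["q6"] = f"Pathologic stage: p{truth.t_category.value} p{n_token}."
    else:
        ev["q9"] = f"The histologic type of the tumor is {hist}."
        ev["q1"] = f"The tumor measures {size_str} in greatest dimension."
        ev["q3"] = f"The tumor is located in the {loc}."
        ev["q2"] = ("Gross extrathyroidal extension into the strap muscles is present, "
                    "and the tumor extends beyond the capsule of the thyroid."
                    if truth.gross_ete else
                    "The tumor is confined to the thyroid, and no extrathyroidal extension is identified.")
        ev["q7"] = ("Vascular invasion is present." if truth.vascular_invasion
                    else "Vascular invasion is not identified.")
        ev["q8"] = ("Lymphatic invasion is present." if truth.lymphatic_invasion
                    else "Lymphatic invasion is not identified.")
        if truth.nodes_examined > 0:
            ev["q4"] = (f"{truth.nodes_positive} of {truth.nodes_examined} {node_label} "
                        f"lymph nodes are positive for malignancy.")
        else:
            ev["q4"] = "No lymph nodes are identified in the specimen."
        ev["q5"] = ev["q4"]
        if truth.aggressive_variant is not Variant.none:
            ev["q10"] = (f"{_VARIANT_PHRASE[truth.aggressive_variant]} variant features "
                         "are present, indicative of a more aggressive histology.")
        else:
            ev["q10"] = "No tall cell, hobnail, or columnar cell variant is identified."
        if truth.second_cancer:
            ev["q11"] = (f"A second focus of {_HISTOLOGY_PHRASE[truth.second_cancer_histology]} "
                         "is present, representing a second thyroid cancer.")
        else:
            ev["q11"] = "No second thyroid cancer is identified."
        ev["q12"] = ev["q11"]
        ev["q6"] = f"The final pathologic stage is p{truth.t_category.value} p{n_token}."
    return ev


def _gross_description(truth: ReportTruth, rng: random.Random,
                       config: StyleConfig) -> Tuple[str, List[float]]:
    dims: List[float] = []
    lines = []
    if config.distractor_dimensions:
        for side in ("right", "left"):
            d = [round(rng.uniform(2.0, 6.0), 1), round(rng.uniform(1.5, 4.0), 1),
                 round(rng.uniform(1.0, 3.0), 1)]
            dims.extend(d)
            weight = round(rng.uniform(4.0, 30.0), 1)
            lines.append(f"The {side} thyroid lobe measures {d[0]} x {d[1]} x {d[2]} cm "
                         f"and weighs {weight} g.")
    lines.append("The specimen is received in formalin and serially sectioned.")
    lines.append("The cut surfaces are tan-red and vaguely nodular.")
    return " ".join(lines), dims


def _filler_block(rng: random.Random, deficit_tokens: int) -> str:
    sentences = []
    tokens = 0
    k = 1
    while tokens < deficit_tokens:
        template = rng.choice(_FILLER_TEMPLATES)
        sent = template.format(label=f"A{k}")
        k += 1
        sentences.append(sent)
        tokens += whitespace_token_count(sent)
    return " ".join(sentences)


def _render(truth: ReportTruth, style: Style, seed: int,
            config: Optional[StyleConfig] = None) -> Tuple[str, List[float], Dict[str, str]]:
    """Render one report; returns (text, distractor_dims_cm, evidence)."""
    config = config or StyleConfig()
    rng = random.Random(f"render:{seed}:{truth.report_id}")
    if truth.category is not Category.thyroid_malignant:
        return _EXCLUDED_TEXTS[truth.category], [], {}

    ev = _fact_sentences(truth, style, rng, config)
    gross, dims = _gross_description(truth, rng, config)

    specimens = ["A. Thyroid, total thyroidectomy."]
    if truth.nodes_examined > 0:
        specimens.append(f"B. {rng.choice(['Level VI', 'Central compartment'])} "
                         "lymph node dissection.")

    if style is Style.synoptic:
        diagnosis_lines = [ev[q] for q in
                           ("q9", "q1", "q3", "q2", "q7", "q8", "q4", "q10", "q11", "q6")]
        diagnosis = "SYNOPTIC SUMMARY:\n" + "\n".join(diagnosis_lines)
    else:
        order = ["q9", "q1", "q3", "q2", "q7", "q8", "q4", "q10", "q11", "q6"]
        diagnosis = "MICROSCOPIC DESCRIPTION AND DIAGNOSIS:\n" + " ".join(ev[q] for q in order)
        if style is Style.mixed:
            diagnosis += ("\n\nSYNOPTIC SUMMARY:\n"
                          f"Tumor site: {_LOCATION_PHRASE[truth.location].capitalize()}.\n"
                          f"Pathologic stage: p{truth.t_category.value} "
                          f"p{derive_n_category(truth.nodes_positive).value}.")

    parts = [
        "SURGICAL PATHOLOGY REPORT",
        f"Accession: TS-{rng.randint(100000, 999999)}",
        "CLINICAL HISTORY: " + rng.choice(_CLINICAL_HISTORY),
        "SPECIMEN(S) SUBMITTED:\n" + "\n".join(specimens),
        "GROSS DESCRIPTION: " + gross,
        diagnosis,
    ]
    text = "\n\n".join(parts)

    make_long = rng.random() < config.long_fraction
    if make_long:
        target = rng.randint(config.token_limit + 300, config.token_limit + 1200)
        deficit = target - whitespace_token_count(text)
        if deficit > 0:
            # split the padding around the diagnosis so answer-bearing text
            # does not sit in one predictable corner of the report
            pad_gross = _filler_block(rng, deficit // 2)
            pad_comment = _filler_block(rng, deficit - deficit // 2)
            parts = parts[:5] + ["SECTIONS: " + pad_gross] + parts[5:] + ["COMMENT: " + pad_comment]
            text = "\n\n".join(parts)
    return text, dims, ev


def render_report(truth: ReportTruth, style: Style, seed: int,
                  config: Optional[StyleConfig] = None) -> str:
    """Render the narrative text for one ground truth (deterministic)."""
    return _render(truth, style, seed, config)[0]


def generate_corpus(n: int, seed: int,
                    style_config: Optional[StyleConfig] = None) -> List[SyntheticReport]:
    """Generate a seeded corpus of n reports with ground truth.

    Category counts follow the configured proportions exactly (largest-
    remainder rounding) with seeded placement; per-report sampling is keyed
    on (seed, report index) so corpora are byte-identical across runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = style_config or StyleConfig()
    counts = _largest_remainder_counts(config.category_proportions, n)
    categories = [c for c, k in counts.items() for _ in range(k)]
    random.Random(f"categories:{seed}").shuffle(categories)

    styles = sorted(config.style_weights)
    weights = [config.style_weights[s] for s in styles]

    reports = []
    for i, category in enumerate(categories):
        rng = random.Random(f"truth:{seed}:{i}")
        report_id = f"R{i + 1:04d}"
        truth = _sample_truth(report_id, category, rng)
        style = rng.choices(styles, weights=weights)[0]
        text, dims, ev = _render(truth, style, seed, config)
        reports.append(SyntheticReport(truth=truth, text=text, style=style,
                                       distractor_dims_cm=dims, evidence=ev))
    return reports


def filter_corpus(corpus: List[SyntheticReport]) -> Tuple[List[SyntheticReport], Dict[Category, int]]:
    """Apply the inclusion filter: keep malignant thyroid reports, tally the
    excluded categories. Partitions the corpus exactly."""
    tally = {c: 0 for c in Category if c is not Category.thyroid_malignant}
    included = []
    for report in corpus:
        if report.truth.category is Category.thyroid_malignant:
            included.append(report)
        else:
            tally[report.truth.category] += 1
    return included, tally
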