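"""The three-stage detection pipeline: localize → extract → analyze.

Four wirings ("setups") are supported, mirroring how a detector, an OCR
engine and a language model can share the three roles:

``setup1``
    dedicated localizer + dedicated extractor + text analyzer;
``setup2``
    a joint localize-and-extract backend (an OCR engine's built-in
    detection) + text analyzer;
``setup3``
    dedicated localizer + a vision analyzer that reads and classifies each
    crop, one request per crop;
``setup4``
    a single end-to-end vision analyzer on the whole image — its outputs
    carry **no coordinates**, so instance-level evaluation is impossible.

Backends are pluggable callables behind small contracts; the module ships
deterministic *oracle* backends (driven by ground-truth labels), a
character-noise OCR double, and a rule-based reference analyzer keyed on the
taxonomy signal words. Real engine adapters (a detection model, an OCR
package, a chat-completion endpoint) can be bound behind the same contracts;
the reference analyzer is a test oracle and offline fallback, not a claim of
parity with a large language model.

All extracted texts of one image are analyzed jointly as a list, so the
analyzer sees aggregated context instead of isolated lines. A failing
backend never aborts a batch: the image is marked failed and feeds the
pipeline error rate.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Literal, Mapping, Optional, Protocol, Sequence

import numpy as np
from pydantic import BaseModel, ValidationError

from . import taxonomy
from . import _lexicons as lex
from .errors import ConfigError, StructuredOutputError
from .geometry import Box, iou
from .simulator import ImprintLabel

__all__ = [
    "TYPE_VOCAB",
    "SetupId",
    "TextRegion",
    "ExtractedText",
    "AnalysisResult",
    "PipelineItem",
    "PipelineOutput",
    "PipelineOptions",
    "Backends",
    "run_pipeline",
    "run_batch",
    "error_rate",
    "oracle_localizer",
    "oracle_extractor",
    "noisy_extractor",
    "reference_analyzer",
    "classify_text",
    "OracleLocalizer",
    "OracleExtractor",
    "NoisyExtractor",
    "ReferenceAnalyzer",
    "OracleVisionAnalyzer",
    "build_analysis_prompt",
    "parse_structured_output",
    "oracle_backends",
    "category_to_type",
    "write_predictions",
    "read_predictions",
    "OcrAdapterConfig",
    "ChatAdapterConfig",
]

#: Closed output vocabulary of the text analyzer.
TYPE_VOCAB = ("date", "identifier", "patient_name", "address", "phone_nr",
              "email", "other", "non-phi")

AnalysisType = Literal["date", "identifier", "patient_name", "address",
                       "phone_nr", "email", "other", "non-phi"]


class SetupId(str, Enum):
    setup1 = "setup1"
    setup2 = "setup2"
    setup3 = "setup3"
    setup4 = "setup4"


@dataclass(frozen=True)
class TextRegion:
    """A detected text region: half-open pixel box and confidence."""

    bbox: Box
    score: float = 1.0


@dataclass(frozen=True)
class ExtractedText:
    """Machine-encoded text read from a region (empty string = failed read)."""

    text: str
    region: Optional[TextRegion] = None


class AnalysisResult(BaseModel):
    """Structured output contract of the text analyzer."""

    type: AnalysisType
    raw_text: str
    reason: str = ""
    language: str = "en"

    @property
    def is_phi_type(self) -> bool:
        return self.type != "non-phi"


@dataclass
class Counters:
    prompt_tokens: int = 0
    response_tokens: int = 0
    requests: int = 0
    wall_time: float = 0.0


@dataclass
class PipelineItem:
    analysis: AnalysisResult
    region: Optional[TextRegion] = None
    text: Optional[ExtractedText] = None


@dataclass
class PipelineOutput:
    """Per-image pipeline result; ``failed`` images feed the error rate."""

    image_id: str
    setup: SetupId
    items: list[PipelineItem] = field(default_factory=list)
    failed: bool = False
    failure_reason: str = ""
    counters: Counters = field(default_factory=Counters)

    @property
    def has_coordinates(self) -> bool:
        return all(item.region is not None for item in self.items)

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "setup": self.setup.value,
            "failed": self.failed,
            "failure_reason": self.failure_reason,
            "counters": vars(self.counters),
            "items": [
                {"analysis": item.analysis.model_dump(),
                 "region": (None if item.region is None
                            else {"bbox": list(item.region.bbox),
                                  "score": item.region.score}),
                 "text": None if item.text is None else item.text.text}
                for item in self.items],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineOutput":
        items = []
        for it in d.get("items", []):
            region = None
            if it.get("region") is not None:
                region = TextRegion(bbox=tuple(it["region"]["bbox"]),
                                    score=float(it["region"].get("score", 1.0)))
            text = None
            if it.get("text") is not None:
                text = ExtractedText(text=it["text"], region=region)
            items.append(PipelineItem(analysis=AnalysisResult(**it["analysis"]),
                                      region=region, text=text))
        return cls(image_id=d["image_id"], setup=SetupId(d["setup"]),
                   items=items, failed=bool(d.get("failed", False)),
                   failure_reason=d.get("failure_reason", ""),
                   counters=Counters(**d.get("counters", {})))


@dataclass
class PipelineOptions:
    """Cross-backend options.

    ``identifier_scope`` controls whether study/series/image identifiers
    count as PHI ("all") or only patient identifiers do ("patient_only").
    ``temperature`` is pinned to 0 so generative analyzers respond as
    deterministically as they can.
    """

    identifier_scope: Literal["all", "patient_only"] = "all"
    temperature: float = 0.0
    iou_match_threshold: float = 0.5


@dataclass
class OcrAdapterConfig:
    """Options forwarded to an external OCR engine adapter. The low-bound
    text score threshold is lowered to 0.2 by default so single-letter
    markers (L, R) and gender abbreviations survive detection."""

    low_bound_threshold: float = 0.2
    languages: tuple[str, ...] = ("en",)


@dataclass
class ChatAdapterConfig:
    """Options for a chat-completion analyzer adapter: temperature 0 and a
    small retry budget for transient server errors before an image is
    marked failed."""

    temperature: float = 0.0
    max_retries: int = 2
    backoff_seconds: float = 1.0


# ---------------------------------------------------------------------------
# backend contracts
# ---------------------------------------------------------------------------

class Localizer(Protocol):
    def __call__(self, image: Optional[np.ndarray],
                 context: Optional[Sequence[ImprintLabel]]) -> list[TextRegion]: ...


class Extractor(Protocol):
    def __call__(self, image: Optional[np.ndarray], region: TextRegion,
                 context: Optional[Sequence[ImprintLabel]]) -> ExtractedText: ...


class JointLocalizerExtractor(Protocol):
    def __call__(self, image: Optional[np.ndarray],
                 context: Optional[Sequence[ImprintLabel]]
                 ) -> list[tuple[TextRegion, ExtractedText]]: ...


class TextAnalyzer(Protocol):
    def __call__(self, texts: Sequence[str],
                 options: PipelineOptions) -> list[AnalysisResult]: ...


class VisionAnalyzer(Protocol):
    def analyze_crop(self, image: Optional[np.ndarray], region: TextRegion,
                     context: Optional[Sequence[ImprintLabel]],
                     options: PipelineOptions) -> AnalysisResult: ...

    def analyze_image(self, image: Optional[np.ndarray],
                      context: Optional[Sequence[ImprintLabel]],
                      options: PipelineOptions) -> list[AnalysisResult]: ...


@dataclass
class Backends:
    localizer: Optional[Localizer] = None
    extractor: Optional[Extractor] = None
    analyzer: Optional[TextAnalyzer] = None
    joint_ocr: Optional[JointLocalizerExtractor] = None
    vision_analyzer: Optional[VisionAnalyzer] = None


_REQUIRED = {
    SetupId.setup1: ("localizer", "extractor", "analyzer"),
    SetupId.setup2: ("joint_ocr", "analyzer"),
    SetupId.setup3: ("localizer", "vision_analyzer"),
    SetupId.setup4: ("vision_analyzer",),
}


def validate_backends(setup: SetupId, backends: Backends) -> None:
    missing = [name for name in _REQUIRED[setup]
               if getattr(backends, name) is None]
    if missing:
        raise ConfigError(f"{setup.value} requires backends {missing}")


# ---------------------------------------------------------------------------
# oracle / reference backends
# ---------------------------------------------------------------------------

def oracle_localizer(image: Optional[np.ndarray],
                     labels: Sequence[ImprintLabel]) -> list[TextRegion]:
    """Ground-truth localizer: returns every label box with score 1."""
    return [TextRegion(bbox=tuple(l.bbox), score=1.0) for l in labels]


def _match_label(region: TextRegion, labels: Sequence[ImprintLabel],
                 threshold: float = 0.5) -> Optional[ImprintLabel]:
    best, best_iou = None, 0.0
    for label in labels:
        value = iou(region.bbox, tuple(label.bbox))
        if value > best_iou:
            best, best_iou = label, value
    return best if best_iou >= threshold else None


def oracle_extractor(image: Optional[np.ndarray], region: TextRegion,
                     labels: Sequence[ImprintLabel]) -> ExtractedText:
    """Ground-truth OCR: returns the stored text of the label the region
    overlaps (IoU ≥ 0.5); an unmatched region reads as empty text."""
    label = _match_label(region, labels)
    return ExtractedText(text=label.text if label else "", region=region)


#: Visually confusable character substitutions (OCR-style errors).
CONFUSABLE = {
    "0": "O", "O": "0", "1": "I", "I": "1", "l": "1", "2": "Z", "Z": "2",
    "3": "E", "E": "3", "4": "A", "A": "4", "5": "S", "S": "5", "6": "G",
    "G": "6", "7": "T", "T": "7", "8": "B", "B": "8", "9": "g", "g": "9",
}


def corrupt_main_text(text: str, char_error_rate: float,
                      rng: np.random.Generator) -> str:
    """Corrupt the *main* part of a composed imprint with confusable
    substitutions at the given per-character rate, leaving any accompanying
    signal word (and separator) intact."""
    split = taxonomy.split_signal_prefix(text)
    if split is None:
        head, main = "", text
    else:
        main = split[2]
        head = text[: len(text) - len(main)]
    corrupted = []
    for ch in main:
        if ch in CONFUSABLE and rng.random() < char_error_rate:
            corrupted.append(CONFUSABLE[ch])
        else:
            corrupted.append(ch)
    return head + "".join(corrupted)


def noisy_extractor(image: Optional[np.ndarray], region: TextRegion,
                    labels: Sequence[ImprintLabel], char_error_rate: float,
                    rng: np.random.Generator | int | None = None) -> ExtractedText:
    """OCR double with character noise restricted to the main text."""
    rng = np.random.default_rng(rng)
    label = _match_label(region, labels)
    if label is None:
        return ExtractedText(text="", region=region)
    return ExtractedText(text=corrupt_main_text(label.text, char_error_rate, rng),
                         region=region)


# --- rule-based reference analyzer -----------------------------------------

_EMAIL_RE = re.compile(r"^\S+@\S+\.\S+$")
_PHONE_RES = (
    re.compile(r"^\d{3}[-.]\d{3}[-.]\d{4}$"),
    re.compile(r"^\(\d{3}\) \d{3}-\d{4}$"),
    re.compile(r"^\+\d{1,3}( \d{3}){2,3}( \d{4})?$"),
    re.compile(r"^\+1 \d{3} \d{3} \d{4}$"),
)
_DATE_RES = (
    re.compile(r"^\d{2}[-/.]\d{2}[-/.]\d{4}$"),
    re.compile(r"^\d{4}[-/.]\d{2}[-/.]\d{2}$"),
    re.compile(r"^\d{1,2} [A-Z][a-z]{2} \d{4}$"),
)
_IDENTIFIER_RES = (
    re.compile(r"^\d{4}\.\d{4}$"),
    re.compile(r"^\d{3}-\d{2}-\d{4}$"),
    re.compile(r"^\d{5,}$"),
    re.compile(r"^\d{2}-\d{3}-\d{3}$"),
)
_STREET_SUFFIXES = ("St", "Ave", "Dr", "Ln", "Blvd", "Rd", "Broadway")
_STATE_ZIP_RE = re.compile(r", [A-Z]{2} \d{5}")
_GENDER_FORMS = {"m", "f", "d", "[m]", "[f]", "[d]", "male", "female", "diverse"}
_MARKER_TOKENS = set(lex.MARKERS)


def _classify_bare(main: str) -> str:
    """Pattern rules for a text with no recognized signal-word prefix."""
    t = main.strip()
    if not t:
        return "non-phi"
    if _EMAIL_RE.match(t):
        return "email"
    if any(r.match(t) for r in _PHONE_RES):
        return "phone_nr"
    if any(r.match(t) for r in _DATE_RES):
        return "date"
    if t.lower() in _GENDER_FORMS:
        return "non-phi"
    if all(tok in _MARKER_TOKENS for tok in t.split()):
        return "non-phi"
    if t.isdigit() and len(t) <= 3:
        # short bare number: could be an age — placeholder rule says non-PHI
        return "non-phi"
    if any(r.match(t) for r in _IDENTIFIER_RES):
        return "identifier"
    if (_STATE_ZIP_RE.search(t)
            or any(f" {suf}" in f" {t}" and suf in t.split(",")[0].split()
                   for suf in _STREET_SUFFIXES)
            or any(t.endswith(c) for c in lex.COUNTRIES)):
        return "address"
    return "non-phi"


def classify_text(text: str, identifier_scope: str = "all") -> tuple[str, str]:
    """Classify one imprint text into the analyzer vocabulary.

    Returns ``(type, reason)``. Signal-word prefixes take precedence (they
    survive OCR noise confined to the main text); bare texts fall back to
    per-category patterns; placeholder-only inputs ("Age:", a bare small
    number) are non-PHI.
    """
    stripped = text.strip()
    if not stripped:
        return "non-phi", "empty text"
    split = taxonomy.split_signal_prefix(stripped)
    if split is not None:
        cat_id, word, main = split
        if not main.strip():
            return "non-phi", f"placeholder '{word}' without a value"
        if cat_id == "identifier":
            if (identifier_scope == "patient_only"
                    and word in taxonomy.STUDY_IDENTIFIER_SIGNALS):
                return "non-phi", (f"'{word}' is a study/image identifier, "
                                   "excluded from PHI under patient_only scope")
            return "identifier", f"signal word '{word}' marks an identifier"
        if taxonomy.is_phi(cat_id):
            return cat_id, f"signal word '{word}' marks PHI category {cat_id}"
        return "non-phi", f"signal word '{word}' marks non-PHI category {cat_id}"
    bare = _classify_bare(stripped)
    if bare == "non-phi":
        return bare, "no PHI pattern recognized"
    return bare, f"text shape matches {bare} pattern"


def reference_analyzer(texts: Sequence[str],
                       identifier_scope: str = "all") -> list[AnalysisResult]:
    """Deterministic rule-based analyzer over the taxonomy signal words and
    per-category patterns; emits one result per input text."""
    results = []
    for text in texts:
        type_, reason = classify_text(text, identifier_scope)
        results.append(AnalysisResult(type=type_, raw_text=text,
                                      reason=reason, language="en"))
    return results


class OracleLocalizer:
    def __call__(self, image, context):
        return oracle_localizer(image, context or [])


class OracleExtractor:
    def __call__(self, image, region, context):
        return oracle_extractor(image, region, context or [])


class NoisyExtractor:
    """OCR double with confusable-character noise at a fixed rate."""

    def __init__(self, char_error_rate: float, seed: int | None = 0):
        self.char_error_rate = char_error_rate
        self._rng = np.random.default_rng(seed)

    def __call__(self, image, region, context):
        return noisy_extractor(image, region, context or [],
                               self.char_error_rate, self._rng)


class ReferenceAnalyzer:
    def __call__(self, texts, options: PipelineOptions):
        return reference_analyzer(texts, options.identifier_scope)


class JointOracleOcr:
    """Joint localize-and-extract oracle (the setup2 backend double)."""

    def __call__(self, image, context):
        labels = context or []
        return [(TextRegion(bbox=tuple(l.bbox), score=1.0),
                 ExtractedText(text=l.text,
                               region=TextRegion(bbox=tuple(l.bbox))))
                for l in labels]


class OracleVisionAnalyzer:
    """Vision-analyzer double: reads ground-truth text under each crop (or
    the whole image) and applies the reference rules. Crops are analyzed in
    isolation — one request per crop — matching the latency profile of a
    real vision model in that wiring."""

    def analyze_crop(self, image, region, context, options: PipelineOptions):
        label = _match_label(region, context or [])
        text = label.text if label else ""
        return reference_analyzer([text], options.identifier_scope)[0]

    def analyze_image(self, image, context, options: PipelineOptions):
        texts = [l.text for l in (context or [])]
        return reference_analyzer(texts, options.identifier_scope)


def oracle_backends(noisy_char_error_rate: float | None = None,
                    seed: int | None = 0) -> Backends:
    """The full deterministic backend set used for offline benchmarking."""
    extractor = (OracleExtractor() if noisy_char_error_rate is None
                 else NoisyExtractor(noisy_char_error_rate, seed))
    return Backends(localizer=OracleLocalizer(), extractor=extractor,
                    analyzer=ReferenceAnalyzer(), joint_ocr=JointOracleOcr(),
                    vision_analyzer=OracleVisionAnalyzer())


# ---------------------------------------------------------------------------
# prompt construction and structured output
# ---------------------------------------------------------------------------

_SCOPE_CLAUSE = (
    "Study-, series- and image-related identifiers (for example Study ID, "
    "Series No, Image ID, Accession No) are NOT considered PHI; only "
    "identifiers of the patient are.\n\n")


def build_analysis_prompt(mode: str = "text",
                          options: PipelineOptions | None = None
                          ) -> tuple[str, dict]:
    """Render the system prompt and structured-output schema for an
    LLM-backed analyzer.

    ``mode`` is ``text`` (list of extracted texts), ``crops`` (one image
    crop per request) or ``end_to_end`` (a whole image). The prompt embeds
    the taxonomy definitions, the aggregated-context instruction, few-shot
    ambiguity examples and the strict output schema; it is byte-identical
    for identical options.
    """
    if mode not in ("text", "crops", "end_to_end"):
        raise ConfigError(f"unknown prompt mode {mode!r}")
    options = options or PipelineOptions()
    cats = taxonomy.list_categories()
    phi_defs = "\n".join(f"- {c.id}: {c.description}" for c in cats if c.is_phi)
    nonphi_defs = "\n".join(f"- {c.id}: {c.description}"
                            for c in cats if not c.is_phi)
    schema = json.dumps(AnalysisResult.model_json_schema(),
                        indent=2, sort_keys=True)
    scope = _SCOPE_CLAUSE if options.identifier_scope == "patient_only" else ""
    template_name = ("system_analysis.txt" if mode == "text"
                     else "system_vision.txt")
    template = (resources.files("phimprint") / "templates"
                / template_name).read_text()
    payload = "a cropped text region from a medical image" if mode == "crops" \
        else "a full medical image"
    prompt = template.format(phi_definitions=phi_defs,
                             nonphi_definitions=nonphi_defs,
                             scope_clause=scope, schema=schema,
                             payload=payload)
    return prompt, AnalysisResult.model_json_schema()


def parse_structured_output(raw: str) -> list[AnalysisResult]:
    """Validate an analyzer response against the output contract.

    Accepts a JSON list of records or ``{"results": [...]}``. Invalid JSON,
    a missing mandatory field or an out-of-vocabulary ``type`` raises
    :class:`StructuredOutputError`; an empty list is a valid empty result.
    """
    try:
        payload = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise StructuredOutputError(f"invalid JSON: {exc.msg}") from exc
    if isinstance(payload, dict) and "results" in payload:
        payload = payload["results"]
    if not isinstance(payload, list):
        raise StructuredOutputError(
            f"expected a list of records, got {type(payload).__name__}")
    results = []
    for i, record in enumerate(payload):
        try:
            results.append(AnalysisResult(**record))
        except (TypeError, ValidationError) as exc:
            raise StructuredOutputError(f"record {i}: {exc}") from exc
    return results


# ---------------------------------------------------------------------------
# pipeline execution
# ---------------------------------------------------------------------------

def run_pipeline(image: Optional[np.ndarray], setup: SetupId | str,
                 backends: Backends,
                 options: PipelineOptions | None = None,
                 context: Optional[Sequence[ImprintLabel]] = None,
                 image_id: str = "") -> PipelineOutput:
    """Process one image through the configured setup.

    ``context`` carries the image's ground-truth labels; only the oracle and
    noise test doubles read it. Backend exceptions are caught and recorded
    on the output (``failed=True``), never raised past the pipeline.
    """
    setup = SetupId(setup)
    options = options or PipelineOptions()
    validate_backends(setup, backends)
    out = PipelineOutput(image_id=image_id, setup=setup)
    try:
        if setup in (SetupId.setup1, SetupId.setup3):
            regions = backends.localizer(image, context)
            if setup is SetupId.setup1:
                texts = [backends.extractor(image, r, context) for r in regions]
                analyses = backends.analyzer([t.text for t in texts], options)
                out.counters.requests += 1
                out.items = [PipelineItem(analysis=a, region=r, text=t)
                             for r, t, a in zip(regions, texts, analyses)]
            else:
                items = []
                for region in regions:
                    analysis = backends.vision_analyzer.analyze_crop(
                        image, region, context, options)
                    out.counters.requests += 1
                    items.append(PipelineItem(analysis=analysis, region=region))
                out.items = items
        elif setup is SetupId.setup2:
            pairs = backends.joint_ocr(image, context)
            analyses = backends.analyzer([t.text for _, t in pairs], options)
            out.counters.requests += 1
            out.items = [PipelineItem(analysis=a, region=r, text=t)
                         for (r, t), a in zip(pairs, analyses)]
        else:  # setup4: end-to-end, no coordinates
            analyses = backends.vision_analyzer.analyze_image(
                image, context, options)
            out.counters.requests += 1
            out.items = [PipelineItem(analysis=a) for a in analyses]
    except Exception as exc:  # failure isolation: record, never re-raise
        out.items = []
        out.failed = True
        out.failure_reason = f"{type(exc).__name__}: {exc}"
    return out


def run_batch(records: Mapping[str, Mapping], setup: SetupId | str,
              backends: Backends,
              options: PipelineOptions | None = None) -> dict[str, PipelineOutput]:
    """Run the pipeline over a loaded dataset (id → record with ``labels``
    and optionally ``pixels``); one output per image, failures isolated."""
    setup = SetupId(setup)
    validate_backends(setup, backends)  # configuration errors surface up front
    outputs = {}
    for image_id, record in records.items():
        outputs[image_id] = run_pipeline(
            record.get("pixels"), setup, backends, options,
            context=record.get("labels"), image_id=image_id)
    return outputs


def error_rate(outputs: Mapping[str, PipelineOutput]) -> float:
    """Fraction of images whose processing failed."""
    if not outputs:
        return 0.0
    return sum(o.failed for o in outputs.values()) / len(outputs)


# ---------------------------------------------------------------------------
# category mapping and serialization
# ---------------------------------------------------------------------------

def category_to_type(sub_class: str) -> str:
    """Map a taxonomy category into the 8-value analyzer vocabulary: PHI
    categories map to themselves, non-PHI categories to ``non-phi``."""
    return sub_class if taxonomy.is_phi(sub_class) else "non-phi"


def write_predictions(outputs: Mapping[str, PipelineOutput], path) -> None:
    """Serialize a batch as JSON-lines, one record per image."""
    from pathlib import Path
    lines = [json.dumps(outputs[k].to_dict()) for k in sorted(outputs)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_predictions(path) -> dict[str, PipelineOutput]:
    from pathlib import Path
    outputs = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        out = PipelineOutput.from_dict(json.loads(line))
        outputs[out.image_id] = out
    return outputs
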