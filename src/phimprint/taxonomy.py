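"""Imprint taxonomy: the 16 burned-in text categories and their content grammars.

Six categories are Protected Health Information (PHI) under the HIPAA
identifier rules — dates tied to an individual, identifiers, patient names,
addresses, phone numbers, emails. The remaining ten (age below 90, gender,
height, weight, exam type, hospital, anatomical markers, scanner info,
diagnosis, imaging personnel) are non-PHI but routinely burned into medical
images, so a detector must tell them apart.

Each category carries a pool of *signal words*: the accompanying text that a
real imprint prefixes to its payload, e.g. ``DOB`` before a birth date or
``Patient ID`` before a record number. An imprint is composed as
``<accompanying><separator><main>``, and the accompanying part may be
omitted to exercise a downstream analyzer's ability to infer the category
from the main text alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
import yaml

from . import _lexicons as lex
from .errors import InvalidContentError, UnknownCategoryError

__all__ = [
    "ImprintCategory",
    "ImprintContent",
    "SEPARATORS",
    "PHI_CATEGORY_IDS",
    "STUDY_IDENTIFIER_SIGNALS",
    "list_categories",
    "get_category",
    "is_phi",
    "generate_content",
    "compose_imprint_text",
    "split_signal_prefix",
    "taxonomy_to_yaml",
    "taxonomy_from_yaml",
]

#: Separator pool between accompanying and main text.
SEPARATORS = (": ", " ", ", ")

#: Date rendering formats sampled by the date grammar.
DATE_FORMATS = ("%d-%m-%Y", "%m/%d/%Y", "%Y-%m-%d", "%d %b %Y")


@dataclass(frozen=True)
class ImprintCategory:
    """One taxonomy entry: id, PHI flag, signal-word pool, human description."""

    id: str
    is_phi: bool
    signal_words: tuple[str, ...]
    description: str


@dataclass(frozen=True)
class ImprintContent:
    """A generated imprint before rendering: category, optional accompanying
    signal word, separator, and the non-empty main payload."""

    category: str
    accompanying: Optional[str]
    separator: str
    main: str


# Signal words whose identifier payload refers to the study/series/image
# rather than the patient; an analyzer configured with
# identifier_scope="patient_only" treats these as non-PHI.
STUDY_IDENTIFIER_SIGNALS = ("Study ID", "Series No", "Image ID", "Accession No")

_PATIENT_IDENTIFIER_SIGNALS = ("Patient ID", "MRN", "SSN", "Insurance No", "Record No")

_CATEGORIES: tuple[ImprintCategory, ...] = (
    ImprintCategory(
        "date", True,
        ("DOB", "Date of Birth", "Study Date", "Admission Date",
         "Discharge Date", "Scan Date", "Date"),
        "All elements of dates related to an individual (birth, admission, "
        "discharge) and ages of 90 or over.",
    ),
    ImprintCategory(
        "identifier", True,
        _PATIENT_IDENTIFIER_SIGNALS + STUDY_IDENTIFIER_SIGNALS,
        "Identifiers related to an individual: patient id, insurance number, "
        "social security number, medical record number.",
    ),
    ImprintCategory(
        "patient_name", True,
        ("Patient Name", "Pat. Name", "Patient", "Name"),
        "Full name or initials of the patient.",
    ),
    ImprintCategory(
        "address", True,
        ("Address", "Addr", "Home Address"),
        "Partial or full patient address: street, city, state, postal code, country.",
    ),
    ImprintCategory(
        "phone_nr", True,
        ("Contact", "Phone", "Tel", "Mobile"),
        "Personal telephone number.",
    ),
    ImprintCategory(
        "email", True,
        ("Email", "E-mail", "Mail"),
        "Personal email address.",
    ),
    ImprintCategory(
        "age_lt90", False,
        ("Age",),
        "Age below 90 years.",
    ),
    ImprintCategory(
        "gender", False,
        ("Gender", "Sex"),
        "Gender of the individual or its abbreviation (m/f/d).",
    ),
    ImprintCategory(
        "height", False,
        ("Height", "Ht"),
        "Height measurement of the patient.",
    ),
    ImprintCategory(
        "weight", False,
        ("Weight", "Wt"),
        "Weight measurement of the patient.",
    ),
    ImprintCategory(
        "exam_type", False,
        ("Exam", "Examination", "Procedure"),
        "Type of scan or procedure performed.",
    ),
    ImprintCategory(
        "hospital", False,
        ("Hospital", "Facility", "Clinic", "Site"),
        "General information about the hospital or imaging facility.",
    ),
    ImprintCategory(
        "marker", False,
        (),
        "Anatomical markers or points of interest (L, R, POST, ANT, ...); "
        "rendered without accompanying text.",
    ),
    ImprintCategory(
        "scanner", False,
        ("Scanner", "Station", "Device"),
        "Scanner type and acquisition settings.",
    ),
    ImprintCategory(
        "diagnosis", False,
        ("Diagnosis", "Dx", "Indication", "Impression", "Comment"),
        "General diagnosis, comments or indications made by doctors.",
    ),
    ImprintCategory(
        "imaging_personnel", False,
        ("Radiologist", "Technologist", "Operator", "Referring Physician",
         "Indicated by", "Performed by", "Read by"),
        "Medical staff involved in the scan: radiologist, technician, "
        "operator, referring physician.",
    ),
)

_BY_ID: dict[str, ImprintCategory] = {c.id: c for c in _CATEGORIES}

#: The six PHI category ids, in taxonomy order.
PHI_CATEGORY_IDS = tuple(c.id for c in _CATEGORIES if c.is_phi)


def list_categories() -> list[ImprintCategory]:
    """Return all 16 registered categories in stable taxonomy order."""
    return list(_CATEGORIES)


def get_category(category_id: str) -> ImprintCategory:
    try:
        return _BY_ID[category_id]
    except KeyError:
        raise UnknownCategoryError(category_id) from None


def is_phi(category_id: str) -> bool:
    """True iff ``category_id`` is one of the six PHI categories."""
    return get_category(category_id).is_phi


# ---------------------------------------------------------------------------
# content grammars
# ---------------------------------------------------------------------------

def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _digits(rng: np.random.Generator, n: int) -> str:
    return "".join(str(int(d)) for d in rng.integers(0, 10, size=n))


_MONTH_ABBR = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


def _gen_date(rng):
    y = int(rng.integers(1950, 2025))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    fmt = _pick(rng, DATE_FORMATS)
    if fmt == "%d %b %Y":
        return f"{d:02d} {_MONTH_ABBR[m - 1]} {y}"
    return (fmt.replace("%d", f"{d:02d}")
               .replace("%m", f"{m:02d}")
               .replace("%Y", f"{y}"))


def _gen_identifier(rng):
    # digit/dot/dash sequences: patient id, SSN-like, MRN, insurance number
    kind = int(rng.integers(4))
    if kind == 0:
        return f"{_digits(rng, 4)}.{_digits(rng, 4)}"
    if kind == 1:
        return f"{_digits(rng, 3)}-{_digits(rng, 2)}-{_digits(rng, 4)}"
    if kind == 2:
        return _digits(rng, int(rng.integers(6, 10)))
    return f"{_digits(rng, 2)}-{_digits(rng, 3)}-{_digits(rng, 3)}"


def _gen_name(rng):
    first = _pick(rng, lex.FIRST_NAMES)
    last = _pick(rng, lex.LAST_NAMES)
    if rng.random() < 0.1:  # initialed form, e.g. "J. Doe"
        return f"{first[0]}. {last}"
    return f"{first} {last}"


def _gen_address(rng):
    number = int(rng.integers(1, 1000))
    street = _pick(rng, lex.STREET_NAMES)
    city, state = _pick(rng, lex.CITIES_STATES)
    postal = _digits(rng, 5)
    country = _pick(rng, lex.COUNTRIES)
    variant = int(rng.integers(4))
    if variant == 0:  # full
        return f"{number} {street}, {city}, {state} {postal}, {country}"
    if variant == 1:  # street + city
        return f"{number} {street}, {city}"
    if variant == 2:  # city, state, postal
        return f"{city}, {state} {postal}"
    return f"{number} {street}"


def _gen_phone(rng):
    variant = int(rng.integers(4))
    a, b, c = _digits(rng, 3), _digits(rng, 3), _digits(rng, 4)
    if variant == 0:
        return f"{a}-{b}-{c}"
    if variant == 1:
        return f"({a}) {b}-{c}"
    if variant == 2:
        return f"+1 {a} {b} {c}"
    return f"{a}.{b}.{c}"


def _gen_email(rng):
    first = _pick(rng, lex.FIRST_NAMES).lower()
    last = _pick(rng, lex.LAST_NAMES).lower()
    domain = _pick(rng, lex.EMAIL_DOMAINS)
    sep = _pick(rng, (".", "_", ""))
    return f"{first}{sep}{last}@{domain}"


def _gen_age(rng):
    return str(int(rng.integers(0, 90)))


_GENDER_FORMS = ("M", "F", "D", "[M]", "[F]", "[D]", "m", "f", "d",
                 "Male", "Female", "Diverse")


def _gen_gender(rng):
    return _pick(rng, _GENDER_FORMS)


def _gen_height(rng):
    if rng.random() < 0.8:
        return f"{int(rng.integers(140, 200))} cm"
    return f"{int(rng.integers(55, 79))} in"


def _gen_weight(rng):
    if rng.random() < 0.8:
        return f"{int(rng.integers(40, 150))} kg"
    return f"{int(rng.integers(90, 330))} lb"


def _gen_marker(rng):
    n = int(rng.integers(1, 4))
    idx = rng.choice(len(lex.MARKERS), size=n, replace=False)
    return " ".join(lex.MARKERS[int(i)] for i in idx)


def _gen_personnel(rng):
    role = _pick(rng, lex.PERSONNEL_ROLES)
    name = f"{_pick(rng, lex.FIRST_NAMES)} {_pick(rng, lex.LAST_NAMES)}"
    return f"{role} {name}".strip()


_GRAMMARS: dict[str, Callable[[np.random.Generator], str]] = {
    "date": _gen_date,
    "identifier": _gen_identifier,
    "patient_name": _gen_name,
    "address": _gen_address,
    "phone_nr": _gen_phone,
    "email": _gen_email,
    "age_lt90": _gen_age,
    "gender": _gen_gender,
    "height": _gen_height,
    "weight": _gen_weight,
    "exam_type": lambda rng: _pick(rng, lex.EXAM_TYPES),
    "hospital": lambda rng: _pick(rng, lex.HOSPITALS),
    "marker": _gen_marker,
    "scanner": lambda rng: _pick(rng, lex.SCANNERS),
    "diagnosis": lambda rng: _pick(rng, lex.DIAGNOSES),
    "imaging_personnel": _gen_personnel,
}


def generate_content(category_id: str,
                     rng: np.random.Generator | int | None = None,
                     omit_accompanying_prob: float = 0.2) -> ImprintContent:
    """Draw one imprint for ``category_id``.

    The main text comes from the category grammar; the accompanying text is a
    signal word from the category pool, omitted with probability
    ``omit_accompanying_prob`` (always omitted for categories with an empty
    pool, such as anatomical markers). Reproducible for a fixed ``rng`` state.
    """
    cat = get_category(category_id)
    if not 0.0 <= omit_accompanying_prob <= 1.0:
        raise InvalidContentError(
            f"omit_accompanying_prob must be in [0, 1], got {omit_accompanying_prob}")
    rng = np.random.default_rng(rng)
    main = _GRAMMARS[cat.id](rng)
    accompanying: Optional[str] = None
    separator = _pick(rng, SEPARATORS)
    if cat.signal_words and rng.random() >= omit_accompanying_prob:
        accompanying = _pick(rng, cat.signal_words)
    return ImprintContent(category=cat.id, accompanying=accompanying,
                          separator=separator, main=main)


def compose_imprint_text(content: ImprintContent) -> str:
    """Render ``<accompanying><separator><main>``, or ``main`` alone."""
    if not content.main:
        raise InvalidContentError("imprint main text must be non-empty")
    text = (content.main if content.accompanying is None
            else f"{content.accompanying}{content.separator}{content.main}")
    if "\n" in text or "\r" in text:
        raise InvalidContentError("imprint text must be a single line")
    return text


# Longest-first signal index shared with the rule-based analyzer and the
# noisy-extraction test double: maps a composed text back to (category,
# signal word, main part) when a known signal prefix is present.
_SIGNAL_INDEX: list[tuple[str, str]] = sorted(
    ((word, cat.id) for cat in _CATEGORIES for word in cat.signal_words),
    key=lambda t: len(t[0]), reverse=True)


def split_signal_prefix(text: str) -> tuple[str, str, str] | None:
    """If ``text`` starts with a known signal word plus separator, return
    ``(category_id, signal_word, main)``; otherwise None.

    Matching is longest-first so that e.g. a study-date signal wins over a
    bare exam signal that happens to be its prefix.
    """
    for word, cat_id in _SIGNAL_INDEX:
        if text == word:
            return cat_id, word, ""
        if text.startswith(word):
            rest = text[len(word):]
            for sep in SEPARATORS + (":", ",", ";", " - "):
                if rest.startswith(sep):
                    return cat_id, word, rest[len(sep):]
    return None


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def taxonomy_to_yaml(categories: list[ImprintCategory] | None = None) -> str:
    """Serialize the taxonomy (default: the registered one) to YAML."""
    cats = categories if categories is not None else list_categories()
    payload = [{**asdict(c), "signal_words": list(c.signal_words)} for c in cats]
    return yaml.safe_dump(payload, sort_keys=False)


def taxonomy_from_yaml(text: str) -> list[ImprintCategory]:
    """Load a taxonomy from YAML produced by :func:`taxonomy_to_yaml`."""
    payload = yaml.safe_load(text)
    return [ImprintCategory(id=d["id"], is_phi=bool(d["is_phi"]),
                            signal_words=tuple(d.get("signal_words", ())),
                            description=d.get("description", ""))
            for d in payload]
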