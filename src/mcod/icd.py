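"""ICD-10 code parsing and assignment to underlying-cause categories.

Mortality tabulations stratify deaths by broad underlying-cause groups
defined as ranges of three-character ICD-10 blocks, e.g. ischemic heart
disease is I20-I25.  Four-character subcodes (I21.9) are classified by
their three-character block, since the groups are defined at block level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ICDRange",
    "CauseCategory",
    "CategoryScheme",
    "DEFAULT_CATEGORIES",
    "OTHER",
    "parse_icd_code",
    "parse_icd_range",
    "classify_underlying_cause",
    "load_category_scheme",
]

#: category name for every code not claimed by a named category
OTHER = "other"

# letter + two digits, optionally a subcode of 1-2 alphanumerics, with or
# without the separating dot (US multiple-cause files omit it: "I219")
_CODE_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.?([A-Za-z0-9]{1,2}))?$")

_DASHES = ("–", "—", "-")  # en-dash as printed, em-dash, hyphen


class ICDParseError(ValueError):
    """Raised for a malformed ICD-10 code or range."""


def parse_icd_code(text: str) -> tuple[str, int]:
    """Parse an ICD-10 code into its three-character block ``(letter, number)``.

    >>> parse_icd_code("I21.9")
    ('I', 21)
    """
    m = _CODE_RE.match(text.strip())
    if m is None:
        raise ICDParseError(f"malformed ICD-10 code: {text!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class ICDRange:
    """Inclusive range of three-character ICD-10 blocks."""

    start: tuple[str, int]
    end: tuple[str, int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ICDParseError(
                f"inverted ICD range: {_fmt(self.start)} > {_fmt(self.end)}"
            )

    def __contains__(self, code: str | tuple[str, int]) -> bool:
        if isinstance(code, str):
            code = parse_icd_code(code)
        return self.start <= code <= self.end

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        if self.start == self.end:
            return _fmt(self.start)
        return f"{_fmt(self.start)}-{_fmt(self.end)}"


def _fmt(block: tuple[str, int]) -> str:
    return f"{block[0]}{block[1]:02d}"


def parse_icd_range(text: str) -> ICDRange:
    """Parse ``"I20-I25"`` (hyphen or en-dash) or a single code ``"G20"``.

    A single code yields a degenerate range (start == end); inverted bounds
    raise :class:`ICDParseError`.
    """
    s = text.strip()
    for dash in _DASHES:
        if dash in s:
            lo, _, hi = s.partition(dash)
            return ICDRange(parse_icd_code(lo), parse_icd_code(hi))
    block = parse_icd_code(s)
    return ICDRange(block, block)


@dataclass(frozen=True)
class CauseCategory:
    """A named underlying-cause stratum: a set of ICD-10 block ranges.

    The catch-all ``other`` category has no ranges; it is the complement of
    the named categories.
    """

    name: str
    ranges: tuple[ICDRange, ...] = field(default_factory=tuple)

    def matches(self, block: tuple[str, int]) -> bool:
        return any(block in r for r in self.ranges)


class CategoryScheme:
    """An ordered, disjoint set of cause categories plus the ``other`` complement.

    The default scheme holds the six strata used for Parkinson's disease
    mortality: ischemic heart disease (I20-I25), malignant neoplasm (C00-C75),
    cerebrovascular disease (I60-I69), pneumonia (J10-J18), Parkinson's
    disease (G20), and ``other``.
    """

    def __init__(self, categories: Sequence[CauseCategory]):
        named = [c for c in categories if c.name != OTHER]
        self._validate_disjoint(named)
        self.categories: tuple[CauseCategory, ...] = tuple(named) + (
            CauseCategory(OTHER),
        )

    @staticmethod
    def _validate_disjoint(categories: Iterable[CauseCategory]) -> None:
        cats = list(categories)
        for letter_ord in range(ord("A"), ord("Z") + 1):
            for num in range(100):
                block = (chr(letter_ord), num)
                owners = [c.name for c in cats if c.matches(block)]
                if len(owners) > 1:
                    raise ValueError(
                        f"categories overlap at {_fmt(block)}: {owners}"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    def classify(self, code: str) -> str:
        """Return the unique category name owning ``code`` (totality holds:
        every well-formed code maps somewhere, falling back to ``other``)."""
        block = parse_icd_code(code)
        for cat in self.categories:
            if cat.name != OTHER and cat.matches(block):
                return cat.name
        return OTHER


DEFAULT_CATEGORIES = CategoryScheme(
    [
        CauseCategory("ischemic_heart_disease", (parse_icd_range("I20-I25"),)),
        CauseCategory("malignant_neoplasm", (parse_icd_range("C00-C75"),)),
        CauseCategory("cerebrovascular_disease", (parse_icd_range("I60-I69"),)),
        CauseCategory("pneumonia", (parse_icd_range("J10-J18"),)),
        CauseCategory("parkinsons_disease", (parse_icd_range("G20"),)),
    ]
)

#: category name coding G20 in the default scheme
PD_CATEGORY = "parkinsons_disease"


def classify_underlying_cause(
    code: str, scheme: CategoryScheme = DEFAULT_CATEGORIES
) -> str:
    """Assign an ICD-10 code to its underlying-cause category name."""
    return scheme.classify(code)


def load_category_scheme(path: str | Path) -> CategoryScheme:
    """Load a category scheme from a YAML mapping of name -> comma-separated
    ranges (``other`` may be listed with an empty value and is always implied).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"category config must be a mapping, got {type(raw).__name__}")
    cats = []
    for name, spec in raw.items():
        if name == OTHER:
            continue
        ranges = tuple(
            parse_icd_range(tok) for tok in str(spec or "").split(",") if tok.strip()
        )
        cats.append(CauseCategory(str(name), ranges))
    return CategoryScheme(cats)
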