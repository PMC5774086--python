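"""Parsing and formatting of scientific names, name usages and concept labels.

A *taxonomic name usage* is the mention of a latinized scientific name in
text, optionally trailed by a taxonomic status abbreviation::

    Heser stoevi Deltschev 2016, sp. n.

A *taxonomic concept label* pairs a Linnaean name with a reference to the
publication circumscribing the concept, joined by the keyword ``sec.``::

    Andropogon virginicus var. tenuispatheus sec. Blomquist (1948)

The grammar implemented here is deliberately small — it covers uninomial
(genus-rank), binomial and trinomial names with optional, possibly
parenthesized, authorship and year — and keeps authorship as an opaque
string.  Full nomenclatural-code validation is out of scope.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, replace

from .vocabulary import StatusClass, classify_status


class NameParseError(ValueError):
    """The string cannot be interpreted as a scientific name."""


class NotAConceptLabelError(ValueError):
    """The string lacks the ``sec.`` keyword of a concept label."""


#: Infraspecific rank markers accepted between epithets.
INFRASPECIFIC_MARKERS = ("var.", "subsp.", "ssp.", "subvar.", "f.", "forma")

_YEAR = re.compile(r"^\d{4}$")
_GENUS = re.compile(r"^[A-Z][a-zàâäéèêëíìîïóòôöúùûüç-]+$")
_EPITHET = re.compile(r"^[a-zàâäéèêëíìîïóòôöúùûüç][a-zàâäéèêëíìîïóòôöúùûüç-]*$")


@dataclass(frozen=True)
class ScientificName:
    """A structured latinized scientific name.

    ``year_comma`` records whether the printed form separates authorship and
    year with a comma ("Taylor, 2010" vs "Deltschev 2016") so formatting can
    reproduce the source string.
    """

    genus: str
    specific_epithet: str | None = None
    infraspecific_marker: str | None = None
    infraspecific_epithet: str | None = None
    authorship: str | None = None
    year: int | None = None
    parenthesized_authorship: bool = False
    year_comma: bool = False
    verbatim: str = ""

    def __post_init__(self):
        if self.infraspecific_epithet and not self.specific_epithet:
            raise ValueError("infraspecific epithet requires a specific epithet")
        if self.year is not None and not 1000 <= self.year <= 9999:
            raise ValueError("year must be a 4-digit integer")
        if not self.verbatim:
            object.__setattr__(self, "verbatim", format_name(self))


@dataclass(frozen=True)
class TaxonomicNameUsageParse:
    """A parsed name usage: the name plus an optional trailing status."""

    name: ScientificName
    status: StatusClass | None = None
    status_verbatim: str | None = None

    def __post_init__(self):
        if (self.status is None) != (self.status_verbatim is None):
            raise ValueError("status and status_verbatim must be set together")


@dataclass(frozen=True)
class TaxonomicConceptLabelParse:
    """A parsed concept label: name + the citation after ``sec.``."""

    name: ScientificName
    sec_reference: str
    verbatim: str = ""

    def __post_init__(self):
        if not self.sec_reference:
            raise ValueError("sec. reference must be non-empty")
        if not self.verbatim:
            object.__setattr__(
                self, "verbatim", f"{format_name(self.name)} sec. {self.sec_reference}"
            )


def _normalize(s: str) -> str:
    return re.sub(r"\s+", " ", unicodedata.normalize("NFC", s)).strip()


def parse_scientific_name(s: str) -> ScientificName:
    """Parse a latinized scientific name string.

    Grammar: ``Genus [epithet] [marker epithet] [authorship [,] year |
    (authorship[, year])]``.  Raises :class:`NameParseError` when the head
    token is not a capitalized latinized word, or when the string is a
    concept label (contains the ``sec.`` keyword) rather than a bare name.
    """
    verbatim = _normalize(s)
    if not verbatim:
        raise NameParseError("empty name string")
    tokens = verbatim.split(" ")
    if "sec." in tokens:
        raise NameParseError(
            "string contains the 'sec.' keyword; use parse_concept_label"
        )
    head = tokens[0].rstrip(",")
    if not _GENUS.match(head):
        raise NameParseError(f"no capitalized latinized head token in {s!r}")
    genus = head
    i = 1
    specific = infraspec = marker = None
    if i < len(tokens) and _EPITHET.match(tokens[i]):
        specific = tokens[i]
        i += 1
    if specific and i + 1 < len(tokens) and tokens[i] in INFRASPECIFIC_MARKERS \
            and _EPITHET.match(tokens[i + 1]):
        marker, infraspec = tokens[i], tokens[i + 1]
        i += 2

    rest = tokens[i:]
    authorship = None
    year = None
    parenthesized = False
    year_comma = False
    if rest:
        tail = " ".join(rest)
        if tail.startswith("(") and tail.endswith(")"):
            parenthesized = True
            tail = tail[1:-1].strip()
        authorship, year, year_comma = _split_year(tail)
        if authorship == "":
            authorship = None
    return ScientificName(
        genus=genus,
        specific_epithet=specific,
        infraspecific_marker=marker,
        infraspecific_epithet=infraspec,
        authorship=authorship,
        year=year,
        parenthesized_authorship=parenthesized,
        year_comma=year_comma,
        verbatim=verbatim,
    )


def _split_year(tail: str) -> tuple[str | None, int | None, bool]:
    """Split an optional trailing 4-digit year off an authorship string."""
    parts = tail.split(" ")
    if parts and _YEAR.match(parts[-1]):
        year = int(parts[-1])
        head = " ".join(parts[:-1])
        comma = head.endswith(",")
        return head.rstrip(",").strip() or None, year, comma
    return tail or None, None, False


def format_name(n: ScientificName) -> str:
    """Render a structured name back to its one-line printed form.

    Inverse of :func:`parse_scientific_name` on fields: ``parse(format(n))``
    reproduces *n* field-wise (verbatim aside).
    """
    parts = [n.genus]
    if n.specific_epithet:
        parts.append(n.specific_epithet)
    if n.infraspecific_epithet:
        parts.append(n.infraspecific_marker or "subsp.")
        parts.append(n.infraspecific_epithet)
    auth = n.authorship or ""
    if n.year is not None:
        sep = ", " if n.year_comma else " "
        auth = f"{auth}{sep}{n.year}" if auth else str(n.year)
    if auth:
        parts.append(f"({auth})" if n.parenthesized_authorship else auth)
    return " ".join(parts)


#: Longest status phrase, in tokens, the usage splitter will look for.
_MAX_STATUS_TOKENS = 3


def parse_taxonomic_name_usage(s: str) -> TaxonomicNameUsageParse:
    """Parse a name usage, splitting a trailing taxonomic status if present.

    The status may be comma-delimited ("..., sp. n.") or plain
    whitespace-delimited; it is recognized by classification against the
    status vocabulary, so year/authorship tokens are never consumed.
    """
    text = _normalize(s)
    if not text:
        raise NameParseError("empty name usage string")

    # Comma-delimited tail first: the natural printed form.
    if "," in text:
        head, tail = text.rsplit(",", 1)
        tail = tail.strip()
        if tail and classify_status(tail) is not StatusClass.UNCLASSIFIED:
            return TaxonomicNameUsageParse(
                name=parse_scientific_name(head),
                status=classify_status(tail),
                status_verbatim=tail,
            )
    # Whitespace-delimited: probe the last 1..k tokens.
    tokens = text.split(" ")
    for k in range(min(_MAX_STATUS_TOKENS, len(tokens) - 1), 0, -1):
        tail = " ".join(tokens[-k:])
        if classify_status(tail) is not StatusClass.UNCLASSIFIED:
            return TaxonomicNameUsageParse(
                name=parse_scientific_name(" ".join(tokens[:-k])),
                status=classify_status(tail),
                status_verbatim=tail,
            )
    return TaxonomicNameUsageParse(name=parse_scientific_name(text))


def parse_concept_label(s: str) -> TaxonomicConceptLabelParse:
    """Parse a taxonomic concept label of the form ``<name> sec. <reference>``.

    The ``sec.`` keyword is matched case-sensitively as an exact token.
    Raises :class:`NotAConceptLabelError` when absent.
    """
    text = _normalize(s)
    tokens = text.split(" ")
    if "sec." not in tokens:
        raise NotAConceptLabelError(f"no 'sec.' keyword in {s!r}")
    idx = tokens.index("sec.")
    name_part = " ".join(tokens[:idx]).rstrip(",").strip()
    reference = " ".join(tokens[idx + 1:]).strip()
    if not reference:
        raise NotAConceptLabelError("empty reference after 'sec.'")
    if not name_part:
        raise NameParseError("empty name before 'sec.'")
    return TaxonomicConceptLabelParse(
        name=parse_scientific_name(name_part),
        sec_reference=reference,
        verbatim=text,
    )


def strip_verbatim(n: ScientificName) -> ScientificName:
    """Copy of *n* with verbatim recomputed from fields (canonical form)."""
    return replace(n, verbatim=format_name(n))
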