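"""Shared text front end: character cleanup, section selection, sentence split.

Angiography reports arrive as free text with hospital-specific section
headings and occasional interleaved Chinese text, decorative characters and
irregular spacing. All models operate on the findings-type and
impression-type sections only, after cleanup, one sentence at a time.

The cleanup keeps the punctuation that carries clinical meaning — in
particular ``> < % ( )`` so that severity quantifiers such as
``(all > 50%)`` survive intact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "clean_text",
    "segment_sections",
    "split_sentences",
    "prepare_report",
    "SectionedReport",
    "Sentence",
    "default_heading_aliases",
]

# Characters preserved by clean_text: letters, digits, space, and clinically
# meaningful punctuation. Everything else (CJK, decorations, control chars)
# is dropped.
_KEEP = re.compile(r"[^A-Za-z0-9 .,:;()%><\-/]+")


def clean_text(raw: str) -> str:
    """Remove CJK characters, special characters and extra spaces.

    Idempotent: applying it twice gives the same result. Runs of whitespace
    (including newlines) collapse to single spaces, so downstream stages see
    a single normalized line.
    """
    text = _KEEP.sub(" ", raw)
    text = re.sub(r"\s+", " ", text)
    return text.strip()


def default_heading_aliases() -> dict[str, list[str]]:
    """Heading alias table shipped with the package (both hospital styles)."""
    path = resources.files("stenoscan.data").joinpath("headings.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh)


#: Section kinds whose text feeds the models.
TARGET_KINDS = ("findings", "impression")


@dataclass
class SectionedReport:
    """A cleaned report segmented into named sections.

    ``target_text`` is the concatenation of the findings-type and
    impression-type sections in document order; if no heading was
    recognized it is the whole cleaned document.
    """

    report_id: str
    sections: dict[str, str] = field(default_factory=dict)
    target_text: str = ""


def _compile_heading_pattern(aliases: dict[str, list[str]]) -> re.Pattern:
    names = sorted((n for al in aliases.values() for n in al), key=len, reverse=True)
    alt = "|".join(re.escape(n) for n in names)
    return re.compile(rf"\b({alt})\s*:", re.IGNORECASE)


def segment_sections(
    cleaned: str,
    aliases: dict[str, list[str]] | None = None,
    report_id: str = "",
) -> SectionedReport:
    """Split a cleaned report at recognized headings and select target text.

    Headings are matched case-insensitively from a configurable alias table
    mapping section kind (e.g. ``findings``) to heading spellings. Text
    before the first heading, and reports with no recognized heading at all,
    fall back to the whole document as target text.
    """
    if aliases is None:
        aliases = default_heading_aliases()
    kind_of = {name.lower(): kind for kind, names in aliases.items() for name in names}
    pat = _compile_heading_pattern(aliases)
    matches = list(pat.finditer(cleaned))
    if not matches:
        return SectionedReport(report_id, {}, cleaned.strip())
    sections: dict[str, str] = {}
    order: list[tuple[str, str]] = []
    for i, m in enumerate(matches):
        start = m.end()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(cleaned)
        kind = kind_of[m.group(1).lower()]
        body = cleaned[start:end].strip()
        sections[m.group(1).lower()] = body
        order.append((kind, body))
    target = " ".join(body for kind, body in order if kind in TARGET_KINDS)
    return SectionedReport(report_id, sections, target.strip())


@dataclass(frozen=True)
class Sentence:
    """A sentence span with character offsets into the target text."""

    text: str
    start: int
    end: int


# Abbreviations whose trailing period must not end a sentence.
_PROTECTED = ("rt", "lt", "no", "dr", "vs", "e.g", "i.e")
_PROTECT_RE = re.compile(
    r"(?<!\w)(" + "|".join(re.escape(a) for a in _PROTECTED) + r")\.$",
    re.IGNORECASE,
)


def split_sentences(target_text: str) -> list[Sentence]:
    """Split target text on sentence-final periods.

    A period ends a sentence when followed by whitespace or end of text,
    unless it sits inside a decimal number or follows a protected
    abbreviation (``rt.``, ``lt.``, ...). Segment notation such as
    ``M1-2`` or ``P2-3`` contains no period and is never split.
    """
    sentences: list[Sentence] = []
    start = 0
    i = 0
    n = len(target_text)
    while i < n:
        ch = target_text[i]
        if ch == ".":
            nxt = target_text[i + 1] if i + 1 < n else " "
            prev = target_text[i - 1] if i > 0 else " "
            if nxt.isspace() or i + 1 == n:
                prefix = target_text[start : i + 1].rstrip()
                if not (prev.isdigit() and nxt.isdigit()) and not _PROTECT_RE.search(prefix):
                    seg = target_text[start : i + 1].strip()
                    if seg:
                        sentences.append(Sentence(seg, start, i + 1))
                    start = i + 1
        i += 1
    tail = target_text[start:].strip()
    if tail:
        sentences.append(Sentence(tail, start, n))
    return sentences


def prepare_report(
    raw_text: str,
    report_id: str = "",
    aliases: dict[str, list[str]] | None = None,
) -> tuple[SectionedReport, list[Sentence]]:
    """Full front end: clean, segment sections, split sentences."""
    cleaned = clean_text(raw_text)
    sectioned = segment_sections(cleaned, aliases=aliases, report_id=report_id)
    return sectioned, split_sentences(sectioned.target_text)
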