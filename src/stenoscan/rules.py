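"""Rule-based stenosis extractor.

A handcrafted, fully interpretable model: a lexicon of severity keywords,
artery name patterns with laterality markers, and negation cues is compiled
to regular expressions and applied sentence by sentence over the findings
and impression sections of a report, yielding an 11-artery binary label
vector.

Matching rules, in the order they run per sentence:

1. Locate artery mentions (longest pattern wins; overlaps are suppressed).
2. Resolve laterality: a side marker (right/rt, left/lt, bilateral/both)
   to the left of a mention governs it; a plural form ("...arteries")
   with no marker means bilateral; an artery-name-first clause ending in
   ", left" / ", right side" assigns that trailing side; a paired artery
   with no side information at all labels both sides (screening favors
   sensitivity over precision). "Vertebral basilar artery" expands to the
   whole vertebrobasilar set {LIVA, RIVA, BA}.
3. Polarity: a negation cue negates every mention from the cue to the end
   of the sentence, crossing conjoined enumerations; "but"/"however"/";"
   terminate the scope early.
4. Severity: a positive severity phrase outside any negation scope marks
   the sentence's affirmed mentions as >=50% ("(all > 50%)" distributes
   over a preceding list); otherwise sub-threshold phrases (mild, bare
   moderate, patent, normal) mark them <50%; otherwise severity is
   unstated and the mention never sets a label.

A report's label for an artery is 1 iff at least one affirmed >=50% mention
exists anywhere in the target sections; an affirmed lesion dominates a
negation of the same artery elsewhere in the report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .arteries import ARTERY_ORDER, ArteryId, LabelVector
from .preprocessing import SectionedReport, Sentence, split_sentences

__all__ = [
    "RuleSet",
    "ArteryMention",
    "CompiledMatcher",
    "compile_rules",
    "default_ruleset",
    "find_artery_mentions",
    "classify_polarity_severity",
    "extract_labels",
]


@dataclass
class RuleSet:
    """Editable lexicon behind the rule-based model.

    All pattern entries are regular expressions (matched case-insensitively,
    word-bounded where they start/end with word characters).
    """

    severity_positive: list[str]
    severity_negative: list[str]
    negation_cues: list[str]
    artery_families: list[dict]
    side_markers: dict[str, list[str]]
    scope_blockers: list[str] = field(default_factory=lambda: ["but", "however"])

    @property
    def artery_patterns(self) -> dict[ArteryId, list[str]]:
        """Per-artery view of the family patterns (for invariant checks)."""
        out: dict[ArteryId, list[str]] = {a: [] for a in ARTERY_ORDER}
        for fam in self.artery_families:
            ids = _family_ids(fam)
            for a in ids:
                out[a].extend(fam["patterns"])
        return out

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            severity_positive=data["severity_positive"],
            severity_negative=data["severity_negative"],
            negation_cues=data["negation_cues"],
            artery_families=data["artery_families"],
            side_markers=data["side_markers"],
            scope_blockers=data.get("scope_blockers", ["but", "however"]),
        )


def default_ruleset() -> RuleSet:
    """Lexicon shipped with the package, reconstructed from expert keywords."""
    path = resources.files("stenoscan.data").joinpath("lexicon.yaml")
    with path.open() as fh:
        data = yaml.safe_load(fh)
    return RuleSet(
        severity_positive=data["severity_positive"],
        severity_negative=data["severity_negative"],
        negation_cues=data["negation_cues"],
        artery_families=data["artery_families"],
        side_markers=data["side_markers"],
        scope_blockers=data.get("scope_blockers", ["but", "however"]),
    )


def _family_ids(fam: dict) -> tuple[ArteryId, ...]:
    if "expands" in fam:
        return tuple(ArteryId(a) for a in fam["expands"])
    if "unpaired" in fam:
        return (ArteryId(fam["unpaired"]),)
    return (ArteryId(fam["left"]), ArteryId(fam["right"]))


@dataclass
class ArteryMention:
    """One located artery reference after laterality expansion."""

    artery_ids: set[ArteryId]
    sentence_index: int
    span: tuple[int, int]
    polarity: str = "affirmed"  # affirmed | negated
    severity: str = "unstated"  # ge50 | lt50 | unstated
    matched_text: str = ""


def _compile_one(pattern: str) -> re.Pattern:
    wrapped = pattern
    if re.match(r"\w", pattern):
        wrapped = r"\b" + wrapped
    if re.search(r"\w$", pattern) or pattern.endswith(")"):
        wrapped = wrapped + r"\b"
    try:
        return re.compile(wrapped, re.IGNORECASE)
    except re.error as exc:
        raise ValueError(f"invalid rule pattern {pattern!r}: {exc}") from exc


# Tokens that may sit between a side marker and the artery name it governs
# (anatomical qualifiers and segment notation).
_FILLER = {
    "of", "the", "a", "an", "distal", "proximal", "main", "trunk", "portion",
    "intracranial", "supraclinoid", "cavernous", "petrous", "segment",
    "junction", "artery", "arteries",
}
_SEGMENT_RE = re.compile(r"^[mpav]\d(?:-\d)?$", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[A-Za-z0-9][\w\-]*\.?|[.,:;()%><]")


class CompiledMatcher:
    """A :class:`RuleSet` compiled for deterministic matching."""

    def __init__(self, ruleset: RuleSet):
        self.ruleset = ruleset
        for name in ("severity_positive", "severity_negative", "negation_cues"):
            if not getattr(ruleset, name):
                raise ValueError(f"lexicon list {name!r} must be non-empty")
        # dedupe while preserving order, then longest-first so e.g.
        # "total occlusion" wins over "occlusion"
        def _prep(pats: list[str]) -> list[re.Pattern]:
            seen = list(dict.fromkeys(pats))
            seen.sort(key=len, reverse=True)
            return [_compile_one(p) for p in seen]

        self.pos_patterns = _prep(ruleset.severity_positive)
        self.neg_patterns = _prep(ruleset.severity_negative)
        self.cue_patterns = _prep(ruleset.negation_cues)
        self.blocker_re = re.compile(
            r"\b(" + "|".join(re.escape(b) for b in ruleset.scope_blockers) + r")\b|;",
            re.IGNORECASE,
        )
        self.family_patterns: list[tuple[dict, re.Pattern]] = []
        for fam in ruleset.artery_families:
            if not fam.get("patterns"):
                raise ValueError(f"artery family {fam.get('name')!r} has no patterns")
            for p in dict.fromkeys(fam["patterns"]):
                self.family_patterns.append((fam, _compile_one(p)))
        covered = {a for fam in ruleset.artery_families for a in _family_ids(fam)}
        missing = [a for a in ARTERY_ORDER if a not in covered]
        if missing:
            raise ValueError(f"arteries without any pattern: {missing}")
        sides = ruleset.side_markers
        self.side_of = {
            tok.lower(): side for side, toks in sides.items() for tok in toks
        }
        self.trailing_side_re = re.compile(
            r",\s*(left|right)(?:\s+side)?\s*\.?\s*$", re.IGNORECASE
        )

    # -- mention location ---------------------------------------------------

    def find_artery_mentions(
        self, sentence: str, sentence_index: int = 0
    ) -> list[ArteryMention]:
        raw: list[tuple[int, int, dict, str]] = []
        for fam, pat in self.family_patterns:
            for m in pat.finditer(sentence):
                raw.append((m.start(), m.end(), fam, m.group(0)))
        # longest-match-first, non-overlapping
        raw.sort(key=lambda r: (r[0] - r[1], r[0]))  # by length desc, then pos
        taken: list[tuple[int, int]] = []
        chosen = []
        for start, end, fam, text in raw:
            if any(s < end and start < e for s, e in taken):
                continue
            taken.append((start, end))
            chosen.append((start, end, fam, text))
        chosen.sort(key=lambda r: r[0])

        mention_spans = [(s, e) for s, e, _, _ in chosen]
        trailing = self.trailing_side_re.search(sentence)
        trailing_side = trailing.group(1).lower() if trailing else None

        mentions: list[ArteryMention] = []
        for start, end, fam, text in chosen:
            ids = self._resolve_side(sentence, start, end, fam, text,
                                     mention_spans, trailing_side)
            if ids:
                mentions.append(
                    ArteryMention(ids, sentence_index, (start, end), matched_text=text)
                )
        return mentions

    def _resolve_side(
        self, sentence, start, end, fam, text, mention_spans, trailing_side
    ) -> set[ArteryId]:
        if "expands" in fam:
            return set(_family_ids(fam))
        if "unpaired" in fam:
            return {ArteryId(fam["unpaired"])}
        left_id, right_id = ArteryId(fam["left"]), ArteryId(fam["right"])
        both = {left_id, right_id}

        side = self._scan_left(sentence, start, mention_spans)
        if side is None and "arteries" in text.lower():
            side = "bilateral"
        if side is None and trailing_side is not None and end < len(sentence):
            # artery-name-first style: "... (PCA): severe stenosis, left"
            if ":" in sentence[end:]:
                side = trailing_side
        if side == "bilateral":
            return both
        if side == "left":
            return {left_id}
        if side == "right":
            return {right_id}
        # no laterality information: label both sides (favor sensitivity)
        return both

    def _scan_left(self, sentence, start, mention_spans) -> str | None:
        prefix = sentence[:start]
        tokens = _TOKEN_RE.findall(prefix)
        for tok in reversed(tokens):
            word = tok.rstrip(".").lower()
            if word in self.side_of:
                return self.side_of[word]
            if word in _FILLER or _SEGMENT_RE.match(word):
                continue
            return None
        return None

    # -- polarity and severity ----------------------------------------------

    def _negation_scopes(self, sentence: str) -> list[tuple[int, int]]:
        scopes = []
        for pat in self.cue_patterns:
            for m in pat.finditer(sentence):
                stop = len(sentence)
                blk = self.blocker_re.search(sentence, m.end())
                if blk:
                    stop = blk.start()
                scopes.append((m.start(), stop))
        return scopes

    def classify_polarity_severity(
        self, sentence: str, mentions: list[ArteryMention]
    ) -> list[ArteryMention]:
        scopes = self._negation_scopes(sentence)

        def in_scope(pos: int) -> bool:
            return any(s <= pos < e for s, e in scopes)

        has_pos = any(
            m.start() is not None and not in_scope(m.start())
            for pat in self.pos_patterns
            for m in pat.finditer(sentence)
        )
        has_neg = any(
            not in_scope(m.start())
            for pat in self.neg_patterns
            for m in pat.finditer(sentence)
        )
        for mention in mentions:
            mention.polarity = "negated" if in_scope(mention.span[0]) else "affirmed"
            if has_pos:
                mention.severity = "ge50"
            elif has_neg:
                mention.severity = "lt50"
            else:
                mention.severity = "unstated"
        return mentions

    # -- report-level extraction --------------------------------------------

    def extract_labels(
        self,
        report: SectionedReport,
        sentences: list[Sentence] | None = None,
        trace: list | None = None,
    ) -> LabelVector:
        if sentences is None:
            sentences = split_sentences(report.target_text)
        positive: set[ArteryId] = set()
        for idx, sent in enumerate(sentences):
            mentions = self.find_artery_mentions(sent.text, idx)
            mentions = self.classify_polarity_severity(sent.text, mentions)
            for m in mentions:
                if trace is not None:
                    trace.append(
                        {
                            "report_id": report.report_id,
                            "sentence": sent.text,
                            "match": m.matched_text,
                            "arteries": sorted(a.value for a in m.artery_ids),
                            "polarity": m.polarity,
                            "severity": m.severity,
                        }
                    )
                if m.polarity == "affirmed" and m.severity == "ge50":
                    positive |= m.artery_ids
        return LabelVector.from_positive(positive)


def compile_rules(ruleset: RuleSet | None = None) -> CompiledMatcher:
    """Compile a lexicon into a deterministic matcher (default lexicon if None)."""
    return CompiledMatcher(ruleset if ruleset is not None else default_ruleset())


# Convenience module-level wrappers over a cached default matcher ------------

_DEFAULT: CompiledMatcher | None = None


def _default_matcher() -> CompiledMatcher:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = compile_rules()
    return _DEFAULT


def find_artery_mentions(sentence: str, matcher: CompiledMatcher | None = None):
    return (matcher or _default_matcher()).find_artery_mentions(sentence)


def classify_polarity_severity(
    sentence: str,
    mentions: list[ArteryMention],
    matcher: CompiledMatcher | None = None,
):
    return (matcher or _default_matcher()).classify_polarity_severity(sentence, mentions)


def extract_labels(
    report: SectionedReport,
    sentences: list[Sentence] | None = None,
    matcher: CompiledMatcher | None = None,
    trace: list | None = None,
) -> LabelVector:
    return (matcher or _default_matcher()).extract_labels(report, sentences, trace)
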