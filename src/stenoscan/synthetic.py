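"""Synthetic angiography-report corpora with gold stenosis labels.

Real MRA reports of this kind are IRB-restricted, so every downstream stage
is developed and tested against generated corpora that emulate the two
hospital writing styles the analysis must bridge:

* ``internal`` dialect — terse, lesion-first phrasing ("Stenosis of right
  MCA M1-2 ... (all > 50%)", "Total occlusion of right distal VA"), four
  sections (basic patient information / clinical information / image
  findings / impression), and *no* mention of normal arteries.
* ``external`` dialect — verbose, artery-name-first phrasing ("Posterior
  cerebral artery (PCA): moderate to severe stenosis, left"), sections
  (basic patient information / methods / findings / impressions), and an
  explicit negative enumeration covering every normal artery ("no evidence
  of occlusion or high-grade stenosis over ...") plus occasional
  out-of-lexicon synonyms such as "paucity".

Gold labels are sampled per artery from configured prevalences (exact
counts or proportions); generated text affirms every positive label in the
findings/impression sections, so a correct extractor can recover the gold
vector exactly when no out-of-lexicon synonyms are used.

Optional noise emulates raw-report clutter — interleaved Chinese (CJK)
characters, decorative special characters and runs of spaces — inserted at
token boundaries so that character cleanup recovers a label-equivalent text.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .arteries import ARTERY_ORDER, ArteryId, LabelVector

__all__ = [
    "CorpusConfig",
    "SyntheticReport",
    "internal_config",
    "external_config",
    "sample_labels",
    "render_report",
    "inject_noise",
    "generate_corpus",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_labels_csv",
    "TABLE1_INTERNAL_COUNTS",
    "TABLE1_EXTERNAL_COUNTS",
]

# Per-artery counts of confirmed (>=50%) stenosis in the two reference
# cohorts the generator emulates (internal n=9614, external n=315).
TABLE1_INTERNAL_COUNTS: dict[ArteryId, int] = {
    ArteryId.RIICA: 740,
    ArteryId.RACA: 416,
    ArteryId.RMCA: 967,
    ArteryId.RPCA: 491,
    ArteryId.RIVA: 1052,
    ArteryId.BA: 554,
    ArteryId.LIICA: 735,
    ArteryId.LACA: 407,
    ArteryId.LMCA: 1005,
    ArteryId.LPCA: 547,
    ArteryId.LIVA: 943,
}
TABLE1_INTERNAL_N = 9614

TABLE1_EXTERNAL_COUNTS: dict[ArteryId, int] = {
    ArteryId.RIICA: 12,
    ArteryId.RACA: 2,
    ArteryId.RMCA: 13,
    ArteryId.RPCA: 6,
    ArteryId.RIVA: 2,
    ArteryId.BA: 9,
    ArteryId.LIICA: 4,
    ArteryId.LACA: 4,
    ArteryId.LMCA: 10,
    ArteryId.LPCA: 3,
    ArteryId.LIVA: 2,
}
TABLE1_EXTERNAL_N = 315


@dataclass
class CorpusConfig:
    """Parameters of one generated corpus."""

    n_reports: int
    dialect: str  # "internal" | "external"
    prevalence: dict[ArteryId, int | float]
    noise_rate: float = 0.0
    oov_synonym_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.dialect not in ("internal", "external"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        for rate_name in ("noise_rate", "oov_synonym_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1], got {r}")
        self.prevalence = {ArteryId(a): v for a, v in self.prevalence.items()}
        for a, v in self.prevalence.items():
            if isinstance(v, (int, np.integer)) and not isinstance(v, bool):
                if v < 0 or v > self.n_reports:
                    raise ValueError(f"count for {a.value} out of range: {v}")
            else:
                if not 0.0 <= float(v) <= 1.0:
                    raise ValueError(f"proportion for {a.value} out of [0,1]: {v}")

    def positive_count(self, artery: ArteryId) -> int:
        v = self.prevalence.get(artery, 0)
        if isinstance(v, (int, np.integer)) and not isinstance(v, bool):
            return int(v)
        return int(round(float(v) * self.n_reports))


def internal_config(
    n_reports: int = TABLE1_INTERNAL_N,
    noise_rate: float = 0.2,
    oov_synonym_rate: float = 0.0,
    seed: int = 0,
) -> CorpusConfig:
    """Internal-dialect corpus at the reference prevalences.

    At the canonical size the per-artery positive counts are reproduced
    exactly; at other sizes the reference proportions are used.
    """
    if n_reports == TABLE1_INTERNAL_N:
        prev: dict[ArteryId, int | float] = dict(TABLE1_INTERNAL_COUNTS)
    else:
        prev = {a: c / TABLE1_INTERNAL_N for a, c in TABLE1_INTERNAL_COUNTS.items()}
    return CorpusConfig(n_reports, "internal", prev, noise_rate, oov_synonym_rate, seed)


def external_config(
    n_reports: int = TABLE1_EXTERNAL_N,
    noise_rate: float = 0.2,
    oov_synonym_rate: float = 0.3,
    seed: int = 0,
) -> CorpusConfig:
    """External-dialect corpus at the reference prevalences."""
    if n_reports == TABLE1_EXTERNAL_N:
        prev: dict[ArteryId, int | float] = dict(TABLE1_EXTERNAL_COUNTS)
    else:
        prev = {a: c / TABLE1_EXTERNAL_N for a, c in TABLE1_EXTERNAL_COUNTS.items()}
    return CorpusConfig(n_reports, "external", prev, noise_rate, oov_synonym_rate, seed)


@dataclass
class SyntheticReport:
    """One generated report with its section map and gold labels."""

    report_id: str
    dialect: str
    sections: dict[str, str]
    full_text: str
    gold: LabelVector

    def to_json(self) -> dict:
        return {
            "report_id": self.report_id,
            "dialect": self.dialect,
            "sections": self.sections,
            "full_text": self.full_text,
            "gold": self.gold.to_dict(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "SyntheticReport":
        return cls(
            d["report_id"],
            d["dialect"],
            d["sections"],
            d["full_text"],
            LabelVector.from_dict(d["gold"]),
        )


# ---------------------------------------------------------------------------
# label sampling


def sample_labels(config: CorpusConfig, rng: np.random.Generator) -> list[LabelVector]:
    """Sample gold label vectors with exact per-artery positive totals.

    Each artery's positive reports are drawn without replacement,
    independently across arteries (only marginal prevalences are modeled;
    multi-vessel correlation is not).
    """
    n = config.n_reports
    mat = np.zeros((n, len(ARTERY_ORDER)), dtype=np.int64)
    for j, artery in enumerate(ARTERY_ORDER):
        k = config.positive_count(artery)
        if k > n:
            raise ValueError(f"positive count for {artery.value} exceeds corpus size")
        if k:
            idx = rng.choice(n, size=k, replace=False)
            mat[idx, j] = 1
    return [LabelVector.from_array(row) for row in mat]


# ---------------------------------------------------------------------------
# report rendering

_FAMILY = {
    "ICA": dict(left=ArteryId.LIICA, right=ArteryId.RIICA,
                name="internal carotid artery", plural="internal carotid arteries",
                abbr="ICA", segments=["", "distal", "proximal"]),
    "ACA": dict(left=ArteryId.LACA, right=ArteryId.RACA,
                name="anterior cerebral artery", plural="anterior cerebral arteries",
                abbr="ACA", segments=["A1", "A2", ""]),
    "MCA": dict(left=ArteryId.LMCA, right=ArteryId.RMCA,
                name="middle cerebral artery", plural="middle cerebral arteries",
                abbr="MCA", segments=["M1", "M1-2", "M2", ""]),
    "PCA": dict(left=ArteryId.LPCA, right=ArteryId.RPCA,
                name="posterior cerebral artery", plural="posterior cerebral arteries",
                abbr="PCA", segments=["P1", "P2", "P2-3 junction", ""]),
    "VA": dict(left=ArteryId.LIVA, right=ArteryId.RIVA,
               name="vertebral artery", plural="vertebral arteries",
               abbr="VA", segments=["", "distal", "V4"]),
    "BA": dict(unpaired=ArteryId.BA, name="basilar artery",
               plural=None, abbr="BA", segments=["", "proximal", "distal"]),
}
_PAIRED = [f for f in _FAMILY if f != "BA"]

_INTERNAL_SEVERITIES = [
    "Severe stenosis of {loc}.",
    "Tight stenosis of {loc}.",
    "Significant stenosis of {loc}.",
    "High-grade stenosis of {loc}.",
    "Total occlusion of {loc}.",
]
_INTERNAL_OOV = [
    "Luminal narrowing of {loc}.",
    "Flow paucity in {loc}.",
]
_INTERNAL_DISTRACTORS = [
    "Mild stenosis of {loc}.",
    "Moderate stenosis of {loc}.",
]
_EXTERNAL_SIDED = [
    "{Name} ({abbr}): moderate to severe stenosis, {side}.",
    "{Name} ({abbr}): severe stenosis, {side} side.",
    "Total occlusion of {side} {name}.",
    "High grade stenosis over {side} {name}.",
]
_EXTERNAL_OOV = [
    "{Name} ({abbr}): flow paucity, {side}.",
    "Paucity of flow signal over {side} {name}.",
]
_EXTERNAL_BA = [
    "Basilar artery (BA): severe stenosis.",
    "High grade stenosis over basilar artery.",
]
_EXTERNAL_BA_OOV = ["Basilar artery (BA): flow paucity."]

_CLINICAL_NOTES = [
    "Acute ischemic stroke with left hemiparesis.",
    "Transient ischemic attack, under evaluation.",
    "Dizziness and gait disturbance for two weeks.",
    "Old infarction, follow-up study.",
    "Known severe stenosis of {loc} under medical treatment.",
]


def _internal_loc(family: str, side: str | None, rng: np.random.Generator) -> str:
    fam = _FAMILY[family]
    seg = str(rng.choice(fam["segments"]))
    if family in ("ICA", "VA", "BA"):
        core = f"{seg} {fam['abbr']}".strip()
    else:
        core = f"{fam['abbr']} {seg}".strip()
    return f"{side} {core}" if side else core


def _pick(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _render_internal(gold, config, rng) -> dict[str, str]:
    positives = gold.positives()
    finding_sentences: list[str] = []

    # group some >=50% lesions into one "(all > 50%)" enumeration
    sided = []
    for fam_key in _PAIRED:
        fam = _FAMILY[fam_key]
        for side in ("right", "left"):
            if fam[side] in positives:
                sided.append((fam_key, side))
    if ArteryId.BA in positives:
        sided.append(("BA", None))
    rng.shuffle(sided)

    group: list[str] = []
    for fam_key, side in sided:
        loc = _internal_loc(fam_key, side, rng)
        if rng.random() < config.oov_synonym_rate:
            finding_sentences.append(_pick(rng, _INTERNAL_OOV).format(loc=loc))
        elif rng.random() < 0.4:
            group.append(loc)
        else:
            finding_sentences.append(_pick(rng, _INTERNAL_SEVERITIES).format(loc=loc))
    if group:
        if len(group) == 1:
            finding_sentences.append(f"Stenosis of {group[0]} (> 50%).")
        else:
            joined = ", ".join(group[:-1]) + " and " + group[-1]
            finding_sentences.append(f"Stenosis of {joined} (all > 50%).")

    # occasional sub-threshold distractor on a normal artery
    negatives = [a for a in ARTERY_ORDER if a not in positives]
    if negatives and rng.random() < 0.25:
        a = negatives[int(rng.integers(len(negatives)))]
        fam_key = next(k for k, f in _FAMILY.items()
                       if a in (f.get("left"), f.get("right"), f.get("unpaired")))
        loc = _internal_loc(fam_key, a.side, rng)
        finding_sentences.append(_pick(rng, _INTERNAL_DISTRACTORS).format(loc=loc))

    if not finding_sentences:
        finding_sentences.append("The major intracranial vessels appear patent.")
    rng.shuffle(finding_sentences)

    impression = ("Intracranial atherosclerosis as described above."
                  if positives else "No significant stenosis.")

    clinical = _pick(rng, _CLINICAL_NOTES)
    if "{loc}" in clinical:
        # decoy lesion history unrelated to the gold labels: exercises
        # section selection (must never leak into target_text)
        fam_key = _pick(rng, _PAIRED)
        side = _pick(rng, ["right", "left"])
        clinical = clinical.format(loc=_internal_loc(fam_key, side, rng))

    return {
        "Basic patient information": _basic_info(rng),
        "Clinical information": clinical,
        "Image findings": " ".join(finding_sentences),
        "Impression": impression,
    }


def _render_external(gold, config, rng) -> dict[str, str]:
    positives = gold.positives()
    finding_sentences: list[str] = []

    handled: set[ArteryId] = set()
    for fam_key in _PAIRED:
        fam = _FAMILY[fam_key]
        pos_sides = [s for s in ("right", "left") if fam[s] in positives]
        if len(pos_sides) == 2 and rng.random() < 0.5:
            if rng.random() < config.oov_synonym_rate:
                finding_sentences.append(
                    f"Paucity of flow signal over bilateral {fam['plural']}.")
            else:
                finding_sentences.append(
                    f"High grade stenosis over bilateral {fam['plural']}.")
            handled |= {fam["left"], fam["right"]}
        else:
            for side in pos_sides:
                tmpl = (_pick(rng, _EXTERNAL_OOV)
                        if rng.random() < config.oov_synonym_rate
                        else _pick(rng, _EXTERNAL_SIDED))
                finding_sentences.append(tmpl.format(
                    Name=fam["name"].capitalize(), name=fam["name"],
                    abbr=fam["abbr"], side=side))
                handled.add(fam[side])
    if ArteryId.BA in positives:
        tmpl = (_pick(rng, _EXTERNAL_BA_OOV)
                if rng.random() < config.oov_synonym_rate
                else _pick(rng, _EXTERNAL_BA))
        finding_sentences.append(tmpl)
        handled.add(ArteryId.BA)

    negation = _negative_enumeration(positives, rng)
    sentences = ([negation] if negation else []) + finding_sentences
    findings = "MRA shows " + " ".join(sentences) if negation else " ".join(sentences)
    # `negation` already starts with "no evidence of ..."; keep the verb
    # phrase only once at the head of the findings paragraph
    if not negation:
        findings = " ".join(finding_sentences) or "Unremarkable MR angiography."

    impression = ("Intracranial atherosclerotic disease as described."
                  if positives else "No evidence of significant intracranial stenosis.")

    return {
        "Basic patient information": _basic_info(rng),
        "Methods": "3D time-of-flight MR angiography of the circle of Willis.",
        "Findings": findings,
        "Impressions": impression,
    }


def _negative_enumeration(positives: set[ArteryId], rng) -> str:
    """One sentence negating every artery that is normal in this report."""
    items: list[str] = []
    neg = {a for a in ARTERY_ORDER if a not in positives}
    vb = {ArteryId.LIVA, ArteryId.RIVA, ArteryId.BA}
    merged_vb = vb <= neg and rng.random() < 0.5
    if merged_vb:
        items.append("the vertebral basilar artery")
        neg = neg - vb
    for fam_key in _PAIRED:
        fam = _FAMILY[fam_key]
        l, r = fam["left"], fam["right"]
        if l in neg and r in neg:
            if fam_key == "ICA" and rng.random() < 0.5:
                items.append("intracranial portion of the internal carotid artery")
            else:
                items.append(f"the bilateral {fam['plural']}")
        elif l in neg:
            items.append(f"the left {fam['name']}")
        elif r in neg:
            items.append(f"the right {fam['name']}")
    if ArteryId.BA in neg:
        items.append("the basilar artery")
    if not items:
        return ""
    if len(items) == 1:
        listed = items[0]
    else:
        listed = ", ".join(items[:-1]) + " and " + items[-1]
    return f"no evidence of occlusion or high-grade stenosis over {listed}."


def _basic_info(rng) -> str:
    age = int(rng.integers(35, 95))
    sex = _pick(rng, ["male", "female"])
    return f"Age {age}. Sex {sex}. Examination MRA of brain."


def render_report(
    gold: LabelVector,
    dialect: str,
    config: CorpusConfig,
    rng: np.random.Generator,
    report_id: str = "",
) -> SyntheticReport:
    """Render one report in the requested dialect for the given gold labels."""
    if dialect == "internal":
        sections = _render_internal(gold, config, rng)
    elif dialect == "external":
        sections = _render_external(gold, config, rng)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    full = "\n".join(f"{name}: {body}" for name, body in sections.items())
    return SyntheticReport(report_id, dialect, sections, full, gold)


# ---------------------------------------------------------------------------
# noise injection

_CJK_SNIPPETS = ["臨床資料", "無明顯異常", "血管狹窄", "請參考影像", "報告完成"]
_SPECIALS = ["##", "**", "®", "—", "\t"]


def inject_noise(text: str, rng: np.random.Generator) -> str:
    """Insert CJK snippets, special characters and extra spaces.

    Noise lands only at token boundaries, so character cleanup recovers a
    text whose extracted labels equal those of the original.
    """
    if not text:
        return text
    tokens = text.split(" ")
    n_insert = max(1, int(rng.integers(1, 4)))
    for _ in range(n_insert):
        pos = int(rng.integers(len(tokens) + 1))
        kind = rng.random()
        if kind < 0.4:
            noise = _pick(rng, _CJK_SNIPPETS)
        elif kind < 0.7:
            noise = _pick(rng, _SPECIALS)
        else:
            noise = " "  # extra run of spaces
        tokens.insert(pos, noise)
    out = " ".join(tokens)
    if rng.random() < 0.5:
        out = out + " " + _pick(rng, _CJK_SNIPPETS) + "。"
    return out


# ---------------------------------------------------------------------------
# corpus assembly and I/O


def generate_corpus(config: CorpusConfig) -> list[SyntheticReport]:
    """Generate a full labeled corpus; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    labels = sample_labels(config, rng)
    reports = []
    for i, gold in enumerate(labels):
        rid = f"{config.dialect}-{i:05d}"
        rep = render_report(gold, config.dialect, config, rng, report_id=rid)
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            rep.sections = {k: inject_noise(v, rng) for k, v in rep.sections.items()}
            rep.full_text = "\n".join(
                f"{name}: {body}" for name, body in rep.sections.items()
            )
        reports.append(rep)
    return reports


def write_corpus_jsonl(reports: list[SyntheticReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rep in reports:
            fh.write(json.dumps(rep.to_json(), ensure_ascii=False) + "\n")


def read_corpus_jsonl(path) -> list[SyntheticReport]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(SyntheticReport.from_json(json.loads(line)))
    return out


def write_labels_csv(reports: list[SyntheticReport], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["report_id"] + [a.value for a in ARTERY_ORDER])
        for rep in reports:
            w.writerow([rep.report_id] + list(rep.gold.to_array()))
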