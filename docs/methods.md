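# Methods

## Problem and setting

Magnetic resonance angiography (MRA) reports record intracranial arterial
stenosis — a major stroke risk factor, particularly prevalent in Asian
populations — as free text. The package turns such a report into a binary
vector over 11 target arteries (left/right intracranial internal carotid,
anterior/middle/posterior cerebral, intracranial vertebral, and the
basilar artery), where 1 means ≥50% diameter stenosis under the NASCET
measurement convention. Two approaches are implemented and compared under
one evaluation protocol: a fully interpretable rule-based extractor and a
small recurrent neural classifier. Real report corpora of this kind are
IRB-restricted, so the package also ships a synthetic report generator that
reproduces the statistical and stylistic structure the analysis depends on.

## Synthetic corpus generator

The generator emulates two hospital writing styles ("dialects"):

* **internal** — terse, lesion-location-first phrasing ("Stenosis of right
  MCA M1-2, left PCA P1 … (all > 50%)", "Total occlusion of right distal
  VA"), sections *basic patient information / clinical information / image
  findings / impression*, and no mention of normal arteries;
* **external** — verbose, artery-name-first phrasing ("Posterior cerebral
  artery (PCA): moderate to severe stenosis, left"), sections *basic
  patient information / methods / findings / impressions*, a negative
  enumeration covering every normal artery ("no evidence of occlusion or
  high-grade stenosis over …"), and — at rate `oov_synonym_rate` — positive
  phrases using out-of-lexicon synonyms such as "paucity".

Gold labels are sampled per artery, independently across arteries, from the
reference prevalences (internal cohort n=9614: e.g. RIVA 1052, LMCA 1005,
RMCA 967, LACA 407; external cohort n=315: between 2 and 13 positives per
artery). Prevalences can be given as exact counts (canonical — the printed
percentages are rounded, e.g. 967/9614 = 10.06% prints as 10.1%, so
proportions cannot reproduce the counts) or as proportions, realized as
round(p·n). At non-canonical corpus sizes the factory configs fall back to
the reference proportions.

Default generation conditions, chosen once: `noise_rate = 0.2` (a fifth of
reports carry interleaved CJK snippets, decorative characters and runs of
spaces, emulating raw-report clutter); `oov_synonym_rate = 0` for the
internal dialect (its vocabulary defines the lexicon) and `0.3` for the
external dialect (out-of-lexicon synonyms are a minority usage observed in
the second hospital's style). Noise is inserted only at token boundaries,
so character cleanup recovers a label-equivalent text by construction. When
both sides of a paired artery are positive, the external dialect merges
them into a single "bilateral" phrase with probability 0.5 (both phrasings
occur in practice). The clinical-information/methods sections carry
boilerplate — occasionally including a decoy lesion history — so that
section selection is genuinely exercised.

What the generator does **not** emulate: multi-vessel label correlation
(only marginal prevalences are modeled), stenosis-percentage values and
laterality of real lesion co-occurrence, misspellings, hedge/uncertainty
language, and free narrative variation beyond the fixed template families.
Tests passing on synthetic corpora therefore show that the pipeline is
correct *under the modeled styles*, not that the shipped lexicon covers any
particular hospital's full phrasing distribution.

## Preprocessing

`clean_text` removes CJK-range characters and everything outside a
preserved set (letters, digits, space, and `. , : ; ( ) % > < - /`) and
collapses whitespace; it is idempotent. The preserved set deliberately
keeps `> < % ( )` because severity quantifiers like "(all > 50%)" are rule
features; naive special-character stripping would destroy them. Cleaning
runs before section segmentation. Section headings are matched
case-insensitively from a configurable alias table shipped with both
hospitals' section names; only findings-type and impression-type sections
feed the models, with the whole document as fallback when no heading is
recognized. Sentence splitting is deterministic and rule-based: periods end
sentences unless inside decimals or after protected abbreviations ("rt.",
"lt."); segment notation (M1-2, P2-3) contains no period and never splits.

## Rule-based extractor

A lexicon (YAML, editable) of severity phrases, artery patterns, negation
cues and side markers is compiled to case-insensitive regular expressions,
longest-match-first so "total occlusion" wins over "occlusion". Per
sentence: artery mentions are located and expanded for laterality (side
marker to the left across anatomical filler words; plural "…arteries" with
no marker → bilateral; trailing ", left/right side" after a colon for
artery-name-first clauses; "vertebral basilar artery" → the full
vertebrobasilar set); a negation cue negates every mention from the cue to
sentence end, with "but"/"however"/";" terminating the scope; severity is
resolved at sentence level — a positive phrase outside any negation scope
marks affirmed mentions ≥50%, otherwise sub-threshold phrases (mild, bare
"moderate", patent, normal) mark them <50%, otherwise severity is unstated
and no label is set. A report's artery label is 1 iff at least one affirmed
≥50% mention exists in the target sections; an affirmed lesion dominates a
negation of the same artery elsewhere in the report.

Deliberate conventions, where practice is genuinely ambiguous:

* bare "occlusion" counts as ≥50% (an occluded artery is the same
  diagnosis class as severe stenosis);
* unqualified "stenosis" sets no label without a quantifier or consensus
  keyword — the label is defined by the ≥50% threshold;
* a paired artery mentioned with no side information labels **both** sides
  (screening favors sensitivity over precision);
* severity governs at sentence granularity; a single sentence mixing two
  different severities over different arteries is resolved toward the
  positive phrase. The generator never emits such sentences; real mixed
  sentences are a known limitation.

## Recurrent classifier

Token embedding (dim 128) → LSTM (64 cells, sequence output) → LSTM (32
cells, final state) → dense sigmoid layer with 11 independent outputs;
dropout 0.2 after each layer during training; mean binary cross-entropy
loss; Adam at learning rate 1e-3. With the default 10,000-type vocabulary
cap this is ≈1.34M parameters. The network and its
backpropagation-through-time are implemented directly on NumPy arrays
(float64), which keeps runs exactly seeded and dependency-light; gradients
are verified against central finite differences in the test suite
(agreement to ~1e-11 absolute).

Choices left open by the architecture: word-level tokenization (lowercased;
`%`, `>`, `<` kept as tokens), maximum sequence length 256 with
post-padding, 20 epochs, batch size 32, no early stopping (determinism).
Batches are re-formed from a fresh random permutation every epoch and
padded per batch; masked positions neither advance the recurrent state nor
contribute gradients. Per-epoch batch reshuffling matters empirically: with
fixed batch composition the optimizer stalls on rare-artery outputs
(held-out per-artery AUROC as low as ≈0.85 on some seeds), while
reshuffled training reaches ≥0.99 on every artery across seeds. The model
consumes the same cleaned findings+impression text as the rule engine, for
comparability. Degenerate all-one-class training data produces a warning
and a constant-probability model rather than an error.

## Evaluation protocol

10-round hold-out cross-validation: each round is an independent random
80/20 split (train size = ceil(0.8·n), reproducing 7692/1922 from 9614);
round seeds are base_seed + round_index. No stratification. Trainable
models are refit per round from a fresh per-round seed; the rule-based
model is built once and re-evaluated on every round's test split. The
external corpus is evaluated in full every round (only trainable models
vary across its rounds, so rule-based external metrics have SD 0).

AUROC is computed two ways, by prediction type: probabilistic outputs use
the trapezoidal ROC area with midrank tie handling (delegated to
scikit-learn and cross-checked in tests against a brute-force
positive–negative pair-counting oracle); hard binary outputs use the
balanced-accuracy form ½(tp/(tp+fn) + tn/(tn+fp)). The two definitions
coincide on binary outputs (asserted exhaustively over all confusion
matrices with total ≤ 20). Sensitivity/specificity use a 0.5 threshold on
probabilities. The binarized with/without-stenosis task uses any-positive
gold, max-probability (probabilistic) or logical-OR (hard) predictions. An
artery with a single class in a round's test labels is excluded from that
round's aggregate with a logged record; aggregates are mean ± SD (ddof=0,
so a constant sequence has SD 0).

## Numerical and degenerate-input conventions

Empty report → all-zero labels. Empty text encodes to an all-padding
sequence and still yields a valid probability vector. Undefined metrics
(single-class inputs, zero denominators) return NaN with a warning rather
than raising. All randomness flows from explicit `numpy.random.default_rng`
seeds; corpus generation is byte-reproducible, and LSTM training is
reproducible on a given machine (BLAS reduction order is the only
potential source of last-bit variation; the tests assert final-loss
agreement to 1e-3 relative).

## Problem sizes used in the shipped checks

Generation and rule-based evaluation run at the full reference scale
(9614 internal + 315 external reports, 10 rounds). Oracle-equivalence
checks use 1000 reports per dialect. The recurrent model is trained for
one full-scale 7692/1922 round (≈2–3 minutes on one CPU core); unit tests
use toy corpora (n ≤ 200) with reduced layer sizes. The dialect-shift
check regenerates the external corpus with `oov_synonym_rate = 0.5`.

## Known limitations

* The shipped lexicon is reconstructed from the keyword families and
  example phrasings the templates implement; applying the extractor to a
  new hospital requires extending the YAML lexicon (the monotonicity
  property guarantees added positive phrases never clear existing labels).
* Laterality resolution assumes the side marker precedes the artery within
  a short anatomical-filler window, or trails after a colon clause;
  long-range or discontinuous laterality ("on the left, both the MCA and
  PCA…") is out of scope.
* Negation scope is linear (cue → sentence end with blockers); no
  hedge/uncertainty classes.
* Lesion localization below artery identity (M1 vs M2) and stenosis
  percentage regression are out of scope.
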