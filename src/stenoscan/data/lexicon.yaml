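# Default rule lexicon for stenosis extraction. All entries are regular
# expressions, matched case-insensitively with word boundaries added at
# word-character edges. Edit or extend via `--rules <yaml>`.
#
# Severity phrases marking >=50% diameter stenosis. Bare "occlusion" counts:
# a fully occluded artery is the same diagnosis class as severe stenosis.
severity_positive:
  - significant stenosis
  - tight stenosis
  - severe stenosis
  - high[- ]grade stenosis
  - moderate to severe stenosis
  - total occlusion
  - occlusion
  - occluded
  - '>\s*50\s*%'

# Phrases marking sub-threshold (<50%) or absent disease. Bare "moderate"
# is negative only when not part of "moderate to severe".
severity_negative:
  - mild
  - moderate(?!\s+to\s+severe)
  - patent
  - normal
  - no significant

# Negation cues: scope runs from the cue to the end of the sentence,
# terminated early by a scope blocker (but / however / semicolon).
negation_cues:
  - no evidence of
  - without evidence of
  - free of
  - 'no\s'

scope_blockers:
  - but
  - however

# Artery families. `left`/`right` give the label ids after laterality
# resolution; `expands` families always resolve to the full listed set
# (the combined vertebrobasilar system). Patterns are tried longest-first.
artery_families:
  - name: VB
    expands: [LIVA, RIVA, BA]
    patterns:
      - vertebral[- ]?basilar arter(?:y|ies)
      - vertebrobasilar arter(?:y|ies)
      - vertebrobasilar system
  - name: ICA
    left: LIICA
    right: RIICA
    patterns:
      - internal carotid arter(?:y|ies)
      - intracranial internal arter(?:y|ies)
      - carotid siphon
      - ICA
  - name: ACA
    left: LACA
    right: RACA
    patterns:
      - anterior cerebral arter(?:y|ies)
      - ACA
  - name: MCA
    left: LMCA
    right: RMCA
    patterns:
      - middle cerebral arter(?:y|ies)
      - MCA
  - name: PCA
    left: LPCA
    right: RPCA
    patterns:
      - posterior cerebral arter(?:y|ies)
      - PCA
  - name: VA
    left: LIVA
    right: RIVA
    patterns:
      - vertebral arter(?:y|ies)
      - VA
  - name: BA
    unpaired: BA
    patterns:
      - basilar arter(?:y|ies)
      - BA

side_markers:
  right: [right, rt]
  left: [left, lt]
  bilateral: [bilateral, both]
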