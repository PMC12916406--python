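# Default registry for the 19 benchmarked missense predictors.
#
# recommended_threshold values are the genome-wide cutoffs documented with
# each tool / in dbNSFP; they are deliberately user-overridable because
# published cutoffs drift between tool versions. Equality with the
# threshold counts as deleterious. score_range is used to keep synthetic
# scores inside each tool's documented scale.
#
# The generic binary map {"D": deleterious, "T": tolerated} applies to tools
# whose categorical output is the two-letter D/T convention; richer
# multi-class outputs are spelled out per tool.
tools:
  - name: AlphaMissense
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.564
    score_range: [0.0, 1.0]
    categorical_map: {"P": deleterious, "B": tolerated, "A": tolerated}
  - name: BayesDel_addAF
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.0692
    score_range: [-1.3, 0.76]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: BayesDel_noAF
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: -0.0570
    score_range: [-1.3, 0.76]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: ClinPred
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.5
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: ESM1b
    output_kind: both
    orientation: lower_damaging
    recommended_threshold: -7.5
    score_range: [-25.0, 0.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: Fathmm-XF_coding
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.5
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "N": tolerated}
  - name: LIST-S2
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.85
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: M-CAP
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.025
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: MetaLR
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.5
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: MetaRNN
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.5
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: MetaSVM
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.0
    score_range: [-2.0, 3.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: MutationAssessor
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 1.935
    score_range: [-5.5, 6.0]
    categorical_map: {"H": deleterious, "M": deleterious, "L": tolerated, "N": tolerated}
  - name: MutationTaster
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.5
    score_range: [0.0, 1.0]
    categorical_map: {"A": deleterious, "D": deleterious, "N": tolerated, "P": tolerated}
  - name: Polyphen2_HDIV
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.5
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "P": deleterious, "B": tolerated}
  - name: Polyphen2_HVAR
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.5
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "P": deleterious, "B": tolerated}
  - name: PROVEAN
    output_kind: both
    orientation: lower_damaging
    recommended_threshold: -2.5
    score_range: [-14.0, 14.0]
    categorical_map: {"D": deleterious, "N": tolerated}
  - name: PrimateAI
    output_kind: both
    orientation: higher_damaging
    recommended_threshold: 0.803
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: SIFT
    output_kind: both
    orientation: lower_damaging
    recommended_threshold: 0.05
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
  - name: SIFT4G
    output_kind: both
    orientation: lower_damaging
    recommended_threshold: 0.05
    score_range: [0.0, 1.0]
    categorical_map: {"D": deleterious, "T": tolerated}
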