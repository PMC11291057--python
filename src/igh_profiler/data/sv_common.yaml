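# Catalog of the seven common IGH structural variants used for
# personalized-reference construction.  Anchors are the nearest flanking
# genes outside each variant region; interior genes define the deleted /
# haplotype-unique content.  sv 3 is the complex region where each
# haplotype carries its own unique gene pair.
svs:
  - sv_id: 1
    description: deletion from IGHD2-8 to IGHD3-3
    left_anchor: IGHD2-2
    right_anchor: IGHD3-9
    interior: [IGHD3-3, IGHD4-4, IGHD5-5, IGHD6-6, IGHD1-7, IGHD2-8]
  - sv_id: 2
    description: deletion of IGHV7-4-1
    left_anchor: IGHV4-4
    right_anchor: IGHV2-5
    interior: [IGHV7-4-1]
  - sv_id: 3
    description: complex haplotype of IGHV3-64D and IGHV5-10-1, or
      IGHV1-8 and IGHV3-9
    left_anchor: IGHV3-7
    right_anchor: IGHV3-11
    hap_a: [IGHV3-64D, IGHV5-10-1]
    hap_b: [IGHV1-8, IGHV3-9]
  - sv_id: 4
    description: deletion of IGHV3-23D
    left_anchor: IGHV3-23
    right_anchor: IGHV3-25
    interior: [IGHV3-23D]
  - sv_id: 5
    description: deletion from IGHV4-30-2 to IGHV3-33
    left_anchor: IGHV3-30
    right_anchor: IGHV4-34
    interior: [IGHV4-30-2, IGHV3-30-3, IGHV4-30-4, IGHV3-30-5, IGHV4-31,
               IGHV3-33]
  - sv_id: 6
    description: deletion from IGHV4-38-2 to IGHV1-38-4
    left_anchor: IGHV3-38
    right_anchor: IGHV4-39
    interior: [IGHV4-38-2, IGHV3-38-3, IGHV1-38-4]
  - sv_id: 7
    description: deletion from IGHV2-70D to IGHV1-69D
    left_anchor: IGHV1-69
    right_anchor: IGHV2-70
    interior: [IGHV2-70D, IGHV1-69-2, IGHV1-69D]
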