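# Default four-region AML panel.
#
# Anchor cg-identifiers, CpG counts (14/10/15/9), aberration directions and
# the two annotated SNPs (rs115701567 chr16:88844998 in the cg27630153
# amplicon; rs917911737 chr19:14225172 in the cg19586199 amplicon) are real.
# Per-CpG genomic positions are SYNTHETIC PLACEHOLDERS laid out at plausible
# spacing around each anchor; replace them with primer-level coordinates for
# use on real alignments.  All positions are 1-based (+)-strand C positions.
regions:
  - region_id: cg15289427
    anchor_cpg: cg15289427
    chrom: chr6
    cpg_positions: [3849601, 3849614, 3849622, 3849639, 3849650, 3849661,
                    3849673, 3849690, 3849703, 3849711, 3849726, 3849742,
                    3849757, 3849769]
    target_index: 8
    direction: hyper_in_aml
    snp_positions: []
  - region_id: cg22797031
    anchor_cpg: cg22797031
    chrom: chr2
    cpg_positions: [120500011, 120500020, 120500033, 120500041, 120500052,
                    120500067, 120500075, 120500088, 120500101, 120500115]
    target_index: 4
    direction: hyper_in_aml
    snp_positions: []
  - region_id: cg27630153
    anchor_cpg: cg27630153
    chrom: chr16
    cpg_positions: [88844910, 88844921, 88844933, 88844942, 88844956,
                    88844968, 88844979, 88844990, 88845003, 88845012,
                    88845025, 88845037, 88845049, 88845060, 88845072]
    target_index: 7
    direction: hypo_in_aml
    snp_positions: [88844998]
  - region_id: cg19586199
    anchor_cpg: cg19586199
    chrom: chr19
    cpg_positions: [14225110, 14225122, 14225131, 14225145, 14225156,
                    14225165, 14225179, 14225188, 14225199]
    target_index: 4
    direction: hypo_in_aml
    snp_positions: [14225172]
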