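"""Compute the four-CpG AML-score for array betas and for BA-seq reads.

The score averages direction-adjusted betas at the four anchor CpGs
(hyper-CpGs enter as beta, hypo-CpGs as 1 - beta): 0 = healthy archetype,
1 = fully aberrant.  Samples above the control-percentile cutoff (0.125 on
array cohorts) are called positive.
"""

from epimrd import (
    ARRAY_CUTOFF,
    CloneProfile,
    classify_sample,
    compute_aml_score,
    default_panel,
    score_sample_reads,
    simulate_sample,
)

panel = default_panel()

betas = {
    "cg15289427": 0.2,
    "cg22797031": 0.4,
    "cg27630153": 0.9,
    "cg19586199": 0.7,
}
score = compute_aml_score(betas, panel)
print(f"array betas {tuple(betas.values())} -> AML-score {score:.3f} "
      f"-> {classify_sample(score, ARRAY_CUTOFF)} at cutoff {ARRAY_CUTOFF}")

# The same score from read-level BA-seq data: anchor beta = methylated-read
# fraction at the region's target CpG.
aml_like = simulate_sample(CloneProfile.aberrant(panel), panel, 1000, seed=7,
                           sample_id="patient")
result = score_sample_reads(aml_like, panel, cutoff=ARRAY_CUTOFF)
print(f"simulated leukemic sample: score {result.score:.3f} -> {result.call}")

control = simulate_sample(CloneProfile.healthy(panel), panel, 1000, seed=8,
                          sample_id="donor")
result = score_sample_reads(control, panel, cutoff=ARRAY_CUTOFF)
print(f"simulated healthy donor:   score {result.score:.3f} -> {result.call}")
# Healthy samples sit near the error floor (~0.02); leukemic samples near 1.
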