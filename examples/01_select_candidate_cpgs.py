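"""Select AML-associated candidate CpGs from simulated array cohorts.

Builds three independent study pairs (control vs AML beta matrices) with the
same 20 planted aberrant CpGs among 480 null CpGs, selects the top
candidates per pair, and intersects across pairs — the replication step that
separates cohort-specific noise from CpGs that are aberrant in AML
generally.
"""

from epimrd import (
    filter_invariant_cpgs,
    intersect_candidates,
    rank_and_select,
    simulate_beta_matrix,
)

sets = []
for seed in (1, 2, 3):
    matrix, planted = simulate_beta_matrix(effect=0.5, noise_sd=0.03, seed=seed)
    eligible = filter_invariant_cpgs(matrix.restrict("control"))
    cs = rank_and_select(matrix, eligible)
    sets.append(cs)
    print(
        f"pair {seed}: {len(eligible)} CpGs pass the extremeness/stability filter, "
        f"{len(cs.hyper)} hyper / {len(cs.hypo)} hypo candidates"
    )

consensus = intersect_candidates(sets)
recovered = len(set(planted) & set(consensus.hyper + consensus.hypo))
print(f"consensus: {len(consensus.hyper)} hyper / {len(consensus.hypo)} hypo CpGs")
print(f"planted-CpG recovery: {recovered}/{len(planted)}")
# Every CpG surviving all three pairs is a reproducible AML marker candidate;
# with a planted |delta-beta| of 0.5 the recovery should be complete.
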