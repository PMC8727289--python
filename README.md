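# epimrd

DNA-methylation epiallele patterns for estimating measurable residual
disease (MRD) in acute myeloid leukemia (AML).

## The problem

MRD — the leukemic burden that remains after therapy — is usually tracked by
qPCR for patient-specific mutations (not available for every patient) or by
flow cytometry (hard to standardise). Aberrant DNA methylation (DNAm) is a
near-universal feature of AML, which suggests an alternative: find CpG sites
that are tightly regulated in healthy blood but commonly flipped in AML, and
quantify the residual aberrant signal in a patient's blood with targeted
bisulfite amplicon sequencing (BA-seq). Because every sequencing read
reports the joint methylation state of all CpGs in an amplicon (an
*epiallele*), single aberrant reads can in principle be detected against a
clean control background — a read-level, mutation-independent MRD readout.

`epimrd` implements this workflow end to end for a panel of four
AML-associated regions (around cg15289427, cg22797031, cg27630153 and
cg19586199, with 14/10/15/9 neighbouring CpGs):

1. **Candidate selection** (`epimrd.selection`) — from 450k-style beta
   matrices: keep CpGs with control mean β < 0.1 or > 0.9 and control
   s.d. < 0.05, rank by Δβ = mean(AML) − mean(control), take the top 100
   per direction, and intersect candidate lists across independent
   control/AML study pairs.
2. **AML-score** (`epimrd.score`) — the mean of direction-adjusted anchor
   betas,

   `AML-score = (β₁ + β₂ + (1 − β₃) + (1 − β₄)) / 4`

   with hyper-CpGs entering as β and hypo-CpGs as 1 − β, so 0 is the
   healthy archetype and 1 fully aberrant. The cutoff is the 99.5th
   percentile of healthy-control scores (≈ 0.125 on array cohorts).
3. **Read-level anomaly detection** (`epimrd.forest`,
   `epimrd.autoencoder`) — per region, classify each read's binary pattern
   as normal/abnormal with either a depth-5 random forest (supervised:
   control reads vs AML-diagnosis reads) or per-cluster tanh autoencoders
   (unsupervised, trained on control reads only; K-means with K = 5 routes
   reads to cell-type-like clusters; a read is abnormal when its
   reconstruction loss exceeds the 99th percentile of training losses).
   The per-sample *anomaly score* is the mean over regions of the fraction
   of abnormal reads, with a cutoff at the 99th percentile of control
   training scores.
4. **Allele symmetry** (`epimrd.symmetry`) — split reads at an
   intra-amplicon heterozygous SNP and compare per-CpG betas and
   whole-pattern frequency distributions between alleles.
5. **Synthetic data and evaluation** (`epimrd.simulate`,
   `epimrd.pipeline`) — seeded generators for beta matrices with planted
   aberrant CpGs, near-binary control reads, coherent aberrant epialleles,
   heterozygous samples and limiting-dilution series, plus a four-method
   benchmark and a dilution sensitivity harness.

Samples with fewer than 50 reads on any amplicon are excluded; control
cohorts are split 7:3 into training/validation at the sample level.

## Worked example

```sh
python examples/02_aml_score.py
```

```
array betas (0.2, 0.4, 0.9, 0.7) -> AML-score 0.250 -> positive at cutoff 0.125
simulated leukemic sample: score 0.980 -> positive
simulated healthy donor:   score 0.023 -> negative
```

The first line evaluates the score equation directly:
(0.2 + 0.4 + 0.1 + 0.3)/4 = 0.25, above the 0.125 array cutoff. The other
two score simulated BA-seq samples read-by-read: the healthy donor sits at
the bisulfite-error floor (ε ≈ 0.02), the leukemic sample near 1.

`python examples/06_dilution_sensitivity.py` trains all four methods on
fresh control cohorts and applies them to a dilution series of leukemic
into healthy DNA; mean scores decline essentially linearly with the
aberrant-DNA fraction (e.g. random forest: 0.98 at f = 1, 0.25 at
f = 0.25, 0.010 at f = 0.01, 0.0 at f = 0) and the printed detection limit
is the smallest fraction still called positive reliably. The other
examples cover candidate selection, both anomaly detectors and allele
symmetry. A thin CLI (`epimrd --help`) exposes the same steps as
subcommands (`select-cpgs`, `score`, `train-rf`, `train-ae`, `classify`,
`benchmark`, `simulate`, `symmetry`, `dilution-eval`).

## Limitations

Amplicon CpG coordinates in the shipped panel are placeholders (the anchor
ids, CpG counts, directions and the two annotated SNPs are real); supply
your own panel YAML for real alignments. The package consumes per-read CpG
calls (e.g. assembled from a bisulfite aligner's CpG-context output) — it
does not trim, align or call methylation itself. See `docs/methods.md` for
the model assumptions and what the synthetic benchmarks do and do not show.
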