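# Methods

This note documents the models, the tunable parameters and their defaults,
the numerical choices, the synthetic-data generator, and the known
limitations of `epimrd`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

Two substrates are analysed:

* **Beta matrices** — CpG × sample methylation levels β ∈ [0, 1] from
  450k-style arrays, with a control/AML group map. Missing betas are
  excluded pairwise from means and standard deviations, never imputed.
* **Read patterns** — each BA-seq read reduced to the ordered binary
  methylation states of one amplicon's CpGs. Collapsed (pattern, count)
  rows are the canonical representation; every downstream operation is
  count-weighted, and results are invariant to splitting a collapsed row
  into duplicates (tested).

Coordinates are 1-based on the (+) strand; a CpG's position is the C of
the dinucleotide. Annotated SNP positions must be ≥ 3 bp from **both**
bases of every CpG — the stricter reading of "3 bp from any CpG" — so a
variant base can never be confounded with a bisulfite conversion event.

The shipped default panel carries the real anchor ids, CpG counts
(14/10/15/9), aberration directions, and the two published SNPs
(rs115701567 chr16:88844998; rs917911737 chr19:14225172); the per-CpG
genomic positions are synthetic placeholders at plausible spacing, clearly
marked in the file, because primer-level coordinates are not bundled.

## Candidate selection

Per study pair: a CpG is *eligible* when its control mean β is < 0.1 or
> 0.9 and its control sample (n−1) s.d. is < 0.05. The extremeness
criterion is applied to the control **mean** (the s.d. criterion already
bounds the spread, so mean is the coherent reading of "β in healthy
donors"). Eligible CpGs are ranked by Δβ = mean(AML) − mean(control),
split by sign, truncated at `top_k` (default 100) per direction; ties
break lexicographically by CpG id for determinism. Candidate sets from
independent study pairs are intersected per direction and reordered by
mean |Δβ|; the intersection is invariant to argument order. CpGs with
fewer than two non-missing control values are excluded and logged, not
raised.

## AML-score

`score = mean over anchors of (β if hyper-in-AML else 1 − β)`, a value in
[0, 1]. It is monotone in each anchor in the direction of aberration and
exchangeable within a direction class (property-tested). The cutoff is
the 99.5th percentile — linear interpolation between order statistics, the
dominant convention — of healthy-control scores; classification is
strictly greater-than, since controls are characterised as *below* the
cutoff. Calibration requires ≥ 10 controls. For BA-seq data the anchor
beta is the count-weighted methylated fraction at the region's target CpG
(the score is defined on the anchor cg-identifiers); an amplicon-mean
variant is exposed as an option. The array-cohort convention 0.125 is
available as `ARRAY_CUTOFF`.

## Read QC and the control split

A sample is excluded when **any** panel region has depth < 50 (strict
less-than; depth 50 is kept). Reads assembled from per-read CpG calls
must cover *all* CpGs of a region; partial reads are discarded and
tallied rather than imputed — imputation would fabricate pattern
structure. Control cohorts are split 7:3 (train fraction 0.7, banker's
rounding, seeded shuffle) at the **sample** level so one donor's reads
never appear on both sides.

## Random forest

One forest per region, features = CpG bit columns. Training labels are
*normal* for every control-training read and *abnormal* for every read of
an AML first-diagnosis sample — deliberate label noise, since diagnosis
samples contain normal reads; the majority signal suffices. Defaults:
100 trees, max depth 5 (depth is the method-defining constraint; tree
count is a package default recorded in the model), seeded, with sample
weights = pattern counts rescaled so both classes carry equal total
weight (computed manually because scikit-learn's `class_weight="balanced"`
ignores sample weights). An optional `restrict_to` argument limits the
abnormal class to flagged diagnosis samples (e.g. NPM1-mutated ones).

## Autoencoder

Bits are encoded as −1 (unmethylated) / +1 (methylated). Optionally,
reads of a region are first clustered by count-weighted K-means (default
K = 5, 10 restarts, seeded; assignment is nearest centroid with ties to
the lowest cluster id; empty clusters are dropped with a warning; K is
reduced with a warning when there are fewer distinct patterns). One
autoencoder is trained per cluster; the no-clustering variant is the
K = 1 special case and is byte-identical to it by construction (tested).

Architecture: input and output width = the region's CpG count (9–15),
hidden widths 8-3-8 (encoder, latent, decoder) — the bottleneck sizes are
the method-defining constraint; a fixed-width input could not accept
14-CpG patterns. All layers use tanh, including the output (targets are
±1); loss is per-read mean squared error. Training: full-batch Adam,
learning rate 0.01, up to 500 epochs with early stop on a loss plateau
(relative improvement < 1e-7 for 30 epochs), count-weighted, seeded and
deterministic. The output bias is initialised to atanh of the weighted
data mean: a tanh network with zero biases is an odd function and would
reconstruct the bitwise complement of its training archetype as well as
the archetype itself, silently blinding the detector to fully flipped
epialleles; anchoring the resting output at the data mean removes that
symmetry and leaves the bottleneck to encode variance only.

A read is abnormal when its loss exceeds the cluster's threshold, the
count-weighted 99th percentile (linear interpolation, matching the
percentile of the count-expanded array; tested against that oracle) of
training-read losses — so at most ~1% of training reads are flagged, up
to one collapsed row's mass of interpolation slack. Unseen reads are
routed to clusters by nearest centroid.

## Anomaly aggregation

Per region, the anomaly ratio is the count-weighted fraction of abnormal
reads; a region without reads (or without a model) is missing. The
anomaly score is the arithmetic mean of available ratios (with a warning
when fewer than all four regions contribute). The sample cutoff is the
99th percentile of control-training sample scores; a sample is positive
strictly above it.

## Synthetic data

The generators emulate the structure of the real inputs, with ground
truth always returned:

* **Beta matrices**: null CpGs share a group-independent mean uniform on
  [0.05, 0.95]; planted CpGs have control mean 0.05 (hyper) or 0.95
  (hypo) and AML mean shifted by ± effect (default 0.5, the "often > 50%"
  regime); Gaussian noise s.d. 0.03 (< the 0.05 filter bound), clipped to
  [0, 1]. Defaults 480 null + 20 planted CpGs, 50 controls, 20 AML.
* **Healthy reads**: per-CpG independent Bernoulli with error rate
  ε = 0.02 against the region's healthy state — approximating bisulfite
  conversion failure plus sequencing error; configurable.
* **Aberrant reads**: the opposite extreme of healthy in every region,
  drawn *coherently* — one uniform draw per read sets all CpGs
  (`bit_i = 1 iff u < p_i`), preserving per-CpG marginals while
  emulating clonal whole-amplicon epiallele aberrations. Healthy reads
  stay CpG-independent.
* **Dilutions**: at fraction f each read is independently aberrant with
  probability f; realized per-region fractions are recorded. Default
  fractions 1.0, 0.5, 0.25, 0.10, 0.05, 0.01, 0.0.
* **Heterozygous samples**: each read takes allele a/b with probability
  1/2, its pattern from that allele's profile, and its base recorded at
  the SNP.

What the generator does **not** model: PCR amplification bias and
chimeras, per-cycle quality decay, cell-type mixture structure in healthy
blood (healthy reads are one homogeneous clone, so K = 5 clustering has
no true subpopulations to find), partially aberrant clones, or
correlation of errors along a read. Tests passing on this generator
therefore demonstrate correctness of the machinery and calibration, not
clinical sensitivity on real blood: real detection limits are coarser
than the synthetic ones because real control reads are heterogeneous and
real leukemic patterns only partly separable.

## Evaluation harnesses and problem sizes

The four-method benchmark shares one QC pass, one 7:3 split and one
training set across methods and reports confusion matrices against
ground-truth labels. The dilution harness trains and calibrates per seed
on a fresh control cohort, then classifies a seeded dilution series; the
detection limit is the smallest nonzero fraction called positive in
≥ 95% of seeds with all larger fractions also reliable.

Cohort sizing is a design point, not an afterthought: a cutoff at the
99th percentile of n training scores is, for n < 100, effectively the
sample maximum, which a fresh control sample exceeds with probability
≈ 1/(n+1) — several times the nominal 1%. The dilution harness therefore
defaults to a 300-donor control cohort (210 training), making the
empirical percentile an interior order statistic with exceedance ≈ 0.5%.
For the same reason, "at most 1% of training samples above the cutoff" is
only attainable with ≥ 100 samples, and the calibration tests use 100.
Test and acceptance runs use desk-scale sizes chosen up front — a few
hundred reads per region for model training, 10 seeds for the dilution
study, 10,000 reads per region for spike-fraction recovery — stated here
as the package's own study conditions.

## Known limitations

* Placeholder panel coordinates (see above); real analyses must supply a
  panel with primer-level positions.
* The forest's supervised labels inherit the normal-read contamination of
  diagnosis samples; its abnormal class is therefore biased towards the
  dominant aberrant patterns.
* Per-cluster autoencoders can memorise their training patterns when the
  pooled read set is small, deflating training losses relative to fresh
  reads and widening the false-positive band of the clustered variant;
  the effect shrinks as the training pattern space saturates.
* The no-AML-training-set advantage of the autoencoder comes at the cost
  of flagging *any* rare pattern, including benign ones — on real data
  even healthy samples carry a floor of abnormal-classified reads, which
  bounds the achievable MRD sensitivity.
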