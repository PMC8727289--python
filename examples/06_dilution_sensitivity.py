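"""Limiting-dilution sensitivity study of all four detection methods.

Leukemic DNA is mixed into healthy DNA at decreasing fractions; per seed,
every method is trained and calibrated on a fresh control cohort, then
applied to the dilution series.  The detection limit is the smallest
fraction a method still calls positive reliably.  (3 seeds and a small
cohort here to keep the example quick; the test suite runs the full
10-seed version.)
"""

from epimrd import DilutionDesign, RunConfig, default_panel, run_dilution_eval

panel = default_panel()
report = run_dilution_eval(
    panel,
    DilutionDesign(reads_per_region=400, seed=0),
    n_seeds=3,
    n_controls=60,
    config=RunConfig(seed=0),
)

header = "fraction  " + "  ".join(f"{m:>10}" for m in report.mean_scores)
print("mean anomaly/AML score by aberrant-DNA fraction:")
print(header)
for f in report.fractions:
    row = "  ".join(f"{report.mean_scores[m][f]:>10.4f}" for m in report.mean_scores)
    print(f"  {f:6g}  {row}")
print("detection limit (smallest reliably positive fraction):")
for m, limit in report.detection_limit.items():
    print(f"  {m}: {limit if limit is not None else 'not reached'}")
# Scores decline roughly linearly with the dilution fraction; on separable
# synthetic patterns the read-level methods reach ~1-5%, far below the
# coarser limits attainable on real, noisier blood samples.
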