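"""Group statistics: cohort t-tests with FDR control and the validation
correlations.

Runs Welch t-tests per timepoint and parameter (animal = experimental
unit), adjusts the whole family by Benjamini-Hochberg, and correlates the
model's recovery probabilities with behavior and scalar indices with axon
density.
"""

from nervedki import StudyConfig, classify_study, simulate_study
from nervedki.classifier import train_from_records
from nervedki.slicewise import filter_outliers
from nervedki.stats import (
    correlate_probability_behavior,
    correlate_scalars_histology,
    pairwise_ttests,
)

study = simulate_study(StudyConfig(seed=1))
kept, _ = filter_outliers(study.records)

tests = pairwise_ttests(kept, ["rd", "ad", "rk"])
sig = tests[tests.significant]
print(f"{len(sig)}/{len(tests)} cohort contrasts significant after FDR")
print(sig[["parameter", "week", "cohort_a", "cohort_b", "p_adjusted"]]
      .head(8).to_string(index=False))

boundary, platt, _ = train_from_records(kept, seed=1)
_, nerves = classify_study(study.records, boundary, platt)

behav = correlate_probability_behavior(nerves, study.behavior, week=12)
print(f"\nprobability vs SFI:          r = {behav['sfi'].r:+.3f} "
      f"(n = {behav['sfi'].n})")
print(f"probability vs FF recovery:  r = {behav['ff'].r:+.3f}")

hist = correlate_scalars_histology(study.records, study.histology)
for name in ("rd", "ad", "rd_ad", "fa"):
    res = hist[name]
    print(f"{name:>6} vs axon density:      r = {res.r:+.3f} "
          f"(p = {'<1e-3' if res.p < 1e-3 else f'{res.p:.3f}'})")
# Expected directions: radial indices and RD/AD fall as axons repopulate
# the distal stump (negative r), FA rises with them (positive r).
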