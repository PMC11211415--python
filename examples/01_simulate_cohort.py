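"""Generate a synthetic treatment cohort and inspect its structure.

Draws 228 subjects from the five default trajectory classes (strong,
delayed, plateau, non-improver, worsening), prints the class counts, the
share of each raw rating category, and writes the four CSV tables the rest
of the pipeline consumes.
"""

import numpy as np

from tmstraj import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(n_subjects=228, seed=1))

counts = np.bincount(cohort.true_class.to_numpy(), minlength=5)
names = ("strong", "delayed", "plateau", "non-improver", "worsening")
print("true class counts:")
for name, c in zip(names, counts):
    print(f"  {name:>13}: {c:3d}  ({100 * c / len(cohort.true_class):.1f}%)")

shares = cohort.ratings["rating"].value_counts(normalize=True).sort_index()
print("\nraw rating shares (1=much worse .. 5=much better):")
print(shares.round(3).to_string())
# category 1 should be rare (< 1% of data points), mirroring real usage

cohort.write_csv("scratch_cohort")
print("\nwrote ratings/metadata/coil/targets/outcomes CSVs to scratch_cohort/")
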