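"""Draw one synthetic dataset and inspect the misclassification it contains.

The default design has 25 clusters of 200 subjects, a true exposure
prevalence near 0.18, and two fallible assessments of the exposure: test 1
with sensitivity 0.55 / specificity 0.95 and test 2 with 0.7 / 0.8.
"""

import numpy as np

from miscount import SimDesign, simulate_dataset

design = SimDesign(seed=42)
data = simulate_dataset(design)

exposed = data.x_true == 1
print(f"subjects: {data.n_subjects} in {data.n_clusters} clusters")
print(f"true exposure prevalence: {data.x_true.mean():.3f}")
print(f"mean count outcome:       {data.y.mean():.2f}")
for name, assess, S, C in (("test 1", data.x1, design.S1, design.C1),
                           ("test 2", data.x2, design.S2, design.C2)):
    emp_S = assess[exposed].mean()
    emp_C = 1 - assess[~exposed].mean()
    print(f"{name}: empirical sensitivity {emp_S:.3f} (design {S}), "
          f"specificity {emp_C:.3f} (design {C})")

data.to_csv("example_data.csv")
print("wrote example_data.csv")

# The empirical sensitivities/specificities match the design values up to
# binomial noise: the assessments really are fallible, so a naive analysis
# that trusts test 1 will misclassify about half of the exposed subjects.
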