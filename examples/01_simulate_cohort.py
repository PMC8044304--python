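"""Generate a synthetic memory-clinic cohort and look at its structure.

The generator draws each subject from a six-component mixture over
(Abeta42/Abeta40 ratio, p-tau, t-tau): one control-like profile, one
heterogeneous wide-variance profile, and four AD-like profiles graded in tau.
"""
import pandas as pd

import csfprofile as cp

spec = cp.default_mixture_spec()
cohort = cp.generate_cohort(spec, n=616, seed=17)

print(f"{len(cohort)} subjects, columns: {', '.join(cohort.columns)}\n")
print("Diagnosis counts (a realistic clinic mix, AD-dominated):")
print(cohort["diagnosis"].value_counts().head(8).to_string(), "\n")

summary = cohort.groupby("_component")[["ratio", "ptau", "ttau"]].median().round(3)
print("Median biomarkers per generating component")
print("(component 1 = control-like: high ratio, low tau;")
print(" components 3-6 = AD-like: low ratio, tau graded upward):")
print(summary.to_string())

by_comp = pd.crosstab(cohort["_component"], cohort["diagnosis"])
print("\nOND subjects per component (most sit in component 1):")
print(by_comp["OND"].to_string())
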