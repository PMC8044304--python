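"""Unsupervised stratification of the cohort by CSF biomarker profile.

Fits full-covariance Gaussian mixtures on z-scored biomarkers for K = 1..10,
picks K by BIC, then summarizes and labels the clusters from the distribution
of clinically defined AD and OND subjects.
"""
import numpy as np

import csfprofile as cp

cohort = cp.generate_cohort(n=616, seed=17)
transform = cp.fit_standardization(cohort)
z = transform.apply(cohort)

k_star, curve = cp.select_num_clusters(z, range(1, 11), seed=17)
print("BIC by K (lower is better):")
print(curve[["K", "bic"]].round(1).to_string(index=False))
print(f"\nSelected K* = {k_star}")

fit = cp.fit_gmm_em(z, k_star, seed=17)
labels = fit.hard_labels

profiles = cp.cluster_profiles(cohort, labels)
print("\nCluster profiles (median [2.5th, 97.5th percentile], natural units):")
for c in sorted(set(labels)):
    row = {r["biomarker"]: r for _, r in
           profiles[profiles.cluster == c].iterrows()}
    print(f"  cluster {c} (n={row['ratio']['n']:3.0f}): "
          f"ratio {row['ratio']['median']:.3f} "
          f"[{row['ratio']['lo']:.3f}, {row['ratio']['hi']:.3f}], "
          f"p-tau {row['ptau']['median']:5.1f}, "
          f"t-tau {row['ttau']['median']:6.1f}")

prev = cp.prevalence_matrix(cohort["diagnosis"], labels, min_n=5)
order, _ = cp.hierarchical_order(prev.to_numpy())
print("\nPrevalence heatmap (% of each diagnosis per cluster, UPGMA row order):")
print(prev.iloc[order].round(0).to_string())

cl = cp.label_clusters(cohort["diagnosis"], labels, ratio=cohort["ratio"])
print(f"\nCluster labels: { {int(k): v for k, v in cl.items()} }")

tol = cp.misdiagnosis_tolerance(cohort["diagnosis"], labels, ratio=cohort["ratio"])
print(f"Misdiagnosis tolerance: relabeling fewer than {tol.m} of {tol.n_ond} "
      f"OND subjects ({tol.fraction:.0%}) as AD cannot change the labeling —")
print("the data-driven stratification is robust to sporadic misdiagnosis.")
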