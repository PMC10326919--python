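"""Resolve diastereomer-like negatives, and flag outliers by Mahalanobis distance.

Diastereomers share every fragment channel with the target compound and
differ only in a few abundance ratios, so unsupervised similarity scores
overlap.  A stepwise logistic regression on the EASI residual channels
learns exactly the shifted-ratio channels and separates the classes
completely.  Independently, the Mahalanobis distance to the training cloud
gives a chi-square outlier test on measured abundances alone.
"""

import numpy as np

import easi

spec = easi.default_spec()
train = easi.nominalize(easi.simulate_replicates(spec, n=128, seed=11))
panel = easi.select_top_k(train, 20)
matrix = easi.assemble_matrix(train, panel)
model = easi.fit_easi(matrix)

pos = easi.nominalize(easi.simulate_lab_shift(spec, delta=1.0, n=60, seed=71))
neg = easi.nominalize(easi.simulate_negatives(spec, "diastereomer", 10, seed=72))
queries = easi.assemble_matrix(pos + neg, panel)
records = easi.predict_matrix(model, queries, "easi")

logit = easi.fit_residual_logit_stepwise(records)
print(f"stepwise logistic selected residual channels: {logit.selected}")
print(f"fitting method: {logit.method} (ridge = complete separation handled)")
results = [easi.classify_logit(logit, r) for r in records]
correct = sum(label == r.truth for (_, label), r in zip(results, records))
probs = np.array([p for p, _ in results])
truth = np.array([r.truth for r in records])
print(f"classified {correct}/{len(records)} correctly at p = 0.5")
print(f"  positives: max p = {probs[truth == 'known_positive'].max():.3f} (< 0.5)")
print(f"  negatives: min p = {probs[truth == 'known_negative'].min():.3f} (> 0.5)")

# Mahalanobis chi-square outlier test on the training cloud
cov = easi.fit_covariance(matrix)
critical, _ = easi.chi2_outlier_test(0.0, df=cov.k_retained, alpha=0.05)
print(f"\nchi-square critical value (df={cov.k_retained}, alpha=0.05): {critical:.1f}")
d_neg = easi.distances_for_matrix(cov, easi.assemble_matrix(neg, panel))
flagged = sum(easi.chi2_outlier_test(d, df=cov.k_retained)[1] for d in d_neg)
print(f"diastereomer-like negatives flagged as outliers: {flagged}/{len(d_neg)}")
print("(distances read as multivariate standard deviations from the mean)")
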