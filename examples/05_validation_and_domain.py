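"""Validate a model internally and map its applicability domain.

Fits the known-truth model on the synthetic bundle's calibration rows, then:
leave-one-out Q², ten Y-randomization refits (all must score below the true
model), and the Williams table of leverages and standardized residuals with
the warning leverage h* = 3(k+1)/n.
"""

from tyroqsar import (
    fit_ols,
    make_qsar_bundle,
    q2_loo,
    warning_leverage,
    williams_table,
    y_randomization,
)

bundle, split = make_qsar_bundle(seed=7)
cal, val = list(split.calibration_ids), list(split.validation_ids)
X, y = bundle.X, bundle.y
model = fit_ols(X.loc[cal], y.loc[cal], bundle.support)

q2, rms = q2_loo(X.loc[cal], y.loc[cal], bundle.support)
print(f"true-support model: R2_c = {model.r2:.3f}, Q2_LOO = {q2:.3f}, "
      f"RMS_CV = {rms:.3f}")

rand = y_randomization(X.loc[cal], y.loc[cal], bundle.support, n_iter=10, seed=7)
print("\nY-randomization (R2 / Q2_LOO per permuted refit):")
print(rand.table.round(3).to_string(index=False))
print(f"all permuted models below the true model: {rand.all_below}")

table = williams_table(model, X.loc[cal], y.loc[cal], X.loc[val], y.loc[val])
hstar = warning_leverage(model.k, len(cal))
print(f"\nWilliams table: h* = {hstar:.3f}")
print(f"high-leverage compounds: {int(table['high_leverage'].sum())}, "
      f"response outliers (|std res| > 2): {int(table['response_outlier'].sum())}")
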