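"""Backward interval elimination and cross-validation outlier screening.

Splits the NIR grid into 20 intervals, greedily removes the intervals
whose absence improves RMSECV, then screens the calibration samples with
the left-out deviation indicator F_y(i) ~ F(1, I-1).
"""
import numpy as np

import fruitspec as fs
from fruitspec.selection import make_intervals, modified_ipls, outlier_scores

batch = fs.generate_batch(fs.GeneratorConfig(n_samples=80, region="NIR", seed=7))
y = batch.concentrations.values("vitamin_c")
# corrupt one reference value, as a mislabeled lab assay would
y_bad = y.copy()
y_bad[11] += 8 * y.std()

chain = fs.parse_chain("SM + Log + 1st Dev + MC")
X = fs.fit_apply(chain, batch.spectra).values

scheme, trace = modified_ipls(X, y, make_intervals(X.shape[1], 20), max_lv=15)
print(f"intervals retained: {int(scheme.retained.sum())} of 20")
print("retained ranges (nm):", scheme.as_nm_ranges(batch.spectra.wavelengths))
full = trace.loc[trace['round'] == 0, 'rmsecv'].iloc[0]
print(f"RMSECV full spectrum {full:.4f} -> after elimination "
      f"{trace.loc[trace['removed'], 'rmsecv'].min():.4f} g/kg")

cv = fs.loo_cv(X[:, scheme.indices()], y_bad, max_lv=15)
rec = outlier_scores(cv, fs.select_lv(cv), alpha=0.01)
flagged = np.flatnonzero(rec.flags)
print(f"flagged samples: {flagged} (F_y = {np.round(rec.f_values[flagged], 1)})")
# the corrupted sample 11 carries by far the largest deviation score
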