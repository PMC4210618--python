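"""Why absolute deviations beat classical variance tests on dirty data.

Simulates a null dataset (no true variability differences) in which 200
of 10,000 features carry a single outlying sample, then compares how
Bartlett's test and the robust deviation test rank those contaminated
features, and their false-positive rates at nominal 0.001.
"""

import numpy as np

from diffvar import SimConfig, method_pvalues, outlier_rank_curve, simulate_dataset

rng = np.random.default_rng(7)
matrix, design, truth = simulate_dataset(SimConfig(n_outliers=200), rng)

for method in ("bartlett", "f_test", "diffvar_abs"):
    p = method_pvalues(method, matrix.values, design)
    curve = outlier_rank_curve(p, truth.has_outlier, top_k=500)
    rate = (p <= 0.001).mean()
    print(f"{method:12s} outliers in top 200: {curve[199]:3d}   "
          f"type-I error at 0.001: {rate:.5f}")
# The classical tests put the contaminated features straight at the top of
# the ranking and reject far more than 0.1% of these truly null features;
# the deviation-based test is barely perturbed.
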