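"""Two-round relaxed-LASSO stability selection with OLS refit and the
anti-overfitting constraints, on a small planted-signal matrix.

Round 1 records the support at the min-MSE and 1-SE penalty of each
cross-validated repetition; round 2 reruns selection on the union at the
1-SE rule; each surviving set is refit by OLS, scored by exhaustive
leave-one-trial-out Q², and the constrained best (p <= n/5,
|adjR² - Q²| <= 0.2, max adjusted R²) becomes the model.
"""

import numpy as np
import pandas as pd

from physiotrust import SelectionConfig, lasso_stability_select, select_model
from physiotrust.model import build_candidates

rng = np.random.default_rng(0)
n, p_noise = 480, 150
X = pd.DataFrame(rng.standard_normal((n, p_noise + 3)),
                 columns=["hr", "scl", "alpha"] + [f"noise{i}" for i in range(p_noise)])
y = 0.55 + 0.10 * X["hr"] - 0.08 * X["scl"] + 0.06 * X["alpha"] \
    + 0.08 * rng.standard_normal(n)
trials = np.repeat(np.arange(n // 8), 8)  # 8 epochs per trial

cfg = SelectionConfig(n_reps_round1=10, n_reps_round2=10, cv_folds=10,
                      n_lambdas=40, seed=0)
sel = lasso_stability_select(X, y, cfg)
print(f"round 1: {len(sel['round1_sets'])} recorded sets "
      f"({len(sel['round1_unique'])} unique), union -> {len(sel['round2_input'])} features")
print(f"round 2: {len(sel['round2_sets'])} sets at the 1-SE rule, "
      f"median size {int(np.median([len(s) for s in sel['round2_sets']]))}")

cands = build_candidates(X, y, trials, sel["round2_sets"])
model = select_model(cands, n_obs=n)
print(f"\nselected model: p={model.p}, adjusted R²={model.adj_r2:.3f}, "
      f"LOTO Q²={model.loto_q2:.3f}")
print("planted predictors recovered:",
      sorted(set(model.predictors) & {"hr", "scl", "alpha"}))
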