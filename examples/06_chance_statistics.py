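"""Chance-level statistics without any neural network.

Inverse-binomial significance thresholds, the bootstrap against the
binomial null, and the pooled-variance t-test comparing two decoders.
"""

import numpy as np

import eegdecode as eg
from eegdecode.stats import ChanceModel

for k in (2, 3, 7, 8):
    print(f"k={k}: chance level {eg.chance_level(k):.2f}%")

cm = ChanceModel(k_classes=7, n_predictions=210, alpha=0.05)
m, pct = eg.binomial_chance_threshold(cm)
print(f"7 classes, 210 predictions: need >= {m} correct ({pct:.1f}%) "
      f"to beat chance at alpha = 0.05")

# eight subjects decoding well above the 1/7 chance rate
accs = [32.0, 28.5, 35.1, 30.2, 27.8, 33.3, 29.0, 31.4]
res = eg.bootstrap_vs_chance(accs, cm, n_iter=100_000, seed=0)
print(f"mean accuracy {res.mean_accuracy:.1f}%, difference from chance "
      f"{res.mean_difference_from_chance:.1f}% "
      f"(95% CI {res.ci95[0]:.1f}..{res.ci95[1]:.1f}), p = {res.p_value:.2g}")

rng = np.random.default_rng(0)
model_a = rng.normal(29, 6, 30)
model_b = rng.normal(36, 7, 30)
t = eg.compare_models(model_b, model_a)
print(f"model comparison: t({t.degrees_of_freedom}) = {t.t_statistic:.2f}, "
      f"p = {t.p_value:.2g}, 95% CI of the difference "
      f"{t.ci95[0]:.2f}..{t.ci95[1]:.2f}")
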