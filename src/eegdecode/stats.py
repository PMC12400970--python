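"""Chance-level inference for decoding accuracies.

Observed per-subject accuracies are compared with a Binomial(n, 1/k) null:
the inverse binomial CDF gives the minimum correct count that exceeds
chance at significance alpha, and a bootstrap over subjects (resampled with
replacement, each paired with a fresh null draw) yields the mean
accuracy-minus-chance difference, its percentile 95% CI and a one-sided
p-value. A pooled-variance two-sample t-test compares two decoders'
per-subject accuracy lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .utils import substream


@dataclass(frozen=True)
class ChanceModel:
    """Binomial null for a k-class decoder scored on n predictions."""

    k_classes: int
    n_predictions: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.k_classes < 2:
            raise ValueError("k_classes must be >= 2")
        if self.n_predictions < 1:
            raise ValueError("n_predictions must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def chance_rate(self) -> float:
        return 1.0 / self.k_classes


@dataclass
class ChanceTestResult:
    mean_accuracy: float  # %
    sd: float  # %
    mean_difference_from_chance: float  # %
    ci95: tuple[float, float]  # %
    p_value: float
    n_bootstrap: int
    seed: int
    chance_level_pct: float
    threshold_accuracy_pct: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(d["ci95"])
        return d


@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    ci95: tuple[float, float]
    mean_difference: float


def chance_level(k: int) -> float:
    """Uniform-guessing accuracy in percent (100/k), to two decimals."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return round(100.0 / k, 2)


def binomial_chance_threshold(cm: ChanceModel) -> tuple[int, float]:
    """Smallest correct count m with P(X >= m) <= alpha under the null.

    X ~ Binomial(n, 1/k); computed by exact tail summation (no normal
    approximation). Returns ``(m, 100*m/n)``; when even m = n cannot reach
    significance, the sentinel ``m = n + 1`` marks an unattainable bound.
    """
    n, p, alpha = cm.n_predictions, cm.chance_rate, cm.alpha
    # P(X >= m) = sf(m - 1); scipy's binom.sf sums the exact pmf tail
    m_values = np.arange(n + 2)
    tail = sps.binom.sf(m_values - 1, n, p)
    ok = np.flatnonzero(tail <= alpha)
    m = int(ok[0]) if len(ok) else n + 1
    return m, 100.0 * m / n


def sample_null_accuracies(cm: ChanceModel, size: int, seed: int = 0) -> np.ndarray:
    """I.i.d. null accuracies X/n (in %) with X ~ Binomial(n, 1/k)."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = substream(seed, "null_accuracies")
    draws = rng.binomial(cm.n_predictions, cm.chance_rate, size=size)
    return 100.0 * draws / cm.n_predictions


def bootstrap_vs_chance(subject_accuracies, cm: ChanceModel,
                        n_iter: int = 100_000, seed: int = 0) -> ChanceTestResult:
    """Bootstrap the mean difference between observed accuracy and the null.

    Each iteration resamples subjects with replacement and draws one
    Binomial(n, 1/k) null accuracy per resampled subject; the recorded
    statistic is mean(observed) - mean(null). CI is the (2.5, 97.5)
    percentile interval; p is the one-sided proportion of iterations with
    difference <= 0, floored at 1/n_iter.

    `subject_accuracies` are percentages (one per participant).
    """
    acc = np.asarray(subject_accuracies, dtype=np.float64)
    if acc.size < 1:
        raise ValueError("need at least one subject accuracy")
    if n_iter < 100:
        import warnings
        warnings.warn("n_iter < 100: percentile CI will be unstable")
    rng = substream(seed, "bootstrap")
    s = acc.size
    idx = rng.integers(0, s, size=(n_iter, s))
    obs_means = acc[idx].mean(axis=1)
    null = rng.binomial(cm.n_predictions, cm.chance_rate, size=(n_iter, s))
    null_means = 100.0 * null.mean(axis=1) / cm.n_predictions
    diffs = obs_means - null_means
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    p = max(float((diffs <= 0).mean()), 1.0 / n_iter)
    m, thresh_pct = binomial_chance_threshold(cm)
    return ChanceTestResult(
        mean_accuracy=float(acc.mean()),
        sd=float(acc.std(ddof=1)) if s > 1 else 0.0,
        mean_difference_from_chance=float(diffs.mean()),
        ci95=(float(lo), float(hi)),
        p_value=p,
        n_bootstrap=int(n_iter),
        seed=int(seed),
        chance_level_pct=chance_level(cm.k_classes),
        threshold_accuracy_pct=thresh_pct,
    )


def compare_models(acc_a, acc_b) -> TTestResult:
    """Pooled-variance two-sample t-test on per-subject accuracy lists.

    df = n1 + n2 - 2; two-sided p; 95% CI of the mean difference a - b.
    With 30 subjects per decoder this is the t(58) comparison.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 accuracies per group")
    df = a.size + b.size - 2
    diff = a.mean() - b.mean()
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    if se == 0:
        # exact equality of all values: no variance to test against
        t_stat = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return TTestResult(float(t_stat), df, p, (float(diff), float(diff)), float(diff))
    t_stat = diff / se
    p = 2.0 * sps.t.sf(abs(t_stat), df)
    tcrit = sps.t.ppf(0.975, df)
    return TTestResult(float(t_stat), int(df), float(p),
                       (float(diff - tcrit * se), float(diff + tcrit * se)),
                       float(diff))
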