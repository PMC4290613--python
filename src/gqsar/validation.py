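"""Model validation statistics: r², LOO q², pred_r², F-test, Y-randomization.

All determination coefficients use the training-set mean activity as the
reference: q² = 1 − Σ(yi − ŷi)² / Σ(yi − ȳ_train)² over leave-one-out
predictions, and pred_r² applies the same formula to an external test set
(so it can go negative for a model worse than the training-mean predictor).
Y-randomization refits the whole selection + regression chain on permuted
activities and summarises the separation between the real statistic h and
the random-model distribution as Z = (h − μ)/σ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import DataError


def q2_loo(fit_predict, X: pd.DataFrame, y):
    """Leave-one-out cross-validated q² with full refit per fold.

    ``fit_predict(X_train, y_train, X_new) -> predictions`` must encapsulate
    the entire fitting procedure including any rescaling, so each fold is
    leakage-free.  Returns (q², per-compound LOO predictions).  The reference
    mean is the mean activity of the full training set.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise DataError("leave-one-out validation needs at least 3 compounds")
    preds = np.empty(n)
    for i in range(n):
        rest = np.ones(n, dtype=bool)
        rest[i] = False
        try:
            out = fit_predict(X.iloc[rest], y[rest], X.iloc[[i]])
        except Exception as exc:
            raise DataError(f"LOO refit failed at fold {i} (id {X.index[i]!r}): {exc}") from exc
        preds[i] = float(np.asarray(out).ravel()[0])
    y_mean = y.mean()
    denom = float(np.sum((y - y_mean) ** 2))
    if denom == 0:
        raise DataError("constant activities: q² undefined")
    return 1.0 - float(np.sum((y - preds) ** 2)) / denom, preds


@dataclass(frozen=True)
class PredictionSet:
    """Actual vs predicted activities with the training-mean reference."""

    actual: tuple
    predicted: tuple
    reference_mean: float

    def __post_init__(self):
        if len(self.actual) != len(self.predicted) or len(self.actual) < 2:
            raise DataError("need equal-length actual/predicted lists of length >= 2")


def pred_r2(p: PredictionSet) -> float:
    """External-validation r²: 1 − Σ(yi − ŷi)² / Σ(yi − ȳ_train)².

    ȳ_train is the training-set mean, so a model no better than predicting
    that mean scores 0 and a worse one scores negative.
    """
    actual = np.asarray(p.actual, dtype=float)
    predicted = np.asarray(p.predicted, dtype=float)
    denom = float(np.sum((actual - p.reference_mean) ** 2))
    if denom == 0:
        raise DataError("all test activities equal the training mean: pred_r² undefined")
    return 1.0 - float(np.sum((actual - predicted) ** 2)) / denom


def r2_and_se(actual, fitted, n: int, df_model: int) -> tuple[float, float]:
    """Squared Pearson correlation of fitted vs actual and the residual SE.

    ``se = sqrt(Σ residual² / (n − df_model − 1))`` where ``df_model`` is the
    model degrees of freedom (latent components for a PLS fit).
    """
    actual = np.asarray(actual, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if n <= df_model + 1:
        raise DataError("not enough residual degrees of freedom")
    if np.ptp(actual) == 0:
        raise DataError("constant activities: r² undefined")
    if np.ptp(fitted) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(actual, fitted)[0, 1] ** 2)
    resid = actual - fitted
    se = math.sqrt(float(resid @ resid) / (n - df_model - 1))
    return r2, se


def f_test(r2: float, n: int, c: int) -> float:
    """Overall model F on component degrees of freedom.

    ``F = (r²/c) / ((1 − r²)/(n − c − 1))``; an exact fit is flagged infinite.
    """
    if not 0 <= r2 <= 1:
        raise DataError("r² must lie in [0, 1]")
    if n <= c + 1:
        raise DataError("n must exceed c + 1")
    if r2 == 1.0:
        return math.inf
    return (r2 / c) / ((1.0 - r2) / (n - c - 1))


def z_to_p(z: float) -> float:
    """One-sided (upper tail) standard-normal p-value."""
    if not math.isfinite(z):
        raise DataError("Z-score must be finite")
    return float(_sps.norm.sf(z))


@dataclass(frozen=True)
class RandomizationResult:
    """Summary of a Y-randomization run for one statistic."""

    statistic: str
    h: float                 # the real-model statistic
    mu: float                # mean of the random-model statistics
    sigma: float             # sd (sample) of the random-model statistics
    z: float                 # (h − mu) / sigma
    best_random: float
    alpha: float             # empirical fraction of random stats >= h
    n_permutations: int
    seed: int

    @property
    def p_value(self) -> float:
        return z_to_p(self.z)


def y_randomization(fit_and_score, X: pd.DataFrame, y, n_permutations: int = 100,
                    seed: int = 0) -> dict[str, RandomizationResult]:
    """Y-randomization: refit the full pipeline on permuted activities.

    ``fit_and_score(X, y) -> {statistic_name: value}`` must rerun the entire
    model-building chain (selection included).  A permutation on which the
    chain yields no model scores 0 for every statistic rather than being
    skipped, so the null distribution is never thinned.  Returns one
    :class:`RandomizationResult` per statistic the scorer reports.
    """
    if n_permutations < 10:
        raise DataError("need at least 10 permutations")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    real = fit_and_score(X, y)
    samples: dict[str, list[float]] = {k: [] for k in real}
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        try:
            scores = fit_and_score(X, y[perm])
        except DataError:
            scores = {}
        for k in samples:
            samples[k].append(float(scores.get(k, 0.0)))
    out = {}
    for name, h in real.items():
        vals = np.array(samples[name])
        mu = float(vals.mean())
        sigma = float(vals.std(ddof=1))
        z = (h - mu) / sigma if sigma > 0 else math.inf if h > mu else 0.0
        out[name] = RandomizationResult(
            statistic=name, h=float(h), mu=mu, sigma=sigma, z=z,
            best_random=float(vals.max()),
            alpha=float(np.mean(vals >= h)),
            n_permutations=n_permutations, seed=seed,
        )
    return out


@dataclass
class ValidationReport:
    """All validation statistics of one fitted model."""

    n_train: int
    n_components: int
    r2: float
    r2_se: float
    q2: float
    q2_se: float
    f_statistic: float
    pred_r2: float | None = None
    pred_r2_se: float | None = None
    randomization: dict[str, RandomizationResult] = field(default_factory=dict)
    train_stats: object = None
    test_stats: object = None
    interpolative: bool | None = None

    def render(self) -> str:
        """Structured text table of the validation statistics."""
        def fmt(x):
            if x is None:
                return "n/a"
            return f"{x:.4f}" if math.isfinite(x) else "inf"

        lines = [
            f"N (training)        {self.n_train}",
            f"Optimum components  {self.n_components}",
            f"r2                  {fmt(self.r2)}",
            f"r2 se               {fmt(self.r2_se)}",
            f"q2                  {fmt(self.q2)}",
            f"q2 se               {fmt(self.q2_se)}",
            f"F test              {fmt(self.f_statistic)}",
            f"pred_r2             {fmt(self.pred_r2)}",
            f"pred_r2 se          {fmt(self.pred_r2_se)}",
        ]
        for name, rr in self.randomization.items():
            p = rr.p_value
            p_txt = "<0.0001" if p < 1e-4 else f"{p:.4f}"
            lines += [
                f"ZScore {name:<13}{fmt(rr.z)}",
                f"Best Rand {name:<10}{fmt(rr.best_random)}",
                f"Alpha Rand {name:<9}{rr.alpha:.5f}",
                f"P value {name:<12}{p_txt}",
            ]
        if self.interpolative is not None:
            lines.append(
                "Test set            "
                + ("interpolative" if self.interpolative else "extrapolative")
            )
        return "\n".join(lines)
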