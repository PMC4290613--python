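"""Stepwise-forward descriptor selection and PLS regression.

Model building follows the classic QSAR recipe: forward selection of
descriptors by partial F statistic under a pairwise cross-correlation cap
(F-to-enter 4.0, F-to-remove 3.0, |r| ≤ 0.5 by default), then a PLS1
(NIPALS) regression on the autoscaled selected block with the number of
latent components chosen by leave-one-out q².  Selection itself runs on
ordinary least-squares fits — the thresholds govern one-term F changes —
and PLS is applied to the final selected set.

The fitted model is stored with coefficients back-transformed to original
descriptor units so it can be written, read and exchanged as a plain linear
equation (intercept + Σ coefficient × descriptor); predictions through the
back-transformed form agree with the latent-space form to numerical
round-off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from . import validation as _validation


@dataclass(frozen=True)
class SelectionConfig:
    """Stepwise-forward selection settings.

    ``max_terms=None`` means the n/5 rule: at most floor(n_train / 5)
    descriptors may enter.
    """

    f_to_enter: float = 4.0
    f_to_remove: float = 3.0
    cross_correlation_limit: float = 0.5
    max_terms: int | None = None
    term_criterion: str = "r2"

    def __post_init__(self):
        if self.f_to_enter <= self.f_to_remove:
            raise ConfigError("f_to_enter must exceed f_to_remove")
        if not 0 < self.cross_correlation_limit <= 1:
            raise ConfigError("cross_correlation_limit must be in (0, 1]")

    def resolved_max_terms(self, n: int) -> int:
        return self.max_terms if self.max_terms is not None else max(1, n // 5)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of an intercept-included least-squares fit."""
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid)


def partial_f(current_model_rss: float, candidate_rss: float, n: int, p_full: int) -> float:
    """Partial F statistic for a one-term model change.

    ``F = (RSS_reduced − RSS_full) / (RSS_full / (n − p_full − 1))`` where the
    full model has ``p_full`` descriptors plus intercept.  A perfect candidate
    (zero full-model RSS) returns ``inf`` — a definite enter.
    """
    df = n - p_full - 1
    if df <= 0:
        raise DataError(f"non-positive residual degrees of freedom ({df})")
    reduction = current_model_rss - candidate_rss
    if candidate_rss <= 0:
        return math.inf if reduction > 0 else 0.0
    return max(0.0, reduction) / (candidate_rss / df)


def stepwise_forward(X: pd.DataFrame, y, cfg: SelectionConfig | None = None):
    """Stepwise-forward descriptor selection with F-to-enter / F-to-remove.

    Each round, among candidates whose absolute pairwise correlation with
    every already-selected descriptor is within the cross-correlation limit,
    the one with the largest partial F enters if it clears ``f_to_enter``;
    then any selected term whose removal F falls to ``f_to_remove`` or below
    leaves.  Stops when nothing changes or ``max_terms`` is reached.  Fully
    deterministic; ties break lexicographically on descriptor name.

    Returns the ordered selected-name list and a human-readable trace.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise DataError("X and y disagree on the number of compounds")
    if X.shape[1] < 1:
        raise DataError("no candidate descriptors")
    if n < 6:
        raise DataError("stepwise selection needs at least 6 compounds")
    variances = X.var(axis=0, ddof=1)
    dead = variances[variances == 0].index.tolist()
    if dead:
        raise DataError(f"zero-variance columns must be pre-filtered: {dead}")

    max_terms = cfg.resolved_max_terms(n)
    corr = X.corr().abs()
    cols = {c: X[c].to_numpy(dtype=float) for c in X.columns}

    selected: list[str] = []
    trace: list[str] = []
    seen_states = {tuple()}

    def rss_of(names) -> float:
        if not names:
            mat = np.empty((n, 0))
        else:
            mat = np.column_stack([cols[c] for c in names])
        return _ols_rss(mat, y)

    current_rss = rss_of(selected)
    while True:
        changed = False
        # --- entry step -------------------------------------------------
        if len(selected) < max_terms and n - (len(selected) + 1) - 1 > 0:
            best_name, best_f, best_rss = None, -math.inf, None
            for name in sorted(c for c in X.columns if c not in selected):
                if any(corr.loc[name, s] > cfg.cross_correlation_limit for s in selected):
                    continue
                cand_rss = rss_of(selected + [name])
                f = partial_f(current_rss, cand_rss, n, len(selected) + 1)
                if f > best_f:  # strict: lexicographic order wins ties
                    best_name, best_f, best_rss = name, f, cand_rss
            if best_name is not None and best_f >= cfg.f_to_enter:
                selected.append(best_name)
                current_rss = best_rss
                trace.append(f"enter {best_name} (partial F = {best_f:.4g})")
                changed = True
        # --- removal step -----------------------------------------------
        if len(selected) > 1:
            worst_name, worst_f = None, math.inf
            for name in sorted(selected):
                reduced_rss = rss_of([s for s in selected if s != name])
                f = partial_f(reduced_rss, current_rss, n, len(selected))
                if f < worst_f:
                    worst_name, worst_f = name, f
            if worst_name is not None and worst_f <= cfg.f_to_remove:
                selected.remove(worst_name)
                current_rss = rss_of(selected)
                trace.append(f"remove {worst_name} (partial F = {worst_f:.4g})")
                changed = True
        state = tuple(sorted(selected))
        if not changed or state in seen_states:
            break
        seen_states.add(state)
    return selected, trace


class PLSModel:
    """PLS1 latent model (NIPALS) on autoscaled X and centered y.

    Attributes: ``weights`` W, ``loadings`` P, ``y_loadings`` q, ``scores`` T
    (one column per latent component) and ``coef_``, the regression vector in
    the scaled space.
    """

    def __init__(self, weights, loadings, y_loadings, scores, coef, n_components):
        self.weights = weights
        self.loadings = loadings
        self.y_loadings = y_loadings
        self.scores = scores
        self.coef_ = coef
        self.n_components = n_components

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(X_scaled, dtype=float) @ self.coef_


def fit_pls(X_scaled, y_centered, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS deflation.

    With ``n_components`` equal to the column rank, predictions coincide with
    the ordinary least-squares solution.  A zero-variance response yields a
    zero regression vector (no extractable component).
    """
    X = np.array(X_scaled, dtype=float)
    y = np.array(y_centered, dtype=float)
    n, k = X.shape
    if not 1 <= n_components <= min(k, n - 2):
        raise ConfigError(
            f"n_components must be in [1, min(n_descriptors, n-2)] = "
            f"[1, {min(k, n - 2)}], got {n_components}"
        )
    Xa, ya = X.copy(), y.copy()
    W, P, Q, T = [], [], [], []
    eps = 1e-12 * max(1.0, float(np.abs(X).max()) ** 2) * max(1.0, float(np.abs(y).max()))
    for _ in range(n_components):
        w = Xa.T @ ya
        norm_w = np.linalg.norm(w)
        if norm_w <= eps:
            break  # no covariance left to model
        w = w / norm_w
        t = Xa @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        p = Xa.T @ t / tt
        q = float(t @ ya) / tt
        Xa = Xa - np.outer(t, p)
        ya = ya - q * t
        W.append(w); P.append(p); Q.append(q); T.append(t)
    if not W:
        zeros = np.zeros(k)
        return PLSModel(np.zeros((k, 0)), np.zeros((k, 0)), np.zeros(0),
                        np.zeros((n, 0)), zeros, 0)
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    Tm = np.column_stack(T)
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return PLSModel(Wm, Pm, qv, Tm, coef, Wm.shape[1])


def _pls_fit_predict(X_train: pd.DataFrame, y_train: np.ndarray,
                     X_new: pd.DataFrame, n_components: int) -> np.ndarray:
    """Autoscale on the training fold, fit PLS, predict new rows (no leakage)."""
    means = X_train.mean(axis=0)
    sds = X_train.std(axis=0, ddof=1).replace(0.0, 1.0)
    y_mean = float(np.mean(y_train))
    nc = min(n_components, X_train.shape[1], len(y_train) - 2)
    model = fit_pls(((X_train - means) / sds).to_numpy(),
                    np.asarray(y_train, float) - y_mean, max(1, nc))
    return model.predict(((X_new - means) / sds).to_numpy()) + y_mean


def choose_components(X_selected: pd.DataFrame, y, max_c: int | None = None) -> int:
    """Latent-component count maximizing leave-one-out q²; ties favour fewer."""
    y = np.asarray(y, dtype=float)
    n, k = X_selected.shape
    if n < 3:
        raise DataError("leave-one-out component selection needs at least 3 compounds")
    cap = min(k, n - 3)  # each LOO fold must still satisfy nc <= n_fold - 2
    max_c = cap if max_c is None else min(max_c, cap)
    if max_c < 1:
        raise DataError("too few compounds for any latent component")
    best_c, best_q2 = 1, -math.inf
    for c in range(1, max_c + 1):
        q2, _ = _validation.q2_loo(
            lambda Xt, yt, Xn, c=c: _pls_fit_predict(Xt, yt, Xn, c), X_selected, y)
        if q2 > best_q2 + 1e-12:
            best_c, best_q2 = c, q2
    return best_c


@dataclass
class FittedModel:
    """Final group-QSAR model in original descriptor units.

    ``coefficients[i]`` multiplies ``descriptor_names[i]`` directly (no
    scaling applied by the caller); ``scaling`` keeps the training per-column
    (mean, sd) and ``training_ranges`` the per-descriptor (min, max) used for
    extrapolation flagging.
    """

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    n_components: int
    scaling: dict[str, tuple[float, float]]
    training_ranges: dict[str, tuple[float, float]]

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.descriptor_names):
            raise ConfigError("one coefficient per descriptor name required")

    # -- prediction ----------------------------------------------------
    def _vector(self, d) -> np.ndarray:
        missing = [k for k in self.descriptor_names if k not in d]
        if missing:
            raise DataError(f"descriptor vector is missing {missing}")
        return np.array([float(d[k]) for k in self.descriptor_names])

    def predict_one(self, d) -> tuple[float, bool]:
        """Predicted pIC50 for one descriptor mapping + extrapolation flag."""
        x = self._vector(d)
        value = float(self.intercept + self.coefficients @ x)
        flag = any(
            not (lo <= xi <= hi)
            for xi, (lo, hi) in zip(x, (self.training_ranges[k] for k in self.descriptor_names))
        )
        return value, flag

    def predict(self, X) -> np.ndarray:
        """Vectorized prediction over a DataFrame holding the model columns."""
        missing = [k for k in self.descriptor_names if k not in X.columns]
        if missing:
            raise DataError(f"descriptor matrix is missing {missing}")
        return (X[self.descriptor_names].to_numpy(dtype=float) @ self.coefficients
                + self.intercept)

    # -- interpretation ------------------------------------------------
    @property
    def scaled_coefficients(self) -> np.ndarray:
        """Coefficients in autoscaled descriptor space (coefficient × column sd)."""
        sds = np.array([self.scaling[k][1] for k in self.descriptor_names])
        return self.coefficients * sds

    def equation(self) -> str:
        """Render the model as a plain linear pIC50 equation."""
        terms = [
            f"({coef:.6g} × {name})"
            for name, coef in zip(self.descriptor_names, self.coefficients)
        ]
        return "pIC50 = " + " + ".join(terms) + f" + {self.intercept:.6g}"

    # -- serialization (round-trips exactly via repr floats) ------------
    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "n_components": int(self.n_components),
            "scaling": {k: [float(a), float(b)] for k, (a, b) in self.scaling.items()},
            "training_ranges": {k: [float(a), float(b)]
                                for k, (a, b) in self.training_ranges.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            descriptor_names=list(d["descriptor_names"]),
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            n_components=int(d["n_components"]),
            scaling={k: (float(a), float(b)) for k, (a, b) in d["scaling"].items()},
            training_ranges={k: (float(a), float(b))
                             for k, (a, b) in d["training_ranges"].items()},
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def finalize(pls: PLSModel, X_train_raw: pd.DataFrame, y_train,
             means: pd.Series, sds: pd.Series) -> FittedModel:
    """Back-transform a scaled-space PLS fit into original descriptor units.

    Predictions through the returned :class:`FittedModel` equal the
    scaled-space predictions to numerical round-off (the transform is exact).
    """
    names = list(X_train_raw.columns)
    y = np.asarray(y_train, dtype=float)
    sd_arr = sds.to_numpy(dtype=float)
    mean_arr = means.to_numpy(dtype=float)
    coef_orig = pls.coef_ / sd_arr
    intercept = float(np.mean(y) - coef_orig @ mean_arr)
    return FittedModel(
        descriptor_names=names,
        coefficients=coef_orig,
        intercept=intercept,
        n_components=pls.n_components,
        scaling={k: (float(m), float(s)) for k, m, s in zip(names, mean_arr, sd_arr)},
        training_ranges={k: (float(X_train_raw[k].min()), float(X_train_raw[k].max()))
                         for k in names},
    )


def contributions(model: FittedModel, X_train: pd.DataFrame | None = None) -> pd.Series:
    """Percentage contribution of each descriptor, summing to 100.

    Computed as normalised absolute autoscaled coefficients
    ``|b_scaled,i| / Σ|b_scaled,j| × 100``; ``X_train`` is accepted for
    interface symmetry but the stored scaling already fixes the result.
    """
    b = np.abs(model.scaled_coefficients)
    total = b.sum()
    if total == 0:
        raise DataError("all model coefficients are zero; contributions undefined")
    return pd.Series(100.0 * b / total, index=model.descriptor_names,
                     name="contribution_pct")
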