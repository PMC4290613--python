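"""Model/Results API tying the pipeline together.

``GroupQSAR`` is built from a descriptor matrix and an activity vector (or
directly from a series of compounds via :meth:`GroupQSAR.from_series`);
``fit()`` runs invariable-descriptor removal, stepwise-forward selection,
LOO-guided component choice and the PLS regression, and returns a
:class:`GroupQSARResults` carrying the back-transformed equation, the
training statistics, and methods for external validation, Y-randomization,
contribution analysis and prediction.

>>> compounds, split_spec, _ = synthetic.arylthioindole_fixture()   # doctest: +SKIP
>>> train, test = dataset.split(compounds, split_spec)
>>> model = GroupQSAR.from_series(train, sites=("R4", "R5", "R6"))
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dataset as _ds
from . import descriptors as _desc
from . import modeling as _mod
from . import validation as _val
from .errors import ConfigError, DataError


class GroupQSAR:
    """Fragment-descriptor QSAR model specification.

    Parameters
    ----------
    descriptors : DataFrame
        Compounds × site-prefixed fragment descriptors (raw units).
    activity : array-like
        pIC50 per compound, aligned with the descriptor rows.
    selection : SelectionConfig, optional
        Stepwise-forward settings (defaults: F-in 4.0, F-out 3.0, |r| ≤ 0.5,
        at most n/5 terms).
    variance_cutoff : float
        Raw-variance threshold for invariable-descriptor removal.
    """

    def __init__(self, descriptors: pd.DataFrame, activity,
                 selection: _mod.SelectionConfig | None = None,
                 variance_cutoff: float = 0.1):
        y = np.asarray(activity, dtype=float)
        if len(y) != descriptors.shape[0]:
            raise DataError("activity length must match descriptor rows")
        self.exog = descriptors
        self.endog = y
        self.selection = selection or _mod.SelectionConfig()
        self.variance_cutoff = variance_cutoff

    @classmethod
    def from_series(cls, compounds, sites=("R4", "R5", "R6"),
                    acceptor_rule: str = "NO", **kwargs) -> "GroupQSAR":
        """Build the model from series compounds by computing the descriptor block."""
        X = _desc.descriptor_block(compounds, sites, acceptor_rule)
        y = [c.pic50 for c in compounds]
        return cls(X, y, **kwargs)

    def fit(self, select: bool = True, descriptor_names=None,
            n_components: int | None = None) -> "GroupQSARResults":
        """Run the full model-building chain and return the results object.

        With ``select=False`` (or an explicit ``descriptor_names`` list) the
        stepwise stage is bypassed and the named columns are fitted directly.
        """
        X_filtered, removed = _ds.remove_invariable(self.exog, self.variance_cutoff)
        y = self.endog
        if descriptor_names is not None:
            select = False
        if select:
            selected, trace = _mod.stepwise_forward(X_filtered, y, self.selection)
            if not selected:
                raise DataError("stepwise selection entered no descriptor "
                                "(no candidate cleared F-to-enter)")
        else:
            selected = list(descriptor_names or X_filtered.columns)
            missing = [c for c in selected if c not in X_filtered.columns]
            if missing:
                raise DataError(f"requested descriptors missing after filtering: {missing}")
            trace = [f"selection bypassed; fitting {selected}"]
        X_sel = X_filtered[selected]
        n = len(y)

        nc = n_components or _mod.choose_components(X_sel, y)
        X_scaled, means, sds = _ds.autoscale(X_sel)
        pls = _mod.fit_pls(X_scaled.to_numpy(), y - y.mean(), nc)
        fitted = _mod.finalize(pls, X_sel, y, means, sds)

        in_sample = fitted.predict(X_sel)
        r2, r2_se = _val.r2_and_se(y, in_sample, n, fitted.n_components)
        q2, loo_pred = _val.q2_loo(
            lambda Xt, yt, Xn: _mod._pls_fit_predict(Xt, yt, Xn, fitted.n_components),
            X_sel, y)
        q2_se = math.sqrt(float(np.sum((y - loo_pred) ** 2))
                          / (n - fitted.n_components - 1))
        f_stat = _val.f_test(r2, n, fitted.n_components)
        return GroupQSARResults(
            model=self, fitted=fitted, selected=selected, trace=trace,
            removed_columns=removed, r2=r2, r2_se=r2_se, q2=q2, q2_se=q2_se,
            loo_predictions=loo_pred, f_statistic=f_stat,
        )

    # internal: one full selection+fit pass used by Y-randomization
    def _fit_and_score(self, X: pd.DataFrame, y: np.ndarray,
                       n_components: int) -> dict[str, float]:
        selected, _ = _mod.stepwise_forward(X, y, self.selection)
        if not selected:
            return {"r2": 0.0, "q2": 0.0}
        X_sel = X[selected]
        nc = min(n_components, len(selected), len(y) - 3)
        X_scaled, means, sds = _ds.autoscale(X_sel)
        pls = _mod.fit_pls(X_scaled.to_numpy(), y - y.mean(), max(1, nc))
        fitted = _mod.finalize(pls, X_sel, y, means, sds)
        r2, _ = _val.r2_and_se(y, fitted.predict(X_sel), len(y), fitted.n_components)
        q2, _ = _val.q2_loo(
            lambda Xt, yt, Xn: _mod._pls_fit_predict(Xt, yt, Xn, fitted.n_components),
            X_sel, y)
        return {"r2": r2, "q2": q2}


@dataclass
class GroupQSARResults:
    """Fitted group-QSAR model with its training diagnostics."""

    model: GroupQSAR
    fitted: _mod.FittedModel
    selected: list[str]
    trace: list[str]
    removed_columns: list[str]
    r2: float
    r2_se: float
    q2: float
    q2_se: float
    loo_predictions: np.ndarray
    f_statistic: float

    # -- convenience accessors ------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Coefficients in original descriptor units plus the intercept."""
        return pd.Series(
            list(self.fitted.coefficients) + [self.fitted.intercept],
            index=self.selected + ["intercept"], name="coefficient")

    @property
    def n_components(self) -> int:
        return self.fitted.n_components

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.fitted.predict(X)

    def contributions(self) -> pd.Series:
        return _mod.contributions(self.fitted)

    def equation(self) -> str:
        return self.fitted.equation()

    # -- external validation --------------------------------------------
    def validate(self, test_X: pd.DataFrame | None, test_y=None) -> _val.ValidationReport:
        """Assemble the full validation report, with external statistics when
        a (non-empty) test set is supplied."""
        pred_r2 = pred_se = None
        test_stats = None
        interpolative = None
        train_stats = _ds.unicolumn(self.model.endog)
        if test_X is not None and len(test_X) > 0:
            test_y = np.asarray(test_y, dtype=float)
            preds = self.predict(test_X)
            pset = _val.PredictionSet(tuple(test_y), tuple(preds),
                                      reference_mean=float(np.mean(self.model.endog)))
            pred_r2 = _val.pred_r2(pset)
            resid = test_y - preds
            pred_se = math.sqrt(float(resid @ resid) / len(test_y))
            test_stats = _ds.unicolumn(test_y)
            interpolative, _ = _ds.interpolation_check(train_stats, test_stats)
        return _val.ValidationReport(
            n_train=self.nobs, n_components=self.n_components,
            r2=self.r2, r2_se=self.r2_se, q2=self.q2, q2_se=self.q2_se,
            f_statistic=self.f_statistic, pred_r2=pred_r2, pred_r2_se=pred_se,
            train_stats=train_stats, test_stats=test_stats,
            interpolative=interpolative,
        )

    def y_randomization(self, n_permutations: int = 100, seed: int = 0
                        ) -> dict[str, _val.RandomizationResult]:
        """Rerun selection + PLS on permuted activities; Z-scores per statistic."""
        X_filtered, _ = _ds.remove_invariable(self.model.exog, self.model.variance_cutoff)
        return _val.y_randomization(
            lambda X, y: self.model._fit_and_score(X, y, self.n_components),
            X_filtered, self.model.endog,
            n_permutations=n_permutations, seed=seed)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary: equation, coefficients, statistics."""
        contrib = self.contributions()
        width = max(len(n) for n in self.selected) + 2
        lines = [
            "Group QSAR (stepwise-forward + PLS) results",
            "=" * 60,
            self.equation(),
            "-" * 60,
            f"{'descriptor':<{width}}{'coefficient':>14}{'scaled':>12}{'contrib %':>11}",
        ]
        for name, coef, b, pct in zip(self.selected, self.fitted.coefficients,
                                      self.fitted.scaled_coefficients, contrib):
            lines.append(f"{name:<{width}}{coef:>14.6g}{b:>12.5g}{pct:>11.3f}")
        lines += [
            f"{'intercept':<{width}}{self.fitted.intercept:>14.6g}",
            "-" * 60,
            f"N = {self.nobs}   components = {self.n_components}   "
            f"descriptors removed by variance filter = {len(self.removed_columns)}",
            f"r2 = {self.r2:.4f} (se {self.r2_se:.4f})   "
            f"q2 = {self.q2:.4f} (se {self.q2_se:.4f})   "
            f"F = {self.f_statistic:.4f}",
        ]
        return "\n".join(lines)
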