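"""Multinomial logistic stress classifier, statsmodels-style.

:class:`StressLogit` is built from a feature matrix and 3-class labels and
``fit()`` returns a :class:`StressLogitResults` carrying the estimates,
their standard errors, diagnostics, prediction methods and a ``summary()``
table. The model is the reference-class parameterisation of the multinomial
logit: with class 0 as reference, the linear predictor of class i is

    y_i = beta_{0,i} + beta_{1,i} x_1 + ... + beta_{m,i} x_m,

and class probabilities follow from the inverse logit (softmax). The fit
maximises the mean log-likelihood minus a small ridge penalty on the
(standardised) slopes — the penalty (default 1e-4) keeps the optimum finite
on separable data, which happens routinely on per-user datasets with as few
as ten labeled nights. Intercepts are never penalised, so the fitted mean
probabilities reproduce the empirical class frequencies exactly.

Features are standardised internally for optimisation; reported
coefficients and standard errors are on the original feature scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .types import ValidationError

__all__ = ["StressLogit", "StressLogitResults", "fit_logit", "DegenerateFitWarning"]

N_CLASSES = 3


class DegenerateFitWarning(UserWarning):
    """A class is absent from the training labels; its probability is 0."""


def _as_matrix(X, feature_names: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if feature_names is None else feature_names
        X = X[names].to_numpy(float)
        return X, names
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
    return X, list(feature_names)


class StressLogit:
    """Three-class multinomial logit model of daily perceived stress.

    Parameters
    ----------
    endog : array-like of int
        Class labels in {0, 1, 2}, one per observation.
    exog : array-like or DataFrame, shape (n, m)
        Feature matrix; no missing values allowed.
    feature_names : list of str, optional
        Names for the columns of ``exog`` (taken from the DataFrame when
        one is passed).
    ridge : float
        Penalty weight on the standardised slopes (per-observation scale,
        so duplicating every row leaves the fit unchanged).
    """

    def __init__(self, endog, exog, feature_names=None, ridge: float = 1e-4):
        X, names = _as_matrix(exog, feature_names)
        y = np.asarray(endog, int)
        if y.ndim != 1 or y.size != X.shape[0]:
            raise ValidationError("endog must be 1-D and match exog rows")
        if y.size == 0:
            raise ValidationError("no observations")
        if np.any((y < 0) | (y >= N_CLASSES)):
            raise ValidationError("labels must lie in {0, 1, 2}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("exog contains missing or non-finite values")
        if ridge < 0:
            raise ValidationError("ridge must be >= 0")
        self.endog = y
        self.exog = X
        self.feature_names = names
        self.ridge = float(ridge)
        self.classes_present = sorted(int(c) for c in np.unique(y))
        # standardisation for optimisation only
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "stress_class",
        features: list[str] | None = None,
        ridge: float = 1e-4,
    ) -> "StressLogit":
        """Build the model from a tidy table with one row per subject-day."""
        if features is None:
            features = [c for c in df.columns if c != label_col]
        sub = df[features + [label_col]].dropna()
        return cls(sub[label_col].to_numpy(int), sub[features], features, ridge)

    # --- penalised likelihood (standardised scale) -----------------------
    def _eta(self, theta: np.ndarray, Z: np.ndarray) -> np.ndarray:
        k = len(self._nonref)
        B = theta.reshape(k, Z.shape[1] + 1)
        eta = np.zeros((Z.shape[0], len(self.classes_present)))
        for j, cls_idx in enumerate(self._nonref_pos):
            eta[:, cls_idx] = B[j, 0] + Z @ B[j, 1:]
        return eta

    def _objective(self, theta: np.ndarray, Z: np.ndarray, yidx: np.ndarray):
        n, m = Z.shape
        k = len(self._nonref)
        B = theta.reshape(k, m + 1)
        eta = self._eta(theta, Z)
        lse = logsumexp(eta, axis=1)
        ll = eta[np.arange(n), yidx] - lse
        pen = 0.5 * self.ridge * np.sum(B[:, 1:] ** 2)
        f = -ll.mean() + pen
        P = softmax(eta, axis=1)
        G = np.zeros_like(B)
        for j, cls_idx in enumerate(self._nonref_pos):
            resid = P[:, cls_idx] - (yidx == cls_idx)
            G[j, 0] = resid.mean()
            G[j, 1:] = resid @ Z / n + self.ridge * B[j, 1:]
        return f, G.ravel()

    def fit(self, maxiter: int = 500, tol: float = 1e-10) -> "StressLogitResults":
        """Maximise the penalised likelihood (L-BFGS, analytic gradient)."""
        present = self.classes_present
        if len(present) < N_CLASSES:
            missing = sorted(set(range(N_CLASSES)) - set(present))
            warnings.warn(
                f"classes {missing} absent from training labels; their "
                "predicted probability is 0",
                DegenerateFitWarning,
                stacklevel=2,
            )
        self._nonref = present[1:]  # reference = lowest present class
        self._nonref_pos = list(range(1, len(present)))
        Z = (self.exog - self._mu) / self._sd
        yidx = np.searchsorted(present, self.endog)
        m = Z.shape[1]
        k = len(self._nonref)
        if k == 0:  # single observed class: nothing to estimate
            coef_std = np.zeros((0, m + 1))
            res = None
        else:
            theta0 = np.zeros(k * (m + 1))
            res = minimize(
                self._objective,
                theta0,
                args=(Z, yidx),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9},
            )
            coef_std = res.x.reshape(k, m + 1)
        coef_raw, cov_raw = self._to_raw_scale(coef_std, Z, yidx)
        eta = self._eta(coef_std.ravel(), Z) if k else np.zeros((len(yidx), 1))
        llf = float(np.sum(eta[np.arange(len(yidx)), yidx] - logsumexp(eta, axis=1)))
        return StressLogitResults(
            feature_names=list(self.feature_names),
            classes_present=present,
            coef=coef_raw,
            cov=cov_raw,
            ridge=self.ridge,
            nobs=len(yidx),
            llf=llf,
            converged=bool(res.success) if res is not None else True,
        )

    def _to_raw_scale(self, coef_std, Z, yidx):
        """Back-transform coefficients (and covariance) from the
        standardised to the original feature scale."""
        k, m1 = coef_std.shape
        m = m1 - 1
        coef_raw = coef_std.copy()
        if k:
            coef_raw[:, 1:] = coef_std[:, 1:] / self._sd
            coef_raw[:, 0] = coef_std[:, 0] - coef_std[:, 1:] @ (self._mu / self._sd)
        if k == 0:
            return coef_raw, np.zeros((0, 0))
        # observed information of the total penalised objective
        n = Z.shape[0]
        eta = self._eta(coef_std.ravel(), Z)
        P = softmax(eta, axis=1)
        Zb = np.hstack([np.ones((n, 1)), Z])
        H = np.zeros((k * m1, k * m1))
        for a, ca in enumerate(self._nonref_pos):
            for b, cb in enumerate(self._nonref_pos):
                wab = P[:, ca] * ((ca == cb) - P[:, cb])
                H[a * m1 : (a + 1) * m1, b * m1 : (b + 1) * m1] = (Zb * wab[:, None]).T @ Zb
        pen = np.zeros(k * m1)
        for a in range(k):
            pen[a * m1 + 1 : (a + 1) * m1] = self.ridge * n
        H += np.diag(pen)
        try:
            cov_std = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_std = np.full((k * m1, k * m1), np.nan)
        # linear map theta_raw = A theta_std, block-diagonal per class
        A1 = np.zeros((m1, m1))
        A1[0, 0] = 1.0
        A1[0, 1:] = -self._mu / self._sd
        A1[1:, 1:] = np.diag(1.0 / self._sd)
        A = np.kron(np.eye(k), A1)
        return coef_raw, A @ cov_std @ A.T


@dataclass
class StressLogitResults:
    """Fitted multinomial logit: estimates, uncertainty, prediction."""

    feature_names: list[str]
    classes_present: list[int]
    coef: np.ndarray  # (len(classes_present)-1, m+1), raw feature scale
    cov: np.ndarray
    ridge: float
    nobs: int
    llf: float
    converged: bool = True
    _colnames: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, float)
        self.cov = np.asarray(self.cov, float)
        self._colnames = ["const"] + list(self.feature_names)

    # --- presentation -----------------------------------------------------
    @property
    def params(self) -> pd.DataFrame:
        idx = [f"class {c}" for c in self.classes_present[1:]]
        return pd.DataFrame(self.coef, index=idx, columns=self._colnames)

    @property
    def bse(self) -> pd.DataFrame:
        k, m1 = self.coef.shape
        if k == 0:
            return pd.DataFrame(columns=self._colnames)
        se = np.sqrt(np.diag(self.cov)).reshape(k, m1)
        idx = [f"class {c}" for c in self.classes_present[1:]]
        return pd.DataFrame(se, index=idx, columns=self._colnames)

    def summary(self) -> str:
        lines = [
            "Multinomial stress logit (reference class "
            f"{self.classes_present[0] if self.classes_present else 0})",
            f"n obs: {self.nobs}   log-likelihood: {self.llf:.3f}   "
            f"ridge: {self.ridge:g}   converged: {self.converged}",
            "",
        ]
        params, bse = self.params, self.bse
        for row in params.index:
            lines.append(row)
            lines.append(f"  {'term':<22}{'coef':>12}{'std err':>12}{'z':>10}")
            for term in params.columns:
                c = params.loc[row, term]
                s = bse.loc[row, term] if row in bse.index else np.nan
                z = c / s if s and np.isfinite(s) and s > 0 else np.nan
                lines.append(f"  {term:<22}{c:>12.4f}{s:>12.4f}{z:>10.2f}")
            lines.append("")
        return "\n".join(lines)

    # --- prediction --------------------------------------------------------
    def _matrix(self, x) -> np.ndarray:
        if isinstance(x, dict) or hasattr(x, "values") and isinstance(getattr(x, "values", None), dict):
            vals = x.values if not isinstance(x, dict) else x
            row = []
            for name in self.feature_names:
                if name not in vals or vals[name] is None:
                    raise ValidationError(f"missing feature value for {name!r}")
                row.append(float(vals[name]))
            return np.array([row])
        if isinstance(x, pd.DataFrame):
            x = x[self.feature_names].to_numpy(float)
        x = np.asarray(x, float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}"
            )
        if not np.all(np.isfinite(x)):
            raise ValidationError("missing feature value in prediction input")
        return x

    def predict_proba(self, x) -> np.ndarray:
        """Class probabilities over all three classes, rows summing to 1.

        Accepts an array, a DataFrame, or a single feature dict /
        FeatureVector; absent training classes get probability 0."""
        X = self._matrix(x)
        eta = np.zeros((X.shape[0], len(self.classes_present)))
        for j in range(self.coef.shape[0]):
            eta[:, j + 1] = self.coef[j, 0] + X @ self.coef[j, 1:]
        p_present = softmax(eta, axis=1)
        out = np.zeros((X.shape[0], N_CLASSES))
        for j, c in enumerate(self.classes_present):
            out[:, c] = p_present[:, j]
        return out

    def classify(self, x) -> np.ndarray:
        """Predicted class per row (argmax, ties toward the lower class)."""
        return np.argmax(self.predict_proba(x), axis=1)

    def daily_scores(self, x) -> np.ndarray:
        """Daily stress scores DS = p . [0, 0.5, 1] per row."""
        return self.predict_proba(x) @ np.array([0.0, 0.5, 1.0])

    # --- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "classes_present": list(self.classes_present),
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "ridge": self.ridge,
            "nobs": int(self.nobs),
            "llf": float(self.llf),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StressLogitResults":
        return cls(
            feature_names=list(d["feature_names"]),
            classes_present=[int(c) for c in d["classes_present"]],
            coef=np.asarray(d["coef"], float).reshape(
                len(d["classes_present"]) - 1 if len(d["classes_present"]) > 1 else 0,
                len(d["feature_names"]) + 1,
            ),
            cov=np.asarray(d["cov"], float),
            ridge=float(d["ridge"]),
            nobs=int(d["nobs"]),
            llf=float(d["llf"]),
            converged=bool(d.get("converged", True)),
        )


def fit_logit(
    X, y, feature_names=None, regularization: float = 1e-4
) -> StressLogitResults:
    """Convenience wrapper: build a :class:`StressLogit` and fit it."""
    return StressLogit(y, X, feature_names=feature_names, ridge=regularization).fit()
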