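"""Weighted least squares with heteroscedasticity-robust inference.

This is the estimator behind every regression in the package: ordinary or
population-weighted least squares on a design matrix built from transformed
columns, with a sandwich (heteroscedasticity-consistent) coefficient
covariance and two-sided t-based p-values.

Weights are treated as analytic weights: they are rescaled internally to sum
to the number of observations, so all reported quantities are invariant to
rescaling the weight column by a positive constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ecostunt")

__all__ = [
    "Term",
    "ModelSpec",
    "RegressionResult",
    "SingularDesignError",
    "DataError",
    "ParameterError",
    "build_design",
    "fit_wls",
    "hc_robust_cov",
    "two_sided_p",
]

TRANSFORMS = ("identity", "log", "square")


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (collinear terms)."""


class DataError(ValueError):
    """Input rows violate the estimator's preconditions."""


class ParameterError(ValueError):
    """A supplied parameter is outside its valid range."""


@dataclass(frozen=True)
class Term:
    """One regressor: a source column plus a transform tag.

    ``label`` is how the term appears in results; it defaults to
    ``column`` for identity, ``ln(column)`` for log and ``column^2``
    for square.
    """

    column: str
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ParameterError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )

    @property
    def label(self) -> str:
        if self.transform == "log":
            return f"ln({self.column})"
        if self.transform == "square":
            return f"{self.column}^2"
        return self.column

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.transform == "log":
            if np.any(values <= 0):
                raise DataError(f"log transform of non-positive values in {self.column!r}")
            return np.log(values)
        if self.transform == "square":
            return values**2
        return values


@dataclass(frozen=True)
class ModelSpec:
    """A regression specification: outcome, ordered terms, optional weights.

    Terms must be unique as (column, transform) pairs; an intercept is
    included by default and is always the first coefficient.
    """

    outcome: str
    terms: tuple[Term, ...]
    weight_column: str | None = None
    intercept: bool = True

    def __post_init__(self) -> None:
        if not self.terms:
            raise ParameterError("ModelSpec requires at least one term")
        pairs = [(t.column, t.transform) for t in self.terms]
        if len(set(pairs)) != len(pairs):
            raise ParameterError(f"duplicate terms in ModelSpec: {pairs}")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def columns_used(self) -> list[str]:
        cols = [self.outcome] + [t.column for t in self.terms]
        if self.weight_column is not None:
            cols.append(self.weight_column)
        # preserve order, drop duplicates
        return list(dict.fromkeys(cols))

    @property
    def term_labels(self) -> list[str]:
        labels = ["const"] if self.intercept else []
        return labels + [t.label for t in self.terms]

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        """Build a spec from a plain mapping (e.g. parsed YAML).

        Expected keys: ``outcome``, ``terms`` (list of ``{column, transform}``
        or plain column names), optional ``weight_column`` and ``intercept``.
        """
        terms = []
        for t in d["terms"]:
            if isinstance(t, str):
                terms.append(Term(t))
            else:
                terms.append(Term(t["column"], t.get("transform", "identity")))
        return cls(
            outcome=d["outcome"],
            terms=tuple(terms),
            weight_column=d.get("weight_column"),
            intercept=d.get("intercept", True),
        )


@dataclass
class RegressionResult:
    """Fit summary: estimates, robust SEs, t, p, weighted R-squared."""

    term_labels: list[str]
    coefficients: np.ndarray
    robust_se: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n_obs: int
    n_params: int
    residuals: np.ndarray
    cov: np.ndarray = field(repr=False, default=None)
    n_dropped: int = 0

    def coef(self, label: str) -> float:
        return float(self.coefficients[self.term_labels.index(label)])

    def se(self, label: str) -> float:
        return float(self.robust_se[self.term_labels.index(label)])

    def conf_int(self, label: str, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for one coefficient."""
        i = self.term_labels.index(label)
        tcrit = stats.t.ppf(0.5 + level / 2, self.n_obs - self.n_params)
        half = tcrit * self.robust_se[i]
        return float(self.coefficients[i] - half), float(self.coefficients[i] + half)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Assemble (X, y, w, n_dropped) from a row table and a spec.

    Rows with a missing value in any used column are dropped (listwise
    deletion) with the count logged and returned.
    """
    cols = spec.columns_used
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"columns absent from data: {missing}")
    sub = data[cols].apply(pd.to_numeric)
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("listwise deletion dropped %d of %d rows", n_dropped, len(sub))
    sub = sub.loc[keep]

    y = sub[spec.outcome].to_numpy(dtype=float)
    columns = [t.apply(sub[t.column].to_numpy(dtype=float)) for t in spec.terms]
    if spec.intercept:
        columns.insert(0, np.ones(len(sub)))
    X = np.column_stack(columns)

    if spec.weight_column is None:
        w = np.ones(len(sub))
    else:
        w = sub[spec.weight_column].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise DataError(f"non-positive weights in {spec.weight_column!r}")
    return X, y, w, n_dropped


def fit_wls(data: pd.DataFrame, spec: ModelSpec, hc: str = "HC1") -> RegressionResult:
    """Fit the weighted least squares model described by ``spec``.

    Coefficients minimize the weighted residual sum of squares; the weighted
    R-squared is computed against the weighted-mean-centered total sum of
    squares. Coefficient covariance is the ``hc`` sandwich (default HC1;
    ``hc="classical"`` gives the homoscedastic s^2 (X'WX)^-1 form) and
    p-values come from the t distribution with n - k degrees of freedom.
    """
    X, y, w, n_dropped = build_design(data, spec)
    n, k = X.shape
    if n <= k:
        raise DataError(f"need more observations ({n}) than parameters ({k})")
    # analytic-weight normalization: sum of weights == n
    w = w * (n / w.sum())

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < k:
        corr = np.corrcoef(X.T) if k > 1 else np.ones((1, 1))
        labels = spec.term_labels
        collinear = [
            f"{labels[i]}~{labels[j]}"
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise SingularDesignError(
            f"design matrix rank {rank} < {k}; collinear terms: {collinear or 'unknown'}"
        )

    resid = y - X @ beta
    rss = float(w @ resid**2)
    ybar = float(w @ y) / n
    tss = float(w @ (y - ybar) ** 2)
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    r2 = float(min(1.0, max(0.0, r2)))

    if hc == "classical":
        try:
            cov = (rss / (n - k)) * np.linalg.inv(Xw.T @ Xw)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("singular X'WX") from exc
    else:
        cov = hc_robust_cov(X, resid, w, variant=hc)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    p = np.array([two_sided_p(ti, n - k) for ti in t])

    return RegressionResult(
        term_labels=spec.term_labels,
        coefficients=beta,
        robust_se=se,
        t_stats=t,
        p_values=p,
        r_squared=r2,
        n_obs=n,
        n_params=k,
        residuals=resid,
        cov=cov,
        n_dropped=n_dropped,
    )


def hc_robust_cov(
    design: np.ndarray,
    residuals: np.ndarray,
    weights: np.ndarray | None = None,
    variant: str = "HC1",
) -> np.ndarray:
    """Sandwich covariance of WLS coefficients.

    bread = (X'WX)^-1; meat = sum_i w_i^2 e_i^2 x_i x_i' (the weighted-design
    form, equivalent to HC0 on the square-root-weight whitened regression).
    HC1 applies the n/(n-k) small-sample factor; HC2 and HC3 divide squared
    residuals by (1-h_i) and (1-h_i)^2 where h_i is the whitened leverage.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    e = np.asarray(residuals, dtype=float)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise DataError("weights must be strictly positive")
    if e.shape != (n,) or w.shape != (n,):
        raise DataError("design, residuals and weights are not conformable")
    if variant not in ("HC0", "HC1", "HC2", "HC3"):
        raise ParameterError(f"unknown robust variant {variant!r}")

    Xw = X * np.sqrt(w)[:, None]
    bread_inv = Xw.T @ Xw
    try:
        bread = np.linalg.inv(bread_inv)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("singular bread matrix X'WX") from exc

    e2 = e**2
    if variant in ("HC2", "HC3"):
        h = np.einsum("ij,jk,ik->i", Xw, bread, Xw)
        adj = np.clip(1.0 - h, 1e-12, None)
        e2 = e2 / adj if variant == "HC2" else e2 / adj**2
    meat = (X * (w**2 * e2)[:, None]).T @ X
    cov = bread @ meat @ bread
    if variant == "HC1":
        cov = cov * n / (n - k)
    return (cov + cov.T) / 2.0


def two_sided_p(t: float, dof: float) -> float:
    """Two-sided p-value of a t statistic: 2 * P(T_dof > |t|)."""
    if dof < 1:
        raise ParameterError(f"degrees of freedom must be >= 1, got {dof}")
    if math.isnan(t):
        return float("nan")
    return float(min(1.0, 2.0 * stats.t.sf(abs(t), dof)))
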