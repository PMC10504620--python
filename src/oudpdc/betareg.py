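"""Beta regression with a logit link for patient-month PDC scores.

The response ``y in (0,1)`` is modelled as Beta with mean ``mu`` and
precision ``phi`` (shape parameters ``mu*phi`` and ``(1-mu)*phi``), the mean
linked to covariates by ``logit(mu) = x'beta`` and a single constant
precision, log-parameterized. Coefficients exponentiate to odds ratios on
the mean.

Because observed PDC hits the boundary (a fully covered month is exactly 1,
where the beta likelihood is undefined), responses are compressed into the
open interval with ``y' = (y*(N-1) + 0.5) / N`` before fitting — the usual
order-preserving adjustment for proportions data.

The likelihood is maximized by BFGS with the analytic gradient from a
least-squares start; standard errors come from the inverse observed
information (numerically differentiated gradient), Wald z tests, and the
pseudo-R² is the squared Pearson correlation between the fitted linear
predictor and ``logit(y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ModelSpec",
    "RegressionResult",
    "BetaRegression",
    "compress_boundary",
    "beta_loglik",
    "beta_loglik_grad",
    "design_matrix",
    "fit_beta_regression",
    "odds_ratio_table",
    "RankDeficientDesign",
]

AGE_BANDS = ("<16", "17-29", "30-39", "40-49", "50-59", ">=60")
AGE_REFERENCE = "17-29"
_AGE_COLUMNS = {
    "<16": "age_lt16",
    "30-39": "age_30_39",
    "40-49": "age_40_49",
    "50-59": "age_50_59",
    ">=60": "age_ge60",
}


class RankDeficientDesign(ValueError):
    """Design matrix is not full column rank; names the offending columns."""


def age_band(age: int) -> str:
    """Assign an age in years to the model's age bands.

    The bands follow the conventional grouping ``<16, 17-29, 30-39, 40-49,
    50-59, >=60``; ages of exactly 16 fall in the youngest band.
    """
    if age < 17:
        return "<16"
    if age < 30:
        return "17-29"
    if age < 40:
        return "30-39"
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    return ">=60"


@dataclass(frozen=True)
class ModelSpec:
    """Covariate layout of the adherence model.

    ``include_n_months`` adds the per-patient count of monthly scores — used
    only by the sensitivity ("all patients") model, where it varies.
    """

    states: tuple[str, ...] = ("1", "2", "3", "4", "5", "6")
    elixhauser: tuple[str, ...] = ("NeuroOther", "Obesity", "FluidsLytes", "Alcohol", "Drugs")
    include_n_months: bool = False
    include_n_f11: bool = True
    boundary_adjustment: str = "smithson_verkuilen"

    def __post_init__(self) -> None:
        if self.boundary_adjustment not in ("smithson_verkuilen", "none"):
            raise ValueError(f"unknown boundary_adjustment {self.boundary_adjustment!r}")
        if len(set(self.states)) != len(self.states):
            raise ValueError("state levels must be unique")

    @property
    def columns(self) -> tuple[str, ...]:
        cols = ["covid"]
        cols += [_AGE_COLUMNS[b] for b in AGE_BANDS if b != AGE_REFERENCE]
        cols += ["sex_male", "pdc_month_2", "pdc_month_3"]
        if self.include_n_months:
            cols.append("n_months_of_pdc")
        if self.include_n_f11:
            cols.append("n_f11_codes")
        cols += [f"state_{s}" for s in self.states[1:]]
        cols += [f"elix_{c}" for c in self.elixhauser]
        return tuple(cols)


def compress_boundary(y, n: int | None = None) -> np.ndarray:
    """Map proportions in [0,1] strictly into (0,1): ``(y*(N-1)+0.5)/N``.

    ``N`` defaults to the number of observations and must be >= 2. The map is
    affine, hence order-preserving.
    """
    y = np.asarray(y, dtype=float)
    if y.size and (y.min() < 0 or y.max() > 1):
        raise ValueError("y must lie in [0, 1]")
    N = len(y) if n is None else n
    if N < 2:
        raise ValueError("boundary compression needs N >= 2")
    return (y * (N - 1) + 0.5) / N


def _check_open_unit(y: np.ndarray) -> None:
    if y.size and (y.min() <= 0 or y.max() >= 1):
        raise ValueError(
            "y must lie strictly in (0, 1); apply compress_boundary first"
        )


def beta_loglik(beta: np.ndarray, log_phi: float, X: np.ndarray, y: np.ndarray) -> float:
    """Beta log-likelihood with logit mean link and constant precision."""
    y = np.asarray(y, float)
    _check_open_unit(y)
    mu = special.expit(np.asarray(X, float) @ np.asarray(beta, float))
    phi = np.exp(log_phi)
    a, b = mu * phi, (1.0 - mu) * phi
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    )


def beta_loglik_grad(
    beta: np.ndarray, log_phi: float, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Analytic gradient of :func:`beta_loglik` in ``(beta, log_phi)``."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    mu = special.expit(X @ np.asarray(beta, float))
    phi = np.exp(log_phi)
    y_star = np.log(y) - np.log1p(-y)
    mu_star = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
    g_beta = phi * (X.T @ ((y_star - mu_star) * mu * (1.0 - mu)))
    dphi = np.sum(
        mu * (y_star - mu_star)
        + np.log1p(-y)
        - special.digamma((1.0 - mu) * phi)
        + special.digamma(phi)
    )
    return np.concatenate([g_beta, [phi * dphi]])


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.nonzero(diag <= tol)[0]]
    if bad:
        raise RankDeficientDesign(f"collinear design column(s): {', '.join(bad)}")


class BetaRegression(RegressorMixin, BaseEstimator):
    """Maximum-likelihood beta regression, scikit-learn style.

    Parameters
    ----------
    fit_intercept : bool
        Prepend a constant column.
    boundary_adjustment : {"smithson_verkuilen", "none"}
        Whether to compress [0,1] responses into (0,1) before fitting.
    tol : float
        Gradient-norm convergence tolerance.
    max_iter : int
        Maximum BFGS iterations.

    Attributes
    ----------
    coef_, intercept_ : ML estimates on the logit scale.
    phi_ : precision estimate.
    bse_ : standard errors aligned with ``[intercept?, coef..., log(phi)]``.
    loglik_, pseudo_r2_, n_iter_, converged_, loglik_path_ : fit diagnostics.
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        boundary_adjustment: str = "smithson_verkuilen",
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        self.fit_intercept = fit_intercept
        self.boundary_adjustment = boundary_adjustment
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X, y, column_names: Sequence[str] | None = None):
        y = np.asarray(y, dtype=float)
        Xd = self._design(X)
        if len(y) != len(Xd):
            raise ValueError("X and y have different lengths")
        if column_names is not None:
            names = list(column_names)
        else:
            names = [f"x{i}" for i in range(Xd.shape[1] - int(self.fit_intercept))]
        if self.fit_intercept:
            names = ["const"] + names
        _check_rank(Xd, names)
        if self.boundary_adjustment == "smithson_verkuilen":
            y = compress_boundary(y)
        _check_open_unit(y)

        # least-squares start on the logit scale; method-of-moments precision
        z = np.log(y) - np.log1p(-y)
        b0, *_ = np.linalg.lstsq(Xd, z, rcond=None)
        resid = z - Xd @ b0
        dof = max(1, len(y) - Xd.shape[1])
        sigma2 = float(resid @ resid) / dof
        mu0 = special.expit(Xd @ b0)
        phi0 = float(np.mean(1.0 / (sigma2 * mu0 * (1.0 - mu0)) - 1.0))
        phi0 = max(phi0, 0.5)
        x0 = np.concatenate([b0, [np.log(phi0)]])

        def negll(theta):
            return -beta_loglik(theta[:-1], theta[-1], Xd, y)

        def neggrad(theta):
            return -beta_loglik_grad(theta[:-1], theta[-1], Xd, y)

        path = [-negll(x0)]
        res = optimize.minimize(
            negll,
            x0,
            jac=neggrad,
            method="BFGS",
            callback=lambda xk: path.append(-negll(xk)),
            options={"gtol": self.tol, "maxiter": self.max_iter},
        )
        theta = res.x
        self.converged_ = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-3
        self.n_iter_ = int(res.nit)
        self.loglik_path_ = np.asarray(path)

        cov = np.linalg.inv(_numeric_hessian(negll_grad=neggrad, theta=theta))
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        k = Xd.shape[1]
        self.names_ = tuple(names)
        self.params_ = theta[:k]
        self.log_phi_ = float(theta[-1])
        self.phi_ = float(np.exp(theta[-1]))
        self.bse_ = bse[:k]
        self.bse_log_phi_ = float(bse[-1])
        self.cov_params_ = cov
        if self.fit_intercept:
            self.intercept_ = float(theta[0])
            self.coef_ = theta[1:k]
        else:
            self.intercept_ = 0.0
            self.coef_ = theta[:k]
        self.loglik_ = float(-res.fun)
        eta = Xd @ theta[:k]
        self.pseudo_r2_ = float(np.corrcoef(eta, z)[0, 1] ** 2) if k > 1 or np.std(eta) > 0 else 0.0
        self.n_obs_ = len(y)
        return self

    def predict(self, X) -> np.ndarray:
        """Estimated mean PDC for each row of ``X``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        return special.expit(self._design(X) @ self.params_)


def _numeric_hessian(negll_grad, theta: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian of the negative-loglik gradient."""
    p = len(theta)
    H = np.empty((p, p))
    for j in range(p):
        step = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        H[:, j] = (negll_grad(tp) - negll_grad(tm)) / (2.0 * step)
    return 0.5 * (H + H.T)


@dataclass
class RegressionResult:
    """Named coefficient table plus fit summary.

    ``table`` has one row per coefficient (the intercept last, labelled
    "const") with columns ``beta, se, z, p, or, or_ci_low, or_ci_high``.
    """

    table: pd.DataFrame
    phi: float
    loglik: float
    pseudo_r2: float
    n_obs: int
    converged: bool
    n_iter: int
    model: BetaRegression = field(repr=False, default=None)

    def coefficient(self, name: str) -> pd.Series:
        return self.table.loc[name]


def design_matrix(
    panel: pd.DataFrame,
    patients: pd.DataFrame,
    comorbidity_flags: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    f11_counts: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Patient-month design matrix and raw response for the adherence model.

    ``panel`` is a PDC panel (one row per patient-month), ``patients`` a
    demographics frame (``patient_id, sex, age_at_index, state``),
    ``comorbidity_flags`` a 0/1 frame indexed by patient_id, and
    ``f11_counts`` the per-patient count of F11-coded diagnosis claims.
    Factors are dummy-coded against the references: age 17-29, female, first
    PDC month, first state level. Raises on patient-months whose demographics
    are missing or whose state is not a declared level.
    """
    spec = spec or ModelSpec()
    pat = patients.set_index("patient_id") if "patient_id" in patients.columns else patients
    missing = sorted(set(panel["patient_id"]) - set(pat.index))
    if missing:
        raise ValueError(f"panel patients missing demographics: {missing[:10]}")
    merged = panel.merge(pat, left_on="patient_id", right_index=True, how="left")

    bad_states = sorted(set(merged["state"].astype(str)) - set(spec.states))
    if bad_states:
        raise ValueError(f"unseen state level(s): {bad_states}")

    X = pd.DataFrame(index=merged.index)
    X["covid"] = merged["covid"].astype(int)
    bands = merged["age_at_index"].astype(int).map(age_band)
    for band, col in _AGE_COLUMNS.items():
        X[col] = (bands == band).astype(int)
    X["sex_male"] = (merged["sex"] == "M").astype(int)
    X["pdc_month_2"] = (merged["month_index"] == 2).astype(int)
    X["pdc_month_3"] = (merged["month_index"] == 3).astype(int)
    if spec.include_n_months:
        n_months = panel.groupby("patient_id")["month_index"].size()
        X["n_months_of_pdc"] = merged["patient_id"].map(n_months).astype(float)
    if spec.include_n_f11:
        if f11_counts is None:
            raise ValueError("spec.include_n_f11 requires f11_counts")
        X["n_f11_codes"] = merged["patient_id"].map(f11_counts).fillna(0).astype(float)
    for s in spec.states[1:]:
        X[f"state_{s}"] = (merged["state"].astype(str) == s).astype(int)
    if comorbidity_flags is None:
        comorbidity_flags = pd.DataFrame(columns=list(spec.elixhauser))
    for cat in spec.elixhauser:
        col = (
            comorbidity_flags[cat]
            if cat in comorbidity_flags.columns
            else pd.Series(0, index=comorbidity_flags.index)
        )
        X[f"elix_{cat}"] = merged["patient_id"].map(col).fillna(0).astype(int)
    X = X[list(spec.columns)]
    y = merged["pdc"].to_numpy(float)
    return X, y


def fit_beta_regression(
    X: pd.DataFrame, y, spec: ModelSpec | None = None
) -> RegressionResult:
    """Fit the adherence model and return a named coefficient table."""
    spec = spec or ModelSpec()
    est = BetaRegression(
        fit_intercept=True, boundary_adjustment=spec.boundary_adjustment
    )
    names = list(X.columns) if hasattr(X, "columns") else None
    est.fit(np.asarray(X, float), y, column_names=names)
    order = (names or list(est.names_[1:])) + ["const"]
    idx = {n: i for i, n in enumerate(est.names_)}
    beta = np.array([est.params_[idx[n]] for n in order])
    se = np.array([est.bse_[idx[n]] for n in order])
    with np.errstate(divide="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * special.ndtr(-np.abs(z))
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "or": np.exp(beta),
            "or_ci_low": np.exp(beta - 1.96 * se),
            "or_ci_high": np.exp(beta + 1.96 * se),
        },
        index=pd.Index(order, name="coefficient"),
    )
    return RegressionResult(
        table=table,
        phi=est.phi_,
        loglik=est.loglik_,
        pseudo_r2=est.pseudo_r2_,
        n_obs=est.n_obs_,
        converged=est.converged_,
        n_iter=est.n_iter_,
        model=est,
    )


def odds_ratio_table(result: RegressionResult) -> pd.DataFrame:
    """Presentation table: ``beta (SE)``, p, OR and its 95% CI per row."""
    if not result.converged:
        raise ValueError("fit did not converge; refusing to format results")
    t = result.table
    out = pd.DataFrame(
        {
            "beta (SE)": [
                f"{b:.3f} ({s:.3f})" for b, s in zip(t["beta"], t["se"])
            ],
            "p": [f"{p:.3g}" for p in t["p"]],
            "OR": t["or"].round(3),
            "OR 95% CI": [
                f"{lo:.3f}-{hi:.3f}"
                for lo, hi in zip(t["or_ci_low"], t["or_ci_high"])
            ],
        },
        index=t.index,
    )
    return out
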