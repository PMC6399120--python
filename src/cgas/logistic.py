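"""Maximum-likelihood logistic regression via iteratively reweighted least squares.

A small, fast core used by every modelling stage (per-SNP scans, the
2^m - 1 exhaustive subset search, stepwise selection, bootstrap refits).
Convergence: max absolute score < 1e-8 or relative log-likelihood change
< 1e-10, at most 100 iterations.  Complete separation is detected
(diverging coefficients) and flagged; the fit is still returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile

_SEP_BETA = 30.0  # |beta| beyond this on standardized-ish designs means separation


class SeparationWarning(UserWarning):
    pass


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, covariance, likelihood, AIC."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    llf: float
    k: int
    n_used: int
    converged: bool
    separation: bool = False
    term_names: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    def wald_or(self, name: str) -> tuple[float, float, float]:
        """Odds ratio with 95% Wald CI for one coefficient."""
        b, se = self.params[name], self.bse[name]
        with np.errstate(over="ignore"):  # separated fits give infinite bounds
            return (
                float(np.exp(b)),
                float(np.exp(b - Z95 * se)),
                float(np.exp(b + Z95 * se)),
            )

    def wald_p(self, name: str) -> float:
        z = self.params[name] / self.bse[name]
        return float(2.0 * stats.norm.sf(abs(z)))

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.params.index)].to_numpy(dtype=float)
        eta = X @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    n, p = X.shape
    if n < p:
        raise ValueError(f"more parameters ({p}) than observations ({n})")
    # rank check via QR; name aliased columns
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    dep = [names[i] for i in np.where(diag <= tol)[0]]
    if dep:
        raise ValueError(f"rank-deficient design; aliased column(s): {', '.join(dep)}")


def fit_logistic(
    response,
    design: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
    freq_weights: np.ndarray | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFit:
    """Fit ``P(y=1) = logistic(X beta)`` by Newton/IRLS.

    Parameters
    ----------
    response:
        Binary 0/1 vector; for aggregated data may be the per-row event
        fraction, with ``freq_weights`` giving row totals.
    design:
        Covariate columns (DataFrame preserves names); an intercept column
        is prepended unless ``add_intercept=False``.
    """
    y = np.asarray(response, dtype=float)
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1 and y.shape[0] != 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    w = np.ones(len(y)) if freq_weights is None else np.asarray(freq_weights, dtype=float)
    mask = w > 0
    y, X, w = y[mask], X[mask], w[mask]
    ybar = float(np.average(y, weights=w))
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("response has a single class; logistic fit undefined")
    _check_design(X, names)

    beta = np.zeros(X.shape[1])
    beta[0 if add_intercept else slice(None)] = 0.0
    if add_intercept:
        beta[0] = np.log(ybar / (1.0 - ybar))
    ll_old = -np.inf
    converged = False
    separation = False
    eta = X @ beta
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
        score = X.T @ (w * (y - mu))
        if np.max(np.abs(score)) < score_tol or (
            np.isfinite(ll_old) and abs(ll - ll_old) <= ll_tol * (abs(ll_old) + 1e-300)
        ):
            converged = True
            break
        ll_old = ll
        wt = w * mu * (1.0 - mu)
        H = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving if the likelihood would decrease
        new_beta = beta + step
        new_eta = X @ new_beta
        for _h in range(20):
            mu_new = np.clip(1.0 / (1.0 + np.exp(-new_eta)), 1e-12, 1 - 1e-12)
            ll_new = float(np.sum(w * (y * np.log(mu_new) + (1 - y) * np.log(1 - mu_new))))
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
            new_beta = beta + step
            new_eta = X @ new_beta
        beta, eta = new_beta, new_eta
        if np.max(np.abs(beta)) > _SEP_BETA:
            separation = True
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-15, 1 - 1e-15)
    ll = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
    wt = w * mu * (1.0 - mu)
    H = (X * wt[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    if separation:
        warnings.warn(
            "possible complete separation; coefficients diverging", SeparationWarning
        )
    idx = pd.Index(names)
    return LogisticFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        llf=ll,
        k=X.shape[1],
        n_used=int(round(w.sum())),
        converged=converged and not separation,
        separation=separation,
        term_names=names,
    )


def lrt_pvalue(fit_full: LogisticFit, fit_reduced: LogisticFit) -> float:
    """Likelihood-ratio test p for nested fits on the same subjects."""
    if fit_full.n_used != fit_reduced.n_used:
        raise ValueError(
            f"fits use different subject sets ({fit_full.n_used} vs {fit_reduced.n_used})"
        )
    df = fit_full.k - fit_reduced.k
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    if not set(fit_reduced.term_names) <= set(fit_full.term_names):
        raise ValueError("reduced model terms are not a subset of the full model")
    lr = 2.0 * (fit_full.llf - fit_reduced.llf)
    lr = max(lr, 0.0)
    return float(stats.chi2.sf(lr, df))
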