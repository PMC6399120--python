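"""Per-SNP case-control association under five inheritance models.

Each SNP is fitted under dominant, recessive, overdominant, additive and
codominant codings of the effect-allele dosage; Akaike's information
criterion picks the best-fitting coding.  The SNP's adjusted p-value is a
likelihood-ratio test of the chosen coding against the covariates-only
model; a label-permutation p-value on the unadjusted likelihood-ratio
statistic accompanies significant SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .cohort import MISSING, GenotypeMatrix, PhenotypeTable
from .logistic import Z95, LogisticFit, fit_logistic, lrt_pvalue

INHERITANCE_MODELS = ("dominant", "recessive", "overdominant", "additive", "codominant")

#: Fixed tie-break order for indistinguishable encodings.
MODEL_ORDER = {m: i for i, m in enumerate(INHERITANCE_MODELS)}

MODEL_DF = {m: (2 if m == "codominant" else 1) for m in INHERITANCE_MODELS}

DEFAULT_COVARIATES = ("sex", "age", "caucasian")


class UntestableSNP(ValueError):
    """Raised when every inheritance encoding of a SNP is constant."""


def encode(dosage, model: str, snp_id: str = "snp") -> pd.DataFrame:
    """Encode effect-allele dosages under one inheritance model.

    dominant (0,1,2)->(0,1,1); recessive ->(0,0,1); overdominant ->(0,1,0);
    additive ->(0,1,2); codominant -> two indicators (heterozygote,
    effect-homozygote).  Missing dosages propagate as NaN so the subject is
    excluded from the fit.
    """
    d = np.asarray(dosage, dtype=float)
    d = np.where(d == MISSING, np.nan, d)
    if model == "dominant":
        cols = {snp_id: np.where(np.isnan(d), np.nan, (d >= 1).astype(float))}
    elif model == "recessive":
        cols = {snp_id: np.where(np.isnan(d), np.nan, (d == 2).astype(float))}
    elif model == "overdominant":
        cols = {snp_id: np.where(np.isnan(d), np.nan, (d == 1).astype(float))}
    elif model == "additive":
        cols = {snp_id: d}
    elif model == "codominant":
        cols = {
            f"{snp_id}_het": np.where(np.isnan(d), np.nan, (d == 1).astype(float)),
            f"{snp_id}_hom": np.where(np.isnan(d), np.nan, (d == 2).astype(float)),
        }
    else:
        raise ValueError(f"unknown inheritance model {model!r}")
    return pd.DataFrame(cols)


class OddsRatio(NamedTuple):
    value: float
    low: float
    high: float
    estimable: bool


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> OddsRatio:
    """Crude odds ratio from a 2x2 table with 95% Wald CI.

    Orientation: ``a`` unexposed controls, ``b`` exposed controls, ``c``
    unexposed cases, ``d`` exposed cases; OR = (d/c)/(b/a) = ad/bc.  Any
    zero cell makes the OR inestimable (flagged).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if min(a, b, c, d) == 0:
        return OddsRatio(float("nan"), float("nan"), float("nan"), False)
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatio(
        float(np.exp(log_or)),
        float(np.exp(log_or - Z95 * se)),
        float(np.exp(log_or + Z95 * se)),
        True,
    )


# ---------------------------------------------------------------------------
# model selection


def _complete_case_mask(
    gm: GenotypeMatrix, pheno: PhenotypeTable, snp: str, covariates: Sequence[str]
) -> np.ndarray:
    mask = gm.dosages(snp) != MISSING
    if covariates:
        cov = pheno.covariate_design(covariates)
        mask &= ~cov.isna().any(axis=1).to_numpy()
    return mask


def _nonconstant(df: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in df.columns if df[c].nunique() > 1]
    return df[keep]


def select_inheritance(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[str, pd.DataFrame, dict[str, LogisticFit]]:
    """Fit all five inheritance models and select the minimum-AIC one.

    All five fits use the same complete-case subject set so AICs are
    comparable.  With only two observed genotype classes, several encodings
    collapse to the same fit; ties (within 1e-9) are broken by the fixed
    order dominant < recessive < overdominant < additive < codominant.
    """
    mask = _complete_case_mask(gm, pheno, snp, covariates)
    d = gm.dosages(snp)[mask]
    y = pheno.outcome[mask]
    cov = (
        pheno.covariate_design(covariates).to_numpy()[mask]
        if covariates
        else np.empty((mask.sum(), 0))
    )
    cov_names = (
        list(pheno.covariate_design(covariates).columns) if covariates else []
    )
    if len(np.unique(d)) < 2:
        raise UntestableSNP(f"{snp}: fewer than 2 observed genotype classes")
    rows, fits = [], {}
    for model in INHERITANCE_MODELS:
        enc = _nonconstant(encode(d, model, snp))
        if enc.shape[1] == 0:
            rows.append(
                {"model": model, "aic": np.nan, "llf": np.nan, "k": np.nan, "testable": False}
            )
            continue
        X = pd.concat(
            [enc.reset_index(drop=True), pd.DataFrame(cov, columns=cov_names)], axis=1
        )
        fit = fit_logistic(y, X)
        fits[model] = fit
        rows.append(
            {"model": model, "aic": fit.aic, "llf": fit.llf, "k": fit.k, "testable": True}
        )
    table = pd.DataFrame(rows)
    if not fits:
        raise UntestableSNP(f"{snp}: all encodings constant")
    best_aic = table["aic"].min()
    tied = table[(table["aic"] - best_aic).abs() <= 1e-9]["model"]
    chosen = min(tied, key=MODEL_ORDER.get)
    return chosen, table, fits


def adjusted_lrt_p(fit_full: LogisticFit, fit_reduced: LogisticFit) -> float:
    """Covariate-adjusted LRT p: chi-square on 2*dlogLik with df = dk."""
    return lrt_pvalue(fit_full, fit_reduced)


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationSpec:
    """Settings for the label-permutation likelihood-ratio test."""

    n_perm: int = 20_000
    seed: int = 0
    batch: int = 2_000

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _saturated_ll(m: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Log-likelihood of the saturated binomial model on cell counts.

    ``m`` case counts (possibly batched, last axis = cells), ``t`` totals.
    """
    return (xlogy(m, m) + xlogy(t - m, t - m) - xlogy(t, t)).sum(axis=-1)


def _additive_ll(x: np.ndarray, t: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Batched 2-parameter logistic log-likelihood for aggregated dosage cells.

    ``x`` cell dosage values (k,), ``t`` totals (k,), ``m`` case counts
    (B, k).  Newton iterations vectorised over the batch.
    """
    m = np.atleast_2d(m).astype(float)
    B, k = m.shape
    mtot = m.sum(axis=1)
    ntot = t.sum()
    p0 = np.clip(mtot / ntot, 1e-9, 1 - 1e-9)
    beta = np.zeros((B, 2))
    beta[:, 0] = np.log(p0 / (1 - p0))
    X = np.column_stack([np.ones(k), x])  # (k, 2)
    for _ in range(60):
        eta = beta @ X.T  # (B, k)
        mu = 1.0 / (1.0 + np.exp(-eta))
        resid = m - t * mu  # (B, k)
        score = resid @ X  # (B, 2)
        w = t * mu * (1 - mu)  # (B, k)
        h00 = (w * X[:, 0] ** 2).sum(axis=1)
        h01 = (w * X[:, 0] * X[:, 1]).sum(axis=1)
        h11 = (w * X[:, 1] ** 2).sum(axis=1)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step0 = (h11 * score[:, 0] - h01 * score[:, 1]) / det
        step1 = (-h01 * score[:, 0] + h00 * score[:, 1]) / det
        beta[:, 0] += step0
        beta[:, 1] += step1
        np.clip(beta, -35, 35, out=beta)
        if np.max(np.abs(score)) < 1e-9:
            break
    eta = beta @ X.T
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-15, 1 - 1e-15)
    return (m * np.log(mu) + (t - m) * np.log(1 - mu)).sum(axis=1)


def _lr_from_cells(
    x_cells: np.ndarray, t: np.ndarray, m: np.ndarray, saturated: bool
) -> np.ndarray:
    """LR = 2 (llf_model - llf_null) on aggregated cell counts (batched)."""
    m = np.atleast_2d(m).astype(float)
    mtot = m.sum(axis=1)
    ntot = t.sum()
    ll_null = _saturated_ll(mtot[:, None], np.array([ntot], dtype=float))
    ll_model = (
        _saturated_ll(m, t.astype(float))
        if saturated
        else _additive_ll(x_cells, t.astype(float), m)
    )
    return np.maximum(2.0 * (ll_model - ll_null), 0.0)


def permutation_p(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp: str,
    model: str,
    spec: PermutationSpec,
) -> float:
    """Permutation p for the unadjusted likelihood-ratio statistic.

    Labels are permuted uniformly ``n_perm`` times under the stated seed;
    p = (1 + #{LR* >= LR_obs}) / (n_perm + 1).  The model is the SNP-only
    logistic fit (no covariates): permuting labels destroys any
    covariate-outcome link, so an adjusted permuted statistic would not be
    exchangeable.  The LR depends on the data only through the per-genotype
    case counts, so each permuted statistic is recomputed from aggregated
    counts (exact reformulation of refitting the model).
    """
    mask = gm.dosages(snp) != MISSING
    d = gm.dosages(snp)[mask].astype(int)
    y = pheno.outcome[mask].astype(np.int8)
    enc = encode(d, model, snp).to_numpy()
    # aggregate subjects into cells of identical encoded value
    cells, cell_idx = np.unique(enc, axis=0, return_inverse=True)
    k = len(cells)
    if k < 2:
        return 1.0
    onehot = np.zeros((len(d), k))
    onehot[np.arange(len(d)), cell_idx] = 1.0
    t = onehot.sum(axis=0)
    n_params = 1 + enc.shape[1]
    saturated = n_params >= k
    x_cells = cells[:, 0] if model == "additive" else None
    m_obs = y @ onehot
    lr_obs = float(_lr_from_cells(x_cells, t, m_obs, saturated)[0])
    rng = np.random.default_rng(spec.seed)
    exceed = 0
    remaining = spec.n_perm
    while remaining > 0:
        b = min(spec.batch, remaining)
        perm = rng.permuted(np.tile(y, (b, 1)), axis=1)
        m = perm.astype(float) @ onehot
        lr = _lr_from_cells(x_cells, t, m, saturated)
        exceed += int((lr >= lr_obs - 1e-9).sum())
        remaining -= b
    return (1 + exceed) / (spec.n_perm + 1)


def permutation_p_freedman_lane(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp: str,
    model: str,
    spec: PermutationSpec,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    n_strata: int = 5,
) -> float:
    """Covariate-respecting permutation variant (off the default path).

    Approximates exchangeability under covariates by permuting case/control
    labels within strata of the covariate-only predicted probability, and
    recomputing the covariate-adjusted LR each time.
    """
    mask = _complete_case_mask(gm, pheno, snp, covariates)
    d = gm.dosages(snp)[mask]
    y = pheno.outcome[mask].astype(np.int8)
    cov = pheno.covariate_design(covariates).loc[mask].reset_index(drop=True)
    enc = _nonconstant(encode(d, model, snp)).reset_index(drop=True)
    fit_red = fit_logistic(y, cov)
    strata = np.searchsorted(
        np.quantile(fit_red.predict(cov), np.linspace(0, 1, n_strata + 1)[1:-1]),
        fit_red.predict(cov),
    )
    full = pd.concat([enc, cov], axis=1)
    lr_obs = 2.0 * (fit_logistic(y, full).llf - fit_red.llf)
    rng = np.random.default_rng(spec.seed)
    exceed = 0
    for _ in range(spec.n_perm):
        y_star = y.copy()
        for s in np.unique(strata):
            idx = np.where(strata == s)[0]
            y_star[idx] = y[rng.permutation(idx)]
        try:
            lr = 2.0 * (fit_logistic(y_star, full).llf - fit_logistic(y_star, cov).llf)
        except ValueError:
            continue
        if lr >= lr_obs - 1e-9:
            exceed += 1
    return (1 + exceed) / (spec.n_perm + 1)


# ---------------------------------------------------------------------------
# the association scan


def _snp_or_from_fit(fit: LogisticFit, snp: str, model: str) -> tuple[str, float, float, float]:
    """Reported OR term for a fitted SNP model.

    The codominant coding has two terms; the summary carries the one with
    larger |log OR| (both stay in the detail output).
    """
    terms = [t for t in fit.params.index if t == snp or t.startswith(f"{snp}_")]
    best = max(terms, key=lambda t: abs(fit.params[t]))
    or_, lo, hi = fit.wald_or(best)
    return best, or_, lo, hi


def assoc_scan(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    spec: PermutationSpec | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-SNP association scan (the univariate results table).

    For each SNP: inheritance-model selection by AIC, Wald OR with 95% CI
    for the chosen coding, covariate-adjusted LRT p, and (for SNPs with
    adjusted p < alpha, when a :class:`PermutationSpec` is given) the
    unadjusted permutation p.  Complete cases per SNP.  Per-SNP failures
    are recorded and the scan continues.
    """
    rows, detail = [], {}
    for v in gm.variants:
        snp = v.snp_id
        base = {"snp_id": snp, "gene": v.gene}
        try:
            model, aic_table, fits = select_inheritance(gm, pheno, snp, covariates)
            fit = fits[model]
            assert fit.aic <= np.nanmin(aic_table["aic"]) + 1e-9
            mask = _complete_case_mask(gm, pheno, snp, covariates)
            y = pheno.outcome[mask]
            if covariates:
                cov = pheno.covariate_design(covariates).loc[mask].reset_index(drop=True)
                fit_red = fit_logistic(y, cov)
            else:
                fit_red = fit_logistic(y, pd.DataFrame(index=range(int(mask.sum()))))
            adj_p = adjusted_lrt_p(fit, fit_red)
            term, or_, lo, hi = _snp_or_from_fit(fit, snp, model)
            perm_p = np.nan
            if spec is not None and adj_p < alpha:
                snp_seed = (spec.seed + 7919 * gm.variant_index(snp)) % (2**31)
                perm_p = permutation_p(
                    gm, pheno, snp, model,
                    PermutationSpec(spec.n_perm, snp_seed, spec.batch),
                )
            rows.append(
                base
                | {
                    "model": model,
                    "adjusted_p": adj_p,
                    "or_point": or_,
                    "or_low": lo,
                    "or_high": hi,
                    "aic": fit.aic,
                    "permutation_p": perm_p,
                    "n_used": fit.n_used,
                    "status": "ok",
                }
            )
            detail[snp] = {
                "aic_table": aic_table,
                "fit": fit,
                "reported_term": term,
                "all_or": {
                    t: fit.wald_or(t)
                    for t in fit.params.index
                    if t == snp or t.startswith(f"{snp}_")
                },
            }
        except (UntestableSNP, ValueError) as exc:
            rows.append(
                base
                | {
                    "model": "",
                    "adjusted_p": np.nan,
                    "or_point": np.nan,
                    "or_low": np.nan,
                    "or_high": np.nan,
                    "aic": np.nan,
                    "permutation_p": np.nan,
                    "n_used": 0,
                    "status": f"failed: {exc}",
                }
            )
    cols = [
        "snp_id", "gene", "model", "adjusted_p", "or_point", "or_low",
        "or_high", "aic", "permutation_p", "n_used", "status",
    ]
    return pd.DataFrame(rows, columns=cols), detail


# ---------------------------------------------------------------------------
# baseline heterogeneity table


def _fisher_2xk_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2xk table by full enumeration (k <= 3)."""
    from scipy.special import gammaln

    table = np.asarray(table, dtype=int)
    k = table.shape[1]
    col = table.sum(axis=0)
    n1 = int(table[0].sum())
    N = int(table.sum())

    def log_c(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    denom = log_c(N, n1)
    obs_logp = sum(log_c(col[j], table[0, j]) for j in range(k)) - denom
    if k == 2:
        _, p = stats.fisher_exact(table)
        return float(p)
    total = 0.0
    for x1 in range(max(0, n1 - col[1] - col[2]), min(col[0], n1) + 1):
        rem = n1 - x1
        x2 = np.arange(max(0, rem - col[2]), min(col[1], rem) + 1)
        x3 = rem - x2
        logp = log_c(col[0], x1) + log_c(col[1], x2) + log_c(col[2], x3) - denom
        total += float(np.exp(logp[logp <= obs_logp + 1e-12]).sum())
    return min(total, 1.0)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with normal approximation and tie correction.

    For tiny pooled samples (<= 12) the p-value is exact, computed by full
    enumeration of group assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)
    if len(x) + len(y) <= 12:
        pooled = np.concatenate([x, y])
        n = len(pooled)
        us = []
        for idx in combinations(range(n), len(x)):
            r = stats.rankdata(pooled)[list(idx)]
            us.append(float(r.sum() - len(x) * (len(x) + 1) / 2))
        us = np.asarray(us)
        if alternative == "less":
            p = float((us <= u + 1e-12).mean())
        elif alternative == "greater":
            p = float((us >= u - 1e-12).mean())
        else:
            mean_u = len(x) * len(y) / 2
            p = min(1.0, 2 * min(
                float((us <= u + 1e-12).mean()), float((us >= u - 1e-12).mean())
            ))
        return u, p
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return u, float(res.pvalue)


def baseline_table(pheno: PhenotypeTable) -> pd.DataFrame:
    """Case-control heterogeneity summary of demographics and risk factors.

    Qualitative variables: counts, percentages, crude OR against the
    reference level and Fisher exact p (full enumeration up to 3 levels,
    chi-square fallback flagged beyond).  Quantitative: mean (SD) and the
    Mann-Whitney two-sided p.
    """
    df = pheno.data
    ctrl = df[df["outcome"] == 0]
    case = df[df["outcome"] == 1]
    rows = []

    def _qualitative(var: str, levels: Sequence, reference) -> None:
        tab = np.array(
            [[int((ctrl[var] == l).sum()) for l in levels],
             [int((case[var] == l).sum()) for l in levels]]
        )
        if tab.shape[1] <= 3:
            p = _fisher_2xk_exact(tab)
            method = "fisher-exact"
        else:
            p = float(stats.chi2_contingency(tab)[1])
            method = "chisq-fallback"
        ref_i = levels.index(reference)
        for i, level in enumerate(levels):
            if i == ref_i:
                or_ = OddsRatio(1.0, 1.0, 1.0, True)
            else:
                or_ = odds_ratio_2x2(tab[0, ref_i], tab[0, i], tab[1, ref_i], tab[1, i])
            n_c, n_k = tab[0, i], tab[1, i]
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "controls_n": n_c,
                    "controls_pct": 100 * n_c / max(len(ctrl), 1),
                    "cases_n": n_k,
                    "cases_pct": 100 * n_k / max(len(case), 1),
                    "or": or_.value,
                    "or_low": or_.low,
                    "or_high": or_.high,
                    "p": p,
                    "test": method,
                }
            )

    _qualitative("sex", ["male", "female"], "male")
    _qualitative("caucasian", [1, 0], 1)
    _qualitative("diabetes", [0, 1], 0)
    _qualitative("hypertension", [0, 1], 0)
    _qualitative("smoking", ["never", "former", "current"], "never")
    u, p = mann_whitney(case["age"], ctrl["age"])
    rows.append(
        {
            "variable": "age",
            "level": "mean (SD)",
            "controls_n": len(ctrl),
            "controls_pct": np.nan,
            "cases_n": len(case),
            "cases_pct": np.nan,
            "or": np.nan,
            "or_low": np.nan,
            "or_high": np.nan,
            "p": p,
            "test": f"mann-whitney; ctrl {ctrl['age'].mean():.1f} ({ctrl['age'].std():.1f}), "
            f"case {case['age'].mean():.1f} ({case['age'].std():.1f})",
        }
    )
    return pd.DataFrame(rows)
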