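"""Risk-model discrimination: ROC/AUC, DeLong comparison, bootstrap CIs.

The AUC is the Mann-Whitney estimator (probability a random case outscores
a random control, ties counted half), which equals the trapezoidal area
under the empirical ROC.  Paired AUCs are compared with DeLong's
structural-components variance; bootstrap CIs resample subjects with
replacement (stratified by outcome), refit the model on each resample and
take the 2.5/97.5 percentiles.  Discrimination is evaluated in-sample
(apparent AUC); expect optimism relative to external validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .cohort import GenotypeMatrix, PhenotypeTable
from .design import RiskModel


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(case score > control score) + half P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - cases.size * (cases.size + 1) / 2
    return float(u / (cases.size * controls.size))


@dataclass
class RocCurve:
    """Empirical ROC points: thresholds with sensitivity/specificity."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_cases: int
    n_controls: int

    @classmethod
    def from_scores(cls, scores, labels) -> "RocCurve":
        fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
        return cls(
            thresholds=thr,
            sensitivity=tpr,
            specificity=1.0 - fpr,
            n_cases=int(np.sum(np.asarray(labels) == 1)),
            n_controls=int(np.sum(np.asarray(labels) == 0)),
        )


def _placements(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (case and control placement values)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    x = scores[labels == 1]  # cases
    y = scores[labels == 0]  # controls
    # placement of each case among controls and vice versa, ties half
    order = np.sort(y)
    v_cases = (
        np.searchsorted(order, x, side="left")
        + np.searchsorted(order, x, side="right")
    ) / (2.0 * len(y))
    order = np.sort(x)
    v_controls = 1.0 - (
        np.searchsorted(order, y, side="left")
        + np.searchsorted(order, y, side="right")
    ) / (2.0 * len(x))
    return v_cases, v_controls


def delong_test(scores_a, scores_b, labels) -> dict:
    """DeLong paired comparison of two correlated AUCs.

    Returns auc_a, auc_b, delta, variance of the difference, z and the
    two-sided normal p.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores and labels must be paired (same subjects)")
    auc_a, auc_b = auc(scores_a, labels), auc(scores_b, labels)
    va_c, va_k = _placements(scores_a, labels)
    vb_c, vb_k = _placements(scores_b, labels)
    m, n = len(va_c), len(va_k)
    s_cases = np.cov(np.vstack([va_c, vb_c]), ddof=1) if m > 1 else np.zeros((2, 2))
    s_controls = np.cov(np.vstack([va_k, vb_k]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s_cases / m + s_controls / n
    var = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    delta = auc_a - auc_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "delta": delta,
        "variance": max(var, 0.0),
        "z": float(z),
        "p": p,
    }


def bootstrap_auc(
    model: RiskModel,
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    n_boot: int = 1000,
    seed: int = 0,
    refit: bool = True,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bootstrap the AUC: stratified resampling, refit per resample.

    Returns (mean AUC, (2.5%, 97.5%) percentile CI, bootstrap draws).
    ``refit=False`` resamples fitted scores only (fast mode).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    model.fit(gm, pheno)
    mask = model.mask_
    y = pheno.outcome[mask]
    idx_all = np.where(mask)[0]
    cases = idx_all[y == 1]
    controls = idx_all[y == 0]
    base_scores = model.predict_proba(gm, pheno)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    subjects = np.asarray(gm.subject_ids)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(cases, size=len(cases), replace=True),
             rng.choice(controls, size=len(controls), replace=True)]
        )
        if refit:
            ids = [f"{s}#{i}" for i, s in enumerate(subjects[take])]
            gm_b = GenotypeMatrix(ids, gm.variants, gm.calls[take])
            ph_b = PhenotypeTable(
                pheno.data.iloc[take].set_axis(ids, axis=0)
            )
            try:
                mdl = RiskModel(model.terms, model.builder.snp_models, model.builder.covariates)
                mdl.fit(gm_b, ph_b)
                aucs[b] = auc(mdl.predict_proba(gm_b, ph_b), ph_b.outcome)
            except ValueError:
                aucs[b] = np.nan
        else:
            aucs[b] = auc(base_scores[take], pheno.outcome[take])
    draws = aucs[~np.isnan(aucs)]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), (float(lo), float(hi)), draws


def optimal_threshold(curve: RocCurve) -> dict:
    """Operating point maximising sensitivity + specificity - 1 (Youden).

    Equivalent to the ROC point furthest from the diagonal.  Ties break
    toward higher specificity.  PPV/NPV are computed at the sample case
    fraction; all four proportions get Wilson 95% CIs.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    finite = np.isfinite(curve.thresholds)
    if not finite.any() or np.all(j[finite] <= 1e-12):
        return {"informative": False, "threshold": float("nan")}
    jmax = j[finite].max()
    cand = np.where(finite & (j >= jmax - 1e-12))[0]
    best = cand[np.argmax(curve.specificity[cand])]
    sens, spec = float(curve.sensitivity[best]), float(curve.specificity[best])
    m, n = curve.n_cases, curve.n_controls
    tp, fn = sens * m, (1 - sens) * m
    tn, fp = spec * n, (1 - spec) * n

    def _wilson(k, tot):
        if tot <= 0:
            return (float("nan"), float("nan"))
        lo, hi = proportion_confint(round(k), round(tot), alpha=0.05, method="wilson")
        return float(lo), float(hi)

    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return {
        "informative": True,
        "threshold": float(curve.thresholds[best]),
        "sensitivity": sens,
        "sensitivity_ci": _wilson(tp, m),
        "specificity": spec,
        "specificity_ci": _wilson(tn, n),
        "ppv": float(ppv),
        "ppv_ci": _wilson(tp, tp + fp),
        "npv": float(npv),
        "npv_ci": _wilson(tn, tn + fn),
    }


@dataclass
class RocComparison:
    """Per-model ROC summary plus all pairwise DeLong contrasts."""

    summary_table: pd.DataFrame
    delong_table: pd.DataFrame
    curves: dict
    scores: dict


def compare_models(
    model_specs: dict[str, RiskModel],
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    n_boot: int = 1000,
    seed: int = 0,
    refit_bootstrap: bool = True,
) -> RocComparison:
    """Fit each risk model, compare in-sample ROC curves.

    All models are evaluated on the shared complete-case subject set (the
    intersection of each model's complete cases) so DeLong comparisons are
    paired.
    """
    if len(model_specs) < 2:
        raise ValueError("need at least two models to compare")
    shared = np.ones(gm.n_subjects, dtype=bool)
    for mdl in model_specs.values():
        mdl.fit(gm, pheno)
        shared &= mdl.mask_
    if not shared.any():
        raise ValueError("no subjects shared across all model complete-case sets")
    y = pheno.outcome[shared]
    scores, curves, rows = {}, {}, []
    for i, (name, mdl) in enumerate(model_specs.items()):
        mdl.fit(gm, pheno, mask=shared)
        s = mdl.predict_proba(gm, pheno)[shared]
        scores[name] = s
        curve = RocCurve.from_scores(s, y)
        curves[name] = curve
        opt = optimal_threshold(curve)
        mean_auc, (lo, hi), _ = bootstrap_auc(
            RiskModel(mdl.terms, mdl.builder.snp_models, mdl.builder.covariates),
            gm.subset_subjects([s_ for s_, k in zip(gm.subject_ids, shared) if k]),
            pheno.subset([s_ for s_, k in zip(gm.subject_ids, shared) if k]),
            n_boot=n_boot,
            seed=(seed + 104729 * i) % (2**31),
            refit=refit_bootstrap,
        )
        rows.append(
            {
                "model": name,
                "auc": auc(s, y),
                "auc_boot_mean": mean_auc,
                "auc_boot_low": lo,
                "auc_boot_high": hi,
                "threshold": opt.get("threshold"),
                "sensitivity": opt.get("sensitivity"),
                "specificity": opt.get("specificity"),
                "ppv": opt.get("ppv"),
                "npv": opt.get("npv"),
                "n": int(shared.sum()),
            }
        )
    pair_rows = []
    for a, b in combinations(model_specs, 2):
        res = delong_test(scores[a], scores[b], y)
        pair_rows.append({"model_a": a, "model_b": b, **res})
    return RocComparison(
        summary_table=pd.DataFrame(rows),
        delong_table=pd.DataFrame(pair_rows),
        curves=curves,
        scores=scores,
    )
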