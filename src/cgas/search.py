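"""Multivariate SNP-model search.

All 2^m - 1 non-empty subsets of the m univariately significant SNPs are
fitted (each under its chosen inheritance coding, always including the
adjusting covariates) on one fixed complete-case subject set, so AICs are
comparable across subsets.  Perfectly collinear (aliased) SNP codings are
detected beforehand; only the first member (panel order) of each aliased
group enters the enumeration, and tied alternatives are reported.  A
bidirectional AIC stepwise pass then considers clinical risk factors and
SNP x clinical / SNP x SNP interactions under a strict hierarchy rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import DEFAULT_COVARIATES
from .cohort import MISSING, GenotypeMatrix, PhenotypeTable
from .design import DesignBuilder, raw_frame
from .logistic import LogisticFit, SeparationWarning, fit_logistic

logger = logging.getLogger("cgas")


@dataclass
class SearchConfig:
    """Settings for the exhaustive subset search and stepwise refinement."""

    snp_terms: list[tuple[str, str]]  # (rsID, inheritance model)
    forced_covariates: tuple[str, ...] = DEFAULT_COVARIATES
    clinical_factors: tuple[str, ...] = ("diabetes", "hypertension")
    alpha: float = 0.05
    aic_tie_tol: float = 1e-6
    max_snps: int = 20
    stepwise_mode: str = "aic"  # or "pvalue"

    def __post_init__(self) -> None:
        if not self.snp_terms:
            raise ValueError("snp_terms must be non-empty")
        if len(self.snp_terms) > self.max_snps:
            raise ValueError(
                f"{len(self.snp_terms)} SNPs exceeds the search guard ({self.max_snps})"
            )

    @property
    def m(self) -> int:
        return len(self.snp_terms)

    @property
    def snp_models(self) -> dict[str, str]:
        return dict(self.snp_terms)


def count_models(m: int) -> int:
    """Number of non-empty SNP subsets: 2^m - 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 2**m - 1


def complete_cases(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp_terms: Sequence[tuple[str, str]] | Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[np.ndarray, dict]:
    """Boolean mask of subjects with complete data for every listed SNP.

    Also returns counts by case/control arm.  No imputation anywhere:
    multivariate fits use exactly this subject set.
    """
    snps = [t[0] if isinstance(t, tuple) else t for t in snp_terms]
    if not snps:
        raise ValueError("snp_terms must be non-empty")
    mask = np.ones(gm.n_subjects, dtype=bool)
    for s in snps:
        mask &= gm.dosages(s) != MISSING
    if covariates:
        mask &= ~pheno.covariate_design(covariates).isna().any(axis=1).to_numpy()
    y = pheno.outcome
    counts = {
        "n": int(mask.sum()),
        "n_cases": int((mask & (y == 1)).sum()),
        "n_controls": int((mask & (y == 0)).sum()),
        "n_total": gm.n_subjects,
    }
    if counts["n"] == 0:
        raise ValueError(
            "no subject has complete data for all listed SNPs; reduce the subset"
        )
    return mask, counts


def detect_aliased(columns: dict[str, pd.DataFrame]) -> list[list[str]]:
    """Group terms whose encoded columns are perfectly collinear.

    Two terms are aliased when each one's encoded block lies exactly in the
    column span of the other (with an intercept) on the analysis sample.
    Within a group, all but the first term (input order) are masked from
    joint models.
    """
    names = list(columns)
    mats = {}
    for name in names:
        a = columns[name].to_numpy(dtype=float)
        mats[name] = np.column_stack([np.ones(len(a)), a])
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(names, 2):
        A, B = mats[a], mats[b]
        ra = np.linalg.matrix_rank(A, tol=1e-8)
        rb = np.linalg.matrix_rank(B, tol=1e-8)
        rj = np.linalg.matrix_rank(np.column_stack([A, B]), tol=1e-8)
        if ra == rb == rj:
            parent[find(b)] = find(a)
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    return [g for g in groups.values() if len(g) > 1]


@dataclass
class ModelSearchResult:
    """Outcome of the exhaustive subset search (plus final stepwise model)."""

    subset_table: pd.DataFrame
    best_subsets: list[tuple[str, ...]]
    chosen_subset: tuple[str, ...]
    aliased_groups: list[list[str]]
    n_used: int
    case_control_counts: dict
    final_fit: LogisticFit | None = None
    final_terms: list[str] = field(default_factory=list)
    eliminated_terms: list[str] = field(default_factory=list)
    final_model_table: pd.DataFrame | None = None


def exhaustive_search(
    gm: GenotypeMatrix, pheno: PhenotypeTable, cfg: SearchConfig
) -> ModelSearchResult:
    """Fit all 2^m - 1 SNP subsets and return the minimum-AIC one(s).

    Subsets within ``aic_tie_tol`` of the minimum are all reported; the
    tie-break picks the lexicographically first subset by panel index
    (mirroring an arbitrary "first SNP" choice among aliased equivalents).
    """
    mask, counts = complete_cases(gm, pheno, cfg.snp_terms, cfg.forced_covariates)
    builder = DesignBuilder(cfg.snp_models, cfg.forced_covariates)
    snps = [s for s, _ in cfg.snp_terms]
    raw = raw_frame(gm, pheno, snps, cfg.forced_covariates).loc[mask]
    cov = builder.covariate_frame(raw)
    enc = {s: builder._term_columns(s, raw) for s in snps}
    aliased_groups = detect_aliased(enc)
    masked = {m for g in aliased_groups for m in g[1:]}
    if masked:
        logger.info("aliased SNP terms masked from joint models: %s", sorted(masked))
    active = [s for s in snps if s not in masked]
    y = pheno.outcome[mask]

    rows = []
    fits: dict[tuple[str, ...], LogisticFit] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for r in range(1, len(active) + 1):
            for subset in combinations(active, r):
                X = pd.concat([cov] + [enc[s] for s in subset], axis=1)
                bitmask = "".join("1" if s in subset else "0" for s in snps)
                try:
                    fit = fit_logistic(y, X)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    rows.append(
                        {"subset": "+".join(subset), "bitmask": bitmask,
                         "aic": np.nan, "llf": np.nan, "k": np.nan,
                         "n": int(mask.sum()), "converged": False,
                         "note": f"failed: {exc}"}
                    )
                    continue
                rows.append(
                    {"subset": "+".join(subset), "bitmask": bitmask,
                     "aic": fit.aic, "llf": fit.llf, "k": fit.k,
                     "n": fit.n_used, "converged": fit.converged, "note": ""}
                )
                if fit.converged:
                    fits[subset] = fit
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("no subset model converged")
    best_aic = min(f.aic for f in fits.values())
    order = {s: i for i, s in enumerate(snps)}
    tied = sorted(
        [s for s, f in fits.items() if f.aic - best_aic <= cfg.aic_tie_tol],
        key=lambda sub: tuple(order[s] for s in sub),
    )
    # expand aliased alternatives: substituting a masked member reproduces
    # the same likelihood, so those subsets tie by construction
    expanded = list(tied)
    for sub in tied:
        for group in aliased_groups:
            rep = group[0]
            if rep in sub:
                for alt in group[1:]:
                    expanded.append(
                        tuple(alt if s == rep else s for s in sub)
                    )
    chosen = tied[0]
    return ModelSearchResult(
        subset_table=table,
        best_subsets=expanded,
        chosen_subset=chosen,
        aliased_groups=aliased_groups,
        n_used=counts["n"],
        case_control_counts=counts,
    )


# ---------------------------------------------------------------------------
# stepwise interaction modelling


def _hierarchy_ok(term: str, present: set[str]) -> bool:
    if ":" not in term:
        return True
    a, b = term.split(":", 1)
    return a in present and b in present


def _removable(term: str, present: set[str]) -> bool:
    if ":" in term:
        return True
    # a parent cannot leave while its interaction remains
    return not any(
        ":" in t and term in t.split(":", 1) for t in present if t != term
    )


def _term_cols(params_index, term: str) -> list[str]:
    """Design-column names belonging to one model term (codominant expands)."""

    def _variants(t: str) -> tuple[str, ...]:
        return (t, f"{t}_het", f"{t}_hom")

    if ":" in term:
        a, b = term.split(":", 1)
        return [
            c for c in params_index
            if ":" in c
            and c.split(":", 1)[0] in _variants(a)
            and c.split(":", 1)[1] in _variants(b)
        ]
    return [c for c in params_index if ":" not in c and c in _variants(term)]


def _final_table(fit: LogisticFit) -> pd.DataFrame:
    rows = []
    for name in fit.params.index:
        or_, lo, hi = fit.wald_or(name)
        rows.append(
            {
                "term": name,
                "beta": fit.params[name],
                "se": fit.bse[name],
                "p": fit.wald_p(name),
                "or": or_,
                "or_low": lo,
                "or_high": hi,
            }
        )
    return pd.DataFrame(rows)


def stepwise_interactions(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    base_subset: Sequence[str],
    cfg: SearchConfig,
    mask: np.ndarray | None = None,
) -> tuple[LogisticFit, list[str], list[str]]:
    """Bidirectional AIC stepwise over SNP mains, clinical factors and interactions.

    Candidate terms: the base SNP main effects, diabetes and hypertension,
    and every SNP x diabetes, SNP x hypertension and SNP x SNP product.
    Hierarchy is enforced (an interaction needs both parents present; a
    parent cannot leave while its interaction remains); adjusting
    covariates are never dropped.  ``mode="pvalue"`` runs backward
    elimination at ``cfg.alpha`` instead.

    Returns (final fit, final terms, eliminated terms in order).
    """
    base_subset = list(base_subset)
    if mask is None:
        if base_subset:
            mask, _ = complete_cases(gm, pheno, base_subset, cfg.forced_covariates)
        else:
            mask = np.ones(gm.n_subjects, dtype=bool)
    builder = DesignBuilder(cfg.snp_models, cfg.forced_covariates)
    raw = raw_frame(gm, pheno, base_subset, cfg.forced_covariates).loc[mask]
    y = pheno.outcome[mask]

    mains = base_subset + list(cfg.clinical_factors)
    inters = [f"{s}:{c}" for s in base_subset for c in cfg.clinical_factors]
    inters += [f"{a}:{b}" for a, b in combinations(base_subset, 2)]
    candidates = mains + inters
    current = list(mains)
    eliminated: list[str] = []

    def _fit(terms: Sequence[str]) -> LogisticFit | None:
        X = builder.build(raw, terms)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SeparationWarning)
                return fit_logistic(y, X)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("stepwise: skipping %s (%s)", "+".join(terms), exc)
            return None

    fit = _fit(current)
    if fit is None:
        raise RuntimeError("initial stepwise model failed to fit")

    if cfg.stepwise_mode == "pvalue":
        # backward elimination of the least significant droppable term
        full_fit = _fit(candidates)
        if full_fit is not None:
            current, fit = list(candidates), full_fit
        while True:
            present = set(current)
            worst, worst_p = None, cfg.alpha
            for term in current:
                if not _removable(term, present):
                    continue
                cols = _term_cols(fit.params.index, term)
                p = min(fit.wald_p(c) for c in cols) if cols else 1.0
                if p >= worst_p:
                    worst, worst_p = term, p
            if worst is None:
                break
            current.remove(worst)
            eliminated.append(worst)
            new_fit = _fit(current)
            if new_fit is None:
                current.append(worst)
                eliminated.pop()
                break
            fit = new_fit
        return fit, current, eliminated

    for _step in range(100):
        present = set(current)
        moves: list[tuple[float, str, str]] = []
        for term in candidates:
            if term in present or not _hierarchy_ok(term, present):
                continue
            f = _fit(current + [term])
            if f is not None:
                moves.append((f.aic, "add", term))
        for term in current:
            if not _removable(term, present):
                continue
            f = _fit([t for t in current if t != term])
            if f is not None:
                moves.append((f.aic, "drop", term))
        if not moves:
            break
        best_aic, action, term = min(moves, key=lambda m: m[0])
        if best_aic >= fit.aic - 1e-8:
            break
        if action == "add":
            current.append(term)
            if term in eliminated:
                eliminated.remove(term)
        else:
            current.remove(term)
            eliminated.append(term)
        fit = _fit(current)
    return fit, current, eliminated


def run_model_search(
    gm: GenotypeMatrix, pheno: PhenotypeTable, cfg: SearchConfig
) -> ModelSearchResult:
    """Exhaustive subset search followed by stepwise interaction refinement."""
    result = exhaustive_search(gm, pheno, cfg)
    mask, _ = complete_cases(gm, pheno, cfg.snp_terms, cfg.forced_covariates)
    fit, terms, eliminated = stepwise_interactions(
        gm, pheno, list(result.chosen_subset), cfg, mask=mask
    )
    result.final_fit = fit
    result.final_terms = terms
    result.eliminated_terms = eliminated
    result.final_model_table = _final_table(fit)
    return result
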