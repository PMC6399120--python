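"""Design-matrix assembly for multivariate risk models.

Terms are names: a SNP rsID (encoded under its chosen inheritance model —
the codominant coding expands to two columns), a clinical factor
(``diabetes``, ``hypertension``), or an interaction ``"a:b"`` whose columns
are all pairwise products of the parents' columns.  Adjusting covariates
(sex, age, race) are handled separately and always included.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import DEFAULT_COVARIATES, encode
from .cohort import MISSING, GenotypeMatrix, PhenotypeTable
from .logistic import LogisticFit, fit_logistic


def raw_frame(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    snp_ids: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Raw per-subject variables: SNP dosages (NaN when missing) + covariates."""
    cols = {s: np.where(gm.dosages(s) == MISSING, np.nan, gm.dosages(s)).astype(float)
            for s in snp_ids}
    raw = pd.DataFrame(cols, index=gm.subject_ids)
    cov = pheno.covariate_design(covariates)
    for extra in ("diabetes", "hypertension"):
        if extra not in cov.columns:
            cov = cov.join(pheno.covariate_design([extra]))
    return raw.join(cov)


class DesignBuilder:
    """Maps term names to numeric design columns.

    Parameters
    ----------
    snp_models:
        Mapping rsID -> inheritance model chosen in the univariate scan.
    covariates:
        Adjusting covariates always included in every model.
    """

    def __init__(
        self,
        snp_models: Mapping[str, str],
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ) -> None:
        self.snp_models = dict(snp_models)
        self.covariates = tuple(covariates)

    def _term_columns(self, term: str, raw: pd.DataFrame) -> pd.DataFrame:
        if ":" in term:
            a, b = term.split(":", 1)
            ca, cb = self._term_columns(a, raw), self._term_columns(b, raw)
            out = {}
            for na in ca.columns:
                for nb in cb.columns:
                    out[f"{na}:{nb}"] = ca[na].to_numpy() * cb[nb].to_numpy()
            return pd.DataFrame(out, index=raw.index)
        if term in self.snp_models:
            enc = encode(
                np.where(np.isnan(raw[term].to_numpy()), MISSING, raw[term].to_numpy()),
                self.snp_models[term],
                term,
            )
            enc.index = raw.index
            enc[raw[term].isna()] = np.nan
            return enc
        if term in raw.columns:
            return raw[[term]].astype(float)
        raise KeyError(f"unknown model term {term!r}")

    def covariate_frame(self, raw: pd.DataFrame) -> pd.DataFrame:
        names = []
        for cov in self.covariates:
            if cov == "sex":
                names.append("sex_male")
            elif cov == "smoking":
                names += ["smoking_former", "smoking_current"]
            else:
                names.append(cov)
        return raw[names].astype(float)

    def build(self, raw: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
        """Full design: adjusting covariates first, then term blocks in order."""
        blocks = [self.covariate_frame(raw)]
        for term in terms:
            blocks.append(self._term_columns(term, raw))
        X = pd.concat(blocks, axis=1)
        if X.columns.has_duplicates:
            dup = X.columns[X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate design columns: {dup}")
        return X

    def profile_row(self, profile: Mapping, terms: Sequence[str]) -> pd.DataFrame:
        """One-row design for a covariate+genotype profile (for predicted ORs)."""
        row = {}
        for key, val in profile.items():
            if key == "sex":
                row["sex_male"] = 1.0 if val == "male" else 0.0
            elif key == "smoking":
                row["smoking_former"] = 1.0 if val == "former" else 0.0
                row["smoking_current"] = 1.0 if val == "current" else 0.0
            else:
                row[key] = float(val)
        raw = pd.DataFrame([row])
        needed = set()
        for t in terms:
            needed.update(t.split(":"))
        unknown = [t for t in needed if t not in raw.columns]
        if unknown:
            raise KeyError(f"profile does not cover term variable(s): {sorted(unknown)}")
        return self.build(raw, terms)


class RiskModel:
    """A logistic risk model over SNP and clinical terms (fit / predict).

    Follows the fit/predict convention: :meth:`fit` estimates coefficients
    on complete cases and stores the fitted :class:`LogisticFit` as
    ``fit_``; :meth:`predict_proba` returns in-sample (or new-sample)
    predicted case probabilities.
    """

    def __init__(
        self,
        terms: Sequence[str],
        snp_models: Mapping[str, str],
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ) -> None:
        self.terms = list(terms)
        self.builder = DesignBuilder(snp_models, covariates)

    def _design(self, gm: GenotypeMatrix, pheno: PhenotypeTable) -> pd.DataFrame:
        snps = sorted({p for t in self.terms for p in t.split(":") if p in self.builder.snp_models})
        raw = raw_frame(gm, pheno, snps, self.builder.covariates)
        return self.builder.build(raw, self.terms)

    def fit(self, gm: GenotypeMatrix, pheno: PhenotypeTable, mask=None) -> "RiskModel":
        X = self._design(gm, pheno)
        y = pheno.outcome
        ok = ~X.isna().any(axis=1).to_numpy()
        if mask is not None:
            ok &= np.asarray(mask)
        self.mask_ = ok
        self.fit_ = fit_logistic(y[ok], X.loc[ok])
        return self

    def predict_proba(self, gm: GenotypeMatrix, pheno: PhenotypeTable) -> np.ndarray:
        X = self._design(gm, pheno)
        return self.fit_.predict(
            np.column_stack([np.ones(len(X)), X[list(self.fit_.params.index[1:])].to_numpy()])
        )


def profile_odds_ratios(
    fit: LogisticFit,
    builder: DesignBuilder,
    terms: Sequence[str],
    profiles: Sequence[Mapping],
    reference: Mapping,
    age_default: float | None = None,
) -> pd.DataFrame:
    """Predicted odds ratios of covariate+genotype profiles vs a reference.

    OR = exp(eta_profile - eta_reference); the CI comes from the delta
    method on the linear-predictor contrast.  Profiles omitting age use
    ``age_default`` (e.g. the sample median).
    """
    from .logistic import Z95

    def _row(profile: Mapping) -> np.ndarray:
        profile = dict(profile)
        if "age" not in profile and age_default is not None:
            profile["age"] = age_default
        X = builder.profile_row(profile, terms)
        X.insert(0, "intercept", 1.0)
        return X[list(fit.params.index)].to_numpy()[0]

    ref_row = _row(reference)
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    rows = []
    for i, prof in enumerate(profiles):
        contrast = _row(prof) - ref_row
        log_or = float(contrast @ beta)
        se = float(np.sqrt(max(contrast @ cov @ contrast, 0.0)))
        rows.append(
            {
                "profile": i,
                "or": np.exp(log_or),
                "or_low": np.exp(log_or - Z95 * se),
                "or_high": np.exp(log_or + Z95 * se),
                "se_log_or": se,
            }
        )
    return pd.DataFrame(rows)
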