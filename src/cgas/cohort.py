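"""Cohort data model: variants, genotype matrix, phenotypes, result bundles.

Genotypes are stored as effect-allele dosages in an ``int8`` array with a
dedicated missing sentinel (:data:`MISSING`).  Every downstream operation
treats missingness explicitly; there is no silent zero-fill and no
imputation anywhere in the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in :class:`GenotypeMatrix.calls`.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")

SMOKING_LEVELS = ("never", "former", "current")


@dataclass(frozen=True)
class VariantInfo:
    """Identity of one biallelic SNP in the panel.

    ``effect_allele`` names which of the two alleles the dosage counts;
    it is either ``"ref"`` or ``"alt"``.
    """

    snp_id: str
    gene: str = ""
    chromosome: str = ""
    allele_ref: str = "A"
    allele_alt: str = "G"
    effect_allele: str = "alt"

    def __post_init__(self) -> None:
        if self.allele_ref == self.allele_alt:
            raise ValueError(
                f"{self.snp_id}: ref and alt alleles are identical ({self.allele_ref})"
            )
        if self.effect_allele not in ("ref", "alt"):
            raise ValueError(f"{self.snp_id}: effect_allele must be 'ref' or 'alt'")

    @property
    def effect_base(self) -> str:
        return self.allele_alt if self.effect_allele == "alt" else self.allele_ref

    @property
    def other_base(self) -> str:
        return self.allele_ref if self.effect_allele == "alt" else self.allele_alt


class GenotypeMatrix:
    """Subjects x SNPs effect-allele dosage matrix with explicit missingness.

    Parameters
    ----------
    subject_ids:
        Ordered unique subject identifiers (length ``n``).
    variants:
        Ordered :class:`VariantInfo` list (length ``m``); rsIDs must be unique.
    calls:
        ``(n, m)`` integer array; each entry in ``{0, 1, 2}`` or
        :data:`MISSING`.
    """

    def __init__(
        self,
        subject_ids: Sequence[str],
        variants: Sequence[VariantInfo],
        calls: np.ndarray,
    ) -> None:
        subject_ids = list(subject_ids)
        if len(set(subject_ids)) != len(subject_ids):
            raise ValueError("duplicate subject identifiers")
        snp_ids = [v.snp_id for v in variants]
        if len(set(snp_ids)) != len(snp_ids):
            dup = sorted({s for s in snp_ids if snp_ids.count(s) > 1})
            raise ValueError(f"duplicated rsID(s) in panel: {', '.join(dup)}")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(subject_ids), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(subject_ids)} subjects x {len(variants)} variants"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2} or missing")
        self.subject_ids = subject_ids
        self.variants = list(variants)
        self.calls = calls
        self._subject_index = {s: i for i, s in enumerate(subject_ids)}
        self._variant_index = {v.snp_id: j for j, v in enumerate(self.variants)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def variant(self, snp_id: str) -> VariantInfo:
        return self.variants[self.variant_index(snp_id)]

    def variant_index(self, snp_id: str) -> int:
        try:
            return self._variant_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def subject_index(self, subject_id: str) -> int:
        try:
            return self._subject_index[subject_id]
        except KeyError:
            raise KeyError(f"subject {subject_id!r} not in matrix") from None

    def dosages(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP (int8, missing as :data:`MISSING`)."""
        return self.calls[:, self.variant_index(snp_id)]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- transforms ----------------------------------------------------------
    def flip_effect_allele(self, snp_id: str) -> "GenotypeMatrix":
        """Return a copy with the coded allele at ``snp_id`` switched.

        Every non-missing call ``c`` maps to ``2 - c``.
        """
        j = self.variant_index(snp_id)
        calls = self.calls.copy()
        col = calls[:, j]
        obs = col != MISSING
        col[obs] = 2 - col[obs]
        v = self.variants[j]
        flipped = dataclasses.replace(
            v, effect_allele="ref" if v.effect_allele == "alt" else "alt"
        )
        variants = list(self.variants)
        variants[j] = flipped
        return GenotypeMatrix(self.subject_ids, variants, calls)

    def subset_subjects(self, subject_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.subject_index(s) for s in subject_ids]
        return GenotypeMatrix(
            [self.subject_ids[i] for i in idx], self.variants, self.calls[idx, :]
        )

    def subset_variants(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(s) for s in snp_ids]
        return GenotypeMatrix(
            self.subject_ids,
            [self.variants[j] for j in idx],
            self.calls[:, idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Dosages as a DataFrame (missing as pandas NA)."""
        df = pd.DataFrame(
            self.calls, index=self.subject_ids, columns=self.snp_ids, dtype="Int8"
        )
        return df.mask(df == MISSING)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_subjects} subjects x {self.n_variants} SNPs)"


@dataclass
class PhenotypeTable:
    """Per-subject outcome and covariates.

    ``data`` columns: ``outcome`` (1 = case, 0 = control), ``sex``
    (male/female), ``age`` (years), ``caucasian`` (0/1), ``diabetes`` (0/1),
    ``hypertension`` (0/1), ``smoking`` (never/former/current); indexed by
    unique subject id.  Race is collapsed to Caucasian / non-Caucasian for
    modelling; a full ``race`` column, when present, is kept only for
    descriptive tables.
    """

    data: pd.DataFrame

    REQUIRED = ("outcome", "sex", "age", "caucasian", "diabetes", "hypertension", "smoking")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate subject identifiers in phenotype table")
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table missing column(s): {missing_cols}")
        if df["outcome"].isna().any():
            raise ValueError("outcome must never be missing")
        if not set(df["outcome"].unique()) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if (df["age"] < 0).any():
            bad = df.index[df["age"] < 0][0]
            raise ValueError(f"negative age for subject {bad!r}")
        bad_sex = set(df["sex"].dropna().unique()) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unknown sex level(s): {sorted(bad_sex)}")
        bad_smk = set(df["smoking"].dropna().unique()) - set(SMOKING_LEVELS)
        if bad_smk:
            raise ValueError(f"unknown smoking level(s): {sorted(bad_smk)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=np.int8)

    def covariate_design(self, covariates: Sequence[str]) -> pd.DataFrame:
        """Numeric design columns for the adjusting covariates.

        ``sex`` becomes a male indicator, ``smoking`` two indicators
        (former, current; never as reference); other covariates are taken
        as numeric.
        """
        cols: dict[str, np.ndarray] = {}
        df = self.data
        for cov in covariates:
            if cov == "sex":
                cols["sex_male"] = (df["sex"] == "male").astype(float).to_numpy()
            elif cov == "smoking":
                cols["smoking_former"] = (df["smoking"] == "former").astype(float).to_numpy()
                cols["smoking_current"] = (df["smoking"] == "current").astype(float).to_numpy()
            elif cov in df.columns:
                cols[cov] = df[cov].to_numpy(dtype=float)
            else:
                raise KeyError(f"unknown covariate {cov!r}")
        return pd.DataFrame(cols, index=df.index)

    def subset(self, subject_ids: Iterable[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(subject_ids)].copy())


def align_cohort(
    gm: GenotypeMatrix, pheno: PhenotypeTable, logger=None
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Intersect genotype and phenotype tables on subject id.

    Subjects present in only one file are dropped with a warning, not an
    error; the order of the genotype matrix is preserved.
    """
    common = [s for s in gm.subject_ids if s in set(pheno.subject_ids)]
    n_drop = (gm.n_subjects - len(common)) + (len(pheno.subject_ids) - len(common))
    if n_drop and logger is not None:
        logger.warning(
            "dropping %d subject(s) present in only one of genotype/phenotype inputs",
            n_drop,
        )
    if not common:
        raise ValueError("no subjects shared between genotype and phenotype inputs")
    return gm.subset_subjects(common), pheno.subset(common)


@dataclass
class ResultsBundle:
    """Everything one pipeline run produces, plus provenance."""

    qc_report: object | None = None
    association_table: pd.DataFrame | None = None
    ld_table: pd.DataFrame | None = None
    search_result: object | None = None
    roc_comparison: object | None = None
    provenance: dict = field(default_factory=dict)
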