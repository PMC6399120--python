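"""Variant- and sample-level quality control.

Missingness, minor-allele frequency, Hardy-Weinberg chi-square and exact
tests, filter application (a SNP is considered in HWE only when *neither*
test rejects it), duplicate-sample concordance and allele-frequency group
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import MISSING, GenotypeMatrix, PhenotypeTable


class GenotypeCounts(NamedTuple):
    """Genotype class counts by effect-allele dosage (0, 1, 2 copies)."""

    n_aa: int
    n_ab: int
    n_bb: int

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb


def genotype_counts(
    gm: GenotypeMatrix, snp: str, subset: Sequence[str] | np.ndarray | None = None
) -> GenotypeCounts:
    """Count genotype classes for one SNP; missing calls are excluded.

    ``subset`` is either a list of subject ids or a boolean mask over the
    matrix rows.
    """
    col = gm.dosages(snp)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.dtype == bool:
            col = col[subset]
        else:
            col = col[[gm.subject_index(s) for s in subset]]
    return GenotypeCounts(
        int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
    )


def minor_allele_frequency(c: GenotypeCounts) -> float:
    """Folded allele frequency min(p, 1-p) of the effect allele."""
    if c.total == 0:
        raise ValueError("allele frequency undefined: no observed genotypes")
    p = (2 * c.n_bb + c.n_ab) / (2.0 * c.total)
    return float(min(p, 1.0 - p))


def hwe_chisq(c: GenotypeCounts) -> tuple[float, float]:
    """1-df chi-square HWE test, no continuity correction.

    Returns ``(nan, nan)`` for a monomorphic SNP (untestable).
    """
    n = c.total
    if n == 0:
        raise ValueError("no observed genotypes")
    p = (2 * c.n_bb + c.n_ab) / (2.0 * n)
    if p == 0.0 or p == 1.0:
        return float("nan"), float("nan")
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([c.n_aa, c.n_ab, c.n_bb], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, 1))


def _hwe_het_log_probs(n: int, n_alleles_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    Enumerates every heterozygote count with the parity of the minor-allele
    total; returns (het counts, log probabilities), normalized.
    """
    n_min = n_alleles_minor
    hets = np.arange(n_min % 2, n_min + 1, 2)
    n_hom_min = (n_min - hets) // 2
    n_hom_maj = n - hets - n_hom_min
    valid = n_hom_maj >= 0
    hets, n_hom_min, n_hom_maj = hets[valid], n_hom_min[valid], n_hom_maj[valid]
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_min + 1)
        - gammaln(n_hom_maj + 1)
    )
    logp -= np.logaddexp.reduce(logp)
    return hets, logp


def hwe_exact(c: GenotypeCounts) -> float:
    """Exact HWE test conditional on the allele counts.

    p = sum of probabilities of all heterozygote configurations whose
    conditional probability is <= that of the observed one.  A monomorphic
    SNP admits a single configuration, so p = 1 (the chi-square companion
    flags it untestable instead).
    """
    n = c.total
    if n == 0:
        raise ValueError("no observed genotypes")
    n_eff = 2 * c.n_bb + c.n_ab
    n_min = min(n_eff, 2 * n - n_eff)
    if n_min == 0:
        return 1.0
    hets, logp = _hwe_het_log_probs(n, n_min)
    obs_logp = logp[hets == c.n_ab][0]
    p = float(np.exp(logp[logp <= obs_logp + 1e-12]).sum())
    return min(p, 1.0)


@dataclass
class QCReport:
    """Per-variant and per-sample QC status with removal reasons."""

    variant_table: pd.DataFrame
    sample_table: pd.DataFrame

    @property
    def kept_snps(self) -> list[str]:
        t = self.variant_table
        return list(t.loc[t["status"] == "kept", "snp_id"])

    @property
    def removed_snps(self) -> dict[str, str]:
        t = self.variant_table
        rm = t[t["status"] == "removed"]
        return dict(zip(rm["snp_id"], rm["removal_reason"]))


def apply_qc_filters(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    max_variant_missing: float = 0.5,
    max_sample_missing: float = 0.5,
    hwe_alpha: float = 0.05,
    require_control_data: bool = True,
    hwe_controls_only: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC filter cascade and report every removal with a reason.

    Order: sample-missingness filter, control-missing filter (SNPs with
    100% missing genotypes in controls), variant-missingness filter, HWE
    filter.  A SNP is in HWE only when neither the chi-square nor the
    exact test rejects at ``hwe_alpha``; HWE is assessed on cases and
    controls pooled by default.
    """
    for name, t in (
        ("max_variant_missing", max_variant_missing),
        ("max_sample_missing", max_sample_missing),
        ("hwe_alpha", hwe_alpha),
    ):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    if gm.subject_ids != pheno.subject_ids:
        raise ValueError("genotype and phenotype subjects are not aligned")

    # 1) sample filter
    miss = gm.missing_mask()
    n_var = max(gm.n_variants, 1)
    sample_missing = miss.sum(axis=1) / n_var
    sample_keep = sample_missing <= max_sample_missing
    sample_table = pd.DataFrame(
        {
            "subject_id": gm.subject_ids,
            "missing_fraction": sample_missing,
            "status": np.where(sample_keep, "kept", "removed"),
        }
    )
    kept_subjects = [s for s, k in zip(gm.subject_ids, sample_keep) if k]
    gm_s = gm.subset_subjects(kept_subjects)
    pheno_s = pheno.subset(kept_subjects)
    is_control = pheno_s.outcome == 0
    is_case = ~is_control

    rows = []
    kept_ids = []
    for v in gm_s.variants:
        col = gm_s.dosages(v.snp_id)
        n = len(col)
        overall_missing = float((col == MISSING).mean()) if n else 1.0
        ctrl = col[is_control]
        case = col[is_case]
        miss_ctrl = float((ctrl == MISSING).mean()) if ctrl.size else float("nan")
        miss_case = float((case == MISSING).mean()) if case.size else float("nan")
        hwe_subset = ctrl if hwe_controls_only else col
        counts = GenotypeCounts(
            int((hwe_subset == 0).sum()),
            int((hwe_subset == 1).sum()),
            int((hwe_subset == 2).sum()),
        )
        maf = minor_allele_frequency(counts) if counts.total else float("nan")
        if counts.total:
            chisq_stat, chisq_p = hwe_chisq(counts)
            exact_p = hwe_exact(counts)
        else:
            chisq_p = exact_p = float("nan")
        status, reason = "kept", ""
        if require_control_data and ctrl.size and (ctrl == MISSING).all():
            status, reason = "removed", "all genotypes missing in controls"
        elif overall_missing > max_variant_missing:
            status, reason = "removed", "missingness"
        elif (np.isfinite(chisq_p) and chisq_p < hwe_alpha) or (
            np.isfinite(exact_p) and exact_p < hwe_alpha
        ):
            status, reason = "removed", "HWE"
        rows.append(
            {
                "snp_id": v.snp_id,
                "gene": v.gene,
                "missing_fraction": overall_missing,
                "missing_fraction_cases": miss_case,
                "missing_fraction_controls": miss_ctrl,
                "maf": maf,
                "hwe_chisq_p": chisq_p,
                "hwe_exact_p": exact_p,
                "status": status,
                "removal_reason": reason,
            }
        )
        if status == "kept":
            kept_ids.append(v.snp_id)
    report = QCReport(variant_table=pd.DataFrame(rows), sample_table=sample_table)
    return gm_s.subset_variants(kept_ids), report


def duplicate_concordance(
    gm: GenotypeMatrix, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Per-pair fraction of SNPs with both calls non-missing and equal.

    A pair with no jointly non-missing SNP gets ``nan`` and is flagged.
    """
    rows = []
    for a, b in pairs:
        ra = gm.calls[gm.subject_index(a)]
        rb = gm.calls[gm.subject_index(b)]
        both = (ra != MISSING) & (rb != MISSING)
        n_joint = int(both.sum())
        conc = float((ra[both] == rb[both]).mean()) if n_joint else float("nan")
        rows.append(
            {
                "subject_a": a,
                "subject_b": b,
                "n_joint": n_joint,
                "concordance": conc,
                "defined": n_joint > 0,
            }
        )
    return pd.DataFrame(rows)


def compare_maf(
    c1: GenotypeCounts | tuple[int, int],
    c2: GenotypeCounts | tuple[int, int],
) -> tuple[float, float]:
    """Compare allele frequencies of two groups by two-sided Fisher exact test.

    Each argument is either genotype counts (converted to minor/major allele
    counts) or a raw ``(n_minor, n_major)`` allele-count pair — the latter
    accommodates external reference frequencies via an effective allele
    count.  Returns (odds ratio, p).
    """

    def _alleles(c) -> tuple[int, int]:
        if isinstance(c, GenotypeCounts):
            eff = 2 * c.n_bb + c.n_ab
            tot = 2 * c.total
            return min(eff, tot - eff), tot - min(eff, tot - eff)
        return int(c[0]), int(c[1])

    a1, b1 = _alleles(c1)
    a2, b2 = _alleles(c2)
    if a1 + b1 == 0 or a2 + b2 == 0:
        raise ValueError("a group has zero allele count")
    table = [[a1, b1], [a2, b2]]
    or_, p = stats.fisher_exact(table, alternative="two-sided")
    return float(or_), float(p)


def reference_allele_counts(freq: float, n_effective: int) -> tuple[int, int]:
    """Convert a reference allele frequency into integer allele counts."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError("frequency outside [0, 1]")
    n_minor = int(round(freq * n_effective))
    return n_minor, n_effective - n_minor
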