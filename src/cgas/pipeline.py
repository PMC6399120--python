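"""End-to-end orchestration: QC -> association -> LD -> search -> ROC.

One global seed feeds per-stage derived streams so every stage is
independently reproducible; all stage parameters default to the analysis
protocol the package implements (20,000 permutations, 1,000 bootstrap
resamples, alpha 0.05).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import DEFAULT_COVARIATES, PermutationSpec, assoc_scan, baseline_table
from .cohort import GenotypeMatrix, PhenotypeTable, ResultsBundle, align_cohort
from .design import RiskModel
from .io import read_genotype_table, read_phenotypes, read_vcf, write_results
from .ld import haplotype_assessment, ld_scan
from .qc import apply_qc_filters
from .roc import compare_models
from .search import SearchConfig, run_model_search

logger = logging.getLogger("cgas")


@dataclass
class RunConfig:
    """All pipeline stage parameters with protocol defaults."""

    genotypes: str | None = None
    phenotypes: str | None = None
    out_dir: str = "results"
    seed: int = 42
    # qc
    max_variant_missing: float = 0.5
    max_sample_missing: float = 0.5
    hwe_alpha: float = 0.05
    require_control_data: bool = True
    # association
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    n_perm: int = 20_000
    alpha: float = 0.05
    # ld
    r2_threshold: float = 0.5
    # search
    aic_tie_tol: float = 1e-6
    max_search_snps: int = 12  # most significant SNPs entering the exhaustive search
    max_snps: int = 20
    stepwise_mode: str = "aic"
    # roc
    n_boot: int = 1000
    refit_bootstrap: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "covariates" in data:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)


def _derived_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, abs(hash(stage)) % (2**31)]).generate_state(1)[0] % (2**31))


def load_inputs(cfg: RunConfig) -> tuple[GenotypeMatrix, PhenotypeTable]:
    if cfg.genotypes is None or cfg.phenotypes is None:
        raise ValueError("genotype and phenotype paths are required")
    gpath, ppath = Path(cfg.genotypes), Path(cfg.phenotypes)
    for p in (gpath, ppath):
        if not p.exists():
            raise FileNotFoundError(p)
    if gpath.suffix in (".vcf", ".gz") or gpath.name.endswith(".vcf.gz"):
        gm = read_vcf(gpath)
    else:
        gm = read_genotype_table(gpath, dialect="dosage")
    pheno = read_phenotypes(ppath)
    return align_cohort(gm, pheno, logger=logger)


def run_pipeline(
    cfg: RunConfig,
    gm: GenotypeMatrix | None = None,
    pheno: PhenotypeTable | None = None,
) -> ResultsBundle:
    """Execute every stage in order and persist the results bundle."""
    if gm is None or pheno is None:
        gm, pheno = load_inputs(cfg)
    bundle = ResultsBundle(
        provenance={
            "seed": cfg.seed,
            "version": __version__,
            "inputs": {"genotypes": cfg.genotypes, "phenotypes": cfg.phenotypes},
            "n_subjects": gm.n_subjects,
            "n_variants": gm.n_variants,
        }
    )

    logger.info("stage qc: %d variants, %d subjects", gm.n_variants, gm.n_subjects)
    gm_qc, qc_report = apply_qc_filters(
        gm, pheno,
        max_variant_missing=cfg.max_variant_missing,
        max_sample_missing=cfg.max_sample_missing,
        hwe_alpha=cfg.hwe_alpha,
        require_control_data=cfg.require_control_data,
    )
    for snp, reason in qc_report.removed_snps.items():
        logger.info("qc: removed %s (%s)", snp, reason)
    pheno_qc = pheno.subset(gm_qc.subject_ids)
    bundle.qc_report = qc_report

    logger.info("stage assoc: %d variants retained", gm_qc.n_variants)
    spec = PermutationSpec(n_perm=cfg.n_perm, seed=_derived_seed(cfg.seed, "perm"))
    assoc_table, assoc_detail = assoc_scan(
        gm_qc, pheno_qc, covariates=cfg.covariates, spec=spec, alpha=cfg.alpha
    )
    bundle.association_table = assoc_table
    bundle.provenance["baseline_table"] = json.loads(
        baseline_table(pheno_qc).to_json(orient="records")
    )

    sig = assoc_table[
        (assoc_table["status"] == "ok") & (assoc_table["adjusted_p"] < cfg.alpha)
    ]
    if len(sig) > cfg.max_search_snps:
        logger.info(
            "capping multivariate search at the %d most significant of %d SNPs",
            cfg.max_search_snps, len(sig),
        )
        sig = sig.nsmallest(cfg.max_search_snps, "adjusted_p")
        sig = sig.loc[sorted(sig.index)]  # keep panel order
    sig_snps = list(sig["snp_id"])
    logger.info("stage ld: %d significant SNPs", len(sig_snps))
    if len(sig_snps) >= 2:
        ld_table = ld_scan(gm_qc, sig_snps, r2_threshold=cfg.r2_threshold)
        in_ld_pairs = [
            (r.snp1, r.snp2) for r in ld_table.itertuples() if r.in_ld
        ]
        if in_ld_pairs:
            hap = haplotype_assessment(gm_qc, in_ld_pairs, alpha=cfg.alpha)
            ld_table = ld_table.merge(
                hap[["snp1", "snp2", "haplotype_supported"]],
                on=["snp1", "snp2"], how="left",
            )
        bundle.ld_table = ld_table
    else:
        bundle.ld_table = pd.DataFrame(
            columns=["snp1", "snp2", "n", "r2", "d_prime", "chisq", "p", "in_ld", "status"]
        )

    if sig_snps:
        logger.info("stage search: %d SNPs -> %d models", len(sig_snps), 2 ** len(sig_snps) - 1)
        scfg = SearchConfig(
            snp_terms=[(s, m) for s, m in zip(sig["snp_id"], sig["model"])],
            forced_covariates=tuple(cfg.covariates),
            alpha=cfg.alpha,
            aic_tie_tol=cfg.aic_tie_tol,
            max_snps=cfg.max_snps,
            stepwise_mode=cfg.stepwise_mode,
        )
        search_result = run_model_search(gm_qc, pheno_qc, scfg)
        bundle.search_result = search_result

        logger.info("stage roc")
        snp_models = scfg.snp_models
        final_snps = [
            t for t in search_result.final_terms if t in snp_models and ":" not in t
        ]
        specs = {
            "snps": RiskModel(list(search_result.chosen_subset), snp_models, cfg.covariates),
            "clinical": RiskModel(["diabetes", "hypertension"], snp_models, cfg.covariates),
            "combined": RiskModel(
                list(search_result.final_terms), snp_models, cfg.covariates
            ),
        }
        bundle.roc_comparison = compare_models(
            specs, gm_qc, pheno_qc,
            n_boot=cfg.n_boot,
            seed=_derived_seed(cfg.seed, "boot"),
            refit_bootstrap=cfg.refit_bootstrap,
        )
    else:
        logger.warning("no significant SNPs; search and ROC stages skipped")

    out = write_results(bundle, cfg.out_dir)
    logger.info("wrote %d result files to %s", len(out), cfg.out_dir)
    return bundle
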