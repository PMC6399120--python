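"""Synthetic case-control cohort generator.

Emulates the statistical structure the analysis assumes: biallelic SNPs in
Hardy-Weinberg proportions, LD pairs drawn as two-locus haplotypes,
clinical covariates, a logistic disease model (with optional
SNP x risk-factor interactions) whose intercept is solved numerically to
hit a target case fraction, and structured missingness — per-SNP random
missingness, block missingness (one subject subset missing a SNP group)
and arm-specific total missingness (SNPs never called in controls).

``paper_template_config`` ships a ready-made configuration approximating
the cohort the package targets: n = 3,004 with an 81.4% case share, strong
clinical risk factors, 12 modest-effect SNPs under stated inheritance
models, three LD pairs, one hypertension interaction and the study-like
missingness profile.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assoc import encode
from .cohort import MISSING, GenotypeMatrix, PhenotypeTable, VariantInfo

_BASES = ("A", "C", "G", "T")


@dataclass
class SnpSpec:
    """One simulated SNP: frequency, inheritance coding, effect size."""

    snp_id: str
    maf: float
    model: str = "additive"
    beta: float = 0.0  # log OR on the encoded term
    gene: str = ""
    chromosome: str = "1"
    interaction_with: str | None = None  # covariate column, e.g. "hypertension"
    interaction_beta: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5]")


@dataclass
class LdPairSpec:
    """Two SNPs drawn jointly from a four-haplotype pool."""

    snp1: str
    snp2: str
    hap_freqs: tuple[float, float, float, float]  # order: 11, 10, 01, 00
    beta1: float = 0.0
    beta2: float = 0.0
    model1: str = "additive"
    model2: str = "additive"
    gene: str = ""
    chromosome: str = "1"
    missing_rate1: float = 0.0
    missing_rate2: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.hap_freqs, dtype=float)
        if (f < 0).any():
            raise ValueError("negative haplotype frequency")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")


def hap_freqs_from_r(maf1: float, maf2: float, r: float) -> tuple[float, float, float, float]:
    """Four haplotype frequencies with given effect-allele MAFs and correlation r."""
    p, q = maf1, maf2
    d = r * np.sqrt(p * (1 - p) * q * (1 - q))
    freqs = (p * q + d, p * (1 - q) - d, (1 - p) * q - d, (1 - p) * (1 - q) + d)
    if min(freqs) < -1e-12:
        raise ValueError("r incompatible with the allele frequencies")
    return tuple(max(f, 0.0) for f in freqs)


@dataclass
class CovariateSpec:
    """Marginal covariate distribution and causal log-OR effects."""

    female_frac: float = 0.5
    age_mean: float = 57.0
    age_sd: float = 12.0
    noncaucasian_frac: float = 0.05
    diabetes_prev: float = 0.2
    hypertension_prev: float = 0.5
    smoking_fracs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # never/former/current
    # optional correlation structure: diabetes prevalence conditional on
    # hypertension, and an additive age shift for hypertensives (the
    # marginal age mean stays ``age_mean``)
    diabetes_prev_by_hypertension: tuple[float, float] | None = None  # (no-hyp, hyp)
    age_hypertension_shift: float = 0.0
    # log ORs per design column
    beta_female: float = 0.0
    beta_age: float = 0.0  # per year, age centred at age_mean
    beta_noncaucasian: float = 0.0
    beta_diabetes: float = 0.0
    beta_hypertension: float = 0.0
    beta_smoking_former: float = 0.0
    beta_smoking_current: float = 0.0


@dataclass
class MissingnessSpec:
    """Structured missingness applied after outcome generation.

    With ``shared_failure_order`` the per-SNP missing subsets are nested
    (one latent per-subject failure score drives every rate), emulating
    plate-failure missingness where the same subjects fail across assays —
    so the complete-case fraction is 1 minus the largest rate rather than
    the product of the per-SNP retention rates.
    """

    block_groups: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    control_missing_snps: tuple[str, ...] = ()
    shared_failure_order: bool = False


@dataclass
class SimConfig:
    n_subjects: int
    case_fraction: float
    seed: int
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    snp_specs: list[SnpSpec] = field(default_factory=list)
    ld_pair_specs: list[LdPairSpec] = field(default_factory=list)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    intercept: float | None = None  # solved for case_fraction when None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground-truth parameters emitted alongside the data."""

    intercept: float
    snp_params: dict
    hap_freqs: dict
    covariate_betas: dict
    case_fraction_target: float

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """HWE dosages: binomial(2, maf) effect-allele counts."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    return rng.binomial(2, maf, size=n).astype(np.int8)


def simulate_ld_pair(
    hap_freqs, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage vectors at two linked loci: two haplotypes per subject."""
    f = np.asarray(hap_freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("negative haplotype frequency")
    f = f / f.sum()
    haps = rng.choice(4, size=(n, 2), p=f)  # 0='11', 1='10', 2='01', 3='00'
    allele1 = np.isin(haps, (0, 1)).astype(np.int8)
    allele2 = np.isin(haps, (0, 2)).astype(np.int8)
    return allele1.sum(axis=1).astype(np.int8), allele2.sum(axis=1).astype(np.int8)


def _draw_covariates(cov: CovariateSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = np.where(rng.random(n) < cov.female_frac, "female", "male")
    hyp = (rng.random(n) < cov.hypertension_prev).astype(int)
    base_mean = cov.age_mean - cov.age_hypertension_shift * cov.hypertension_prev
    age = np.clip(
        rng.normal(base_mean, cov.age_sd, n) + cov.age_hypertension_shift * hyp, 18, 95
    )
    cauc = (rng.random(n) >= cov.noncaucasian_frac).astype(int)
    if cov.diabetes_prev_by_hypertension is not None:
        p_no, p_yes = cov.diabetes_prev_by_hypertension
        diab = (rng.random(n) < np.where(hyp == 1, p_yes, p_no)).astype(int)
    else:
        diab = (rng.random(n) < cov.diabetes_prev).astype(int)
    smoking = rng.choice(
        ["never", "former", "current"], size=n, p=np.asarray(cov.smoking_fracs)
    )
    return pd.DataFrame(
        {"sex": sex, "age": age, "caucasian": cauc, "diabetes": diab,
         "hypertension": hyp, "smoking": smoking}
    )


def _covariate_eta(cov: CovariateSpec, df: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(df))
    eta += cov.beta_female * (df["sex"] == "female").to_numpy()
    eta += cov.beta_age * (df["age"].to_numpy() - cov.age_mean)
    eta += cov.beta_noncaucasian * (1 - df["caucasian"].to_numpy())
    eta += cov.beta_diabetes * df["diabetes"].to_numpy()
    eta += cov.beta_hypertension * df["hypertension"].to_numpy()
    eta += cov.beta_smoking_former * (df["smoking"] == "former").to_numpy()
    eta += cov.beta_smoking_current * (df["smoking"] == "current").to_numpy()
    return eta


def _encoded(dose: np.ndarray, model: str) -> np.ndarray:
    enc = encode(dose, model, "s")
    if model == "codominant":
        raise ValueError("codominant effect betas are not supported in simulation")
    return np.nan_to_num(enc.to_numpy()[:, 0])


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    def mean_risk(c):
        return float(np.mean(1.0 / (1.0 + np.exp(-(eta + c))))) - target

    return brentq(mean_risk, -30, 30, xtol=1e-10)


_VARIANT_BASE_CYCLE = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Draw one cohort under the configured disease model.

    Covariates and genotypes are drawn independently; the linear predictor
    sums the intercept, encoded SNP effects, covariate effects and
    interaction terms; the outcome is Bernoulli(logistic(eta)).
    Missingness is applied afterwards.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    df = _draw_covariates(cfg.covariates, n, rng)

    in_pair = {s for p in cfg.ld_pair_specs for s in (p.snp1, p.snp2)}
    doses: dict[str, np.ndarray] = {}
    order: list[SnpSpec] = []
    spec_by_id = {s.snp_id: s for s in cfg.snp_specs}
    for p in cfg.ld_pair_specs:
        d1, d2 = simulate_ld_pair(p.hap_freqs, n, rng)
        doses[p.snp1], doses[p.snp2] = d1, d2
    for s in cfg.snp_specs:
        if s.snp_id not in in_pair:
            doses[s.snp_id] = simulate_genotypes(s.maf, n, rng)
        order.append(s)
    unknown = in_pair - set(spec_by_id)
    if unknown:
        raise ValueError(f"LD pair references unspecified SNP(s): {sorted(unknown)}")

    eta = _covariate_eta(cfg.covariates, df)
    for s in cfg.snp_specs:
        enc = _encoded(doses[s.snp_id], s.model)
        eta += s.beta * enc
        if s.interaction_with is not None:
            partner = (
                df[s.interaction_with].to_numpy(dtype=float)
                if s.interaction_with in df.columns
                else _encoded(doses[s.interaction_with], spec_by_id[s.interaction_with].model)
            )
            eta += s.interaction_beta * enc * partner

    intercept = cfg.intercept if cfg.intercept is not None else _solve_intercept(
        eta, cfg.case_fraction
    )
    prob = 1.0 / (1.0 + np.exp(-(eta + intercept)))
    y = (rng.random(n) < prob).astype(int)
    if y.min() == y.max():
        raise ValueError(
            f"simulated outcome is single-class (case share {y.mean():.3f}); "
            "check effect sizes and intercept"
        )

    # --- missingness ------------------------------------------------------
    calls = np.column_stack([doses[s.snp_id] for s in order]).astype(np.int8)
    col_of = {s.snp_id: j for j, s in enumerate(order)}
    if cfg.missingness.shared_failure_order:
        u = rng.random(n)  # one failure score drives every rate (nested sets)
        for snps, frac in cfg.missingness.block_groups:
            for s in snps:
                calls[u < frac, col_of[s]] = MISSING
        for s in order:
            if s.missing_rate > 0:
                calls[u < s.missing_rate, col_of[s.snp_id]] = MISSING
    else:
        for snps, frac in cfg.missingness.block_groups:
            block = rng.random(n) < frac
            for s in snps:
                calls[block, col_of[s]] = MISSING
        for s in order:
            if s.missing_rate > 0:
                calls[rng.random(n) < s.missing_rate, col_of[s.snp_id]] = MISSING
    for s in cfg.missingness.control_missing_snps:
        calls[y == 0, col_of[s]] = MISSING

    subject_ids = [f"S{i:05d}" for i in range(n)]
    variants = []
    for j, s in enumerate(order):
        ref, alt = _VARIANT_BASE_CYCLE[j % len(_VARIANT_BASE_CYCLE)]
        variants.append(
            VariantInfo(
                snp_id=s.snp_id, gene=s.gene, chromosome=s.chromosome,
                allele_ref=ref, allele_alt=alt, effect_allele="alt",
            )
        )
    gm = GenotypeMatrix(subject_ids, variants, calls)
    pheno_df = df.copy()
    pheno_df.insert(0, "outcome", y)
    pheno_df.index = pd.Index(subject_ids, name="subject_id")
    pheno = PhenotypeTable(pheno_df)
    truth = SimTruth(
        intercept=float(intercept),
        snp_params={
            s.snp_id: {
                "maf": s.maf, "model": s.model, "beta": s.beta,
                "interaction_with": s.interaction_with,
                "interaction_beta": s.interaction_beta,
            }
            for s in cfg.snp_specs
        },
        hap_freqs={f"{p.snp1}|{p.snp2}": list(p.hap_freqs) for p in cfg.ld_pair_specs},
        covariate_betas={
            k: v for k, v in asdict(cfg.covariates).items() if k.startswith("beta_")
        },
        case_fraction_target=cfg.case_fraction,
    )
    return gm, pheno, truth


# ---------------------------------------------------------------------------
# study-template configuration


#: Table-1-style targets: (marginal prevalence, crude OR) per binary covariate.
_TEMPLATE_COVARIATE_TARGETS = {
    "female": (0.399, 0.71),
    "noncaucasian": (0.031, 1.95),
    "diabetes": (0.227, 2.83),
    "hypertension": (0.807, 18.63),
    "smoking_former": (0.369, 0.80),   # vs never; Table-1 former-reference ORs recoded
    "smoking_current": (0.199, 0.93),
}

_TEMPLATE_CASE_FRACTION = 0.814
_CALIBRATION_SEED = 987_654_321  # internal, fixed: calibration is part of the template
_CALIBRATION_N = 400_000


def _calibrate_covariate_betas(
    cov: CovariateSpec,
    case_fraction: float,
    snp_specs: list[SnpSpec] = (),
    ld_pairs: list[LdPairSpec] = (),
) -> CovariateSpec:
    """Tune causal covariate log-ORs so *crude* by-arm ORs match the targets.

    A conditional log-OR understates the crude (marginal) OR when other
    strong risk factors sit in the linear predictor (non-collapsibility),
    so each beta is adjusted iteratively on one large fixed reference
    population — which includes the SNP effects and any SNP x covariate
    interaction — until the implied crude OR matches its target.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    df = _draw_covariates(cov, _CALIBRATION_N, rng)
    cols = {
        "female": (df["sex"] == "female").to_numpy(float),
        "noncaucasian": (1 - df["caucasian"]).to_numpy(float),
        "diabetes": df["diabetes"].to_numpy(float),
        "hypertension": df["hypertension"].to_numpy(float),
        "smoking_former": (df["smoking"] == "former").to_numpy(float),
        "smoking_current": (df["smoking"] == "current").to_numpy(float),
    }
    # fixed genotype contribution (mains + interactions with drawn covariates)
    geno_eta = np.zeros(_CALIBRATION_N)
    in_pair = {s for p in ld_pairs for s in (p.snp1, p.snp2)}
    doses = {}
    for p in ld_pairs:
        doses[p.snp1], doses[p.snp2] = simulate_ld_pair(p.hap_freqs, _CALIBRATION_N, rng)
    for s in snp_specs:
        d = doses.get(s.snp_id)
        if d is None:
            d = simulate_genotypes(s.maf, _CALIBRATION_N, rng)
        enc = _encoded(d, s.model)
        geno_eta += s.beta * enc
        if s.interaction_with is not None and s.interaction_with in df.columns:
            geno_eta += s.interaction_beta * enc * df[s.interaction_with].to_numpy(float)

    betas = {k: float(np.log(t[1])) for k, t in _TEMPLATE_COVARIATE_TARGETS.items()}
    age_c = df["age"].to_numpy() - cov.age_mean
    for _ in range(40):
        eta = cov.beta_age * age_c + geno_eta
        for k, x in cols.items():
            eta = eta + betas[k] * x
        c = _solve_intercept(eta, case_fraction)
        p = 1.0 / (1.0 + np.exp(-(eta + c)))
        max_err = 0.0
        for k, x in cols.items():
            p1, p0 = p[x == 1].mean(), p[x == 0].mean()
            crude = (p1 / (1 - p1)) / (p0 / (1 - p0))
            err = np.log(_TEMPLATE_COVARIATE_TARGETS[k][1]) - np.log(crude)
            betas[k] += err
            max_err = max(max_err, abs(err))
        if max_err < 1e-6:
            break
    from dataclasses import replace

    return replace(
        cov,
        beta_female=betas["female"],
        beta_noncaucasian=betas["noncaucasian"],
        beta_diabetes=betas["diabetes"],
        beta_hypertension=betas["hypertension"],
        beta_smoking_former=betas["smoking_former"],
        beta_smoking_current=betas["smoking_current"],
    )


# the 12 template effect SNPs: (rsID, gene, chrom, model, OR, MAF, random missing rate)
_TEMPLATE_EFFECT_SNPS = [
    ("rs1126616", "SPP1", "4", "dominant", 1.31, 0.24, 0.0626),
    ("rs35068180", "MMP3", "11", "overdominant", 1.29, 0.44, 0.0616),
    ("rs2238135", "VDR", "12", "recessive", 1.74, 0.30, 0.0626),
    ("rs3102735", "OPG", "8", "overdominant", 1.32, 0.15, 0.0600),
    ("rs1800247", "BGLAP", "1", "overdominant", 1.28, 0.30, 0.0639),
    ("rs385564", "KL", "13", "dominant", 1.27, 0.40, 0.0639),
    ("rs679620", "MMP3", "11", "overdominant", 1.25, 0.44, 0.0632),
    ("rs2248359", "CYP24A1", "20", "recessive", 1.40, 0.45, 0.0),
    ("rs1564858", "TNFRSF11B", "8", "dominant", 1.32, 0.15, 0.0),
    ("rs4236", "MGP", "12", "dominant", 1.23, 0.40, 0.0619),
    ("rs9138", "SPP1", "4", "dominant", 1.22, 0.24, 0.0619),
    ("rs731236", "VDR", "12", "dominant", 1.22, 0.35, 0.0619),
]


@lru_cache(maxsize=4)
def _template_base(interaction: bool) -> tuple:
    cov0 = CovariateSpec(
        female_frac=0.399,
        age_mean=57.34,
        age_sd=12.6,
        noncaucasian_frac=0.031,
        diabetes_prev=0.227,
        hypertension_prev=0.807,
        smoking_fracs=(0.432, 0.369, 0.199),
        # diabetics are largely hypertensive and hypertensives are older, so
        # the crude diabetes/age contrasts arise mostly through confounding
        # with hypertension and the conditional effects stay modest
        diabetes_prev_by_hypertension=(0.08, 0.262),
        age_hypertension_shift=4.5,
        beta_age=0.01,
    )

    snp_specs: list[SnpSpec] = []
    for rsid, gene, chrom, model, or_, maf, miss in _TEMPLATE_EFFECT_SNPS:
        beta = float(np.log(or_))
        inter_with, inter_beta = None, 0.0
        if interaction and rsid == "rs2248359":
            # hypertension-specific risk genotype: weak main effect, strong
            # interaction; the marginal effect lands near the univariate OR
            beta, inter_with, inter_beta = -0.28, "hypertension", 0.99
        if rsid == "rs9138":
            beta = 0.0  # carried entirely through its perfect-LD partner
        snp_specs.append(
            SnpSpec(
                snp_id=rsid, maf=maf, model=model, beta=beta, gene=gene,
                chromosome=chrom, interaction_with=inter_with,
                interaction_beta=inter_beta, missing_rate=miss,
            )
        )

    ld_pairs = [
        LdPairSpec(
            "rs679620", "rs35068180", hap_freqs_from_r(0.44, 0.44, 0.9),
            gene="MMP3", chromosome="11",
        ),
        # perfectly correlated pair: reproduces the aliasing / tied-subset
        # phenomenon in the multivariate search
        LdPairSpec(
            "rs9138", "rs1126616", hap_freqs_from_r(0.24, 0.24, 1.0),
            gene="SPP1", chromosome="4",
        ),
        LdPairSpec(
            "rs3102735", "rs1564858", hap_freqs_from_r(0.15, 0.15, 0.9),
            gene="TNFRSF11B", chromosome="8",
        ),
    ]

    # 54 null SNPs (panel total 79 = 12 effect + 13 control-missing + 54 null)
    null_rng = np.random.default_rng(20190226)
    null_specs = [
        SnpSpec(
            snp_id=f"rsN{i:04d}", maf=float(null_rng.uniform(0.05, 0.45)),
            model="additive", beta=0.0, gene=f"GENE{i % 17}",
            chromosome=str(1 + i % 22),
            missing_rate=float(null_rng.uniform(0.0, 0.08)),
        )
        for i in range(54)
    ]
    ctrl_missing = [
        SnpSpec(
            snp_id=f"rsC{i:04d}", maf=float(null_rng.uniform(0.05, 0.45)),
            model="additive", beta=0.0, gene=f"GENE{i % 17}",
            chromosome=str(1 + i % 22),
        )
        for i in range(13)
    ]
    missing = MissingnessSpec(
        block_groups=[(("rs2248359", "rs1564858"), 0.463)],
        control_missing_snps=tuple(s.snp_id for s in ctrl_missing),
        shared_failure_order=True,
    )
    cov = _calibrate_covariate_betas(
        cov0, _TEMPLATE_CASE_FRACTION, snp_specs, ld_pairs
    )
    return cov, snp_specs + null_specs + ctrl_missing, ld_pairs, missing


def paper_template_config(
    seed: int,
    n_subjects: int = 3004,
    interaction: bool = True,
    with_missingness: bool = True,
) -> SimConfig:
    """The shipped study-like configuration (see module docstring)."""
    cov, snp_specs, ld_pairs, missing = _template_base(interaction)
    if not with_missingness:
        snp_specs = [
            SnpSpec(**{**asdict(s), "missing_rate": 0.0}) for s in snp_specs
        ]
        missing = MissingnessSpec()
    return SimConfig(
        n_subjects=n_subjects,
        case_fraction=_TEMPLATE_CASE_FRACTION,
        seed=seed,
        covariates=cov,
        snp_specs=list(snp_specs),
        ld_pair_specs=list(ld_pairs),
        missingness=missing,
    )
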