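"""Readers and writers: VCF / tabular genotypes, phenotype tables, results.

Only biallelic SNP records with GT fields are accepted from VCF; dosages
count the effect allele, which defaults to the minor allele in the full
sample (overridable per SNP).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cohort import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    ResultsBundle,
    VariantInfo,
    _VALID_BASES,
)

logger = logging.getLogger("cgas")

_TRUE = {"1", "yes", "y", "true"}
_FALSE = {"0", "no", "n", "false"}


def _apply_effect_allele_rule(
    gm: GenotypeMatrix,
    rule: str | Mapping[str, str] = "minor",
) -> GenotypeMatrix:
    """Recode dosages so they count the chosen effect allele.

    ``rule`` is ``"minor"`` (default: the minor allele in the full sample;
    ties keep alt), ``"alt"``, ``"ref"``, or a per-SNP mapping
    ``{snp_id: "ref"|"alt"}`` falling back to minor for unlisted SNPs.
    """
    for v in list(gm.variants):
        want: str
        if isinstance(rule, Mapping):
            want = rule.get(v.snp_id, "minor")
        else:
            want = rule
        if want == "minor":
            col = gm.dosages(v.snp_id)
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            freq = obs.sum() / (2.0 * obs.size)  # current effect-allele freq
            if freq > 0.5:
                gm = gm.flip_effect_allele(v.snp_id)
        elif want in ("ref", "alt"):
            if gm.variant(v.snp_id).effect_allele != want:
                gm = gm.flip_effect_allele(v.snp_id)
        else:
            raise ValueError(f"unknown effect-allele rule {want!r}")
    return gm


def read_vcf(path, effect_allele_rule: str | Mapping[str, str] = "minor") -> GenotypeMatrix:
    """Read a VCF of biallelic SNPs into a :class:`GenotypeMatrix`.

    Raises on multiallelic records, duplicated rsIDs, non-SNP alleles and
    absent GT fields.  ``./.`` maps to missing.
    """
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    if not subjects:
        raise ValueError(f"{path}: VCF has no sample columns (no GT data)")
    variants: list[VariantInfo] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record rejected: {rec.ID or rec.POS}")
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or not {ref, alt} <= _VALID_BASES:
            raise ValueError(f"non-SNP record rejected: {rec.ID or rec.POS}")
        gene = rec.INFO.get("GENE") or ""
        variants.append(
            VariantInfo(
                snp_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                gene=gene,
                chromosome=str(rec.CHROM),
                allele_ref=ref,
                allele_alt=alt,
                effect_allele="alt",
            )
        )
        gts = rec.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        cols.append(dose.astype(np.int8))
    calls = (
        np.column_stack(cols) if cols else np.empty((len(subjects), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(subjects, variants, calls)
    return _apply_effect_allele_rule(gm, effect_allele_rule)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only) for the matrix; alt-coded dosages."""
    # emit alt-allele dosages regardless of the in-memory effect coding
    path = Path(path)
    contigs = []
    for v in gm.variants:
        chrom = v.chromosome or "1"
        if chrom not in contigs:
            contigs.append(chrom)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *[f"##contig=<ID={c}>" for c in contigs],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.subject_ids),
    ]
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, v in enumerate(gm.variants):
        col = gm.calls[:, j]
        if v.effect_allele == "ref":  # re-express as alt dosage
            col = np.where(col == MISSING, MISSING, 2 - col)
        info = f"GENE={v.gene}" if v.gene else "."
        chrom = v.chromosome or "1"
        lines.append(
            f"{chrom}\t{j + 1}\t{v.snp_id}\t{v.allele_ref}\t{v.allele_alt}\t.\t.\t"
            f"{info}\tGT\t" + "\t".join(gt_code[int(c)] for c in col)
        )
    path.write_text("\n".join(lines) + "\n")


def read_genotype_table(
    path,
    dialect: str = "allele-pair",
    missing_token: str = "NN",
    effect_allele_rule: str | Mapping[str, str] = "minor",
    sep: str | None = None,
) -> GenotypeMatrix:
    """Read a delimited genotype table (one row per subject, one column per SNP).

    ``dialect="allele-pair"`` expects unordered base pairs like ``"AC"``
    (``"CA"`` is equivalent); ``dialect="dosage"`` expects 0/1/2.  Empty
    cells and ``missing_token`` map to missing.
    """
    if dialect not in ("dosage", "allele-pair"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = sep if sep is not None else ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    subjects = [str(s) for s in df.index]
    variants: list[VariantInfo] = []
    cols: list[np.ndarray] = []
    for snp in df.columns:
        raw = df[snp].to_numpy()
        if dialect == "dosage":
            dose = np.full(len(raw), MISSING, dtype=np.int8)
            for i, val in enumerate(raw):
                val = val.strip()
                if val in ("", missing_token):
                    continue
                if val not in ("0", "1", "2"):
                    raise ValueError(f"{snp}: invalid dosage {val!r}")
                dose[i] = int(val)
            variants.append(VariantInfo(snp_id=snp, allele_ref="A", allele_alt="G"))
            cols.append(dose)
            continue
        alleles: set[str] = set()
        pairs: list[tuple[str, str] | None] = []
        for val in raw:
            val = val.strip().upper()
            if val in ("", missing_token):
                pairs.append(None)
                continue
            if len(val) != 2 or not set(val) <= _VALID_BASES:
                raise ValueError(f"{snp}: invalid genotype {val!r}")
            pairs.append((val[0], val[1]))
            alleles.update(val)
        if len(alleles) > 2:
            raise ValueError(f"{snp}: {len(alleles)} alleles observed (biallelic expected)")
        obs = sorted(alleles) or ["A", "C"]
        ref = obs[0]
        alt = obs[1] if len(obs) == 2 else next(b for b in "ACGT" if b != ref)
        dose = np.full(len(pairs), MISSING, dtype=np.int8)
        for i, pair in enumerate(pairs):
            if pair is not None:
                dose[i] = sum(1 for a in pair if a == alt)
        variants.append(VariantInfo(snp_id=snp, allele_ref=ref, allele_alt=alt))
        cols.append(dose)
    calls = (
        np.column_stack(cols) if cols else np.empty((len(subjects), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(subjects, variants, calls)
    return _apply_effect_allele_rule(gm, effect_allele_rule)


def _parse_binary(val, column: str, row) -> int:
    s = str(val).strip().lower()
    if s in _TRUE:
        return 1
    if s in _FALSE:
        return 0
    raise ValueError(f"row {row!r}: unknown level {val!r} for column {column!r}")


def read_phenotypes(path, sep: str | None = None) -> PhenotypeTable:
    """Read a delimited phenotype/covariate table into a :class:`PhenotypeTable`."""
    sep = sep if sep is not None else ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "subject_id" not in raw.columns:
        raw = raw.rename(columns={raw.columns[0]: "subject_id"})
    if "outcome" not in raw.columns:
        raise ValueError("phenotype table has no 'outcome' column")
    rows = {}
    for col in ("outcome", "caucasian", "diabetes", "hypertension"):
        if col not in raw.columns:
            raise ValueError(f"phenotype table has no {col!r} column")
        rows[col] = [
            _parse_binary(v, col, r) for v, r in zip(raw[col], raw["subject_id"])
        ]
    sex = [s.strip().lower() for s in raw["sex"]]
    bad = set(sex) - {"male", "female", "m", "f"}
    if bad:
        raise ValueError(f"unknown sex level(s): {sorted(bad)}")
    sex = ["male" if s in ("male", "m") else "female" for s in sex]
    smoking = [s.strip().lower() for s in raw["smoking"]]
    df = pd.DataFrame(
        {
            "outcome": rows["outcome"],
            "sex": sex,
            "age": pd.to_numeric(raw["age"]).to_numpy(),
            "caucasian": rows["caucasian"],
            "diabetes": rows["diabetes"],
            "hypertension": rows["hypertension"],
            "smoking": smoking,
        },
        index=pd.Index([str(s) for s in raw["subject_id"]], name="subject_id"),
    )
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index_label="subject_id")


# ---------------------------------------------------------------------------
# results bundle


def _fmt_or(or_, lo, hi) -> str:
    if not np.isfinite(or_):
        return "inestimable"
    return f"{or_:.6g} ({lo:.6g}–{hi:.6g})"


def write_results(bundle: ResultsBundle, out_dir) -> list[Path]:
    """Write one TSV per populated result table plus a JSON summary.

    Column order is deterministic and reruns with the same inputs and seed
    are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"provenance": bundle.provenance}

    def _emit(df: pd.DataFrame | None, name: str) -> None:
        if df is None:
            return
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
        summary[name] = json.loads(df.to_json(orient="records"))

    _emit(getattr(bundle.qc_report, "variant_table", None), "qc_variants")
    _emit(getattr(bundle.qc_report, "sample_table", None), "qc_samples")
    assoc = bundle.association_table
    if assoc is not None and "or_point" in assoc.columns:
        assoc = assoc.copy()
        assoc["or_ci"] = [
            _fmt_or(o, lo, hi)
            for o, lo, hi in zip(assoc["or_point"], assoc["or_low"], assoc["or_high"])
        ]
    _emit(assoc, "association")
    _emit(bundle.ld_table, "ld")
    _emit(getattr(bundle.search_result, "subset_table", None), "search_subsets")
    _emit(getattr(bundle.search_result, "final_model_table", None), "final_model")
    _emit(getattr(bundle.roc_comparison, "summary_table", None), "roc_summary")
    _emit(getattr(bundle.roc_comparison, "delong_table", None), "roc_delong")
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    written.append(p)
    return written
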