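"""Multivariate model search: enumeration, aliasing, stepwise interactions."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cgas.cohort import MISSING, GenotypeMatrix
from cgas.design import DesignBuilder, profile_odds_ratios, raw_frame
from cgas.search import (
    SearchConfig,
    complete_cases,
    count_models,
    detect_aliased,
    exhaustive_search,
    run_model_search,
    stepwise_interactions,
)
from cgas.simulate import (
    LdPairSpec,
    SimConfig,
    SnpSpec,
    hap_freqs_from_r,
    simulate_cohort,
)
from test_qc import _matrix_from_columns, _pheno


class TestCountModels:
    @pytest.mark.parametrize("m,expected", [(12, 4095), (1, 1), (3, 7)])
    def test_values(self, m, expected):
        assert count_models(m) == expected

    @pytest.mark.parametrize("m", range(1, 11))
    def test_matches_enumeration(self, m):
        subsets = sum(1 for r in range(1, m + 1) for _ in combinations(range(m), r))
        assert count_models(m) == subsets

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            count_models(0)


class TestCompleteCases:
    def test_full_cohort_when_no_missingness(self, small_cohort):
        gm, pheno, _ = small_cohort
        mask, counts = complete_cases(gm, pheno, ["rsA", "rsB"])
        assert counts["n"] == gm.n_subjects
        assert mask.all()

    def test_unlisted_snp_missingness_ignored(self):
        gm = _matrix_from_columns(
            {"rs1": [0, 1, 2, 1], "rs2": [MISSING, 1, 0, 2]}
        )
        mask, counts = complete_cases(gm, _pheno([0, 1, 0, 1]), ["rs1"])
        assert counts["n"] == 4

    def test_block_missingness_fraction(self):
        # a 46% block at one SNP leaves ~54% complete cases
        cfg = SimConfig(
            n_subjects=4000, case_fraction=0.5, seed=21,
            snp_specs=[SnpSpec("rsM", maf=0.3), SnpSpec("rsN", maf=0.3)],
        )
        gm, pheno, _ = simulate_cohort(cfg)
        rng = np.random.default_rng(3)
        calls = gm.calls.copy()
        calls[rng.random(4000) < 0.46, 0] = MISSING
        gm2 = GenotypeMatrix(gm.subject_ids, gm.variants, calls)
        _, counts = complete_cases(gm2, pheno, ["rsM", "rsN"])
        assert counts["n"] / 4000 == pytest.approx(0.54, abs=0.03)
        assert counts["n_cases"] + counts["n_controls"] == counts["n"]

    def test_empty_result_advises(self):
        gm = _matrix_from_columns({"rs1": [MISSING] * 4})
        with pytest.raises(ValueError, match="reduce"):
            complete_cases(gm, _pheno([0, 1, 0, 1]), ["rs1"])


class TestDetectAliased:
    def test_duplicated_column_grouped(self):
        a = pd.DataFrame({"rs1": [0.0, 1, 1, 0, 1]})
        groups = detect_aliased({"rs1": a, "rs2": a.rename(columns={"rs1": "rs2"})})
        assert groups == [["rs1", "rs2"]]

    def test_encoding_level_aliasing(self):
        # different raw dosages, identical dominant encodings
        d1 = np.array([0, 1, 2, 0, 1])
        d2 = np.array([0, 2, 1, 0, 2])
        from cgas.assoc import encode

        groups = detect_aliased(
            {"rs1": encode(d1, "dominant", "rs1"), "rs2": encode(d2, "dominant", "rs2")}
        )
        assert groups == [["rs1", "rs2"]]

    def test_independent_columns_ungrouped(self, rng):
        cols = {
            f"rs{i}": pd.DataFrame({f"rs{i}": rng.integers(0, 3, 50).astype(float)})
            for i in range(4)
        }
        assert detect_aliased(cols) == []

    def test_affine_collinearity_detected(self):
        x = np.array([0.0, 1, 2, 0, 1, 2])
        a = pd.DataFrame({"rs1": x})
        b = pd.DataFrame({"rs2": 2 - x})  # complementary coding
        assert detect_aliased({"rs1": a, "rs2": b}) == [["rs1", "rs2"]]


def _search_cohort(seed=31, n=1500, with_alias=False):
    specs = [
        SnpSpec("rs1", maf=0.3, model="dominant", beta=np.log(1.8)),
        SnpSpec("rs2", maf=0.35, model="additive", beta=np.log(1.5)),
        SnpSpec("rs3", maf=0.25, model="dominant", beta=0.0),
        SnpSpec("rs4", maf=0.4, model="recessive", beta=0.0),
    ]
    pairs = []
    if with_alias:
        specs.append(SnpSpec("rs1b", maf=0.3, model="dominant", beta=0.0))
        pairs = [LdPairSpec("rs1", "rs1b", hap_freqs_from_r(0.3, 0.3, 1.0))]
    cfg = SimConfig(
        n_subjects=n, case_fraction=0.5, seed=seed, snp_specs=specs,
        ld_pair_specs=pairs,
    )
    return simulate_cohort(cfg)


def _cfg(gm, models=None, **kw):
    models = models or {}
    terms = [(s, models.get(s, "additive")) for s in gm.snp_ids]
    return SearchConfig(snp_terms=terms, **kw)


class TestExhaustiveSearch:
    def test_single_snp_trivial(self, small_cohort):
        gm, pheno, _ = small_cohort
        cfg = SearchConfig(snp_terms=[("rsA", "dominant")])
        res = exhaustive_search(gm, pheno, cfg)
        assert res.chosen_subset == ("rsA",)
        assert len(res.subset_table) == 1

    def test_chosen_minimises_aic_and_fixed_n(self):
        gm, pheno, _ = _search_cohort()
        cfg = _cfg(gm, {"rs1": "dominant", "rs2": "additive"})
        res = exhaustive_search(gm, pheno, cfg)
        ok = res.subset_table[res.subset_table.converged]
        best_row = ok.loc[ok.aic.idxmin()]
        assert best_row["subset"] == "+".join(res.chosen_subset)
        # all 2^m - 1 fits on the same complete-case subject set
        assert ok["n"].nunique() == 1
        assert len(res.subset_table) == count_models(gm.n_variants)

    def test_aliased_pair_reports_tied_alternatives(self):
        gm, pheno, _ = _search_cohort(with_alias=True)
        cfg = _cfg(gm, {"rs1": "dominant", "rs1b": "dominant", "rs2": "additive"})
        res = exhaustive_search(gm, pheno, cfg)
        assert ["rs1", "rs1b"] in res.aliased_groups
        assert "rs1" in res.chosen_subset
        # the substituted alternative is reported as an equally good subset
        alt = tuple("rs1b" if s == "rs1" else s for s in res.chosen_subset)
        assert alt in res.best_subsets

    def test_alias_masking_preserves_best_loglik(self):
        gm, pheno, _ = _search_cohort(with_alias=True)
        cfg = _cfg(gm, {"rs1": "dominant", "rs1b": "dominant", "rs2": "additive"})
        res = exhaustive_search(gm, pheno, cfg)
        # refit with the alternate aliased member: identical log-likelihood
        from cgas.logistic import fit_logistic

        mask, _ = complete_cases(gm, pheno, cfg.snp_terms, cfg.forced_covariates)
        builder = DesignBuilder(cfg.snp_models, cfg.forced_covariates)
        raw = raw_frame(gm, pheno, gm.snp_ids, cfg.forced_covariates).loc[mask]
        y = pheno.outcome[mask]
        fit_a = fit_logistic(y, builder.build(raw, list(res.chosen_subset)))
        alt = ["rs1b" if s == "rs1" else s for s in res.chosen_subset]
        fit_b = fit_logistic(y, builder.build(raw, alt))
        assert fit_a.llf == pytest.approx(fit_b.llf, abs=1e-8)

    def test_causal_subset_recovery(self):
        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            gm, pheno, _ = _search_cohort(seed=200 + seed, n=2000)
            cfg = _cfg(gm, {"rs1": "dominant", "rs2": "additive"})
            res = exhaustive_search(gm, pheno, cfg)
            hits += {"rs1", "rs2"} <= set(res.chosen_subset)
        assert hits > n_rep / 2

    def test_guard_on_m(self):
        with pytest.raises(ValueError, match="guard"):
            SearchConfig(snp_terms=[(f"rs{i}", "additive") for i in range(21)])


class TestStepwise:
    def test_empty_base_gives_clinical_model(self, small_cohort):
        gm, pheno, _ = small_cohort
        cfg = SearchConfig(snp_terms=[("rsA", "dominant")])
        fit, terms, _ = stepwise_interactions(gm, pheno, [], cfg)
        assert set(terms) <= {"diabetes", "hypertension"}
        for cov in ("sex_male", "age", "caucasian"):
            assert cov in fit.params.index

    def test_hierarchy_invariant(self):
        gm, pheno, _ = _search_cohort(seed=77)
        cfg = _cfg(gm, {"rs1": "dominant", "rs2": "additive"})
        _, terms, _ = stepwise_interactions(gm, pheno, ["rs1", "rs2", "rs3"], cfg)
        present = set(terms)
        for t in terms:
            if ":" in t:
                a, b = t.split(":", 1)
                assert a in present and b in present

    def test_interaction_recovery_single_cohort(self):
        # strong planted hypertension interaction is retained
        cfg_sim = SimConfig(
            n_subjects=3000, case_fraction=0.6, seed=5,
            covariates=__import__("cgas.simulate", fromlist=["CovariateSpec"]).CovariateSpec(
                hypertension_prev=0.5, beta_hypertension=np.log(3.0)
            ),
            snp_specs=[
                SnpSpec("rsI", maf=0.45, model="recessive", beta=-0.28,
                        interaction_with="hypertension", interaction_beta=1.4),
                SnpSpec("rsO", maf=0.3, model="dominant", beta=np.log(1.4)),
            ],
        )
        gm, pheno, _ = simulate_cohort(cfg_sim)
        cfg = SearchConfig(snp_terms=[("rsI", "recessive"), ("rsO", "dominant")])
        _, terms, _ = stepwise_interactions(gm, pheno, ["rsI", "rsO"], cfg)
        assert "rsI:hypertension" in terms

    def test_pvalue_mode_null_keeps_mains_mostly(self):
        kept_clean = 0
        n_rep = 10
        for seed in range(n_rep):
            gm, pheno, _ = _search_cohort(seed=300 + seed, n=1200)
            cfg = _cfg(
                gm, {"rs1": "dominant", "rs2": "additive"}, stepwise_mode="pvalue"
            )
            _, terms, _ = stepwise_interactions(gm, pheno, ["rs1", "rs2"], cfg)
            kept_clean += not any(":" in t for t in terms)
        assert kept_clean > n_rep / 2


class TestProfileOddsRatios:
    def _fitted(self):
        gm, pheno, _ = _search_cohort(seed=55)
        cfg = _cfg(gm, {"rs1": "dominant", "rs2": "additive"})
        res = run_model_search(gm, pheno, cfg)
        builder = DesignBuilder(cfg.snp_models, cfg.forced_covariates)
        return res, builder

    def _base_profile(self, res, **kw):
        prof = {"sex": "male", "age": 60, "caucasian": 1,
                "diabetes": 0, "hypertension": 0}
        for t in res.final_terms:
            for part in t.split(":"):
                if part.startswith("rs"):
                    prof.setdefault(part, 0)
        prof.update(kw)
        return prof

    def test_reference_profile_or_one(self):
        res, builder = self._fitted()
        ref = self._base_profile(res)
        out = profile_odds_ratios(res.final_fit, builder, res.final_terms, [ref], ref)
        assert out.iloc[0]["or"] == pytest.approx(1.0)
        assert out.iloc[0]["or_low"] == pytest.approx(1.0)
        assert out.iloc[0]["or_high"] == pytest.approx(1.0)

    def test_contrast_matches_hand_computation(self):
        # profile OR equals exp(contrast . beta) computed directly
        res, builder = self._fitted()
        term = next(t for t in res.final_terms if ":" not in t)
        ref = self._base_profile(res)
        prof = dict(ref)
        prof[term] = 2 if term.startswith("rs") else 1
        out = profile_odds_ratios(res.final_fit, builder, res.final_terms, [prof], ref)
        row_p = builder.profile_row(prof, res.final_terms)
        row_r = builder.profile_row(ref, res.final_terms)
        beta = res.final_fit.params
        contrast = (row_p - row_r).iloc[0]
        expected = float(np.exp(sum(contrast[c] * beta[c] for c in contrast.index)))
        assert out.iloc[0]["or"] == pytest.approx(expected, rel=1e-10)

    def test_unknown_profile_variable_rejected(self):
        res, builder = self._fitted()
        ref = self._base_profile(res)
        with pytest.raises((KeyError, ValueError)):
            builder.profile_row({"nonsense": 1}, res.final_terms)
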