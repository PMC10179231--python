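"""Regression engine, staged selection, pruning, FDR and QQ utilities."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mecgwas import (
    GenotypeMatrix,
    StagePlan,
    encode_genotype,
    encode_genotypes,
    fdr_qvalues,
    qq_data,
    snp_regression,
    staged_gwas,
)
from mecgwas.assoc import combine_stages, ld_prune


def make_geno(calls, chrom=None, sex=None):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    snps = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": (np.arange(m) + 1) * 1000,
            "minor": ["G"] * m,
            "major": ["A"] * m,
        }
    )
    return GenotypeMatrix([f"S{i}" for i in range(n)], snps, calls, sex)


class TestEncoding:
    @pytest.mark.parametrize(
        "count, model, expected",
        [
            (0, "additive", 0), (1, "additive", 1), (2, "additive", 2),
            (0, "dominant", 0), (1, "dominant", 1), (2, "dominant", 1),
            (0, "recessive", 0), (1, "recessive", 0), (2, "recessive", 1),
        ],
    )
    def test_codings(self, count, model, expected):
        assert encode_genotype(count, model) == expected

    def test_missing_propagates(self):
        assert np.isnan(encode_genotype(np.nan, "dominant"))
        out = encode_genotypes(np.array([0.0, np.nan, 2.0]), "recessive")
        assert np.isnan(out[1]) and out[2] == 1.0

    def test_bad_model_rejected(self):
        with pytest.raises(ValueError):
            encode_genotype(1, "codominant")


class TestSnpRegression:
    def test_noise_free_construction_recovers_beta(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        age = rng.uniform(20, 85, 100)
        y = 2.0 * g + 0.004 * age
        res = snp_regression(y, g, age[:, None])
        assert res.beta == pytest.approx(2.0, rel=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(5):
            n = 117
            g = rng.binomial(2, 0.25, n).astype(float)
            C = rng.normal(size=(n, 4))
            y = 0.1 * g + C @ rng.normal(size=4) + rng.normal(size=n)
            res = snp_regression(y, g, C)
            fit = sm.OLS(y, sm.add_constant(np.column_stack([g, C]))).fit()
            assert res.beta == pytest.approx(fit.params[1], abs=1e-8)
            assert res.se == pytest.approx(fit.bse[1], abs=1e-8)
            assert res.p == pytest.approx(fit.pvalues[1], abs=1e-8)
            assert res.n_used == n

    def test_null_pvalues_uniform(self, rng):
        """Permuting the phenotype severs the association: rejection at 5%
        stays within binomial bounds."""
        n, reps = 80, 1000
        g = rng.binomial(2, 0.3, n).astype(float)
        C = rng.normal(size=(n, 2))
        hits = 0
        for _ in range(reps):
            y = rng.normal(size=n)
            res = snp_regression(y, g, C)
            hits += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 4 * se

    def test_monomorphic_returns_none(self, rng):
        y = rng.normal(size=50)
        assert snp_regression(y, np.ones(50)) is None

    def test_collinear_with_covariate_returns_none(self, rng):
        g = rng.binomial(2, 0.3, 60).astype(float)
        y = rng.normal(size=60)
        assert snp_regression(y, g, g[:, None]) is None

    def test_missing_genotypes_drop_rows(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        g[:10] = np.nan
        y = rng.normal(size=100)
        res = snp_regression(y, g)
        assert res.n_used == 90


class TestCombineStages:
    def test_identical_stage_copies_equal_single_cohort_beta(self, rng):
        n = 60
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        g2 = np.concatenate([g, g])
        y2 = np.concatenate([y, y])
        single = snp_regression(y, g)
        pooled = combine_stages(y2, g2, None, np.ones(2 * n, dtype=bool))
        assert pooled.beta == pytest.approx(single.beta, rel=1e-10)

    def test_pooled_fit_equals_oracle_on_concatenated_data(self, rng):
        n = 150
        g = rng.binomial(2, 0.3, n).astype(float)
        C = rng.normal(size=(n, 3))
        y = 0.2 * g + rng.normal(size=n)
        mask = np.zeros(n, dtype=bool)
        mask[:100] = True  # stages 1..2
        res = combine_stages(y, g, C, mask)
        fit = sm.OLS(y[mask], sm.add_constant(np.column_stack([g[mask], C[mask]]))).fit()
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)


class TestStagedGwas:
    def test_single_stage_equals_thresholded_regression(self, rng):
        n, m = 90, 40
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        geno = make_geno(calls)
        y = rng.normal(size=n)
        plan = StagePlan.contiguous(n, 1)
        records = staged_gwas(geno, y, None, plan)
        for j, rec in enumerate(records):
            res = snp_regression(y, calls[:, j])
            assert rec.stage_results[1].p == pytest.approx(res.p, abs=1e-12)
            assert rec.survived_stage[1] == (res.p < 0.05)

    def test_survivor_never_rejected_by_any_stage(self, rng):
        n, m = 351, 300
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        geno = make_geno(calls)
        y = rng.normal(size=n)
        plan = StagePlan.contiguous(n, 3)
        records = staged_gwas(geno, y, None, plan)
        for rec in records:
            if rec.survived_all:
                for s, res in rec.stage_results.items():
                    assert res.p < plan.alpha

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        n, m = 351, 120
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        geno = make_geno(calls)
        y = 0.5 * calls[:, 17] + rng.normal(size=n)
        plan = StagePlan.contiguous(n, 3)
        records = staged_gwas(geno, y, None, plan)
        rec = records[17]
        assert rec.genome_wide_significant
        assert rec.q < 0.05

    def test_x_chromosome_excludes_males(self, rng):
        n, m = 200, 3
        calls = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        sex = np.array(["M"] * 120 + ["F"] * 80)
        geno = make_geno(calls, chrom=["1", "X", "X"], sex=sex)
        y = rng.normal(size=n)
        records = staged_gwas(geno, y, None, StagePlan.contiguous(n, 1))
        assert records[0].stage_results[1].n_used == n
        # X markers: only the 80 females enter the fit
        assert records[1].stage_results[1].n_used == 80

    def test_plan_size_mismatch_rejected(self, rng):
        geno = make_geno(rng.binomial(2, 0.3, size=(50, 5)).astype(float))
        y = rng.normal(size=50)
        y[0] = np.nan
        with pytest.raises(ValueError):
            staged_gwas(geno, y, None, StagePlan.contiguous(50, 2))


class TestLdPrune:
    def _records(self, geno, pvals):
        from mecgwas.assoc import AssocRecord, RegressionResult

        recs = []
        for j, p in enumerate(pvals):
            rec = AssocRecord(
                snp=geno.snps["id"].iloc[j], chrom="1",
                pos=int(geno.snps["pos"].iloc[j]), model="additive")
            rec.combined_results[3] = RegressionResult(0.1, 0.02, 5.0, p, 100)
            recs.append(rec)
        return recs

    def test_duplicate_snp_keeps_smaller_p(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        geno = make_geno(np.column_stack([g, g]))
        kept, dropped = ld_prune(self._records(geno, [1e-6, 1e-4]), geno)
        assert [r.snp for r in kept] == ["snp0"]
        assert dropped == {"snp1": "snp0"}

    def test_all_below_threshold_keeps_everything(self, rng):
        calls = rng.binomial(2, 0.3, size=(300, 4)).astype(float)
        geno = make_geno(calls)
        kept, dropped = ld_prune(self._records(geno, [1e-5, 1e-4, 1e-3, 1e-2]), geno)
        assert len(kept) == 4 and not dropped

    def test_chain_keeps_ends_of_correlation_chain(self):
        """A-B and B-C in strong LD but A-C not: greedy keeps A then C."""
        rng = np.random.default_rng(11)
        n = 4000

        def degrade(g, rate):
            out = g.copy()
            mask = rng.random(n) < rate
            out[mask] = rng.binomial(2, 0.5, mask.sum())
            return out

        a = rng.binomial(2, 0.5, n).astype(float)
        b = degrade(a, 0.09)
        c = degrade(b, 0.09)
        from mecgwas import ld_em

        r_ab, r_bc, r_ac = ld_em(a, b).r2, ld_em(b, c).r2, ld_em(a, c).r2
        assert r_ab >= 0.8 and r_bc >= 0.8 and r_ac < 0.8
        geno = make_geno(np.column_stack([a, b, c]))
        kept, dropped = ld_prune(self._records(geno, [1e-6, 1e-5, 1e-4]), geno)
        assert [r.snp for r in kept] == ["snp0", "snp2"]
        assert dropped == {"snp1": "snp0"}


class TestFdrAndQq:
    def test_hand_computed_bh(self):
        q = fdr_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_qvalues(np.array([0.42]))[0] == pytest.approx(0.42)

    def test_empty_input(self):
        assert fdr_qvalues(np.array([])).size == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30), st.integers(0, 1000))
    def test_bh_properties(self, ps, seed):
        """q >= p, q monotone in p, and invariant under input permutation."""
        p = np.array(ps)
        q = fdr_qvalues(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(seed).permutation(len(p))
        assert fdr_qvalues(p[perm]) == pytest.approx(q[perm], abs=1e-12)

    def test_qq_single_point(self):
        exp, obs = qq_data(np.array([0.1]))
        assert exp[0] == pytest.approx(0.3010, abs=5e-5)
        assert obs[0] == pytest.approx(1.0)

    def test_qq_uniform_near_identity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=5000)
        exp, obs = qq_data(p)
        mid = slice(1000, 4000)  # bulk of the distribution
        assert np.max(np.abs(exp[mid] - obs[mid])) < 0.12

    def test_qq_output_monotone(self, rng):
        exp, obs = qq_data(rng.uniform(size=100))
        assert np.all(np.diff(exp) <= 0) and np.all(np.diff(obs) <= 0)

    def test_zero_p_clipped(self):
        exp, obs = qq_data(np.array([0.0, 0.5]), floor=1e-10)
        assert obs[0] == pytest.approx(10.0)
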