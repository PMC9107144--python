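"""Additive QTL mapping: OLS core, cis/trans scans, permutation empirical
p-values and the eGene threshold rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import ols_oracle
from qtlmodules.containers import ExpressionMatrix, SummaryStatSet
from qtlmodules.errors import InputError, MonomorphicVariantError
from qtlmodules.io import read_bedpe
from qtlmodules.qtl import (
    egene_threshold,
    empirical_gene_p,
    filter_fixed_threshold,
    fit_additive,
    map_cis,
    map_trans,
    mark_significant,
    ols_scan,
)
from qtlmodules.synthetic import (
    PlantedEffect,
    SimulationSpec,
    gene_annotation,
    simulate_expression,
    simulate_genotypes,
    trans_interaction_ranges,
)
from conftest import make_genotypes


def _expr(geno, values, tissue="tissue01", genes=None):
    genes = genes or [f"g{i + 1:04d}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=geno.dosages.index, columns=genes),
        tissue_id=tissue,
    )


class TestFitAdditive:
    def test_noise_free_line(self):
        d = np.tile([0.0, 1.0, 2.0], 7)[:20]
        beta, se, p, df = fit_additive(d, 0.5 * d)
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert 0 < p <= 1e-300  # underflows to the numeric floor

    def test_orthogonal_design_zero_slope(self):
        dosage = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        expr = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        beta, _, _, _ = fit_additive(dosage, expr)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_small_design_matches_normal_equations(self):
        dosage = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        expr = np.array([1.0, 1.2, 1.9, 2.1, 3.0, 3.2])
        beta, se, p, df = fit_additive(dosage, expr)
        b0, s0, p0, d0 = ols_oracle(dosage, expr)
        assert beta == pytest.approx(b0, rel=1e-12)
        assert beta == pytest.approx(1.0)  # Sxy/Sxx = 4.0/4.0 by hand
        assert se == pytest.approx(s0, rel=1e-12)
        assert p == pytest.approx(p0, rel=1e-12)
        assert df == d0

    def test_monomorphic_and_mismatch_errors(self):
        with pytest.raises(MonomorphicVariantError):
            fit_additive(np.ones(10), np.arange(10.0))
        with pytest.raises(InputError):
            fit_additive(np.zeros(5), np.zeros(4))
        with pytest.raises(InputError):
            fit_additive(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def test_allele_flip_negates_beta_exactly(self, rng):
        d = rng.integers(0, 3, 50).astype(float)
        y = rng.normal(size=50)
        b1, s1, p1, _ = fit_additive(d, y)
        b2, s2, p2, _ = fit_additive(2.0 - d, y)
        assert b2 == pytest.approx(-b1, rel=1e-12)
        assert s2 == pytest.approx(s1, rel=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_random_designs_match_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            d = rng.integers(0, 3, n).astype(float)
            if d.std() == 0:
                continue
            y = rng.normal(size=n) + rng.normal() * d
            beta, se, p, _ = fit_additive(d, y)
            b0, s0, p0, _ = ols_oracle(d, y)
            assert beta == pytest.approx(b0, rel=1e-8)
            assert se == pytest.approx(s0, rel=1e-8)
            assert p == pytest.approx(p0, rel=1e-8, abs=1e-300)

    def test_pairwise_complete_deletion(self):
        d = np.array([0, 1, 2, 0, 1, 2, np.nan], dtype=float)
        y = np.array([0.1, 1.1, 2.2, 0.0, 0.9, 2.1, 5.0])
        beta, _, _, df = fit_additive(d, y)
        b0, _, _, d0 = ols_oracle(d[:6], y[:6])
        assert beta == pytest.approx(b0, rel=1e-12)
        assert df == d0


class TestMapCis:
    def test_window_zero_tests_exactly_tss_variant(self, small_geno, rng):
        genes = pd.DataFrame(
            {"chrom": "1", "tss": [int(small_geno.variants.iloc[2]["pos"])]},
            index=["g0001"],
        )
        expr = _expr(small_geno, rng.normal(size=(60, 1)))
        result = map_cis(small_geno, expr, genes, window_bp=0)
        assert list(result["variant_id"]) == [small_geno.variant_ids[2]]

    def test_planted_effect_recovered(self):
        spec = SimulationSpec(
            n_samples=300, n_variants=1, ld_block_size=1, maf_range=(0.5, 0.5),
            n_tissues=1, n_genes=1, n_modules=0, module_size=0,
            inverse_normal=False,
            planted_eqtls=[PlantedEffect("v0001", "g0001", ["tissue01"], 0.8)],
            seed=123,
        )
        geno = simulate_genotypes(spec)
        tissues, _ = simulate_expression(geno, spec)
        genes = gene_annotation(spec, geno)
        result = map_cis(geno, tissues[0], genes)
        assert result["beta"].iloc[0] == pytest.approx(0.8, abs=0.25)
        assert result["p_nominal"].iloc[0] < 1e-10

    def test_no_shared_samples_errors(self, small_geno, rng):
        expr = ExpressionMatrix(
            values=pd.DataFrame(rng.normal(size=(5, 1)), index=list("abcde"),
                                columns=["g0001"]),
            tissue_id="t",
        )
        genes = pd.DataFrame({"chrom": "1", "tss": [1]}, index=["g0001"])
        with pytest.raises(InputError):
            map_cis(small_geno, expr, genes)


class TestMapTrans:
    def _setup(self, rng):
        geno = make_genotypes(
            (rng.binomial(1, 0.4, (80, 3)) + rng.binomial(1, 0.4, (80, 3))).astype(float),
            positions=[1_000, 2_000_000, 4_000_000],
        )
        genes = pd.DataFrame(
            {"chrom": "1", "tss": [1_500, 2_000_500, 5_000_000]},
            index=["g0001", "g0002", "g0003"],
        )
        expr = _expr(geno, rng.normal(size=(80, 3)))
        return geno, genes, expr

    def test_empty_interactions_give_zero_tests(self, rng):
        geno, genes, expr = self._setup(rng)
        empty = pd.DataFrame(columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])
        assert map_trans(geno, expr, genes, empty).empty

    def test_single_target_window_gives_one_record(self, rng):
        geno, genes, expr = self._setup(rng)
        # anchor at v0001 (pos 1000), target window around g0002's TSS only
        inter = pd.DataFrame(
            [("1", 0, 2_000, "1", 1_999_000, 2_001_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        result = map_trans(geno, expr, genes, inter, cis_window_bp=1_000_000)
        assert len(result) == 1
        assert result.iloc[0]["variant_id"] == "v0001"
        assert result.iloc[0]["gene_id"] == "g0002"
        assert result.iloc[0]["kind"] == "trans"

    def test_cis_genes_excluded_from_trans(self, rng):
        geno, genes, expr = self._setup(rng)
        inter = pd.DataFrame(
            [("1", 0, 2_000, "1", 0, 6_000_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        result = map_trans(geno, expr, genes, inter, cis_window_bp=1_000_000)
        assert set(result["gene_id"]) == {"g0002", "g0003"}  # g0001 is cis

    def test_malformed_bedpe_reports_line(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("1\t0\t100\t1\t200\t300\n1\t0\tx\t1\t200\t300\n")
        with pytest.raises(Exception) as err:
            read_bedpe(path)
        assert "line 2" in str(err.value)

    def test_planted_trans_sign_recovered(self):
        hits = 0
        for seed in range(20):
            spec = SimulationSpec(
                n_samples=300, n_variants=2, ld_block_size=1, maf_range=(0.3, 0.5),
                n_tissues=1, n_genes=2, n_modules=0, module_size=0,
                planted_eqtls=[PlantedEffect("v0001", "g0002", ["tissue01"], 0.8,
                                             kind="trans")],
                seed=seed,
            )
            geno = simulate_genotypes(spec)
            tissues, _ = simulate_expression(geno, spec)
            genes = gene_annotation(spec, geno)
            inter = trans_interaction_ranges(spec, geno, genes)
            result = map_trans(geno, tissues[0], genes, inter)
            planted = result[(result["variant_id"] == "v0001") & (result["gene_id"] == "g0002")]
            hits += len(planted) == 1 and planted["beta"].iloc[0] > 0
        assert hits == 20


class TestEmpiricalGeneP:
    def _study(self, seed=0, beta=0.0, n=120, m=8):
        effects = [PlantedEffect("v0001", "g0001", ["tissue01"], beta)] if beta else []
        spec = SimulationSpec(
            n_samples=n, n_variants=m, ld_block_size=1, maf_range=(0.2, 0.5),
            n_tissues=1, n_genes=2, n_modules=0, module_size=0,
            planted_eqtls=effects, seed=seed,
        )
        geno = simulate_genotypes(spec)
        tissues, _ = simulate_expression(geno, spec)
        return geno, tissues[0], gene_annotation(spec, geno)

    def test_observed_beating_all_permutations(self):
        geno, expr, genes = self._study(beta=2.0)
        emp = empirical_gene_p(geno, expr, genes, "g0001", B=999, seed=1)
        assert emp.empirical_p == pytest.approx(1 / 1000)

    def test_b_zero_is_a_precondition_error(self):
        geno, expr, genes = self._study()
        with pytest.raises(InputError):
            empirical_gene_p(geno, expr, genes, "g0001", B=0)

    def test_gene_without_cis_variants_skipped(self, caplog):
        geno, expr, genes = self._study()
        genes.loc["g0001", "tss"] = 500_000_000
        assert empirical_gene_p(geno, expr, genes, "g0001", B=100) is None

    def test_deterministic_given_seed(self):
        geno, expr, genes = self._study()
        e1 = empirical_gene_p(geno, expr, genes, "g0002", B=200, seed=42)
        e2 = empirical_gene_p(geno, expr, genes, "g0002", B=200, seed=42)
        assert e1.empirical_p == e2.empirical_p
        np.testing.assert_array_equal(e1.perm_min_ps, e2.perm_min_ps)

    def test_invariant_under_monotone_relabeling_of_nominal_p(self):
        """Empirical p depends only on ranks, so any monotone transform of
        the nominal min-p values leaves it unchanged."""
        geno, expr, genes = self._study(beta=0.5)
        emp = empirical_gene_p(geno, expr, genes, "g0001", B=300, seed=7)
        B = emp.perm_min_ps.size
        direct = (1 + np.sum(emp.perm_min_ps <= emp.p_min_observed)) / (B + 1)
        transformed = (1 + np.sum(np.sqrt(emp.perm_min_ps) <= np.sqrt(emp.p_min_observed))) / (B + 1)
        assert emp.empirical_p == pytest.approx(direct) == pytest.approx(transformed)


class TestEgeneThreshold:
    def _empirical(self, gene, p_emp, perm=None):
        from qtlmodules.qtl import GeneEmpirical

        perm = perm if perm is not None else np.linspace(0.001, 1, 200)
        return GeneEmpirical(gene_id=gene, tissue_id="t", p_min_observed=p_emp,
                             empirical_p=p_emp, perm_min_ps=np.asarray(perm))

    def test_all_null_genes_give_zero_egenes(self):
        frame = egene_threshold([self._empirical(f"g{i}", 1.0) for i in range(5)])
        assert not frame["is_egene"].any()

    def test_single_strong_gene_is_egene(self):
        frame = egene_threshold([self._empirical("g1", 0.001)], fdr=0.05)
        assert frame["is_egene"].all()
        assert frame.attrs["p_star"] == pytest.approx(0.001)

    def test_threshold_is_quantile_of_permutation_null(self):
        perm = np.linspace(0.0, 1.0, 1001)
        frame = egene_threshold([self._empirical("g1", 0.02, perm)], fdr=0.05)
        assert frame["nominal_threshold"].iloc[0] == pytest.approx(
            np.quantile(perm, 0.02)
        )

    def test_empty_input_errors(self):
        with pytest.raises(InputError):
            egene_threshold([])

    def test_mark_significant_requires_egene_and_threshold(self):
        qtls = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v1"],
                "gene_id": ["g1", "g1", "g2"],
                "tissue_id": ["t", "t", "t"],
                "beta": [1.0, 0.2, 1.0],
                "se": [0.1, 0.1, 0.1],
                "p_nominal": [1e-6, 0.2, 1e-6],
                "df": [100] * 3,
                "kind": ["cis"] * 3,
            }
        )
        egenes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "tissue_id": ["t", "t"],
                "p_min_observed": [1e-6, 1e-6],
                "empirical_p": [0.001, 0.9],
                "is_egene": [True, False],
                "nominal_threshold": [1e-3, np.nan],
            }
        )
        flagged = mark_significant(qtls, egenes)
        assert list(flagged["significant"]) == [True, False, False]


def test_filter_fixed_threshold_strict_inequality():
    table = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(10)],
            "beta": 0.1,
            "se": 0.01,
            "p": [5e-8, 4.9e-8, 1e-9, 1e-7, 0.5, 0.04, 5.1e-8, 1e-20, 0.9, 0.3],
            "n": 1000,
            "maf": 0.2,
        }
    )
    stats_set = SummaryStatSet(trait_id="prot", table=table)
    kept = filter_fixed_threshold(stats_set, alpha=5e-8)
    # exactly-at-threshold record is excluded; 3 records fall strictly below
    assert set(kept.table["variant_id"]) == {"v1", "v2", "v7"}
    empty = filter_fixed_threshold(
        SummaryStatSet(trait_id="x", table=table.iloc[:0]), alpha=5e-8
    )
    assert empty.table.empty
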