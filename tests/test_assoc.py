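import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from blocklmm.assoc import (
    combine_kernels,
    estimate_weights,
    fit_null,
    mixture_pvalue,
    single_snp_gwas,
    snpset_gwas,
)
from blocklmm.evaluate import significance_threshold
from blocklmm.kernels import GramMatrix, KernelSpec, additive_grm, gram_matrix
from blocklmm.lmm import fit_single_kernel
from blocklmm.simulate import simulate_phenotype


def _gm(values):
    return GramMatrix(np.asarray(values, dtype=float), ids=[f"s{i}" for i in range(len(values))])


class TestCombineKernels:
    def test_zero_set_weight_leaves_polygenic_kernel(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((3, 3))
        Kc, Kri = _gm(A @ A.T), _gm(np.eye(3))
        Ks = combine_kernels(Kc, Kri, w_c=0.7, w_ri=0.0)
        assert np.allclose(Ks.values, 0.7 * Kc.values)

    def test_identity_z_toy_weighted_sum(self):
        Kc = _gm([[2.0, 1.0, 0.0], [1.0, 2.0, 1.0], [0.0, 1.0, 2.0]])
        Kri = _gm(np.eye(3))
        Ks = combine_kernels(Kc, Kri, w_c=0.5, w_ri=0.5)
        assert np.allclose(Ks.values, 0.5 * Kc.values + 0.5 * np.eye(3))

    def test_replicated_design_z_expands_kernel(self):
        Kc = _gm([[1.0, 0.5], [0.5, 1.0]])
        Z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])  # 3 obs on 2 genotypes
        Ks = combine_kernels(Kc, Kc, w_c=1.0, w_ri=0.0, Zc=Z, Zri=Z)
        assert Ks.values.shape == (3, 3)
        assert Ks.values[0, 1] == pytest.approx(1.0)  # same genotype

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_kernels(_gm(np.eye(3)), _gm(np.eye(4)), 0.5, 0.5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            combine_kernels(_gm(np.eye(2)), _gm(np.eye(2)), -0.1, 0.5)


class TestMixturePvalue:
    def test_zero_deviance_gives_p_one(self):
        assert mixture_pvalue(0.0) == pytest.approx(1.0)

    def test_chi2_oracle_value(self):
        # D = 3.8414588 is the 95th percentile of chi2_1, so p = 0.5 * 0.05
        assert mixture_pvalue(3.8414588) == pytest.approx(0.025, abs=1e-7)

    def test_matches_half_survival_for_positive_deviance(self):
        for D in (0.5, 1.0, 2.7, 10.0):
            assert mixture_pvalue(D) == pytest.approx(0.5 * chi2.sf(D, 1), rel=1e-12)

    def test_negative_deviance_clamped(self):
        assert mixture_pvalue(-1e-6) == pytest.approx(1.0)

    def test_pi0_zero_is_plain_chi2(self):
        assert mixture_pvalue(3.8414588, pi0=0.0) == pytest.approx(0.05, abs=1e-6)


class TestMixturePvalueProperties:
    @given(st.floats(min_value=0.0, max_value=100.0),
           st.floats(min_value=0.0, max_value=100.0))
    @settings(deadline=None, derandomize=True)
    def test_monotone_decreasing_in_deviance(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert mixture_pvalue(hi) <= mixture_pvalue(lo)

    @given(st.floats(min_value=-10.0, max_value=1e6),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, derandomize=True)
    def test_always_a_valid_probability(self, d, pi0):
        p = mixture_pvalue(d, pi0)
        assert 0.0 <= p <= 1.0


class TestEstimateWeights:
    def test_identical_kernels_degenerate_to_single_fit(self, small_panel, small_panel_kc):
        geno, _ = small_panel
        Kc, structure = small_panel_kc
        rng = np.random.default_rng(1)
        y = rng.standard_normal(geno.n_samples)
        X = np.column_stack([np.ones(geno.n_samples), structure])
        mk = estimate_weights(y, X, Kc, Kc)
        single = fit_single_kernel(y, X, Kc, "REML")
        assert mk.lR_model == pytest.approx(single.lR, abs=1e-6)

    def test_weights_on_simplex(self, small_panel, small_panel_kc):
        geno, sets = small_panel
        Kc, structure = small_panel_kc
        rng = np.random.default_rng(2)
        y = rng.standard_normal(geno.n_samples)
        X = np.column_stack([np.ones(geno.n_samples), structure])
        Kri = gram_matrix(geno.codes[:, sets[0].marker_indices], KernelSpec(), geno.samples)
        mk = estimate_weights(y, X, Kc, Kri)
        assert mk.w_c + mk.w_ri == pytest.approx(1.0)
        assert 0.0 <= mk.w_ri <= 1.0
        assert mk.sigma_c2 >= 0 and mk.sigma_ri2 >= 0

    def test_pure_polygenic_data_puts_weight_on_background(self, small_panel, small_panel_kc):
        """Simulating with sigma_ri2 = 0, the median estimated set weight stays near 0."""
        geno, sets = small_panel
        Kc, structure = small_panel_kc
        n = geno.n_samples
        X = np.column_stack([np.ones(n), structure])
        s, U = np.linalg.eigh(Kc.values)
        Kri = gram_matrix(geno.codes[:, sets[0].marker_indices], KernelSpec(), geno.samples)
        rng = np.random.default_rng(3)
        w_hats = []
        for _ in range(20):
            u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.standard_normal(n))
            y = u / u.std() * np.sqrt(0.5) + rng.standard_normal(n) * np.sqrt(0.5)
            w_hats.append(estimate_weights(y, X, Kc, Kri).w_ri)
        assert np.median(w_hats) <= 0.15

    def test_planted_set_effect_recovers_large_weight(self, small_panel, small_panel_kc):
        geno, sets = small_panel
        Kc, structure = small_panel_kc
        n = geno.n_samples
        X = np.column_stack([np.ones(n), structure])
        big = max(sets, key=lambda s: s.size)
        Kri = gram_matrix(geno.codes[:, big.marker_indices], KernelSpec(), geno.samples)
        sr, Ur = np.linalg.eigh(Kri.values)
        rng = np.random.default_rng(4)
        w_hats = []
        for _ in range(20):
            u = Ur @ (np.sqrt(np.clip(sr, 0, None)) * rng.standard_normal(n))
            y = u / u.std() * np.sqrt(0.6) + rng.standard_normal(n) * np.sqrt(0.4)
            w_hats.append(estimate_weights(y, X, Kc, Kri).w_ri)
        assert np.median(w_hats) >= 0.5


class TestNullFitAndNesting:
    def test_fit_null_is_single_kernel_fit(self, small_panel, small_panel_kc):
        geno, _ = small_panel
        Kc, structure = small_panel_kc
        rng = np.random.default_rng(5)
        y = rng.standard_normal(geno.n_samples)
        X = np.column_stack([np.ones(geno.n_samples), structure])
        assert fit_null(y, X, Kc).lR == fit_single_kernel(y, X, Kc, "REML").lR

    def test_repeat_calls_bit_identical(self, small_panel, small_panel_kc):
        geno, _ = small_panel
        Kc, structure = small_panel_kc
        rng = np.random.default_rng(6)
        y = rng.standard_normal(geno.n_samples)
        X = np.column_stack([np.ones(geno.n_samples), structure])
        f1, f2 = fit_null(y, X, Kc), fit_null(y, X, Kc)
        assert f1.lR == f2.lR and f1.delta == f2.delta
        assert np.array_equal(f1.beta_hat, f2.beta_hat)

    def test_alternative_dominates_null(self, small_panel, small_panel_kc):
        """Nested models: the two-kernel restricted likelihood is never below
        the polygenic-only null (the null is the w_ri = 0 boundary)."""
        geno, sets = small_panel
        Kc, structure = small_panel_kc
        n = geno.n_samples
        X = np.column_stack([np.ones(n), structure])
        rng = np.random.default_rng(7)
        for k in range(5):
            y = rng.standard_normal(n)
            Kri = gram_matrix(geno.codes[:, sets[k].marker_indices], KernelSpec(), geno.samples)
            mk = estimate_weights(y, X, Kc, Kri)
            null = fit_null(y, X, Kc)
            assert mk.lR_model >= null.lR - 1e-6


class TestSnpsetGwas:
    def test_result_count_and_p_range(self, small_panel, small_panel_kc):
        geno, sets = small_panel
        Kc, structure = small_panel_kc
        rng = np.random.default_rng(8)
        y = rng.standard_normal(geno.n_samples)
        res = snpset_gwas(geno, y, sets[:8], structure=structure, Kc=Kc)
        assert len(res) == 8
        assert all(0.0 < r.p_value <= 1.0 for r in res)
        assert all(r.deviance >= 0.0 for r in res)

    def test_results_sorted_by_position(self, small_panel, small_panel_kc):
        geno, sets = small_panel
        Kc, structure = small_panel_kc
        rng = np.random.default_rng(9)
        y = rng.standard_normal(geno.n_samples)
        res = snpset_gwas(geno, y, list(reversed(sets[:6])), structure=structure, Kc=Kc)
        starts = [r.span_start for r in res]
        assert starts == sorted(starts)

    def test_sample_mismatch_rejected(self, small_panel):
        geno, sets = small_panel
        with pytest.raises(ValueError, match="length"):
            snpset_gwas(geno, np.zeros(10), sets[:2])

    def test_neg_log10_consistency(self, small_panel, small_panel_kc):
        geno, sets = small_panel
        Kc, structure = small_panel_kc
        rng = np.random.default_rng(10)
        y = rng.standard_normal(geno.n_samples)
        for r in snpset_gwas(geno, y, sets[:4], structure=structure, Kc=Kc):
            assert r.neg_log10_p == pytest.approx(-np.log10(r.p_value), abs=1e-12)


class TestSingleSnpGwas:
    def test_p3d_close_to_exact_per_marker_reml(self):
        """Sharing null variance components across markers changes -log10 p
        by less than 0.2 against exact per-marker REML at n = 200."""
        from blocklmm.kernels import structure_eigenvectors
        from blocklmm.simulate import GenotypeSimSpec, simulate_genotypes

        geno, sets = simulate_genotypes(GenotypeSimSpec(n_samples=200, seed=2024))
        Kc = additive_grm(geno.codes, ids=geno.samples)
        structure = structure_eigenvectors(Kc, 2)
        sim = simulate_phenotype(geno, sets, scenario="coupling", seed=11)
        rng = np.random.default_rng(12)
        pick = rng.choice(geno.n_markers, size=20, replace=False)
        sub = geno.subset_markers(np.sort(pick))
        approx = single_snp_gwas(sub, sim.y, structure=structure, Kc=Kc)
        exact = single_snp_gwas(sub, sim.y, structure=structure, Kc=Kc, exact=True)
        for a, e in zip(approx, exact):
            assert abs(a.neg_log10_p - e.neg_log10_p) < 0.2

    def test_monomorphic_marker_p_one(self, small_panel, small_panel_kc):
        geno, _ = small_panel
        Kc, structure = small_panel_kc
        sub = geno.subset_markers(np.arange(5))
        sub.codes = sub.codes.copy()
        sub.codes[:, 0] = -1
        rng = np.random.default_rng(13)
        y = rng.standard_normal(geno.n_samples)
        res = single_snp_gwas(sub, y, structure=structure, Kc=Kc)
        by_id = {r.unit_id: r for r in res}
        assert by_id[sub.markers[0]].p_value == 1.0

    def test_planted_qtn_recovered_at_bh_fdr(self):
        """A single large-effect QTN passes genome-wide BH-FDR 0.01 in most
        seeded simulations."""
        from blocklmm.kernels import structure_eigenvectors
        from blocklmm.simulate import GenotypeSimSpec, simulate_genotypes

        n = 250
        geno, _ = simulate_genotypes(GenotypeSimSpec(n_samples=n, seed=2024))
        Kc = additive_grm(geno.codes, ids=geno.samples)
        structure = structure_eigenvectors(Kc, 2)
        s, U = np.linalg.eigh(Kc.values)
        rng = np.random.default_rng(14)
        hits = 0
        for rep in range(20):
            j = int(rng.integers(geno.n_markers))
            g = geno.codes[:, j].astype(float)
            u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.standard_normal(n))
            y = (
                g / g.std() * np.sqrt(0.35)
                + u / u.std() * np.sqrt(0.3)
                + rng.standard_normal(n) * np.sqrt(0.35)
            )
            res = single_snp_gwas(geno, y, structure=structure, Kc=Kc)
            cutoff = significance_threshold([r.p_value for r in res], "BH", 0.01)
            by_id = {r.unit_id: r for r in res}
            hits += by_id[geno.markers[j]].neg_log10_p >= cutoff
        assert hits >= 16
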