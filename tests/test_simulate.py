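import numpy as np
import pytest

from famcond import ldsc
from famcond import path_models as pm
from famcond import simulate as sim
from famcond.sumstats_io import InputError


class TestFamilies:
    def test_mendelian_relatedness(self):
        cfg = sim.SimConfig(n_families=50_000, n_variants=4, seed=11)
        d = sim.simulate_families(cfg)
        g = d.genotypes
        for j in range(4):
            r_par = np.corrcoef(g["mother"][:, j], g["self"][:, j])[0, 1]
            assert r_par == pytest.approx(0.5, abs=0.01)
            r_grand = np.corrcoef(g["mother"][:, j], g["child"][:, j])[0, 1]
            assert r_grand == pytest.approx(0.25, abs=0.015)
        # dosages stay in {0, 1, 2}
        for arr in g.values():
            assert set(np.unique(arr)) <= {0, 1, 2}

    def test_unconditional_slopes_follow_transmission_algebra(self):
        """(o, m) = (0.1, 0): Y1 on G_self slopes 0.1, on G_mother 0.05."""
        n_var = 3
        cfg = sim.SimConfig(
            n_families=100_000,
            n_variants=n_var,
            seed=12,
            true_effects=np.tile([0.1, 0.0], (n_var, 1)),
            residual_sd=(1.0, 1.0),
            residual_corr=0.0,
        )
        d = sim.simulate_families(cfg)
        y1 = d.phenotypes["own"]
        for j in range(n_var):
            gs = d.genotypes["self"][:, j].astype(float)
            gm = d.genotypes["mother"][:, j].astype(float)
            slope_self = np.cov(gs, y1)[0, 1] / np.var(gs)
            slope_mother = np.cov(gm, y1)[0, 1] / np.var(gm)
            assert slope_self == pytest.approx(0.1, abs=0.02)
            assert slope_mother == pytest.approx(0.05, abs=0.02)

    def test_unit_variance_and_target_correlation_defaults(self):
        n_var = 50
        cfg = sim.SimConfig(
            n_families=100_000,
            n_variants=n_var,
            seed=13,
            true_effects=np.tile([0.06, -0.04], (n_var, 1)),
        )
        d = sim.simulate_families(cfg)
        assert d.pheno_corr == pytest.approx(0.24, abs=1e-12)
        for key in ("own", "offspring"):
            assert np.var(d.phenotypes[key]) == pytest.approx(1.0, abs=0.02)
        emp = np.corrcoef(d.phenotypes["own"], d.phenotypes["offspring"])[0, 1]
        assert emp == pytest.approx(0.24, abs=0.02)

    def test_reproducible_under_fixed_seed(self):
        cfg = dict(n_families=500, n_variants=10, seed=99)
        a = sim.simulate_families(sim.SimConfig(**cfg))
        b = sim.simulate_families(sim.SimConfig(**cfg))
        for key in a.genotypes:
            np.testing.assert_array_equal(a.genotypes[key], b.genotypes[key])
        for key in a.phenotypes:
            np.testing.assert_array_equal(a.phenotypes[key], b.phenotypes[key])

    def test_invalid_configs_rejected(self):
        with pytest.raises(InputError):
            sim.SimConfig(n_families=0, n_variants=10)
        with pytest.raises(InputError):
            sim.SimConfig(n_families=10, n_variants=2, allele_freqs=np.array([0.0, 0.5]))
        with pytest.raises(InputError):
            sim.SimConfig(n_families=10, n_variants=2, overlap_fraction=1.5)


class TestRunGwas:
    def test_null_type_one_error(self):
        cfg = sim.SimConfig(n_families=4_000, n_variants=2_000, seed=14)
        d = sim.simulate_families(cfg)
        table = sim.run_gwas(d, "self", "own")
        from scipy import stats

        p = 2 * stats.norm.sf(np.abs(table.zscores))
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 2_000)

    def test_duplicated_mask_is_deterministic(self):
        cfg = sim.SimConfig(n_families=2_000, n_variants=20, seed=15)
        d = sim.simulate_families(cfg)
        mask = np.zeros(2_000, dtype=bool)
        mask[:1_000] = True
        t1 = sim.run_gwas(d, "self", "own", mask)
        t2 = sim.run_gwas(d, "self", "own", mask.copy())
        np.testing.assert_array_equal(t1.records["beta"], t2.records["beta"])
        np.testing.assert_array_equal(t1.records["se"], t2.records["se"])

    def test_unadjusted_expectation_is_mixed_effect(self):
        """E[beta_own] ~ o + m/2 across many variants."""
        n_var = 400
        o, m = 0.08, -0.05
        cfg = sim.SimConfig(
            n_families=20_000,
            n_variants=n_var,
            seed=16,
            true_effects=np.tile([o, m], (n_var, 1)),
            residual_corr=0.2,  # high polygenic load: target corr infeasible
        )
        d = sim.simulate_families(cfg)
        table = sim.run_gwas(d, "self", "own")
        est = table.records["beta"]
        mcse = est.std() / np.sqrt(n_var)
        assert abs(est.mean() - (o + 0.5 * m)) < 3 * mcse

    def test_monomorphic_variant_flagged(self):
        cfg = sim.SimConfig(
            n_families=100, n_variants=2, seed=17,
            allele_freqs=np.array([0.5, 0.001]),
        )
        d = sim.simulate_families(cfg)
        d.genotypes["self"][:, 1] = 0  # force monomorphic
        table = sim.run_gwas(d, "self", "own")
        assert bool(table.records.at[1, "monomorphic"])
        assert np.isnan(table.records.at[1, "beta"])
        assert not table.records.at[0, "monomorphic"]

    def test_empty_mask_rejected(self):
        cfg = sim.SimConfig(n_families=100, n_variants=2, seed=18)
        d = sim.simulate_families(cfg)
        with pytest.raises(InputError):
            sim.run_gwas(d, "self", "own", np.zeros(100, dtype=bool))


class TestOverlapDesign:
    @pytest.mark.parametrize(
        "frac,n,expected",
        [(0.0, 1000, 0), (0.3, 1000, 300), (1.0, 1000, 1000)],
    )
    def test_intersection_size(self, frac, n, expected):
        a, b = sim.make_overlap_design(n, frac, seed=1)
        assert (a & b).sum() == expected
        assert (a | b).sum() <= n
        if frac == 0.0:
            assert not (a & b).any()
        if frac == 1.0:
            np.testing.assert_array_equal(a, b)


class TestLdscZscores:
    def test_null_products_average_zero(self):
        panel = sim.make_ld_panel(5_000, seed=19)
        z1, z2 = sim.simulate_ldsc_zscores(panel, 0.0, 0.0, 0.0, 10_000, 10_000, seed=19)
        assert abs(np.mean(z1 * z2)) < 3 / np.sqrt(5_000)
        assert np.var(z1) == pytest.approx(1.0, abs=0.05)

    def test_closed_loop_with_intercept_estimator(self):
        """cross_trait_intercept recovers the generating overlap intercept."""
        panel = sim.make_ld_panel(20_000, seed=20, m=200_000)
        n1, n2, ns, rp = 90_000, 70_000, 30_000, 0.24
        z1, z2 = sim.simulate_ldsc_zscores(panel, 0.3, 0.25, 0.5, n1, n2, ns, rp, seed=20)
        est = ldsc.cross_trait_intercept(z1, z2, panel, n1, n2)
        expected = ldsc.intercept_from_overlap(ns, n1, n2, rp)
        assert est.intercept == pytest.approx(expected, abs=2.576 * est.intercept_se)

    def test_invalid_parameters_rejected(self):
        panel = sim.make_ld_panel(500, seed=21)
        with pytest.raises(InputError):
            sim.simulate_ldsc_zscores(panel, 1.5, 0.3, 0.0, 1000, 1000)
        with pytest.raises(InputError):
            sim.simulate_ldsc_zscores(panel, 0.3, 0.3, 2.0, 1000, 1000)
        with pytest.raises(InputError):
            sim.simulate_ldsc_zscores(panel, 0.3, 0.3, 0.0, 1000, 1000, n_overlap=5000)


class TestFullPipelineRecovery:
    def test_all_estimators_recover_truth(self, birthweight_sim_pair):
        """simulate -> two GWAS -> three estimators: |bias| < 2 MCSE each."""
        from famcond import gsem_conditional as gc
        from famcond import linear_approx as la
        from famcond import sem_sumstats as ss

        data, hset, _, _ = birthweight_sim_pair
        truth = {"offspring": 0.06, "maternal": -0.04}
        results = {
            "linear": la.adjust_table(hset),
            "gsem": gc.conditional_gwas(
                hset, pm.birthweight_model(), intercept_matrix=np.eye(2)
            ),
            "sem": ss.sem_adjust_table(hset, r_pheno=data.pheno_corr),
        }
        for name, df in results.items():
            for label, t in truth.items():
                est = df[f"beta_{label}"]
                mcse = est.std() / np.sqrt(len(est))
                assert abs(est.mean() - t) < 2 * mcse, (name, label)
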