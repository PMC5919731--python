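"""Mixed-model association: check adjustment, REML, boundary LRT law."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import gamma

import namgei as ng
from namgei.errors import MissingCheckError
from namgei.genomat import compute_kinship, recode_parental_origin
from namgei.mmassoc import (
    bonferroni_threshold,
    env_phenotype,
    fit_null,
    lrt_neglog10p,
    lrt_pvalue,
)
from namgei.mmassoc import test_marker as run_marker_test
from conftest import make_pheno


class TestAdjustByChecks:
    def test_equal_checks_leave_yields_unchanged(self):
        pheno = make_pheno(
            [
                ("R1", "E1", 1, 3000.0, False),
                ("R2", "E1", 2, 3100.0, False),
                ("C1", "E1", 1, 2500.0, True),
                ("C1", "E1", 2, 2500.0, True),
            ]
        )
        adj = ng.adjust_by_checks(pheno)
        assert adj["yield"].tolist() == [3000.0, 3100.0]
        assert not adj["is_check"].any()

    def test_constructed_block_offset_removed(self):
        pheno = make_pheno(
            [
                ("R1", "E1", 1, 3100.0, False),
                ("R2", "E1", 2, 3000.0, False),
                ("C1", "E1", 1, 2600.0, True),  # block 1 runs +100
                ("C1", "E1", 2, 2500.0, True),
            ]
        )
        adj = ng.adjust_by_checks(pheno).set_index("ril_id")["yield"]
        assert adj["R1"] == pytest.approx(3050.0)  # 3100 - (2600 - 2550)
        assert adj["R2"] == pytest.approx(3050.0)

    def test_adjustment_reduces_variance(self, small_geno):
        trial = ng.TrialDesign(
            environments=["E1", "E2"],
            env_effects=[3000.0, 3000.0],
            block_sd=400.0,
            residual_sd=50.0,
        )
        sim = ng.simulate_phenotypes(small_geno, trial, seed=21)
        raw = sim.pheno[~sim.pheno["is_check"]]
        adj = ng.adjust_by_checks(sim.pheno)
        for env in ("E1", "E2"):
            assert (
                adj[adj["env"] == env]["yield"].var()
                < raw[raw["env"] == env]["yield"].var()
            )

    def test_block_without_checks_is_named(self):
        pheno = make_pheno(
            [
                ("R1", "E1", 1, 3000.0, False),
                ("R2", "E1", 2, 3000.0, False),
                ("C1", "E1", 1, 2500.0, True),
            ]
        )
        with pytest.raises(MissingCheckError, match="E1"):
            ng.adjust_by_checks(pheno)


class TestBoundaryPvalueLaw:
    def test_half_df_chi2_matches_gamma_quadrature(self):
        """The 0.5-df chi-square is gamma(shape 1/4, scale 2); check by quadrature."""
        dens = gamma(a=0.25, scale=2.0).pdf
        for x in [0.01, 0.1, 0.5, 1.0, 2.42, 5.0, 10.0]:
            tail, _ = integrate.quad(dens, x, np.inf, limit=200)
            assert lrt_pvalue(x, "chi2_0.5df") == pytest.approx(tail, abs=1e-8)

    def test_boundary_values(self):
        assert lrt_pvalue(0.0, "chi2_0.5df") == 1.0
        assert lrt_pvalue(0.0, "mixture_0_1") == 1.0
        assert lrt_neglog10p(0.0, "chi2_0.5df") == 0.0
        # the mixture halves the one-df tail
        assert lrt_pvalue(3.0, "mixture_0_1") == pytest.approx(
            0.5 * (1 - 0.9167354820)  # chi2(1) cdf at 3.0
            , abs=1e-6,
        )

    def test_laws_cross_near_one(self):
        # the half-df law is larger near zero but lighter in the tail than
        # the 50:50 {chi2_0, chi2_1} mixture
        assert lrt_pvalue(0.5, "chi2_0.5df") > lrt_pvalue(0.5, "mixture_0_1")
        for x in [2.0, 4.0, 8.0]:
            assert lrt_pvalue(x, "chi2_0.5df") < lrt_pvalue(x, "mixture_0_1")


class TestBonferroni:
    def test_genomewide_threshold_values(self):
        assert bonferroni_threshold(0.05, 4312) == pytest.approx(4.9357, abs=1e-4)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.30103, abs=1e-5)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestFitNull:
    def test_no_polygenic_signal_gives_small_ratio(self, mid_geno):
        """iid phenotypes on a real kinship: the polygenic share stays near 0."""
        K = compute_kinship(mid_geno)
        ratios = []
        for s in range(10):
            y = np.random.default_rng(500 + s).standard_normal(K.n)
            ratios.append(fit_null(y, None, K).ratio_psi)
        assert np.median(ratios) < 0.05

    def test_variance_ratio_recovery(self, mid_geno):
        """y = psi + e with ratio 4 is recovered within [2, 8] in >=90% of seeds."""
        K = compute_kinship(mid_geno)
        L = np.linalg.cholesky(K.matrix + 1e-8 * np.eye(K.n))
        hits = 0
        for s in range(20):
            r = np.random.default_rng(200 + s)
            y = L @ r.standard_normal(K.n) * 2.0 + r.standard_normal(K.n)
            est = fit_null(y, None, K).ratio_psi
            hits += 2.0 <= est <= 8.0
        assert hits >= 18

    def test_duplicated_records_collapse_before_fitting(self, small_geno, trial5):
        """Plot duplication leaves per-RIL means, hence the fit, unchanged."""
        sim = ng.simulate_phenotypes(small_geno, trial5, seed=31)
        adj = ng.adjust_by_checks(sim.pheno)
        doubled = pd.concat([adj, adj], ignore_index=True)
        y1 = env_phenotype(adj, "E1")
        y2 = env_phenotype(doubled, "E1")
        pd.testing.assert_series_equal(y1, y2)
        K = compute_kinship(small_geno)
        f1 = fit_null(y1.reindex(small_geno.ril_ids).to_numpy(), None, K)
        f2 = fit_null(y2.reindex(small_geno.ril_ids).to_numpy(), None, K)
        assert f1.ratio_psi == pytest.approx(f2.ratio_psi, rel=1e-10)

    def test_non_psd_kinship_rejected(self):
        K = -np.eye(5)
        with pytest.raises(np.linalg.LinAlgError):
            fit_null(np.zeros(5), None, K)


class TestTestMarker:
    def test_monomorphic_marker_is_null(self, small_geno):
        K = compute_kinship(small_geno)
        y = np.random.default_rng(0).standard_normal(small_geno.n_rils)
        null = fit_null(y, None, K)
        t = run_marker_test(np.zeros((small_geno.n_rils, 0)), null, y, None, K)
        assert t.lrt == 0.0 and t.pvalue == 1.0
        assert t.family_effects.empty

    def test_fast_and_full_modes_agree(self, small_geno, trial5):
        rng = np.random.default_rng(3)
        qtl = ng.QtlSpec(marker_index=5, family_effects=rng.normal(0, 250, 4))
        sim = ng.simulate_phenotypes(small_geno, trial5, [qtl], seed=41, polygenic_sd=150.0)
        adj = ng.adjust_by_checks(sim.pheno)
        y = env_phenotype(adj, "E1").reindex(small_geno.ril_ids).to_numpy()
        K = compute_kinship(small_geno)
        inc = recode_parental_origin(small_geno)
        null = fit_null(y, None, K)
        for k in (0, 5, 11):
            Z = inc.incidence(k, segregating_only=True)
            fams = inc.segregating_families(k)
            tf = run_marker_test(Z, null, y, None, K, mode="fast", families=fams)
            tl = run_marker_test(Z, null, y, None, K, mode="full", families=fams)
            # the fast mode fixes the polygenic ratio at the null optimum,
            # so magnitudes agree only approximately
            assert tf.lrt == pytest.approx(tl.lrt, rel=0.25, abs=0.6)

    def test_recovers_injected_effects(self, small_geno, noiseless_trial5):
        """With no noise, the BLUP effects shrink toward the injected values."""
        effects = np.array([300.0, -200.0, 150.0, 0.0])
        qtl = ng.QtlSpec(marker_index=7, family_effects=effects)
        sim = ng.simulate_phenotypes(
            small_geno, noiseless_trial5, [qtl], sens=ng.SensitivitySpec(slope_sd=0.0), seed=43
        )
        adj = ng.adjust_by_checks(sim.pheno)
        y = env_phenotype(adj, "E1").reindex(small_geno.ril_ids).to_numpy()
        K = compute_kinship(small_geno)
        inc = recode_parental_origin(small_geno)
        null = fit_null(y, None, K)
        Z = inc.incidence(7, segregating_only=True)
        fams = inc.segregating_families(7)
        t = run_marker_test(Z, null, y, None, K, mode="fast", families=fams)
        truth = pd.Series(effects, index=list(small_geno.families)).reindex(t.family_effects.index)
        assert t.lrt > 50
        np.testing.assert_allclose(t.family_effects, truth, atol=60.0)


class TestGenomeScan:
    def test_lrt_invariant_to_phenotype_affine_transform(self, small_geno):
        rng = np.random.default_rng(7)
        y = pd.Series(rng.standard_normal(small_geno.n_rils) * 300 + 3000, index=small_geno.ril_ids)
        s1 = ng.genome_scan(small_geno, y)
        s2 = ng.genome_scan(small_geno, 2.0 * y)
        s3 = ng.genome_scan(small_geno, y + 1000.0)
        for a, b, c in zip(s1.tests, s2.tests, s3.tests):
            assert a.lrt == pytest.approx(b.lrt, abs=1e-5)
            assert a.lrt == pytest.approx(c.lrt, abs=1e-5)

    def test_threshold_uses_marker_count(self, small_geno):
        y = pd.Series(
            np.random.default_rng(8).standard_normal(small_geno.n_rils), index=small_geno.ril_ids
        )
        scan = ng.genome_scan(small_geno, y, alpha_level=0.05)
        assert scan.threshold == pytest.approx(-np.log10(0.05 / small_geno.n_markers))

    def test_single_family_population_scan(self):
        """With one family the scan degenerates to a plain single-population GWAS."""
        rng = np.random.default_rng(9)
        codes = rng.choice([0, 2], size=(60, 25)).astype(np.int8)
        marker_ids = [f"M{k}" for k in range(25)]
        geno = ng.GenotypeMatrix(
            codes=codes,
            ril_ids=np.array([f"R{i}" for i in range(60)], dtype=object),
            family_ids=np.array(["F1"] * 60, dtype=object),
            marker_ids=np.array(marker_ids, dtype=object),
            marker_map=pd.DataFrame({"marker_id": marker_ids, "chrom": 1, "pos": range(25)}),
        )
        y = pd.Series(
            (2.0 - codes[:, 3]) * 1.5 + rng.standard_normal(60), index=geno.ril_ids
        )
        scan = ng.genome_scan(geno, y)
        assert all(len(t.family_effects) <= 1 for t in scan.tests)
        assert scan.top_marker() == "M3"
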