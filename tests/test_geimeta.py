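"""GEI meta-analysis: WLS null, rank-1 SVD term, likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest

import namgei as ng
from namgei.errors import DegenerateInputError, InsufficientSegregationError
from namgei.geimeta import (
    EffectPanel,
    build_env_contexts,
    fit_meta_null,
    gei_lrt,
    gei_test_marker,
    n_informative_envs,
    rank1_interaction,
)


def panel_from(A, N=None, parents=None, marker="M1"):
    A = pd.DataFrame(np.atleast_2d(np.asarray(A, dtype=float)))
    A.index = [f"F{i}" for i in range(A.shape[0])]
    A.columns = [f"E{j}" for j in range(A.shape[1])]
    if N is None:
        N = pd.DataFrame(1.0, index=A.index, columns=A.columns)
    else:
        N = pd.DataFrame(np.atleast_2d(np.asarray(N, dtype=float)), index=A.index, columns=A.columns)
    pf = dict(zip(A.index, parents)) if parents else {}
    return EffectPanel(marker_id=marker, A=A, N=N, parent_of_family=pf)


def als_rank1_oracle(E, n_iter=2000, seed=0):
    """Independent alternating-least-squares best rank-1 fit (power iteration)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(E.shape[1])
    for _ in range(n_iter):
        u = E @ v / (v @ v)
        v = E.T @ u / (u @ u)
    d = np.linalg.norm(u) * np.linalg.norm(v)
    return np.outer(u, v), d


class TestFitMetaNull:
    def test_equal_weight_mean(self):
        fit = fit_meta_null(panel_from([[10.0, 20.0]]))
        assert fit.delta.iloc[0] == pytest.approx(15.0)
        np.testing.assert_allclose(fit.residual_matrix.to_numpy(), [[-5.0, 5.0]])

    def test_weighted_mean(self):
        fit = fit_meta_null(panel_from([[10.0, 20.0]], N=[[1.0, 3.0]]))
        assert fit.delta.iloc[0] == pytest.approx(17.5)

    def test_matches_dense_normal_equations(self, rng):
        """delta from the per-parent weighted means equals the WLS solve."""
        nf, ne = 7, 5
        A = rng.normal(size=(nf, ne)) * 50
        N = rng.integers(0, 30, size=(nf, ne)).astype(float)
        parents = ["P1", "P2", "P1", "P3", "P2", "P3", "P1"]
        panel = panel_from(A, N=N, parents=parents)
        fit = fit_meta_null(panel)
        # dense oracle: stack observed cells, solve (W' diag(N) W) d = W' diag(N) a
        rows = []
        for i, f in enumerate(panel.families):
            for j in range(ne):
                if N[i, j] > 0:
                    rows.append((parents[i], A[i, j], N[i, j]))
        plist = panel.parents
        W = np.array([[1.0 if p == q else 0.0 for q in plist] for p, _, _ in rows])
        a = np.array([r[1] for r in rows])
        w = np.array([r[2] for r in rows])
        delta = np.linalg.solve(W.T @ (w[:, None] * W), W.T @ (w * a))
        np.testing.assert_allclose(fit.delta.reindex(plist).to_numpy(), delta, atol=1e-10)
        # normal equations: weighted residuals orthogonal to W columns
        resid = a - W @ delta
        np.testing.assert_allclose(W.T @ (w * resid), 0.0, atol=1e-8)

    def test_all_zero_weights_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_meta_null(panel_from([[1.0, 2.0]], N=[[0.0, 0.0]]))

    def test_unobserved_cells_are_excluded(self):
        fit = fit_meta_null(panel_from([[10.0, 99.0, 20.0]], N=[[1.0, 0.0, 1.0]]))
        assert fit.delta.iloc[0] == pytest.approx(15.0)
        assert fit.residual_matrix.iloc[0, 1] == 0.0
        assert fit.n_cells == 2


class TestRank1Interaction:
    def test_exact_rank_one_matrix(self):
        panel = panel_from([[1.0, 2.0], [2.0, 4.0]])
        fit = fit_meta_null(panel)
        fit.residual_matrix = pd.DataFrame(
            [[1.0, 2.0], [2.0, 4.0]], index=panel.A.index, columns=panel.A.columns
        )
        alt = rank1_interaction(fit)
        assert alt.d1 == pytest.approx(5.0)
        assert alt.pc_load == pytest.approx(1.0)
        np.testing.assert_allclose(alt.gamma.to_numpy(), [[1.0, 2.0], [2.0, 4.0]], atol=1e-12)

    def test_identity_degenerate(self):
        panel = panel_from(np.eye(2))
        fit = fit_meta_null(panel)
        fit.residual_matrix = pd.DataFrame(np.eye(2), index=panel.A.index, columns=panel.A.columns)
        alt = rank1_interaction(fit)
        assert alt.d1 == pytest.approx(1.0)
        assert alt.pc_load == pytest.approx(0.5)
        # sign convention: leading loading entry positive
        nz = np.flatnonzero(np.abs(alt.u) > 1e-12)
        assert alt.u[nz[0]] > 0

    def test_matches_als_oracle(self, rng):
        for rep in range(20):
            E = rng.normal(size=(6, 5))
            panel = panel_from(E)
            fit = fit_meta_null(panel)
            fit.residual_matrix = pd.DataFrame(E, index=panel.A.index, columns=panel.A.columns)
            alt = rank1_interaction(fit)
            gamma_oracle, d_oracle = als_rank1_oracle(E, seed=rep)
            np.testing.assert_allclose(alt.gamma.to_numpy(), gamma_oracle, atol=1e-8)
            assert alt.d1 == pytest.approx(d_oracle, abs=1e-8)

    def test_eckart_young_residual_identity(self, rng):
        """RSS after removing gamma equals the sum of trailing squared singulars."""
        E = rng.normal(size=(8, 6))
        panel = panel_from(E)
        fit = fit_meta_null(panel)
        fit.residual_matrix = pd.DataFrame(E, index=panel.A.index, columns=panel.A.columns)
        alt = rank1_interaction(fit)
        s = np.linalg.svd(E, compute_uv=False)
        rss = float((alt.new_residuals.to_numpy() ** 2).sum())
        assert rss == pytest.approx(float((s[1:] ** 2).sum()), rel=1e-10)

    def test_too_small_matrix_rejected(self):
        panel = panel_from([[1.0, 2.0]])
        fit = fit_meta_null(panel)
        with pytest.raises(ValueError):
            rank1_interaction(fit)

    def test_masked_als_matches_svd_on_complete_data(self, rng):
        E = rng.normal(size=(5, 4))
        panel = panel_from(E)
        fit = fit_meta_null(panel)
        fit.residual_matrix = pd.DataFrame(E, index=panel.A.index, columns=panel.A.columns)
        a = rank1_interaction(fit)
        b = rank1_interaction(fit, masked=True)
        np.testing.assert_allclose(a.gamma.to_numpy(), b.gamma.to_numpy(), atol=1e-6)


class TestGeiLrt:
    def test_perfectly_additive_panel(self):
        A = np.outer([10.0, -5.0, 3.0], np.ones(4))
        panel = panel_from(A)
        t = gei_test_marker(panel)
        assert t.lrt == 0.0 and t.pvalue == 1.0
        assert not t.significant

    def test_constructed_multiplicative_signal_saturates(self, rng):
        """delta + u d v' with no noise: pc_load 1 and an underflowing p-value."""
        u = np.array([1.0, -0.5, 0.25, 0.75])
        v = np.array([0.5, -1.0, 0.25, 1.0, -0.75])
        delta = np.array([5.0, 10.0, -5.0, 0.0])
        A = delta[:, None] + 40.0 * np.outer(u, v)
        t = gei_test_marker(panel_from(A))
        assert t.pc_load == pytest.approx(1.0)
        assert t.neglog10p > 50.0
        assert t.significant

    def test_df_counts_parents_and_environments(self):
        A = np.arange(12.0).reshape(3, 4) ** 1.5
        t = gei_test_marker(panel_from(A))
        assert t.df == (3 - 1) + (4 - 1) + 1
        assert t.n_parents == 3 and t.n_env == 4

    def test_null_calibration_documented_anticonservative(self, rng):
        """Naive-df p-values over-reject on null panels; the empirical
        -log10 p >= 50 flag is the operative genome-wide guard."""
        rejections, flags = 0, 0
        reps = 300
        for _ in range(reps):
            A = rng.normal(size=(8, 6))
            t = gei_test_marker(panel_from(A))
            rejections += t.pvalue < 0.05
            flags += t.neglog10p >= 50.0
        assert rejections / reps > 0.5  # far above the nominal 5%
        assert flags == 0

    def test_decomposition_identity_on_simulated_panels(self, small_geno, trial5):
        """A - W delta = gamma + eps cell-wise on observed cells."""
        sim = ng.simulate_phenotypes(small_geno, trial5, seed=51, polygenic_sd=100.0)
        adj = ng.adjust_by_checks(sim.pheno)
        ctx = build_env_contexts(small_geno, adj)
        checked = 0
        for m in small_geno.marker_ids[:10]:
            try:
                panel = ng.collect_effects(small_geno, adj, str(m), contexts=ctx)
            except InsufficientSegregationError:
                continue
            null = fit_meta_null(panel)
            alt = rank1_interaction(null)
            mask = panel.mask()
            lhs = panel.A.to_numpy() - null.delta.reindex(
                [panel.parent_of_family[f] for f in panel.families]
            ).to_numpy()[:, None]
            rhs = alt.gamma.to_numpy() + alt.new_residuals.to_numpy()
            np.testing.assert_allclose(lhs[mask], rhs[mask], atol=1e-10)
            checked += 1
        assert checked >= 5


class TestCollectEffects:
    def test_bookkeeping_of_absent_families(self, small_geno, trial5):
        pres = pd.DataFrame(
            1.0, index=list(small_geno.families), columns=list(trial5.environments)
        )
        pres.loc["F03", "E2"] = 0.0
        trial = ng.TrialDesign(
            environments=trial5.environments,
            env_effects=trial5.env_effects,
            presence=pres,
            residual_sd=200.0,
        )
        sim = ng.simulate_phenotypes(small_geno, trial, seed=61)
        adj = ng.adjust_by_checks(sim.pheno)
        panel = ng.collect_effects(small_geno, adj, "M00003")
        assert panel.N.loc["F03", "E2"] == 0.0
        assert panel.A.loc["F03", "E2"] == 0.0

    def test_constant_effects_across_environments_without_noise(self, small_geno):
        trial = ng.TrialDesign(
            environments=["E1", "E2", "E3"],
            env_effects=[3000.0, 3500.0, 4000.0],
            residual_sd=0.0,
            block_sd=0.0,
        )
        effects = np.array([250.0, -150.0, 100.0, 50.0])
        qtl = ng.QtlSpec(marker_index=3, family_effects=effects)
        sim = ng.simulate_phenotypes(
            small_geno, trial, [qtl], sens=ng.SensitivitySpec(slope_sd=0.0), seed=62
        )
        adj = ng.adjust_by_checks(sim.pheno)
        panel = ng.collect_effects(small_geno, adj, "M00004")
        A, mask = panel.A.to_numpy(), panel.mask()
        for i in range(A.shape[0]):
            vals = A[i, mask[i]]
            if len(vals):
                np.testing.assert_allclose(vals, vals[0], atol=1e-6)

    def test_duplicated_records_double_weights_only(self, small_geno, trial5):
        sim = ng.simulate_phenotypes(small_geno, trial5, seed=63)
        adj = ng.adjust_by_checks(sim.pheno)
        doubled = pd.concat([adj, adj], ignore_index=True)
        p1 = ng.collect_effects(small_geno, adj, "M00005")
        p2 = ng.collect_effects(small_geno, doubled, "M00005")
        np.testing.assert_allclose(p1.A.to_numpy(), p2.A.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(2 * p1.N.to_numpy(), p2.N.to_numpy())
        d1 = fit_meta_null(p1).delta
        d2 = fit_meta_null(p2).delta
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-8)

    def test_insufficient_segregation_raises(self, trial5):
        # marker 0 segregates in one family only
        codes = np.full((20, 3), 2, dtype=np.int8)
        rng = np.random.default_rng(3)
        codes[:10, 0] = rng.choice([0, 2], size=10)
        codes[:, 1] = rng.choice([0, 2], size=20)
        codes[:, 2] = rng.choice([0, 2], size=20)
        marker_ids = ["M0", "M1", "M2"]
        geno = ng.GenotypeMatrix(
            codes=codes,
            ril_ids=np.array([f"R{i}" for i in range(20)], dtype=object),
            family_ids=np.array(["F1"] * 10 + ["F2"] * 10, dtype=object),
            marker_ids=np.array(marker_ids, dtype=object),
            marker_map=pd.DataFrame({"marker_id": marker_ids, "chrom": 1, "pos": [1, 2, 3]}),
        )
        sim = ng.simulate_phenotypes(geno, trial5, seed=64)
        adj = ng.adjust_by_checks(sim.pheno)
        with pytest.raises(InsufficientSegregationError):
            ng.collect_effects(geno, adj, "M0")


class TestGeiScan:
    def test_scan_is_deterministic(self, small_geno, trial5):
        sim = ng.simulate_phenotypes(small_geno, trial5, seed=71)
        adj = ng.adjust_by_checks(sim.pheno)
        t1 = ng.gei_scan(small_geno, adj, marker_ids=[str(m) for m in small_geno.marker_ids[:8]])
        t2 = ng.gei_scan(small_geno, adj, marker_ids=[str(m) for m in small_geno.marker_ids[:8]])
        assert [t.lrt for t in t1] == [t.lrt for t in t2]
        assert [t.pc_load for t in t1] == [t.pc_load for t in t2]

    def test_interaction_scale_monotonicity(self, small_geno):
        """Stronger simulated multiplicative GEI never weakens the median LRT."""
        medians = []
        for scale in (0.0, 120.0, 300.0):
            lrts = []
            for s in range(5):
                rng = np.random.default_rng(700 + s)
                lo = rng.standard_normal(5)
                lo -= lo.mean()
                lo /= lo.std()
                qtl = ng.QtlSpec(
                    marker_index=9,
                    family_effects=rng.normal(0, 80, 4),
                    env_loadings=lo,
                    interaction_scale=scale,
                )
                trial = ng.TrialDesign(
                    environments=[f"E{j}" for j in range(5)],
                    env_effects=np.linspace(2800, 4200, 5),
                    residual_sd=300.0,
                )
                sim = ng.simulate_phenotypes(small_geno, trial, [qtl], seed=710 + s)
                adj = ng.adjust_by_checks(sim.pheno)
                panel = ng.collect_effects(small_geno, adj, "M00010")
                lrts.append(gei_test_marker(panel).lrt)
            medians.append(np.median(lrts))
        assert medians[0] <= medians[1] <= medians[2]

    def test_informative_environment_guard(self):
        # one dominant column among zeros would saturate the rank-1 term
        A = np.zeros((4, 6))
        A[:, 2] = [30.0, -12.0, 4.0, -22.0]
        assert n_informative_envs(panel_from(A)) == 1
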