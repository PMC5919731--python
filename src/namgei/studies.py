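"""Scaled-down validation studies exercising the full analysis chain.

Each function simulates data under the package's study conditions, runs the
relevant analysis end to end and returns the measured quantity.  They back
both the validation test-suite and the reproduction script.  Population
sizes are reduced from the full 39-family x 140-RIL design to 10 x 50 so a
complete battery runs in minutes on one core; effect sizes follow the
scaled design (additive family effects of about half a residual SD,
multiplicative GEI on the same order as the additive effects).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .envtools import cluster_environments, env_profiles
from .fwstab import fw_regression, stability_gwas
from .geimeta import EffectPanel, fit_meta_null, gei_scan, rank1_interaction
from .mmassoc import adjust_by_checks, scan_environment
from .simdata import (
    NamDesign,
    QtlSpec,
    SensitivitySpec,
    TrialDesign,
    simulate_genotypes,
    simulate_phenotypes,
    soynam_trial,
)

#: scaled-down population used throughout the power studies
N_FAMILIES = 10
N_RILS = 50
N_MARKERS = 150
RESIDUAL_SD = 400.0
POLYGENIC_SD = 300.0


def _geno(seed: int, n_markers: int = N_MARKERS):
    design = NamDesign(
        n_families=N_FAMILIES,
        n_rils_per_family=N_RILS,
        n_markers=n_markers,
        n_chromosomes=10,
        seed=seed,
    )
    return simulate_genotypes(design)


# ---------------------------------------------------------------------------
# additive-QTL detection
# ---------------------------------------------------------------------------

def additive_power_study(base_seed: int, n_seeds: int = 20) -> float:
    """Fraction of replicates where the injected additive QTL tops the scan.

    Family effects are drawn N(0, 200 kg/ha) — about half the residual SD —
    against a polygenic background; one environment of a two-environment
    trial is scanned.
    """
    hits = 0
    for s in range(n_seeds):
        geno = _geno(base_seed + s)
        rng = np.random.default_rng(base_seed + 1000 + s)
        qtl = QtlSpec(marker_index=75, family_effects=rng.normal(0.0, 200.0, N_FAMILIES))
        trial = TrialDesign(
            environments=["E1", "E2"], env_effects=[3000.0, 4000.0], residual_sd=RESIDUAL_SD
        )
        sim = simulate_phenotypes(
            geno, trial, [qtl], seed=base_seed + 2000 + s, polygenic_sd=POLYGENIC_SD
        )
        adj = adjust_by_checks(sim.pheno)
        scan = scan_environment(geno, adj, "E1")
        hits += scan.top_marker() == str(geno.marker_ids[75])
    return hits / n_seeds


# ---------------------------------------------------------------------------
# multiplicative-GEI detection
# ---------------------------------------------------------------------------

def gei_power_study(base_seed: int, n_seeds: int = 20, n_env: int = 8) -> tuple[float, float]:
    """(top-hit fraction, median pc_load at the causal marker).

    The causal marker carries family effects N(0, 100) plus a rank-1
    multiplicative term of scale 150 kg/ha on standardized environment
    loadings; the meta-scan must rank it first by LRT.
    """
    hits = 0
    pc_loads = []
    for s in range(n_seeds):
        geno = _geno(base_seed + s)
        rng = np.random.default_rng(base_seed + 1000 + s)
        lo = rng.standard_normal(n_env)
        lo -= lo.mean()
        lo /= lo.std()
        qtl = QtlSpec(
            marker_index=30,
            family_effects=rng.normal(0.0, 100.0, N_FAMILIES),
            env_loadings=lo,
            interaction_scale=150.0,
        )
        trial = TrialDesign(
            environments=[f"E{j + 1}" for j in range(n_env)],
            env_effects=np.linspace(2500.0, 5000.0, n_env),
            residual_sd=RESIDUAL_SD,
        )
        sim = simulate_phenotypes(
            geno, trial, [qtl], seed=base_seed + 2000 + s, polygenic_sd=POLYGENIC_SD
        )
        adj = adjust_by_checks(sim.pheno)
        tests = gei_scan(geno, adj)
        best = max(tests, key=lambda t: t.lrt)
        causal = str(geno.marker_ids[30])
        hits += best.marker_id == causal
        pc_loads.extend(t.pc_load for t in tests if t.marker_id == causal)
    return hits / n_seeds, float(np.median(pc_loads))


# ---------------------------------------------------------------------------
# FW stability GWAS
# ---------------------------------------------------------------------------

def fw_trial(n_env: int = 15, residual_sd: float = 250.0) -> TrialDesign:
    """Productivity gradient spanning the published environment-mean range."""
    return TrialDesign(
        environments=[f"E{j + 1:02d}" for j in range(n_env)],
        env_effects=np.linspace(2364.0, 5057.0, n_env),
        residual_sd=residual_sd,
    )


def fw_power_study(base_seed: int, n_seeds: int = 20) -> tuple[float, list[float]]:
    """(Bonferroni detection fraction for a slope QTL, per-seed slope recovery r).

    The causal marker shifts the FW slope by 0.2 per founder allele on top
    of a slope SD of 0.2.
    """
    hits = 0
    corrs = []
    for s in range(n_seeds):
        geno = _geno(base_seed + s)
        slope_qtl = QtlSpec(marker_index=100, family_effects=np.full(N_FAMILIES, 0.2))
        sens = SensitivitySpec(slope_sd=0.2, genetic_slope_markers=[slope_qtl])
        sim = simulate_phenotypes(geno, fw_trial(), sens=sens, seed=base_seed + 2000 + s)
        adj = adjust_by_checks(sim.pheno)
        fw = fw_regression(adj)
        scan = stability_gwas(geno, fw)
        nl = {t.marker_id: t.neglog10p for t in scan.tests}
        hits += nl[str(geno.marker_ids[100])] >= scan.threshold
        sl = fw.slopes()
        corrs.append(float(np.corrcoef(sl, sim.true_slopes.reindex(sl.index))[0, 1]))
    return hits / n_seeds, corrs


def fw_exact_behaviour() -> tuple[float, float]:
    """(slope of the mean genotype, slope of a constant genotype), no noise."""
    idx_means = pd.Series({"A": 2000.0, "B": 3000.0, "C": 4000.0})
    from .fwstab import EnvIndex

    index = EnvIndex(means=idx_means, centered=idx_means - idx_means.mean())
    mean_geno = pd.DataFrame(
        {
            "ril_id": "R_mean",
            "env": list(idx_means.index),
            "block": 1,
            "yield": idx_means.to_numpy(),
            "is_check": False,
        }
    )
    const_geno = mean_geno.assign(ril_id="R_flat", **{"yield": 3000.0})
    fit = fw_regression(pd.concat([mean_geno, const_geno]), index)
    t = fit.table.set_index("ril_id")
    return float(t.loc["R_mean", "slope"]), float(t.loc["R_flat", "slope"])


def fw_histogram_study(base_seed: int) -> float:
    """Mean estimated FW slope on a soynam-like unbalanced simulation."""
    geno = _geno(base_seed)
    trial = soynam_trial(n_families=N_FAMILIES)
    sens = SensitivitySpec(slope_sd=0.2)
    sim = simulate_phenotypes(geno, trial, sens=sens, seed=base_seed + 1)
    adj = adjust_by_checks(sim.pheno)
    fw = fw_regression(adj)
    return float(fw.slopes().mean())


# ---------------------------------------------------------------------------
# null calibration of the per-marker boundary LRT
# ---------------------------------------------------------------------------

def null_calibration_study(
    base_seed: int, n_datasets: int = 5, n_markers: int = 200
) -> tuple[float, int]:
    """(fraction of null marker tests with p < 0.05, number of tests).

    Phenotypes carry polygenic signal (drawn with the kinship covariance of
    the very markers being tested) plus residual noise but no QTL, so every
    marker test is null under the fitted model.
    """
    pvals = []
    for d in range(n_datasets):
        geno = _geno(base_seed + d, n_markers=n_markers)
        trial = TrialDesign(
            environments=["E1", "E2"], env_effects=[3000.0, 4000.0], residual_sd=RESIDUAL_SD
        )
        sim = simulate_phenotypes(
            geno, trial, seed=base_seed + 3000 + d, polygenic_sd=POLYGENIC_SD
        )
        adj = adjust_by_checks(sim.pheno)
        for env in ("E1", "E2"):
            scan = scan_environment(geno, adj, env)
            pvals.extend(t.pvalue for t in scan.tests)
    pvals = np.asarray(pvals)
    return float(np.mean(pvals < 0.05)), len(pvals)


# ---------------------------------------------------------------------------
# linear-algebra oracles
# ---------------------------------------------------------------------------

def _als_rank1(E: np.ndarray, max_iter: int = 100_000, seed: int = 0) -> np.ndarray:
    """Alternating least squares for the best rank-1 fit, run to convergence."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(E.shape[1])
    prev = None
    for _ in range(max_iter):
        u = E @ v / (v @ v)
        v = E.T @ u / (u @ u)
        cur = np.outer(u, v)
        if prev is not None and np.abs(cur - prev).max() <= 1e-13 * max(1.0, np.abs(cur).max()):
            break
        prev = cur
    return cur


def svd_vs_als_study(base_seed: int, n_matrices: int = 200) -> float:
    """Max |gamma_svd - gamma_als| over random residual matrices up to 10x10."""
    rng = np.random.default_rng(base_seed)
    worst = 0.0
    for rep in range(n_matrices):
        m = int(rng.integers(2, 11))
        n = int(rng.integers(2, 11))
        E = rng.normal(size=(m, n))
        A = pd.DataFrame(E, index=[f"F{i}" for i in range(m)], columns=[f"E{j}" for j in range(n)])
        panel = EffectPanel(marker_id="m", A=A, N=A * 0 + 1.0)
        fit = fit_meta_null(panel)
        fit.residual_matrix = A
        alt = rank1_interaction(fit)
        gamma_oracle = _als_rank1(E, seed=base_seed + rep)
        worst = max(worst, float(np.abs(alt.gamma.to_numpy() - gamma_oracle).max()))
    return worst


def wls_oracle_study(base_seed: int, n_panels: int = 100) -> float:
    """Max |delta - dense normal-equations solution| over random panels."""
    rng = np.random.default_rng(base_seed)
    worst = 0.0
    for _ in range(n_panels):
        nf = int(rng.integers(2, 9))
        ne = int(rng.integers(2, 9))
        A = rng.normal(size=(nf, ne)) * 50
        N = rng.integers(0, 20, size=(nf, ne)).astype(float)
        if not (N > 0).any():
            N[0, 0] = 1.0
        parents = [f"P{rng.integers(0, max(2, nf - 1))}" for _ in range(nf)]
        fams = [f"F{i}" for i in range(nf)]
        panel = EffectPanel(
            marker_id="m",
            A=pd.DataFrame(A, index=fams, columns=[f"E{j}" for j in range(ne)]),
            N=pd.DataFrame(N, index=fams, columns=[f"E{j}" for j in range(ne)]),
            parent_of_family=dict(zip(fams, parents)),
        )
        fit = fit_meta_null(panel)
        plist = panel.parents
        rows = [
            (parents[i], A[i, j], N[i, j])
            for i in range(nf)
            for j in range(ne)
            if N[i, j] > 0
        ]
        W = np.array([[1.0 if p == q else 0.0 for q in plist] for p, _, _ in rows])
        a = np.array([r[1] for r in rows])
        w = np.array([r[2] for r in rows])
        M = W.T @ (w[:, None] * W)
        keep = np.diag(M) > 0
        delta = np.zeros(len(plist))
        delta[keep] = np.linalg.solve(M[np.ix_(keep, keep)], (W.T @ (w * a))[keep])
        got = fit.delta.reindex(plist).to_numpy()
        worst = max(worst, float(np.abs(got[keep] - delta[keep]).max()))
    return worst


def decomposition_identity_study(base_seed: int) -> float:
    """Max cell-wise |(A - W delta) - (gamma + eps)| over simulated panels."""
    from .geimeta import build_env_contexts, collect_effects
    from .errors import InsufficientSegregationError

    geno = _geno(base_seed, n_markers=40)
    trial = TrialDesign(
        environments=[f"E{j + 1}" for j in range(5)],
        env_effects=np.linspace(2800.0, 4400.0, 5),
        residual_sd=RESIDUAL_SD,
    )
    sim = simulate_phenotypes(geno, trial, seed=base_seed + 1, polygenic_sd=POLYGENIC_SD)
    adj = adjust_by_checks(sim.pheno)
    ctx = build_env_contexts(geno, adj)
    worst = 0.0
    for m in geno.marker_ids:
        try:
            panel = collect_effects(geno, adj, str(m), contexts=ctx)
        except InsufficientSegregationError:
            continue
        null = fit_meta_null(panel)
        alt = rank1_interaction(null)
        mask = panel.mask()
        fitted = null.delta.reindex(
            [panel.parent_of_family[f] for f in panel.families]
        ).to_numpy()[:, None]
        lhs = panel.A.to_numpy() - fitted
        rhs = alt.gamma.to_numpy() + alt.new_residuals.to_numpy()
        worst = max(worst, float(np.abs((lhs - rhs)[mask]).max()))
    return worst


# ---------------------------------------------------------------------------
# environment clustering
# ---------------------------------------------------------------------------

def ward_oracle_study(base_seed: int, n_sets: int = 50) -> float:
    """Fraction of random 4-environment sets whose merge sequence matches a
    brute-force Lance-Williams ward.D agglomeration."""
    rng = np.random.default_rng(base_seed)
    agree = 0
    for _ in range(n_sets):
        X = rng.normal(size=(4, 3)) * 5
        labels = [f"E{i}" for i in range(4)]
        dend = cluster_environments(pd.DataFrame(X, index=labels))
        oracle = _ward_d_bruteforce(X, labels)
        sets = dend.subtree_leaf_sets()
        ok = all(
            sets[step] == left | right and abs(dend.heights[step] - h) <= 1e-8 * max(1.0, h)
            for step, (left, right, h) in enumerate(oracle)
        )
        agree += ok
    return agree / n_sets


def _ward_d_bruteforce(X, labels):
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: frozenset([labels[i]]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {
        (i, j): float(np.linalg.norm(X[i] - X[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    merges = []
    nxt = n
    active = list(range(n))
    while len(active) > 1:
        i, j = min(
            (tuple(sorted((a, b))) for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda p: (d[p], p),
        )
        h = d[(i, j)]
        merges.append((clusters[i], clusters[j], h))
        for k in active:
            if k in (i, j):
                continue
            d[tuple(sorted((nxt, k)))] = (
                (sizes[i] + sizes[k]) * d[tuple(sorted((i, k)))]
                + (sizes[j] + sizes[k]) * d[tuple(sorted((j, k)))]
                - sizes[k] * h
            ) / (sizes[i] + sizes[j] + sizes[k])
        clusters[nxt] = clusters[i] | clusters[j]
        sizes[nxt] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return merges


def soynam_cluster_study(base_seed: int) -> bool:
    """True when the three >4700 kg/ha preset environments form one subtree.

    Run in the noise-free limit: the preset environment means sit as close
    as ~8 kg/ha apart, so the published grouping is identifiable from
    main-effect profiles only when plot noise is negligible (real trials
    recover it through correlated family-by-environment structure that a
    main-effects generator does not produce).
    """
    geno = _geno(base_seed, n_markers=20)
    trial = soynam_trial(n_families=N_FAMILIES, unbalanced=False, block_sd=0.0, residual_sd=0.0)
    sim = simulate_phenotypes(
        geno, trial, sens=SensitivitySpec(slope_sd=0.0), seed=base_seed + 1
    )
    adj = adjust_by_checks(sim.pheno)
    fam_of = pd.Series(geno.family_ids, index=pd.Index(geno.ril_ids, name="ril_id"))
    dend = cluster_environments(env_profiles(adj, fam_of))
    return frozenset({"NE2011", "NE2012", "IN2013"}) in dend.subtree_leaf_sets()


# ---------------------------------------------------------------------------
# headline threshold
# ---------------------------------------------------------------------------

def genomewide_threshold_study(base_seed: int, n_markers: int = 4312) -> float:
    """Bonferroni -log10 p cut reported by a genome scan over n_markers SNPs."""
    design = NamDesign(
        n_families=2, n_rils_per_family=15, n_markers=n_markers, n_chromosomes=20,
        seed=base_seed,
    )
    geno = simulate_genotypes(design)
    rng = np.random.default_rng(base_seed + 1)
    from .mmassoc import genome_scan

    y = pd.Series(
        3000.0 + 300.0 * rng.standard_normal(geno.n_rils),
        index=pd.Index(geno.ril_ids, name="ril_id"),
    )
    scan = genome_scan(geno, y, alpha_level=0.05)
    return float(scan.threshold)
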