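"""Multiparental mixed-model association scans with boundary LRTs.

The model for one environment (or one derived phenotype such as the FW
slope) is

    y = X beta + Z_k alpha + psi + e,
    alpha ~ N(0, I sigma2_alpha),  psi ~ N(0, K sigma2_psi),
    e ~ N(0, I sigma2_eps),

where ``Z_k`` is the marker-by-family founder-dosage incidence at marker
*k* (columns restricted to segregating families) and ``K`` the genomic
relationship matrix.  Each marker is tested with the restricted-likelihood
ratio LRT = -2 (L0 - L1); because sigma2_alpha sits on the boundary of the
parameter space under the null, p-values use a chi-square law with 0.5
degrees of freedom by default (the 50:50 {chi2_0, chi2_1} mixture is
available as an alternative).

Two fitting strategies are provided per marker:

* ``mode="full"`` re-optimizes all three variance components jointly
  (coordinate descent over the two variance ratios, each solved by bounded
  scalar search on a log grid) — the reference implementation;
* ``mode="fast"`` keeps the polygenic-to-residual ratio fixed at its
  null-model optimum and profiles only the marker variance, which reduces
  every marker test to a small SVD plus a one-dimensional search and makes
  genome scans over thousands of markers interactive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .errors import MissingCheckError
from .genomat import GenotypeMatrix, Kinship, ParentalIncidence, compute_kinship, recode_parental_origin

_LOG10 = math.log(10.0)
_RATIO_BOUNDS = (1e-6, 1e6)
NEGLOG10P_CAP = 320.0


# ---------------------------------------------------------------------------
# p-value laws for the variance-component boundary test
# ---------------------------------------------------------------------------

def lrt_pvalue(lrt: float, law: str = "chi2_0.5df") -> float:
    """Survival probability of the LRT under the chosen boundary null law."""
    lrt = max(0.0, float(lrt))
    if law == "chi2_0.5df":
        return float(chi2.sf(lrt, 0.5))
    if law == "mixture_0_1":
        return 1.0 if lrt == 0.0 else float(0.5 * chi2.sf(lrt, 1.0))
    raise ValueError(f"unknown p-value law: {law!r}")


def lrt_neglog10p(lrt: float, law: str = "chi2_0.5df") -> float:
    """-log10 p with extended range via the log survival function."""
    lrt = max(0.0, float(lrt))
    if law == "chi2_0.5df":
        logsf = float(chi2.logsf(lrt, 0.5))
    elif law == "mixture_0_1":
        logsf = 0.0 if lrt == 0.0 else float(math.log(0.5) + chi2.logsf(lrt, 1.0))
    else:
        raise ValueError(f"unknown p-value law: {law!r}")
    return min(NEGLOG10P_CAP, -logsf / _LOG10)


def bonferroni_threshold(alpha_level: float, n_markers: int) -> float:
    """-log10 of the per-marker Bonferroni cutoff alpha / m."""
    if not (0.0 < alpha_level < 1.0):
        raise ValueError("alpha_level must lie in (0, 1)")
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return -math.log10(alpha_level / n_markers)


# ---------------------------------------------------------------------------
# check-based field adjustment (augmented design)
# ---------------------------------------------------------------------------

def adjust_by_checks(pheno: pd.DataFrame) -> pd.DataFrame:
    """Remove block-level field effects estimated from the check plots.

    Each non-check yield is reduced by (mean of checks in its block - mean
    of checks in its environment); check records are dropped from the
    output.  Every (environment, block) combination carrying test records
    must contain at least one check plot.
    """
    checks = pheno[pheno["is_check"]]
    tests = pheno[~pheno["is_check"]].copy()
    blk_mean = checks.groupby(["env", "block"])["yield"].mean()
    env_mean = checks.groupby("env")["yield"].mean()
    need = set(map(tuple, tests[["env", "block"]].drop_duplicates().to_numpy()))
    have = set(blk_mean.index)
    orphans = sorted(need - have)
    if orphans:
        raise MissingCheckError(f"blocks without check plots: {orphans}")
    key = pd.MultiIndex.from_frame(tests[["env", "block"]])
    adj = blk_mean.reindex(key).to_numpy() - env_mean.reindex(tests["env"]).to_numpy()
    tests["yield"] = tests["yield"].to_numpy() - adj
    return tests.reset_index(drop=True)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

@dataclass
class VarComp:
    """Variance components of one (restricted-likelihood) model fit."""

    sigma2_alpha: float
    sigma2_psi: float
    sigma2_eps: float
    loglik: float
    beta: np.ndarray
    ratio_psi: float  # sigma2_psi / sigma2_eps
    # rotation cache for fast per-marker tests (eigen-basis of K)
    _s: np.ndarray = field(default=None, repr=False)
    _U: np.ndarray = field(default=None, repr=False)
    _yr: np.ndarray = field(default=None, repr=False)
    _Xr: np.ndarray = field(default=None, repr=False)
    _logdet_xtx: float = field(default=0.0, repr=False)


def _reml_from_rotated(yr, Xr, d, logdet_xtx):
    """Restricted log-likelihood pieces given per-coordinate variances d."""
    n, p = Xr.shape
    W = Xr / d[:, None]
    A = Xr.T @ W
    bvec = W.T @ yr
    beta = np.linalg.solve(A, bvec)
    r = yr - Xr @ beta
    rss = max(float(r @ (r / d)), 1e-300)  # zero-variance phenotypes degenerate
    sign, logdet_a = np.linalg.slogdet(A)
    sig2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * (math.log(2 * math.pi) + 1.0 + math.log(sig2))
        + float(np.sum(np.log(d)))
        + logdet_a
        - logdet_xtx
    )
    return ll, beta, sig2, r


def _maximize_scalar(fun, lo=_RATIO_BOUNDS[0], hi=_RATIO_BOUNDS[1], grid=17):
    """Maximize fun(ratio) over [lo, hi]: coarse log grid, then Brent polish."""
    lam = np.exp(np.linspace(math.log(lo), math.log(hi), grid))
    vals = np.array([fun(v) for v in lam])
    i = int(np.argmax(vals))
    a = math.log(lam[max(0, i - 1)])
    b = math.log(lam[min(grid - 1, i + 1)])
    res = optimize.minimize_scalar(
        lambda t: -fun(math.exp(t)), bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    best_t = res.x if -res.fun >= vals[i] else math.log(lam[i])
    return math.exp(best_t), max(-res.fun, float(vals[i]))


def fit_null(y: np.ndarray, X: np.ndarray | None, K: Kinship | np.ndarray) -> VarComp:
    """REML fit of the polygenic null model y = X beta + psi + e.

    Uses the eigendecomposition of K to profile the restricted likelihood
    over the single ratio sigma2_psi / sigma2_eps.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Km = K.matrix if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    if Km.shape != (n, n):
        raise ValueError("K dimensions do not match y")
    s, U = np.linalg.eigh(Km)
    if s[0] < -1e-6 * max(1.0, float(s[-1])):
        raise np.linalg.LinAlgError("kinship matrix is not PSD within tolerance")
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)

    def ll_of(lam):
        return _reml_from_rotated(yr, Xr, lam * s + 1.0, logdet_xtx)[0]

    lam_hat, ll = _maximize_scalar(ll_of)
    _, beta, sig2, _ = _reml_from_rotated(yr, Xr, lam_hat * s + 1.0, logdet_xtx)
    return VarComp(
        sigma2_alpha=0.0,
        sigma2_psi=lam_hat * sig2,
        sigma2_eps=sig2,
        loglik=ll,
        beta=beta,
        ratio_psi=lam_hat,
        _s=s,
        _U=U,
        _yr=yr,
        _Xr=Xr,
        _logdet_xtx=logdet_xtx,
    )


@dataclass
class MarkerTest:
    """LRT result and per-family shrinkage allele effects for one marker."""

    marker_id: str
    lrt: float
    pvalue: float
    neglog10p: float
    family_effects: pd.Series
    families_tested: int


def _null_result(marker_id: str) -> MarkerTest:
    return MarkerTest(
        marker_id=marker_id,
        lrt=0.0,
        pvalue=1.0,
        neglog10p=0.0,
        family_effects=pd.Series(dtype=float),
        families_tested=0,
    )


def _fast_marker_ll(yw, Xw, P, sv2, logdet_c, logdet_xtx):
    """Factory: restricted log-likelihood in the whitened basis as f(lam_a).

    ``P, sv2`` come from the thin SVD of the whitened incidence Z_w; the
    covariance is sigma2_eps * (lam_a Z_w Z_w' + I) and the Woodbury form
    keeps each evaluation O(n * rank).
    """
    n, p = Xw.shape
    Py = P.T @ yw
    PX = P.T @ Xw
    xtx = Xw.T @ Xw
    xty = Xw.T @ yw
    yty = float(yw @ yw)

    def pieces(lam_a):
        e = lam_a * sv2
        shrink = e / (1.0 + e)
        A = xtx - PX.T @ (shrink[:, None] * PX)
        bvec = xty - PX.T @ (shrink * Py)
        beta = np.linalg.solve(A, bvec)
        r = yw - Xw @ beta
        Pr = Py - PX @ beta
        rss = float(r @ r - Pr @ (shrink * Pr))
        rss = max(rss, 1e-300)
        sign, logdet_a = np.linalg.slogdet(A)
        sig2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * (math.log(2 * math.pi) + 1.0 + math.log(sig2))
            + float(np.sum(np.log1p(e)))
            + logdet_c
            + logdet_a
            - logdet_xtx
        )
        return ll, beta, sig2, r, shrink

    return pieces


def _chol_reml(y, X, V, logdet_xtx):
    """Restricted log-likelihood for covariance sigma2 * V via Cholesky."""
    n, p = X.shape
    c, low = cho_factor(V, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    A = X.T @ Vi_X
    beta = np.linalg.solve(A, X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ cho_solve((c, low), r))
    rss = max(rss, 1e-300)
    sign, logdet_a = np.linalg.slogdet(A)
    sig2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * (math.log(2 * math.pi) + 1.0 + math.log(sig2))
        + logdet_v
        + logdet_a
        - logdet_xtx
    )
    return ll, beta, sig2, r, (c, low)


def test_marker(
    Z: np.ndarray,
    null_fit: VarComp,
    y: np.ndarray,
    X: np.ndarray | None,
    K: Kinship | np.ndarray,
    *,
    marker_id: str = "",
    families: np.ndarray | None = None,
    mode: str = "full",
    pvalue_law: str = "chi2_0.5df",
) -> MarkerTest:
    """Likelihood-ratio test of one marker's family-specific allele effects.

    ``Z`` must contain only the columns of segregating families (a marker
    monomorphic in every family is reported as LRT 0, p-value 1, no
    effects).  Family allele-effect estimates are the BLUPs of alpha at the
    optimum, in kg/ha per founder-allele dosage.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    marker_id = marker_id or "marker"
    if Z.shape[1] == 0 or not np.any(Z.std(axis=0) > 0):
        return _null_result(marker_id)
    if families is None:
        families = np.array([f"fam{j}" for j in range(Z.shape[1])], dtype=object)

    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]

    if mode == "fast":
        lrt, alpha_hat = _test_marker_fast(Z, null_fit)
    elif mode == "full":
        lrt, alpha_hat = _test_marker_full(Z, null_fit, y, X, K)
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    lrt = max(0.0, lrt)
    return MarkerTest(
        marker_id=marker_id,
        lrt=lrt,
        pvalue=lrt_pvalue(lrt, pvalue_law),
        neglog10p=lrt_neglog10p(lrt, pvalue_law),
        family_effects=pd.Series(alpha_hat, index=pd.Index(families, name="family_id"), name="effect"),
        families_tested=Z.shape[1],
    )


def _test_marker_fast(Z, null_fit: VarComp):
    """Profile only the marker variance, polygenic ratio fixed at the null."""
    s, U, yr, Xr = null_fit._s, null_fit._U, null_fit._yr, null_fit._Xr
    d0 = null_fit.ratio_psi * s + 1.0
    sqrt_d0 = np.sqrt(d0)
    yw = yr / sqrt_d0
    Xw = Xr / sqrt_d0[:, None]
    Zw = (U.T @ Z) / sqrt_d0[:, None]
    P, sv, _ = np.linalg.svd(Zw, full_matrices=False)
    keep = sv > 1e-12 * max(1.0, sv[0])
    P, sv = P[:, keep], sv[keep]
    if len(sv) == 0:
        return 0.0, np.zeros(Z.shape[1])
    logdet_c = float(np.sum(np.log(d0)))
    pieces = _fast_marker_ll(yw, Xw, P, sv**2, logdet_c, null_fit._logdet_xtx)

    ll0 = pieces(0.0)[0]
    lam_hat, ll1 = _maximize_scalar(lambda lam: pieces(lam)[0])
    if ll1 < ll0:
        lam_hat, ll1 = 0.0, ll0
    _, beta, sig2, r, shrink = pieces(lam_hat)
    # BLUP: alpha_hat = lam_a * Zw' D^{-1} r  in the whitened basis
    Pr = P.T @ r
    Dinv_r = r - P @ (shrink * Pr)
    alpha_hat = lam_hat * (Zw.T @ Dinv_r)
    return 2.0 * (ll1 - ll0), alpha_hat


def _test_marker_full(Z, null_fit: VarComp, y, X, K):
    """Joint re-optimization of both variance ratios by coordinate descent."""
    Km = K.matrix if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    n = len(y)
    ZZt = Z @ Z.T
    logdet_xtx = null_fit._logdet_xtx

    def ll_of(lam_p, lam_a):
        V = lam_a * ZZt + lam_p * Km + np.eye(n)
        return _chol_reml(y, X, V, logdet_xtx)[0]

    lam_p = max(null_fit.ratio_psi, _RATIO_BOUNDS[0])
    lam_a = _RATIO_BOUNDS[0]
    best = ll_of(lam_p, lam_a)
    for _ in range(3):
        lam_a, _ = _maximize_scalar(lambda v: ll_of(lam_p, v))
        lam_p, new = _maximize_scalar(lambda v: ll_of(v, lam_a))
        if new - best < 1e-8:
            best = new
            break
        best = new
    ll1 = best
    ll0 = null_fit.loglik
    V = lam_a * ZZt + lam_p * Km + np.eye(n)
    _, beta, sig2, r, chol = _chol_reml(y, X, V, logdet_xtx)
    alpha_hat = lam_a * (Z.T @ cho_solve(chol, r))
    return 2.0 * (ll1 - ll0), alpha_hat


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-marker tests from one association scan plus the Bonferroni cut."""

    tests: list[MarkerTest]
    threshold: float
    alpha_level: float
    environment: str | None = None
    adj_r2: pd.Series | None = None

    def to_frame(self, marker_map: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker_id": [t.marker_id for t in self.tests],
                "lrt": [t.lrt for t in self.tests],
                "pvalue": [t.pvalue for t in self.tests],
                "neglog10p": [t.neglog10p for t in self.tests],
                "n_families": [t.families_tested for t in self.tests],
            }
        )
        if self.adj_r2 is not None:
            df["adj_r2"] = self.adj_r2.reindex(df["marker_id"]).to_numpy()
        df["env"] = self.environment if self.environment is not None else "all"
        if marker_map is not None:
            df = marker_map.merge(df, on="marker_id", how="right")
        return df

    def effects_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tests:
            for fam, eff in t.family_effects.items():
                rows.append((t.marker_id, fam, eff))
        return pd.DataFrame(rows, columns=["marker_id", "family_id", "effect"])

    def top_marker(self) -> str:
        scores = [t.neglog10p for t in self.tests]
        return self.tests[int(np.argmax(scores))].marker_id


def genome_scan(
    geno: GenotypeMatrix,
    y: pd.Series,
    alpha_level: float = 0.05,
    *,
    mode: str = "fast",
    pvalue_law: str = "chi2_0.5df",
    environment: str | None = None,
    incidence: ParentalIncidence | None = None,
    kinship: Kinship | None = None,
    null: VarComp | None = None,
) -> ScanResult:
    """Scan every marker against a per-RIL phenotype.

    ``y`` is indexed by ``ril_id``; RILs absent from the genotype matrix (or
    with undefined phenotype) are dropped.  Precomputed incidence, kinship
    or null fits may be passed to share work across scans on the same RIL
    subset.
    """
    y = y.dropna()
    pos = {r: i for i, r in enumerate(geno.ril_ids)}
    keep = [r for r in y.index if r in pos]
    if len(keep) < 2:
        raise ValueError("fewer than two phenotyped RILs overlap the genotypes")
    if len(keep) != geno.n_rils:
        geno = geno.subset_rils(np.array([pos[r] for r in keep], dtype=int))
        incidence = kinship = null = None
    yv = y.reindex(geno.ril_ids).to_numpy(dtype=float)

    if incidence is None:
        incidence = recode_parental_origin(geno)
    if kinship is None:
        kinship = compute_kinship(geno)
    if null is None:
        null = fit_null(yv, None, kinship)

    tests = []
    for k in range(geno.n_markers):
        Z = incidence.incidence(k, segregating_only=True)
        tests.append(
            test_marker(
                Z,
                null,
                yv,
                None,
                kinship,
                marker_id=str(geno.marker_ids[k]),
                families=incidence.segregating_families(k),
                mode=mode,
                pvalue_law=pvalue_law,
            )
        )
    return ScanResult(
        tests=tests,
        threshold=bonferroni_threshold(alpha_level, geno.n_markers),
        alpha_level=alpha_level,
        environment=environment,
    )


def env_phenotype(pheno_adj: pd.DataFrame, env: str) -> pd.Series:
    """Per-RIL mean adjusted yield in one environment (non-check records)."""
    sub = pheno_adj[pheno_adj["env"] == env]
    if "is_check" in sub.columns:
        sub = sub[~sub["is_check"]]
    if sub.empty:
        raise ValueError(f"no records for environment {env!r}")
    return sub.groupby("ril_id")["yield"].mean()


def scan_environment(
    geno: GenotypeMatrix,
    pheno_adj: pd.DataFrame,
    env: str,
    alpha_level: float = 0.05,
    **kwargs,
) -> ScanResult:
    """Single-environment yield scan on check-adjusted phenotypes."""
    y = env_phenotype(pheno_adj, env)
    kwargs.setdefault("environment", env)
    return genome_scan(geno, y, alpha_level, **kwargs)
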