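"""Rank-1 multiplicative genotype-by-environment meta-analysis.

For one marker, the per-environment association scans yield a family-by-
environment matrix A of allele-effect estimates with observation-count
weights N.  The additive (null) model regresses the effects on the
parental-source incidence W by weighted least squares,

    alpha = W delta + e,

and the alternative adds a rank-1 multiplicative interaction extracted as
the first singular component of the weighted-least-squares residual matrix,

    alpha = W delta + gamma + eps,   gamma_ij = u_i d_1 v_j.

The two models are compared by a Gaussian profiled-variance likelihood
ratio, LRT = n * ln(RSS0 / RSS1) on the weighted residual sums of squares,
referred to a chi-square law whose degrees of freedom count the free
parameters of the bilinear term.  The conventional genome-wide flag uses a
high empirical cutoff (default 50 on -log10 p) because the SVD-maximized
statistic is optimistically calibrated under the naive reference law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import DegenerateInputError, InsufficientSegregationError
from .genomat import (
    GenotypeMatrix,
    Kinship,
    ParentalIncidence,
    compute_kinship,
    recode_parental_origin,
)
from .mmassoc import NEGLOG10P_CAP, VarComp, env_phenotype, fit_null, test_marker

_LOG10 = math.log(10.0)

DEFAULT_GEI_THRESHOLD = 50.0  # empirical -log10 p cutoff for the meta-LRT


@dataclass
class EffectPanel:
    """Family x environment allele effects with observation-count weights.

    ``A[f, j]`` is the estimated allele effect (kg/ha per founder dosage) of
    family *f* in environment *j*; ``N[f, j]`` the number of plot records
    behind it (0 marks unobserved cells, which are excluded from every
    sum).  ``parent_of_family`` maps each family to its founder parent (the
    columns of the incidence W); in a classical NAM design this is one to
    one.
    """

    marker_id: str
    A: pd.DataFrame
    N: pd.DataFrame
    parent_of_family: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.A.shape != self.N.shape:
            raise ValueError("A and N must have the same shape")
        if (self.N.to_numpy() < 0).any():
            raise ValueError("weights must be non-negative")
        if not self.parent_of_family:
            self.parent_of_family = {f: f for f in self.A.index}

    @property
    def families(self) -> list:
        return list(self.A.index)

    @property
    def environments(self) -> list:
        return list(self.A.columns)

    @property
    def parents(self) -> list:
        seen = []
        for f in self.families:
            p = self.parent_of_family[f]
            if p not in seen:
                seen.append(p)
        return seen

    def mask(self) -> np.ndarray:
        return self.N.to_numpy() > 0

    def to_long(self) -> pd.DataFrame:
        rows = []
        mask = self.mask()
        A, N = self.A.to_numpy(), self.N.to_numpy()
        for i, f in enumerate(self.families):
            for j, e in enumerate(self.environments):
                if mask[i, j]:
                    rows.append((self.marker_id, f, e, A[i, j], N[i, j]))
        return pd.DataFrame(rows, columns=["marker_id", "family_id", "env", "effect", "weight"])


@dataclass
class MetaFit:
    """Weighted-least-squares fit of the additive parent-effect model."""

    panel: EffectPanel
    delta: pd.Series
    residual_matrix: pd.DataFrame
    weighted_rss: float
    n_cells: int


def fit_meta_null(panel: EffectPanel) -> MetaFit:
    """WLS of the effect panel on parental source: alpha = W delta + e.

    With one column of W per parent, the normal equations reduce to the
    N-weighted mean of each parent's observed cells.  Residuals are zero on
    unobserved cells.
    """
    A = panel.A.to_numpy(dtype=float)
    N = panel.N.to_numpy(dtype=float)
    mask = N > 0
    if not mask.any():
        raise DegenerateInputError("all panel weights are zero")
    parents = panel.parents
    fam_parent = np.array([panel.parent_of_family[f] for f in panel.families], dtype=object)
    delta = {}
    for p in parents:
        rows = fam_parent == p
        w = N[rows][mask[rows]]
        a = A[rows][mask[rows]]
        delta[p] = float(np.sum(w * a) / np.sum(w)) if w.sum() > 0 else 0.0
    fitted = np.array([delta[p] for p in fam_parent])[:, None]
    E = np.where(mask, A - fitted, 0.0)
    wrss = float(np.sum(N * E * E))
    return MetaFit(
        panel=panel,
        delta=pd.Series(delta, name="delta"),
        residual_matrix=pd.DataFrame(E, index=panel.A.index, columns=panel.A.columns),
        weighted_rss=wrss,
        n_cells=int(mask.sum()),
    )


@dataclass
class Rank1Interaction:
    """First singular component of the meta-model residual matrix."""

    u: np.ndarray
    d1: float
    v: np.ndarray
    gamma: pd.DataFrame
    pc_load: float
    new_residuals: pd.DataFrame


def rank1_interaction(fit: MetaFit, *, masked: bool = False, max_iter: int = 500, tol: float = 1e-12) -> Rank1Interaction:
    """Best rank-1 approximation of the residual matrix (the gamma term).

    The default takes the first singular triplet of the zero-filled
    residual matrix (unobserved cells contribute zero residual).  With
    ``masked`` the component is instead fitted by alternating least squares
    over the observed cells only.  The sign convention makes the first
    nonzero entry of u positive; ``pc_load`` is the fraction of residual
    variation captured, d1^2 / sum(d_i^2).
    """
    E = fit.residual_matrix.to_numpy(dtype=float)
    if E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("rank-1 interaction needs at least 2 families and 2 environments")
    if masked:
        u, d1, v = _masked_rank1(E, fit.panel.mask(), max_iter, tol)
        total = float(np.sum(E[fit.panel.mask()] ** 2))
        pc_load = min(1.0, d1**2 / total) if total > 0 else 1.0
    else:
        U, S, Vt = np.linalg.svd(E, full_matrices=False)
        u, d1, v = U[:, 0], float(S[0]), Vt[0]
        total = float(np.sum(S**2))
        pc_load = d1**2 / total if total > 0 else 1.0
    # sign convention: first entry of u with non-negligible magnitude positive
    nz = np.flatnonzero(np.abs(u) > 1e-12)
    if nz.size and u[nz[0]] < 0:
        u, v = -u, -v
    gamma = np.outer(u, v) * d1
    eps = np.where(fit.panel.mask(), E - gamma, 0.0)
    idx, cols = fit.residual_matrix.index, fit.residual_matrix.columns
    return Rank1Interaction(
        u=u,
        d1=d1,
        v=v,
        gamma=pd.DataFrame(gamma, index=idx, columns=cols),
        pc_load=float(pc_load),
        new_residuals=pd.DataFrame(eps, index=idx, columns=cols),
    )


def _masked_rank1(E, mask, max_iter, tol):
    """Alternating least squares for one component over observed cells."""
    m = mask.astype(float)
    Em = E * m
    v = Em.sum(axis=0)
    norm = np.linalg.norm(v)
    v = v / norm if norm > 0 else np.ones(E.shape[1]) / math.sqrt(E.shape[1])
    u = np.zeros(E.shape[0])
    prev = np.inf
    for _ in range(max_iter):
        denom_u = m @ (v * v)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(denom_u > 0, (Em @ v) / denom_u, 0.0)
        denom_v = (u * u) @ m
        with np.errstate(divide="ignore", invalid="ignore"):
            v_raw = np.where(denom_v > 0, (u @ Em) / denom_v, 0.0)
        rss = float(np.sum(m * (E - np.outer(u, v_raw)) ** 2))
        v_norm = np.linalg.norm(v_raw)
        if v_norm == 0:
            break
        u = u * v_norm
        v = v_raw / v_norm
        if abs(prev - rss) <= tol * max(1.0, rss):
            break
        prev = rss
    d1 = np.linalg.norm(u)
    u = u / d1 if d1 > 0 else u
    return u, float(d1), v


@dataclass
class GeiTest:
    """Meta-analysis LRT of the rank-1 interaction at one marker."""

    marker_id: str
    lrt: float
    df: int
    pvalue: float
    neglog10p: float
    pc_load: float
    n_parents: int
    n_env: int
    significant: bool


def gei_lrt(
    panel: EffectPanel,
    null_fit: MetaFit,
    alt: Rank1Interaction,
    *,
    threshold: float = DEFAULT_GEI_THRESHOLD,
    df_override: int | None = None,
) -> GeiTest:
    """Likelihood-ratio test of the additive vs rank-1 interaction model.

    LRT = n_cells * ln(RSS0 / RSS1) on weighted residual sums of squares;
    degrees of freedom default to the free-parameter count of the bilinear
    term, (n_parents - 1) + (n_env - 1) + 1.
    """
    N = panel.N.to_numpy(dtype=float)
    mask = N > 0
    E = null_fit.residual_matrix.to_numpy()
    eps = alt.new_residuals.to_numpy()
    rss0 = float(np.sum(N * E * E))
    rss1 = float(np.sum(N * eps * eps))
    n = null_fit.n_cells

    obs_parents = {panel.parent_of_family[f] for f, has in zip(panel.families, mask.any(axis=1)) if has}
    n_parents = len(obs_parents)
    n_env = int(mask.any(axis=0).sum())
    df = df_override if df_override is not None else max(1, (n_parents - 1) + (n_env - 1) + 1)

    if rss0 <= 0:
        lrt, neglog10p, pvalue = 0.0, 0.0, 1.0
    elif rss1 <= rss0 * 1e-300:
        lrt = float("inf")
        neglog10p, pvalue = NEGLOG10P_CAP, 0.0
    else:
        lrt = max(0.0, n * math.log(rss0 / rss1))
        pvalue = float(chi2.sf(lrt, df))
        neglog10p = min(NEGLOG10P_CAP, -float(chi2.logsf(lrt, df)) / _LOG10)
    return GeiTest(
        marker_id=panel.marker_id,
        lrt=lrt,
        df=df,
        pvalue=pvalue,
        neglog10p=neglog10p,
        pc_load=alt.pc_load,
        n_parents=n_parents,
        n_env=n_env,
        significant=neglog10p >= threshold,
    )


# ---------------------------------------------------------------------------
# per-environment effect collection
# ---------------------------------------------------------------------------

@dataclass
class _EnvContext:
    """Reusable per-environment fitting state shared across markers."""

    env: str
    geno: GenotypeMatrix
    incidence: ParentalIncidence
    kinship: Kinship
    null: VarComp
    y: np.ndarray
    record_counts: pd.Series  # plot records per family
    marker_pos: Mapping[str, int]


def build_env_contexts(
    geno: GenotypeMatrix,
    pheno_adj: pd.DataFrame,
    *,
    min_rils: int = 10,
) -> dict[str, _EnvContext]:
    """Fit the polygenic null once per environment for reuse across markers."""
    contexts: dict[str, _EnvContext] = {}
    pos = {r: i for i, r in enumerate(geno.ril_ids)}
    counts_all = (
        pheno_adj[~pheno_adj["is_check"]]
        if "is_check" in pheno_adj.columns
        else pheno_adj
    )
    for env in pd.unique(counts_all["env"]):
        y = env_phenotype(pheno_adj, env)
        keep = [r for r in y.index if r in pos]
        if len(keep) < min_rils:
            continue
        sub = geno.subset_rils(np.array([pos[r] for r in keep], dtype=int))
        yv = y.reindex(sub.ril_ids).to_numpy(dtype=float)
        inc = recode_parental_origin(sub)
        kin = compute_kinship(sub)
        null = fit_null(yv, None, kin)
        env_recs = counts_all[counts_all["env"] == env]
        env_recs = env_recs[env_recs["ril_id"].isin(set(sub.ril_ids))]
        fam_of = pd.Series(sub.family_ids, index=sub.ril_ids)
        rec_counts = env_recs.groupby(fam_of.reindex(env_recs["ril_id"]).to_numpy()).size()
        contexts[env] = _EnvContext(
            env=env,
            geno=sub,
            incidence=inc,
            kinship=kin,
            null=null,
            y=yv,
            record_counts=rec_counts,
            marker_pos={m: k for k, m in enumerate(sub.marker_ids)},
        )
    return contexts


def _ols_family_effects(ctx: _EnvContext, k: int, seg: np.ndarray) -> pd.Series:
    """Per-family OLS slope of the phenotype on founder dosage (unshrunk)."""
    fam_idx = ctx.geno.family_indices()
    fams = list(ctx.geno.families)
    out = {}
    for fam in seg:
        rows = fam_idx == fams.index(fam)
        dos = (2.0 - ctx.geno.codes[rows, k]).astype(float)
        yv = ctx.y[rows]
        vx = dos.var()
        if vx <= 0:
            continue
        out[fam] = float(np.cov(dos, yv, bias=True)[0, 1] / vx)
    return pd.Series(out, dtype=float)


def collect_effects(
    geno: GenotypeMatrix,
    pheno_adj: pd.DataFrame,
    marker_id: str,
    *,
    contexts: dict[str, _EnvContext] | None = None,
    mode: str = "fast",
    effects: str = "ols",
    parent_of_family: Mapping[str, str] | None = None,
) -> EffectPanel:
    """Estimate one marker's family allele effects in every environment.

    ``A[f, j]`` is the allele effect of family *f* in environment *j* and
    ``N[f, j]`` the number of plot records behind it (0 when the family is
    absent or the marker does not segregate there).  With
    ``effects="ols"`` (default) the effects are unshrunk within-family OLS
    slopes on founder dosage, whose sampling variance scales with 1/N as
    the weighted meta-model assumes.  ``effects="blup"`` uses the
    mixed-model shrinkage estimates from the per-environment marker test
    instead; note that REML boundary fits then produce identically-zero
    effect columns whose shrinkage is inconsistent across environments,
    which can mimic multiplicative structure.
    """
    if effects not in ("ols", "blup"):
        raise ValueError(f"unknown effects estimator {effects!r}")
    if contexts is None:
        contexts = build_env_contexts(geno, pheno_adj)
    families = list(geno.families)
    envs = list(contexts)
    A = pd.DataFrame(0.0, index=families, columns=envs)
    N = pd.DataFrame(0.0, index=families, columns=envs)
    seg_families: set = set()
    for env, ctx in contexts.items():
        k = ctx.marker_pos.get(marker_id)
        if k is None:
            continue
        seg = ctx.incidence.segregating_families(k)
        seg_families.update(seg)
        if len(seg) == 0:
            continue
        if effects == "ols":
            eff = _ols_family_effects(ctx, k, seg)
        else:
            Z = ctx.incidence.incidence(k, segregating_only=True)
            eff = test_marker(
                Z,
                ctx.null,
                ctx.y,
                None,
                ctx.kinship,
                marker_id=marker_id,
                families=seg,
                mode=mode,
            ).family_effects
        for fam in seg:
            if fam in eff.index:
                A.loc[fam, env] = float(eff[fam])
                N.loc[fam, env] = float(ctx.record_counts.get(fam, 0))
    if len(seg_families) < 2:
        raise InsufficientSegregationError(
            f"marker {marker_id} segregates in fewer than 2 families"
        )
    return EffectPanel(
        marker_id=marker_id,
        A=A,
        N=N,
        parent_of_family=dict(parent_of_family or {}),
    )


def n_informative_envs(panel: EffectPanel) -> int:
    """Environments carrying a nonzero observed allele-effect estimate.

    An environment whose per-environment scan put the marker variance on
    the REML boundary contributes identically-zero effects; such columns
    support no interaction contrast.  With fewer than 3 informative
    environments the weighted row-centered residual matrix is (generically)
    exactly rank 1 and the rank-1 alternative saturates (RSS1 = 0), so the
    profiled-likelihood test is undefined.
    """
    A = panel.A.to_numpy()
    mask = panel.mask()
    return int(((np.abs(A) > 0) & mask).any(axis=0).sum())


def gei_test_marker(panel: EffectPanel, *, threshold: float = DEFAULT_GEI_THRESHOLD, masked: bool = False) -> GeiTest:
    """Null fit, rank-1 extraction and LRT for one collected panel."""
    null = fit_meta_null(panel)
    alt = rank1_interaction(null, masked=masked)
    return gei_lrt(panel, null, alt, threshold=threshold)


def gei_scan(
    geno: GenotypeMatrix,
    pheno_adj: pd.DataFrame,
    marker_ids: Sequence[str] | None = None,
    *,
    threshold: float = DEFAULT_GEI_THRESHOLD,
    mode: str = "fast",
    effects: str = "ols",
    masked: bool = False,
    parent_of_family: Mapping[str, str] | None = None,
) -> list[GeiTest]:
    """Meta-analysis LRT over a set of markers (all markers by default).

    Markers that cannot support the test are skipped: segregation in fewer
    than 2 families (the meta-model is undefined), an all-zero effect panel
    (no allele signal anywhere), or fewer than 3 informative environments
    (the rank-1 alternative saturates exactly; see
    :func:`n_informative_envs`).  The scan is deterministic given its
    inputs.
    """
    contexts = build_env_contexts(geno, pheno_adj)
    if len(contexts) < 2:
        raise DegenerateInputError("GEI meta-analysis needs at least 2 environments")
    if marker_ids is None:
        marker_ids = [str(m) for m in geno.marker_ids]
    out: list[GeiTest] = []
    for m in marker_ids:
        try:
            panel = collect_effects(
                geno, pheno_adj, m, contexts=contexts, mode=mode,
                effects=effects, parent_of_family=parent_of_family,
            )
        except InsufficientSegregationError:
            continue
        if n_informative_envs(panel) < 3:
            continue
        out.append(gei_test_marker(panel, threshold=threshold, masked=masked))
    return out


def gei_frame(tests: Sequence[GeiTest], marker_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate GEI tests; optionally join chromosome/position columns."""
    df = pd.DataFrame(
        {
            "marker_id": [t.marker_id for t in tests],
            "lrt": [t.lrt for t in tests],
            "df": [t.df for t in tests],
            "pvalue": [t.pvalue for t in tests],
            "neglog10p": [t.neglog10p for t in tests],
            "pc_load": [t.pc_load for t in tests],
            "n_parents": [t.n_parents for t in tests],
            "n_env": [t.n_env for t in tests],
            "significant": [t.significant for t in tests],
        }
    )
    if marker_map is not None:
        df = marker_map.merge(df, on="marker_id", how="right")
    return df
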