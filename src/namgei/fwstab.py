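"""Finlay-Wilkinson joint regression and the stability GWAS.

Each RIL's yields are regressed on an environmental productivity index (the
mean yield of all test entries per environment, centered).  The regression
slope b is the FW stability index: b = 1 is the population-average response
(dynamic stability), b = 0 a flat response (static stability), b > 1 above-
average sensitivity to environmental quality.  The slope itself is then
used as the phenotype of a genome-wide association scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDesignError
from .genomat import GenotypeMatrix, recode_parental_origin
from .mmassoc import ScanResult, genome_scan


@dataclass
class EnvIndex:
    """Environmental productivity index: per-environment mean yields."""

    means: pd.Series
    centered: pd.Series

    def __post_init__(self) -> None:
        self.means = self.means.astype(float)
        self.centered = self.centered.astype(float)


def environment_index(pheno: pd.DataFrame) -> EnvIndex:
    """Mean non-check yield per environment, plus its centered version."""
    df = pheno[~pheno["is_check"]] if "is_check" in pheno.columns else pheno
    means = df.groupby("env")["yield"].mean()
    if len(means) < 2:
        raise InvalidDesignError("Finlay-Wilkinson needs at least 2 environments")
    return EnvIndex(means=means, centered=means - means.mean())


@dataclass
class FwFit:
    """Per-RIL FW regression results.

    ``table`` has columns ``ril_id, slope, intercept, deviation_mse, n_env``;
    the slope is NaN for RILs observed in fewer than ``min_env``
    environments.  The intercept is the fitted yield at the average
    environment (centered index 0), in kg/ha.
    """

    table: pd.DataFrame
    index: EnvIndex
    min_env: int

    def slopes(self) -> pd.Series:
        s = self.table.set_index("ril_id")["slope"]
        return s.dropna()


def fw_regression(pheno: pd.DataFrame, index: EnvIndex | None = None, *, min_env: int = 3) -> FwFit:
    """Ordinary least squares of each RIL's yields on the centered index.

    RILs are regressed only over the environments where they were observed;
    with fewer than ``min_env`` observed environments (default 3 — two
    points would fit perfectly) the slope is undefined.  ``deviation_mse``
    is the residual mean square on n_env - 2 degrees of freedom.
    """
    df = pheno[~pheno["is_check"]] if "is_check" in pheno.columns else pheno
    if index is None:
        index = environment_index(df)
    # one observation per (RIL, env): average duplicate plots first
    cell = df.groupby(["ril_id", "env"], sort=True)["yield"].mean().reset_index()
    cell["x"] = index.centered.reindex(cell["env"]).to_numpy()

    g = cell.groupby("ril_id", sort=True)
    n = g.size()
    sx = g["x"].sum()
    sy = g["yield"].sum()
    sxx = g.apply(lambda t: float(np.dot(t["x"], t["x"])), include_groups=False)
    sxy = g.apply(lambda t: float(np.dot(t["x"], t["yield"])), include_groups=False)
    syy = g.apply(lambda t: float(np.dot(t["yield"], t["yield"])), include_groups=False)

    cxx = sxx - sx * sx / n
    cxy = sxy - sx * sy / n
    cyy = syy - sy * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cxy / cxx
        intercept = sy / n - slope * (sx / n)
        rss = cyy - cxy * cxy / cxx
        dev_mse = rss / (n - 2).clip(lower=1)
    bad = (n < min_env) | ~np.isfinite(slope)
    slope[bad] = np.nan
    intercept[bad] = np.nan
    dev_mse[bad] = np.nan
    dev_mse = dev_mse.clip(lower=0.0)

    table = pd.DataFrame(
        {
            "ril_id": n.index,
            "slope": slope.to_numpy(dtype=float),
            "intercept": intercept.to_numpy(dtype=float),
            "deviation_mse": dev_mse.to_numpy(dtype=float),
            "n_env": n.to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    return FwFit(table=table, index=index, min_env=min_env)


def marker_adjusted_r2(geno: GenotypeMatrix, y: pd.Series) -> pd.Series:
    """Adjusted R^2 of the phenotype on founder dosage, marker by marker.

    Fixed-effect OLS of y on the segregating-family dosage columns; a
    descriptive variance-explained companion to the mixed-model LRT.
    """
    y = y.dropna()
    pos = {r: i for i, r in enumerate(geno.ril_ids)}
    keep = np.array([pos[r] for r in y.index if r in pos], dtype=int)
    sub = geno.subset_rils(keep)
    inc = recode_parental_origin(sub)
    yv = y.reindex(sub.ril_ids).to_numpy(dtype=float)
    yc = yv - yv.mean()
    tss = float(yc @ yc)
    n = len(yv)
    out = np.zeros(sub.n_markers)
    for k in range(sub.n_markers):
        Z = inc.incidence(k, segregating_only=True)
        p = Z.shape[1]
        if p == 0 or tss <= 0 or n - p - 1 <= 0:
            out[k] = 0.0
            continue
        Zc = Z - Z.mean(axis=0, keepdims=True)
        coef, rss_arr, *_ = np.linalg.lstsq(Zc, yc, rcond=None)
        rss = float(rss_arr[0]) if rss_arr.size else float(np.sum((yc - Zc @ coef) ** 2))
        r2 = 1.0 - rss / tss
        out[k] = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return pd.Series(out, index=pd.Index(sub.marker_ids, name="marker_id"), name="adj_r2")


def stability_gwas(
    geno: GenotypeMatrix,
    fwfit: FwFit,
    alpha_level: float = 0.05,
    *,
    mode: str = "fast",
    pvalue_law: str = "chi2_0.5df",
) -> ScanResult:
    """Genome scan with the FW slope as the phenotype.

    One record per RIL, no blocks; the returned scan also carries the
    per-marker adjusted R^2 of the slope on founder dosage.
    """
    slopes = fwfit.slopes()
    if slopes.empty:
        raise InvalidDesignError("no RIL has a defined FW slope")
    scan = genome_scan(
        geno,
        slopes,
        alpha_level,
        mode=mode,
        pvalue_law=pvalue_law,
        environment="fw_slope",
    )
    scan.adj_r2 = marker_adjusted_r2(geno, slopes)
    return scan
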