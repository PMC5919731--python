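"""End-to-end orchestration: impute, recode, scan, FW, GEI, clustering."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .envtools import cluster_environments, env_profiles
from .errors import InsufficientSegregationError, ValidationError
from .fwstab import environment_index, fw_regression, stability_gwas
from .genomat import GenotypeMatrix, compute_kinship, impute_missing, recode_parental_origin
from .geimeta import DEFAULT_GEI_THRESHOLD, gei_frame, gei_scan
from .mmassoc import adjust_by_checks, scan_environment
from .io import write_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable thresholds and modes of the full pipeline."""

    alpha_level: float = 0.05
    gei_threshold_neglog10p: float = DEFAULT_GEI_THRESHOLD
    pvalue_law: str = "chi2_0.5df"
    fast_scan_mode: bool = True
    min_env_for_fw: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_level < 1.0):
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.gei_threshold_neglog10p <= 0:
            raise ValueError("gei_threshold_neglog10p must be > 0")
        if self.pvalue_law not in ("chi2_0.5df", "mixture_0_1"):
            raise ValueError(f"unknown pvalue_law {self.pvalue_law!r}")


def validate_ids(geno: GenotypeMatrix, pheno: pd.DataFrame) -> None:
    """Every non-check phenotype RIL must be genotyped."""
    known = set(geno.ril_ids)
    tests = pheno[~pheno["is_check"]] if "is_check" in pheno.columns else pheno
    orphans = sorted(set(tests["ril_id"]) - known)
    if orphans:
        shown = ", ".join(map(str, orphans[:10]))
        more = f" (+{len(orphans) - 10} more)" if len(orphans) > 10 else ""
        raise ValidationError(f"phenotype RILs missing from genotypes: {shown}{more}")


def run_pipeline(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every analysis stage and write all outputs under ``out_dir``.

    Stages: impute missing calls, parental-origin recoding, kinship,
    check-based field adjustment, per-environment association scans, FW
    regression and stability GWAS, GEI meta-scan, environment clustering.
    Returns the run manifest (also written as ``manifest.json``).
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = "fast" if config.fast_scan_mode else "full"

    validate_ids(geno, pheno)
    logger.info("imputing %d RILs x %d markers", geno.n_rils, geno.n_markers)
    geno = impute_missing(geno)
    recode_parental_origin(geno)  # validates; rebuilt per RIL subset downstream
    compute_kinship(geno)
    adj = adjust_by_checks(pheno)

    envs = sorted(pd.unique(adj["env"]))
    summary: list[str] = []
    scan_frames, effect_frames = [], []
    for env in envs:
        logger.info("scanning environment %s", env)
        scan = scan_environment(
            geno, adj, env, config.alpha_level, mode=mode, pvalue_law=config.pvalue_law
        )
        df = scan.to_frame(geno.marker_map)
        scan_frames.append(df)
        eff = scan.effects_frame()
        eff.insert(1, "env", env)
        effect_frames.append(eff)
        hits = df[df["neglog10p"] >= scan.threshold]["marker_id"].tolist()
        summary.append(f"[{env}] markers above Bonferroni ({scan.threshold:.3f}): {hits}")
    write_table(pd.concat(scan_frames, ignore_index=True), out / "scan_by_env.tsv")
    write_table(pd.concat(effect_frames, ignore_index=True), out / "scan_effects.tsv")

    index = environment_index(adj)
    fw = fw_regression(adj, index, min_env=config.min_env_for_fw)
    fam_of = pd.Series(geno.family_ids, index=pd.Index(geno.ril_ids, name="ril_id"))
    fw_table = fw.table.copy()
    fw_table.insert(1, "family_id", fam_of.reindex(fw_table["ril_id"]).to_numpy())
    write_table(fw_table, out / "fw.tsv")

    fw_scan = stability_gwas(geno, fw, config.alpha_level, mode=mode, pvalue_law=config.pvalue_law)
    fw_df = fw_scan.to_frame(geno.marker_map)
    write_table(fw_df, out / "fw_gwas.tsv")
    fw_hits = fw_df[fw_df["neglog10p"] >= fw_scan.threshold]["marker_id"].tolist()
    summary.append(f"[fw] markers above Bonferroni ({fw_scan.threshold:.3f}): {fw_hits}")

    try:
        gtests = gei_scan(geno, adj, threshold=config.gei_threshold_neglog10p, mode=mode)
        gdf = gei_frame(gtests, geno.marker_map)
        write_table(gdf, out / "gei.tsv")
        ghits = gdf[gdf["significant"]]["marker_id"].tolist()
        summary.append(
            f"[gei] markers above -log10 p {config.gei_threshold_neglog10p:g}: {ghits}"
        )
    except InsufficientSegregationError as exc:  # pragma: no cover - degenerate inputs
        summary.append(f"[gei] skipped: {exc}")

    profiles = env_profiles(adj, fam_of)
    dend = cluster_environments(profiles)
    (out / "env_clusters.nwk").write_text(dend.to_newick() + "\n")
    write_table(dend.merge_heights_frame(), out / "env_cluster_heights.tsv")

    manifest = {
        "package": "namgei",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "n_rils": int(geno.n_rils),
        "n_markers": int(geno.n_markers),
        "environments": [str(e) for e in envs],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest
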