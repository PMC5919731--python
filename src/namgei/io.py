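"""Readers and writers for the package's plain-text file formats.

Genotype CSV: rows = RILs, first columns ``ril_id,family_id``, then one
column per marker with codes 0/1/2 (``NA`` for missing).  Marker map CSV:
``marker_id,chrom,pos``.  Phenotype TSV: ``ril_id,env,block,yield,is_check``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genomat import MISSING, GenotypeMatrix


def write_genotypes(geno: GenotypeMatrix, geno_path: str | Path, map_path: str | Path) -> None:
    codes = geno.codes.astype(object)
    codes[geno.codes == MISSING] = pd.NA
    df = pd.DataFrame(codes, columns=list(geno.marker_ids))
    df.insert(0, "family_id", geno.family_ids)
    df.insert(0, "ril_id", geno.ril_ids)
    df.to_csv(geno_path, index=False)
    geno.marker_map.to_csv(map_path, index=False)


def read_genotypes(geno_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(geno_path, dtype={"ril_id": str, "family_id": str})
    marker_map = pd.read_csv(map_path)
    marker_ids = [c for c in df.columns if c not in ("ril_id", "family_id")]
    codes = df[marker_ids].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(
        codes=codes,
        ril_ids=df["ril_id"].to_numpy(dtype=object),
        family_ids=df["family_id"].to_numpy(dtype=object),
        marker_ids=np.array(marker_ids, dtype=object),
        marker_map=marker_map,
    )


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    cols = ["ril_id", "env", "block", "yield", "is_check"]
    pheno[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ril_id": str, "env": str})
    df["is_check"] = df["is_check"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
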