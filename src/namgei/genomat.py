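"""Genotype containers, parental-origin recoding, imputation and kinship.

Genotype codes are oriented toward the shared (common) parent of the NAM
population: at every marker, ``2`` is homozygous for the common-parent
allele, ``0`` homozygous for the family-specific founder allele and ``1``
heterozygous.  Founder-allele dosage is therefore ``2 - code``.  Missing
calls use the sentinel :data:`MISSING`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """RIL-by-marker genotype codes with family labels and a marker map.

    Parameters
    ----------
    codes
        ``(n_rils, n_markers)`` integer array with entries in ``{0, 1, 2}``
        or :data:`MISSING`.
    ril_ids, family_ids
        Per-RIL identifiers; ``family_ids[i]`` is the biparental family of
        ``ril_ids[i]``.
    marker_ids
        Per-marker identifiers, aligned with the columns of ``codes``.
    marker_map
        DataFrame with columns ``marker_id, chrom, pos``.
    """

    codes: np.ndarray
    ril_ids: np.ndarray
    family_ids: np.ndarray
    marker_ids: np.ndarray
    marker_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.ril_ids = np.asarray(self.ril_ids, dtype=object)
        self.family_ids = np.asarray(self.family_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        n, m = self.codes.shape
        if len(self.ril_ids) != n or len(self.family_ids) != n:
            raise ValueError("ril_ids/family_ids length must match codes rows")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length must match codes columns")
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if set(self.marker_map["marker_id"]) != set(self.marker_ids):
            raise ValueError("marker_map does not cover marker_ids")

    @property
    def n_rils(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def families(self) -> np.ndarray:
        """Unique family labels in order of first appearance."""
        _, idx = np.unique(self.family_ids, return_index=True)
        return self.family_ids[np.sort(idx)]

    @property
    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def family_indices(self) -> np.ndarray:
        """Per-RIL integer index into :attr:`families`."""
        fams = self.families
        lookup = {f: i for i, f in enumerate(fams)}
        return np.array([lookup[f] for f in self.family_ids], dtype=np.int64)

    def subset_rils(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Restrict to a boolean mask or integer index array over RILs."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            codes=self.codes[keep].copy(),
            ril_ids=self.ril_ids[keep].copy(),
            family_ids=self.family_ids[keep].copy(),
            marker_ids=self.marker_ids.copy(),
            marker_map=self.marker_map.copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset_rils(np.arange(self.n_rils))


def _family_code_counts(geno: GenotypeMatrix) -> np.ndarray:
    """Counts of each code per (family, code, marker): shape (n_fam, 3, n_markers)."""
    fams = geno.families
    counts = np.zeros((len(fams), 3, geno.n_markers), dtype=np.int64)
    fam_idx = geno.family_indices()
    for fi in range(len(fams)):
        sub = geno.codes[fam_idx == fi]
        for c in range(3):
            counts[fi, c] = (sub == c).sum(axis=0)
    return counts


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls with the within-family modal code at each marker.

    Ties break toward the lower code.  A (family, marker) cell with no
    observed call falls back to the family's overall modal code across all
    markers (and to the common-parent homozygote if the family has no calls
    at all).  The operation is deterministic and always succeeds.
    """
    if not geno.has_missing:
        return geno
    out = geno.copy()
    fam_idx = out.family_indices()
    counts = _family_code_counts(out)
    for fi in range(len(out.families)):
        rows = fam_idx == fi
        sub = out.codes[rows]
        miss = sub == MISSING
        if not miss.any():
            continue
        cnt = counts[fi]  # (3, n_markers)
        # argmax over the code axis breaks ties toward the lower code
        mode = cnt.argmax(axis=0).astype(np.int8)
        empty = cnt.sum(axis=0) == 0
        if empty.any():
            observed = sub[sub != MISSING]
            fam_mode = (
                np.int8(np.bincount(observed, minlength=3).argmax())
                if observed.size
                else np.int8(2)
            )
            mode[empty] = fam_mode
        fill = np.broadcast_to(mode, sub.shape)
        sub[miss] = fill[miss]
        out.codes[rows] = sub
    return out


@dataclass
class ParentalIncidence:
    """Marker-by-family incidence of founder-allele dosage.

    For a RIL in family *f* with code *c* at marker *k*, the incidence
    matrix ``Z_k`` has ``2 - c`` in column *f* and zeros elsewhere; columns
    of families where the marker does not segregate are zeroed.  This is
    the random-effect design of the multiparental association model, which
    lets one marker carry a different allele effect in every family.
    """

    geno: GenotypeMatrix = field(repr=False)
    families: np.ndarray = field(init=False)
    _fam_idx: np.ndarray = field(init=False, repr=False)
    _seg: np.ndarray = field(init=False, repr=False)  # (n_markers, n_families)

    def __post_init__(self) -> None:
        if self.geno.has_missing:
            raise ValueError("genotypes contain missing calls; run impute_missing first")
        self.families = self.geno.families
        self._fam_idx = self.geno.family_indices()
        counts = _family_code_counts(self.geno)  # (n_fam, 3, n_markers)
        n0, n1, n2 = counts[:, 0, :], counts[:, 1, :], counts[:, 2, :]
        # segregating: a het observed, or both homozygote classes observed
        self._seg = ((n1 > 0) | ((n0 > 0) & (n2 > 0))).T  # (n_markers, n_fam)

    @property
    def n_markers(self) -> int:
        return self.geno.n_markers

    def segregating_mask(self, k: int) -> np.ndarray:
        """Boolean per-family segregation indicator at marker ``k``."""
        return self._seg[k]

    def segregating_families(self, k: int) -> np.ndarray:
        return self.families[self._seg[k]]

    def dosage(self, k: int) -> np.ndarray:
        """Founder-allele dosage ``2 - code`` per RIL at marker ``k``."""
        return (2 - self.geno.codes[:, k]).astype(np.float64)

    def incidence(self, k: int, *, segregating_only: bool = False) -> np.ndarray:
        """Dense ``Z_k``: RIL x family founder-allele dosage at marker ``k``.

        With ``segregating_only`` the columns are restricted to families in
        which the marker segregates (the form entering the mixed model).
        """
        dos = self.dosage(k)
        z = np.zeros((self.geno.n_rils, len(self.families)))
        z[np.arange(self.geno.n_rils), self._fam_idx] = dos
        z[:, ~self._seg[k]] = 0.0
        if segregating_only:
            z = z[:, self._seg[k]]
        return z


def recode_parental_origin(geno: GenotypeMatrix) -> ParentalIncidence:
    """Recode genotypes into per-marker RIL x family founder-dosage incidence."""
    return ParentalIncidence(geno)


@dataclass
class Kinship:
    """Genomic relationship matrix ``K = alpha * M M'`` from centered codes.

    ``scale_constant`` is the ``alpha`` chosen so that ``mean(diag(K)) = 1``,
    putting the polygenic variance on the phenotypic scale.
    """

    matrix: np.ndarray
    scale_constant: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_kinship(geno: GenotypeMatrix) -> Kinship:
    """Additive linear-kernel relationship matrix from marker-centered codes."""
    if geno.has_missing:
        raise ValueError("genotypes contain missing calls; run impute_missing first")
    if geno.n_rils < 2:
        raise DegenerateInputError("kinship requires at least two RILs")
    M = geno.codes.astype(np.float64)
    M -= M.mean(axis=0, keepdims=True)
    G = M @ M.T
    mean_diag = float(np.mean(np.diag(G)))
    if mean_diag <= 0:
        raise DegenerateInputError("all markers are monomorphic; kinship undefined")
    alpha = 1.0 / mean_diag
    K = G * alpha
    K = (K + K.T) / 2.0
    return Kinship(matrix=K, scale_constant=alpha)
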