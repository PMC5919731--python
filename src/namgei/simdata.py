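"""Synthetic NAM populations and multi-environment yield trials.

The generator mirrors the statistical structure of a soybean-style nested
association mapping (NAM) experiment: many biparental families sharing one
common parent, F5-derived RILs genotyped at biallelic SNPs coded toward the
common parent, and unreplicated multi-environment yield trials laid out as
augmented designs with repeated check cultivars.

The phenotype model for a RIL *i* grown in environment *j* is

    y_ij = mu + x_j * b_i + sum_q dos_iq * (beta_qf + s_q * l_qj)
         + psi_i + block + e_ij

where ``x_j`` is the centered environment effect, ``b_i`` the RIL's
environmental sensitivity (its true Finlay-Wilkinson slope), ``dos_iq`` the
founder-allele dosage at QTL *q*, ``beta_qf`` the family-specific additive
effect, ``s_q * l_qj`` a rank-1 multiplicative interaction with the
environment loading ``l_qj``, and ``psi_i`` an optional polygenic term drawn
with covariance proportional to the marker kinship.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError
from .genomat import MISSING, GenotypeMatrix

#: Expected heterozygote frequency in an F5-derived RIL (four selfing rounds).
F5_HET_FREQ = 1.0 / 16.0


@dataclass
class NamDesign:
    """Shape of a NAM genotyping panel.

    ``p_family_segregating`` is the probability that a given marker
    segregates in a given family, i.e. that the family founder carries the
    non-common-parent allele; real NAM SNP panels are chosen to maximize
    this, so the default is high.
    """

    n_families: int = 39
    n_rils_per_family: int = 140
    n_markers: int = 500
    n_chromosomes: int = 20
    common_parent_id: str = "CP"
    founder_ids: Sequence[str] | None = None
    p_family_segregating: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise InvalidDesignError("need at least 2 families")
        if self.n_rils_per_family < 1:
            raise InvalidDesignError("need at least 1 RIL per family")
        if self.n_markers < self.n_chromosomes:
            raise InvalidDesignError("need at least one marker per chromosome")
        if self.founder_ids is None:
            self.founder_ids = tuple(f"P{i + 1:02d}" for i in range(self.n_families))
        self.founder_ids = tuple(self.founder_ids)
        if len(self.founder_ids) != self.n_families:
            raise InvalidDesignError("founder_ids must have one entry per family")
        if len(set(self.founder_ids)) != self.n_families:
            raise InvalidDesignError("founder_ids must be distinct")
        if self.common_parent_id in self.founder_ids:
            raise InvalidDesignError("common parent cannot also be a family founder")

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(f"F{i + 1:02d}" for i in range(self.n_families))


def simulate_genotypes(design: NamDesign) -> GenotypeMatrix:
    """Draw RIL genotypes at F5 expected genotype frequencies.

    Markers are simulated independently within family (linkage is not
    modeled; the downstream tests operate marker by marker).  At a
    segregating marker the genotype frequencies are the F5 expectations
    P(het) = 1/16 and P(either homozygote) = 15/32; at a non-segregating
    marker every RIL is homozygous for the shared allele (code 2).  Markers
    are assigned to chromosomes contiguously.
    """
    rng = np.random.default_rng(design.seed)
    n_fam, n_ril, m = design.n_families, design.n_rils_per_family, design.n_markers

    codes = np.empty((n_fam * n_ril, m), dtype=np.int8)
    ril_ids, family_ids = [], []
    p_hom = (1.0 - F5_HET_FREQ) / 2.0
    for fi, fam in enumerate(design.family_ids):
        seg = rng.random(m) < design.p_family_segregating
        block = np.full((n_ril, m), 2, dtype=np.int8)
        n_seg = int(seg.sum())
        if n_seg:
            block[:, seg] = rng.choice(
                np.array([0, 1, 2], dtype=np.int8),
                size=(n_ril, n_seg),
                p=[p_hom, F5_HET_FREQ, p_hom],
            )
        codes[fi * n_ril : (fi + 1) * n_ril] = block
        ril_ids.extend(f"{fam}_R{r + 1:03d}" for r in range(n_ril))
        family_ids.extend([fam] * n_ril)

    chrom_of = np.concatenate(
        [np.full(len(part), c + 1) for c, part in enumerate(np.array_split(np.arange(m), design.n_chromosomes))]
    )
    pos = np.zeros(m, dtype=np.int64)
    for c in np.unique(chrom_of):
        on_c = chrom_of == c
        pos[on_c] = (np.arange(int(on_c.sum())) + 1) * 100_000
    marker_ids = np.array([f"M{k + 1:05d}" for k in range(m)], dtype=object)
    marker_map = pd.DataFrame({"marker_id": marker_ids, "chrom": chrom_of, "pos": pos})

    return GenotypeMatrix(
        codes=codes,
        ril_ids=np.array(ril_ids, dtype=object),
        family_ids=np.array(family_ids, dtype=object),
        marker_ids=marker_ids,
        marker_map=marker_map,
    )


@dataclass
class TrialDesign:
    """Multi-environment trial layout: environments, blocks, checks, noise.

    ``presence`` gives the per-(family, environment) inclusion fraction in
    [0, 1] (rows = families, columns = environments); ``None`` means every
    family is fully present everywhere.  ``env_effects`` are absolute
    environment mean yields in kg/ha.
    """

    environments: Sequence[str]
    env_effects: Sequence[float]
    presence: pd.DataFrame | None = None
    n_blocks_per_env: int = 4
    block_sd: float = 100.0
    check_ids: Sequence[str] = ("CHK1", "CHK2", "CHK3")
    check_offsets: Sequence[float] | None = None
    residual_sd: float = 450.0

    def __post_init__(self) -> None:
        self.environments = tuple(self.environments)
        self.env_effects = np.asarray(self.env_effects, dtype=float)
        if len(self.environments) < 2:
            raise InvalidDesignError("need at least 2 environments")
        if len(self.env_effects) != len(self.environments):
            raise InvalidDesignError("env_effects must align with environments")
        if self.n_blocks_per_env < 1:
            raise InvalidDesignError("every environment needs at least one block")
        if not self.check_ids:
            raise InvalidDesignError("check_ids must be nonempty")
        self.check_ids = tuple(self.check_ids)
        if self.check_offsets is None:
            # symmetric spread of genotype-free check means around the env mean
            k = len(self.check_ids)
            self.check_offsets = tuple(150.0 * (i - (k - 1) / 2.0) for i in range(k))
        self.check_offsets = tuple(self.check_offsets)
        if len(self.check_offsets) != len(self.check_ids):
            raise InvalidDesignError("check_offsets must align with check_ids")
        if self.presence is not None:
            if list(self.presence.columns) != list(self.environments):
                raise InvalidDesignError("presence columns must equal environments")
            vals = self.presence.to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise InvalidDesignError("presence fractions must lie in [0, 1]")


@dataclass
class QtlSpec:
    """One simulated QTL: family main effects plus a rank-1 GEI term.

    ``family_effects`` (kg/ha per founder-allele dosage, one per family) are
    the additive effects; the interaction contribution of environment *j* is
    ``interaction_scale * env_loadings[j]`` per dosage, shared across
    families (a rank-1 family-uniform multiplicative structure).  When used
    as a sensitivity QTL the family effects are in slope units per dosage
    and the interaction fields are ignored.
    """

    marker_index: int
    family_effects: Sequence[float]
    env_loadings: Sequence[float] | None = None
    interaction_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.interaction_scale < 0:
            raise InvalidDesignError("interaction_scale must be >= 0")
        self.family_effects = np.asarray(self.family_effects, dtype=float)
        if self.env_loadings is not None:
            self.env_loadings = np.asarray(self.env_loadings, dtype=float)


@dataclass
class SensitivitySpec:
    """Distribution of per-RIL environmental sensitivity (true FW slopes)."""

    slope_mean: float = 1.0
    slope_sd: float = 0.2
    genetic_slope_markers: Sequence[QtlSpec] = ()

    def __post_init__(self) -> None:
        if self.slope_sd < 0:
            raise InvalidDesignError("slope_sd must be >= 0")
        self.genetic_slope_markers = tuple(self.genetic_slope_markers)


@dataclass
class PhenoSim:
    """Simulated phenotypes plus the ground truth used by test harnesses."""

    pheno: pd.DataFrame
    true_slopes: pd.Series
    qtls: tuple[QtlSpec, ...]
    trial: TrialDesign


def simulate_phenotypes(
    geno: GenotypeMatrix,
    trial: TrialDesign,
    qtls: Sequence[QtlSpec] = (),
    sens: SensitivitySpec | None = None,
    seed: int = 0,
    polygenic_sd: float = 0.0,
) -> PhenoSim:
    """Generate one plot record per retained (RIL, environment) pair.

    Checks are genotype-free entries replicated in every block of every
    environment.  The returned table has columns
    ``ril_id, env, block, yield, is_check`` and is byte-identical across
    calls with equal seeds.
    """
    if sens is None:
        sens = SensitivitySpec()
    n_env = len(trial.environments)
    fams = list(geno.families)
    fam_idx = geno.family_indices()
    for q in tuple(qtls) + tuple(sens.genetic_slope_markers):
        if not (0 <= q.marker_index < geno.n_markers):
            raise InvalidDesignError(f"QTL marker index {q.marker_index} out of range")
        if len(q.family_effects) != len(fams):
            raise InvalidDesignError("QTL family_effects must have one entry per family")
    for q in qtls:
        if q.interaction_scale > 0 and (q.env_loadings is None or len(q.env_loadings) != n_env):
            raise InvalidDesignError("interacting QTL needs one env_loading per environment")

    rng = np.random.default_rng(seed)
    mu = float(np.mean(trial.env_effects))
    x = trial.env_effects - mu  # centered environment effects

    # true sensitivities
    b = sens.slope_mean + sens.slope_sd * rng.standard_normal(geno.n_rils)
    for q in sens.genetic_slope_markers:
        b += (2.0 - geno.codes[:, q.marker_index]) * q.family_effects[fam_idx]

    # genetic values per (RIL, env)
    g = np.zeros((geno.n_rils, n_env))
    for q in qtls:
        dos = (2.0 - geno.codes[:, q.marker_index]).astype(float)
        per_env = q.family_effects[fam_idx][:, None]
        if q.interaction_scale > 0:
            per_env = per_env + q.interaction_scale * np.asarray(q.env_loadings)[None, :]
        g += dos[:, None] * per_env

    psi = np.zeros(geno.n_rils)
    if polygenic_sd > 0:
        M = geno.codes.astype(float)
        M -= M.mean(axis=0, keepdims=True)
        u = rng.standard_normal(geno.n_markers)
        denom = math.sqrt(float(np.mean(np.sum(M * M, axis=1))))
        if denom > 0:
            psi = (M @ u) * (polygenic_sd / denom)

    if trial.presence is not None:
        pres = trial.presence.reindex(index=fams).to_numpy(dtype=float)
        if np.isnan(pres).any():
            raise InvalidDesignError("presence table missing some families")
    else:
        pres = np.ones((len(fams), n_env))

    block_eff = rng.normal(0.0, trial.block_sd, size=(n_env, trial.n_blocks_per_env))

    recs: list[pd.DataFrame] = []
    for j, env in enumerate(trial.environments):
        keep = rng.random(geno.n_rils) < pres[fam_idx, j]
        idx = np.flatnonzero(keep)
        blocks = (np.arange(len(idx)) % trial.n_blocks_per_env) + 1
        noise = rng.normal(0.0, trial.residual_sd, size=len(idx))
        y = mu + x[j] * b[idx] + g[idx, j] + psi[idx] + block_eff[j, blocks - 1] + noise
        recs.append(
            pd.DataFrame(
                {
                    "ril_id": geno.ril_ids[idx],
                    "env": env,
                    "block": blocks,
                    "yield": y,
                    "is_check": False,
                }
            )
        )
        # check plots: every check entry once per block
        n_chk = len(trial.check_ids)
        chk_block = np.repeat(np.arange(1, trial.n_blocks_per_env + 1), n_chk)
        chk_ids = np.tile(np.array(trial.check_ids, dtype=object), trial.n_blocks_per_env)
        chk_off = np.tile(np.asarray(trial.check_offsets, dtype=float), trial.n_blocks_per_env)
        chk_noise = rng.normal(0.0, trial.residual_sd, size=len(chk_ids))
        chk_y = trial.env_effects[j] + chk_off + block_eff[j, chk_block - 1] + chk_noise
        recs.append(
            pd.DataFrame(
                {
                    "ril_id": chk_ids,
                    "env": env,
                    "block": chk_block,
                    "yield": chk_y,
                    "is_check": True,
                }
            )
        )

    pheno = pd.concat(recs, ignore_index=True)
    true_slopes = pd.Series(b, index=pd.Index(geno.ril_ids, name="ril_id"), name="true_slope")
    return PhenoSim(pheno=pheno, true_slopes=true_slopes, qtls=tuple(qtls), trial=trial)


def inject_missing(geno: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set a Bernoulli(rate) random subset of calls to missing."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missingness rate must lie in [0, 1)")
    if rate == 0.0:
        return geno
    out = geno.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(out.codes.shape) < rate
    out.codes[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# SoyNAM-like preset: 18 location-year environments with the published mean
# yields (kg/ha) and an unbalanced family-presence pattern in which partial
# environments host only a subset of families.
# ---------------------------------------------------------------------------

SOYNAM_ENV_MEANS: Mapping[str, float] = {
    "IL2011": 2780.0,
    "NE2011": 5057.0,
    "IA2012": 2776.0,
    "IL2012": 3386.0,
    "IN2012": 4231.0,
    "KS2012": 3871.0,
    "MI2012": 2364.0,
    "MO2012": 3414.0,
    "NE2012": 4728.0,
    "OH1_2012": 3394.0,
    "OH2_2012": 2823.0,
    "IA2013": 2871.0,
    "IL2013": 3115.0,
    "IN2013": 5050.0,
    "KS2013": 2747.0,
    "MO2013": 4091.0,
    "OH1_2013": 3629.0,
    "OH2_2013": 4420.0,
}

#: Fraction of the full RIL set with non-missing plots in each environment.
SOYNAM_ENV_FRACTIONS: Mapping[str, float] = {
    "IL2011": 2500 / 5143,
    "NE2011": 2500 / 5143,
    "IA2012": 5111 / 5143,
    "IL2012": 5138 / 5143,
    "IN2012": 5041 / 5143,
    "KS2012": 3158 / 5143,
    "MI2012": 816 / 5143,
    "MO2012": 819 / 5143,
    "NE2012": 5127 / 5143,
    "OH1_2012": 1606 / 5143,
    "OH2_2012": 1626 / 5143,
    "IA2013": 5100 / 5143,
    "IL2013": 5137 / 5143,
    "IN2013": 5136 / 5143,
    "KS2013": 3230 / 5143,
    "MO2013": 804 / 5143,
    "OH1_2013": 1619 / 5143,
    "OH2_2013": 1571 / 5143,
}


def soynam_trial(
    n_families: int = 39,
    *,
    unbalanced: bool = True,
    within_family_presence: float = 0.97,
    n_blocks_per_env: int = 4,
    block_sd: float = 100.0,
    residual_sd: float = 450.0,
) -> TrialDesign:
    """Trial design with the 18 SoyNAM-like environment means.

    With ``unbalanced``, each environment hosts only the number of families
    implied by its published RIL fraction; which families are present
    rotates deterministically across environments so each family is absent
    from some partial environments, mimicking the partial-RIL-set trials.
    """
    envs = list(SOYNAM_ENV_MEANS)
    effects = [SOYNAM_ENV_MEANS[e] for e in envs]
    presence = None
    if unbalanced:
        fams = [f"F{i + 1:02d}" for i in range(n_families)]
        pres = np.zeros((n_families, len(envs)))
        for j, env in enumerate(envs):
            frac = SOYNAM_ENV_FRACTIONS[env]
            n_present = min(n_families, max(2, round(frac * n_families / within_family_presence)))
            start = (3 * j) % n_families
            cols = (start + np.arange(n_present)) % n_families
            pres[cols, j] = within_family_presence
        presence = pd.DataFrame(pres, index=fams, columns=envs)
    return TrialDesign(
        environments=envs,
        env_effects=effects,
        presence=presence,
        n_blocks_per_env=n_blocks_per_env,
        block_sd=block_sd,
        residual_sd=residual_sd,
    )
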