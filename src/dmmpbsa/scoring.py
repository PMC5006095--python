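"""Score assembly: HADDOCK score, MM-PBSA, and dampened dMM-PBSA.

The binding free energy estimate groups the four binding-difference components
into a polar block (intermolecular Coulomb + polar solvation difference) and a
nonpolar block (intermolecular Lennard-Jones + gamma*SASA difference):

    dG_comp(alpha) = alpha * (dE_coul + dG_polar) + (dE_LJ + dG_nonpolar)

alpha = 1 is canonical MM-PBSA; alpha = 0.2 is the dampened dMM-PBSA variant.
Because alpha only rescales an already-computed block, both scores come from a
single Poisson-Boltzmann calculation per pose.  Cluster statistics use the mean
of the best 4 members and the standard error sigma/sqrt(N).
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

from .mm_energy import NonbondedParams, intermolecular_mm
from .model_io import ChainSplit, EnergyComponents, Structure, split_complex
from .pb_solver import GridSpec, PBError, PBParams, build_grids, polar_solvation
from .surface_area import NonpolarParams, buried_surface_area

logger = logging.getLogger("dmmpbsa")

__all__ = [
    "ScoringParams",
    "HaddockWeights",
    "BindingBreakdown",
    "PoseScore",
    "ClusterScore",
    "ScoringConfig",
    "haddock_score",
    "mmpbsa_energy",
    "score_pose",
    "cluster_best4",
    "rank_clusters",
]

ALPHA_MMPBSA = 1.0
ALPHA_DMMPBSA = 0.2


@dataclass(frozen=True)
class HaddockWeights:
    w_elec: float = 0.2
    w_lj: float = 1.0
    w_desolv: float = 1.0
    w_air: float = 0.1


@dataclass(frozen=True)
class ScoringParams:
    """Dampening factor alpha and the empirical docking-score weights."""

    alpha: float = ALPHA_DMMPBSA
    haddock_weights: HaddockWeights = field(default_factory=HaddockWeights)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            logger.warning("alpha=%s outside [0, 1]; computing anyway", self.alpha)


@dataclass(frozen=True)
class BindingBreakdown:
    """Binding differences (complex minus free partners), kJ/mol."""

    d_ecoul: float
    d_elj: float
    d_gpolar: float
    d_gnonpolar: float

    def __post_init__(self) -> None:
        for name in ("d_ecoul", "d_elj", "d_gpolar", "d_gnonpolar"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def polar_block(self) -> float:
        return self.d_ecoul + self.d_gpolar

    @property
    def nonpolar_block(self) -> float:
        return self.d_elj + self.d_gnonpolar


@dataclass(frozen=True)
class PoseScore:
    pose_id: str
    haddock: float | None  # a.u.; None when desolvation/AIR inputs are absent
    mmpbsa: float          # kJ/mol, alpha = 1
    dmmpbsa: float         # kJ/mol, alpha = 0.2
    breakdown: BindingBreakdown
    bsa: float             # A^2
    haddock_partial: bool = False
    mm_source: str = "computed"


@dataclass
class ClusterScore:
    cluster_id: int
    member_ids: list[str]
    best4_mean: float
    best4_se: float
    n_used: int
    short_cluster: bool = False  # fewer than 4 members were available
    mean_irmsd: float | None = None


@dataclass
class ScoringConfig:
    """Bundle of all parameter blocks used along the scoring pipeline."""

    nonbonded: NonbondedParams = field(default_factory=NonbondedParams)
    pb: PBParams = field(default_factory=PBParams)
    nonpolar: NonpolarParams = field(default_factory=NonpolarParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)


def haddock_score(c: EnergyComponents, params: ScoringParams = ScoringParams()) -> float:
    """Weighted empirical docking score 0.2 E_elec + E_LJ + E_desolv + 0.1 E_AIR."""
    w = params.haddock_weights
    return w.w_elec * c.e_elec + w.w_lj * c.e_lj + w.w_desolv * c.e_desolv + w.w_air * c.e_air


def mmpbsa_energy(b: BindingBreakdown, alpha: float) -> float:
    """dG_comp(alpha) = alpha * (dE_coul + dG_polar) + (dE_LJ + dG_nonpolar)."""
    if not (0.0 <= alpha <= 1.0):
        logger.warning("alpha=%s outside [0, 1]; computing anyway", alpha)
    return alpha * b.polar_block + b.nonpolar_block


def score_pose(
    complex_: Structure,
    split: ChainSplit,
    config: ScoringConfig = None,
    mm_source: str = "computed",
    energy_table: dict[str, EnergyComponents] | None = None,
    pose_id: str | None = None,
    grids: tuple[GridSpec, GridSpec] | None = None,
) -> PoseScore:
    """Full per-pose scoring: split, MM terms, PB polar term, SASA nonpolar term.

    ``mm_source='table'`` takes the intermolecular Coulomb/LJ terms (and the
    desolvation/AIR terms of the empirical docking score) from a parsed decoy
    energy table; ``'computed'`` evaluates them directly from the structure,
    in which case desolvation and AIR default to zero and the docking score is
    flagged partial.  One PB calculation feeds both the alpha=1 and alpha=0.2
    outputs.
    """
    if config is None:
        config = ScoringConfig()
    pose_id = pose_id if pose_id is not None else (complex_.title or "pose")
    receptor, peptide = split_complex(complex_, split)

    if mm_source == "table":
        if energy_table is None or pose_id not in energy_table:
            raise ValueError(f"mm_source='table' but no energy row for pose {pose_id!r}")
        row = energy_table[pose_id]
        d_ecoul, d_elj = row.e_elec, row.e_lj
        e_desolv, e_air = row.e_desolv, row.e_air
        partial = False
    elif mm_source == "computed":
        mm = intermolecular_mm(receptor, peptide, config.nonbonded)
        d_ecoul, d_elj = mm.e_coul, mm.e_lj
        e_desolv, e_air = 0.0, 0.0
        partial = True
    else:
        raise ValueError(f"mm_source must be 'table' or 'computed', got {mm_source!r}")

    polar = polar_solvation(complex_, receptor, peptide, config.pb, grids=grids)
    bsa = buried_surface_area(complex_, receptor, peptide, config.nonpolar)
    # binding nonpolar term: gamma * (SASA_c - SASA_r - SASA_p) = -gamma * BSA
    d_gnonpolar = -config.nonpolar.gamma * bsa

    breakdown = BindingBreakdown(
        d_ecoul=d_ecoul, d_elj=d_elj, d_gpolar=polar.dg_polar, d_gnonpolar=d_gnonpolar
    )
    hs = haddock_score(
        EnergyComponents(pose_id, d_ecoul, d_elj, e_desolv, e_air, max(bsa, 0.0)),
        config.scoring,
    )
    return PoseScore(
        pose_id=pose_id,
        haddock=hs,
        mmpbsa=mmpbsa_energy(breakdown, ALPHA_MMPBSA),
        dmmpbsa=mmpbsa_energy(breakdown, config.scoring.alpha),
        breakdown=breakdown,
        bsa=bsa,
        haddock_partial=partial,
        mm_source=mm_source,
    )


def cluster_best4(
    scores: list[tuple[str, float]],
    members: list[str],
    cluster_id: int = 0,
    n_best: int = 4,
) -> ClusterScore:
    """Mean and standard error over a cluster's ``n_best`` lowest-scoring members.

    SE = sigma/sqrt(N) with the sample (N-1) standard deviation and N the
    number of averaged members.  Clusters with fewer than ``n_best`` members
    use all of them and are flagged ``short_cluster``.
    """
    if not members:
        raise ValueError("cluster has no members")
    lookup = dict(scores)
    missing = [m for m in members if m not in lookup]
    if missing:
        raise ValueError(f"no score for member(s) {missing[:5]}")
    ranked = sorted(members, key=lambda m: (lookup[m], m))
    used = ranked[:n_best]
    vals = [lookup[m] for m in used]
    mean = statistics.fmean(vals)
    if len(vals) > 1:
        se = statistics.stdev(vals) / math.sqrt(len(vals))
    else:
        se = 0.0
    return ClusterScore(
        cluster_id=cluster_id,
        member_ids=list(members),
        best4_mean=mean,
        best4_se=se,
        n_used=len(used),
        short_cluster=len(members) < n_best,
    )


def rank_clusters(clusters: list[ClusterScore]) -> list[ClusterScore]:
    """Ascending by best-4 mean (lower = better); stable tie-break by cluster id."""
    if not clusters:
        raise ValueError("no clusters to rank")
    return sorted(clusters, key=lambda c: (c.best4_mean, c.cluster_id))
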