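"""Computational alanine scanning on fixed docked poses.

A residue is mutated to alanine by truncating its side chain at the beta
carbon (no repacking or minimisation: single-structure end-point convention),
and ddG = dG_wt - dG_mutALA is evaluated under both MM-PBSA (alpha = 1) and
dMM-PBSA (alpha = 0.2).  Wild type and mutant reuse the wild-type complex's PB
grids so that grid-placement artifacts cancel in the difference.  Over a
structural ensemble (e.g. an NMR bundle) the per-structure values are averaged
with standard error sigma/sqrt(N).
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, replace

from .model_io import ChainSplit, ModelError, ParameterTable, Structure, default_parameter_table
from .pb_solver import build_grids
from .scoring import ScoringConfig, score_pose

logger = logging.getLogger("dmmpbsa")

__all__ = ["MutationSpec", "DdgResult", "mutate_to_ala", "ddg_alanine"]

#: atoms retained on truncation to alanine
_ALA_ATOMS = {"N", "H", "CA", "C", "O", "CB", "OXT"}
_FORBIDDEN = {"GLY": "has no CB", "PRO": "backbone is cyclic", "ALA": "already alanine"}


@dataclass(frozen=True)
class MutationSpec:
    """Address of the residue to mutate (target is always alanine)."""

    chain_id: str
    residue_index: int


@dataclass(frozen=True)
class DdgResult:
    ddg_mmpbsa: float          # ensemble mean, kJ/mol
    ddg_dmmpbsa: float         # ensemble mean, kJ/mol
    per_structure: tuple[tuple[float, float], ...]  # (mmpbsa, dmmpbsa) per member
    se_mmpbsa: float
    se_dmmpbsa: float

    def __post_init__(self) -> None:
        if self.se_mmpbsa < 0 or self.se_dmmpbsa < 0:
            raise ValueError("standard errors must be >= 0")


def mutate_to_ala(
    structure: Structure,
    spec: MutationSpec,
    params: ParameterTable | None = None,
) -> Structure:
    """Return a copy with the addressed residue truncated to alanine.

    Side-chain atoms beyond CB are deleted; CB is retyped with alanine's CB
    charge/radius/LJ parameters from the table; the backbone (and every other
    residue) is untouched.  Gly, Pro, and Ala targets are errors.
    """
    if params is None:
        params = default_parameter_table()
    target = [
        a for a in structure.atoms
        if a.chain_id == spec.chain_id and a.residue_index == spec.residue_index
    ]
    if not target:
        raise ModelError(
            f"no residue {spec.residue_index} in chain {spec.chain_id!r}"
        )
    resname = target[0].residue_name
    if resname in _FORBIDDEN:
        raise ModelError(f"cannot mutate {resname} {spec.chain_id}{spec.residue_index}: "
                         f"{_FORBIDDEN[resname]}")
    names = {a.name for a in target}
    if "CB" not in names or not {"N", "CA", "C"}.issubset(names):
        raise ModelError(
            f"residue {resname} {spec.chain_id}{spec.residue_index} lacks backbone + CB atoms"
        )
    ala_cb = params.lookup("ALA", "CB")
    out = []
    for a in structure.atoms:
        if a.chain_id == spec.chain_id and a.residue_index == spec.residue_index:
            if a.name not in _ALA_ATOMS:
                continue  # side chain beyond CB: deleted
            if a.name == "CB":
                a = replace(a, residue_name="ALA", charge=ala_cb.charge,
                            radius=ala_cb.radius, lj_sigma=ala_cb.lj_sigma,
                            lj_epsilon=ala_cb.lj_epsilon)
            else:
                a = replace(a, residue_name="ALA")
        out.append(a)
    return Structure(out, title=f"{structure.title}_{resname}{spec.residue_index}A")


def ddg_alanine(
    ensemble: list[Structure],
    split: ChainSplit,
    spec: MutationSpec,
    config: ScoringConfig | None = None,
    params: ParameterTable | None = None,
) -> DdgResult:
    """ddG = dG_wt - dG_mutALA over a structure ensemble, both alpha values.

    For each member the wild type and the alanine mutant are scored on the
    grids built from the wild-type complex (identical grids, so the grid
    artifacts largely cancel in the difference); the ensemble mean and
    standard error sigma/sqrt(N) are reported with N the ensemble size.
    """
    if not ensemble:
        raise ValueError("ensemble must contain at least one structure")
    if config is None:
        config = ScoringConfig()
    per: list[tuple[float, float]] = []
    for i, wt in enumerate(ensemble):
        mut = mutate_to_ala(wt, spec, params)
        grids = build_grids(wt, config.pb)
        try:
            s_wt = score_pose(wt, split, config, grids=grids, pose_id=f"wt_{i}")
            s_mut = score_pose(mut, split, config, grids=grids, pose_id=f"mut_{i}")
        except Exception as exc:
            raise RuntimeError(f"scoring failed for ensemble member {i}: {exc}") from exc
        per.append((s_wt.mmpbsa - s_mut.mmpbsa, s_wt.dmmpbsa - s_mut.dmmpbsa))
    mm = [v[0] for v in per]
    dmm = [v[1] for v in per]
    n = len(per)
    se = (
        (statistics.stdev(mm) / math.sqrt(n), statistics.stdev(dmm) / math.sqrt(n))
        if n > 1 else (0.0, 0.0)
    )
    return DdgResult(
        ddg_mmpbsa=statistics.fmean(mm),
        ddg_dmmpbsa=statistics.fmean(dmm),
        per_structure=tuple(per),
        se_mmpbsa=se[0],
        se_dmmpbsa=se[1],
    )
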