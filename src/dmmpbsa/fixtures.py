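"""Deterministic synthetic inputs for the whole scoring pipeline.

Everything here is a pure function of (seed, parameters), using the
counter-based Philox generator so outputs are identical across platforms:
Born ions for PB validation, toy protein-peptide complexes with a
cross-interface salt bridge, rigid-body decoy ensembles with controlled
displacement (hence controlled i-RMSD), pseudo docking energy tables, and
synthetic benchmark tables with a tunable population correlation.  These
emulate the statistical structure of real docking output, not protein
topology or force-field realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .evaluation import BenchmarkRecord
from .mm_energy import intermolecular_mm
from .model_io import (
    AtomRecord,
    ChainSplit,
    EnergyComponents,
    Structure,
    split_complex,
    write_decoy_energies,
    write_pqr,
)
from .surface_area import buried_surface_area

__all__ = [
    "FixtureConfig",
    "Decoy",
    "born_ion",
    "toy_complex",
    "make_decoys",
    "decoy_energy_table",
    "synthetic_benchmark",
    "write_fixture_set",
]

#: experimental dG_bind range (kJ/mol) spanned by the 19-complex benchmark
DG_BIND_RANGE = (-45.0, -17.0)


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_poses: int = 200        # docking runs produce 200 models per complex
    displacement_scale: float = 25.0  # A, largest decoy displacement
    n_systems: int = 19
    target_r: float = 0.65

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        if abs(self.target_r) > 1:
            raise ValueError("|target_r| must be <= 1")


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, stream]))


def born_ion(charge: float, radius: float) -> Structure:
    """A single charged sphere at the origin (the PB validation input)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return Structure(
        [AtomRecord(1, "ION", "ION", "A", 1, np.zeros(3), charge, radius)],
        title=f"born_q{charge}_r{radius}",
    )


# residue template: local positions, names, charges (backbone-like, net 0)
_RES_TEMPLATE = [
    ("N", np.array([0.0, 0.0, 0.0]), -0.40, 1.55),
    ("CA", np.array([1.2, 0.6, 0.1]), 0.10, 1.70),
    ("C", np.array([2.4, -0.1, 0.3]), 0.45, 1.70),
    ("O", np.array([2.6, -1.2, 0.7]), -0.15, 1.50),
]
_LJ = {"N": (3.25, 0.711), "C": (3.50, 0.276), "O": (2.96, 0.879)}


def _residue_atoms(serial0, chain, resname, resid, base, jitter, extra=None):
    atoms = []
    serial = serial0
    for k, (name, offset, q, r) in enumerate(_RES_TEMPLATE):
        sigma, eps = _LJ[name[0]]
        atoms.append(
            AtomRecord(serial, name, resname, chain, resid,
                       base + offset + jitter[k], q, r, lj_sigma=sigma, lj_epsilon=eps)
        )
        serial += 1
    if extra is not None:
        name, offset, q, r = extra
        sigma, eps = _LJ[name[0]]
        atoms.append(
            AtomRecord(serial, name, resname, chain, resid,
                       base + offset + jitter[-1], q, r, lj_sigma=sigma, lj_epsilon=eps)
        )
        serial += 1
    return atoms, serial


def toy_complex(seed: int = 0) -> tuple[Structure, ChainSplit]:
    """A rigid ~18-atom receptor (chain A) + ~9-atom peptide (chain B) in contact.

    Four backbone-like receptor residues lie along x; the second carries a
    charged CB-like atom (+0.6 e) pointing up.  The two peptide residues sit
    about 4 A above it, one carrying a -0.6 e side-chain atom, forming a
    cross-interface salt bridge.  Coordinates get a small seeded jitter, so
    different seeds give different (but always contacting) geometries.
    """
    rng = _rng(seed, stream=1)
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(4):
        jitter = 0.15 * rng.standard_normal((5, 3))
        extra = ("CB", np.array([1.2, 1.0, 1.4]), 0.60, 1.70) if i == 1 else None
        res, serial = _residue_atoms(serial, "A", "ALA", i + 1,
                                     np.array([3.1 * i, 0.0, 0.0]), jitter, extra)
        atoms += res
    for j in range(2):
        jitter = 0.15 * rng.standard_normal((5, 3))
        extra = ("CB", np.array([1.2, 0.2, -1.3]), -0.60, 1.70) if j == 0 else None
        res, serial = _residue_atoms(serial, "B", "ALA", j + 1,
                                     np.array([2.0 + 3.1 * j, 1.2, 5.4]), jitter, extra)
        atoms += res
    complex_ = Structure(atoms, title=f"toy_{seed}")
    split = ChainSplit({"A"}, {"B"})
    # contact guarantee: the salt-bridge pair sits ~3-4 A apart
    rec, pep = split_complex(complex_, split)
    dmin = cdist(rec.coords, pep.coords).min()
    assert 2.0 < dmin < 5.0, f"toy complex lost contact (min distance {dmin:.2f})"
    return complex_, split


@dataclass(frozen=True)
class Decoy:
    """One rigid-body pose with its generating transform recorded."""

    structure: Structure
    rotation_deg: float
    translation: tuple[float, float, float]
    displacement: float  # |translation| in A


def make_decoys(
    complex_: Structure, split: ChainSplit, cfg: FixtureConfig = FixtureConfig()
) -> list[Decoy]:
    """Rigid peptide perturbations spanning near-native to far-displaced poses.

    Pose 0 is the unperturbed complex; subsequent poses translate the peptide
    by magnitudes increasing up to ``displacement_scale`` (with seeded jitter
    on direction) and rotate it about its centroid by an angle proportional to
    the displacement.  The true transform is recorded per pose.
    """
    rng = _rng(cfg.seed, stream=2)
    receptor, peptide = split_complex(complex_, split)
    pep_coords = peptide.coords
    centroid = pep_coords.mean(axis=0)
    decoys: list[Decoy] = []
    for p in range(cfg.n_poses):
        if p == 0:
            mag, angle = 0.0, 0.0
            direction = np.zeros(3)
            axis = np.array([0.0, 0.0, 1.0])
        else:
            mag = cfg.displacement_scale * p / (cfg.n_poses - 1 if cfg.n_poses > 1 else 1)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            # push away from the receptor so large displacements always separate
            away = centroid - receptor.coords.mean(axis=0)
            away /= np.linalg.norm(away)
            direction = 0.7 * away + 0.3 * direction
            direction /= np.linalg.norm(direction)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = 4.0 * mag  # degrees
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis)
        new_coords = rot.apply(pep_coords - centroid) + centroid + mag * direction
        atoms = list(receptor.atoms)
        for a, xyz in zip(peptide.atoms, new_coords):
            atoms.append(replace(a, position=xyz))
        decoys.append(
            Decoy(
                structure=Structure(atoms, title=f"{complex_.title}_pose{p}"),
                rotation_deg=angle,
                translation=tuple(mag * direction),
                displacement=float(mag),
            )
        )
    return decoys


def decoy_energy_table(
    decoys: list[Decoy], split: ChainSplit, cfg: FixtureConfig = FixtureConfig()
) -> list[EnergyComponents]:
    """Pseudo docking-energy rows for parser and empirical-score paths.

    Coulomb/LJ terms are computed from each pose; the desolvation and
    restraint-violation columns are synthetic (seeded noise roughly
    proportional to interface burial), since those are docking-engine outputs
    this package only ever reads.
    """
    rng = _rng(cfg.seed, stream=3)
    rows = []
    for d in decoys:
        rec, pep = split_complex(d.structure, split)
        mm = intermolecular_mm(rec, pep)
        bsa = max(buried_surface_area(d.structure, rec, pep), 0.0)
        e_desolv = -0.005 * bsa + rng.normal(0.0, 1.0)
        e_air = abs(rng.normal(0.0, 5.0)) * (1.0 + d.displacement / 5.0)
        rows.append(
            EnergyComponents(
                pose_id=d.structure.title,
                e_elec=mm.e_coul, e_lj=mm.e_lj,
                e_desolv=float(e_desolv), e_air=float(e_air), bsa=float(bsa),
            )
        )
    return rows


def synthetic_benchmark(cfg: FixtureConfig = FixtureConfig()) -> list[BenchmarkRecord]:
    """A benchmark table whose score columns correlate with dG_bind at target_r.

    dG_bind is uniform over the experimental range; each score column is a
    linear transform of standardized dG_bind mixed with Gaussian noise,
    score_z = r z + sqrt(1 - r^2) eps, so the population correlation equals
    ``target_r`` (sign flipped for the BSA column, which anticorrelates with
    binding strength).  At |target_r| = 1 the noise coefficient is exactly
    zero and the sample correlation is 1; a nonzero noise scale would be
    inconsistent there, which this parametrisation rules out by construction.
    K_D is back-computed from dG_bind.
    """
    if cfg.n_systems < 5:
        raise ValueError("need n_systems >= 5")
    r = cfg.target_r
    rng = _rng(cfg.seed, stream=4)
    dg = rng.uniform(*DG_BIND_RANGE, size=cfg.n_systems)
    z = (dg - dg.mean()) / dg.std()

    def column(scale: float, offset: float, sign: float = 1.0) -> np.ndarray:
        eps = rng.standard_normal(cfg.n_systems)
        mixed = sign * r * z + math.sqrt(max(0.0, 1.0 - r * r)) * eps
        return offset + scale * mixed

    haddock = column(25.0, -85.0)
    dg_comp = column(300.0, -800.0)
    d_dg_comp = column(100.0, -330.0)
    vdw = column(60.0, -180.0)
    bsa = np.maximum(column(300.0, 1200.0, sign=-1.0), 50.0)
    records = []
    for i in range(cfg.n_systems):
        records.append(
            BenchmarkRecord(
                system_id=f"SYN{i:02d}_A:B",
                kd=math.exp(dg[i] / (8.31446e-3 * 298.15)),
                dg_bind=float(dg[i]),
                haddock=float(haddock[i]),
                dg_comp=float(dg_comp[i]),
                d_dg_comp=float(d_dg_comp[i]),
                vdw=float(vdw[i]),
                bsa=float(bsa[i]),
            )
        )
    return records


def write_fixture_set(directory: str | Path, cfg: FixtureConfig = FixtureConfig()) -> dict:
    """Write a complete fixture set (PQR decoys, energy TSV, benchmark TSV).

    Returns a manifest of written paths; used by the ``fixtures`` CLI command.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    complex_, split = toy_complex(cfg.seed)
    decoys = make_decoys(complex_, split, cfg)
    pose_dir = directory / "poses"
    pose_dir.mkdir(exist_ok=True)
    pose_paths = []
    for d in decoys:
        p = pose_dir / f"{d.structure.title}.pqr"
        write_pqr(d.structure, p)
        pose_paths.append(str(p))
    energies = decoy_energy_table(decoys, split, cfg)
    energy_path = directory / "energies.tsv"
    write_decoy_energies(energies, energy_path)
    bench = synthetic_benchmark(cfg)
    bench_path = directory / "benchmark.tsv"
    pd.DataFrame(
        [
            {"system_id": b.system_id, "kd": b.kd, "dg_bind": b.dg_bind,
             "haddock": b.haddock, "dg_comp": b.dg_comp, "d_dg_comp": b.d_dg_comp,
             "vdw": b.vdw, "bsa": b.bsa}
            for b in bench
        ]
    ).to_csv(bench_path, sep="\t", index=False)
    native_path = directory / "native.pqr"
    write_pqr(complex_, native_path)
    return {
        "native": str(native_path),
        "poses": pose_paths,
        "energies": str(energy_path),
        "benchmark": str(bench_path),
        "split": "A:B",
    }
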