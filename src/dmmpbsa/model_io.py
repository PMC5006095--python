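"""Molecular structure I/O for MM-PBSA rescoring.

Reads and writes whitespace-separated PQR files (per-atom partial charge and
intrinsic Poisson-Boltzmann radius in the last two numeric columns), reads plain
PDB ATOM records with charge/radius/Lennard-Jones assignment from a bundled
reduced amino-acid parameter table, parses per-pose docking energy tables, and
splits complexes into receptor and peptide selections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dmmpbsa")

__all__ = [
    "AtomRecord",
    "Structure",
    "ChainSplit",
    "EnergyComponents",
    "ParameterTable",
    "read_pqr",
    "write_pqr",
    "read_pdb_assign",
    "read_decoy_energies",
    "write_decoy_energies",
    "split_complex",
    "merge",
    "assign_lj",
    "default_parameter_table",
]


class ModelError(ValueError):
    """Raised for malformed structures, files, or parameter lookups."""


@dataclass
class AtomRecord:
    """One atom: identity, position (A), partial charge (e), PB radius (A).

    ``lj_sigma``/``lj_epsilon`` (A, kJ/mol) are optional Lennard-Jones
    parameters; they are populated by :func:`read_pdb_assign` or by the fixture
    generators and are required only by the direct MM energy fallback.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_index: int
    position: np.ndarray
    charge: float
    radius: float
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.serial <= 0:
            raise ModelError(f"atom serial must be positive, got {self.serial}")
        if not self.name:
            raise ModelError("atom name must be non-empty")
        if self.radius < 0:
            raise ModelError(f"atom {self.serial}: radius must be >= 0, got {self.radius}")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ModelError(f"atom {self.serial}: position must be a finite 3-vector")
        if not math.isfinite(self.charge):
            raise ModelError(f"atom {self.serial}: charge must be finite")


@dataclass
class Structure:
    """An ordered collection of atoms (a complex, a receptor, or a peptide)."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ModelError("a Structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ModelError("atom serials must be unique")
        if not math.isfinite(self.total_charge):
            raise ModelError("total charge must be finite")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def lj_params(self) -> tuple[np.ndarray, np.ndarray]:
        """(sigma, epsilon) arrays; raises if any atom lacks LJ parameters."""
        missing = [a.serial for a in self.atoms if a.lj_sigma is None or a.lj_epsilon is None]
        if missing:
            raise ModelError(f"atoms missing LJ parameters: serials {missing[:5]}...")
        sigma = np.array([a.lj_sigma for a in self.atoms], dtype=float)
        epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        return sigma, epsilon


@dataclass(frozen=True)
class ChainSplit:
    """Partition of a complex's chains into receptor and peptide sides."""

    receptor_chains: frozenset[str]
    peptide_chains: frozenset[str]

    def __init__(self, receptor_chains: Iterable[str], peptide_chains: Iterable[str]):
        object.__setattr__(self, "receptor_chains", frozenset(receptor_chains))
        object.__setattr__(self, "peptide_chains", frozenset(peptide_chains))
        if not self.receptor_chains or not self.peptide_chains:
            raise ModelError("both receptor and peptide chain sets must be non-empty")
        if self.receptor_chains & self.peptide_chains:
            raise ModelError(
                f"receptor and peptide chains overlap: {sorted(self.receptor_chains & self.peptide_chains)}"
            )

    @classmethod
    def from_string(cls, spec: str) -> "ChainSplit":
        """Parse an ``AB:C``-style partition string (receptor:peptide)."""
        try:
            rec, pep = spec.split(":")
        except ValueError as exc:
            raise ModelError(f"chain split must look like 'A:B', got {spec!r}") from exc
        return cls(set(rec), set(pep))


@dataclass(frozen=True)
class EnergyComponents:
    """Per-pose docking energy terms in kJ/mol (BSA in A^2)."""

    pose_id: str
    e_elec: float
    e_lj: float
    e_desolv: float
    e_air: float
    bsa: float

    def __post_init__(self) -> None:
        for name in ("e_elec", "e_lj", "e_desolv", "e_air", "bsa"):
            if not math.isfinite(getattr(self, name)):
                raise ModelError(f"pose {self.pose_id}: {name} must be finite")
        if self.bsa < 0:
            raise ModelError(f"pose {self.pose_id}: bsa must be >= 0, got {self.bsa}")


@dataclass(frozen=True)
class AtomParams:
    charge: float
    radius: float
    lj_sigma: float
    lj_epsilon: float


class ParameterTable:
    """(residue_name, atom_name) -> charge/radius/LJ lookup for plain PDB input."""

    def __init__(self, entries: Mapping[tuple[str, str], AtomParams]):
        self._entries = dict(entries)
        for (res, atom), p in self._entries.items():
            if p.radius <= 0:
                raise ModelError(f"parameter table: radius must be > 0 for {res}/{atom}")
            if p.lj_epsilon < 0:
                raise ModelError(f"parameter table: lj_epsilon must be >= 0 for {res}/{atom}")

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def lookup(self, residue_name: str, atom_name: str) -> AtomParams:
        try:
            return self._entries[(residue_name, atom_name)]
        except KeyError:
            raise ModelError(
                f"no parameters for atom {atom_name!r} in residue {residue_name!r}"
            ) from None

    def residues(self) -> set[str]:
        return {res for res, _ in self._entries}


_DEFAULT_TABLE: ParameterTable | None = None


def default_parameter_table() -> ParameterTable:
    """Load the bundled reduced amino-acid parameter set (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.files("dmmpbsa.data").joinpath("amino_params.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        entries = {
            (row.residue_name, row.atom_name): AtomParams(
                charge=row.charge, radius=row.radius,
                lj_sigma=row.lj_sigma, lj_epsilon=row.lj_epsilon,
            )
            for row in df.itertuples()
        }
        _DEFAULT_TABLE = ParameterTable(entries)
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> Structure:
    """Read a whitespace-separated PQR file.

    Each ATOM/HETATM line must have at least 10 whitespace-separated fields;
    charge and radius are taken from the last two numeric fields.  Both the
    10-field (no chain id) and 11-field (with chain id) dialects are accepted.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            if len(fields) < 10:
                raise ModelError(
                    f"{path.name}:{lineno}: PQR ATOM line has {len(fields)} fields, expected >= 10"
                )
            has_chain = len(fields) >= 11 and not _is_number(fields[4])
            try:
                serial = int(fields[1])
                name = fields[2]
                residue_name = fields[3]
                if has_chain:
                    chain_id = fields[4]
                    residue_index = int(fields[5])
                    x, y, z = (float(v) for v in fields[6:9])
                else:
                    chain_id = "A"
                    residue_index = int(fields[4])
                    x, y, z = (float(v) for v in fields[5:8])
                charge = float(fields[-2])
                radius = float(fields[-1])
            except ValueError as exc:
                raise ModelError(f"{path.name}:{lineno}: malformed PQR line: {exc}") from exc
            atoms.append(
                AtomRecord(serial, name, residue_name, chain_id, residue_index,
                           np.array([x, y, z]), charge, radius)
            )
    if not atoms:
        raise ModelError(f"{path.name}: no ATOM/HETATM records found")
    return Structure(atoms, title=path.stem)


def write_pqr(structure: Structure, path: str | Path) -> None:
    """Write a whitespace-separated PQR file (charge/radius as final columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"REMARK written by dmmpbsa: {structure.title}\n")
        for a in structure.atoms:
            x, y, z = a.position
            fh.write(
                f"ATOM {a.serial:6d} {a.name:<4s} {a.residue_name:<4s} {a.chain_id} "
                f"{a.residue_index:5d} {x:12.4f} {y:12.4f} {z:12.4f} "
                f"{a.charge:10.4f} {a.radius:8.4f}\n"
            )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# PDB with parameter assignment
# ---------------------------------------------------------------------------

def read_pdb_assign(path: str | Path, params: ParameterTable | None = None) -> Structure:
    """Read fixed-column PDB ATOM records and assign charges/radii/LJ parameters.

    Atoms with alternate-location indicators other than blank or 'A' are dropped
    with a warning; insertion codes are an error; any (residue, atom) pair
    missing from the table is an error (silent omission would corrupt the total
    charge).
    """
    path = Path(path)
    if params is None:
        params = default_parameter_table()
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            altloc = line[16].strip()
            if altloc not in ("", "A"):
                logger.warning("%s:%d: dropping altloc %r atom", path.name, lineno, altloc)
                continue
            icode = line[26].strip()
            if icode:
                raise ModelError(f"{path.name}:{lineno}: insertion codes are not supported")
            name = line[12:16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            try:
                serial = int(line[6:11])
                residue_index = int(line[22:26])
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            except ValueError as exc:
                raise ModelError(f"{path.name}:{lineno}: malformed PDB ATOM line: {exc}") from exc
            if residue_name not in params.residues():
                raise ModelError(
                    f"{path.name}:{lineno}: residue {residue_name!r} not in parameter table"
                )
            p = params.lookup(residue_name, name)
            atoms.append(
                AtomRecord(serial, name, residue_name, chain_id, residue_index,
                           np.array([x, y, z]), p.charge, p.radius,
                           lj_sigma=p.lj_sigma, lj_epsilon=p.lj_epsilon)
            )
    if not atoms:
        raise ModelError(f"{path.name}: no ATOM records found")
    return Structure(atoms, title=path.stem)


def assign_lj(structure: Structure, params: ParameterTable | None = None,
              strict: bool = False) -> Structure:
    """Fill missing Lennard-Jones parameters by (residue, atom) table lookup.

    PQR files carry charges and radii but no LJ parameters; this assigns them
    from the bundled table where an entry exists, leaving the PQR charges and
    radii untouched.  With ``strict=True`` a missing entry is an error;
    otherwise the atom keeps ``lj_sigma=None`` (and the direct MM fallback
    will refuse to run on it).
    """
    if params is None:
        params = default_parameter_table()
    atoms = []
    for a in structure.atoms:
        if a.lj_sigma is None and (a.residue_name, a.name) in params:
            p = params.lookup(a.residue_name, a.name)
            a = replace(a, lj_sigma=p.lj_sigma, lj_epsilon=p.lj_epsilon)
        elif a.lj_sigma is None and strict:
            raise ModelError(
                f"no LJ parameters for atom {a.name!r} in residue {a.residue_name!r}"
            )
        atoms.append(a)
    return Structure(atoms, title=structure.title)


# ---------------------------------------------------------------------------
# Decoy energy tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("pose_id", "e_elec", "e_lj", "e_desolv", "e_air", "bsa")

# tolerant mapping from HADDOCK 2.1-style column headers
_HADDOCK_ALIASES = {
    "#struc": "pose_id", "structure": "pose_id",
    "Eelec": "e_elec", "Einter_elec": "e_elec",
    "Evdw": "e_lj", "Einter_vdw": "e_lj",
    "Edesolv": "e_desolv", "Edesol": "e_desolv",
    "Eair": "e_air", "EAIR": "e_air",
    "BSA": "bsa",
}


def read_decoy_energies(path: str | Path, haddock_names: bool = False) -> list[EnergyComponents]:
    """Parse a per-pose docking energy TSV into :class:`EnergyComponents` rows.

    The native dialect has a header line ``pose_id e_elec e_lj e_desolv e_air
    bsa``; extra columns are ignored.  With ``haddock_names=True`` a tolerant
    mapping from HADDOCK 2.1 column names is applied first.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if haddock_names:
        df = df.rename(columns=_HADDOCK_ALIASES)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"{path.name}: missing required column(s) {missing}")
    records: list[EnergyComponents] = []
    for i, row in df.iterrows():
        values = {}
        for col in _REQUIRED_COLUMNS[1:]:
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ModelError(
                    f"{path.name}: non-numeric value {row[col]!r} at row {i}, column {col!r}"
                ) from exc
        records.append(EnergyComponents(pose_id=str(row["pose_id"]), **values))
    return records


def write_decoy_energies(records: Sequence[EnergyComponents], path: str | Path) -> None:
    """Write EnergyComponents rows in the native TSV dialect."""
    df = pd.DataFrame(
        [
            {"pose_id": r.pose_id, "e_elec": r.e_elec, "e_lj": r.e_lj,
             "e_desolv": r.e_desolv, "e_air": r.e_air, "bsa": r.bsa}
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Complex partitioning
# ---------------------------------------------------------------------------

def split_complex(structure: Structure, split: ChainSplit) -> tuple[Structure, Structure]:
    """Split a complex into (receptor, peptide) by chain id.

    Coordinates are untouched: the unbound states keep the bound conformation
    (rigid end-point convention, which also makes the internal bonded energy
    cancel in the binding difference).
    """
    covered = split.receptor_chains | split.peptide_chains
    extra = structure.chains - covered
    if extra:
        raise ModelError(f"chains {sorted(extra)} in structure are absent from the split")
    missing = covered - structure.chains
    if missing:
        raise ModelError(f"split lists chain(s) {sorted(missing)} not present in the structure")
    rec = [a for a in structure.atoms if a.chain_id in split.receptor_chains]
    pep = [a for a in structure.atoms if a.chain_id in split.peptide_chains]
    return (
        Structure(rec, title=f"{structure.title}_receptor"),
        Structure(pep, title=f"{structure.title}_peptide"),
    )


def merge(receptor: Structure, peptide: Structure, title: str = "complex") -> Structure:
    """Re-join receptor and peptide atom lists into one complex."""
    return Structure(list(receptor.atoms) + list(peptide.atoms), title=title)
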