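"""Pose evaluation and benchmark statistics.

Interface RMSD (i-RMSD): backbone RMSD over interface residues after optimal
least-squares superposition; poses under 2 A are "near-native".  Also provides
i-RMSD-based greedy clustering, near-native success curves over ranked
clusters, Pearson correlation with two-tailed p-values, the Shapiro-Wilk
normality test, and the K_D -> dG_bind = RT ln K_D conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model_io import ChainSplit, Structure, split_complex

__all__ = [
    "InterfaceSpec",
    "BenchmarkRecord",
    "CorrelationResult",
    "SuccessCurve",
    "interface_residues",
    "irmsd",
    "cluster_poses",
    "success_curve",
    "pearson",
    "shapiro_wilk",
    "kd_to_dg",
    "load_benchmark_table",
    "benchmark_correlations",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
NEAR_NATIVE_IRMSD = 2.0  # A
GAS_CONSTANT = 8.31446e-3  # kJ mol^-1 K^-1


@dataclass(frozen=True)
class InterfaceSpec:
    """Interface definition: heavy-atom cross-contact cutoff, fit atom set."""

    contact_cutoff: float = 10.0
    atom_set: tuple[str, ...] = BACKBONE_ATOMS

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark system: experimental affinity plus computed scores."""

    system_id: str
    kd: float | None
    dg_bind: float
    haddock: float
    dg_comp: float
    d_dg_comp: float
    vdw: float
    bsa: float
    mean_irmsd: float | None = None

    def __post_init__(self) -> None:
        if self.kd is not None and self.kd <= 0:
            raise ValueError(f"{self.system_id}: kd must be > 0")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n < 3:
            raise ValueError("need n >= 3")


@dataclass(frozen=True)
class SuccessCurve:
    """Percentage of systems with a near-native pose among top-N clusters."""

    percentages: tuple[float, ...]  # index 0 = N=1

    def __post_init__(self) -> None:
        p = self.percentages
        if any(not (0.0 <= v <= 100.0) for v in p):
            raise ValueError("percentages must lie in [0, 100]")
        if any(b < a - 1e-9 for a, b in zip(p, p[1:])):
            raise ValueError("success curve must be non-decreasing in N")


def _heavy(structure: Structure) -> list:
    return [a for a in structure.atoms if not a.name.startswith("H")]


def interface_residues(
    complex_: Structure, split: ChainSplit, spec: InterfaceSpec = InterfaceSpec()
) -> set[tuple[str, int]]:
    """Residues of either partner with any heavy-atom cross-contact.

    Returns (chain_id, residue_index) pairs for residues having at least one
    heavy atom within ``contact_cutoff`` of a heavy atom of the other partner.
    """
    receptor, peptide = split_complex(complex_, split)
    rec = _heavy(receptor)
    pep = _heavy(peptide)
    d = cdist(np.array([a.position for a in rec]), np.array([a.position for a in pep]))
    in_contact = d <= spec.contact_cutoff
    out: set[tuple[str, int]] = set()
    ri, pi = np.nonzero(in_contact)
    for i in set(ri):
        out.add((rec[i].chain_id, rec[i].residue_index))
    for j in set(pi):
        out.add((pep[j].chain_id, pep[j].residue_index))
    return out


def _interface_atom_keys(
    reference: Structure, split: ChainSplit, spec: InterfaceSpec
) -> list[tuple[str, int, str]]:
    resids = interface_residues(reference, split, spec)
    keys = [
        (a.chain_id, a.residue_index, a.name)
        for a in reference.atoms
        if (a.chain_id, a.residue_index) in resids and a.name in spec.atom_set
    ]
    return keys


def irmsd(
    reference: Structure,
    model: Structure,
    split: ChainSplit,
    spec: InterfaceSpec = InterfaceSpec(),
) -> float:
    """Interface RMSD (A) of a model against a reference pose.

    The interface is computed on the reference; the model is superposed onto
    the reference by optimal least-squares rotation (Kabsch) over the backbone
    atoms of the interface residues, and the RMSD over those same atoms is
    returned.
    """
    keys = _interface_atom_keys(reference, split, spec)
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} interface atoms; need >= 3")
    ref_map = {(a.chain_id, a.residue_index, a.name): a.position for a in reference.atoms}
    mod_map = {(a.chain_id, a.residue_index, a.name): a.position for a in model.atoms}
    missing = [k for k in keys if k not in mod_map]
    if missing:
        raise ValueError(f"model lacks interface atom(s) {missing[:3]}")
    p_ref = np.array([ref_map[k] for k in keys])
    p_mod = np.array([mod_map[k] for k in keys])
    p_ref_c = p_ref - p_ref.mean(axis=0)
    p_mod_c = p_mod - p_mod.mean(axis=0)
    _, rssd = Rotation.align_vectors(p_ref_c, p_mod_c)
    return float(rssd / math.sqrt(len(keys)))


def irmsd_matrix(
    reference: Structure,
    models: list[Structure],
    split: ChainSplit,
    spec: InterfaceSpec = InterfaceSpec(),
) -> np.ndarray:
    """Pairwise i-RMSD between models, interface defined on the reference.

    The interface residues and fit atoms come from the (native) reference, so
    far-displaced pose pairs remain comparable; each model pair is superposed
    over those atoms before the RMSD is taken.
    """
    keys = _interface_atom_keys(reference, split, spec)
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} interface atoms; need >= 3")
    stacks = []
    for m in models:
        amap = {(a.chain_id, a.residue_index, a.name): a.position for a in m.atoms}
        missing = [k for k in keys if k not in amap]
        if missing:
            raise ValueError(f"model {m.title!r} lacks interface atom(s) {missing[:3]}")
        stacks.append(np.array([amap[k] for k in keys]))
    n = len(models)
    out = np.zeros((n, n))
    for i in range(n):
        pi = stacks[i] - stacks[i].mean(axis=0)
        for j in range(i + 1, n):
            pj = stacks[j] - stacks[j].mean(axis=0)
            _, rssd = Rotation.align_vectors(pi, pj)
            out[i, j] = out[j, i] = float(rssd / math.sqrt(len(keys)))
    return out


def cluster_poses(irmsd_matrix: np.ndarray, cutoff: float = 2.5) -> list[list[int]]:
    """Greedy neighbour-count clustering of a pairwise i-RMSD matrix.

    Repeatedly picks the unassigned pose with the most unassigned neighbours
    within ``cutoff`` (ties broken by lowest index), forms a cluster from it
    and those neighbours, and removes them.  Singletons are allowed.  Fully
    deterministic given the matrix.
    """
    m = np.asarray(irmsd_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("i-RMSD matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("i-RMSD matrix must be symmetric")
    if np.any(m < 0) or np.any(np.abs(np.diag(m)) > 1e-8):
        raise ValueError("i-RMSD matrix must be non-negative with zero diagonal")
    n = m.shape[0]
    unassigned = set(range(n))
    clusters: list[list[int]] = []
    adj = m <= cutoff
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if j != i and adj[i, j])
            if count > best_count:
                best, best_count = i, count
        members = [best] + [j for j in sorted(unassigned) if j != best and adj[best, j]]
        clusters.append(sorted(members))
        unassigned -= set(members)
    return clusters


def success_curve(
    systems: list[list[list[float]]], n_max: int | None = None
) -> SuccessCurve:
    """Near-native success percentages vs number of top clusters considered.

    ``systems[s]`` is that system's ranked clusters, each a list of the best-4
    members' i-RMSD values (A).  For each N, a system counts as a success if
    any member of its top-N clusters is below the 2 A near-native threshold.
    """
    if not systems:
        raise ValueError("need at least one system")
    if n_max is None:
        n_max = max(len(cl) for cl in systems)
    pct = []
    for n in range(1, n_max + 1):
        hits = sum(
            1 for clusters in systems
            if any(v < NEAR_NATIVE_IRMSD for cl in clusters[:n] for v in cl)
        )
        pct.append(100.0 * hits / len(systems))
    return SuccessCurve(tuple(pct))


def pearson(x, y, gaussian_p: bool = False) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed p-value.

    The p-value uses the exact t distribution with n-2 degrees of freedom;
    ``gaussian_p=True`` instead applies the Fisher-z normal approximation
    (the two are numerically indistinguishable at the benchmark's n = 19).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    if gaussian_p:
        z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15)) * math.sqrt(len(x) - 3)
        p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston's algorithm)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= len(x) <= 50):
        raise ValueError("Shapiro-Wilk here supports 3 <= n <= 50")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def kd_to_dg(kd: float, temperature: float = 298.15) -> float:
    """dG_bind = RT ln K_D (kJ/mol); negative for K_D < 1 M."""
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    return GAS_CONSTANT * temperature * math.log(kd)


# ---------------------------------------------------------------------------
# Benchmark table
# ---------------------------------------------------------------------------

def load_benchmark_table(path: str | Path | None = None) -> list[BenchmarkRecord]:
    """Load a benchmark TSV; defaults to the bundled 19-complex table."""
    if path is None:
        fh = resources.files("dmmpbsa.data").joinpath("benchmark19.tsv").open()
    else:
        fh = open(path)
    with fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    records = []
    for row in df.itertuples():
        records.append(
            BenchmarkRecord(
                system_id=str(row.system_id),
                kd=float(row.kd) if "kd" in df.columns and not pd.isna(row.kd) else None,
                dg_bind=float(row.dg_bind),
                haddock=float(row.haddock),
                dg_comp=float(row.dg_comp),
                d_dg_comp=float(row.d_dg_comp),
                vdw=float(row.vdw),
                bsa=float(row.bsa),
            )
        )
    return records


def benchmark_correlations(
    records: list[BenchmarkRecord], gaussian_p: bool = False
) -> dict[str, CorrelationResult]:
    """Correlate experimental dG_bind against each score/term column."""
    dg = [r.dg_bind for r in records]
    out = {}
    for name, col in [
        ("haddock", [r.haddock for r in records]),
        ("dg_comp", [r.dg_comp for r in records]),
        ("d_dg_comp", [r.d_dg_comp for r in records]),
        ("vdw", [r.vdw for r in records]),
        ("bsa", [r.bsa for r in records]),
    ]:
        out[name] = pearson(dg, col, gaussian_p=gaussian_p)
    return out
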