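"""Shared fixtures: toy complexes, fast PB settings, a salt-bridge system."""

from __future__ import annotations

import numpy as np
import pytest

from dmmpbsa import (
    AtomRecord,
    ChainSplit,
    NonpolarParams,
    PBParams,
    ScoringConfig,
    Structure,
    default_parameter_table,
    toy_complex,
)


@pytest.fixture(scope="session")
def toy():
    """Deterministic contacting receptor/peptide toy complex."""
    return toy_complex(seed=0)


@pytest.fixture(scope="session")
def fast_pb() -> PBParams:
    """Coarse, salt-free PB settings for tests that probe identities, not accuracy."""
    return PBParams(salt=0.0, nonlinear=False, grid_spacing=0.8,
                    fine_pad=6.0, coarse_pad=12.0)


@pytest.fixture(scope="session")
def fast_config(fast_pb) -> ScoringConfig:
    return ScoringConfig(pb=fast_pb, nonpolar=NonpolarParams(n_sphere_points=240))


def _residue(chain: str, resname: str, resid: int, placed: dict[str, np.ndarray],
             serial0: int, table) -> list[AtomRecord]:
    atoms = []
    serial = serial0
    for name, pos in placed.items():
        p = table.lookup(resname, name)
        atoms.append(
            AtomRecord(serial, name, resname, chain, resid, np.asarray(pos, float),
                       p.charge, p.radius, lj_sigma=p.lj_sigma, lj_epsilon=p.lj_epsilon)
        )
        serial += 1
    return atoms


@pytest.fixture(scope="session")
def salt_bridge_complex():
    """LYS(A1)...GLU(B1) salt bridge plus a remote apolar LEU(A2).

    The lysine ammonium sits ~2.7 A from a glutamate carboxylate oxygen across
    the chain interface; the leucine side chain is uncharged and ~12 A from
    the interface, so truncating it should barely change the binding energy.
    Parameters come from the bundled table, so alanine mutation is exercised
    exactly as on parsed PDB input.
    """
    table = default_parameter_table()
    atoms = []
    atoms += _residue("A", "LYS", 1, {
        "N": (0.0, 0.0, 0.0), "CA": (1.45, 0.0, 0.0), "C": (2.2, 1.2, 0.0),
        "O": (1.7, 2.3, 0.0), "CB": (2.0, -1.3, 0.3), "CG": (3.5, -1.4, 0.4),
        "CD": (4.2, -2.7, 0.6), "CE": (5.7, -2.8, 0.7), "NZ": (6.4, -4.05, 0.9),
    }, 1, table)
    atoms += _residue("A", "LEU", 2, {
        "N": (-11.0, 0.0, 0.0), "CA": (-9.55, 0.0, 0.0), "C": (-8.8, 1.2, 0.0),
        "O": (-9.3, 2.3, 0.0), "CB": (-9.0, -1.3, 0.3), "CG": (-7.5, -1.4, 0.4),
        "CD1": (-6.9, -2.7, 0.7), "CD2": (-6.8, -0.2, 1.1),
    }, 20, table)
    atoms += _residue("B", "GLU", 1, {
        "OE1": (8.8, -5.3, 1.0), "CD": (9.9, -4.7, 1.5), "OE2": (10.0, -3.5, 1.7),
        "CG": (11.0, -5.6, 1.6), "CB": (12.3, -4.9, 1.9), "CA": (13.5, -5.8, 2.1),
        "N": (14.7, -5.0, 2.3), "C": (13.8, -7.0, 1.3), "O": (13.2, -8.0, 1.6),
    }, 40, table)
    return Structure(atoms, title="saltbridge"), ChainSplit({"A"}, {"B"})
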