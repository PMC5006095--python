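"""i-RMSD, clustering, success curves, and benchmark statistics."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dmmpbsa import (
    AtomRecord,
    ChainSplit,
    InterfaceSpec,
    Structure,
    benchmark_correlations,
    cluster_poses,
    interface_residues,
    irmsd,
    kd_to_dg,
    load_benchmark_table,
    pearson,
    shapiro_wilk,
    success_curve,
)


def kabsch_quaternion_rmsd(p, q):
    """Independent superposition oracle via the quaternion eigenvalue method."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    # correlation matrix of model (q) against reference (p)
    r = q.T @ p
    f = np.array([
        [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
        [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
        [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
        [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0], r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
    ])
    lam = np.linalg.eigvalsh(f)[-1]
    msd = max((np.sum(p**2) + np.sum(q**2) - 2.0 * lam) / len(p), 0.0)
    return math.sqrt(msd)


def pearson_oracle(x, y):
    """Hand-rolled product-moment r and two-tailed t-test p."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    n = len(x)
    tstat = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * tdist.sf(abs(tstat), n - 2)
    return r, p


def two_residue_complex(gap=5.0):
    atoms = []
    serial = 1
    for chain, base in (("A", np.zeros(3)), ("B", np.array([0.0, 0.0, gap]))):
        for name, off in (("N", [0, 0, 0]), ("CA", [1.4, 0.5, 0]),
                          ("C", [2.4, -0.4, 0]), ("O", [2.6, -1.5, 0.4])):
            atoms.append(AtomRecord(serial, name, "GLY", chain, 1,
                                    base + np.asarray(off, float), 0.0, 1.6))
            serial += 1
    return Structure(atoms, title="tiny"), ChainSplit({"A"}, {"B"})


class TestInterfaceResidues:
    def test_far_partners_empty(self):
        cx, split = two_residue_complex(gap=100.0)
        assert interface_residues(cx, split) == set()

    def test_contacting_pair_includes_both(self):
        cx, split = two_residue_complex(gap=5.0)
        res = interface_residues(cx, split)
        assert ("A", 1) in res and ("B", 1) in res

    def test_monotone_in_cutoff(self, toy):
        cx, split = toy
        small = interface_residues(cx, split, InterfaceSpec(contact_cutoff=5.0))
        large = interface_residues(cx, split, InterfaceSpec(contact_cutoff=10.0))
        assert small <= large


class TestIrmsd:
    def test_self_is_zero(self, toy):
        cx, split = toy
        assert irmsd(cx, cx, split) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_of_whole_complex_is_zero(self, toy):
        cx, split = toy
        rot = Rotation.from_euler("xyz", [20, 40, 60], degrees=True)
        moved = Structure([
            AtomRecord(a.serial, a.name, a.residue_name, a.chain_id, a.residue_index,
                       rot.apply(a.position) + np.array([1.0, 2.0, 3.0]),
                       a.charge, a.radius)
            for a in cx.atoms
        ], title="moved")
        assert irmsd(cx, moved, split) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quaternion_oracle(self, seed, toy):
        cx, split = toy
        rng = np.random.default_rng(seed)
        perturbed = Structure([
            AtomRecord(a.serial, a.name, a.residue_name, a.chain_id, a.residue_index,
                       a.position + (rng.normal(0, 1.5, 3) if a.chain_id == "B" else 0),
                       a.charge, a.radius)
            for a in cx.atoms
        ], title="pert")
        got = irmsd(cx, perturbed, split)
        # oracle on the same interface backbone atom set
        from dmmpbsa.evaluation import _interface_atom_keys
        keys = _interface_atom_keys(cx, split, InterfaceSpec())
        ref_map = {(a.chain_id, a.residue_index, a.name): a.position for a in cx.atoms}
        mod_map = {(a.chain_id, a.residue_index, a.name): a.position for a in perturbed.atoms}
        expected = kabsch_quaternion_rmsd(
            np.array([ref_map[k] for k in keys]), np.array([mod_map[k] for k in keys])
        )
        assert got == pytest.approx(expected, abs=1e-6)

    def test_too_few_interface_atoms_is_error(self):
        cx, split = two_residue_complex(gap=100.0)
        with pytest.raises(ValueError, match="interface"):
            irmsd(cx, cx, split)


class TestIrmsdMatrix:
    def test_consistent_with_reference_irmsd(self, toy):
        from dmmpbsa import FixtureConfig, make_decoys
        from dmmpbsa.evaluation import irmsd_matrix
        cx, split = toy
        decoys = make_decoys(cx, split, FixtureConfig(seed=0, n_poses=4))
        models = [cx] + [d.structure for d in decoys[1:]]
        m = irmsd_matrix(cx, models, split)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0.0)
        # row 0 (native as one of the models) matches the direct computation
        for j in range(1, len(models)):
            assert m[0, j] == pytest.approx(irmsd(cx, models[j], split), abs=1e-9)


class TestClusterPoses:
    def test_all_close_single_cluster(self):
        m = np.full((5, 5), 1.0); np.fill_diagonal(m, 0.0)
        assert cluster_poses(m, cutoff=2.5) == [[0, 1, 2, 3, 4]]

    def test_two_blocks(self):
        m = np.full((6, 6), 20.0)
        m[:3, :3] = 1.0
        m[3:, 3:] = 1.0
        np.fill_diagonal(m, 0.0)
        assert cluster_poses(m, cutoff=2.5) == [[0, 1, 2], [3, 4, 5]]

    def test_tie_goes_to_first_formed_cluster(self):
        # chain 0-1-2-3-4: poses 1, 2, 3 all have two neighbours; the tie
        # breaks to the lowest index (1), whose cluster absorbs pose 2
        m = np.full((5, 5), 9.0)
        for i, j, v in [(0, 1, 1.0), (1, 2, 2.0), (2, 3, 2.0), (3, 4, 1.0)]:
            m[i, j] = m[j, i] = v
        np.fill_diagonal(m, 0.0)
        clusters = cluster_poses(m, cutoff=2.5)
        assert clusters == [[0, 1, 2], [3, 4]]

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_poses(m)


class TestSuccessCurve:
    def test_example_percentages(self):
        systems = [
            [[0.5, 3.0]],   # hit at N=1
            [[4.0], [1.0]], # hit at N=2
            [[5.0], [6.0]], # never
            [[1.5]],        # hit at N=1
        ]
        curve = success_curve(systems, n_max=2)
        assert curve.percentages[0] == pytest.approx(50.0)
        assert curve.percentages[1] == pytest.approx(75.0)

    def test_monotone_and_saturates_at_fraction_with_any_hit(self):
        rng = np.random.default_rng(3)
        systems = [
            [list(rng.uniform(0.5, 12.0, 4)) for _ in range(rng.integers(1, 6))]
            for _ in range(12)
        ]
        n_max = max(len(s) for s in systems)
        curve = success_curve(systems, n_max=n_max)
        assert all(b >= a for a, b in zip(curve.percentages, curve.percentages[1:]))
        has_any = sum(1 for s in systems if any(v < 2.0 for cl in s for v in cl))
        assert curve.percentages[-1] == pytest.approx(100.0 * has_any / len(systems))

    def test_system_without_near_native_never_counts(self):
        curve = success_curve([[[3.0], [2.5], [8.0]]], n_max=3)
        assert all(v == 0.0 for v in curve.percentages)


class TestPearson:
    def test_benchmark_haddock_column(self):
        records = load_benchmark_table()
        res = pearson([r.dg_bind for r in records], [r.haddock for r in records])
        assert round(res.r, 2) == 0.63

    def test_perfect_line(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)
        assert pearson(3 * x + 2, y).r == pytest.approx(pearson(x, y).r)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_rolled_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=19), rng.normal(size=19)
        res = pearson(x, y)
        r0, p0 = pearson_oracle(x, y)
        assert res.r == pytest.approx(r0, abs=1e-12)
        assert res.p == pytest.approx(p0, rel=1e-9)

    def test_gaussian_p_close_to_t_at_n19(self):
        records = load_benchmark_table()
        dg = [r.dg_bind for r in records]
        hd = [r.haddock for r in records]
        assert pearson(dg, hd, gaussian_p=True).p == pytest.approx(
            pearson(dg, hd).p, abs=0.005
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_full_correlation_row(self):
        results = benchmark_correlations(load_benchmark_table())
        rounded = {k: round(v.r, 2) for k, v in results.items()}
        assert rounded == {"haddock": 0.63, "dg_comp": 0.49, "d_dg_comp": 0.66,
                          "vdw": 0.53, "bsa": -0.58}


class TestShapiroWilk:
    # reference sample with W/p frozen from an independent R run of shapiro.test
    REFERENCE = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]

    def test_reference_sample(self):
        w, p = shapiro_wilk(self.REFERENCE)
        assert w == pytest.approx(0.7888, abs=0.01)
        assert p == pytest.approx(0.0067, abs=0.005)

    def test_w_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w, _ = shapiro_wilk(rng.normal(size=19))
            assert 0.0 < w <= 1.0

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(42)
        hits = sum(shapiro_wilk(rng.standard_normal(19))[1] > 0.05 for _ in range(1000))
        assert hits >= 900

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)


class TestKdToDg:
    def test_unit_kd_is_zero(self):
        assert kd_to_dg(1.0) == 0.0

    @pytest.mark.parametrize("kd,printed", [
        (5.00e-5, -24.51),   # micromolar binder
        (8.00e-8, -40.44),   # nanomolar binder
        (1.90e-6, -31.84),   # table value inconsistent with RT ln Kd; keep loose
    ])
    def test_against_printed_benchmark_values(self, kd, printed):
        # printed dG_bind values carry rounding/temperature inconsistencies
        assert kd_to_dg(kd) == pytest.approx(printed, abs=0.9)

    def test_tight_agreement_where_consistent(self):
        assert kd_to_dg(5.00e-5) == pytest.approx(-24.51, abs=0.3)
        assert kd_to_dg(8.00e-8) == pytest.approx(-40.44, abs=0.3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kd_to_dg(0.0)
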