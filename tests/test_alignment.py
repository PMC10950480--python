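"""Superposition and scoring: Kabsch optimality, hand-computed RMSD/GDT
values, TM functional form, batch-vs-sequential equality, invariances."""

import dataclasses

import numpy as np
import pytest

from structfig.alignment import (
    GDT_CUTOFFS,
    align_pair,
    batch_align,
    gdt,
    gdt_fractions_from_distances,
    gdt_scores_from_fractions,
    kabsch_superpose,
    pair_residues,
    rmsd,
    tm_d0,
    tm_from_distances,
    tm_score,
)
from structfig.errors import (
    DegenerateGeometryError,
    PairingError,
    TooFewPairsError,
)
from structfig.fixtures import PerturbSpec, apply_rigid, ideal_helix, perturb


def _mutate(model, res_seq, new_name):
    for chain in model.chains:
        for i, res in enumerate(chain.residues):
            if res.res_seq == res_seq:
                res.res_name = new_name
                res.atoms = [
                    dataclasses.replace(a, res_name=new_name) for a in res.atoms
                ]
    return model


def _shift_numbering(model, offset):
    for chain in model.chains:
        for res in chain.residues:
            res.res_seq += offset
            res.atoms = [
                dataclasses.replace(a, res_seq=a.res_seq + offset)
                for a in res.atoms
            ]
    return model


class TestPairing:
    def test_strict_identity_pairing(self, helix30):
        mob = apply_rigid(helix30, (1, 1, 0), 30.0, (1, 2, 3))
        corr = pair_residues(helix30, mob, mode="strict")
        assert len(corr) == 30
        assert corr.pairs == tuple((i, i) for i in range(30))

    def test_by_number_intersects(self, helix30):
        mob = _shift_numbering(ideal_helix(30), 10)  # residues 11..40
        corr = pair_residues(helix30, mob, mode="by-number")
        assert len(corr) == 20
        assert [k[1] for k in corr.ref_keys] == list(range(11, 31))

    def test_strict_mismatch_names_position(self, helix30):
        mob = _mutate(ideal_helix(30), 5, "GLY")
        with pytest.raises(PairingError, match="position 5"):
            pair_residues(helix30, mob, mode="strict")

    def test_strict_length_mismatch(self, helix30):
        with pytest.raises(PairingError, match="equal-length"):
            pair_residues(helix30, ideal_helix(20), mode="strict")

    def test_too_few_pairs(self, helix30):
        mob = _shift_numbering(ideal_helix(30), 28)  # overlap = 2
        with pytest.raises(TooFewPairsError):
            pair_residues(helix30, mob, mode="by-number")


class TestKabsch:
    def test_identity_on_equal_clouds(self, rng):
        P = rng.normal(size=(10, 3))
        R, t, value = kabsch_superpose(P, P)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)
        assert value <= 1e-10

    def test_recovers_known_rigid_transform(self, rng):
        P = rng.normal(size=(10, 3))
        angle = np.pi / 2
        Rz = np.array(
            [[np.cos(angle), -np.sin(angle), 0],
             [np.sin(angle), np.cos(angle), 0],
             [0, 0, 1]]
        )
        Q = P @ Rz.T + np.array([5.0, 0.0, 0.0])
        R, t, value = kabsch_superpose(P, Q)
        assert value <= 1e-10
        assert np.allclose(R @ Rz, np.eye(3), atol=1e-8)

    def test_rotation_always_proper(self, rng):
        for _ in range(20):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            R, _, _ = kabsch_superpose(P, Q)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)
            assert np.isclose(np.linalg.det(R), 1.0, atol=1e-8)

    def test_centroids_coincide(self, rng):
        P, Q = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        R, t, _ = kabsch_superpose(P, Q)
        assert np.allclose((Q @ R.T + t).mean(axis=0), P.mean(axis=0))

    def test_beats_coarse_rotation_grid(self, rng):
        # exhaustive 6-degree Euler grid as an independent optimality
        # oracle on a few small clouds (the finer grid runs elsewhere)
        from scipy.spatial.transform import Rotation

        deg = np.arange(0, 360, 6.0)
        beta = np.arange(0, 181, 6.0)
        A, B, C = np.meshgrid(deg, beta, deg, indexing="ij")
        grid = Rotation.from_euler(
            "ZYZ", np.column_stack([A.ravel(), B.ravel(), C.ravel()]), degrees=True
        ).as_matrix()
        for _ in range(5):
            P, Q = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
            Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
            const = np.sum(Pc ** 2) + np.sum(Qc ** 2)
            traces = np.einsum("nab,bc,ca->n", grid, Qc.T @ Pc, np.eye(3))
            grid_min = np.sqrt(np.maximum(const - 2 * traces.max(), 0) / len(P))
            _, _, ours = kabsch_superpose(P, Q)
            assert ours <= grid_min + 1e-9

    def test_too_few_points(self):
        with pytest.raises(TooFewPairsError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestRmsd:
    def test_single_pair_hand_value(self):
        assert rmsd(np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]])) == 1.0

    def test_two_pair_hand_value(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0]])
        Q = np.array([[3.0, 4, 0], [1, 0, 0]])
        assert np.isclose(rmsd(P, Q), np.sqrt(25 / 2))

    def test_matches_per_pair_summation_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 20))
            P, Q = rng.normal(size=(n, 3)), rng.normal(size=(n, 3))
            expected = np.sqrt(
                sum(np.sum((p - q) ** 2) for p, q in zip(P, Q)) / n
            )
            assert np.isclose(rmsd(P, Q), expected, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def _oracle_gdt_fraction(P, Q, cutoff, max_iter=10):
    """Independent re-enumeration of the documented seed-and-refine search,
    written as plain loops."""
    L = len(P)
    windows = [list(range(L))]
    for w in (3, 5, 7):
        for s in range(L - w + 1):
            windows.append(list(range(s, s + w)))
    best = 0.0
    for idx in windows:
        try:
            R, t, _ = kabsch_superpose(P[idx], Q[idx])
        except DegenerateGeometryError:
            continue
        poses = [(R, t)]
        current = idx
        for _ in range(max_iter):
            d = [np.linalg.norm(P[i] - (R @ Q[i] + t)) for i in range(L)]
            sub = [i for i in range(L) if d[i] <= cutoff]
            if len(sub) < 3 or sub == list(current):
                break
            current = sub
            try:
                R, t, _ = kabsch_superpose(P[sub], Q[sub])
            except DegenerateGeometryError:
                break
            poses.append((R, t))
        for R_, t_ in poses:
            n_in = sum(
                np.linalg.norm(P[i] - (R_ @ Q[i] + t_)) <= cutoff
                for i in range(L)
            )
            best = max(best, n_in / L)
    return best


class TestGdt:
    def test_identical_structures_score_100(self, rng):
        P = rng.normal(size=(12, 3))
        fractions, ts, ha = gdt(P, P.copy())
        assert all(f == 1.0 for f in fractions.values())
        assert ts == 100.0 and ha == 100.0

    def test_hand_computable_fixed_superposition(self):
        fractions = gdt_fractions_from_distances([0.4, 1.5, 3.0, 9.0], GDT_CUTOFFS)
        assert fractions[1.0] == 0.25
        assert fractions[2.0] == 0.50
        assert fractions[4.0] == 0.75
        assert fractions[8.0] == 0.75
        ts, _ = gdt_scores_from_fractions(fractions)
        assert ts == 56.25

    def test_fractions_monotone_in_cutoff(self, helix30):
        mob = perturb(helix30, PerturbSpec(sigma=1.0, seed=3))
        corr = pair_residues(helix30, mob)
        fractions, _, _ = gdt(corr.ref_coords, corr.mob_coords)
        cutoffs = sorted(fractions)
        values = [fractions[c] for c in cutoffs]
        assert values == sorted(values)

    def test_heuristic_matches_seed_enumeration_oracle(self, rng):
        P = rng.normal(size=(8, 3)) * 3
        Q = P + rng.normal(size=(8, 3)) * 1.5
        fractions, _, _ = gdt(P, Q)
        for cutoff in GDT_CUTOFFS:
            oracle = _oracle_gdt_fraction(P, Q, cutoff)
            full_fit_d = None
            R, t, _ = kabsch_superpose(P, Q)
            full = np.mean(np.linalg.norm(P - (Q @ R.T + t), axis=1) <= cutoff)
            assert fractions[cutoff] >= full - 1e-12
            assert np.isclose(fractions[cutoff], oracle, atol=1e-12)

    def test_empty_cutoffs_error(self, rng):
        P = rng.normal(size=(5, 3))
        with pytest.raises(PairingError):
            gdt(P, P, cutoffs=())


class TestTmScore:
    def test_identical_structures_score_1(self, rng):
        P = rng.normal(size=(25, 3))
        assert np.isclose(tm_score(P, P.copy()), 1.0, atol=1e-9)

    def test_all_residues_at_d0_score_half(self):
        L = 40
        d0 = tm_d0(L)
        assert np.isclose(tm_from_distances([d0] * L, L), 0.5, atol=1e-12)

    def test_d0_formula_and_floor(self):
        assert np.isclose(tm_d0(20, floor=False), 0.3204, atol=5e-4)
        assert tm_d0(20) == 0.5
        assert tm_d0(21) == 0.5
        # long chains are unaffected by the floor
        assert np.isclose(tm_d0(150, floor=False), tm_d0(150))

    def test_heuristic_at_least_full_length_fit(self, helix30):
        mob = perturb(helix30, PerturbSpec(sigma=1.5, seed=5))
        corr = pair_residues(helix30, mob)
        P, Q = corr.ref_coords, corr.mob_coords
        R, t, _ = kabsch_superpose(P, Q)
        d = np.linalg.norm(P - (Q @ R.T + t), axis=1)
        plain = tm_from_distances(d, len(P))
        assert tm_score(P, Q) >= plain - 1e-12

    def test_l_norm_too_small(self, rng):
        P = rng.normal(size=(5, 3))
        with pytest.raises(PairingError):
            tm_score(P, P, L_norm=2)


class TestAlignPair:
    def test_rigid_copy_perfect_scores(self, helix30):
        mob = apply_rigid(helix30, (0.3, -1, 2), 72.0, (4, -5, 6))
        result = align_pair(helix30, mob)
        assert result.rmsd <= 1e-9
        assert np.isclose(result.tm_score, 1.0, atol=1e-9)
        assert np.isclose(result.gdt_ts, 100.0, atol=1e-9)
        assert np.all(result.per_residue_distance <= 1e-9)

    def test_small_perturbation_rmsd_bound(self, helix30):
        mob = perturb(helix30, PerturbSpec(sigma=0.1, seed=2))
        result = align_pair(helix30, mob, methods=("rmsd",))
        assert 0 < result.rmsd < 0.35  # 2 sigma sqrt(3) envelope

    def test_per_residue_distances_reconcile_with_rmsd(self, helix30):
        mob = perturb(helix30, PerturbSpec(sigma=0.8, seed=9))
        result = align_pair(helix30, mob, methods=("rmsd",))
        assert np.isclose(
            np.mean(result.per_residue_distance ** 2), result.rmsd ** 2, atol=1e-9
        )

    def test_scores_invariant_under_common_rigid_transform(self, helix30):
        mob = perturb(helix30, PerturbSpec(sigma=0.7, seed=4))
        r1 = align_pair(helix30, mob)
        moved_ref = apply_rigid(helix30, (1, 2, 3), 35.0, (-3, 1, 8))
        moved_mob = apply_rigid(mob, (1, 2, 3), 35.0, (-3, 1, 8))
        r2 = align_pair(moved_ref, moved_mob)
        assert np.isclose(r1.rmsd, r2.rmsd, atol=1e-9)
        assert np.isclose(r1.tm_score, r2.tm_score, atol=1e-9)
        assert np.isclose(r1.gdt_ts, r2.gdt_ts, atol=1e-9)


class TestBatch:
    def test_batch_equals_sequential_bitwise(self, helix30):
        mobiles = [
            perturb(helix30, PerturbSpec(sigma=0.5, seed=s)) for s in range(10)
        ]
        batch, errors = batch_align(helix30, mobiles)
        assert errors == [None] * 10
        for mob, got in zip(mobiles, batch):
            ref = align_pair(helix30, mob)
            assert got.rmsd == ref.rmsd
            assert got.tm_score == ref.tm_score
            assert got.gdt_ts == ref.gdt_ts and got.gdt_ha == ref.gdt_ha
            assert np.array_equal(got.per_residue_distance, ref.per_residue_distance)
            assert np.array_equal(got.rotation, ref.rotation)

    def test_singleton_batch(self, helix30):
        results, errors = batch_align(helix30, [helix30])
        assert errors == [None]
        assert results[0].rmsd == align_pair(helix30, helix30).rmsd

    def test_failures_collected_not_fatal(self, helix30):
        mobiles = [
            perturb(helix30, PerturbSpec(sigma=0.2, seed=s)) for s in range(9)
        ]
        mobiles.insert(4, ideal_helix(10))  # length mismatch
        results, errors = batch_align(helix30, mobiles)
        assert sum(r is not None for r in results) == 9
        assert results[4] is None and "equal-length" in errors[4]


def test_monotone_degradation_with_noise(helix30):
    from structfig.fixtures import ideal_helix

    ref = ideal_helix(100)
    scores = []
    for sigma in (0.1, 0.5, 1.0, 2.0):
        mob = perturb(ref, PerturbSpec(sigma=sigma, seed=7))
        r = align_pair(ref, mob)
        scores.append((r.rmsd, r.tm_score, r.gdt_ts))
    rmsds, tms, gdts = zip(*scores)
    assert all(a < b for a, b in zip(rmsds, rmsds[1:]))
    assert all(a > b for a, b in zip(tms, tms[1:]))
    assert all(a > b for a, b in zip(gdts, gdts[1:]))
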