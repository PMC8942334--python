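"""Superposition, AFP chaining, flexible twists, scoring, and P-values."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import rigid_transform
from structphylo.align3d import (
    AlignParams,
    NullCalibration,
    alignment_score,
    block_rotation,
    calibrate_null,
    find_afps,
    flexible_align,
    kabsch,
    rigid_align,
    score_pvalue,
    seq_identity,
)
from structphylo.secstruct import CoreAssignment, HelixSegment
from structphylo.structio import CaTrace
from structphylo.synthetic_data import (
    BundleSpec,
    apply_block_rotation,
    ideal_helix,
    perturb,
    random_bundle_pair,
)
from structphylo.structio import ca_trace


def quaternion_superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent oracle: Horn's quaternion eigenvector method."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    Sxx = P0.T @ Q0
    K = np.array([
        [Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2], Sxx[1, 2] - Sxx[2, 1], Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] - Sxx[1, 0]],
        [Sxx[1, 2] - Sxx[2, 1], Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2], Sxx[0, 1] + Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2]],
        [Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] + Sxx[1, 0], -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2], Sxx[1, 2] + Sxx[2, 1]],
        [Sxx[0, 1] - Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2], Sxx[1, 2] + Sxx[2, 1], -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P0 ** 2) + np.sum(Q0 ** 2) - 2.0 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch(P, P)
        assert sup.rmsd < 1e-12
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_recovers_planted_rotation(self):
        P = np.random.default_rng(1).normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True)
        Q = rot.apply(P) + np.array([5.0, 0.0, 0.0])
        sup = kabsch(P, Q)
        assert sup.rmsd < 1e-12
        angle = np.rad2deg(np.linalg.norm(Rotation.from_matrix(sup.rotation).as_rotvec()))
        assert abs(angle - 90.0) < 1e-9

    def test_matches_quaternion_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            P = rng.normal(size=(n, 3)) * rng.uniform(1, 10)
            Q = rng.normal(size=(n, 3)) * rng.uniform(1, 10)
            assert abs(kabsch(P, Q).rmsd - quaternion_superpose_rmsd(P, Q)) < 1e-6

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(8, 3)) * 3.0
        rot = Rotation.from_euler("xyz", [25, -40, 65], degrees=True)
        Q = rot.apply(P) + rng.normal(0, 0.5, size=(8, 3))
        # brute force over a 2-degree zyz Euler grid, using
        # rmsd^2 = (|P|^2 + |Q|^2 - 2 tr(R H)) / n with H the cross-covariance
        P0, Q0 = P - P.mean(axis=0), Q - Q.mean(axis=0)
        H = P0.T @ Q0
        gp, gq, n = np.sum(P0 ** 2), np.sum(Q0 ** 2), len(P)
        grid = np.arange(0, 360, 2.0)
        half = np.arange(-90, 91, 2.0)
        bc = np.array(np.meshgrid(half, grid, indexing="ij")).reshape(2, -1).T
        best = np.inf
        for a in grid:
            angles = np.column_stack([np.full(len(bc), a), bc])
            Ms = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
            tr = np.einsum("kij,ji->k", Ms, H)
            best = min(best, float(np.sqrt(np.maximum((gp + gq - 2 * tr) / n, 0)).min()))
        assert kabsch(P, Q).rmsd <= best + 1e-9
        assert abs(kabsch(P, Q).rmsd - best) < 0.05

    def test_errors(self):
        with pytest.raises(ValueError, match="\\(n, 3\\)"):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)


class TestAFPs:
    def test_self_alignment_diagonal_windows(self, core_trace):
        sub = core_trace.subtrace(range(20))
        afps = find_afps(sub, sub, afp_len=8, afp_rmsd_max=3.0)
        diag = {(a.i, a.j) for a in afps if a.i == a.j}
        assert {(i, i) for i in range(13)} <= diag

    def test_incompatible_geometry_empty(self):
        helix = ideal_helix(20)
        line = CaTrace([(i + 1, "", "ALA", "A") for i in range(20)],
                       np.column_stack([3.8 * np.arange(20.0), np.zeros(20), np.zeros(20)]))
        assert find_afps(helix, line, 8, 1.0) == []

    def test_diverged_pair_keeps_diagonal(self, core_spec, core_structure):
        tr = ca_trace(core_structure.models[0])
        tr2 = ca_trace(perturb(core_structure, 0.2, seed=8).models[0])
        afps = find_afps(tr, tr2, 8, 3.0)
        present = {(a.i, a.j) for a in afps}
        assert all((i, i) in present for i in range(len(tr) - 7))


class TestRigidFlexible:
    def test_self_alignment_complete(self, core_trace):
        aln = rigid_align(core_trace, core_trace)
        assert aln.n_equiv == len(core_trace)
        assert aln.rmsd < 0.01
        assert not aln.twists

    def test_rigid_invariance_under_rotation(self, core_trace):
        base = rigid_align(core_trace, core_trace)
        for seed in (0, 1):
            moved = CaTrace(core_trace.labels, rigid_transform(core_trace.coords, seed))
            aln = rigid_align(core_trace, moved)
            assert aln.pairs == base.pairs
            assert aln.rmsd < 1e-3

    def test_hinge_limits_rigid_coverage(self, hinge_pair):
        tr, trh = hinge_pair
        aln = rigid_align(tr, trh)
        assert aln.n_equiv < 0.6 * len(tr)

    def test_flexible_recovers_hinge_with_one_twist(self, hinge_pair):
        tr, trh = hinge_pair
        aln = flexible_align(tr, trh)
        assert aln.n_equiv >= 0.95 * len(tr)
        assert len(aln.twists) == 1
        assert aln.rmsd < 1.0

    def test_flexible_self_alignment_zero_twists(self, core_trace):
        assert not flexible_align(core_trace, core_trace).twists

    def test_score_symmetry(self):
        for seed in range(20):
            A, B = random_bundle_pair(seed + 3000)
            sab = flexible_align(A, B).raw_score
            sba = flexible_align(B, A).raw_score
            assert abs(sab - sba) <= 0.01 * max(sab, sba, 1.0)

    def test_flexible_at_least_rigid_minus_twist_penalty(self):
        params = AlignParams()
        for seed in (11, 12, 13):
            A, B = random_bundle_pair(seed)
            r = rigid_align(A, B, params).raw_score
            f = flexible_align(A, B, params).raw_score
            assert f >= r - params.twist_penalty - 1e-9

    def test_no_alignment_result(self):
        helix = ideal_helix(20)
        line = CaTrace([(i + 1, "", "ALA", "A") for i in range(20)],
                       np.column_stack([3.8 * np.arange(20.0), np.zeros(20), np.zeros(20)]))
        aln = rigid_align(helix, line)
        assert aln.n_equiv == 0 and aln.p_value == 1.0 and aln.raw_score == 0.0


class TestScore:
    def test_perfect_positions(self):
        assert alignment_score(np.zeros(250)) == 1000.0

    def test_twist_penalty(self):
        assert alignment_score(np.zeros(250), n_twists=2) == 900.0

    def test_beyond_cutoff_scores_zero(self):
        assert alignment_score(np.full(50, 5.0)) == 0.0
        assert alignment_score(np.full(50, 12.0)) == 0.0

    def test_negative_deviation_rejected(self):
        with pytest.raises(ValueError):
            alignment_score([-1.0])


class TestPValues:
    CAL = NullCalibration(location=200.0, scale=60.0, n_samples=100, seed=0)

    def test_closed_form_at_location(self):
        assert score_pvalue(200.0, self.CAL) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_limits_and_monotonicity(self):
        assert score_pvalue(-1e9, self.CAL) == 1.0
        grid = [score_pvalue(s, self.CAL) for s in np.linspace(-500, 3000, 50)]
        assert all(a >= b for a, b in zip(grid, grid[1:]))
        assert grid[-1] > 0

    def test_calibration_reproducible_and_sane(self, core_trace):
        cal = calibrate_null(random_bundle_pair, n=60, seed=5)
        cal2 = calibrate_null(random_bundle_pair, n=60, seed=5)
        assert (cal.location, cal.scale) == (cal2.location, cal2.scale)
        scores = [flexible_align(*random_bundle_pair(5 * 100003 + k)).raw_score
                  for k in range(60)]
        p_med = score_pvalue(float(np.median(scores)), cal)
        assert abs(p_med - 0.5) <= 0.05
        self_p = score_pvalue(flexible_align(core_trace, core_trace).raw_score, cal)
        assert self_p < 0.05

    def test_calibration_needs_enough_samples(self):
        with pytest.raises(ValueError):
            calibrate_null(random_bundle_pair, n=10, seed=0)


def _ground_truth_core(spec: BundleSpec, trace_a: CaTrace, trace_b: CaTrace) -> CoreAssignment:
    """Core assignment built from the generator's known helix ranges."""
    pairs = []
    for a, b in spec.helix_ranges:
        sa = HelixSegment(a, b, np.array([0.0, 0.0, 1.0]), trace_a.coords[a:b + 1].mean(axis=0))
        sb = HelixSegment(a, b, np.array([0.0, 0.0, 1.0]), trace_b.coords[a:b + 1].mean(axis=0))
        pairs.append((sa, sb))
    return CoreAssignment(pairs=pairs)


class TestBlockRotation:
    def test_identity_is_zero(self, core_spec, core_trace):
        core = _ground_truth_core(core_spec, core_trace, core_trace)
        assert block_rotation(core_trace, core_trace, core).angle < 1e-6

    @pytest.mark.parametrize("angle", [10.0, 45.0, 90.0, 115.0, 160.0])
    def test_planted_angles_recovered(self, core_spec, core_structure, core_trace, angle):
        stop = core_spec.helix_ranges[2][1] + 3
        rot = apply_block_rotation(core_structure, (0, stop), [0, 0, 1], angle,
                                   core_trace.coords[stop])
        trh = ca_trace(rot.models[0])
        core = _ground_truth_core(core_spec, core_trace, trh)
        rep = block_rotation(core_trace, trh, core)
        assert abs(rep.angle - angle) < 1.0

    @pytest.mark.parametrize("angle", [45.0, 115.0])
    def test_planted_angles_under_noise(self, core_spec, core_structure, core_trace, angle):
        stop = core_spec.helix_ranges[2][1] + 3
        rot = apply_block_rotation(core_structure, (0, stop), [0, 0, 1], angle,
                                   core_trace.coords[stop])
        noisy = ca_trace(perturb(rot, 0.5, seed=9).models[0])
        core = _ground_truth_core(core_spec, core_trace, noisy)
        rep = block_rotation(core_trace, noisy, core)
        assert abs(rep.angle - angle) < 5.0

    def test_missing_label_errors(self, core_spec, core_trace):
        core = _ground_truth_core(core_spec, core_trace, core_trace)
        core.pairs = core.pairs[:3]
        with pytest.raises(LookupError):
            block_rotation(core_trace, core_trace, core)


class TestSeqIdentity:
    def _aln(self, n):
        from structphylo.align3d import StructAlignment
        return StructAlignment(pairs=[(i, i) for i in range(n)])

    def test_identical(self):
        assert seq_identity(self._aln(4), "ACDE", "ACDE") == 100.0

    def test_disjoint(self):
        assert seq_identity(self._aln(4), "ACDE", "FGHI") == 0.0

    def test_half(self):
        assert seq_identity(self._aln(4), "ACDE", "ACXX") == 50.0

    def test_empty_errors(self):
        from structphylo.align3d import StructAlignment
        with pytest.raises(ValueError):
            seq_identity(StructAlignment(pairs=[]), "A", "A")
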