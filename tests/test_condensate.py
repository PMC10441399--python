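"""Contact order parameter, clustering, H-bond and SASA analyses."""

import numpy as np
import pytest

from sytllps import condensate
from sytllps.cgsim import Frame, Topology, Trajectory
from sytllps.condensate import (
    AnalysisError,
    ContactParams,
    ContactSeries,
    HBondCriteria,
    cluster_chains,
    compute_deltaQ,
    compute_Q,
    compute_q_single,
    compute_sasa,
    contact_series,
    detect_hbonds,
    qij,
    sasa_masking_report,
)


def make_topology(n_chains, beads_per_chain, charges=None):
    n = n_chains * beads_per_chain
    bonds = []
    for c in range(n_chains):
        off = c * beads_per_chain
        bonds.extend((off + i, off + i + 1) for i in range(beads_per_chain - 1))
    return Topology(
        n_chains=n_chains,
        beads_per_chain=beads_per_chain,
        bond_pairs=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        charge=np.zeros(n) if charges is None else charges,
        stickiness=np.zeros(n),
        bead_sigma=np.full(n, 0.6),
    )


def q_bruteforce(coords, box, r0, pbc=True):
    """O(N^2) python double-loop oracle for the contact order parameter."""
    n = coords.shape[0]
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = coords[i] - coords[j]
            if pbc:
                d = d - box * np.round(d / box)
            r = np.sqrt(np.dot(d, d))
            total += 1.0 / (1.0 + (r / r0) ** 6)
    return total


class TestSwitchingFunction:
    def test_reference_values(self):
        assert qij(0.0) == 1.0
        assert qij(0.5, 0.5) == 0.5
        assert qij(1.0, 0.5) == pytest.approx(1.0 / 65.0)

    def test_rational_form_identity_off_singularity(self):
        # 1/(1+x^6) equals (1-x^6)/(1-x^12) wherever the latter is defined
        r = np.array([0.1, 0.3, 0.499, 0.501, 0.9, 2.0])
        x = r / 0.5
        assert np.allclose(qij(r, 0.5), (1 - x**6) / (1 - x**12))

    def test_monotone_decreasing_and_bounded(self):
        r = np.linspace(0.0, 5.0, 200)
        q = qij(r, 0.5)
        assert np.all(np.diff(q) < 0)
        assert np.all((q > 0) & (q <= 1))
        assert qij(50.0, 0.5) < 1e-10


class TestContactOrderParameter:
    def test_two_beads_at_r0(self):
        topo = make_topology(1, 2)
        frame = Frame(np.array([[1.0, 1, 1], [1.5, 1, 1]]), box_edge_nm=10.0)
        assert compute_Q(frame, topo, ContactParams()) == pytest.approx(0.5)

    def test_three_collinear_beads(self):
        topo = make_topology(1, 3)
        frame = Frame(
            np.array([[1.0, 1, 1], [1.5, 1, 1], [2.0, 1, 1]]), box_edge_nm=10.0
        )
        expected = 0.5 + 0.5 + 1.0 / 65.0
        assert compute_Q(frame, topo, ContactParams()) == pytest.approx(expected)

    def test_matches_bruteforce_oracle_on_random_frames(self):
        rng = np.random.default_rng(21)
        topo = make_topology(2, 10)
        params = ContactParams()
        for _ in range(100):
            coords = rng.uniform(0, 6.0, (20, 3))
            frame = Frame(coords, box_edge_nm=6.0)
            assert compute_Q(frame, topo, params) == pytest.approx(
                q_bruteforce(coords, 6.0, 0.5), abs=1e-12 * 400
            )

    def test_minimum_image_wraps(self):
        topo = make_topology(1, 2)
        # across the boundary: true separation 0.5, naive 9.5
        frame = Frame(np.array([[0.25, 1, 1], [9.75, 1, 1]]), box_edge_nm=10.0)
        assert compute_Q(frame, topo, ContactParams()) == pytest.approx(0.5)
        no_pbc = ContactParams(pbc=False)
        assert compute_Q(frame, topo, no_pbc) < 1e-6

    def test_exclude_bonded_policy(self):
        topo = make_topology(1, 3)
        coords = np.array([[1.0, 1, 1], [1.5, 1, 1], [2.0, 1, 1]])
        frame = Frame(coords, box_edge_nm=10.0)
        full = compute_Q(frame, topo, ContactParams())
        reduced = compute_Q(frame, topo, ContactParams(exclusions="exclude-bonded"))
        assert reduced == pytest.approx(full - 1.0)  # two bonded pairs at r0

    def test_size_mismatch_rejected(self):
        topo = make_topology(1, 3)
        frame = Frame(np.zeros((4, 3)), box_edge_nm=10.0)
        with pytest.raises(AnalysisError):
            compute_Q(frame, topo, ContactParams())


class TestQSingleAndDeltaQ:
    def test_rigid_chain_average_is_single_frame_q(self):
        topo = make_topology(1, 5)
        coords = np.cumsum(
            np.vstack([[2.0, 2, 2], *([[0.38, 0, 0]] * 4)]), axis=0
        )
        frames = [Frame(coords, 10.0, time_ps=t) for t in range(4)]
        traj = Trajectory(topology=topo, frames=frames)
        q1 = compute_Q(frames[0], topo, ContactParams())
        assert compute_q_single(traj, ContactParams()) == pytest.approx(q1)

    def test_two_frame_average(self):
        topo = make_topology(1, 2)
        near = Frame(np.array([[1.0, 1, 1], [1.5, 1, 1]]), 10.0)
        far = Frame(np.array([[1.0, 1, 1], [4.0, 1, 1]]), 10.0)
        traj = Trajectory(topology=topo, frames=[near, far])
        qa = compute_Q(near, topo, ContactParams())
        qb = compute_Q(far, topo, ContactParams())
        assert compute_q_single(traj, ContactParams()) == pytest.approx((qa + qb) / 2)

    def test_straight_chain_closed_form(self):
        # beads on a line at 0.38 nm spacing: pair distances are k*0.38
        n = 63
        topo = make_topology(1, n)
        coords = np.zeros((n, 3))
        coords[:, 0] = 2.0 + 0.38 * np.arange(n)
        frame = Frame(coords, 40.0)
        expected = sum(
            (n - k) / (1.0 + (0.38 * k / 0.5) ** 6) for k in range(1, n)
        )
        traj = Trajectory(topology=topo, frames=[frame])
        assert compute_q_single(traj, ContactParams()) == pytest.approx(expected)

    def test_multichain_rejected_for_baseline(self):
        topo = make_topology(2, 2)
        traj = Trajectory(
            topology=topo, frames=[Frame(np.zeros((4, 3)) + 1.0, 10.0)]
        )
        with pytest.raises(AnalysisError):
            compute_q_single(traj, ContactParams())

    def test_deltaq_identity_and_dispersed_limit(self):
        assert np.allclose(compute_deltaQ(np.array([10.0, 12.0]), 2, 5.0), [0.0, 2.0])
        # N frozen identical chains far apart: dQ ~ 0
        n_chains, n_res = 10, 5
        topo = make_topology(n_chains, n_res)
        conf = np.cumsum(
            np.vstack([[0.0, 0, 0], *([[0.38, 0, 0]] * (n_res - 1))]), axis=0
        )
        box = 60.0
        coords = np.vstack(
            [conf + np.array([3.0 + 5.5 * k, 3.0 + 5.5 * k, 3.0]) for k in range(n_chains)]
        )
        frame = Frame(coords, box)
        q = compute_Q(frame, topo, ContactParams())
        topo1 = make_topology(1, n_res)
        q_single = compute_q_single(
            Trajectory(topology=topo1, frames=[Frame(conf + 3.0, box)]),
            ContactParams(),
        )
        dq = compute_deltaQ(np.array([q]), n_chains, q_single)
        assert abs(dq[0]) < 1e-3

    def test_contact_series_asserts_identity(self):
        with pytest.raises(AnalysisError):
            ContactSeries(
                times_ps=np.array([0.0]),
                Q=np.array([5.0]),
                q_single_mean=1.0,
                n_chains=2,
                deltaQ=np.array([99.0]),
            )


class TestClustering:
    def test_distant_chains_are_singletons(self):
        topo = make_topology(3, 2)
        coords = np.array(
            [[1, 1, 1], [1.4, 1, 1], [5, 5, 5], [5.4, 5, 5], [9, 9, 1], [9.4, 9, 1]],
            dtype=float,
        )
        res = cluster_chains(Frame(coords, 20.0), topo, 0.8)
        assert len(np.unique(res.labels)) == 3
        assert res.largest_fraction == pytest.approx(1 / 3)

    def test_shared_close_pair_merges_two_chains(self):
        topo = make_topology(2, 2)
        coords = np.array(
            [[1, 1, 1], [1.4, 1, 1], [1.9, 1, 1], [2.3, 1, 1]], dtype=float
        )
        res = cluster_chains(Frame(coords, 20.0), topo, 0.8)
        assert res.labels[0] == res.labels[1]
        assert res.largest_fraction == 1.0

    def test_chain_of_contacts_with_isolated_chain(self):
        # A-B-C connected transitively; D alone
        topo = make_topology(4, 1)
        coords = np.array(
            [[1.0, 1, 1], [1.6, 1, 1], [2.2, 1, 1], [8.0, 8, 8]]
        )
        res = cluster_chains(Frame(coords, 20.0), topo, 0.8)
        assert res.labels[0] == res.labels[1] == res.labels[2]
        assert res.labels[3] != res.labels[0]
        assert sorted(res.sizes.tolist()) == [1, 3]
        assert res.largest_fraction == pytest.approx(0.75)

    def test_matches_bruteforce_components(self):
        rng = np.random.default_rng(5)
        topo = make_topology(5, 4)
        for _ in range(20):
            coords = rng.uniform(0, 8.0, (20, 3))
            frame = Frame(coords, 8.0)
            res = cluster_chains(frame, topo, 0.9)
            # brute-force union-find over chain pairs
            parent = list(range(5))
            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x
            cid = topo.chain_ids
            for i in range(20):
                for j in range(20):
                    if cid[i] >= cid[j]:
                        continue
                    d = coords[i] - coords[j]
                    d -= 8.0 * np.round(d / 8.0)
                    if np.linalg.norm(d) < 0.9:
                        a, b = find(cid[i]), find(cid[j])
                        parent[a] = b
            groups = [find(c) for c in range(5)]
            same_ref = np.equal.outer(groups, groups)
            same_res = np.equal.outer(res.labels, res.labels)
            assert np.array_equal(same_ref, same_res)


class TestHydrogenBonds:
    D = np.array([[0.0, 0, 0]])

    def test_collinear_within_distance_is_bond(self):
        h = np.array([[0.1, 0, 0]])
        a = np.array([[0.30, 0, 0]])
        assert detect_hbonds(self.D, h, a) == [(0, 0)]

    def test_distance_failure(self):
        h = np.array([[0.1, 0, 0]])
        a = np.array([[0.40, 0, 0]])
        assert detect_hbonds(self.D, h, a) == []

    def test_angle_failure(self):
        # D->A along x, D->H at 45 degrees
        h = np.array([[0.07, 0.07, 0]])
        a = np.array([[0.30, 0, 0]])
        assert detect_hbonds(self.D, h, a) == []

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(9)
        h = np.array([[0.09, 0.02, 0]])
        a = np.array([[0.28, 0.05, 0.02]])
        base = detect_hbonds(self.D, h, a)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        t = rng.uniform(-5, 5, 3)
        rot = lambda x: x @ q.T + t
        moved = detect_hbonds(rot(self.D), rot(h), rot(a))
        assert moved == base

    def test_hydrogen_vertex_convention_differs(self):
        # bent geometry: passes at the donor vertex, fails at the hydrogen
        h = np.array([[0.10, 0.0, 0]])
        a = np.array([[0.2, 0.20, 0]])  # D-A 0.28 nm, A-D-H 45 deg -> no bond
        assert detect_hbonds(self.D, h, a) == []
        crit_h = HBondCriteria(angle_vertex="hydrogen")
        # collinear case passes under both conventions
        a2 = np.array([[0.3, 0, 0]])
        assert detect_hbonds(self.D, h * [[1, 0, 0]], a2, crit_h) == [(0, 0)]

    def test_occupancy_and_lifetime(self):
        d = np.zeros((4, 1, 3))
        h = np.tile([[0.1, 0, 0]], (4, 1, 1))
        a = np.tile([[0.3, 0, 0]], (4, 1, 1))
        a[2, 0, 0] = 0.45  # broken in frame 2
        table = condensate.hbond_occupancy(d, h, a)
        assert len(table) == 1
        assert table.occupancy.iloc[0] == pytest.approx(0.75)
        assert table.mean_lifetime_frames.iloc[0] == pytest.approx(1.5)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        rho = 0.15
        sasa = compute_sasa(np.zeros((1, 3)), np.array([rho]))
        exact = 4 * np.pi * (rho + 0.14) ** 2
        assert sasa[0] == pytest.approx(exact, rel=1e-12)

    def test_fully_overlapping_spheres(self):
        coords = np.zeros((2, 3))
        coords[1] += 1e-9
        sasa = compute_sasa(coords, np.array([0.15, 0.15]))
        exact = 4 * np.pi * (0.15 + 0.14) ** 2
        assert sasa.sum() == pytest.approx(exact, rel=0.02)

    def test_convergence_is_monotone(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 0.6, (5, 3))
        radii = np.full(5, 0.17)
        errs = []
        for n in (240, 960, 3840):
            a = compute_sasa(coords, radii, n_sphere_points=n)
            b = compute_sasa(coords, radii, n_sphere_points=4 * n)
            errs.append(np.abs(a - b).max())
        assert errs[0] >= errs[-1]

    def test_buried_probe_bead(self):
        # central bead caged by 26 neighbours on a cubic shell
        offsets = [
            np.array([i, j, k], float)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        coords = np.vstack([[0.0, 0, 0], 0.35 * np.vstack(offsets)])
        radii = np.full(len(coords), 0.17)
        sasa = compute_sasa(coords, radii)
        isolated = 4 * np.pi * (0.17 + 0.14) ** 2
        assert sasa[0] < 0.02 * isolated

    def test_input_validation(self):
        with pytest.raises(AnalysisError):
            compute_sasa(np.zeros((1, 3)), np.array([0.1]), n_sphere_points=8)
        with pytest.raises(AnalysisError):
            compute_sasa(np.zeros((1, 3)), np.array([-0.1]))


class TestSasaMasking:
    def setup_frames(self):
        offsets = [
            np.array([i, j, k], float)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        buried = np.vstack([[0.0, 0, 0], 0.35 * np.vstack(offsets)])
        exposed = np.vstack([[0.0, 0, 0], 5.0 * np.vstack(offsets)])
        return buried, exposed

    def test_identical_contexts_delta_zero_within_ci(self):
        buried, _ = self.setup_frames()
        radii = np.full(len(buried), 0.17)
        rid = np.arange(len(buried))
        res = sasa_masking_report(
            [0], [buried] * 3, [buried] * 3, radii, rid, n_bootstrap=200
        )
        row = res.table.iloc[0]
        assert row.delta_nm2 == pytest.approx(0.0, abs=1e-12)
        assert row.ci_low <= 0.0 <= row.ci_high

    def test_burial_gives_negative_delta_with_ci_excluding_zero(self):
        buried, exposed = self.setup_frames()
        radii = np.full(len(buried), 0.17)
        rid = np.arange(len(buried))
        rng = np.random.default_rng(0)
        cond = [buried + 0.001 * rng.standard_normal(buried.shape) for _ in range(5)]
        isol = [exposed + 0.001 * rng.standard_normal(buried.shape) for _ in range(5)]
        res = sasa_masking_report([0], cond, isol, radii, rid, n_bootstrap=300)
        row = res.table.iloc[0]
        assert row.delta_nm2 < 0
        assert row.ci_high < 0

    def test_empty_targets_empty_table(self):
        buried, _ = self.setup_frames()
        radii = np.full(len(buried), 0.17)
        rid = np.arange(len(buried))
        res = sasa_masking_report([], [buried], [buried], radii, rid)
        assert res.table.empty

    def test_unknown_target_rejected(self):
        buried, _ = self.setup_frames()
        radii = np.full(len(buried), 0.17)
        rid = np.arange(len(buried))
        with pytest.raises(AnalysisError):
            sasa_masking_report([999], [buried], [buried], radii, rid)
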