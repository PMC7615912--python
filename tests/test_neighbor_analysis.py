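"""Directional nearest-neighbor statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from polysite.neighbor_analysis import (
    DistanceHistogram,
    class_distance_correlation,
    close_neighbor_fraction,
    directional_neighbor_enrichment,
    distance_histogram,
    histogram_mode,
    nearest_entry_to_exit,
    nearest_exit_to_entry,
    site_positions,
)
from polysite.rigid_geometry import Pose, SiteDefinition

from conftest import particle_set_from_poses, random_poses


def brute_force_nearest(from_xyz, to_xyz, tomos, cutoff):
    """Independent O(n^2) scan: per point, min distance to any other same-
    tomogram target point."""
    n = len(from_xyz)
    out = np.full(n, np.nan)
    nbr = np.full(n, -1)
    for i in range(n):
        best, who = np.inf, -1
        for j in range(n):
            if i == j or tomos[i] != tomos[j]:
                continue
            d = float(np.linalg.norm(from_xyz[i] - to_xyz[j]))
            if d < best:
                best, who = d, j
        if who >= 0 and best <= cutoff:
            out[i], nbr[i] = best, who
    return out, nbr


@pytest.mark.parametrize("seed,n,cutoff", [(0, 60, 120.0), (1, 120, 120.0), (2, 80, 300.0)])
def test_directional_searches_match_brute_force(sites, seed, n, cutoff):
    rng = np.random.default_rng(seed)
    poses = random_poses(rng, n, box=1500.0)
    tomos = [f"t{int(k)}" for k in rng.integers(0, 3, n)]
    ps = particle_set_from_poses(poses, tomo_ids=tomos)
    E = site_positions(ps, sites["mrna_entry"])
    X = site_positions(ps, sites["mrna_exit"])
    for fn, frm, to in [(nearest_entry_to_exit, E, X), (nearest_exit_to_entry, X, E)]:
        rec = fn(ps, sites, cutoff=cutoff)
        exp_d, exp_j = brute_force_nearest(frm, to, tomos, cutoff)
        got = rec["distance"].to_numpy()
        assert np.allclose(np.nan_to_num(got, nan=-1), np.nan_to_num(exp_d, nan=-1), atol=1e-9)
        for i in range(n):
            if exp_j[i] >= 0:
                assert rec["neighbor_id"][i] == ps.ids()[exp_j[i]]


def test_single_particle_has_no_neighbor(sites):
    ps = particle_set_from_poses([Pose.identity()])
    rec = nearest_entry_to_exit(ps, sites)
    assert rec["neighbor_id"][0] is None and np.isnan(rec["distance"][0])


def test_pair_just_beyond_cutoff_is_absent(sites):
    # place B so that entry(A)->exit(B) is exactly 130 A with a 120 A cutoff
    e = sites["mrna_entry"].offset_ref
    x = sites["mrna_exit"].offset_ref
    a = Pose.identity()
    b = Pose(e + np.array([130.0, 0, 0]) - x, np.eye(3))
    ps = particle_set_from_poses([a, b])
    rec = nearest_entry_to_exit(ps, sites, cutoff=120.0)
    assert np.isnan(rec["distance"][0])
    rec = nearest_entry_to_exit(ps, sites, cutoff=130.0)
    assert np.isclose(rec["distance"][0], 130.0)


def test_directions_mirror_each_other(sites):
    # if i's nearest exit is j at distance d, then j's nearest entry is at
    # most d away (and vice versa); the global minimum is shared exactly
    rng = np.random.default_rng(3)
    ps = particle_set_from_poses(random_poses(rng, 90, box=1200.0))
    fwd = nearest_entry_to_exit(ps, sites)
    rev = nearest_exit_to_entry(ps, sites)
    rev_d = dict(zip(rev["anchor_id"], rev["distance"]))
    fwd_d = dict(zip(fwd["anchor_id"], fwd["distance"]))
    for _, r in fwd.dropna(subset=["distance"]).iterrows():
        assert rev_d[r["neighbor_id"]] <= r["distance"] + 1e-9
    for _, r in rev.dropna(subset=["distance"]).iterrows():
        assert fwd_d[r["neighbor_id"]] <= r["distance"] + 1e-9
    d1, d2 = fwd["distance"].dropna(), rev["distance"].dropna()
    if len(d1) and len(d2):
        assert np.isclose(d1.min(), d2.min(), atol=1e-9)


def test_no_cross_tomogram_pairs(sites):
    # identical geometry in two tomograms: any neighbor must share the tomogram
    rng = np.random.default_rng(4)
    poses = random_poses(rng, 40, box=600.0)
    ps = particle_set_from_poses(poses + poses, tomo_ids=["t1"] * 40 + ["t2"] * 40)
    rec = nearest_entry_to_exit(ps, sites)
    ids = dict(zip(ps.ids(), ps.tomogram_ids()))
    for _, row in rec.dropna(subset=["distance"]).iterrows():
        assert ids[row["anchor_id"]] == ids[row["neighbor_id"]]


def test_results_invariant_under_rigid_motion_and_reordering(sites):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(5)
    poses = random_poses(rng, 70, box=1000.0)
    ps = particle_set_from_poses(poses)
    base = nearest_entry_to_exit(ps, sites)["distance"].to_numpy()

    G = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-500, 500, 3)
    moved = [Pose(G @ p.position + t, G @ p.R) for p in poses]
    d_moved = nearest_entry_to_exit(particle_set_from_poses(moved), sites)["distance"].to_numpy()
    assert np.allclose(np.nan_to_num(base, nan=-1), np.nan_to_num(d_moved, nan=-1), atol=1e-6)

    perm = rng.permutation(len(poses))
    d_perm = nearest_entry_to_exit(
        particle_set_from_poses([poses[i] for i in perm]), sites
    )["distance"].to_numpy()
    assert np.allclose(
        np.nan_to_num(base[perm], nan=-1), np.nan_to_num(d_perm, nan=-1), atol=1e-9
    )


class TestHistogram:
    def _records(self, distances):
        return pd.DataFrame(
            {
                "anchor_id": [f"p{i}" for i in range(len(distances))],
                "neighbor_id": "x",
                "direction": "entry_to_exit",
                "distance": distances,
                "tomogram_id": "t",
            }
        )

    def test_identical_distances_fill_one_bin(self):
        h = distance_histogram(self._records([33.0] * 7))
        assert h.counts.sum() == 7 and (h.counts > 0).sum() == 1

    def test_total_counts_finite_distances_only(self):
        h = distance_histogram(self._records([10.0, np.nan, 50.0, np.nan]))
        assert h.n_total == 2 == h.counts.sum()

    def test_counts_match_sort_and_bucket_oracle(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0, 120, 500)
        h = distance_histogram(self._records(d), bin_width=2.5)
        for k, (lo, hi) in enumerate(zip(h.bin_edges[:-1], h.bin_edges[1:])):
            assert h.counts[k] == int(np.sum((d >= lo) & (d < hi)))

    def test_bins_are_half_open(self):
        h = distance_histogram(self._records([2.5]), bin_width=2.5)
        assert h.counts[1] == 1 and h.counts[0] == 0

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram(self._records([1.0]), bin_width=0)

    def test_mode_center_and_tie_break(self):
        h = DistanceHistogram(np.array([0.0, 2.5, 5.0, 7.5]), np.array([1, 5, 5]), 11)
        assert histogram_mode(h) == 3.75  # tie resolved toward smaller distance
        single = DistanceHistogram(np.array([0.0, 2.5]), np.array([4]), 4)
        assert histogram_mode(single) == 1.25

    def test_mode_of_empty_histogram_rejected(self):
        h = DistanceHistogram(np.array([0.0, 2.5]), np.array([0]), 0)
        with pytest.raises(ValueError):
            histogram_mode(h)

    def test_frame_export_in_nm(self):
        h = distance_histogram(self._records([30.0]), bin_width=5.0)
        frame = h.to_frame()
        assert frame.loc[6, "bin_lo_nm"] == 3.0 and frame.loc[6, "count"] == 1


class TestCloseNeighborFraction:
    def test_isolated_monosomes_give_zero(self, sites):
        poses = [Pose(np.array([i * 1000.0, 0, 0]), np.eye(3)) for i in range(12)]
        out = close_neighbor_fraction(particle_set_from_poses(poses), sites, cutoff_close=60.0)
        assert out["mean"] == 0.0

    def test_k_collided_pairs_among_n(self, sites, pose_library):
        from polysite.rigid_geometry import compose

        rel = pose_library["collided"]
        poses = []
        for k in range(3):  # 3 pairs in contact
            lead = Pose(np.array([k * 3000.0, 0, 0]), np.eye(3))
            poses += [lead, compose(lead, rel)]
        for m in range(6):  # 6 isolated monosomes
            poses.append(Pose(np.array([m * 3000.0, 5000.0, 0]), np.eye(3)))
        out = close_neighbor_fraction(particle_set_from_poses(poses), sites, cutoff_close=60.0)
        assert np.isclose(out["mean"], 6 / 12)

    def test_mean_sd_across_tomograms(self, sites, pose_library):
        from polysite.rigid_geometry import compose

        rel = pose_library["collided"]
        lead = Pose(np.zeros(3), np.eye(3))
        pair = [lead, compose(lead, rel)]
        mono = [Pose(np.array([0, 6000.0, 0]), np.eye(3)), Pose(np.array([6000.0, 6000.0, 0]), np.eye(3))]
        # tomo A: pair + 2 monosomes (0.5); tomo B: 2 monosomes (0.0)
        poses = pair + mono + mono
        tomos = ["A"] * 4 + ["B"] * 2
        out = close_neighbor_fraction(particle_set_from_poses(poses, tomo_ids=tomos), sites)
        assert np.isclose(out["mean"], 0.25)
        assert np.isclose(out["sd"], np.std([0.5, 0.0], ddof=1))


class TestDirectionalEnrichment:
    def test_leading_members_have_exit_side_neighbors_only(self, sites, pose_library):
        from polysite.rigid_geometry import compose

        rel = pose_library["collided"]
        poses, labels = [], []
        for k in range(5):
            lead = Pose(np.array([k * 3000.0, 0, 0]), np.eye(3))
            poses += [lead, compose(lead, rel)]
            labels += ["stalled_lead", "trailing"]
        ps = particle_set_from_poses(poses, labels=labels)
        out = directional_neighbor_enrichment(ps, sites, "stalled_lead", cutoff=120.0)
        assert out["entry_side_fraction"] == 0.0 and out["exit_side_fraction"] == 1.0

    def test_unknown_label_rejected(self, sites):
        ps = particle_set_from_poses([Pose.identity()], labels=["a"])
        with pytest.raises(ValueError, match="absent"):
            directional_neighbor_enrichment(ps, sites, "zzz")

    def test_stalled_lead_scenario_ratio_below_one(self, sites, mixed_field_noise_free):
        # collided-queue leads (chain tail-to-3'-end) see trailing neighbors at
        # the exit side but nothing at the entry side
        field = mixed_field_noise_free
        truth = field.truth.set_index("particle_id")
        labels = []
        for pid in field.particles.ids():
            row = truth.loc[pid]
            is_lead = row["geometry"] == "collided" and row["chain_index"] == truth[
                truth["polysome_id"] == row["polysome_id"]
            ]["chain_index"].max()
            labels.append("lead" if is_lead else "other")
        ps = particle_set_from_poses(field.particles.poses(), tomo_ids=field.particles.tomogram_ids(), labels=labels)
        out = directional_neighbor_enrichment(ps, sites, "lead", cutoff=120.0)
        assert out["exit_side_fraction"] == 1.0
        assert out["ratio"] < 0.5


class TestClassDistanceCorrelation:
    def test_identity_and_negated_covariates(self, sites):
        rng = np.random.default_rng(8)
        ps = particle_set_from_poses(random_poses(rng, 30, box=500.0), labels=["c"] * 30)
        d = nearest_entry_to_exit(ps, sites, cutoff=1e9)["distance"].to_numpy()
        assert np.isclose(class_distance_correlation(ps, sites, "c", d)["rho"], 1.0)
        assert np.isclose(class_distance_correlation(ps, sites, "c", -d)["rho"], -1.0)

    def test_matches_manual_rank_computation(self, sites):
        rng = np.random.default_rng(9)
        ps = particle_set_from_poses(random_poses(rng, 20, box=400.0), labels=["c"] * 20)
        cov = rng.normal(size=20)
        out = class_distance_correlation(ps, sites, "c", cov)
        d = nearest_entry_to_exit(ps, sites, cutoff=1e30)["distance"].to_numpy()
        rd = pd.Series(d).rank().to_numpy()
        rc = pd.Series(cov).rank().to_numpy()
        manual = np.corrcoef(rd, rc)[0, 1]  # Pearson on ranks
        assert np.isclose(out["rho"], manual, atol=1e-12)
        assert out["n"] == 20

    def test_too_few_points_rejected(self, sites):
        ps = particle_set_from_poses([Pose.identity()], labels=["c"])
        with pytest.raises(ValueError):
            class_distance_correlation(ps, sites, "c", np.array([1.0]))
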