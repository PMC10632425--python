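"""Leaflets, contacts, residence, density maps and side-chain angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from asymcycle.lipid_dynamics import (
    assign_leaflets,
    basic_surface_residues,
    contact_series,
    dwell_times,
    kde_density_map,
    min_distance_series,
    residence_fractions,
    sidechain_angle_series,
)
from asymcycle.synthetic_data import (
    BindingSite,
    LipidTruthSpec,
    gen_lipid_trajectory,
)
from conftest import make_micro_trajectory, micro_frame


def rigid_transform_trajectory(traj, rotation=None, translation=(0, 0, 0)):
    import copy

    out = copy.copy(traj)
    coords = traj.coords.copy()
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    out.coords = coords + np.asarray(translation, dtype=float)
    return out


class TestLeaflets:
    def test_two_slab_fixture_splits_evenly(self, lipid_traj_small):
        traj, truth = lipid_traj_small
        la = assign_leaflets(traj)
        assert set(la.ids("upper")) == set(truth["leaflet_design"]["upper"])
        assert set(la.ids("lower")) == set(truth["leaflet_design"]["lower"])

    def test_invariant_to_global_z_translation(self, lipid_traj_small):
        traj, _ = lipid_traj_small
        la0 = assign_leaflets(traj)
        la5 = assign_leaflets(rigid_transform_trajectory(traj, translation=(0, 0, 5)))
        assert la0.leaflet == la5.leaflet
        assert np.allclose(la5.midplane_z - la0.midplane_z, 5.0)

    def test_flip_flopping_lipid_assigned_by_majority(self):
        # two lipids pinned at +/-20 A set the midplane near zero; a third
        # spends 70% of frames above it and must land in the upper leaflet
        from asymcycle.structure_io import TrajectoryView

        n = 100
        coords = np.zeros((n, 4, 3))
        coords[:, 0] = [0.0, 0.0, 0.0]  # one protein atom
        coords[:, 1] = [10.0, 0.0, 20.0]
        coords[:, 2] = [10.0, 0.0, -20.0]
        for f in range(n):
            coords[f, 3] = [15.0, 0.0, 12.0 if f < 70 else -12.0]
        traj = TrajectoryView(
            coords=coords,
            dt_ns=1.0,
            chain=np.array(["A", "L", "L", "L"], dtype=object),
            resid=np.array([1, 900, 901, 902]),
            resname=np.array(["ALA", "POPC", "POPC", "POPC"], dtype=object),
            name=np.array(["CA", "P", "P", "P"], dtype=object),
            element=np.array(["C", "P", "P", "P"], dtype=object),
            is_protein=np.array([True, False, False, False]),
            is_lipid=np.array([False, True, True, True]),
            lipid_id=np.array([-1, 0, 1, 2]),
            is_phosphorus=np.array([False, True, True, True]),
        )
        la = assign_leaflets(traj)
        assert la.leaflet[2] == "upper"
        assert la.leaflet[0] == "upper" and la.leaflet[1] == "lower"

    def test_no_lipids_is_error(self, lipid_traj_small):
        traj, _ = lipid_traj_small
        import copy

        bare = copy.copy(traj)
        bare.is_phosphorus = np.zeros_like(traj.is_phosphorus)
        with pytest.raises(ValueError):
            assign_leaflets(bare)


class TestMinDistance:
    def test_coincident_atoms_give_zero(self):
        traj = make_micro_trajectory([micro_frame(lipid_p=(1.0, 0.0, 0.0))])
        d = min_distance_series(traj, 0)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_distance_exact(self):
        # nearest protein atom to the lipid P is CA(2) at (1,0,0)
        traj = make_micro_trajectory([micro_frame(ca=(1, 0, 0), nz=(2, 0, 0), lipid_p=(9.5, 0, 0))])
        d = min_distance_series(traj, 0)
        assert d[0] == pytest.approx(7.5, abs=1e-9)

    def test_matches_brute_force_oracle(self, lipid_traj_small):
        traj, _ = lipid_traj_small
        sub = traj.coords[:25]
        import copy

        small = copy.copy(traj)
        small.coords = sub
        lid = int(traj.lipid_ids[0])
        series = min_distance_series(small, lid)
        lip = np.flatnonzero((small.lipid_id == lid) & small.heavy)
        prot = np.flatnonzero(small.is_protein & small.heavy)
        for f in range(small.n_frames):
            brute = np.inf
            for i in lip:
                for j in prot:
                    brute = min(brute, np.linalg.norm(small.coords[f, i] - small.coords[f, j]))
            assert series[f] == pytest.approx(brute, abs=1e-10)

    def test_unknown_lipid_id_raises(self, lipid_traj_small):
        traj, _ = lipid_traj_small
        with pytest.raises(ValueError, match="unknown lipid"):
            min_distance_series(traj, 999)


class TestResidence:
    def test_always_bound_site_is_exactly_one(self):
        spec = LipidTruthSpec(
            n_lipids_per_leaflet=5, n_frames=200,
            binding_sites=(BindingSite(101, 1.0, 20.0),), seed=8,
        )
        traj, _ = gen_lipid_trajectory(spec)
        summ = residence_fractions(traj, [("A", 101)])
        assert summ.fractions[("A", 101)] == 1.0

    def test_never_bound_site_is_zero(self):
        spec = LipidTruthSpec(
            n_lipids_per_leaflet=5, n_frames=200,
            binding_sites=(BindingSite(101, 0.0, 20.0),), seed=8,
        )
        traj, _ = gen_lipid_trajectory(spec)
        summ = residence_fractions(traj, [("A", 101)])
        assert summ.fractions[("A", 101)] == 0.0

    def test_estimator_matches_markov_truth(self, lipid_traj_small):
        traj, truth = lipid_traj_small
        residues = [tuple(s["residue"]) for s in truth["binding_sites"]]
        summ = residence_fractions(traj, residues)
        for site in truth["binding_sites"]:
            est = summ.fractions[tuple(site["residue"])]
            assert est == pytest.approx(site["realized_bound_fraction"], abs=0.005)

    def test_summary_stats_are_box_plot_quantities(self, lipid_traj_small):
        traj, truth = lipid_traj_small
        residues = [tuple(s["residue"]) for s in truth["binding_sites"]]
        stats = residence_fractions(traj, residues).stats()
        v = np.array([s["realized_bound_fraction"] for s in truth["binding_sites"]])
        assert stats["min"] <= stats["q1"] <= stats["mean"] or stats["min"] <= stats["q1"] <= stats["max"]
        assert stats["max"] == pytest.approx(v.max(), abs=0.005)
        assert stats["n"] == len(residues)

    def test_empty_residue_list_is_error(self, lipid_traj_small):
        traj, _ = lipid_traj_small
        with pytest.raises(ValueError, match="empty"):
            residence_fractions(traj, [])

    def test_dwell_times_partition_bound_frames(self, lipid_traj_small):
        traj, truth = lipid_traj_small
        res = tuple(truth["binding_sites"][0]["residue"])
        cs = contact_series(traj, res)
        dw = dwell_times(cs)
        assert dw.sum() == cs.bound.sum()
        assert np.all(dw >= 1)


@pytest.fixture(scope="module")
def stationary_and_gliding():
    common = dict(n_lipids_per_leaflet=1, n_frames=1500, seed=12)
    stat_spec = LipidTruthSpec(binding_sites=(BindingSite(101, 1.0, 50.0),), **common)
    glide_spec = LipidTruthSpec(n_gliding=1, **common)
    stat, _ = gen_lipid_trajectory(stat_spec)
    glide, _ = gen_lipid_trajectory(glide_spec)
    return stat, glide


class TestDensityMap:
    def test_density_normalized(self, stationary_and_gliding):
        stat, _ = stationary_and_gliding
        la = assign_leaflets(stat)
        dmap = kde_density_map(stat, la, "upper")
        assert dmap.mass == pytest.approx(1.0, abs=1e-3)

    def test_stationary_peak_near_pinned_position(self, stationary_and_gliding):
        # bandwidth set to the pinned lipid's jitter scale: Scott's rule
        # undersmooths the mode of near-duplicate points
        stat, _ = stationary_and_gliding
        la = assign_leaflets(stat)
        dmap = kde_density_map(stat, la, "upper", bandwidth=0.5)
        p_idx = np.flatnonzero(stat.is_phosphorus)
        # the upper-leaflet bound lipid is lipid 0 by construction
        mean_xy = stat.coords[:, p_idx[0], :2].mean(axis=0)
        px, py, _ = dmap.peak
        assert np.hypot(px - mean_xy[0], py - mean_xy[1]) <= dmap.bandwidth

    def test_stationary_peak_exceeds_gliding_peak(self, stationary_and_gliding):
        stat, glide = stationary_and_gliding
        peaks = {}
        for tag, traj in (("stat", stat), ("glide", glide)):
            la = assign_leaflets(traj)
            dmap = kde_density_map(traj, la, "upper", bandwidth=0.5)
            peaks[tag] = dmap.peak[2]
        assert peaks["stat"] > peaks["glide"]

    def test_doubling_resolution_moves_peak_less_than_one_cell(self, stationary_and_gliding):
        # the gliding trajectory has a broad (multi-A) bandwidth, so the two
        # resolutions produce genuinely different grids
        _, glide = stationary_and_gliding
        la = assign_leaflets(glide)
        d1 = kde_density_map(glide, la, "upper", grid_spacing=1.0)
        d2 = kde_density_map(glide, la, "upper", grid_spacing=0.5)
        assert d1.grid_spacing == 1.0 and d2.grid_spacing == 0.5
        assert abs(d1.peak[0] - d2.peak[0]) <= 1.0
        assert abs(d1.peak[1] - d2.peak[1]) <= 1.0

    def test_empty_shell_raises(self, stationary_and_gliding):
        stat, _ = stationary_and_gliding
        la = assign_leaflets(stat)
        with pytest.raises(ValueError, match="no lipid phosphorus"):
            kde_density_map(stat, la, "upper", shell=0.1)


class TestSidechainAngle:
    def test_collinear_geometry_is_zero(self):
        traj = make_micro_trajectory([micro_frame(ca=(1, 0, 0), nz=(2, 0, 0))])
        series = sidechain_angle_series(traj, ("A", 2))
        assert series.angles[0] == pytest.approx(0.0, abs=1e-3)

    def test_orthogonal_geometry_is_ninety(self):
        traj = make_micro_trajectory([micro_frame(ca=(1, 0, 0), nz=(1, 1, 0))])
        series = sidechain_angle_series(traj, ("A", 2))
        assert series.angles[0] == pytest.approx(90.0, abs=1e-3)

    def test_invariant_under_global_rotation(self):
        frames = [micro_frame(ca=(1, 0, 0), nz=(1.3, 0.8, 0.4))]
        traj = make_micro_trajectory(frames)
        base = sidechain_angle_series(traj, ("A", 2)).angles[0]
        rot = Rotation.from_euler("xyz", [31, -57, 112], degrees=True).as_matrix()
        rotated = rigid_transform_trajectory(traj, rotation=rot, translation=(3, -8, 2))
        after = sidechain_angle_series(rotated, ("A", 2)).angles[0]
        assert after == pytest.approx(base, abs=1e-9)

    def test_non_basic_residue_rejected(self):
        traj = make_micro_trajectory([micro_frame()])
        with pytest.raises(ValueError, match="LYS or ARG"):
            sidechain_angle_series(traj, ("A", 1))

    def test_missing_neighbor_is_error(self, lipid_traj_small):
        traj, _ = lipid_traj_small
        # resid 124 is the last anchor: residue 125 does not exist
        with pytest.raises(ValueError, match="neighbour residue"):
            sidechain_angle_series(traj, ("A", 124))

    def test_angles_within_range_on_generated_trajectory(self, lipid_traj_small):
        traj, _ = lipid_traj_small
        series = sidechain_angle_series(traj, ("A", 103))
        ok = np.isfinite(series.angles)
        assert np.all((series.angles[ok] >= 0) & (series.angles[ok] <= 180))


class TestRigidInvariance:
    def test_residence_invariant_under_rigid_transform(self, lipid_traj_small):
        traj, truth = lipid_traj_small
        residues = [tuple(s["residue"]) for s in truth["binding_sites"][:2]]
        base = residence_fractions(traj, residues)
        rot = Rotation.from_euler("zyx", [40, 10, -25], degrees=True).as_matrix()
        moved = rigid_transform_trajectory(traj, rotation=rot, translation=(7, -4, 11))
        after = residence_fractions(moved, residues)
        assert base.fractions == after.fractions


def test_basic_surface_residues_finds_exposed_anchors(lipid_traj_small):
    traj, _ = lipid_traj_small
    found = basic_surface_residues(traj, threshold=0.2)
    # every anchor lysine points into the bilayer and must be detected
    anchors = {("A", r) for r in range(101, 125)}
    assert anchors.issubset(set(found))
    # the ALA ring residues are not basic and must not appear
    assert all(r >= 101 for _, r in found)
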