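"""Morphometry: volumes, surface areas, sphericity, contacts, deviations."""

import numpy as np
import pytest

from morphodyn import synthetic as sy
from morphodyn.morphometry import (
    AbsentCellError,
    LabeledVolume,
    UnannotatedCellError,
    adjacent_frame_volume_deviation,
    boundary_layer_count,
    cell_surface_area,
    cell_volume,
    contact_areas,
    extract_contacts,
    extract_features,
    sphericity,
    voxel_face_area,
)


def ball_volume(r_vox: int, spacing=(1.0, 1.0, 1.0)) -> LabeledVolume:
    ax = [np.arange(int(2 * r_vox / (s / min(spacing))) + 7) for s in spacing]
    n = 2 * r_vox + 7
    x, y, z = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
    grid = ((x**2 + y**2 + z**2) <= r_vox**2).astype(np.int32)
    return LabeledVolume(grid, spacing)


class TestVolume:
    def test_voxel_count_times_voxel_volume(self):
        grid = np.zeros((12, 12, 12), dtype=np.int32)
        grid[:10, :10, :10] = 1  # 1000 voxels
        vol = LabeledVolume(grid, (0.5, 0.5, 0.5))
        assert cell_volume(vol, 1) == pytest.approx(125.0)

    def test_single_voxel(self):
        grid = np.zeros((3, 3, 3), dtype=np.int32)
        grid[1, 1, 1] = 4
        assert cell_volume(LabeledVolume(grid, (0.4, 0.5, 2.0)), 4) == pytest.approx(0.4)

    def test_absent_label_signals(self):
        grid = np.ones((3, 3, 3), dtype=np.int32)
        with pytest.raises(AbsentCellError):
            cell_volume(LabeledVolume(grid, (1, 1, 1)), 9)


class TestSurfaceAndSphericity:
    def test_ball_area_within_3_percent(self):
        vol = ball_volume(20)
        a = cell_surface_area(vol, 1)
        assert abs(a - 4 * np.pi * 400) / (4 * np.pi * 400) < 0.03
        assert 0.95 <= sphericity(cell_volume(vol, 1), a) <= 1.02

    def test_sphericity_bias_bound_on_balls(self):
        for r in (10, 14, 20):
            vol = ball_volume(r)
            s = sphericity(cell_volume(vol, 1), cell_surface_area(vol, 1))
            assert s <= 1.02

    def test_single_voxel_has_finite_positive_area(self):
        grid = np.zeros((3, 3, 3), dtype=np.int32)
        grid[1, 1, 1] = 1
        assert cell_surface_area(LabeledVolume(grid, (1, 1, 1)), 1) > 0

    def test_split_cube_adds_twice_the_cut_plane(self):
        n = 24
        grid = np.zeros((n + 4, n + 4, n + 4), dtype=np.int32)
        grid[2 : n + 2, 2 : n + 2, 2 : n + 2] = 1
        whole = LabeledVolume(grid, (1.0, 1.0, 1.0))
        a_whole = cell_surface_area(whole, 1)
        halves = grid.copy()
        halves[2 : n // 2 + 2][halves[2 : n // 2 + 2] == 1] = 1
        halves[n // 2 + 2 : n + 2][halves[n // 2 + 2 : n + 2] == 1] = 2
        hv = LabeledVolume(halves, (1.0, 1.0, 1.0))
        cut = n * n
        # exact bookkeeping on the voxel-face estimator
        vf = voxel_face_area(hv, 1) + voxel_face_area(hv, 2) - voxel_face_area(whole, 1)
        assert vf == pytest.approx(2 * cut, rel=1e-12)
        # the mesh estimator rounds the fresh cut edges, so allow a wider band
        a_sum = cell_surface_area(hv, 1) + cell_surface_area(hv, 2)
        assert a_sum - a_whole == pytest.approx(2 * cut, rel=0.15)

    def test_cube_closed_form(self):
        s = 7.0
        assert sphericity(s**3, 6 * s**2) == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-12)

    def test_sphere_closed_form_is_one(self):
        r = 3.3
        assert sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2) == pytest.approx(1.0)

    def test_large_area_drives_sphericity_to_zero(self):
        assert sphericity(1.0, 1e9) < 1e-6

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            sphericity(1.0, -2.0)

    def test_scaling_covariance_exact(self):
        vol1 = ball_volume(8)
        vol2 = LabeledVolume(vol1.grid, (2.0, 2.0, 2.0))
        assert cell_volume(vol2, 1) == pytest.approx(8 * cell_volume(vol1, 1), rel=1e-12)
        assert cell_surface_area(vol2, 1) == pytest.approx(
            4 * cell_surface_area(vol1, 1), rel=1e-6  # mesh verts are float32
        )
        assert voxel_face_area(vol2, 1) == pytest.approx(4 * voxel_face_area(vol1, 1), rel=1e-12)

    def test_voxel_face_oracle_on_block(self):
        grid = np.zeros((6, 6, 6), dtype=np.int32)
        grid[1:5, 1:5, 1:5] = 1
        # 4x4x4 block: 6 faces x 16 voxel faces
        assert voxel_face_area(LabeledVolume(grid, (1, 1, 1)), 1) == pytest.approx(96.0)


def brute_force_contacts(grid: np.ndarray, spacing) -> dict:
    """Independent all-voxel-pairs adjacency enumeration (oracle)."""
    dx, dy, dz = spacing
    fa = {0: dy * dz, 1: dx * dz, 2: dx * dy}
    out: dict = {}
    nx, ny, nz = grid.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                a = grid[i, j, k]
                if a == 0:
                    continue
                for axis, (di, dj, dk) in enumerate(((1, 0, 0), (0, 1, 0), (0, 0, 1))):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if ii < nx and jj < ny and kk < nz:
                        b = grid[ii, jj, kk]
                        if b != 0 and b != a:
                            key = (min(a, b), max(a, b))
                            out[key] = out.get(key, 0.0) + fa[axis]
    return out


class TestContacts:
    def test_full_face_contact_area(self):
        grid = np.zeros((20, 10, 10), dtype=np.int32)
        grid[:10] = 1
        grid[10:] = 2
        areas = contact_areas(LabeledVolume(grid, (0.5, 0.5, 0.5)))
        assert areas == {(1, 2): pytest.approx(25.0)}  # 100 faces x 0.25

    def test_one_voxel_gap_means_no_contact(self):
        grid = np.zeros((21, 10, 10), dtype=np.int32)
        grid[:10] = 1
        grid[11:] = 2
        assert contact_areas(LabeledVolume(grid, (0.5, 0.5, 0.5))) == {}

    def test_symmetry_of_pair_key(self):
        grid = np.zeros((4, 4, 4), dtype=np.int32)
        grid[:2] = 5
        grid[2:] = 3
        areas = contact_areas(LabeledVolume(grid, (1, 1, 1)))
        assert list(areas) == [(3, 5)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(8, 21, size=3))
        # random smooth label field: nearest of a few random seed points
        k = int(rng.integers(3, 7))
        pts = rng.uniform(0, 1, size=(k, 3)) * np.array(shape)
        coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
        d = ((coords[..., None, :] - pts) ** 2).sum(-1)
        grid = (np.argmin(d, axis=-1) + 1).astype(np.int32)
        grid[rng.uniform(size=shape) < 0.1] = 0  # punch exterior holes
        spacing = tuple(rng.uniform(0.4, 1.5, size=3))
        fast = contact_areas(LabeledVolume(grid, spacing))
        slow = brute_force_contacts(grid, spacing)
        assert set(fast) == set(slow)
        for key in fast:
            assert fast[key] == pytest.approx(slow[key], rel=1e-9)


@pytest.fixture(scope="module")
def rendered(small_spec):
    prog = sy.LineageProgram(
        divisions=[
            sy.DivisionProgram("P0", ("AB", "P1"), 0.0, 0.0, 1.35),
            sy.DivisionProgram("AB", ("ABa", "ABp"), 20.0, 0.0, 1.0),
        ]
    )
    tree = sy.generate_lineage(prog, small_spec, seed=0)
    homes = sy.home_positions(tree, prog, small_spec)
    frames = [
        sy.render_labels(tree, prog, small_spec, f, homes=homes) for f in (20, 21, 22, 23)
    ]
    return prog, tree, frames


class TestExtractFeatures:

    def test_roundtrip_volumes_within_5_percent(self, rendered, small_spec):
        prog, tree, frames = rendered
        tracks = extract_features(frames, tree)
        for f_idx, vol in enumerate(frames):
            fr = vol.frame
            fracs = sy.target_fractions(tree, prog, small_spec, fr)
            total = sum(
                tracks[n].volume[fr - tracks[n].frames[0]] for n in fracs if n in tracks
            )
            for name, frac in fracs.items():
                v = tracks[name].volume[fr - tracks[name].frames[0]]
                if frac * total / small_spec.eggshell_volume > 0:
                    assert abs(v / total - frac) / frac < 0.05

    def test_division_splits_tracks_at_cytokinesis(self, rendered):
        prog, tree, frames = rendered
        tracks = extract_features(frames, tree)
        div = tree["AB"].division_frame  # frame 22 (anaphase 20 + lag 2)
        assert tracks["AB"].frames[-1] == div - 1
        assert tracks["ABa"].frames[0] == div

    def test_volume_conservation_per_frame(self, rendered):
        _, tree, frames = rendered
        tracks = extract_features(frames, tree, feature_list=("volume",))
        vol = frames[0]
        total = np.count_nonzero(vol.grid) * vol.voxel_volume
        live = [n for n in tracks if vol.frame in tracks[n].frames]
        s = sum(tracks[n].volume[vol.frame - tracks[n].frames[0]] for n in live)
        assert s == pytest.approx(total, rel=1e-12)

    def test_unnamed_labels_rejected(self):
        grid = np.zeros((4, 4, 4), dtype=np.int32)
        grid[:2] = 1
        grid[2:] = 2
        vol = LabeledVolume(grid, (1, 1, 1), names={1: "AB"})
        with pytest.raises(UnannotatedCellError):
            extract_features([vol])

    def test_static_single_cell_movie_constant_track(self):
        grid = np.zeros((8, 8, 8), dtype=np.int32)
        grid[2:6, 2:6, 2:6] = 1
        frames = [
            LabeledVolume(grid, (1, 1, 1), frame=i, time_min=i * 0.5, names={1: "P0"})
            for i in range(3)
        ]
        tracks = extract_features(frames)
        assert np.ptp(tracks["P0"].volume) == 0.0
        assert np.ptp(tracks["P0"].sphericity) == 0.0

    def test_optional_shape_features(self):
        grid = np.zeros((12, 8, 8), dtype=np.int32)
        grid[1:11, 2:6, 2:6] = 1  # elongated box
        vol = LabeledVolume(grid, (1, 1, 1), names={1: "AB"})
        tracks = extract_features([vol], feature_list=("volume", "axis_lengths", "elongation", "flatness"))
        tr = tracks["AB"]
        assert tr.features["elongation"][0] < 1.0
        lengths = tr.features["axis_lengths"][0]
        assert lengths[0] > lengths[1] >= lengths[2]


class TestContactTracksAndDeviation:
    def test_extract_contacts_tracks_areas(self):
        g1 = np.zeros((8, 4, 4), dtype=np.int32)
        g1[:4] = 1
        g1[4:] = 2
        g2 = g1.copy()
        g2[4:] = 0  # contact disappears at frame 1
        names = {1: "AB", 2: "P1"}
        frames = [
            LabeledVolume(g1, (1, 1, 1), frame=0, names=names),
            LabeledVolume(g2, (1, 1, 1), frame=1, names=names),
        ]
        tracks = extract_contacts(frames)
        ct = tracks[("AB", "P1")]
        assert ct.integral_area == pytest.approx(16.0)
        assert ct.contact_frames == 1

    def test_constant_volume_deviation_zero(self):
        from morphodyn.morphometry import FeatureTrack

        tr = FeatureTrack("AB", np.arange(5), np.arange(5) * 0.5, {"volume": np.full(5, 7.0)})
        assert adjacent_frame_volume_deviation(tr) == 0.0

    def test_deviation_direct_values(self):
        from morphodyn.morphometry import FeatureTrack

        tr = FeatureTrack("AB", np.arange(2), np.arange(2.0), {"volume": np.array([100.0, 110.0])})
        assert adjacent_frame_volume_deviation(tr) == pytest.approx(10 / 105)
        tr2 = FeatureTrack(
            "AB", np.arange(3), np.arange(3.0), {"volume": np.array([1.0, 2.0, 4.0])}
        )
        assert adjacent_frame_volume_deviation(tr2) == pytest.approx(2 / 3)

    def test_length_one_track_undefined(self):
        from morphodyn.morphometry import FeatureTrack

        tr = FeatureTrack("AB", np.arange(1), np.arange(1.0), {"volume": np.array([5.0])})
        with pytest.raises(ValueError):
            adjacent_frame_volume_deviation(tr)


class TestBoundaryLayer:
    def test_block_counts(self):
        grid = np.zeros((12, 12, 12), dtype=np.int32)
        grid[1:11, 1:11, 1:11] = 1
        assert boundary_layer_count(LabeledVolume(grid, (1, 1, 1)), 1) == 1000 - 512

    def test_small_blocks(self):
        g = np.zeros((5, 5, 5), dtype=np.int32)
        g[1:4, 1:4, 1:4] = 1
        assert boundary_layer_count(LabeledVolume(g, (1, 1, 1)), 1) == 26
        g2 = np.zeros((3, 3, 3), dtype=np.int32)
        g2[1, 1, 1] = 1
        assert boundary_layer_count(LabeledVolume(g2, (1, 1, 1)), 1) == 1
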