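"""Phantom generator: geometry invariants, determinism, exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from muvnet import (
    DeviceGeometry,
    PlacementError,
    RenderParams,
    StromalCell,
    ValidationError,
    VesselGraph,
    make_default_geometry,
    read_zstack,
    render,
    render_zstack,
    sample_network,
    sample_scene,
    write_phantom,
    write_zstack,
)
from muvnet.synthgen import LABEL_BACKGROUND, LABEL_VESSEL

from conftest import noiseless_params, single_segment_scene
from oracles import stadium_area


class TestGeometry:
    def test_default_layout(self, geometry):
        assert len(geometry.pore_positions) == 54
        assert geometry.channel_length == 10500
        assert geometry.channel_width == 1300
        assert geometry.media_channel_width == 500

    def test_pores_evenly_spaced_with_half_margins(self, geometry):
        bottom = [x for x, y in geometry.pore_positions if y == 0]
        top = [x for x, y in geometry.pore_positions if y == 1300]
        assert len(bottom) == len(top) == 27
        spacing = 10500 / 27
        assert bottom[0] == pytest.approx(spacing / 2)
        assert np.allclose(np.diff(bottom), spacing)
        assert bottom == top  # mirrored across the channel

    def test_nonpositive_window_radius_rejected(self):
        with pytest.raises(ValidationError):
            make_default_geometry(pore_window_radius=0)

    @pytest.mark.parametrize(
        "mutation",
        [
            lambda p: p[:-1],                      # wrong pore count
            lambda p: [(x, 650.0) for x, _ in p],  # off the long edges
            lambda p: p[1:2] + p[0:1] + p[2:],     # x not increasing
        ],
    )
    def test_pore_invariants_enforced(self, geometry, mutation):
        with pytest.raises(ValidationError):
            DeviceGeometry(
                pore_positions=mutation(list(geometry.pore_positions)),
                pore_window_radius=geometry.pore_window_radius,
            )


class TestSampleNetwork:
    def test_connected_pore_count_matches_request(self, geometry):
        for n in (0, 1, 10):
            graph = sample_network(geometry, n_connected_pores=n, seed=7)
            assert len(graph.connected_pores) == n

    def test_zero_pores_means_no_pore_anchored_segments(self, geometry):
        graph = sample_network(geometry, n_connected_pores=0, seed=3)
        assert graph.pore_anchors == {}
        assert len(graph.segments) > 0  # interior network still exists

    def test_too_many_pores_rejected(self, geometry):
        with pytest.raises(ValidationError):
            sample_network(geometry, n_connected_pores=55)

    def test_same_seed_reproduces_graph_and_render(self, geometry):
        scenes = [sample_scene(geometry, n_connected_pores=5, n_cells=10,
                               seed=42) for _ in range(2)]
        params = RenderParams(pixel_size=8.0, seed=42)
        (img_a, truth_a), (img_b, truth_b) = (render(s, params) for s in scenes)
        assert img_a.pixels.tobytes() == img_b.pixels.tobytes()
        assert truth_a.label_map.tobytes() == truth_b.label_map.tobytes()
        assert truth_a.coverage_fraction == truth_b.coverage_fraction
        assert truth_a.connected_pores == truth_b.connected_pores

    def test_self_loop_and_bad_diameter_rejected(self):
        with pytest.raises(ValidationError):
            VesselGraph(nodes=np.zeros((2, 2)), segments=[(0, 0, 10.0)])
        with pytest.raises(ValidationError):
            VesselGraph(nodes=np.zeros((2, 2)), segments=[(0, 1, 0.0)])


class TestRender:
    def test_image_dimensions_round_up(self, geometry):
        scene = single_segment_scene(geometry, (1000, 650), (2000, 650), 40)
        img, _ = render(scene, noiseless_params(pixel_size=8.0))
        assert img.pixels.shape == (163, 1313)  # ceil(1300/8), ceil(10500/8)

    def test_single_segment_matches_stadium_area(self, geometry):
        # y=651 keeps the tube boundary off the pixel-centre rows: boundary
        # ties are a half-pixel rasterization ambiguity, not an area error
        scene = single_segment_scene(geometry, (1000, 651), (2000, 651), 40)
        _, truth = render(scene, noiseless_params(pixel_size=4.0))
        analytic = stadium_area(1000, 40) / (10500 * 1300)
        assert truth.coverage_fraction == pytest.approx(analytic, rel=0.02)

    def test_empty_scene_is_background_only(self, geometry):
        scene = single_segment_scene(geometry, (0, 0), (1, 0), 1)
        scene.graph.segments.clear()
        img, truth = render(scene, noiseless_params(pixel_size=8.0))
        assert truth.coverage_fraction == 0.0
        assert (truth.label_map == LABEL_BACKGROUND).all()
        assert np.unique(img.pixels).size == 1

    def test_coverage_consistent_across_resolutions(self, geometry):
        scene = sample_scene(geometry, n_connected_pores=8, n_cells=0,
                             n_debris=0, seed=11)
        covs = [render(scene, noiseless_params(pixel_size=p))[1].coverage_fraction
                for p in (2.0, 4.0)]
        assert covs[0] == pytest.approx(covs[1], rel=0.02)

    def test_adding_a_segment_never_decreases_coverage(self, geometry):
        scene = sample_scene(geometry, n_connected_pores=5, n_cells=0,
                             n_debris=0, seed=13)
        _, before = render(scene, noiseless_params(pixel_size=8.0))
        scene.graph.nodes = np.vstack([scene.graph.nodes, [[3000, 400], [4000, 900]]])
        k = len(scene.graph.nodes)
        scene.graph.segments.append((k - 2, k - 1, 30.0))
        _, after = render(scene, noiseless_params(pixel_size=8.0))
        assert after.coverage_fraction >= before.coverage_fraction

    def test_coverage_equals_label_map_fraction_exactly(self, geometry):
        scene = sample_scene(geometry, n_connected_pores=5, seed=5)
        _, truth = render(scene, noiseless_params(pixel_size=8.0))
        assert truth.coverage_fraction == (truth.label_map == LABEL_VESSEL).mean()

    def test_subpixel_vessel_triggers_warning(self, geometry):
        scene = single_segment_scene(geometry, (1000, 650), (2000, 650), 10)
        _, truth = render(scene, noiseless_params(pixel_size=8.0))
        assert any("unreliable" in w for w in truth.warnings)

    def test_phantom_roundtrip_to_disk(self, geometry, tmp_path):
        scene = single_segment_scene(geometry, (1000, 650), (2000, 650), 40)
        img, truth = render(scene, noiseless_params(pixel_size=8.0))
        paths = write_phantom(tmp_path / "p", img, truth)
        import json
        import tifffile

        assert tifffile.imread(paths["image"]).tobytes() == img.pixels.tobytes()
        sidecar = json.loads((tmp_path / "p" / "truth.json").read_text())
        assert sidecar["coverage_fraction"] == truth.coverage_fraction
        assert sidecar["connected_pores"] == sorted(truth.connected_pores)


@pytest.fixture(scope="module")
def vessel_scene():
    return sample_scene(make_default_geometry(), n_connected_pores=6,
                        n_cells=0, n_debris=0, seed=21)


class TestRenderZStack:

    def test_planted_contacts_are_face_adjacent(self, vessel_scene):
        from scipy import ndimage

        cells = [StromalCell(radius_um=6, contact=(i < 3)) for i in range(10)]
        stack, truth = render_zstack(vessel_scene, cells, noiseless_params(seed=4))
        vessel = stack.red_channel > 0.3 * 65535
        green = stack.green_channel > 0.3 * 65535
        dt = ndimage.distance_transform_cdt(~vessel, metric="taxicab")
        labels, n = ndimage.label(green, structure=np.ones((3, 3, 3), bool))
        assert n == 10
        dmins = sorted(
            int(dt[labels == lab].min()) for lab in range(1, n + 1)
        )
        assert dmins[:3] == [1, 1, 1]          # contact: face-adjacent
        assert all(d >= 2 for d in dmins[3:])  # non-contact: >= 2 voxels away

    def test_truth_fraction_matches_planted_design(self, vessel_scene):
        cells = [StromalCell(radius_um=6, contact=(i < 8)) for i in range(50)]
        _, truth = render_zstack(vessel_scene, cells, noiseless_params(seed=9))
        assert truth.contact_fraction == pytest.approx(0.16)
        assert truth.n_cells == 50

    def test_single_touching_cell_fraction_one(self, vessel_scene):
        _, truth = render_zstack(vessel_scene, [StromalCell(contact=True)],
                                 noiseless_params(seed=1))
        assert truth.contact_fraction == 1.0

    def test_zero_cells_leaves_truth_undefined(self, vessel_scene):
        _, truth = render_zstack(vessel_scene, [], noiseless_params(seed=1))
        assert truth.contact_flags == []
        assert truth.contact_fraction is None

    def test_impossible_noncontact_placement_raises(self, vessel_scene):
        # a field almost fully occupied by a huge vessel: nowhere is >= 2
        # voxels away, so a non-contact cell cannot be placed
        seg = max(vessel_scene.graph.segment_endpoints(),
                  key=lambda s: np.linalg.norm(s[1] - s[0]))
        c = (seg[0] + seg[1]) / 2
        fat = single_segment_scene(vessel_scene.geometry,
                                   c - [300, 0], c + [300, 0], 400)
        with pytest.raises(PlacementError):
            render_zstack(
                fat, [StromalCell(radius_um=6, contact=False)],
                noiseless_params(seed=2),
                fov_um=(c[0] - 32, c[1] - 32, c[0] + 32, c[1] + 32),
                depth_um=32.0,
            )

    def test_zstack_roundtrip_to_disk(self, vessel_scene, tmp_path):
        cells = [StromalCell(radius_um=6, contact=(i % 2 == 0)) for i in range(4)]
        stack, truth = render_zstack(vessel_scene, cells, noiseless_params(seed=6))
        write_zstack(tmp_path, stack, truth)
        back = read_zstack(tmp_path / "zstack.tif")
        assert back.red_channel.tobytes() == stack.red_channel.tobytes()
        assert back.green_channel.tobytes() == stack.green_channel.tobytes()
        assert back.voxel_size == tuple(stack.voxel_size)
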