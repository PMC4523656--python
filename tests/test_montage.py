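"""Montage specifications, 10-20 placement geometry and electrode voxelisation."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import tdcsim as t
from tdcsim.montage import locate_1020, place_montage, standard_montage

SIX = ndimage.generate_binary_structure(3, 1)


class TestStandardMontages:
    @pytest.mark.parametrize("name,positions,n_active", [
        ("A", {"F3", "F4"}, 1),
        ("B", {"T3", "right_arm"}, 1),
        ("C", {"C3", "C4", "right_arm"}, 2),
        ("D", {"Fz", "right_tibia"}, 1),
    ])
    def test_composition(self, name, positions, n_active):
        spec = standard_montage(name)
        assert {e.position for e in spec.electrodes} == positions
        assert sum(e.role == "active" for e in spec.electrodes) == n_active
        assert sum(e.role == "reference" for e in spec.electrodes) == 1
        assert spec.injected_current_mA == 1.0

    def test_unknown_montage_raises(self):
        with pytest.raises(KeyError, match="'E'"):
            standard_montage("E")

    def test_pad_fits_in_sponge(self):
        for name in "ABCD":
            for e in standard_montage(name).electrodes:
                assert e.pad_size[0] <= e.sponge_size[0]
                assert e.pad_size[1] <= e.sponge_size[1]

    def test_montage_requires_reference(self):
        with pytest.raises(ValueError):
            t.MontageSpec("X", (t.ElectrodeSpec("F3", "active"),))


class TestTenTwenty:
    def test_fz_on_midline(self, small_head):
        p, *_ = locate_1020(small_head, "Fz")
        assert abs(p[1]) < small_head.grid.spacing[1]

    def test_c3_c4_mirror_symmetric(self, small_head):
        p3, *_ = locate_1020(small_head, "C3")
        p4, *_ = locate_1020(small_head, "C4")
        assert np.allclose(p3 * [1, -1, 1], p4, atol=small_head.grid.spacing[1])

    def test_f3_anterior_left_of_vertex(self, small_head):
        p, *_ = locate_1020(small_head, "F3")
        assert p[0] > 0 and p[1] > 0

    def test_points_on_scalp_sphere(self, small_head):
        R = small_head.meta["scalp_outer_radius"]
        for pos in ("Fz", "C3", "T3", "F4"):
            p, *_ = locate_1020(small_head, pos)
            assert np.linalg.norm(p) == pytest.approx(R, rel=1e-12)

    def test_sphere_fit_without_metadata(self, small_head):
        bare = small_head.copy()
        bare.meta = {}
        p_meta, *_ = locate_1020(small_head, "Cz")
        p_fit, *_ = locate_1020(bare, "Cz")
        assert np.linalg.norm(p_meta - p_fit) < 2 * max(small_head.grid.spacing)

    def test_unsupported_position_raises(self, small_head):
        with pytest.raises(KeyError, match="P9"):
            locate_1020(small_head, "P9")


@pytest.fixture(scope="module")
def adult_head_2mm():
    params = t.AnthropometryParams.scaled_reference("duke_like", 1.77, voxel_size=2.0)
    return t.build_layered_sphere_head(params)


class TestPlacement:
    def test_pad_voxel_count_matches_footprint(self, adult_head_2mm):
        # 5 x 7 cm pad, thicknesses chosen as voxel multiples so the realised
        # slab equals the nominal one; 10% tolerance covers curvature.
        elecs = tuple(dataclasses.replace(e, pad_thickness=2.0, sponge_thickness=6.0)
                      for e in standard_montage("A").electrodes)
        placed = place_montage(adult_head_2mm, t.MontageSpec("A", elecs))
        expected = 70.0 * 50.0 * 2.0 / adult_head_2mm.grid.voxel_volume_mm3
        assert abs(placed.active_nodes.sum() - expected) / expected < 0.10

    def test_symmetric_montage_mirror_symmetric_labels(self, adult_head_2mm):
        placed = place_montage(adult_head_2mm, standard_montage("A"))
        lab = placed.volume.labels
        assert np.array_equal(lab, lab[:, ::-1, :])

    def test_extracephalic_on_head_only_raises(self, adult_head_2mm):
        with pytest.raises(ValueError, match="body phantom"):
            place_montage(adult_head_2mm, standard_montage("B"))

    def test_overlapping_pads_raise(self, adult_head_2mm):
        spec = t.MontageSpec("X", (t.ElectrodeSpec("C3", "active"),
                                   t.ElectrodeSpec("C3", "reference")))
        with pytest.raises(ValueError, match="overlap"):
            place_montage(adult_head_2mm, spec)

    def test_pad_touches_skin_only_through_sponge(self, adult_head_2mm):
        placed = place_montage(adult_head_2mm, standard_montage("A"))
        lab = placed.volume.labels
        pad = lab == placed.volume.id_of("electrode_pad")
        skin = lab == placed.volume.id_of("skin")
        assert not np.any(ndimage.binary_dilation(pad, SIX) & skin)

    def test_sponges_bridge_skin_and_pad(self, adult_head_2mm):
        placed = place_montage(adult_head_2mm, standard_montage("A"))
        lab = placed.volume.labels
        sponge = lab == placed.volume.id_of("sponge")
        comp, n = ndimage.label(sponge, SIX)
        assert n == 2  # one sponge per electrode, never merged
        for c in range(1, n + 1):
            grown = ndimage.binary_dilation(comp == c, SIX)
            assert np.any(grown & (lab == placed.volume.id_of("skin")))
            assert np.any(grown & (lab == placed.volume.id_of("electrode_pad")))

    def test_replacement_bit_identical(self, adult_head_2mm):
        a = place_montage(adult_head_2mm, standard_montage("A"))
        b = place_montage(adult_head_2mm, standard_montage("A"))
        assert np.array_equal(a.volume.labels, b.volume.labels)
        assert np.array_equal(a.active_nodes, b.active_nodes)

    def test_node_sets_disjoint(self, adult_head_2mm):
        placed = place_montage(adult_head_2mm, standard_montage("A"))
        assert not np.any(placed.active_nodes & placed.reference_nodes)

    def test_extracephalic_placement_on_body(self, small_body):
        placed = place_montage(small_body, standard_montage("B"))
        assert placed.active_nodes.sum() > 0
        assert placed.reference_nodes.sum() > 0
        lab = placed.volume.labels
        pad = lab == placed.volume.id_of("electrode_pad")
        skin = lab == placed.volume.id_of("skin")
        assert not np.any(ndimage.binary_dilation(pad, SIX) & skin)

    def test_montage_c_merges_two_active_pads(self, small_body):
        placed = place_montage(small_body, standard_montage("C", electrode_scale=0.8))
        comp, n = ndimage.label(placed.active_nodes, SIX)
        assert n == 2  # C3 and C4 pads, wired to one potential
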