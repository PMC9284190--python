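"""Forward simulator: scene generation, rendering identities,
determinism, and ground truth."""

import numpy as np
import pytest

import pentaplex as px
from pentaplex.simulate import abundance_images, cell_masks


class TestGenerateScene:
    def test_empty_scene_is_valid(self, panel):
        scene = px.generate_scene(0, seed=1, markers=panel.markers(), shape=(64, 64))
        assert len(scene.cells) == 0
        assert px.ground_truth_table(scene).empty

    def test_phenotype_mix_near_multinomial(self, panel):
        scene = px.generate_scene(
            1000, seed=1, markers=panel.markers(), phenotype_mix={"tumor": 0.7, "immune": 0.3}
        )
        counts = px.ground_truth_table(scene)["phenotype"].value_counts()
        assert len(scene.cells) == 1000
        # 3.5 sigma of Binomial(1000, 0.7) around 700
        assert abs(counts["tumor"] - 700) < 3.5 * np.sqrt(1000 * 0.7 * 0.3)

    def test_determinism(self, panel):
        s1 = px.generate_scene(50, seed=11, markers=panel.markers())
        s2 = px.generate_scene(50, seed=11, markers=panel.markers())
        for c1, c2 in zip(s1.cells, s2.cells):
            assert c1 == c2

    def test_lineage_marker_assignment(self, panel):
        """Tumor cells express the QUAD markers but no CD45; immune
        cells the reverse (nonspecific background aside)."""
        scene = px.generate_scene(200, seed=2, markers=panel.markers())
        truth = px.ground_truth_table(scene)
        tumor = truth[truth.phenotype == "tumor"]
        immune = truth[truth.phenotype == "immune"]
        # expressed levels are ~50x the nonspecific background
        assert tumor[["true_HER2", "true_EpCAM", "true_MUC1", "true_EGFR"]].min().min() > 10
        assert tumor["true_CD45"].max() < 10
        assert immune["true_CD45"].min() > 10
        assert immune["true_HER2"].max() < 10

    def test_overcrowded_frame_raises(self, panel):
        with pytest.raises(RuntimeError, match="larger frame|too small|place"):
            px.generate_scene(400, seed=1, markers=panel.markers(), shape=(100, 100))

    def test_nucleus_contained_in_cell(self, panel):
        scene = px.generate_scene(30, seed=4, markers=panel.markers())
        for cell in scene.cells:
            assert cell.nucleus_axes[0] <= cell.cell_axes[0]
            assert cell.nucleus_axes[1] <= cell.cell_axes[1]


class TestRenderAcquisition:
    def test_noiseless_quench_identity(self, small_scene, panel, A, quiet_noise):
        """stained - autofluorescence reference == A @ F exactly when
        noise and quench residual are off."""
        stack = px.render_acquisition(small_scene, panel, 1, A, quiet_noise)
        af0 = px.render_acquisition(small_scene, panel, 0, A, quiet_noise)
        corrected, _ = px.quench_subtract(
            px.subtract_dark(stack.stained, stack.dark_planes()),
            px.subtract_dark(af0.stained, af0.dark_planes()),
        )
        F = abundance_images(small_scene, panel, 1, A.col_labels)
        expected = np.tensordot(A.A, F, axes=(1, 0))
        np.testing.assert_allclose(corrected, expected, atol=1e-8)

    def test_rendering_linear_in_marker_levels(self, panel, A, quiet_noise):
        scene = px.generate_scene(20, seed=6, markers=panel.markers())
        doubled = px.Scene(
            width_px=scene.width_px,
            height_px=scene.height_px,
            cells=tuple(
                px.CellTruth(
                    center=c.center, cell_axes=c.cell_axes, nucleus_axes=c.nucleus_axes,
                    orientation=c.orientation, phenotype=c.phenotype,
                    marker_levels={m: 2 * v for m, v in c.marker_levels.items()},
                    dapi_level=2 * c.dapi_level,
                )
                for c in scene.cells
            ),
            autofluorescence_level=0.0,
            pixel_size_um=scene.pixel_size_um,
        )
        base = px.Scene(
            width_px=scene.width_px, height_px=scene.height_px, cells=scene.cells,
            autofluorescence_level=0.0, pixel_size_um=scene.pixel_size_um,
        )
        s1 = px.render_acquisition(base, panel, 1, A, quiet_noise)
        s2 = px.render_acquisition(doubled, panel, 1, A, quiet_noise)
        d1 = s1.stained - quiet_noise.dark_offset
        d2 = s2.stained - quiet_noise.dark_offset
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-8)

    def test_conservation_of_total_signal(self, small_scene, panel, A, quiet_noise):
        stack = px.render_acquisition(small_scene, panel, 1, A, quiet_noise)
        F = abundance_images(small_scene, panel, 1, A.col_labels)
        af = small_scene.autofluorescence_rows(A.n_rows)
        n_px = small_scene.shape[0] * small_scene.shape[1]
        expected = (A.A @ F.reshape(A.n_fluors, -1)).sum() + af.sum() * n_px \
            + quiet_noise.dark_offset * A.n_rows * n_px
        assert stack.stained.sum() == pytest.approx(expected, rel=1e-10)

    def test_determinism_byte_identical(self, small_scene, panel, A):
        noise = px.NoiseModel(seed=42)
        s1 = px.render_acquisition(small_scene, panel, 1, A, noise)
        s2 = px.render_acquisition(small_scene, panel, 1, A, noise)
        assert s1.stained.tobytes() == s2.stained.tobytes()
        assert s1.quenched.tobytes() == s2.quenched.tobytes()

    def test_igg_cycle_on_unstained_scene_is_background_only(self, panel, A, quiet_noise):
        """An IgG-control channel on a scene with zero nonspecific
        binding renders pure autofluorescence."""
        scene = px.generate_scene(10, seed=8, markers=panel.markers())
        stripped = px.Scene(
            width_px=scene.width_px, height_px=scene.height_px,
            cells=tuple(
                px.CellTruth(
                    center=c.center, cell_axes=c.cell_axes, nucleus_axes=c.nucleus_axes,
                    orientation=c.orientation, phenotype=c.phenotype,
                    marker_levels={m: 0.0 for m in c.marker_levels},
                    dapi_level=c.dapi_level,
                )
                for c in scene.cells
            ),
            autofluorescence_level=2.0,
        )
        stack = px.render_acquisition(stripped, panel, 4, A, quiet_noise)
        dark_sub = px.subtract_dark(stack.stained, stack.dark_planes())
        # IgG markers live on non-DAPI fluors; L720 rows see no DAPI, so
        # they contain only the uniform autofluorescence level
        l720 = A.led_names.index("L720")
        rows = dark_sub[3 * l720 : 3 * l720 + 3]
        np.testing.assert_allclose(rows, 2.0, atol=1e-8)

    def test_unknown_fluor_in_panel_raises(self, small_scene, A, quiet_noise):
        bad_panel = px.CyclePanel(
            cycles=({"DAPI": "DAPI", "FITC": "HER2"},),
        )
        with pytest.raises(KeyError, match="FITC"):
            px.render_acquisition(small_scene, bad_panel, 1, A, quiet_noise)

    def test_large_transform_rejected(self, small_scene, panel, A, quiet_noise):
        h = small_scene.shape[0]
        with pytest.raises(ValueError, match="out of bounds"):
            px.render_acquisition(
                small_scene, panel, 1, A, quiet_noise,
                px.RigidTransform(translation_px=(0.6 * h, 0.0)),
            )


class TestPanelValidation:
    def test_marker_must_be_unique(self):
        with pytest.raises(ValueError, match="more than once"):
            px.CyclePanel(
                cycles=(
                    {"DAPI": "DAPI", "AF488": "HER2"},
                    {"DAPI": "DAPI", "AF555": "HER2"},
                )
            )

    def test_dapi_required_every_cycle(self):
        with pytest.raises(ValueError, match="DAPI"):
            px.CyclePanel(cycles=({"AF488": "HER2"},))

    def test_default_panel_well_formed(self, panel):
        assert panel.n_cycles == 4
        assert panel.marker_channel("HER2") == (1, "AF488")
        assert panel.is_igg(4, "AF555")
        assert len(panel.markers()) == 20


class TestBeadsAndTruth:
    def test_bead_slide_deterministic_with_truth(self, A):
        noise = px.NoiseModel(seed=5)
        s1, t1 = px.generate_bead_slide(20, {"DAPI": 200.0, "AF647": 300.0}, A, noise, seed=5)
        s2, t2 = px.generate_bead_slide(20, {"DAPI": 200.0, "AF647": 300.0}, A, noise, seed=5)
        assert s1.stained.tobytes() == s2.stained.tobytes()
        assert len(t1) == 40
        assert t1.equals(t2)

    def test_ground_truth_row_per_cell(self, small_scene):
        truth = px.ground_truth_table(small_scene)
        assert len(truth) == len(small_scene.cells)
        assert (truth.loc[truth.phenotype == "tumor", "true_CD45"] < 10).all()

    def test_cell_masks_nucleus_subset_of_cell(self, small_scene):
        cell = small_scene.cells[0]
        nuc, outer, _ = cell_masks(small_scene, cell)
        assert (nuc & ~outer).sum() == 0
        assert nuc.sum() < outer.sum()


def test_defocus_stack_blurs_away_from_focus():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 1, (64, 64))
    planes = px.defocus_stack(img, n_planes=7, focus_index=3)
    assert len(planes) == 7
    np.testing.assert_array_equal(planes[3], img)
    # variance strictly decreases with blur distance on each side
    var = [p.var() for p in planes]
    assert var[3] == max(var)
    assert var[0] < var[1] < var[2] and var[6] < var[5] < var[4]
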