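"""Cell table construction, normalization, positivity and phenotypes."""

import numpy as np
import pandas as pd
import pytest

import pentaplex as px
from pentaplex.quantify import RULES_MOSAIC, igg_stats_from_table
from pentaplex.segmentation import LabelMasks
from pentaplex.unmix import FluorImageSet


def single_cell_masks(value_shape=(40, 40)):
    nuclei = np.zeros(value_shape, np.int32)
    cells = np.zeros(value_shape, np.int32)
    rr, cc = np.mgrid[: value_shape[0], : value_shape[1]]
    cells[(rr - 20) ** 2 + (cc - 20) ** 2 <= 100] = 1
    nuclei[(rr - 20) ** 2 + (cc - 20) ** 2 <= 25] = 1
    return LabelMasks(nuclei, cells)


def images_for(panel, shape, fill):
    """FluorImageSet per cycle with constant abundance ``fill``."""
    out = {}
    for c, cyc in enumerate(panel.cycles, start=1):
        imgs = {fluor: np.full(shape, float(fill)) for fluor in cyc}
        out[c] = FluorImageSet(images=imgs, residual=np.zeros(shape))
    return out


class TestQuantify:
    def test_uniform_abundance_gives_exact_mean(self, panel):
        masks = single_cell_masks()
        table = px.quantify(masks, images_for(panel, (40, 40), 7.0), panel)
        assert len(table) == 1
        for m in panel.markers():
            assert table[f"mean_{m}"].iloc[0] == pytest.approx(7.0)

    def test_scaling_images_scales_means(self, panel):
        masks = single_cell_masks()
        t1 = px.quantify(masks, images_for(panel, (40, 40), 3.0), panel)
        t2 = px.quantify(masks, images_for(panel, (40, 40), 6.0), panel)
        for m in panel.markers():
            assert t2[f"mean_{m}"].iloc[0] == pytest.approx(2 * t1[f"mean_{m}"].iloc[0])

    def test_union_mean_is_area_weighted(self):
        """Mean over a two-part cell equals the area-weighted mean of
        the parts (linearity of the mean)."""
        panel = px.CyclePanel(cycles=({"DAPI": "DAPI", "AF488": "X"},))
        nuclei = np.zeros((10, 20), np.int32)
        cells = np.zeros((10, 20), np.int32)
        cells[2:8, 2:8] = 1   # 36 px at value 2
        cells[2:8, 10:13] = 1  # 18 px at value 8
        nuclei[4:6, 4:6] = 1
        img = np.zeros((10, 20)); img[:, :9] = 2.0; img[:, 9:] = 8.0
        fis = {1: FluorImageSet(images={"DAPI": img, "AF488": img}, residual=np.zeros((10, 20)))}
        table = px.quantify(LabelMasks(nuclei, cells), fis, panel)
        expected = (36 * 2 + 18 * 8) / 54
        assert table["mean_X"].iloc[0] == pytest.approx(expected)

    def test_missing_cycle_raises(self, panel):
        masks = single_cell_masks()
        images = images_for(panel, (40, 40), 1.0)
        del images[2]
        with pytest.raises(KeyError, match="cycle 2"):
            px.quantify(masks, images, panel)


class TestNormalize:
    @staticmethod
    def table_with(values, marker="HER2"):
        return pd.DataFrame({f"mean_{marker}": values})

    def test_constant_values_normalize_to_one(self):
        out, refs = px.normalize(self.table_with(np.full(20, 5.0)))
        np.testing.assert_allclose(out["norm_HER2"], 1.0)
        assert refs.loc["HER2", "p_low"] == 5.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(2.0, 0.5, 100)
        out1, _ = px.normalize(self.table_with(vals))
        out2, _ = px.normalize(self.table_with(vals * 37.0))
        np.testing.assert_allclose(out1["norm_HER2"], out2["norm_HER2"], rtol=1e-12)

    def test_low_percentile_maps_to_one(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(1.0, 0.4, 500)
        out, refs = px.normalize(self.table_with(vals))
        p10_norm = np.percentile(out["norm_HER2"], 10)
        assert p10_norm == pytest.approx(1.0, rel=1e-9)
        # winsorized at p99/p10
        assert out["norm_HER2"].max() == pytest.approx(
            refs.loc["HER2", "p_high"] / refs.loc["HER2", "p_low"]
        )

    def test_degenerate_baseline_raises(self):
        vals = np.concatenate([np.zeros(50), np.ones(50)])
        with pytest.raises(ValueError, match="degenerate baseline"):
            px.normalize(self.table_with(vals))

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError, match=">= 10"):
            px.normalize(self.table_with(np.ones(5)))


class TestPositivity:
    def test_threshold_is_mean_plus_three_sd(self):
        stats = px.IgGStats(mean={"AF488": 10.0}, sd={"AF488": 2.0}, n_cells=50)
        assert stats.threshold("AF488") == pytest.approx(16.0)

    def test_strict_inequality_at_boundary(self):
        panel = px.CyclePanel(
            cycles=(
                {"DAPI": "DAPI", "AF488": "HER2"},
                {"DAPI": "DAPI", "AF488": "IgG-AF488"},
            ),
            igg_controls=frozenset({(2, "AF488")}),
        )
        table = pd.DataFrame({"norm_HER2": [16.1, 16.0, 15.9],
                              "norm_IgG-AF488": [1.0, 1.0, 1.0]})
        stats = px.IgGStats(mean={"AF488": 10.0}, sd={"AF488": 2.0}, n_cells=50)
        out, thresholds = px.call_positivity(table, stats, panel)
        assert thresholds["HER2"] == pytest.approx(16.0)
        assert out["pos_HER2"].tolist() == [True, False, False]

    def test_zero_sd_threshold_equals_mean(self):
        stats = px.IgGStats(mean={"AF647": 4.0}, sd={"AF647": 0.0}, n_cells=10)
        assert stats.threshold("AF647") == 4.0

    def test_missing_igg_channel_raises(self):
        panel = px.CyclePanel(
            cycles=(
                {"DAPI": "DAPI", "AF488": "HER2"},
                {"DAPI": "DAPI", "AF555": "IgG-AF555"},
            ),
            igg_controls=frozenset({(2, "AF555")}),
        )
        table = pd.DataFrame({"norm_HER2": [1.0] * 10, "norm_IgG-AF555": [1.0] * 10})
        stats = px.IgGStats(mean={"AF555": 1.0}, sd={"AF555": 0.1}, n_cells=10)
        with pytest.raises(KeyError, match="AF488"):
            px.call_positivity(table, stats, panel)

    def test_constant_threshold_fallback_warns(self):
        panel = px.CyclePanel(cycles=({"DAPI": "DAPI", "AF488": "HER2"},))
        table = pd.DataFrame({"norm_HER2": [1.0, 3.0]})
        with pytest.warns(UserWarning, match="constant threshold"):
            out, thr = px.call_positivity(table, None, panel, constant_threshold=2.0)
        assert thr["HER2"] == 2.0
        assert out["pos_HER2"].tolist() == [False, True]
        with pytest.raises(ValueError, match="constant_threshold"):
            px.call_positivity(table, None, panel)

    def test_igg_stats_from_table(self, panel):
        rng = np.random.default_rng(0)
        cols = {f"norm_{m}": rng.lognormal(0, 0.2, 100) for m in panel.markers()}
        stats = igg_stats_from_table(pd.DataFrame(cols), panel)
        assert set(stats.mean) == {"AF488", "BV605", "AF555", "AF647", "CF750"}
        assert stats.n_cells == 100


class TestPhenotypes:
    @staticmethod
    def flags(**kw):
        base = {m: [0] for m in ("CD45", "HER2", "EpCAM", "MUC1", "EGFR", "ER", "PR", "Ki67")}
        base.update({k: [int(v)] for k, v in kw.items()})
        return pd.DataFrame({f"pos_{m}": v for m, v in base.items()}).astype(bool)

    def test_cd45_positive_is_immune(self):
        out = px.classify_phenotypes(self.flags(CD45=1))
        assert out["phenotype"].iloc[0] == "immune"

    def test_quad_positive_without_cd45_is_tumor(self):
        out = px.classify_phenotypes(self.flags(HER2=1))
        assert out["phenotype"].iloc[0] == "tumor"

    def test_all_negative_is_other(self):
        out = px.classify_phenotypes(self.flags())
        assert out["phenotype"].iloc[0] == "other"

    def test_first_match_wins(self):
        # CD45+ and HER2+ -> immune because the immune rule is first
        out = px.classify_phenotypes(self.flags(CD45=1, HER2=1))
        assert out["phenotype"].iloc[0] == "immune"

    def test_mosaic_rules(self):
        out = px.classify_phenotypes(self.flags(HER2=1, Ki67=1), rules=RULES_MOSAIC)
        assert out["phenotype"].iloc[0] == "multi-marker"
        out = px.classify_phenotypes(self.flags(Ki67=1), rules=RULES_MOSAIC)
        assert out["phenotype"].iloc[0] == "Ki67-only"
        out = px.classify_phenotypes(self.flags(), rules=RULES_MOSAIC)
        assert out["phenotype"].iloc[0] == "quad-negative"

    def test_malformed_rule_raises_with_text(self):
        with pytest.raises(ValueError, match="NOPE"):
            px.classify_phenotypes(self.flags(), rules=(("bad", "NOPE &&& 1"),))
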