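"""Channel means, white-plate correction and the 20 vegetation indices."""

import math

import numpy as np
import pytest

import spadvi.indices as vi

import spadvi.synthscene as sy
from spadvi.errors import CorrectionError, EmptyMaskError


def cm(**values):
    return vi.ChannelMeans(values=values, n_pixels=1)


class TestMaskMean:
    def test_constant_image(self):
        img = np.full((4, 4, 3), 7.0)
        m = vi.mask_mean(img, np.ones((4, 4), bool), ("red", "green", "blue"))
        assert all(v == 7.0 for v in m.values.values())
        assert m.n_pixels == 16

    def test_two_pixels(self):
        img = np.zeros((1, 2, 1))
        img[0, 0, 0], img[0, 1, 0] = 10, 20
        m = vi.mask_mean(img, np.ones((1, 2), bool), ("x",))
        assert m["x"] == 15.0

    def test_checkerboard_against_bruteforce(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(8, 8, 2))
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0
        m = vi.mask_mean(img, mask, ("a", "b"))
        expect_a = np.mean([img[r, c, 0] for r in range(8) for c in range(8)
                            if (r + c) % 2 == 0])
        assert m["a"] == pytest.approx(expect_a)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            vi.mask_mean(np.ones((2, 2, 1)), np.zeros((2, 2), bool), ("x",))


class TestWhiteCorrect:
    def test_plant_equal_panel_gives_ones(self):
        out = vi.white_correct(cm(red=3.0, green=5.0), cm(red=3.0, green=5.0))
        assert all(v == 1.0 for v in out.values.values())

    def test_common_scaling_cancels(self):
        plant, panel = cm(red=0.2, green=0.4), cm(red=0.9, green=0.95)
        base = vi.white_correct(plant, panel)
        scaled = vi.white_correct(
            cm(red=0.2 * 7, green=0.4 * 7), cm(red=0.9 * 7, green=0.95 * 7))
        for c in base.values:
            assert scaled[c] == pytest.approx(base[c])

    def test_zero_panel_rejected(self):
        with pytest.raises(CorrectionError):
            vi.white_correct(cm(red=1.0), cm(red=0.0))

    def test_corrected_means_invariant_to_illumination(self, spectral_model):
        """Fixed-exposure renders at illumination 1.0 vs 0.25: corrected
        truth-mask channel means agree within quantization error."""
        rec = sy.SeedlingRecord("x", 0.0, 28.0, 28.0)
        means = {}
        for il in (1.0, 0.25):
            cfg = sy.ShadeConfig(levels=(0.0,), mean_spad=(28.0,),
                                 sd_spad=(3.0,), n_per_level=1,
                                 illumination_scale=(il,))
            sc = sy.render_scene(rec, spectral_model, cfg, 13,
                                 exposure="fixed")
            plant = vi.mask_mean(sc.ms, sc.truth_mask, sy.BANDS)
            panel = vi.region_mean(sc.ms, sc.white_panel, sy.BANDS)
            means[il] = vi.white_correct(plant, panel)
        for band in sy.BANDS:
            assert means[1.0][band] == pytest.approx(means[0.25][band],
                                                     abs=2e-3)


class TestRgbIndices:
    def test_neutral_gray_substitution(self):
        iv = vi.rgb_indices(cm(red=0.5, green=0.5, blue=0.5))
        assert iv.values["ExG"] == pytest.approx(0.0)
        assert iv.values["RGRI"] == 1.0
        assert iv.values["GBRI"] == 1.0
        assert iv.values["NGRDI"] == 0.0
        assert iv.values["MGRVI"] == 0.0
        assert iv.values["CIVE"] == pytest.approx(18.79495)

    def test_zero_red_degenerates(self):
        iv = vi.rgb_indices(cm(red=0.0, green=0.4, blue=0.2))
        assert iv.values["RGRI"] == 0.0
        assert not iv.valid["VEG"]

    def test_against_independent_formula_evaluation(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            r, g, b = rng.uniform(0.01, 1.0, 3)
            iv = vi.rgb_indices(cm(red=r, green=g, blue=b))
            exg = 2 * g - r - b
            expected = {
                "ExG": exg,
                "ExGR": exg - (1.4 * r - g),
                "NGRDI": (g - r) / (g + r),
                "NGBDI": (g - b) / (g + b),
                "RGRI": r / g,
                "GBRI": b / g,
                "CIVE": 0.441 * r - 0.811 * g + 0.385 * b + 18.78745,
                "VEG": g / (r ** 0.667 * b ** 0.333),
                "RGBVI": (g ** 2 - b * r ** 2) / (g ** 2 + b * r ** 2),
                "MGRVI": (g ** 2 - r ** 2) / (g ** 2 + r ** 2),
            }
            for name, val in expected.items():
                assert iv.values[name] == pytest.approx(val, rel=1e-12), name

    def test_literature_rgbvi_variant(self):
        r, g, b = 0.3, 0.5, 0.2
        lit = vi.rgb_indices(cm(red=r, green=g, blue=b),
                             literature_formulas=True)
        assert lit.values["RGBVI"] == pytest.approx(
            (g * g - b * r) / (g * g + b * r))


class TestMsIndices:
    def test_nir_equal_red_degenerate(self):
        iv = vi.ms_indices(cm(blue=0.1, red=0.3, nir=0.3, red_edge=0.2))
        assert iv.values["NDVI"] == 0.0
        assert iv.values["DVI"] == 0.0
        assert iv.values["RVI"] == 1.0
        assert not iv.valid["RDVI"]   # 0/0 radicand
        assert not iv.valid["sCCCI"]  # NDRE / 0

    def test_printed_formula_substitution(self):
        iv = vi.ms_indices(cm(blue=0.05, red=0.2, nir=0.8, red_edge=0.4))
        assert iv.values["NDVI"] == pytest.approx(0.6)
        assert iv.values["RVI"] == pytest.approx(4.0)
        assert iv.values["DVI"] == pytest.approx(0.6)
        assert iv.values["RDVI"] == pytest.approx(1.0)  # sqrt(NDVI/DVI)
        assert iv.values["NDRE"] == pytest.approx(0.4 / 1.2)
        assert iv.values["RERVI"] == pytest.approx(2.0)
        assert iv.values["REVI"] == pytest.approx(1.0)
        assert iv.values["REDVI"] == pytest.approx(0.4)
        assert iv.values["sCCCI"] == pytest.approx((0.4 / 1.2) / 0.6)
        assert iv.values["EVI"] == pytest.approx(
            2.5 * 0.6 / (0.8 + 6 * 0.2 - 7.5 * 0.05 + 1))

    def test_rervi_minus_revi_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            b, r, n, re = rng.uniform(0.02, 1.0, 4)
            iv = vi.ms_indices(cm(blue=b, red=r, nir=n, red_edge=re))
            assert iv.values["RERVI"] - iv.values["REVI"] == pytest.approx(
                1.0, abs=1e-12)

    def test_literature_rdvi_variant(self):
        iv = vi.ms_indices(cm(blue=0.05, red=0.2, nir=0.8, red_edge=0.4),
                           literature_formulas=True)
        assert iv.values["RDVI"] == pytest.approx(0.6 / math.sqrt(1.0))


class TestFeatureTable:
    def test_normalized_difference_indices_bounded(self, feature_table):
        for col in ("ms_NDVI", "ms_NDRE", "rgb_NGRDI", "rgb_NGBDI",
                    "rgb_MGRVI"):
            vals = feature_table[col].dropna()
            assert np.all(np.abs(vals) <= 1.0)

    def test_index_illumination_invariance_default_pipeline(
            self, small_cfg, spectral_model):
        """Same seedling imaged under every shade level's illumination:
        every valid index from the auto-exposed camera pair agrees within
        0.02 after white-plate correction."""
        rec = sy.sample_population(small_cfg, seed=3)[0]
        rows = []
        for lvl in small_cfg.levels:
            alias = sy.SeedlingRecord(rec.id, lvl, rec.spad_true,
                                      rec.spad_measured)
            sc = sy.render_scene(alias, spectral_model, small_cfg, 404)
            rows.append(vi.indices_from_scene(sc))
        import pandas as pd
        df = pd.DataFrame(rows)
        cols = [c for c in df.columns
                if c.startswith(("rgb_", "ms_")) and "jaccard" not in c]
        dev = df[cols].max() - df[cols].min()
        assert float(dev.max()) < 0.02
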