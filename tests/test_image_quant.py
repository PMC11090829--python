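"""Image quantitation: thresholding, tiling, the tissue filter, counting."""

import numpy as np
import pytest
import tifffile

from orgfid import (
    QuantImage,
    count_positive_nuclei,
    default_tile_side,
    filter_tiles,
    quantify_section,
    read_section_image,
    threshold_channel,
    tile_image,
)
from orgfid.errors import ConfigurationError, DegenerateThresholdError
from orgfid.image_quant import BinaryMask, SectionQuant


def _img(channels, **meta):
    defaults = dict(
        channel_roles={"k8": 0, "k14": 1},
        section_id="s1",
        patient_id="p1",
        subtype="synthetic",
        condition="test",
        source_kind="ST",
    )
    defaults.update(meta)
    return QuantImage(pixels=np.asarray(channels), **defaults)


class TestReadSectionImage:
    def test_multipage_tiff_round_trip(self, tmp_path):
        data = np.arange(2 * 8 * 9, dtype=np.uint16).reshape(2, 8, 9)
        path = tmp_path / "sec.tif"
        tifffile.imwrite(path, data)
        img = read_section_image(path, {"k8": 0, "k14": 1}, {"condition": "A7"})
        assert img.n_channels == 2
        assert img.condition == "A7"
        np.testing.assert_array_equal(img.pixels, data)

    def test_role_index_out_of_range(self, tmp_path):
        path = tmp_path / "sec.tif"
        tifffile.imwrite(path, np.zeros((2, 4, 4), dtype=np.uint8))
        with pytest.raises(ConfigurationError):
            read_section_image(path, {"k8": 0, "k14": 5})

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_section_image(tmp_path / "nope.tif", {"k8": 0, "k14": 0})

    def test_per_channel_files_shape_mismatch(self, tmp_path):
        a, b = tmp_path / "a.tif", tmp_path / "b.tif"
        tifffile.imwrite(a, np.zeros((4, 4), dtype=np.uint8))
        tifffile.imwrite(b, np.zeros((5, 4), dtype=np.uint8))
        from orgfid.errors import ImageFormatError

        with pytest.raises(ImageFormatError):
            read_section_image([a, b], {"k8": 0, "k14": 1})


class TestThresholdChannel:
    def test_otsu_separates_bimodal(self):
        chan = np.zeros((20, 20))
        chan[5:10, 5:10] = 200.0
        img = _img([chan, chan])
        mask = threshold_channel(img, "k8", min_object_px=0)
        np.testing.assert_array_equal(mask.pixels, chan == 200.0)

    def test_fixed_threshold_is_strict(self):
        chan = np.array([[50, 100, 101, 150]], dtype=float)
        img = _img([chan, chan])
        mask = threshold_channel(img, "k8", method="fixed", fixed_value=100,
                                 min_object_px=0)
        np.testing.assert_array_equal(mask.pixels, [[False, False, True, True]])
        assert mask.threshold_used == 100

    def test_small_speckle_removed(self):
        chan = np.zeros((30, 30))
        chan[0, 0:3] = 200.0  # 3-px speckle
        chan[10:20, 10:20] = 200.0  # 100-px object
        img = _img([chan, chan])
        mask = threshold_channel(img, "k8", method="fixed", fixed_value=100,
                                 min_object_px=10)
        assert mask.positive_area == 100
        assert not mask.pixels[0, 0]

    def test_constant_channel_degenerate(self):
        img = _img([np.full((5, 5), 7.0), np.zeros((5, 5))])
        with pytest.raises(DegenerateThresholdError):
            threshold_channel(img, "k8")

    def test_absent_role(self):
        img = _img([np.zeros((5, 5)), np.zeros((5, 5))])
        with pytest.raises(ConfigurationError):
            threshold_channel(img, "marker:p63")

    def test_area_conservation(self):
        rng = np.random.default_rng(3)
        chan = rng.uniform(0, 255, (32, 32))
        img = _img([chan, chan])
        mask = threshold_channel(img, "k8", min_object_px=0)
        assert mask.positive_area + int((~mask.pixels).sum()) == img.image_area_px


class TestQuantifySection:
    @staticmethod
    def _mask(px, role):
        return BinaryMask(pixels=px, role=role, threshold_used=0, method="fixed")

    def test_disjoint_union_tissue(self):
        k8 = np.zeros((20, 20), bool)
        k8[:5, :20] = True  # 100 px
        k14 = np.zeros((20, 20), bool)
        k14[10:15, :10] = True  # 50 px
        img = _img([k8.astype(float), k14.astype(float)])
        q = quantify_section(img, {"k8": self._mask(k8, "k8"),
                                   "k14": self._mask(k14, "k14")})
        assert (q.k8_area_px, q.k14_area_px, q.tissue_area_px) == (100, 50, 150)

    def test_overlapping_union_tissue(self):
        # 100 + 100 px regions sharing 40 px -> union of 160 px
        k8 = np.zeros((20, 20), bool)
        k8[0:5, 0:20] = True
        k14 = np.zeros((20, 20), bool)
        k14[3:8, 0:20] = True
        assert int((k8 & k14).sum()) == 40
        img = _img([k8.astype(float), k14.astype(float)])
        q = quantify_section(img, {"k8": self._mask(k8, "k8"),
                                   "k14": self._mask(k14, "k14")})
        assert q.tissue_area_px == int((k8 | k14).sum()) == 160

    def test_missing_mask(self):
        img = _img([np.zeros((4, 4)), np.zeros((4, 4))])
        with pytest.raises(ConfigurationError):
            quantify_section(img, {"k8": self._mask(np.zeros((4, 4), bool), "k8")})


class TestTiling:
    def test_exact_grid(self):
        img = _img([np.zeros((1000, 1000)), np.zeros((1000, 1000))])
        tiles = tile_image(img, 250)
        assert len(tiles) == 16
        assert all(t.shape == (250, 250) for t in tiles)

    def test_edge_remainders_kept(self):
        img = _img([np.zeros((1100, 1000)), np.zeros((1100, 1000))])
        tiles = tile_image(img, 250)
        assert len(tiles) == 20
        remainders = [t for t in tiles if t.shape == (100, 250)]
        assert len(remainders) == 4

    def test_organoid_passes_through(self):
        img = _img([np.zeros((300, 300)), np.zeros((300, 300))],
                   source_kind="organoid")
        tiles = tile_image(img, 100)
        assert tiles == [img]

    def test_oversized_tile_warns(self):
        img = _img([np.zeros((50, 50)), np.zeros((50, 50))])
        with pytest.warns(UserWarning, match="exceeds"):
            tiles = tile_image(img, 100)
        assert len(tiles) == 1

    def test_tiling_conserves_area_and_signal(self, rng):
        chan = (rng.uniform(0, 255, (530, 470))).astype(np.float32)
        img = _img([chan, chan])
        tiles = tile_image(img, 128)
        assert sum(t.image_area_px for t in tiles) == img.image_area_px
        # per-pixel signal conserved: thresholding each tile at a fixed
        # value and summing equals thresholding the parent
        total = sum(
            threshold_channel(t, "k8", method="fixed", fixed_value=128,
                              min_object_px=0).positive_area
            for t in tiles
        )
        parent = threshold_channel(img, "k8", method="fixed", fixed_value=128,
                                   min_object_px=0).positive_area
        assert total == parent

    def test_default_tile_side_matches_mean_organoid_area(self):
        imgs = [
            _img([np.zeros((n, n)), np.zeros((n, n))], source_kind="organoid")
            for n in (100, 200)
        ]
        # mean area = (10000 + 40000)/2 = 25000 -> side 158
        assert default_tile_side(imgs) == round(np.sqrt(25000))


class TestTissueFilter:
    @staticmethod
    def _pair(tissue_px, area=10000):
        side = int(np.sqrt(area))
        img = _img([np.zeros((side, side)), np.zeros((side, side))])
        q = SectionQuant(
            section_id="t", patient_id="p", subtype="synthetic", condition="c",
            source_kind="ST", image_area_px=area, tissue_area_px=tissue_px,
            k8_area_px=tissue_px, k14_area_px=0,
        )
        return (img, q)

    @pytest.mark.parametrize(
        "tissue_px,kept",
        [(400, False), (500, False), (600, True)],  # 4%, exactly 5%, 6%
    )
    def test_five_percent_rule_is_strict(self, tissue_px, kept):
        result = filter_tiles([self._pair(tissue_px)])
        assert bool(result) is kept

    def test_order_preserved_and_empty_allowed(self):
        pairs = [self._pair(px) for px in (600, 100, 900)]
        kept = filter_tiles(pairs)
        assert [p[1].tissue_area_px for p in kept] == [600, 900]
        assert filter_tiles([self._pair(100)]) == []


class TestCountNuclei:
    @staticmethod
    def _nuclei_image(sizes, gap=12):
        chan = np.zeros((40, len(sizes) * gap + gap))
        for i, s in enumerate(sizes):
            side = int(np.ceil(np.sqrt(s)))
            block = np.zeros((side, side))
            block.flat[:s] = 200.0
            chan[5 : 5 + side, 5 + i * gap : 5 + i * gap + side] = block
        return _img([chan, chan], channel_roles={"k8": 0, "k14": 0,
                                                 "marker:ki67": 1})

    def test_counts_disjoint_nuclei(self):
        img = self._nuclei_image([60] * 7)
        assert count_positive_nuclei(img, "marker:ki67", 50, 5000) == 7

    def test_blank_channel_counts_zero(self):
        img = _img([np.zeros((20, 20)), np.zeros((20, 20))],
                   channel_roles={"k8": 0, "k14": 0, "marker:cc3": 1})
        assert count_positive_nuclei(img, "marker:cc3", 50, 5000) == 0

    def test_size_window_excludes_small(self):
        img = self._nuclei_image([60, 60, 60, 60, 60, 20, 20])
        assert count_positive_nuclei(img, "marker:ki67", 50, 5000) == 5
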