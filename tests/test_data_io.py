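import os
import textwrap

import numpy as np
import pandas as pd
import pytest

from nodseg.data_io import (CTVolume, NoduleAnnotation, PatchPair,
                            PreprocessConfig, extract_patch,
                            lidc_contours_to_mask, preprocess_volume,
                            read_volume, split_subsets, voxel_to_world,
                            world_to_voxel, write_volume, read_annotations)
from nodseg.phantom_generator import synthetic_thorax


@pytest.fixture
def small_volume(rng):
    return CTVolume(rng.normal(-500, 200, size=(8, 8, 8)).astype(np.float32),
                    origin=(10.0, -20.0, 5.0), spacing=(0.7, 0.7, 2.5),
                    series_id="t")


class TestVolumeIO:
    def test_roundtrip_preserves_everything(self, tmp_path, small_volume):
        path = str(tmp_path / "vol.mhd")
        write_volume(small_volume, path)
        back = read_volume(path)
        assert np.allclose(back.voxels, small_volume.voxels)
        assert back.origin == pytest.approx(small_volume.origin)
        assert back.spacing == pytest.approx(small_volume.spacing)

    def test_declared_spacing_surfaces(self, tmp_path, small_volume):
        vol = CTVolume(small_volume.voxels, small_volume.origin,
                       (0.7, 0.7, 2.5), "s")
        path = str(tmp_path / "s.mhd")
        write_volume(vol, path)
        assert read_volume(path).spacing == pytest.approx((0.7, 0.7, 2.5))

    def test_truncated_raw_reports_byte_counts(self, tmp_path, small_volume):
        path = str(tmp_path / "vol.mhd")
        write_volume(small_volume, path)
        raw = str(tmp_path / "vol.raw")
        data = open(raw, "rb").read()
        open(raw, "wb").write(data[: len(data) // 2])
        with pytest.raises(ValueError, match=r"\d+ bytes"):
            read_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(str(tmp_path / "nope.mhd"))

    def test_degenerate_volume_rejected(self):
        with pytest.raises(ValueError):
            CTVolume(np.zeros((4, 4)), (0, 0, 0), (1, 1, 1))
        with pytest.raises(ValueError):
            CTVolume(np.zeros((4, 4, 4)), (0, 0, 0), (1, 0, 1))


class TestCoordinates:
    def test_origin_maps_to_zero(self, small_volume):
        assert world_to_voxel(small_volume.origin, small_volume) == (0, 0, 0)

    def test_hand_rounding(self):
        vol = CTVolume(np.zeros((8, 8, 8), dtype=np.float32),
                       (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
        # world (x, y, z) = (5.4, 2.0, 3.0) -> voxel (z, y, x) = (3, 2, 5)
        assert world_to_voxel((5.4, 2.0, 3.0), vol) == (3, 2, 5)

    def test_roundtrip_within_half_voxel(self, small_volume, rng):
        for _ in range(20):
            idx = tuple(int(v) for v in rng.integers(0, 8, size=3))
            w = voxel_to_world(idx, small_volume)
            assert world_to_voxel(w, small_volume) == idx
            w2 = np.asarray(voxel_to_world(world_to_voxel(w, small_volume),
                                           small_volume))
            assert np.all(np.abs(w2 - np.asarray(w))
                          <= np.asarray(small_volume.spacing) / 2 + 1e-9)

    def test_out_of_bounds_mentions_both_systems(self, small_volume):
        with pytest.raises(ValueError, match="origin"):
            world_to_voxel((500.0, 500.0, 500.0), small_volume)


class TestPreprocess:
    def test_masked_region_zero_and_idempotent(self, rng):
        vox = rng.normal(-400, 300, size=(8, 10, 10)).astype(np.float32)
        vol = CTVolume(vox, (0, 0, 0), (1, 1, 1))
        mask = np.zeros_like(vox, dtype=np.uint8)
        mask[2:6, 2:8, 2:8] = 1
        cfg = PreprocessConfig(resample=False)
        out1, m1 = preprocess_volume(vol, mask, cfg)
        assert np.all(out1.voxels[mask == 0] == 0.0)
        # in-mask mean is removed
        assert abs(out1.voxels[mask == 1].mean()) < 1e-5
        out2, _ = preprocess_volume(out1, m1, cfg)
        assert np.abs(out2.voxels - out1.voxels).max() < 1e-6

    def test_allones_mask_reduces_to_normalize_demean(self, rng):
        vox = rng.normal(-200, 100, size=(6, 6, 6)).astype(np.float32)
        vol = CTVolume(vox, (0, 0, 0), (1, 1, 1))
        cfg = PreprocessConfig(resample=False)
        out, _ = preprocess_volume(vol, np.ones_like(vox), cfg)
        clipped = np.clip(vox, -1000, 400)
        want = (clipped - clipped.min()) / (clipped.max() - clipped.min())
        want -= want.mean()
        assert np.abs(out.voxels - want).max() < 1e-5

    def test_constant_volume_resamples_to_constant(self):
        vox = np.full((8, 8, 8), 100.0, dtype=np.float32)
        vol = CTVolume(vox, (0, 0, 0), (2.0, 2.0, 2.0))
        out, m = preprocess_volume(vol, np.ones_like(vox),
                                   PreprocessConfig(target_spacing=(1.0, 1.0, 1.0)))
        assert out.voxels.shape == (16, 16, 16)
        assert np.abs(out.voxels - out.voxels.flat[0]).max() < 1e-6
        assert set(np.unique(m)) <= {0, 1}

    def test_shape_mismatch_rejected(self, small_volume):
        with pytest.raises(ValueError, match="mask"):
            preprocess_volume(small_volume, np.ones((4, 4, 4)))

    def test_end_to_end_on_synthetic_thorax(self):
        vol, lung, ann = synthetic_thorax(diameter_mm=12.0)
        cfg = PreprocessConfig(target_spacing=(2.0, 1.0, 1.0))
        out, mask = preprocess_volume(vol, lung, cfg)
        assert out.voxels.shape == mask.shape
        # nodule voxels (HU 30) map above the parenchyma background
        center = world_to_voxel(ann.center_world, out)
        assert out.voxels[center] > np.median(out.voxels[mask > 0])


class TestExtractPatch:
    def _volume_with_sphere(self, shape=(32, 120, 120), r_mm=6.0,
                            spacing=(1.0, 1.0, 1.0)):
        zz, yy, xx = np.indices(shape).astype(float)
        cz, cy, cx = [(s - 1) / 2 for s in shape]
        dist = np.sqrt(((zz - cz) * spacing[2]) ** 2
                       + ((yy - cy) * spacing[1]) ** 2
                       + ((xx - cx) * spacing[0]) ** 2)
        mask = (dist <= r_mm).astype(np.uint8)
        vol = CTVolume(mask * 0.5, (0.0, 0.0, 0.0), spacing)
        ann = NoduleAnnotation("s", (cx, cy, cz), 2 * r_mm)
        return vol, mask, ann

    def test_centered_nodule_no_padding(self):
        vol, mask, ann = self._volume_with_sphere()
        pair = extract_patch(vol, mask, ann)
        assert pair.image.shape == (16, 96, 96)
        com = np.array([c.mean() for c in np.nonzero(pair.mask)])
        assert np.abs(com - np.array([7.5, 47.5, 47.5])).max() <= 1.0

    def test_corner_annotation_padded_to_contract(self):
        vol, mask, _ = self._volume_with_sphere()
        ann = NoduleAnnotation("s", (1.0, 1.0, 1.0), 6.0)
        pair = extract_patch(vol, mask, ann)
        assert pair.image.shape == (16, 96, 96)
        assert pair.mask.shape == (16, 96, 96)

    def test_sphere_voxel_count_preserved(self):
        """Cropping must not lose nodule voxels: the patch mask count equals
        an independent brute-force count of the sphere voxelization."""
        vol, mask, ann = self._volume_with_sphere(r_mm=5.0)
        pair = extract_patch(vol, mask, ann)
        zz, yy, xx = np.indices(vol.shape).astype(float)
        inside = ((zz - 15.5) ** 2 + (yy - 59.5) ** 2 + (xx - 59.5) ** 2) <= 25.0
        assert pair.mask.sum() == int(inside.sum())

    def test_annotation_outside_volume(self):
        vol, mask, _ = self._volume_with_sphere()
        ann = NoduleAnnotation("s", (119.0, 119.0, 500.0), 6.0)
        with pytest.raises(ValueError):
            extract_patch(vol, mask, ann)

    def test_binary_mask_enforced(self):
        with pytest.raises(ValueError, match="binary"):
            PatchPair(np.zeros((16, 96, 96)), np.full((16, 96, 96), 2.0))


def _square_session(x0=5, y0=5, size=9, z=4.0):
    pts = [(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)]
    edge = "".join(
        f"<edgeMap><xCoord>{x}</xCoord><yCoord>{y}</yCoord></edgeMap>"
        for x, y in pts)
    return (f"<readingSession><unblindedReadNodule><roi>"
            f"<imageZposition>{z}</imageZposition>{edge}"
            f"</roi></unblindedReadNodule></readingSession>")


def _square_xml(x0=5, y0=5, size=9, z=4.0):
    return f"<LidcReadMessage>{_square_session(x0, y0, size, z)}</LidcReadMessage>"


class TestLidcContours:
    def _vol(self):
        return CTVolume(np.zeros((8, 32, 32), dtype=np.float32),
                        (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))

    def test_square_contour_inclusive_fill(self):
        """A 10x10-pixel square contour rasterizes to exactly 100 voxels on
        its slice (analytic area with inclusive edges)."""
        mask = lidc_contours_to_mask(_square_xml(), self._vol())
        assert mask.sum() == 100
        assert mask[4].sum() == 100
        assert mask[:4].sum() == 0 and mask[5:].sum() == 0

    def test_empty_xml_gives_empty_mask(self):
        mask = lidc_contours_to_mask("<LidcReadMessage/>", self._vol())
        assert mask.sum() == 0

    def test_unmatched_z_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="z-position"):
            mask = lidc_contours_to_mask(_square_xml(z=100.0), self._vol())
        assert mask.sum() == 0

    def test_two_reader_consensus(self):
        # readers draw disjoint squares: at 50% consensus with 2 readers a
        # voxel needs >= 1 vote, so the union survives
        xml = ("<LidcReadMessage>" + _square_session(2, 2, 4, 3.0)
               + _square_session(20, 20, 4, 3.0) + "</LidcReadMessage>")
        union = lidc_contours_to_mask(xml, self._vol(), consensus=0.5)
        assert union.sum() == 2 * 25
        strict = lidc_contours_to_mask(xml, self._vol(), consensus=1.0)
        assert strict.sum() == 0

    def test_file_path_input(self, tmp_path):
        p = tmp_path / "ann.xml"
        p.write_text(_square_xml())
        assert lidc_contours_to_mask(str(p), self._vol()).sum() == 100


class TestSplitSubsets:
    def test_toy_table_split(self):
        df = pd.DataFrame({"series_id": [f"s{i}" for i in range(10)],
                           "subset": list(range(10))})
        train, val = split_subsets(df)
        assert len(train) == 8 and len(val) == 2
        assert set(val) == {"s8", "s9"}
        assert not set(train) & set(val)

    def test_unknown_subset_rejected(self):
        df = pd.DataFrame({"series_id": ["a"], "subset": [12]})
        with pytest.raises(ValueError, match="unknown subset"):
            split_subsets(df)

    def test_series_in_both_rejected(self):
        df = pd.DataFrame({"series_id": ["a", "a"], "subset": [0, 9]})
        with pytest.raises(ValueError, match="both"):
            split_subsets(df)


def test_read_annotations_dialect(tmp_path):
    csv = tmp_path / "annotations.csv"
    csv.write_text(textwrap.dedent("""\
        seriesuid,coordX,coordY,coordZ,diameter_mm
        1.2.3,-100.5,40.2,-210.0,6.4
        4.5.6,3.0,4.0,5.0,22.1
        """))
    anns = read_annotations(str(csv))
    assert len(anns) == 2
    assert anns[0].center_world == (-100.5, 40.2, -210.0)
    assert anns[1].diameter_mm == 22.1
    with pytest.raises(ValueError):
        NoduleAnnotation("x", (0, 0, 0), -1.0)
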