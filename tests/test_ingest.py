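"""Colorbar LUT construction, colorized-image conversion, DICOM round trip."""

import numpy as np
import pytest

from teatherm import (
    ColorbarSpec,
    TemperatureMap,
    build_lut,
    convert,
    discretization_steps,
    generate,
    iron_colormap,
    read_dicom,
    render,
    write_dicom,
)
from teatherm.ingest import MAX_DISTINCT_COLORS


class TestBuildLut:
    def test_endpoints_anchor_to_range(self):
        colors = np.array([[0, 0, 0], [255, 255, 255]], dtype=np.uint8)
        lut = build_lut(ColorbarSpec(5.0, 40.0, colors))
        assert lut.temps_c[0] == 5.0
        assert lut.temps_c[-1] == 40.0

    def test_linear_position_assignment(self):
        """351 evenly spaced colors over [5, 40]: entry k maps to 5.0 + 0.1 k."""
        lut = build_lut(ColorbarSpec(5.0, 40.0, iron_colormap(351)))
        # independent linear-position oracle
        expected = [round(5.0 + 35.0 * k / 350.0, 1) for k in range(351)]
        np.testing.assert_allclose(lut.temps_c, expected, atol=1e-12)
        np.testing.assert_array_equal(lut.stored, np.arange(50, 401))

    def test_deterministic(self):
        cb = ColorbarSpec(5.0, 40.0, iron_colormap(64))
        a, b = build_lut(cb), build_lut(cb)
        np.testing.assert_array_equal(a.colors, b.colors)
        np.testing.assert_array_equal(a.temps_c, b.temps_c)

    def test_temperatures_within_range_and_quantized(self):
        lut = build_lut(ColorbarSpec(12.3, 37.9, iron_colormap(97)))
        assert lut.temps_c.min() >= 12.3 - 1e-9
        assert lut.temps_c.max() <= 37.9 + 1e-9
        np.testing.assert_allclose(lut.temps_c * 10, np.round(lut.temps_c * 10), atol=1e-9)

    @pytest.mark.parametrize(
        "t_min,t_max,n", [(40.0, 5.0, 4), (5.0, 5.0, 4)], ids=["inverted", "degenerate"]
    )
    def test_bad_range_rejected(self, t_min, t_max, n):
        with pytest.raises(ValueError):
            ColorbarSpec(t_min, t_max, iron_colormap(n))

    def test_single_color_rejected(self):
        with pytest.raises(ValueError):
            ColorbarSpec(5.0, 40.0, np.zeros((1, 3), dtype=np.uint8))

    def test_discretization_bound(self):
        """5-40 degC at 0.1 degC precision admits exactly 350 steps."""
        assert discretization_steps(5.0, 40.0) == 350

    def test_color_space_bound(self):
        lut = build_lut(ColorbarSpec(5.0, 40.0, iron_colormap(351)))
        assert lut.n_distinct_colors <= MAX_DISTINCT_COLORS


class TestConvert:
    def test_exact_color_matches_lut_entry(self):
        lut = build_lut(ColorbarSpec(5.0, 40.0, iron_colormap(351)))
        img = np.tile(lut.colors[-1], (3, 4, 1)).astype(np.uint8)
        tmap = convert(img, lut)
        assert (tmap.pixels == 400).all()  # t_max = 40.0 degC stored as 400

    def test_idempotent_on_lut_colors(self):
        """Converting a rendering of the LUT's own colors recovers every entry."""
        lut = build_lut(ColorbarSpec(5.0, 40.0, iron_colormap(128)))
        img = lut.colors.reshape(8, 16, 3)
        tmap = convert(img, lut)
        np.testing.assert_array_equal(tmap.pixels.ravel(), lut.stored)

    def test_phantom_round_trip_half_bin(self, small_phantom, small_spec):
        """Render -> convert recovers ground truth within half a bin (0.05 degC)."""
        lut = build_lut(small_spec.colorbar())
        rec = convert(small_phantom.image, lut)
        err = np.abs(rec.celsius - small_phantom.tmap.celsius)
        assert err.max() <= 0.05

    def test_distinct_values_bounded_by_lut(self, small_phantom):
        lut = build_lut(ColorbarSpec(5.0, 40.0, iron_colormap(64)))
        tmap = convert(small_phantom.image, lut)
        assert len(np.unique(tmap.pixels)) <= len(lut)

    def test_nearest_color_tie_breaks_low(self):
        colors = np.array([[10, 0, 0], [30, 0, 0]], dtype=np.uint8)
        lut = build_lut(ColorbarSpec(5.0, 40.0, colors))
        img = np.full((1, 1, 3), 0, dtype=np.uint8)
        img[0, 0, 0] = 20  # equidistant from both entries
        assert convert(img, lut).celsius[0, 0] == 5.0

    def test_empty_image_rejected(self):
        lut = build_lut(ColorbarSpec(5.0, 40.0, iron_colormap(4)))
        with pytest.raises(ValueError):
            convert(np.zeros((0, 0, 3), dtype=np.uint8), lut)


class TestTemperatureMap:
    def test_storage_is_tenths_of_celsius(self):
        tmap = TemperatureMap.from_celsius(np.array([[31.2, 5.0], [40.0, 20.7]]))
        np.testing.assert_array_equal(tmap.pixels, [[312, 50], [400, 207]])
        np.testing.assert_allclose(tmap.celsius, [[31.2, 5.0], [40.0, 20.7]])

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            TemperatureMap.from_celsius(np.array([[-1.0]]))


class TestDicom:
    def test_round_trip_bit_exact(self, tmp_path, small_phantom):
        path = tmp_path / "t.dcm"
        write_dicom(small_phantom.tmap, path)
        back = read_dicom(path)
        np.testing.assert_array_equal(back.pixels, small_phantom.tmap.pixels)
        assert back.meta == small_phantom.tmap.meta

    def test_rescale_slope_declares_celsius(self, tmp_path):
        import pydicom

        tmap = TemperatureMap(np.full((4, 4), 312, dtype=np.uint16))
        path = tmp_path / "t.dcm"
        write_dicom(tmap, path)
        ds = pydicom.dcmread(path)
        assert float(ds.RescaleSlope) == 0.1
        assert float(ds.RescaleIntercept) == 0.0
        # stored 312 -> real-world 31.2 degC
        assert ds.pixel_array[0, 0] * float(ds.RescaleSlope) == pytest.approx(31.2)

    def test_second_reader_agrees(self, tmp_path):
        """A 640x480 phantom file is readable by an independent DICOM reader."""
        import SimpleITK

        from teatherm import PhantomSpec

        ph = generate(PhantomSpec(noise_sigma=0.0), seed=3)
        path = tmp_path / "full.dcm"
        write_dicom(ph.tmap, path)
        img = SimpleITK.ReadImage(str(path))
        assert img.GetSize() == (640, 480, 1) or img.GetSize() == (640, 480)
        arr = SimpleITK.GetArrayFromImage(img).squeeze()
        np.testing.assert_allclose(arr, ph.tmap.celsius, atol=1e-6)

    def test_missing_pixels_rejected(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        path = tmp_path / "empty.dcm"
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
        with pytest.raises(ValueError, match="pixel"):
            read_dicom(path)
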