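"""Volume / annotation / sample-table I/O round-trips and conventions."""

import numpy as np
import pandas as pd
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from qspect.radiomics2d import FEATURE_COLUMNS
from qspect.volume_io import (
    Modality,
    TissueClass,
    Units,
    Volume3D,
    read_roi_labels,
    read_sample_table,
    read_volume,
    rois_from_label_array,
    write_sample_table,
    write_volume,
)


def _write_dicom_series(directory, stored, intercept=-1024.0, slope=1.0, spacing=(2.5, 0.8, 0.8)):
    """Minimal CT DICOM series with rescale slope/intercept."""
    series_uid = generate_uid()
    dz, dy, dx = spacing
    for k in range(stored.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * dz]
        ds.PixelSpacing = [dy, dx]
        ds.Rows, ds.Columns = stored.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = slope
        ds.PixelData = stored[k].astype(np.uint16).tobytes()
        ds.save_as(directory / f"slice_{k:03d}.dcm", enforce_file_format=True)


class TestDicomReading:
    def test_hu_equals_stored_plus_intercept(self, tmp_path, rng):
        stored = rng.integers(0, 3000, size=(4, 8, 8)).astype(np.uint16)
        _write_dicom_series(tmp_path, stored)
        vol = read_volume(tmp_path, Modality.CT)
        np.testing.assert_allclose(vol.values, stored.astype(float) - 1024.0)
        assert vol.spacing == (2.5, 0.8, 0.8)
        assert vol.units is Units.HU

    def test_nonexistent_path_errors(self):
        with pytest.raises(IOError):
            read_volume("/nonexistent/series", Modality.CT)

    def test_non_uniform_slice_spacing_errors(self, tmp_path, rng):
        stored = rng.integers(0, 100, size=(4, 4, 4)).astype(np.uint16)
        _write_dicom_series(tmp_path, stored)
        # move the last slice to create a gap
        last = sorted(tmp_path.glob("*.dcm"))[-1]
        ds = pydicom.dcmread(last)
        ds.ImagePositionPatient = [0.0, 0.0, 30.0]
        ds.save_as(last, enforce_file_format=True)
        with pytest.raises(IOError, match="spacing"):
            read_volume(tmp_path, Modality.CT)


class TestNiftiRoundTrip:
    def test_values_and_spacing_preserved(self, tmp_path, rng):
        vol = Volume3D(rng.normal(size=(5, 6, 7)), (3.0, 1.25, 1.25), Modality.SPECT, Units.NORMALIZED)
        write_volume(vol, tmp_path / "v.nii")
        back = read_volume(tmp_path / "v.nii", Modality.SPECT, units=Units.NORMALIZED)
        np.testing.assert_allclose(back.values, vol.values, atol=1e-12)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_all_zero_volume(self, tmp_path):
        vol = Volume3D(np.zeros((3, 4, 5)), (1.0, 1.0, 1.0), Modality.SPECT, Units.COUNTS)
        write_volume(vol, tmp_path / "z.nii")
        back = read_volume(tmp_path / "z.nii", Modality.SPECT)
        assert np.all(back.values == 0)

    def test_unwritable_path_errors(self):
        vol = Volume3D(np.zeros((2, 2, 2)), (1, 1, 1), Modality.SPECT, Units.COUNTS)
        with pytest.raises(IOError):
            write_volume(vol, "/nonexistent/dir/v.nii")


class TestVolumeValidation:
    def test_implausible_hu_rejected(self):
        with pytest.raises(ValueError, match="HU"):
            Volume3D(np.full((2, 2, 2), -2000.0), (1, 1, 1), Modality.CT, Units.HU)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            Volume3D(np.full((2, 2, 2), -5.0), (1, 1, 1), Modality.SPECT, Units.COUNTS)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            Volume3D(np.zeros((2, 2, 2)), (0.0, 1, 1), Modality.SPECT, Units.COUNTS)


class TestRoiExtraction:
    def test_single_block_single_roi(self):
        labels = np.zeros((3, 20, 20), dtype=int)
        labels[1, 5:15, 5:15] = 2
        rois = rois_from_label_array(labels, "p1")
        assert len(rois) == 1
        assert rois[0].label is TissueClass.PE
        assert len(rois[0]) == 100
        assert rois[0].slice_index == 1

    def test_two_disjoint_blocks_two_rois(self):
        labels = np.zeros((1, 20, 20), dtype=int)
        labels[0, 1:5, 1:5] = 3
        labels[0, 10:14, 10:14] = 3
        rois = rois_from_label_array(labels)
        assert len(rois) == 2
        assert all(r.label is TissueClass.PNEUMONIA for r in rois)

    def test_same_label_different_slices_separate_rois(self):
        labels = np.zeros((3, 10, 10), dtype=int)
        labels[0, 2:6, 2:6] = 1
        labels[2, 2:6, 2:6] = 1
        rois = rois_from_label_array(labels)
        assert len(rois) == 2
        assert sorted(r.slice_index for r in rois) == [0, 2]

    def test_partition_consistency(self, rng):
        """Union of extracted ROI pixels equals the nonzero label voxels."""
        labels = np.zeros((2, 16, 16), dtype=int)
        labels[rng.random((2, 16, 16)) < 0.3] = 1
        labels[rng.random((2, 16, 16)) < 0.1] = 4
        rois = rois_from_label_array(labels)
        reconstructed = set()
        for roi in rois:
            for (r, c) in roi.pixels:
                reconstructed.add((roi.slice_index, r, c))
        expected = {tuple(v) for v in np.argwhere(labels > 0)}
        assert reconstructed == expected

    def test_invalid_label_code_rejected(self):
        labels = np.zeros((1, 4, 4), dtype=int)
        labels[0, 0, 0] = 9
        with pytest.raises(ValueError, match="0..6"):
            rois_from_label_array(labels)

    def test_roundtrip_via_nifti(self, tmp_path):
        labels = np.zeros((2, 10, 10), dtype=float)
        labels[1, 2:8, 2:8] = 5
        vol = Volume3D(labels, (1, 1, 1), Modality.CT, Units.HU)
        write_volume(vol, tmp_path / "labels.nii")
        rois = read_roi_labels(tmp_path / "labels.nii", patient_id="p7")
        assert len(rois) == 1
        assert rois[0].patient_id == "p7"
        assert rois[0].label is TissueClass.BACKGROUND


class TestSampleTable:
    def _table(self, rng, n=3):
        meta = pd.DataFrame(
            {
                "patient_id": ["p0"] * n,
                "roi_id": range(n),
                "slice_index": [1] * n,
                "row": [5] * n,
                "col": [6] * n,
                "window_side": [3] * n,
                "label": [1] * n,
            }
        )
        feats = pd.DataFrame(rng.normal(size=(n, 28)), columns=FEATURE_COLUMNS)
        return pd.concat([meta, feats], axis=1)

    def test_roundtrip_lossless(self, tmp_path, rng):
        table = self._table(rng)
        write_sample_table(table, tmp_path / "t.tsv")
        back = read_sample_table(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back, table, check_dtype=False, atol=1e-12, rtol=0)

    def test_empty_table_header_only(self, tmp_path, rng):
        table = self._table(rng, n=0)
        write_sample_table(table, tmp_path / "e.tsv")
        back = read_sample_table(tmp_path / "e.tsv")
        assert len(back) == 0
        assert list(back.columns) == list(table.columns)

    def test_default_configuration_has_28_feature_columns(self, tmp_path, rng):
        table = self._table(rng)
        write_sample_table(table, tmp_path / "t.tsv")
        back = read_sample_table(tmp_path / "t.tsv")
        feature_cols = [c for c in back.columns if c.startswith(("ct_", "spect_"))]
        assert len(feature_cols) == 28

    def test_missing_feature_values_rejected(self, tmp_path, rng):
        table = self._table(rng)
        table.loc[1, FEATURE_COLUMNS[3]] = np.nan
        with pytest.raises(ValueError, match="missing"):
            write_sample_table(table, tmp_path / "bad.tsv")
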