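"""Shared fixtures: small phantoms and a synthetic DICOM series writer."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from neuroprint import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_case():
    """Default 64^3 phantom at moderate noise, shared across tests."""
    return generate_phantom(PhantomSpec(seed=7, noise_sigma=5.0))


@pytest.fixture(scope="session")
def quiet_phantom_case():
    return generate_phantom(PhantomSpec(seed=7, noise_sigma=2.0))


def write_dicom_slice(path, pixel_array, z_mm, series_uid, *,
                      spacing=(1.0, 1.0), orientation=(1, 0, 0, 0, 1, 0)):
    """Write one synthetic MR slice with the geometry tags the reader uses."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "MR"
    ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
    ds.ImageOrientationPatient = [float(v) for v in orientation]
    ds.PixelSpacing = [float(spacing[0]), float(spacing[1])]
    arr = np.asarray(pixel_array, dtype=np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


@pytest.fixture
def dicom_series_dir(tmp_path):
    """3-slice 8x8 synthetic series written out of order (z = 2, 0, 1)."""
    series_uid = generate_uid()
    rng = np.random.default_rng(0)
    planes = {z: rng.integers(0, 500, size=(8, 8)) for z in (0.0, 1.0, 2.0)}
    # filenames chosen so lexical order disagrees with position order
    for name, z in (("a.dcm", 2.0), ("b.dcm", 0.0), ("c.dcm", 1.0)):
        write_dicom_slice(tmp_path / name, planes[z], z, series_uid)
    return tmp_path, planes
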