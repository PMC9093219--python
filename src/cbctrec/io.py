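"""Volume and projection file IO.

Volumes: MetaImage (.mhd + .raw) and NIfTI (.nii/.nii.gz) through SimpleITK,
with voxel values, spacing and grid-centre offset round-tripping losslessly
(float64 payloads).  Projections: HDF5 (dataset ``projections[view, row,
col]`` with the geometry stored as root attributes) or multi-page TIFF with
the geometry as a JSON image description.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .geometry import ConeBeamGeometry, ProjectionSet, Volume, VolumeGrid

__all__ = ["VolumeFormatError", "read_volume", "write_volume",
           "read_projections", "write_projections"]


class VolumeFormatError(ValueError):
    """Malformed volume/projection file; the message names the offending
    field."""


_MHD_BYTES = {
    "MET_DOUBLE": 8, "MET_FLOAT": 4, "MET_SHORT": 2, "MET_USHORT": 2,
    "MET_CHAR": 1, "MET_UCHAR": 1, "MET_INT": 4, "MET_UINT": 4,
    "MET_LONG": 8, "MET_ULONG": 8,
}


def _validate_mhd(path: str) -> None:
    """Pre-validate an MHD header's RAW payload size so a truncated file
    fails with the expected vs actual byte counts."""
    fields: dict[str, str] = {}
    with open(path, "r") as fh:
        for line in fh:
            if "=" in line:
                key, val = line.split("=", 1)
                fields[key.strip()] = val.strip()
    try:
        dims = [int(t) for t in fields["DimSize"].split()]
        etype = fields["ElementType"]
        datafile = fields["ElementDataFile"]
    except KeyError as exc:
        raise VolumeFormatError(f"MHD header missing field {exc}") from None
    if etype not in _MHD_BYTES:
        raise VolumeFormatError(f"unsupported ElementType {etype!r}")
    if datafile.upper() == "LOCAL":
        return
    nchan = int(fields.get("ElementNumberOfChannels", 1))
    expected = int(np.prod(dims)) * _MHD_BYTES[etype] * nchan
    raw_path = os.path.join(os.path.dirname(path), datafile)
    if not os.path.exists(raw_path):
        raise VolumeFormatError(f"ElementDataFile {datafile!r} not found")
    actual = os.path.getsize(raw_path)
    if actual != expected:
        raise VolumeFormatError(
            f"RAW payload size mismatch for {datafile!r}: expected "
            f"{expected} bytes ({'x'.join(map(str, dims))} {etype}), "
            f"found {actual} bytes"
        )


def write_volume(path: str, volume: Volume) -> None:
    """Write a volume as .mhd/.raw or NIfTI; spacing carries the voxel size
    and the image origin encodes the grid-centre offset."""
    import SimpleITK as sitk

    grid = volume.grid
    # SimpleITK arrays are indexed (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing(tuple(float(s) for s in grid.voxel_size))
    lower = grid.lower_corner
    half = np.asarray(grid.voxel_size, float) / 2.0
    img.SetOrigin(tuple(lower + half))
    sitk.WriteImage(img, path)


def read_volume(path: str) -> Volume:
    """Read .mhd/.raw or NIfTI back into a `Volume` (inverse of
    `write_volume`)."""
    import SimpleITK as sitk

    if path.endswith(".mhd"):
        _validate_mhd(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read volume {path!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img).T.astype(np.float64)
    spacing = tuple(float(s) for s in img.GetSpacing())
    first_center = np.asarray(img.GetOrigin(), float)
    shape = arr.shape
    center = first_center - np.asarray(spacing) / 2.0 \
        + np.asarray(shape) * np.asarray(spacing) / 2.0
    grid = VolumeGrid(shape, spacing, tuple(center))
    return Volume(grid, np.ascontiguousarray(arr))


def _geometry_dict(geom: ConeBeamGeometry) -> dict:
    return {
        "dist_source_detector": geom.dist_source_detector,
        "dist_source_origin": geom.dist_source_origin,
        "view_angles": [float(a) for a in geom.view_angles],
        "detector_shape": list(geom.detector_shape),
        "detector_pixel": list(geom.detector_pixel),
        "detector_offset": list(geom.detector_offset),
    }


def _geometry_from_dict(d: dict) -> ConeBeamGeometry:
    return ConeBeamGeometry(
        float(d["dist_source_detector"]),
        float(d["dist_source_origin"]),
        np.asarray(d["view_angles"], dtype=np.float64),
        tuple(int(v) for v in d["detector_shape"]),
        tuple(float(v) for v in d["detector_pixel"]),
        tuple(float(v) for v in d.get("detector_offset", (0.0, 0.0))),
    )


def write_projections(path: str, projections: ProjectionSet) -> None:
    """Write projections as HDF5 (.h5/.hdf5) or multi-page TIFF."""
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("projections", data=projections.frames)
            for key, val in _geometry_dict(projections.geometry).items():
                dset.attrs[key] = val
    elif path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, projections.frames,
                         photometric="minisblack",
                         description=json.dumps(
                             _geometry_dict(projections.geometry)))
    else:
        raise VolumeFormatError(f"unsupported projection format: {path!r}")


def read_projections(path: str) -> ProjectionSet:
    """Inverse of `write_projections` (lossless round trip)."""
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            if "projections" not in fh:
                raise VolumeFormatError(
                    "HDF5 file lacks the 'projections' dataset")
            dset = fh["projections"]
            frames = np.asarray(dset, dtype=np.float64)
            geom = _geometry_from_dict({k: dset.attrs[k] for k in dset.attrs})
    elif path.endswith((".tif", ".tiff")):
        import tifffile

        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray().astype(np.float64)
            desc = tif.pages[0].description
            try:
                geom = _geometry_from_dict(json.loads(desc))
            except (json.JSONDecodeError, KeyError) as exc:
                raise VolumeFormatError(
                    f"TIFF lacks a geometry description: {exc}") from exc
    else:
        raise VolumeFormatError(f"unsupported projection format: {path!r}")
    if frames.ndim == 2:
        frames = frames[None]
    return ProjectionSet(geom, frames)
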