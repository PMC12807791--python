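"""Cine-loop volume I/O and field-of-view extraction.

A recorded cine loop of B-mode frames is stacked into a 3D volume indexed
(depth row, lateral column, elevational frame).  Depth increases away from
the transducer.  The elevational axis is in *frame units*: under freehand
scanning the physical interframe distance is unknown and non-uniform, so no
downstream computation ever assigns it a physical spacing.

``extract_fov`` strips the static overlay surrounding the imaging region and
removes the first and last rows, where surface reflections and weak deep
signal make intensities unreliable, producing the raw analysis volume (x0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class CineVolume:
    """A stacked cine loop with physical in-plane coordinates.

    Attributes
    ----------
    voxels : ndarray, shape (rows, columns, frames)
        Non-negative intensities; (depth, lateral, elevational) order.
    axial_spacing : float
        mm per pixel along depth.
    lateral_spacing : float
        mm per pixel along the lateral axis.
    depth_offset : float
        Physical depth (mm) of the first retained row, so that
        ``depth_offset + row * axial_spacing`` is the depth of any row.
    """

    voxels: np.ndarray
    axial_spacing: float
    lateral_spacing: float
    depth_offset: float = 0.0
    frame_rate: float | None = None
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InputError("voxels must be a 3D (rows, cols, frames) array")
        if self.n_frames < 3:
            raise InputError("a cine volume needs at least 3 frames")
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ConfigurationError("pixel spacings must be positive")
        if np.min(self.voxels) < 0:
            raise InputError("intensities must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[2]

    def row_depth_mm(self, row) -> np.ndarray | float:
        """Physical depth (mm) of a row index (array-friendly)."""
        return self.depth_offset + np.asarray(row) * self.axial_spacing

    @property
    def depth_extent_cm(self) -> tuple[float, float]:
        """(top, bottom) physical depth of the volume in cm."""
        return (self.depth_offset / 10.0,
                (self.depth_offset + self.n_rows * self.axial_spacing) / 10.0)


def _spacing_from_dicom(ds) -> tuple[float, float] | None:
    """PixelSpacing is (row spacing, column spacing) = (axial, lateral)."""
    if getattr(ds, "PixelSpacing", None):
        r, c = ds.PixelSpacing
        return float(r), float(c)
    # multi-frame: shared functional groups
    try:
        pm = ds.SharedFunctionalGroupsSequence[0].PixelMeasuresSequence[0]
        r, c = pm.PixelSpacing
        return float(r), float(c)
    except (AttributeError, IndexError):
        return None


def _frames_from_dicom(path: Path) -> tuple[np.ndarray, tuple[float, float] | None, float | None]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    elif arr.ndim != 3:
        raise InputError(f"unsupported DICOM pixel data shape {arr.shape}")
    rate = None
    if getattr(ds, "CineRate", None):
        rate = float(ds.CineRate)
    elif getattr(ds, "FrameTime", None):  # ms per frame
        rate = 1000.0 / float(ds.FrameTime)
    return arr, _spacing_from_dicom(ds), rate


def read_cine(
    source: str | Path | Sequence[np.ndarray],
    pixel_spacing: tuple[float, float] | None = None,
    acquisition_id: str = "",
) -> CineVolume:
    """Read a cine loop into a :class:`CineVolume`.

    ``source`` may be a multi-frame DICOM file, a directory of single-frame
    DICOMs (sorted by InstanceNumber) or PNG/TIFF frames (sorted by name),
    or an explicit ordered sequence of 2D arrays.  ``pixel_spacing`` is the
    (axial, lateral) spacing in mm and overrides any metadata; it is
    mandatory when the source carries none.  Intensities are preserved
    bit-exact.
    """
    frames: np.ndarray
    spacing = None
    rate = None

    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise InputError(f"input not found: {path}")
        if path.is_dir():
            frames, spacing = _read_frame_directory(path)
        else:
            frames, spacing, rate = _frames_from_dicom(path)
        frames = np.ascontiguousarray(np.moveaxis(frames, 0, -1))
    else:
        frame_list = [np.asarray(f) for f in source]
        if not frame_list:
            raise InputError("empty frame list")
        shapes = {f.shape for f in frame_list}
        if len(shapes) > 1:
            raise InputError(f"inconsistent frame shapes: {sorted(shapes)}")
        if frame_list[0].ndim != 2:
            raise InputError("frames must be 2D grayscale arrays")
        frames = np.stack(frame_list, axis=-1)

    if pixel_spacing is not None:
        spacing = (float(pixel_spacing[0]), float(pixel_spacing[1]))
    if spacing is None or any(s <= 0 for s in spacing):
        raise ConfigurationError(
            "pixel spacing missing or non-positive; pass pixel_spacing=(axial_mm, lateral_mm)"
        )
    if frames.shape[2] < 3:
        raise InputError(f"need >= 3 frames for an elevational stack, got {frames.shape[2]}")

    return CineVolume(
        voxels=frames,
        axial_spacing=spacing[0],
        lateral_spacing=spacing[1],
        frame_rate=rate,
        acquisition_id=acquisition_id,
    )


def _read_frame_directory(path: Path) -> tuple[np.ndarray, tuple[float, float] | None]:
    import pydicom

    dcm_files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".dicom"})
    img_files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if dcm_files:
        datasets = [pydicom.dcmread(str(p)) for p in dcm_files]
        datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        arrs = [d.pixel_array for d in datasets]
        spacing = _spacing_from_dicom(datasets[0])
    elif img_files:
        import imageio.v3 as iio

        arrs = [np.asarray(iio.imread(p)) for p in img_files]
        arrs = [a[..., 0] if a.ndim == 3 else a for a in arrs]
        spacing = None
    else:
        raise InputError(f"no DICOM or PNG/TIFF frames in {path}")
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise InputError(f"inconsistent frame shapes: {sorted(shapes)}")
    return np.stack(arrs, axis=0), spacing


def _first_zero_line(is_zero: np.ndarray, center: int, offset: int, direction: int) -> int | None:
    """Index of the first all-zero line scanning outward from center ± offset."""
    n = is_zero.shape[0]
    start = center - offset if direction < 0 else center + offset
    indices = range(min(start, n - 1), -1, -1) if direction < 0 else range(max(start, 0), n)
    for i in indices:
        if is_zero[i]:
            return i
    return None


def extract_fov(
    volume: CineVolume,
    min_offset: int = 50,
    trim_rows: int = 10,
    overlay_value: int = 0,
) -> CineVolume:
    """Crop the overlay away and trim unreliable rows, producing x0.

    For each of the four in-plane directions, the crop boundary is the first
    row/column equal to ``overlay_value`` everywhere (across all frames)
    found scanning outward starting ``min_offset`` pixels from the frame
    centre; the zero line itself is excluded.  If none is found the frame
    edge is kept.  The first and last ``trim_rows`` rows along depth are
    then removed and ``depth_offset`` updated accordingly.
    """
    v = volume.voxels
    if np.all(v == overlay_value):
        raise InputError("frame is entirely overlay/zero valued")
    zero_rows = np.all(v == overlay_value, axis=(1, 2))
    zero_cols = np.all(v == overlay_value, axis=(0, 2))
    rc, cc = volume.n_rows // 2, volume.n_cols // 2

    top = _first_zero_line(zero_rows, rc, min_offset, -1)
    bottom = _first_zero_line(zero_rows, rc, min_offset, +1)
    left = _first_zero_line(zero_cols, cc, min_offset, -1)
    right = _first_zero_line(zero_cols, cc, min_offset, +1)

    r0 = 0 if top is None else top + 1
    r1 = volume.n_rows if bottom is None else bottom
    c0 = 0 if left is None else left + 1
    c1 = volume.n_cols if right is None else right

    r0t, r1t = r0 + trim_rows, r1 - trim_rows
    if r1t - r0t < 32 or c1 - c0 < 32:
        raise InputError(
            "overlay detection consumed the image: "
            f"FOV {r1t - r0t}x{c1 - c0} is smaller than 32x32"
        )

    return replace(
        volume,
        voxels=v[r0t:r1t, c0:c1].copy(),
        depth_offset=volume.depth_offset + r0t * volume.axial_spacing,
    )


def _to_sitk(volume: CineVolume):
    import SimpleITK as sitk

    # numpy (rows, cols, frames) -> sitk size (x=frames, y=cols, z=rows)
    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing((1.0, volume.lateral_spacing, volume.axial_spacing))
    img.SetOrigin((0.0, 0.0, volume.depth_offset))
    return img


def save_volume(volume: CineVolume, path: str | Path) -> None:
    """Persist a volume as NRRD or NIfTI with spacing metadata.

    The elevational axis is stored with unit spacing (frame units).
    """
    import SimpleITK as sitk

    path = Path(path)
    if path.suffix not in {".nrrd", ".nii", ".gz"} and not str(path).endswith(".nii.gz"):
        raise ConfigurationError(f"unsupported volume format: {path.suffix}")
    sitk.WriteImage(_to_sitk(volume), str(path))


def load_volume(path: str | Path, acquisition_id: str = "") -> CineVolume:
    """Load a volume previously written by :func:`save_volume`."""
    import SimpleITK as sitk

    path = Path(path)
    if not path.exists():
        raise InputError(f"input not found: {path}")
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z=rows, y=cols, x=frames)
    sx, sy, sz = img.GetSpacing()
    return CineVolume(
        voxels=arr,
        axial_spacing=sz,
        lateral_spacing=sy,
        depth_offset=img.GetOrigin()[2],
        acquisition_id=acquisition_id,
    )
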