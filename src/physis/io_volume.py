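"""Volume I/O with physical spacing metadata.

All grids in this package share one coordinate convention:

* axis 0 is the bone's longitudinal axis, proximal (joint surface) at index 0,
  distal (shaft) at the highest index;
* axes 1 and 2 span the transverse plane (called *u* and *v* downstream);
* voxel spacing is isotropic and expressed in micrometres (μm);
* the physical position of voxel ``(i, j, k)`` is ``origin + spacing * (i, j, k)``
  (voxel centres).

Input volumes must be pre-oriented to this convention; no per-operation
orientation flags exist. Supported containers are multi-page TIFF stacks
(or a directory of per-slice TIFFs), NIfTI-1, and raw binary with a YAML
sidecar recording shape, dtype and spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "as_mask",
]

#: Relative tolerance used when deciding whether file metadata is isotropic.
_ISO_RTOL = 1e-3


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic physical spacing.

    Parameters
    ----------
    data
        3D array, axis 0 longitudinal (proximal → distal).
    spacing
        Voxel edge length in μm (isotropic).
    origin
        Physical offset of voxel ``(0, 0, 0)`` in μm.
    """

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be > 0 μm, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not all(math.isfinite(o) for o in self.origin):
            raise ValueError(f"origin must be finite, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(self.spacing) ** 3


@dataclass
class BinaryMask(VoxelVolume):
    """A boolean 3D grid sharing the :class:`VoxelVolume` conventions.

    ``provenance`` records how the mask was produced (e.g. the realized
    binarization threshold); it travels with the mask into reports.
    """

    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)


def as_mask(vol: VoxelVolume, provenance: dict | None = None) -> BinaryMask:
    """View a volume's nonzero voxels as a :class:`BinaryMask`."""
    return BinaryMask(
        vol.data.astype(bool), vol.spacing, vol.origin, provenance or {}
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "tiff_stack"
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    if suffixes.endswith(".raw"):
        return "raw"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def _require_isotropic(zooms, path) -> float:
    zooms = [float(z) for z in zooms]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    ref = zooms[0]
    if any(abs(z - ref) > _ISO_RTOL * ref for z in zooms[1:]):
        raise ValueError(
            f"{path}: anisotropic spacing {tuple(zooms)} μm; this pipeline "
            "requires isotropic voxels"
        )
    return ref


def _read_tiff(path: Path, spacing_override: float | None) -> VoxelVolume:
    if path.is_dir():
        slices = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not slices:
            raise ValueError(f"{path}: directory contains no TIFF slices")
        data = np.stack([tifffile.imread(s) for s in slices], axis=0)
        if spacing_override is None:
            raise ValueError(
                f"{path}: per-slice TIFF directories carry no spacing metadata; "
                "pass spacing_override"
            )
        return VoxelVolume(data, float(spacing_override))

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = None
        meta = tf.imagej_metadata or {}
        z = meta.get("spacing")
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if z is not None and xres is not None and yres is not None:
            # resolution tags are pixels per unit as a rational
            sx = xres.value[1] / xres.value[0]
            sy = yres.value[1] / yres.value[0]
            spacing = _require_isotropic((float(z), sy, sx), path)
    if data.ndim == 2:
        data = data[None]
    if spacing_override is not None:
        spacing = float(spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing recoverable from TIFF metadata and no "
            "spacing_override given"
        )
    return VoxelVolume(data, spacing)


def _read_nifti(path: Path, spacing_override: float | None) -> VoxelVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    spacing = (
        float(spacing_override)
        if spacing_override is not None
        else _require_isotropic(zooms, path)
    )
    # NIfTI arrays are (x, y, z); our convention puts the longitudinal axis first.
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    return VoxelVolume(np.ascontiguousarray(data), spacing)


def _read_raw(path: Path, spacing_override: float | None) -> VoxelVolume:
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise ValueError(f"{path}: raw volumes require a {sidecar.name} sidecar")
    meta = yaml.safe_load(sidecar.read_text())
    try:
        shape = tuple(int(s) for s in meta["shape"])
        dtype = np.dtype(meta["dtype"]) if meta["dtype"] != "bool" else np.uint8
        spacing = meta.get("spacing_um")
    except KeyError as exc:  # pragma: no cover - malformed sidecar
        raise ValueError(f"{sidecar}: missing key {exc}") from exc
    if spacing_override is not None:
        spacing = spacing_override
    if spacing is None:
        raise ValueError(f"{path}: sidecar has no spacing_um and no override given")
    data = np.fromfile(path, dtype=dtype).reshape(shape)
    if meta["dtype"] == "bool":
        data = data.astype(bool)
    return VoxelVolume(data, float(spacing))


def read_volume(
    path: Union[str, Path],
    format_hint: str = "auto",
    spacing_override: float | None = None,
) -> VoxelVolume:
    """Read a 3D volume in canonical axis order.

    Parameters
    ----------
    path
        File (or, for per-slice TIFF stacks, directory) to read.
    format_hint
        One of ``{"auto", "tiff_stack", "nifti", "raw"}``.
    spacing_override
        Isotropic voxel spacing in μm, overriding file metadata. When the
        file carries no recoverable spacing and no override is given this is
        an error — there is no default spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    readers = {"tiff_stack": _read_tiff, "nifti": _read_nifti, "raw": _read_raw}
    if fmt not in readers:
        raise ValueError(f"unknown format {fmt!r}")
    return readers[fmt](path, spacing_override)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_volume(
    vol: VoxelVolume, path: Union[str, Path], format: str | None = None
) -> None:
    """Write a volume or mask; round-trips bit-exactly for integer/bool data.

    Boolean masks are stored as uint8 on disk (the raw sidecar records the
    original dtype so raw round-trips restore ``bool``).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    fmt = _detect_format(path) if format is None else format

    data = vol.data
    is_bool = data.dtype == bool
    if fmt == "tiff_stack":
        out = data.astype(np.uint8) if is_bool else data
        s = vol.spacing
        tifffile.imwrite(
            path,
            out,
            imagej=True,
            resolution=(1.0 / s, 1.0 / s),
            metadata={"spacing": s, "unit": "um", "axes": "ZYX"},
        )
    elif fmt == "nifti":
        out = data.astype(np.uint8) if is_bool else data
        affine = np.diag([vol.spacing, vol.spacing, vol.spacing, 1.0])
        img = nib.Nifti1Image(np.transpose(out, (2, 1, 0)), affine)
        img.header.set_zooms((vol.spacing,) * 3)
        nib.save(img, str(path))
    elif fmt == "raw":
        out = data.astype(np.uint8) if is_bool else data
        out.tofile(path)
        sidecar = path.with_suffix(".yaml")
        sidecar.write_text(
            yaml.safe_dump(
                {
                    "shape": list(data.shape),
                    "dtype": "bool" if is_bool else data.dtype.name,
                    "spacing_um": float(vol.spacing),
                    "order": "C",
                },
                sort_keys=False,
            )
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
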