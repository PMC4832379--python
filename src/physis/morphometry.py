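"""Morphometry of the growth-plate cartilage layer: Tb.Th, S/V and SMI.

Three classic descriptors of a binary 3D structure:

* **Tb.Th (local thickness)** — at every voxel, the diameter of the largest
  sphere that contains it and fits entirely inside the structure
  (Hildebrand–Rüegsegger definition); reported as mean ± SD over the
  structure in μm.
* **S/V** — surface area over volume, μm⁻¹. Surface area comes from a
  triangulated iso-surface of the smoothed signed Euclidean distance field
  (``method="mesh"``), or from a 3-direction Crofton intercept estimate
  (``method="crofton"``).
* **SMI (structure model index)** — ``6·V·S′/S²`` where ``S′`` is the
  derivative of surface area under an infinitesimal outward surface
  dilation. An ideal plate scores 0, an ideal cylinder 3, an ideal sphere 4;
  concave structures can go negative. The derivative is realized by
  displacing every vertex of the triangulated surface along its outward
  normal by ``dilation_step`` and recomputing the area of the *same* mesh —
  keeping the triangulation fixed cancels the faceting bias that would
  otherwise swamp the finite difference.

All estimators assume isotropic spacing and are exactly invariant under
axis-aligned 90° rotations and translations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.measure import marching_cubes, mesh_surface_area

from .io_volume import BinaryMask

__all__ = [
    "MorphometryResult",
    "local_thickness",
    "surface_area",
    "surface_to_volume",
    "structure_model_index",
    "compute_morphometry",
]

#: Gaussian pre-smoothing (voxels) applied to the signed distance field
#: before iso-surfacing. Large enough to suppress the EDT quantization
#: staircase (which inflates triangulated areas by ~8%), small enough to
#: keep edge rounding of rectilinear solids under ~5%.
_MESH_SIGMA = 0.7


@dataclass
class MorphometryResult:
    """Bundle of cartilage-layer morphometry with estimator provenance."""

    thickness_mean: float  # μm
    thickness_sd: float  # μm
    surface_area: float  # μm²
    volume: float  # μm³
    s_over_v: float  # μm⁻¹
    smi: float  # dimensionless
    params: dict

    def to_dict(self) -> dict:
        return {
            "thickness_mean_um": self.thickness_mean,
            "thickness_sd_um": self.thickness_sd,
            "surface_area_um2": self.surface_area,
            "volume_um3": self.volume,
            "s_over_v_per_um": self.s_over_v,
            "smi": self.smi,
            "params": self.params,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _require_nonempty(mask: BinaryMask) -> None:
    if not mask.data.any():
        raise ValueError("morphometry is undefined on an empty mask")


# ---------------------------------------------------------------------------
# local thickness
# ---------------------------------------------------------------------------


@njit(cache=False)
def _paint_spheres(thick, coords, radii, nz, ny, nx):  # pragma: no cover - jitted
    """Assign to each voxel the diameter of the largest covering inscribed
    sphere. Centres are processed in descending radius so each voxel's final
    value is written early and later, smaller spheres mostly no-op."""
    for n in range(coords.shape[0]):
        r = radii[n]
        cz, cy, cx = coords[n, 0], coords[n, 1], coords[n, 2]
        d = 2.0 * r
        reach = r - 0.5
        ri = int(np.floor(reach))
        r2 = reach * reach
        for dz in range(-ri, ri + 1):
            z = cz + dz
            if z < 0 or z >= nz:
                continue
            for dy in range(-ri, ri + 1):
                y = cy + dy
                if y < 0 or y >= ny:
                    continue
                rem = r2 - dz * dz - dy * dy
                if rem < 0:
                    continue
                for dx in range(-ri, ri + 1):
                    x = cx + dx
                    if x < 0 or x >= nx:
                        continue
                    if dx * dx <= rem and thick[z, y, x] < d:
                        thick[z, y, x] = d
    return thick


def local_thickness(mask: BinaryMask):
    """Per-voxel local thickness map with (mean, sd) in μm.

    The inscribed-sphere radius at a candidate centre is its Euclidean
    distance to the nearest background voxel centre; a sphere of radius *r*
    covers the voxels strictly inside it (centre distance ≤ r − ½ voxel).

    Returns
    -------
    (thickness_map, mean, sd)
        ``thickness_map`` is float64 in μm (0 outside the mask); mean/sd are
        taken over mask voxels.
    """
    _require_nonempty(mask)
    edt = ndimage.distance_transform_edt(mask.data)
    coords = np.argwhere(mask.data).astype(np.int64)
    radii = edt[mask.data]
    order = np.argsort(radii)[::-1]
    thick = np.zeros(mask.data.shape, dtype=np.float64)
    nz, ny, nx = mask.data.shape
    _paint_spheres(
        thick, coords[order], radii[order].astype(np.float64), nz, ny, nx
    )
    thick *= mask.spacing
    vals = thick[mask.data]
    return thick, float(vals.mean()), float(vals.std())


# ---------------------------------------------------------------------------
# surface area
# ---------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mid-voxel interface (voxel units,
    positive outside). The half-voxel correction places the zero level midway
    between the boundary voxel centres."""
    din = ndimage.distance_transform_edt(mask)
    dout = ndimage.distance_transform_edt(~mask)
    return np.where(mask, -(din - 0.5), dout - 0.5)


def _iso_mesh(mask: np.ndarray, sigma: float = _MESH_SIGMA):
    """Triangulated 0-level surface of the smoothed signed distance field.

    The mask is cropped to its bounding box (plus padding) first, so the
    result is exactly translation invariant. Structures so thin that
    smoothing erases the zero crossing fall back to the unsmoothed field.
    Returns (vertices, faces, outward unit normals) in voxel units.
    """
    bbox = ndimage.find_objects(mask.astype(np.uint8))[0]
    cropped = np.pad(mask[bbox], 4)
    f = gaussian_filter(_signed_distance(cropped).astype(np.float32), sigma)
    if f.min() >= 0:  # sub-resolution structure smoothed away
        f = _signed_distance(cropped).astype(np.float32)
    verts, faces, normals, _ = marching_cubes(f, level=0.0)
    # marching_cubes orients normals down the gradient; sdf grows outward
    normals = -normals
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return verts, faces, normals


def _crofton_area(mask: np.ndarray, spacing: float) -> float:
    """3-direction Crofton estimate: S = (2/3)·h²·(boundary crossings).

    Unbiased for isotropically oriented surfaces; underestimates strongly
    axis-aligned faces (a cube reads 2/3 of its true area).
    """
    crossings = 0
    for axis in range(3):
        crossings += int(np.sum(np.diff(mask, axis=axis) != 0))
        # boundary faces at the array edge also cross
        first = np.take(mask, 0, axis=axis)
        last = np.take(mask, -1, axis=axis)
        crossings += int(first.sum()) + int(last.sum())
    return (2.0 / 3.0) * spacing**2 * crossings


def surface_area(mask: BinaryMask, method: str = "mesh") -> float:
    """Surface area of the mask boundary in μm²."""
    _require_nonempty(mask)
    if method == "mesh":
        verts, faces, _ = _iso_mesh(mask.data)
        return float(mesh_surface_area(verts, faces)) * mask.spacing**2
    if method == "crofton":
        return _crofton_area(mask.data, mask.spacing)
    raise ValueError(f"unknown surface_area method {method!r}")


def surface_to_volume(mask: BinaryMask, method: str = "mesh") -> float:
    """S/V in μm⁻¹ (volume = voxel count × spacing³)."""
    _require_nonempty(mask)
    volume = float(mask.data.sum()) * mask.spacing**3
    return surface_area(mask, method) / volume


# ---------------------------------------------------------------------------
# structure model index
# ---------------------------------------------------------------------------


def structure_model_index(
    mask: BinaryMask, dilation_step: float | None = None
) -> float:
    """SMI = 6·V·S′/S² (plate 0, cylinder 3, sphere 4).

    ``dilation_step`` is the outward surface displacement ε in μm (default
    one voxel). Structures thinner than two dilation steps make the
    derivative unreliable and trigger a warning.
    """
    _require_nonempty(mask)
    s = mask.spacing
    if dilation_step is None:
        dilation_step = s
    if dilation_step <= 0:
        raise ValueError("dilation_step must be > 0 μm")
    eps_vox = dilation_step / s

    max_inscribed = ndimage.distance_transform_edt(mask.data).max() * s
    if 2 * max_inscribed < 2 * dilation_step:
        warnings.warn(
            "structure thinner than 2× dilation_step: SMI derivative unreliable",
            stacklevel=2,
        )

    verts, faces, normals = _iso_mesh(mask.data)
    s0 = mesh_surface_area(verts, faces)
    s1 = mesh_surface_area(verts + eps_vox * normals, faces)
    s_prime = (s1 - s0) / eps_vox  # voxel units: μm²/μm after scaling below
    volume = float(mask.data.sum())
    # spacing cancels: 6·(V h³)·(S′ h)/(S h²)² = 6·V·S′/S²
    return float(6.0 * volume * s_prime / s0**2)


def compute_morphometry(mask: BinaryMask, dilation_step: float | None = None):
    """All cartilage-layer morphometry in one pass."""
    _require_nonempty(mask)
    _, th_mean, th_sd = local_thickness(mask)
    area = surface_area(mask, method="mesh")
    volume = float(mask.data.sum()) * mask.spacing**3
    smi = structure_model_index(mask, dilation_step)
    return MorphometryResult(
        thickness_mean=th_mean,
        thickness_sd=th_sd,
        surface_area=area,
        volume=volume,
        s_over_v=area / volume,
        smi=smi,
        params={
            "thickness": "largest-inscribed-sphere (distance ridge painting)",
            "surface": f"marching-cubes on signed EDT, sigma={_MESH_SIGMA} vox",
            "smi": "mesh-normal dilation derivative, 6*V*S'/S^2",
            "dilation_step_um": float(
                dilation_step if dilation_step is not None else mask.spacing
            ),
            "spacing_um": float(mask.spacing),
        },
    )
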