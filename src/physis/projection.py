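"""Joint-surface projection, areal-density maps and quadrant counts.

Bridges are projected as centroids along the longitudinal axis onto the
transverse (u, v) plane — one point per bridge, so every map and count
conserves the bridge total. The areal density *d* is the number of bridges
per square window (default 256 μm × 256 μm) tiled over the projected plate
footprint; the mean density averages over footprint windows only, so windows
that never see anatomy do not dilute it.

Binning convention: half-open tiles [left, right) × [bottom, top); a point
exactly on a tile boundary goes to the higher-index tile. Quadrant tie-break:
points exactly on a split line go to the medial / anterior side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bridging import BridgeSet
from .segmentation import PLATE, LabelledJoint

__all__ = [
    "ProjectedPoint",
    "DensityMap",
    "QuadrantCounts",
    "project_bridges",
    "plate_footprint",
    "density_map",
    "mean_areal_density",
    "quadrant_counts",
]

DEFAULT_WINDOW_UM = 256.0


@dataclass(frozen=True)
class ProjectedPoint:
    """A bridge centroid on the transverse plane (physical μm)."""

    bridge_id: int
    u: float
    v: float


@dataclass
class DensityMap:
    """Tiled grid of bridge counts per window.

    ``origin_uv`` is the physical (u, v) of the low corner of tile (0, 0);
    ``footprint`` marks tiles overlapping the projected plate region.
    """

    counts: np.ndarray
    window: float
    origin_uv: tuple[float, float]
    footprint: np.ndarray

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0 μm")
        if self.counts.shape != self.footprint.shape:
            raise ValueError("counts and footprint must share a shape")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        i, j = np.nonzero(np.ones_like(self.counts, dtype=bool))
        return pd.DataFrame(
            {
                "tile_u": i,
                "tile_v": j,
                "u_left_um": self.origin_uv[0] + i * self.window,
                "v_left_um": self.origin_uv[1] + j * self.window,
                "count": self.counts[i, j],
                "in_footprint": self.footprint[i, j],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")


@dataclass
class QuadrantCounts:
    anterior_lateral: int
    anterior_medial: int
    posterior_lateral: int
    posterior_medial: int
    axis_split: dict

    @property
    def total(self) -> int:
        return (
            self.anterior_lateral
            + self.anterior_medial
            + self.posterior_lateral
            + self.posterior_medial
        )

    def to_dict(self) -> dict:
        return {
            "anterior_lateral": self.anterior_lateral,
            "anterior_medial": self.anterior_medial,
            "posterior_lateral": self.posterior_lateral,
            "posterior_medial": self.posterior_medial,
        }


def project_bridges(bs: BridgeSet) -> list[ProjectedPoint]:
    """Orthogonal projection of each bridge centroid along axis 0."""
    return [
        ProjectedPoint(b.id, b.centroid_um[1], b.centroid_um[2]) for b in bs.bridges
    ]


def plate_footprint(joint: LabelledJoint, origin=(0.0, 0.0)):
    """Project the plate region along axis 0.

    Returns ``(mask2d, spacing_um, origin_uv)`` in the frame shared with the
    projected points.
    """
    mask2d = (joint.labels == PLATE).any(axis=0)
    return mask2d, joint.spacing, (float(origin[0]), float(origin[1]))


def density_map(
    points: list[ProjectedPoint],
    window: float = DEFAULT_WINDOW_UM,
    plate_footprint: np.ndarray | None = None,
    origin_uv: tuple[float, float] = (0.0, 0.0),
    footprint_spacing: float | None = None,
    footprint_origin: tuple[float, float] = (0.0, 0.0),
) -> DensityMap:
    """Bin projected points into non-overlapping window × window tiles.

    The tiling is anchored at ``origin_uv`` and auto-expands to cover every
    point and the whole footprint — a point outside the current extent grows
    the grid rather than being dropped. ``plate_footprint`` is a 2D boolean
    pixel mask (with ``footprint_spacing`` μm pixels anchored at
    ``footprint_origin``); a tile belongs to the footprint when at least one
    true pixel centre falls inside it.
    """
    if window <= 0:
        raise ValueError("window must be > 0 μm")
    pu = np.array([p.u for p in points], dtype=float)
    pv = np.array([p.v for p in points], dtype=float)
    iu = np.floor((pu - origin_uv[0]) / window).astype(int)
    iv = np.floor((pv - origin_uv[1]) / window).astype(int)

    fi = fj = np.empty(0, dtype=int)
    if plate_footprint is not None and plate_footprint.any():
        if footprint_spacing is None:
            raise ValueError("plate_footprint requires footprint_spacing")
        ii, jj = np.nonzero(plate_footprint)
        fu = footprint_origin[0] + ii * footprint_spacing
        fv = footprint_origin[1] + jj * footprint_spacing
        fi = np.floor((fu - origin_uv[0]) / window).astype(int)
        fj = np.floor((fv - origin_uv[1]) / window).astype(int)

    all_i = np.concatenate([iu, fi])
    all_j = np.concatenate([iv, fj])
    if all_i.size == 0:
        counts = np.zeros((1, 1), dtype=int)
        return DensityMap(counts, window, origin_uv, np.zeros((1, 1), dtype=bool))

    imin, jmin = all_i.min(), all_j.min()
    shape = (all_i.max() - imin + 1, all_j.max() - jmin + 1)
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, (iu - imin, iv - jmin), 1)
    fp = np.zeros(shape, dtype=bool)
    fp[fi - imin, fj - jmin] = True
    anchored = (origin_uv[0] + imin * window, origin_uv[1] + jmin * window)
    return DensityMap(counts, window, anchored, fp)


def mean_areal_density(dm: DensityMap) -> float:
    """Mean bridges per window over the plate footprint (dimensionless rate)."""
    n_tiles = int(dm.footprint.sum())
    if n_tiles == 0:
        raise ValueError("density map has an empty plate footprint")
    return float(dm.counts.sum()) / n_tiles


_ANTERIOR_OF = {"+u": "+v", "+v": "-u", "-u": "-v", "-v": "+u"}


def _signed(axis: str, du: np.ndarray, dv: np.ndarray) -> np.ndarray:
    comp = du if axis[1] == "u" else dv
    return comp if axis[0] == "+" else -comp


def quadrant_counts(
    points: list[ProjectedPoint],
    center_uv: tuple[float, float],
    medial_direction: str = "+u",
) -> QuadrantCounts:
    """Split points into anatomical quadrants about ``center_uv``.

    ``medial_direction`` names the transverse direction pointing medially;
    the anterior direction is the medial one rotated +90° in the (u, v)
    plane. Points exactly on a split line count as medial / anterior.
    """
    if medial_direction not in _ANTERIOR_OF:
        raise ValueError(f"medial_direction must be one of {set(_ANTERIOR_OF)}")
    anterior_direction = _ANTERIOR_OF[medial_direction]
    du = np.array([p.u - center_uv[0] for p in points])
    dv = np.array([p.v - center_uv[1] for p in points])
    medial = _signed(medial_direction, du, dv) >= 0
    anterior = _signed(anterior_direction, du, dv) >= 0
    return QuadrantCounts(
        anterior_lateral=int(np.sum(anterior & ~medial)),
        anterior_medial=int(np.sum(anterior & medial)),
        posterior_lateral=int(np.sum(~anterior & ~medial)),
        posterior_medial=int(np.sum(~anterior & medial)),
        axis_split={
            "center_uv": [float(center_uv[0]), float(center_uv[1])],
            "medial_direction": medial_direction,
            "anterior_direction": anterior_direction,
        },
    )
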