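"""Synthetic joint phantoms with exact ground truth.

No public scan accompanies the study design this package implements, so the
test bed is synthetic: two mineralized cylinders (epiphysis proximal,
metaphysis distal) separated by a thin, optionally domed, low-intensity
cartilage layer, pierced by a configurable number of bone-intensity pegs —
the ground-truth bridges. Additive Gaussian intensity noise exercises the
binarization path. A fixed :class:`PhantomSpec` plus seed reproduces the
volume bit for bit.

Default parameters are the package's reference study conditions: a
64×96×96 grid at 5 μm (a ≈0.3×0.5×0.5 mm field around the plate, laboratory
micro-CT scale), a 30 μm cartilage layer with mild dome curvature, 12.5 μm
bridge radius and ≥30 μm mutual separation, and 5% Gaussian noise.

:func:`make_ideal_shape` supplies the digitized plate / cylinder / sphere
used to anchor the structure model index at its textbook values 0 / 3 / 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io_volume import BinaryMask, VoxelVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_plate_phantom",
    "make_ideal_shape",
    "ideal_shape_suite",
    "write_fixture_suite",
]

#: Phantom intensities (arbitrary attenuation units).
BONE_INTENSITY = 100.0
CARTILAGE_INTENSITY = 10.0
BACKGROUND_INTENSITY = 0.0

#: Longitudinal overshoot of a peg into each bone body, voxels.
_PEG_EXTENSION_VOX = 2.0


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic joint volume."""

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing_um: float = 5.0
    plate_thickness_um: float = 30.0
    plate_curvature: float = 0.1  # dome height as a fraction of footprint radius
    body_gap_position: float = 0.5  # fractional axis-0 position of the layer
    n_bridges: int = 5
    bridge_radius_um: float = 12.5
    bridge_positions: list[tuple[float, float]] | str = "random"  # (u, v) μm
    min_bridge_separation_um: float = 30.0
    noise_sigma: float = 0.05  # fraction of bone intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bridges < 0:
            raise ValueError("n_bridges must be ≥ 0")
        if self.bridge_radius_um < self.spacing_um:
            raise ValueError("bridge radius must be ≥ 1 voxel")
        if not (0 < self.body_gap_position < 1):
            raise ValueError("body_gap_position must be in (0, 1)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["shape"] = list(self.shape)
        if d["bridge_positions"] != "random":
            d["bridge_positions"] = [list(p) for p in d["bridge_positions"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["shape"] = tuple(d["shape"])
        if d.get("bridge_positions", "random") != "random":
            d["bridge_positions"] = [tuple(p) for p in d["bridge_positions"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows about a phantom.

    ``bridge_centers_um`` are (u, v, z) physical coordinates of each peg's
    intersection with the plate mid-surface; masks are boolean grids in the
    phantom's frame. ``plate_mask`` is the cartilage layer *excluding* peg
    voxels; body masks exclude pegs likewise.
    """

    bridge_centers_um: list[tuple[float, float, float]]
    bridge_masks: list[np.ndarray]
    plate_mask: np.ndarray
    epiphysis_mask: np.ndarray
    metaphysis_mask: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)


def _dome_mid_surface(spec: PhantomSpec, d2_over_r2: np.ndarray, rdisk: float):
    """Longitudinal position of the plate mid-surface per transverse column.

    A paraboloid dome, apex displaced proximally by curvature × footprint
    radius; curvature 0 is a flat plate.
    """
    nz = spec.shape[0]
    z0 = spec.body_gap_position * nz
    return z0 - spec.plate_curvature * rdisk * (1.0 - d2_over_r2)


def make_plate_phantom(spec: PhantomSpec):
    """Render a phantom volume and its ground truth.

    Raises
    ------
    ValueError
        If the requested bridges cannot be placed in the footprint at the
        stated separation within a bounded number of rejection-sampling
        attempts, or if fixed positions violate the geometry.
    """
    nz, ny, nx = spec.shape
    s = spec.spacing_um
    rng = np.random.default_rng(spec.seed)

    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rdisk = 0.45 * min(ny, nx)  # footprint radius, voxels
    yy, xx = np.mgrid[:ny, :nx].astype(float)
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    disk = d2 <= rdisk**2

    t_vox = spec.plate_thickness_um / s
    zmid = _dome_mid_surface(spec, d2 / rdisk**2, rdisk)
    z = np.arange(nz, dtype=float)[:, None, None]
    zlo, zhi = 4, nz - 5  # background padding proximal/distal
    inside = disk[None] & (z >= zlo) & (z <= zhi)
    layer = inside & (np.abs(z - zmid[None]) <= t_vox / 2)
    epi_body = inside & (z < zmid[None]) & ~layer
    meta_body = inside & (z > zmid[None]) & ~layer

    # --- peg placement -----------------------------------------------------
    r_vox = spec.bridge_radius_um / s
    sep_vox = spec.min_bridge_separation_um / s
    margin = r_vox + 3.0
    if rdisk <= margin and spec.n_bridges > 0:
        raise ValueError("bridge radius too large for the phantom footprint")

    if spec.bridge_positions == "random":
        centers: list[tuple[float, float]] = []
        max_tries = 2000 * max(spec.n_bridges, 1)
        tries = 0
        while len(centers) < spec.n_bridges:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not place {spec.n_bridges} bridges at separation "
                    f"{spec.min_bridge_separation_um} μm after {max_tries} attempts"
                )
            py = rng.uniform(cy - rdisk, cy + rdisk)
            px = rng.uniform(cx - rdisk, cx + rdisk)
            if (py - cy) ** 2 + (px - cx) ** 2 > (rdisk - margin) ** 2:
                continue
            if any(
                (py - a) ** 2 + (px - b) ** 2 < (sep_vox + 2 * r_vox) ** 2
                for a, b in centers
            ):
                continue
            centers.append((py, px))
    else:
        centers = [(u / s, v / s) for (u, v) in spec.bridge_positions]
        if len(centers) != spec.n_bridges:
            raise ValueError("bridge_positions length must equal n_bridges")
        for py, px in centers:
            if (py - cy) ** 2 + (px - cx) ** 2 > (rdisk - margin) ** 2:
                raise ValueError(f"bridge at ({py}, {px}) vox outside footprint")

    pegs = np.zeros(spec.shape, dtype=bool)
    peg_masks, centers_um = [], []
    for py, px in centers:
        zm = float(
            _dome_mid_surface(
                spec, ((py - cy) ** 2 + (px - cx) ** 2) / rdisk**2, rdisk
            )
        )
        pm = ((yy - py) ** 2 + (xx - px) ** 2 <= r_vox**2)[None] & (
            np.abs(z - zm) <= t_vox / 2 + _PEG_EXTENSION_VOX
        )
        peg_masks.append(pm)
        pegs |= pm
        centers_um.append((py * s, px * s, zm * s))

    plate_gt = layer & ~pegs
    vol = np.full(spec.shape, BACKGROUND_INTENSITY, dtype=np.float32)
    vol[epi_body | meta_body | pegs] = BONE_INTENSITY
    vol[plate_gt] = CARTILAGE_INTENSITY
    if spec.noise_sigma > 0:
        vol += rng.normal(
            0.0, spec.noise_sigma * BONE_INTENSITY, spec.shape
        ).astype(np.float32)

    gt = GroundTruth(
        bridge_centers_um=centers_um,
        bridge_masks=peg_masks,
        plate_mask=plate_gt,
        epiphysis_mask=epi_body & ~pegs,
        metaphysis_mask=meta_body & ~pegs,
        spec=spec,
    )
    return VoxelVolume(vol, s), gt


# ---------------------------------------------------------------------------
# ideal shapes
# ---------------------------------------------------------------------------

_PAD = 4  # voxels of background on every face


def make_ideal_shape(kind: str, spacing_um: float = 1.0, **size_params) -> BinaryMask:
    """Digitize an ideal solid, centred in a padded grid.

    Parameters by kind (all μm):

    * ``plate``: ``thickness_um``, ``extent_um`` (square lateral extent)
    * ``cylinder``: ``radius_um``, ``length_um``
    * ``sphere``: ``radius_um``
    """
    s = spacing_um

    def vox(x):
        return x / s

    if kind == "plate":
        t, L = vox(size_params["thickness_um"]), vox(size_params["extent_um"])
        t, L = int(round(t)), int(round(L))
        if t < 2 or L < 2:
            raise ValueError("plate under resolution floor (≥ 2 voxels)")
        m = np.zeros((t + 2 * _PAD, L + 2 * _PAD, L + 2 * _PAD), dtype=bool)
        m[_PAD : _PAD + t, _PAD : _PAD + L, _PAD : _PAD + L] = True
    elif kind == "cylinder":
        r, L = vox(size_params["radius_um"]), vox(size_params["length_um"])
        L = int(round(L))
        if r < 2 or L < 2:
            raise ValueError("cylinder under resolution floor")
        n = int(np.ceil(2 * r)) + 2 * _PAD + 1
        c = (n - 1) / 2.0
        y, x = np.ogrid[:n, :n]
        disk = (y - c) ** 2 + (x - c) ** 2 <= r**2
        m = np.zeros((L + 2 * _PAD, n, n), dtype=bool)
        m[_PAD : _PAD + L] = disk[None]
    elif kind == "sphere":
        r = vox(size_params["radius_um"])
        if r < 2:
            raise ValueError("sphere under resolution floor")
        n = int(np.ceil(2 * r)) + 2 * _PAD + 1
        c = (n - 1) / 2.0
        zz, y, x = np.ogrid[:n, :n, :n]
        m = (zz - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r**2
    else:
        raise ValueError(f"unknown ideal shape {kind!r}")
    return BinaryMask(m, s, provenance={"kind": kind, **size_params})


def ideal_shape_suite(level: int = 2, spacing_um: float = 1.0) -> dict:
    """The three SMI anchor shapes at refinement ``level`` 0, 1 or 2.

    The sphere refines by radius doubling (discretization error only); the
    plate and cylinder refine by doubling their lateral extent / length at
    fixed thickness / radius, growing the aspect ratio toward the unbounded
    ideal — their leading SMI error is the finite-extent term, which uniform
    scaling would leave unchanged.
    """
    if level not in (0, 1, 2):
        raise ValueError("level must be 0, 1 or 2")
    f = 2**level
    s = spacing_um
    return {
        "plate": make_ideal_shape(
            "plate", s, thickness_um=4 * s, extent_um=200 * f * s
        ),
        "cylinder": make_ideal_shape(
            "cylinder", s, radius_um=10 * s, length_um=125 * f * s
        ),
        "sphere": make_ideal_shape("sphere", s, radius_um=20 * f * s),
    }


def write_fixture_suite(outdir) -> list[Path]:
    """Emit the canonical fixture phantoms and ideal shapes to ``outdir``.

    Flat and domed plates, 0/2/5/20-bridge cases and the three ideal shapes
    at three refinement levels, each volume beside a YAML spec (phantoms) or
    provenance entry (shapes).
    """
    from .io_volume import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cases = {
        "flat_plate": PhantomSpec(n_bridges=0, plate_curvature=0.0, seed=101),
        "domed_plate": PhantomSpec(n_bridges=0, plate_curvature=0.2, seed=102),
        "bridges_0": PhantomSpec(n_bridges=0, seed=110),
        "bridges_2": PhantomSpec(n_bridges=2, seed=112),
        "bridges_5": PhantomSpec(n_bridges=5, seed=115),
        "bridges_20": PhantomSpec(n_bridges=20, seed=120),
    }
    for name, spec in cases.items():
        vol, _ = make_plate_phantom(spec)
        vpath = outdir / f"{name}.tif"
        write_volume(vol, vpath)
        spec.to_yaml(outdir / f"{name}.yaml")
        written.append(vpath)

    for level in (0, 1, 2):
        for kind, mask in ideal_shape_suite(level).items():
            path = outdir / f"ideal_{kind}_L{level}.tif"
            write_volume(mask, path)
            written.append(path)
    return written
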