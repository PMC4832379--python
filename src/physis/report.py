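"""End-to-end pipeline orchestration and cohort reporting.

One :class:`PipelineConfig` drives the whole protocol per specimen:
binarize → clean → extract plate → split bodies → detect (and optionally
merge) bridges → project → density map + quadrant counts → cartilage
morphometry. Specimens fail in isolation — one corrupt file yields an error
row, not a cohort abort — and a cohort summary reports per-group
mean ± SEM (SEM = sd/√n) of every scalar measure. The measurement pipeline
is deterministic; the only randomness (phantom synthesis) flows from the
config seed, so identical config + inputs give byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .bridging import detect_bridges, merge_touching_bridges
from .io_volume import read_volume, write_volume
from .morphometry import compute_morphometry
from .phantoms import PhantomSpec, make_plate_phantom
from .projection import (
    DEFAULT_WINDOW_UM,
    DensityMap,
    ProjectedPoint,
    density_map,
    mean_areal_density,
    plate_footprint,
    project_bridges,
    quadrant_counts,
)
from .segmentation import (
    binarize_bone,
    extract_plate_region,
    remove_small_components,
    split_epiphysis_metaphysis,
)

__all__ = [
    "PipelineConfig",
    "SpecimenSpec",
    "CohortSummary",
    "run_pipeline",
    "render_density_figure",
]

log = logging.getLogger("physis")

_CSV_FLOAT = "%.6g"


@dataclass
class SpecimenSpec:
    """One input: either a volume on disk or an inline phantom spec."""

    id: str
    group: str = "default"
    path: str | None = None
    format_hint: str = "auto"
    spacing_override: float | None = None
    phantom: dict | None = None

    def load(self, seed: int):
        if (self.path is None) == (self.phantom is None):
            raise ValueError(
                f"specimen {self.id!r}: exactly one of path/phantom required"
            )
        if self.path is not None:
            return read_volume(self.path, self.format_hint, self.spacing_override)
        params = dict(self.phantom)
        params.setdefault("seed", seed)
        vol, _ = make_plate_phantom(PhantomSpec(**params))
        return vol


@dataclass
class PipelineConfig:
    specimens: list[SpecimenSpec]
    output_dir: str = "physis_out"
    seed: int = 0
    # segmentation
    binarization_method: str = "otsu"
    binarization_threshold: float | None = None
    min_component_um3: float = 0.0
    closing_radius_um: float | None = None  # default: 2 × plate thickness estimate
    plate_thickness_estimate_um: float | None = None
    # bridging
    bridge_dilation_um: float | None = None  # default: 1 voxel
    merge_separation_um: float = 0.0
    # projection
    window_um: float = DEFAULT_WINDOW_UM
    quadrant_center_uv: tuple[float, float] | None = None  # default: footprint centroid
    medial_direction: str = "+u"
    # morphometry
    morphometry: bool = True
    write_figures: bool = True
    write_volumes: bool = False

    def __post_init__(self) -> None:
        if self.window_um <= 0:
            raise ValueError("window_um must be > 0")
        if self.closing_radius_um is None and self.plate_thickness_estimate_um is None:
            raise ValueError(
                "provide closing_radius_um or plate_thickness_estimate_um "
                "(closing radius defaults to 2× the thickness estimate)"
            )

    @property
    def closing_radius(self) -> float:
        if self.closing_radius_um is not None:
            return self.closing_radius_um
        return 2.0 * self.plate_thickness_estimate_um

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        specimens = [SpecimenSpec(**s) for s in raw.pop("specimens")]
        if "quadrant_center_uv" in raw and raw["quadrant_center_uv"] is not None:
            raw["quadrant_center_uv"] = tuple(raw["quadrant_center_uv"])
        return cls(specimens=specimens, **raw)


@dataclass
class CohortSummary:
    """Per-specimen measurements plus per-group mean ± SEM."""

    specimens: pd.DataFrame
    groups: pd.DataFrame
    errors: list[dict] = field(default_factory=list)

    @property
    def partial_failure(self) -> bool:
        return len(self.errors) > 0


_SCALARS = [
    "n_bridges",
    "mean_areal_density",
    "anterior_lateral",
    "anterior_medial",
    "posterior_lateral",
    "posterior_medial",
    "thickness_mean_um",
    "thickness_sd_um",
    "s_over_v_per_um",
    "smi",
]


def _process_specimen(spec: SpecimenSpec, config: PipelineConfig, outdir: Path):
    t0 = time.perf_counter()
    vol = spec.load(config.seed)
    bone = binarize_bone(
        vol, config.binarization_method, config.binarization_threshold
    )
    if config.min_component_um3 > 0:
        bone = remove_small_components(bone, config.min_component_um3)
    plate = extract_plate_region(bone, config.closing_radius)
    joint = split_epiphysis_metaphysis(bone, plate)

    dilation = (
        config.bridge_dilation_um
        if config.bridge_dilation_um is not None
        else vol.spacing
    )
    bs = detect_bridges(joint, bone, dilation)
    if config.merge_separation_um > 0:
        bs = merge_touching_bridges(bs, config.merge_separation_um)

    points = project_bridges(bs)
    fp2d, fp_spacing, fp_origin = plate_footprint(joint)
    dm = density_map(
        points,
        window=config.window_um,
        plate_footprint=fp2d,
        footprint_spacing=fp_spacing,
        footprint_origin=fp_origin,
    )
    d_mean = mean_areal_density(dm)

    if config.quadrant_center_uv is not None:
        center = config.quadrant_center_uv
    else:
        ii, jj = np.nonzero(fp2d)
        center = (
            float(ii.mean() * fp_spacing + fp_origin[0]),
            float(jj.mean() * fp_spacing + fp_origin[1]),
        )
    qc = quadrant_counts(points, center, config.medial_direction)

    row = {
        "specimen": spec.id,
        "group": spec.group,
        "n_bridges": bs.n_bridges,
        "fully_bridged": joint.fully_bridged,
        "mean_areal_density": d_mean,
        **qc.to_dict(),
    }

    morph = None
    if config.morphometry:
        from .io_volume import BinaryMask

        plate_only = BinaryMask(
            joint.plate_region & ~bone.data, vol.spacing, vol.origin
        )
        morph = compute_morphometry(plate_only)
        row.update(
            {
                "thickness_mean_um": morph.thickness_mean,
                "thickness_sd_um": morph.thickness_sd,
                "s_over_v_per_um": morph.s_over_v,
                "smi": morph.smi,
            }
        )

    # ------------------------------------------------------------------ disk
    sdir = outdir / spec.id
    sdir.mkdir(parents=True, exist_ok=True)
    bs.to_csv(sdir / "bridges.csv")
    bs.to_json(sdir / "bridges.json")
    dm.to_csv(sdir / "density_map.csv")
    pd.DataFrame([qc.to_dict()]).to_csv(
        sdir / "quadrants.csv", index=False, float_format=_CSV_FLOAT
    )
    if morph is not None:
        morph.to_json(sdir / "morphometry.json")
    if config.write_figures:
        render_density_figure(dm, points, sdir / "density_map.png")
    if config.write_volumes:
        from .io_volume import VoxelVolume

        write_volume(
            VoxelVolume(joint.labels, vol.spacing, vol.origin),
            sdir / "labels.tif",
        )
    provenance = {
        "specimen": spec.id,
        "parameters": {
            "binarization": bone.provenance,
            "closing_radius_um": config.closing_radius,
            "bridge_dilation_um": dilation,
            "merge_separation_um": config.merge_separation_um,
            "window_um": config.window_um,
            "quadrant_center_uv": list(center),
            "medial_direction": config.medial_direction,
            "seed": config.seed,
        },
        "fully_bridged": bool(joint.fully_bridged),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    (sdir / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=False))
    log.info("specimen %s: %d bridges in %.2fs", spec.id, bs.n_bridges,
             provenance["elapsed_s"])
    return row


def summarize_groups(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean ± SEM (SEM = sd/√n, sample sd) of scalar measures."""
    records = []
    for group, sub in rows.groupby("group", sort=True):
        rec = {"group": group, "n": len(sub)}
        for colname in _SCALARS:
            if colname not in sub:
                continue
            vals = sub[colname].astype(float)
            n = len(vals)
            rec[f"{colname}_mean"] = vals.mean()
            sd = vals.std(ddof=1) if n > 1 else 0.0
            rec[f"{colname}_sem"] = sd / np.sqrt(n) if n > 0 else np.nan
        records.append(rec)
    return pd.DataFrame(records)


def run_pipeline(config: PipelineConfig) -> CohortSummary:
    """Run the full protocol over a cohort; write artifacts under output_dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, errors = [], []
    for spec in config.specimens:
        try:
            rows.append(_process_specimen(spec, config, outdir))
        except Exception as exc:  # per-specimen isolation
            log.error("specimen %s failed: %s", spec.id, exc)
            errors.append({"specimen": spec.id, "group": spec.group,
                           "error": str(exc)})

    specimens = pd.DataFrame(rows)
    groups = summarize_groups(specimens) if len(specimens) else pd.DataFrame()
    specimens.to_csv(outdir / "specimens.csv", index=False, float_format=_CSV_FLOAT)
    groups.to_csv(outdir / "summary.csv", index=False, float_format=_CSV_FLOAT)
    if errors:
        pd.DataFrame(errors).to_csv(outdir / "errors.csv", index=False)
    return CohortSummary(specimens, groups, errors)


def render_density_figure(
    dm: DensityMap, points: list[ProjectedPoint], path
) -> None:
    """Heatmap of bridges per window with centroid overlay, colorbar in
    bridges/window. A JSON sidecar records the data behind the figure."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    w = dm.window
    extent = (
        dm.origin_uv[1],
        dm.origin_uv[1] + dm.counts.shape[1] * w,
        dm.origin_uv[0] + dm.counts.shape[0] * w,
        dm.origin_uv[0],
    )
    fig, ax = plt.subplots(figsize=(5, 4.2))
    shown = np.where(dm.footprint | (dm.counts > 0), dm.counts, np.nan)
    im = ax.imshow(shown, extent=extent, cmap="magma", interpolation="nearest")
    if points:
        ax.plot(
            [p.v for p in points],
            [p.u for p in points],
            "+",
            color="cyan",
            markersize=6,
            label=f"{len(points)} bridges",
        )
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("v (μm)")
    ax.set_ylabel("u (μm)")
    fig.colorbar(im, ax=ax, label=f"bridges per {w:g} μm window")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    sidecar = {
        "n_points": len(points),
        "total_count": dm.total,
        "window_um": w,
        "n_footprint_tiles": int(dm.footprint.sum()),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
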