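# physis

Quantification of growth-plate fusion in 3D micro-CT volumes of long-bone
epiphyses: detection and counting of individual **bony bridges** crossing the
epiphyseal growth plate, **areal-density maps** and anatomical **quadrant
counts** of their positions on the joint-surface projection, and
**morphometry** of the growth-plate cartilage layer (local thickness Tb.Th,
surface-to-volume ratio S/V, structure model index SMI).

The growth plate (physis) is the cartilage layer between the epiphysis and
metaphysis of a growing bone. As growth ends, mineralized columns — bony
bridges — form across the cartilage and eventually fuse the plate. Counting
and mapping these bridges in micro-CT is a sensitive readout of premature or
accelerated growth-plate closure, for example in mouse models of
osteoarthritis. This package gives that readout an observer-free, purely
topological definition and a reproducible pipeline around it, aimed at
skeletal-biology labs analysing laboratory or synchrotron micro-CT scans.

## Method

Given a reconstructed volume with isotropic spacing (axis 0 = longitudinal,
proximal at index 0):

1. **Binarize** mineralized tissue (Otsu or fixed threshold), optionally
   dropping components below a volume floor.
2. **Extract the plate**: morphological closing of the bone mask with a
   Euclidean ball (radius ≈ 2× plate thickness) creates a cavity where the
   cartilage layer separates the two bone bodies; the cavity component in
   face contact with both bodies is the plate region.
3. **Split bodies**: deleting the plate's longitudinal band from the bone
   mask yields the epiphysis (proximal) and metaphysis (distal); bone left
   inside the band is the set of bridge candidates.
4. **Detect bridges**: 26-connected components of in-band bone; a component
   is a bridge iff it is adjacent to *both* bodies (one-sided spurs are
   discarded). Each bridge is characterized by volume, centroid and minimum
   transverse cross-section; near-touching bridges can be merged by a
   single-linkage distance criterion.
5. **Project and map**: bridge centroids are projected along axis 0;
   counts are tiled into 256 μm × 256 μm windows over the projected plate
   footprint (areal density *d* = bridges per window) and split into
   anterior/posterior × medial/lateral quadrants.
6. **Morphometry** of the cartilage layer:
   Tb.Th by the largest-inscribed-sphere definition, S and S/V from a
   triangulated iso-surface of the signed Euclidean distance field, and
   SMI = 6·V·S′/S² with S′ the derivative of surface area under an outward
   surface dilation — an ideal plate, cylinder and sphere score 0, 3 and 4.

Because no public dataset accompanies the protocol, the package ships a
phantom generator (`physis.phantoms`) that renders two mineralized bodies
separated by a curved cartilage layer pierced by a known number of pegs,
with full ground truth — the basis of the entire test suite.

## Worked example

Synthesize a phantom joint with 8 planted bridges and run the stages from
the command line:

```sh
$ python -c "from physis import *; \
             vol, gt = make_plate_phantom(PhantomSpec(seed=11, n_bridges=8)); \
             write_volume(vol, 'joint.tif')"
$ physis bridges joint.tif -o bridges.csv --closing-radius 60
8 bridges -> bridges.csv
$ head -4 bridges.csv
id,centroid_z_um,centroid_u_um,centroid_v_um,volume_um3,min_cross_section_um2
1,140.395,181.053,241.842,14250,200
2,142.237,311.053,243.158,14250,25
3,142.5,223.75,141.25,15000,500
$ physis morph joint.tif -o morph.json --closing-radius 60
Tb.Th 29.3 ± 3.1 μm, S/V 0.07916 μm⁻¹, SMI 1.16 -> morph.json
```

All 8 planted bridges are recovered, with centroids in physical μm and
volumes of ≈ 15000 μm³ (a 12.5 μm-radius peg crossing a 30 μm layer, plus
band clipping). The 30 μm cartilage layer reads Tb.Th = 29.3 ± 3.1 μm, and
its SMI of 1.16 describes a predominantly plate-like layer with rim and
tunnel contributions pushing it above the ideal-plate value of 0.

Cohorts run from a YAML config (`physis run config.yaml`), producing
per-specimen bridge tables, density-map CSV/PNG, quadrant counts,
morphometry JSON, provenance YAML, and a per-group mean ± SEM summary.
`physis fixtures <dir>` writes the canonical synthetic test volumes.

## Layout

- `src/physis/io_volume.py` — TIFF/NIfTI/raw I/O, coordinate conventions
- `src/physis/segmentation.py` — binarization, plate extraction, body split
- `src/physis/bridging.py` — bridge detection, characterization, merging
- `src/physis/projection.py` — projection, density maps, quadrants
- `src/physis/morphometry.py` — Tb.Th, surface area, S/V, SMI
- `src/physis/phantoms.py` — synthetic joints and ideal shapes
- `src/physis/report.py`, `src/physis/cli.py` — pipeline, reports, CLI
- `docs/methods.md` — estimator details, parameter guidance, limitations
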