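# wormetrics

Length, volume and surface-area measurement of single nematodes
(e.g. *C. elegans*) from micrographs.

A worm photograph is binarized and rotated horizontal; the mask is
thinned to a one-pixel midline ("spine line"); the midline is traced
end to end with a moving perpendicular profile line, then extended to
the worm's true tips using the mask outline; the diameter is measured
normal to the midline at every traced point; and the body is integrated
as a chain of circular truncated cones:

    V = (1/3) π (r1² + r1·r2 + r2²) h
    S = π (r1 + r2) √((r1 − r2)² + h²)

Midline curvature k = dφ/ds and straightened silhouettes are also
available. The method assumes one worm per image, a circular cross
section, and fails deliberately (with a structured error) when the worm
overlaps or approaches itself within the profile line's reach.

A synthetic-worm generator (`wormetrics.synthetic`) renders parametric
curved tubes — straight, circular-arc, sine and hairpin centerlines —
with analytically known length, volume, surface area and curvature, and
is the ground-truth oracle for the test suite.

## CLI

Two-stage batch workflow. Raw photos live in `<dir>/photos/`; masks are
written to `<dir>/binary/`:

```sh
# stage 1: photos -> clean horizontal binary masks
wormetrics binarize worms/ --threshold otsu --close 1 --open 2

# stage 2: masks -> per-worm width tables + summary
wormetrics measure worms/binary --scale 0.005 --unit mm --straighten
```

`--scale` (physical units per pixel) is mandatory — images must be
spatially calibrated. `measure` writes, per worm, `output<name>.txt`
(tab-separated arc position and width) and a batch summary `output.txt`
with columns `File`, `Length`, `Volume`, `Surface area`. Worms that
cannot be measured (self-overlap, self-proximity, width failures) get a
status row instead of numbers; the run continues.

Generate ground-truthed phantoms:

```sh
wormetrics synth sine --n 18 --seed 1 --out-dir phantoms/
```

## Library

```python
from wormetrics import MeasureConfig, measure_mask, read_mask

mask = read_mask("binary/worm1.png", scale=0.005)     # mm per pixel
morph, widths, spine, oriented = measure_mask(mask, MeasureConfig(scale=0.005))
print(morph.length, morph.volume, morph.surface_area)
```

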