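# flowmorph

Quantitative morphometrics of endothelial responses to fluid shear stress
(FSS), for vascular-biology groups scoring flow experiments from
microscopy: monolayers under laminar flow, zebrafish trunk vessels, aortic
en-face preparations, permeability stains and 3-D sprouting assays.
Every readout ships with a ground-truthed synthetic scene generator, so
the whole measurement chain can be validated end to end without any
imaging data.

## What it measures

- **Nuclear/cell orientation and elongation.** Each nucleus mask is fitted
  with its moment-equivalent ellipse (semi-axes *a* ≥ *b*). The axial
  angle between the major axis and the flow direction is folded to
  [0°, 90°] and histogrammed in 10° bins; the *aligned fraction* is the
  percentage of cells within 0–30° of flow. Elongation is the first
  eccentricity *e* = √(*a*² − *b*²)/*a*.
- **Junctional linearization index (JLI).** Cell outline perimeter divided
  by the perimeter of its convex hull: 1 for cells with straight
  (linearized) junctions, above 1 for irregular junctions.
- **Golgi polarization.** The directed angle of the nucleus-centroid →
  Golgi-centroid vector, with 0° defined as against the flow; summarized
  by the circular mean, circular SD √(−2 ln R̄), and a rose histogram.
- **Dye extravasation.** RGB → HSV conversion; the blue fraction is the
  proportion of ROI pixels with hue in [120°, 240°].
- **Permeability / density.** Foreground area fraction per field, and
  labelled-object count per mm².
- **Vessel geometry.** Mean diameter from chords perpendicular to the tube
  axis (or 2× medial-axis distance for curved vessels), and per-slice
  cross-section counts of a 3-D stack binned by equivalent diameter
  2√(area/π).
- **Sprouting depth.** Foreground area vs depth below the gel surface and
  mean sprout length (centroid depth of invading cells).

The synthetic generator produces monolayers with a controlled axial
orientation law (von Mises on the doubled angle, or uniform), target
eccentricity, tunable junction irregularity and Golgi offsets; vessel
phantoms of known width; RGB tissue with a known blue fraction; and 3-D
stacks of cells at known depths — each with a per-object truth table.

## Worked example

Simulate a flow-aligned monolayer and measure orientation, junctions and
Golgi polarization in one run:

```sh
cat > demo.json <<'EOF'
{
  "out_dir": "demo_run",
  "metrics": ["orientation", "jli", "golgi"],
  "seed": 11,
  "simulate": {
    "kind": "monolayer",
    "n_cells": 60, "width": 768, "height": 768,
    "junction_irregularity": 2.0,
    "golgi_offset_law": {"kind": "von_mises", "mean_deg": 0, "kappa": 8}
  }
}
EOF
flowmorph run --config demo.json
```

which prints (abridged):

```
orientation/aligned_fraction = 100.0
orientation/mean_eccentricity = 0.7979060412219782
jli/n_cells = 36
jli/mean_jli = 1.0233223415658828
golgi/n_pairs = 60
golgi/circular_mean = 0.36597354972861623
golgi/circular_sd = 24.865074628212195
golgi/resultant_length = 0.9101296646676398
```

All 60 nuclei lie within 30° of the flow axis (the scene was generated
with a concentrated axial law, κ = 50), measured mean eccentricity 0.798
recovers the generated 0.8, the mildly roughened junctions score a JLI
just above 1 on the 36 interior cells, and the Golgi blobs sit upstream
(circular mean 0.4°, close to the generated von Mises mean of 0°, with a
circular SD matching its κ = 8 spread). The run directory contains
`per_object.csv`, `summary.csv`, a resolved `config_snapshot.json` and a
`run.log`; re-running the snapshot reproduces the CSVs byte for byte.

The same library is importable directly (`import flowmorph`), and the
other subcommands — `simulate`, `segment`, `measure`, `report` — expose
the individual stages.

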