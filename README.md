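# podpheno

Image-based soybean pod phenotyping and yield estimation.

Breeders and phenotyping platforms estimate soybean yield from two
ingredients: how many pods a plant carries, and what a single pod weighs.
`podpheno` implements the measurement side of that workflow as a tested
Python library with a command-line interface:

* **Pod phenotypes from images.** An isolated pod photographed next to a
  2 cm × 2 cm dark calibration marker is reduced to a closed contour
  (Gaussian smoothing → Canny edges → morphological close → contour
  extraction), and five traits are computed in physical units:
  - *length* — long axis of the minimum-area circumscribed rectangle,
  - *width* — maximum inscribed circle diameter `D = 2R`, with the circle
    centered at the shoelace centroid `(m, n)` of the contour,
  - *area* — template calibration `S_d = W_d · S_k / W_k` (pod pixel count
    scaled by the marker's physical area over its pixel count),
  - *chord* and *convex arc* — tip-to-tip distance and convex-hull
    perimeter minus chord; the chord/arc ratio indexes pod straightness.
* **Detection-model components.** Pure-function references for the box
  overlap measures and losses used by single-stage pod detectors —
  `IOU = J/U`, `GIOU = J/U − (A−U)/A`, and the extended-IOU loss
  `L_EIOU = 1 − IOU + ρ²(b,b^gt)/c² + (w−w^gt)²/c_w² + (h−h^gt)²/c_h²` —
  plus the coordinate-attention forward pass
  `y_c(i,j) = x_c(i,j) · g^h_c(i) · g^w_c(j)` built from directional
  average pooling.
* **Detection evaluation.** The TP/FP matching protocol (retain
  predictions with confidence > 0.3, match greedily in descending
  confidence at IOU > 0.5, first match wins), precision/recall, the PR
  sweep with AP/mAP, and per-growth-stage count tables with model
  differencing.
* **Single-pod weight and yield.** A 5-120-1 fully connected
  backpropagation network maps the five traits to single-pod weight;
  per-plant yield is weight × pod count, and totals carry a relative-error
  report against measured weights.
* **Synthetic ground truth.** Every stage is testable offline: pods are
  rendered as (optionally bent) stadium silhouettes with analytically
  known traits, detection scenes come with constructed TP/FP outcomes, and
  trait→weight tables follow a known linear map plus noise.

## Worked example

Render a synthetic pod (length 4.56 cm, width 1.02 cm — the mean mature
pod of the Heihe 49 variety) with its marker, then measure it back:

```sh
$ podpheno synth --out pod.png --seed 1
wrote pod.png and pod.truth.csv
$ podpheno measure pod.png
{"length_cm": 4.56, "width_cm": 1.02, "area_cm2": 4.43, "chord_cm": 4.56, "arc_cm": 5.74}
```

The five traits come back in cm/cm² via the marker calibration; for this
straight pod the chord equals the length and the measured area matches the
analytic stadium area (4.43 cm²) of the generating shape.

Roll a single-pod weight up to plant and total yield:

```sh
$ podpheno yield-plant --pod-weight 0.726 --pods 19 --scale 12.004 --measured-total 149.60
plant_weight_g: 13.794
total_weight_g: 165.583
relative_error: 0.107
```

A pod weighing 0.726 g on a plant bearing 19 pods gives 13.794 g per
plant; extrapolated over 12 plants and compared with the 149.60 g actually
weighed, the prediction is 10.7% off.

`podpheno demo --seed 1 --out demo/` runs the full synthetic pipeline
(generate → measure → evaluate a detection scene → train the weight
network) and writes a JSON + Markdown report.

## Layout

```
src/podpheno/
  synthetic.py      # pod/scene/table generators with analytic ground truth
  preprocessing.py  # smoothing, edges, closing, contour + marker scale
  phenotype.py      # the five traits
  boxes.py          # Box, IOU/GIOU/EIOU
  attention.py      # coordinate-attention forward pass
  evaluation.py     # matching, P/R, PR curve, AP/mAP, stage tables
  yield_model.py    # 5-120-1 BP network, error stats, yield roll-ups
  pipeline.py       # end-to-end demo with config + report
  cli.py, io.py     # command-line surface and file formats
```

See `docs/methods.md` for the measurement and model details, parameter
defaults, and known limitations.
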