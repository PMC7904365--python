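# oct-edema

Joint enhancement + level-set delineation of **macular edema** in retinal
OCT B-scans.

Macular edema — fluid accumulation in the macula, the principal
sight-threatening complication of retinal vein occlusion — appears on
optical coherence tomography as dark (hypo-reflective) cavities inside the
bright retinal band. Delineating those cavities automatically is hard
because OCT is a coherent modality: the images carry strong multiplicative
speckle and low contrast. This package implements a two-step joint model:

1. **Bioinspired enhancement** — speckle suppression by Gaussian filtering,
   edge restoration by a global structure-transfer filter, and contrast
   enhancement by single-scale Retinex (SSR); and
2. **SBGFRLS segmentation** — a selective binary and Gaussian filtering
   regularized level set driven by a signed pressure force, which finds the
   retinal band and, inside it, the edema cavities.

Because clinical scans are rarely shareable, the package ships a seeded
**phantom generator** that emulates a curved retinal band with elliptical
fluid cavities under the observation model `I = S·N_s + N_b` (unit-mean
gamma speckle `N_s`, additive Gaussian background noise `N_b`), so the
whole pipeline is testable end-to-end against known ground truth.

## The model

With `I` the (enhanced) image and φ the level-set field, the contour
evolves under

    ∂φ/∂t = SPF(I) · α · |∇φ|,
    SPF(I) = (I − (c1+c2)/2) / max|I − (c1+c2)/2|  ∈ [−1, 1],

where `c1`, `c2` are the mean intensities inside (φ > 0) and outside the
contour and α is the balloon force. After each update φ is re-binarized to
{+1, −1} and smoothed with a Gaussian — regularization by filtering instead
of re-initialization. The SPF's sign makes the contour shrink outside the
bright object and expand inside it, so the final partition does not depend
on where the initial contour starts.

Enhancement quality is scored by contrast-to-noise ratio and equivalent
number of looks over homogeneous ROIs,

    CNR = (1/R) Σ_r (μ_r − μ_b)/√(σ_r² + σ_b²),    ENL = (1/R) Σ_r μ_r²/σ_r²,

and segmentation quality by the pixelwise confusion suite: accuracy,
precision, sensitivity, specificity, Dice, IoU and Cohen's κ (Dice > 0.70
is conventionally "excellent agreement").

## Worked example

Simulate a speckled B-scan phantom and run the full pipeline:

```bash
cat > edema.yaml <<'YAML'
version: 1
seed: 0
phantom:
  speckle_shape: 4.0
  background_noise_sd: 0.02
YAML
oct-edema run --config edema.yaml --out-dir run_out
```

which writes the input, enhanced image, masks, a `manifest.json` (config
echo, seed, per-stage checksums — reruns are bit-reproducible) and prints

```json
{
  "cnr": 17.925238547613198,
  "enl": 1819.852767361212,
  "retina": { "dice": 0.9818397295130538, "sensitivity": 1.0, ... },
  "edema":  { "dice": 0.9749131609417213, "iou": 0.9510542168674698,
              "accuracy": 0.998016357421875, "kappa": 0.9738811093092351, ... }
}
```

CNR/ENL are computed on the enhanced image over the ground-truth retina ROI
(the speckled original scores CNR ≈ 2.5, ENL ≈ 7.5, so enhancement raises
contrast ~7-fold and smoothness ~240-fold); the retina and edema blocks
score the segmented masks against the phantom's ground truth — both far
above the 0.70 "excellent agreement" threshold. Individual stages are also
available as subcommands:

```bash
oct-edema simulate --seed 0 --out-dir sim/
oct-edema enhance sim/image.png --out enhanced.png [--save-intermediates dir/]
oct-edema segment enhanced.png --out-retina r.png --out-edema e.png \
    --overlay overlay.png --history history.csv
oct-edema evaluate --pred e.png --truth sim/edema_mask.png
```

`history.csv` traces the evolution (`iteration,c1,c2,changed_fraction`);
on default phantoms the contour converges in ~20–25 iterations against a
cap of 500.

The same functionality is available as a library:

```python
from oct_edema import default_spec, generate_phantom, enhance, segment

pair = generate_phantom(default_spec(seed=0))
result = segment(enhance(pair.image))
```

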