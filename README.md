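# kneealign

Fully automatic measurement of **anatomical varus/valgus knee alignment**
from standard anteroposterior (AP) knee radiographs, for researchers and
engineers building or validating landmark-based orthopaedic measurement
systems (e.g. around total knee arthroplasty planning and follow-up).

## The measurement

On an AP knee radiograph the **anatomical femorotibial angle (aFTA)** is the
signed angle between the femoral and tibial anatomical (shaft) axes:

```
aFTA = lateral_sign x (theta_tibia - theta_femur)
```

where each `theta` is the orientation of the proximal-to-distal axis vector
measured from the image-down direction, and the lateral side is detected
automatically from the fibula landmarks (the fibula is lateral), making the
signed angle invariant to horizontal flips.  Valgus ("knock-knee") is
positive, varus ("bow-leg") negative.  Healthy alignment is about +5 to +7
degrees of valgus; above +7 indicates a valgus deformity, below 0 a varus
deformity, and the acceptable post-operative band is 2.4-7.2 degrees of
valgus.

Landmarks follow four fixed schemas — 110/134 points pre-operatively and
157/181 points post-operatively (the "extended" variants add 24 shaft
points) — and eight named measurement recipes resolve axis endpoints as
single landmarks or midpoints of symmetric landmark pairs (e.g. the
pre-operative femoral shaft axis connects the midpoints of points 44,0 and
42,2; notch/spine variants anchor an axis at the intercondylar notch,
tibial spine groove or tibial plateau centre).

The package provides:

- `kneealign.landmarks` — schemas, plain-text pts file I/O, left-knee
  orientation normalisation, validation;
- `kneealign.measurement` — the eight aFTA recipes, signed-angle geometry
  and clinical classification;
- `kneealign.agreement` — the statistics used to validate such systems:
  ICC(2,1) with F-based confidence intervals and interpretation bands,
  mean absolute difference (MAD), Bland-Altman bias and 95% limits of
  agreement;
- `kneealign.synthetic` — procedural knee templates with known true aFTA,
  degradation models (annotation jitter, image rotation, shaft truncation)
  and a pseudo-radiograph renderer;
- `kneealign.detector` — a compact scikit-learn-style random-forest
  regression-voting constrained-local-model landmark detector
  (`RegressionVotingDetector`, fit/predict);
- `kneealign.cli` / `kneealign.pipeline` — batch orchestration:
  `simulate`, `measure`, `agree`, `train-detect`, `detect`, `demo`.

## Worked example

Simulate a small annotated dataset, measure it, and compare the dataset
against itself after re-measuring (here: automatic vs manual stand-ins):

```bash
kneealign simulate --out ds --schema pre_extended --n 8 --seed 3 --noise-sd 0.3
kneealign measure  --manifest ds/manifest.csv --out auto.csv
kneealign demo --skip-detector --seed 1 --n-test 30
```

The demo prints (output reproduced verbatim):

```
== end-to-end demo: PreX-fem-notch-tib-shafts on pre_extended (n=30) ==
ICC (95% CI)            0.99 (0.99-1.00) [excellent]
MAD (SD)                0.3° (±0.2°)
BA bias (SD)            0.0° (±0.4°)
BA limits of agreement  ±0.8°
median point error: 0.63 px
```

Reading: on 30 synthetic knees the "automatic" measurements (here truth
points re-jittered by 0.5 px; drop `--skip-detector` to train and run the
landmark detector instead) agree with the ground-truth-point measurements
with an intraclass correlation of 0.99 (excellent band), a mean absolute
difference of 0.3 degrees, no systematic bias, and 95% of differences
within ±0.8 degrees.  A measurement CSV row looks like:

```
image_id,schema_id,definition_name,aFTA_deg,...,classification,in_acceptable_range,...
synth_0000,pre_extended,PreX-fem-tib-shafts,12.5368,...,valgus_deformity,False,...
```

i.e. a 12.5-degree valgus knee, classified as a valgus deformity, outside
the 2.4-7.2 degree acceptable post-operative band.

In Python the same pieces compose directly:

```python
from kneealign import make_template, inject_alignment, measure_set

knee = inject_alignment(make_template("pre_extended"), 6.0)
for r in measure_set(knee):
    print(r.definition_name, round(r.aFTA_deg, 3), r.classification)
# PreX-fem-tib-shafts 6.0 usual
# PreX-fem-notch-tib-shafts 6.0 usual
```

## Limitations

The synthetic templates are procedural stand-ins, not anatomical atlases;
passing tests demonstrate the correctness of the geometry, statistics and
search machinery, not clinical-grade detection accuracy on real
radiographs.  See `docs/methods.md` for the model, parameter and design
details.
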