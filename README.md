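# stiflemetrics

Static 3D biomechanical profiling of the kangaroo stifle (the marsupial
knee), for biomechanists and comparative anatomists interested in what a
patella-free extensor mechanism implies for joint function — e.g. as a
biomimetic reference point for managing end-stage patellofemoral pain in
humans.

Kangaroos lack an ossified patella; a fibrocartilage pad sits in the
quadriceps tendon instead, and the tibial tuberosity (TT) projects far
anteriorly. This package turns the manual CAD measurement protocol used to
profile *Macropus giganteus* stifles into an automated, tested pipeline
over three kinds of input: a named anatomical landmark set (JSON, mm),
triangle surface meshes of the bones and extensor mechanism (STL), and a
labelled muscle voxel mask (NIfTI). It computes, per limb:

- **Segment lengths** — femoral length FL (greater trochanter to
  intercondylar notch, on the sagittal plane) and tibial length TL
  (tibial plateau to lateral malleolus, on the coronal plane), in mm.
- **Flexion angle** — the included femur–tibia midshaft angle at the knee
  in the sagittal plane, by the law of cosines (full extension = 180°).
- **Extensor moment arm** — the perpendicular (common-perpendicular)
  distance between the transepicondylar axis (medial to lateral
  collateral-ligament sulcus) and the extensor-mechanism line of action
  (principal in-plane direction of a least-squares plane fitted to the
  extensor path points). A torque-effective arm |((p−a)×f̂)·â| is
  reported as a secondary diagnostic.
- **TP:TT plane metrics** — three parallel anterior-normal planes on the
  tibial model: through the most anterior TT point (P1), the anterior
  cortex (P2) and the posteriormost plateau point (P3); D1 = d(P1,P2),
  D2 = d(P2,P3), TP:TT ratio = D2/D1, TT projection index = 100·D1/TL.
- **Quadriceps cross-sectional area** — mean voxel-counted area of RF,
  VL, VI and VM over ~10 coronal slices at the femoral midlength, summed
  to QCA (cm²); QCA·FL/1000 approximates quadriceps volume (cm²·m).
- **Pennation angles** — acute law-of-cosines angle between the
  aponeurosis axis and a fascicle line for VL and RF.

Per-limb profiles aggregate into a median/range summary table (the
representative statistics for a four-limb, two-specimen sample). Because
no imaging data were deposited with the original study, a parametric
**synthetic limb generator** (`stiflemetrics.synthetic`) provides the
validation substrate: primitive-based femur/tibia/extensor geometry,
ellipsoidal muscle bellies and landmark sets for which every one of the
ten metrics is analytically known, so the pipeline's accuracy is testable
by parameter recovery.

## Worked example

Simulate a limb whose ground truth is the published median profile, then
measure it end to end:

```python
from stiflemetrics import measure_limb
from stiflemetrics.synthetic import SyntheticLimbSpec, generate_limb

limb = generate_limb(SyntheticLimbSpec())   # FL 200.7, TL 400.4, MA 28.9, ...
metrics, details = measure_limb(limb.landmarks, limb.tibia, limb.mask)
print(metrics.fl, metrics.tl, metrics.moment_arm, metrics.tp_tt_ratio)
```

prints

```
200.7 400.4 28.900000000000034 1.8
```

i.e. the femoral length (mm), tibial length (mm), extensor moment arm
(mm) and TP:TT ratio are recovered at floating-point accuracy; of the ten
metrics only the voxel-counted QCA deviates from truth (by ~0.1%). The
same workflow is available from the shell:

```sh
stifle simulate --seed 1 --out limb1
stifle measure --landmarks limb1/landmarks.json --tibia limb1/tibia.stl \
       --mask limb1/muscles.nii.gz --out limb1/metrics.json --log limb1/audit.jsonl
stifle profile --metrics limb1/metrics.json --out report
```

The numbered scripts under `analysis/` run the study-level analyses:
`01_summarize_study_table.py` aggregates the four published per-limb rows
into the median/range table (the median row — TL 400.4 mm, FL 200.7 mm,
flexion 74.1°, QCA 83.9 cm², QCA·FL 16.7 cm²·m, moment arm 28.9 mm, TT
index 17.9, TP:TT 1.8, pennation VL/RF 27.4°/28.6° — emerges verbatim);
`02_measure_synthetic_cohort.py` builds and measures a four-limb
synthetic cohort; `03_recovery_sensitivity.py` tabulates noiseless
recovery over 50 random limbs (worst error 0.11%, in QCA) and moment-arm
sensitivity to 1 mm landmark noise (bias −0.03 mm, SD 0.76 mm). Tables
land under `results/`.

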