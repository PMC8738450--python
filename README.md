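# osteoreduce

Headless assessment core for training the surgical **reduction of
supracondylar humerus fractures**, as practiced in minimally invasive plate
osteosynthesis (MIPO). MIPO fixes a fracture through a small incision under
imaging guidance; its most common residual complication is **malrotation** of
the distal fragment. Training simulators therefore need an objective,
quantitative way to grade how close a trainee's fragment arrangement is to
the patient's own anatomy. This package implements that grading pipeline —
everything downstream of the rendering and hand-tracking of a VR simulator —
for simulator developers, surgical-education researchers, and anyone who
needs a reproducible reduction-quality metric on triangle meshes.

## What it computes

The anatomical target of a reduction is the patient's **mirrored
contralateral humerus** (the healthy opposite side reflected across the
sagittal plane). The pipeline:

1. detects humeral landmarks on both bones: head center, bicipital groove,
   trochlea and capitulum centers, medial/lateral epicondyles, the humeral
   shaft axis (HSA), epicondylar axis (ECA), flexion–extension axis (FEA),
   and the two Müller reference cubes anchored to the epiphyses;
2. registers the template to the reduced bone by least-squares rigid
   superposition anchored on the shaft side (the surgeon's fixed reference);
3. computes a 15-component metric vector: six landmark distances, four axis
   angles, two length differences, the Jaccard overlaps of the Müller cubes,
   and the area discrepancy of the distal rotation triangle;
4. aggregates it into the reduction-accuracy coefficient

   ρ = Σᵢ wᵢ sᵢ / Σᵢ wᵢ,  sᵢ = clamp(1 − devᵢ/τᵢ, 0, 1)

   (overlap metrics enter as their own value), with ρ = 0 meaning no
   reduction and ρ = 1 a perfect one;
5. grades the session with the gamified score

   score = (k₁ ρ − k₂ t − k₃ n_c) · h

   where *t* is the elapsed time in seconds, *n_c* the number of on-demand
   accuracy checks (each modelling an intraoperative X-ray), and *h* a
   penalty multiplier applied if the healthy-template overlay was used.
   Defaults: k₁ = 1000, k₂ = 0.1, k₃ = 10, h = 0.7.

Because real CT-derived bones cannot be redistributed, the package includes
a deterministic **synthetic humerus generator** (shaft, offset spherical
head, bicipital groove, condyles, epicondyles) with exact analytic
ground-truth landmarks, plus a virtual fracture module that plane-cuts the
bone and rigidly displaces the distal fragment. Every stage is testable
end-to-end against ground truth without any patient data.

## Worked example

Run the whole chain on synthetic data — generate a mirror pair, fracture and
displace the right humerus, replay a perfect-reduction session (one
corrective move, one accuracy check, 20 s), and grade it:

```sh
$ osteoreduce run --seed 1 --out report.json
Reduction session report
========================

Final score:          987.93
Reduction accuracy:   rho = 0.9999
Time elapsed:         20.0 s
Reduction checks:     1
Template used:        no

Metric                            Unit           Value   Score
--------------------------------------------------------------
Capitulum                         mm             0.000   1.000
Trochlea                          mm             0.000   1.000
...
Distal Mueller cube overlapping   fraction       1.000   1.000
Proximal Mueller cube overlapping fraction       1.000   1.000
Area of the rotation triangle     mm^2           0.001   0.999
```

The score is (1000·0.9999 − 0.1·20 − 10·1)·1 ≈ 987.93: a perfect reduction
earns k₁ ≈ 1000, minus 2 points for the 20 seconds and 10 points for the
single X-ray check. Every metric row is the deviation between the reduced
bone and the mirrored template; with an exact mirror pair and an exact
reduction they are all ~0 (overlaps ~1).

The individual stages are also available as subcommands (`generate`,
`fracture`, `replay`, `detect`, `compare`, `score`) exchanging STL/PLY/OBJ
meshes, JSON landmark/metric files and JSON-Lines session logs, and as
library functions (`osteoreduce.generate_pair`, `detect_landmarks`,
`compute_metric_vector`, `compute_rho`, `compute_score`, ...).

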