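# blastograde

Automated quality grading of bovine blastocyst micrographs.

In commercial *in vitro* embryo production, day-7 blastocysts are graded by
eye under an inverted microscope using the International Embryo Technology
Society (IETS) scale — 1 (excellent/good), 2 (fair), 3 (poor) — before
transfer.  Visual grading is subjective: experienced embryologists disagree
with each other and with themselves on the same image.  `blastograde`
implements a fully automated alternative: mathematical variables extracted
from a single micrograph feed a small feed-forward neural network whose
architecture is chosen by a genetic algorithm, and the grade is the
consensus of the best three networks.

## Pipeline

1. **Standardize** — greyscale (BT.601 luma), isotropic resize + centre-pad
   to 1024 × 1280, linear stretch of the 1st..99th intensity percentiles
   onto [0, 255].
2. **Segment** — edge-based detection of the embryo circle (centre
   `(r, c)`, radius `R`), then three masks: ER (disk of radius `R + 5` px),
   RR (disk of radius `R − 40` px) and TE (the 45 px annulus between them,
   covering zona pellucida + trophectoderm).
3. **Texture & morphology** — grey-level co-occurrence matrices
   (8 intensity levels, `d = 1`, four angles, symmetric) per region with
   contrast / correlation / energy / homogeneity; intensity statistics
   (mean, mode, "mean count", "bright"); four concentric TE sub-ring
   descriptors `C1..C4`; a watershed transform of the intensity surface
   inside ER whose largest drainage basin is the inner cell mass (ICM),
   yielding the basin count WSN and ICM solidity / eccentricity / mean.
   Together: a canonical 36-variable vector.
4. **Collinearity pruning** — iterative elimination by variance inflation
   factor, `VIF_i = 1 / (1 − R_i²)`, removing the worst variable per
   iteration until all `VIF ≤ 10`; 24 named variables form the model
   schema.
5. **Learn** — feed-forward networks (1–3 hidden layers, 10–120 neurons,
   7 transfer functions, 5 classic batch trainers, mse loss on one-hot
   grades, 70/15/15 split with early stopping) searched by a genetic
   algorithm over 9-gene architecture genomes (10% elitism, 60% offspring
   with 5% per-gene mutation, 30% fresh random).
6. **Evaluate / classify** — confusion matrix with per-class and total
   success and the serious-error rate (off by two grades), one-vs-rest ROC
   with AUC, Fleiss'/Cohen's kappa; the `classify` command grades an image
   through the best three networks and reports their majority.

A seeded synthetic micrograph generator (`blastograde synth`) plants a
circular embryo with zona ring, textured trophectoderm, blastocoel and a
grade-dependent dark ICM, with full ground truth — so the entire pipeline
is testable without proprietary image data.

## Worked example

```bash
# 300 synthetic embryos (100 per grade) with ground truth
blastograde synth --n-per-grade 100 --seed 0 --out run/images

# feature table and collinearity report
blastograde extract run/images --manifest run/images/manifest.csv --out run/features.csv
blastograde vif run/features.csv --out run/vif.json

# desk-scale architecture search (population 20, 30 generations)
blastograde evolve run/features.csv --population 20 --generations 30 \
    --seed 7 --fitness-max-epochs 60 --out run/ga

# grade one image with the best three networks
blastograde classify run/images/embryo_0000_g1.png \
    --model run/ga/model_1.json --model run/ga/model_2.json --model run/ga/model_3.json
```

The `evolve` step prints, for the run above:

```
Genetic architecture search
===============================================
population 20, 30 generations, fitness on test partition
best fitness: 0.9778
  #1: acc=0.9778 layers=(115,) tf=('satlin',)/purelin train=traincgf
  #2: acc=0.9778 layers=(114,) tf=('satlin',)/purelin train=traincgf
  #3: acc=0.9778 layers=(75,) tf=('hardlim',)/purelin train=traingdm
```

i.e. the search converged on single-hidden-layer networks that grade
97.8% of the held-out synthetic test images correctly (chance is 33%; the
synthetic grades are deliberately overlapping but separable).  `classify`
then prints each network's three output scores (the grade "histogram"),
its grade, and the ensemble consensus.

The same stages are scriptable from Python via `ANNClassifier` /
`TrainedModel` (statsmodels-style model/results objects), `gasearch.evolve`
and `pipeline.run_pipeline`; see the module docstrings.

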