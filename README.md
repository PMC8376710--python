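# connectocam

Classification of parameter-weighted structural connectomes with a
customized 1×1-filter convolutional network, and Grad-CAM attribution of the
neural connections that drive the classification.

## The problem

Diffusion MRI tractography summarizes a brain's white-matter wiring as a
symmetric *structural connectome matrix*: an 84×84 table of streamline
counts (NOS) between the regions of the Desikan-Killiany parcellation plus
bilateral subcortical and cerebellar nodes.  Weighting each edge by a
tract-averaged microstructural parameter — DTI (FA, MD, AD, RD), DKI (MK,
AK, RK), NODDI (ICVF, ISOVF, ODI) or myelin/g-ratio metrics (MVF, AVF, g) —
yields matrices that carry tissue-property information beyond fiber counts,
with

    AVF = (1 − MVF)(1 − ISOVF)·ICVF,        g = √(AVF / (MVF + AVF)).

This package implements, end to end, a pipeline for asking two questions of
such data: *can a patient group (e.g., Parkinson's disease) be discriminated
from controls from these matrices*, and *which connections does the trained
classifier rely on*?  Because clinical connectome cohorts are rarely
shareable, the package ships a synthetic-cohort generator with planted,
known group effects, so every stage is testable against ground truth.

## The method

1. **Preprocessing** — each matrix's 3486 independent edges
   ((84·84−84)/2) are extracted, padded with 114 zeros to 3600 values,
   reshaped to a 60×60 grid, and divided by the grid maximum.  The transform
   is exactly invertible, which is what lets attribution maps return to the
   connection space.
2. **Classifier** — a CNN customized for data without spatial structure:
   four convolutional layers (8, 16, 16, 32 channels) all with filter size
   1, no pooling, then fully connected layers (4096, 4096, 2; a reduced
   256-unit preset is provided for fast runs).  Softmax cross-entropy,
   AdaGrad, minibatch 15, 20 epochs, 6-fold Gaussian-noise augmentation
   (sd 0.002–0.010).
3. **Evaluation** — stratified 5-fold cross-validation with 10 trials per
   fold (best trial kept), scores pooled so each subject is scored once;
   Mann-Whitney AUC with DeLong confidence intervals, paired DeLong tests
   between matrix types (Bonferroni 0.05/10), sensitivity/specificity/
   accuracy at a 0.5 cutoff.
4. **Attribution** — Grad-CAM at the 4th convolutional layer for each
   correctly classified patient; because filters are size 1 and pooling is
   absent the heat map is natively 60×60 (pin-point, no blur).  Maps are
   max-normalized per patient, reorganized to 84×84, pooled, and ranked into
   a top-k connection table, optionally split by dominant symptom side.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Microstructure identities and the 14-matrix suite
(`examples/01_microstructure_weighting.py`):

```
AVF(MVF=0.2, ISOVF=0.1, ICVF=0.5) = 0.36
g-ratio(MVF=0.51, AVF=0.49)      = 0.70

matrix suite for one subject: 14 matrices
  NOS, FA, MD, AD, RD, MK, AK, RK, ICVF, ISOVF, ODI, AVF, MVF, GRATIO
```

Cross-validated classification of a small synthetic cohort with a planted
3× effect on basal-ganglia↔cerebellum edges
(`examples/03_classify_cohort.py`):

```
per-fold validation AUC: 0.920 1.000 1.000
pooled AUC: 0.800 (95% CI 0.626-0.974)
sensitivity 33% (5/15), specificity 80% (12/15), accuracy 57%
```

The pooled AUC is the probability that a randomly chosen patient outranks a
randomly chosen control; with 15 subjects per group the interval is wide,
and the low sensitivity shows that under-trained scores cluster near 0.5
even when they rank well.  `examples/04_gradcam_connections.py` runs a
similar cohort through cross-validation and Grad-CAM and prints the
top-ranked connections with the planted circuit marked.

A full pipeline run (simulate → weight → cross-validate → compare →
Grad-CAM) is a single command over a YAML config:

```bash
connectocam run --config myrun.yaml --seed 7 --outdir out/
```

or from Python via `connectocam.run_pipeline`.  Subcommands `simulate`,
`weight`, `train`, `evaluate` and `gradcam` expose the stages separately.

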