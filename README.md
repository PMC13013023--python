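# branchflow

Morphometric analysis of branching in neuronal and glial arbors, built
around functionally interpretable scale factors rather than generic shape
descriptors. The package is for neuroinformatics researchers who work
with SWC reconstructions (e.g. NeuroMorpho.Org-style tracings of
dendrites, astrocytes, microglia) and want to (a) quantify asymmetric
radius scaling at branching junctions, (b) relate it to signal power loss
under passive cable attenuation, and (c) benchmark how well those
quantities separate cell types.

## The model

An arbor is a hierarchy of branches. At a bifurcation with parent radius
`r_p` and daughter radii `r_1, r_2`, the radius scale factors are
`β_i = r_i / r_p`, summarized by

    β̄ = (β_1 + β_2) / 2,   Δβ = (β_1 − β_2) / 2,

with daughter 1 the longer daughter (so the length half-difference
Δγ ≥ 0 and Δβ keeps its sign: positive when the longer daughter is also
the wider one). Junction position is measured by the leaf number `L_n`
(number of tips distal to a branch; tips carry 1) and its normalized form

    L_n,rel = log2(L_n,max / L_n),

which is 0 at the soma end and grows toward the tips. Junctions where
either β ≥ 0.999 are removed before analysis: they are artifacts of the
imaging resolution floor (all radii pinned at the pixel size).

Treating each segment as an ohmic wire (`R_k = l_k / r_k²` with constants
absorbed), the power dissipated by unit current through an N-level
cascade with per-level factors `(β̄_j, |Δβ_j|, γ̄_j, |Δγ_j|)` is

    P = R_N,TOT · Σ_{k=0..N} Π_{j=k..N−1} [ (β̄_j+|Δβ_j|)²/(γ̄_j+|Δγ_j|)
                                          + (β̄_j−|Δβ_j|)²/(γ̄_j−|Δγ_j|) ],

each bracket term being a daughter's conductance ratio β² / γ relative to
its parent (empty product = 1).

Classification uses the raw per-junction features — either the 2D space
`(β̄, Δβ)` or the 3D space adding `L_n,rel` — with seven standard methods
(LR, radial-kernel SVM, KNN, RF, DT, Gaussian naive Bayes, small MLP),
cell-wise train/test splits (never splitting a cell's junctions across
sets), and ROC AUC with DeLong 95% confidence intervals plus per-cell
majority-vote accuracy.

A bundled synthetic generator produces complete binary arbors with
prescribed level-dependent scale-factor profiles, ratio noise and a
pixel-quantization operator, so the whole pipeline is testable offline.

## Worked example

```python
from branchflow import (ArborSpec, CohortSpec, run_comparison, report_table)
from branchflow.synthetic_data import level_localized_specs
from branchflow.pipeline import cohort_feature_tables

# two classes sharing identical pooled (β̄, Δβ) marginals, differing only
# in how β̄ varies with junction level
spec_a, spec_b = level_localized_specs(depth=6)
cohort = CohortSpec({"levelA": spec_a, "levelB": spec_b},
                    n_cells_per_class=12, seed=7)
tables = cohort_feature_tables(cohort)
report = run_comparison(tables, seed=7, methods=("RF", "LR"))
print(report_table(report))
```

prints

      method feature_mode       auc  auc_ci_low  auc_ci_high image_accuracy knn_k
    0     RF           2d  0.475323    0.416968     0.533677            2/6  None
    1     LR           2d  0.502338    0.443918     0.560757            3/6  None
    2     RF           3d  0.762717    0.715323     0.810110            6/6  None
    3     LR           3d  0.518295    0.459256     0.577333            3/6  None

Read: in the 2D feature space both classifiers sit at chance (AUC ≈ 0.5,
CIs covering 0.5) because the pooled scale-factor distributions are
identical by construction. Adding the junction-position feature lifts the
random forest to AUC 0.76 and perfect per-cell accuracy (6/6 test cells),
while logistic regression cannot exploit the nonlinear level structure —
the signature of a class difference that is localized to particular cell
regions rather than global.

The numbered scripts under `analysis/` (simulate cohorts → extract
features → power-loss schedules → full 7-classifier benchmark) run the
complete study on synthetic cohorts and write their tables under
`results/`.

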