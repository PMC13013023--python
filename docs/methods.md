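# Methods

## From samples to branches

SWC reconstructions are parsed as ordered 7-column sample tables
(id, type, x, y, z, radius, parent; micrometres; ids as stored, no
renumbering). Files with non-positive radii, duplicate ids, dangling
parents or cycles are rejected outright — silent repair of radii would
bias every downstream daughter/parent ratio, and the resolution filter
already handles the one systematic radius artifact we model. Multiple
roots are allowed; each starts its own tree.

Branches are maximal unbranched sample chains. Branch points are detected
topologically (a sample with ≥ 2 children) rather than from gaps in the
id numbering; the two rules coincide on contiguously numbered files, but
the topological rule is invariant under renumbering. Soma samples
(type 1) belong to no branch; each neurite's first branch starts at the
first non-soma sample hanging off the soma or a root. Per branch we
record the arithmetic mean of its sample radii (`r_k`) and its path
length (`l_k`), summing consecutive inter-sample distances *including*
the connecting segment from the parent's last sample, so that branch
lengths partition the cable length of the arbor.

## Leaf numbers

A branch's leaf number `L_n` counts the tips distal to it; we use the
convention that a tip counts itself once (`L_n = 1` at tips), so a parent
of two terminal daughters has `L_n = 2`, every interior branch is the sum
over its children, and the root of a tree carries that tree's tip count.
An alternative convention sets tips to 0; it is inconsistent with
tip-parents carrying 2 (each tip must contribute 1) and would make
`L_n,rel = log2(L_max / L_n)` infinite at tips, so we do not use it.
`L_n,rel` is 0 at the branch attaining the per-cell maximum and grows
toward the tips, giving a cell-size-independent position coordinate.

## Junction features and the resolution filter

Each branch with exactly two children yields one junction with
`β_i = r_daughter / r_parent` and `γ_i = l_daughter / l_parent`.
Daughter 1 is the longer daughter (exact length ties fall back to the
wider daughter), which fixes `Δγ ≥ 0` and makes `Δβ` a signed quantity;
classifiers consume the signed value by default (an `abs_diff` switch
folds it). Trifurcations are excluded from features and counted — the
mean/half-difference parametrization is binary — and junctions keep their
parent branch's `L_n` and `L_n,rel`. Junctions where either `β ≥ 0.999`
are removed: when radii hit the imaging pixel floor, consecutive radii
become equal and ratios collapse to 1 regardless of true caliber. The
filter is idempotent and its removal counts are logged. `γ` features are
computed and exported but never used for classification; branch-length
estimates in tracing data are too unreliable under this level labeling
for length scaling to be meaningful, so the analysis rests on radius
scaling.

## Power-loss recursion

With each segment an ohmic cylinder (`R = l / r²`, resistivity and π
absorbed into the unit), an N-level cascade with per-level factors
`(β̄_j, |Δβ_j|, γ̄_j, |Δγ_j|)` dissipates

    P = R_N,TOT Σ_{k=0..N} Π_{j=k..N−1} B_j,
    B_j = (β̄_j+|Δβ_j|)²/(γ̄_j+|Δγ_j|) + (β̄_j−|Δβ_j|)²/(γ̄_j−|Δγ_j|),

empty product = 1, `R_N,TOT` the lumped terminal resistance. Each bracket
term is one daughter's conductance ratio `β²/γ` relative to its parent;
pairing the smaller radius ratio with the smaller length ratio is the
reading consistent with the daughter-wise definition of the factors. A
`second_denominator="plus"` switch evaluates the variant that reuses
`γ̄+|Δγ|` in both terms; the two coincide whenever `|Δγ| = 0`. Uniform
schedules reduce to a geometric series `R·(f^{N+1}−1)/(f−1)` (or
`R·(N+1)` at bracket value 1, the area-preserving cascade `β̄ = √½`),
which the tests use as a loop-free oracle at relative error ≤ 1e−12. The
module evaluates the recursion as a function of a schedule; it does not
assert equivalence with a series-parallel reduction of any explicit tree.

## Synthetic arbors

The generator emits complete binary trees of `depth` generations: on a
complete tree, a junction at generation g has parent leaf number
`2^(depth−g)` and relative leaf number exactly g, so level-dependent
profiles have closed-form expected features. Defaults: root radius 1 µm,
root length 100 µm, `β̄ = 0.7`, `Δβ = 0.1`, `γ̄ = 0.8`, `Δγ = 0.1`,
5 samples per branch, no noise — a caricature of a mid-sized dendritic
arbor in which radii decay ~0.7 per generation. Ratio noise is truncated
Gaussian, clipped to keep every ratio inside (0.01, 0.999²) so that the
generator itself never produces ratios at the filter threshold; only the
pixel-quantization operator (`r → max(p, p·round(r/p))`) creates the
spurious `β = 1` junctions the filter exists for. Branch samples are
evenly spaced and constant-radius (the per-branch mean radius is exact);
optional perpendicular jitter perturbs interior samples. Cohorts derive
per-cell seeds from the cohort seed via counter-based SeedSequence
spawning, so generation order cannot affect reproducibility.

For level-localized class comparisons, both classes share one
level-dependent `β̄` profile (default: slope 0.05 per level around 0.65,
centered on the junction-count-weighted mean level, `Δβ = 0.08`, noise
SD 0.03); class A evaluates it at each junction's true level while
class B draws the level from the junction-count distribution
(`2^g` junctions at level g). The pooled 2D feature marginals of the two
classes are then identical in distribution by construction, while the
level-conditional means differ — the regime in which only the 3D feature
space separates the classes.

What the generator does *not* emulate: random topology and incomplete
trees, spatial embedding constraints (self-avoidance, tortuosity),
correlated noise along a cell, tracing errors other than the radius
quantization floor, and per-cell variability in depth or size. Passing
tests therefore certify the pipeline's arithmetic and the qualitative
2D-vs-3D mechanism under controlled conditions, not performance on real
reconstructions.

## Classification protocol

Two-class comparisons are balanced by cell count (the larger class's
cells are subsampled, seeded; junction counts per cell remain unequal),
then split train/test by whole cells, stratified by class, with
train fraction 0.75 (clamped so each class keeps ≥ 1 test cell); no
junction of a test cell ever appears in training. Methods: logistic
regression; SVM with radial kernel (C = 1, kernel width from the median
pairwise-distance heuristic on standardized training features,
sigmoid-calibrated probability scores); KNN with odd k ∈ {1..51} chosen
by AUC on a seeded 25% cell-wise validation split of the training set
(chosen k reported); random forest (100 trees); decision tree; Gaussian
naive Bayes; MLP with one hidden layer of 8 logistic units (≤ 10⁴
iterations). Features are standardized (train-set mean/SD) for LR, SVM,
KNN and NN; tree-based methods and naive Bayes see raw features. All
stochastic components are seeded; hyperparameters are recorded in each
result for auditability. No multiple-testing correction is applied across
the 14 method × mode cells; the AUC table is descriptive.

AUC is the normalized Mann–Whitney statistic (ties ½) with a DeLong
structural-components variance for the 95% CI, clipped to [0, 1];
degenerate variance (perfect separation) collapses the interval onto the
AUC. Per-cell ("image") accuracy hard-labels each junction at score 0.5,
averages within a cell, and calls the cell positive when the mean exceeds
0.5, with an exact tie called negative (logged); it is reported as
k/n cells.

## Numerical and design notes

- SWC floats are written in shortest round-trip form, so write→read is
  exact on the sample table.
- Level averaging (`level_profile`) exists for visualization only;
  classification always uses raw junction rows.
- The power recursion treats half-differences as magnitudes; sign flips
  of stored `Δβ`, `Δγ` inputs cannot change P.
- Degenerate inputs: single-sample root branches get path length 0
  (their junctions keep β but carry NaN γ, retained for radius features);
  empty junction sets, single-class training sets, NaN features and
  invalid thresholds/fractions raise named errors rather than degrading.
- Problem sizes in the bundled analyses and tests (depth 5–6 trees,
  12–20 cells per class, 10–20 seeded replicates) were chosen as the
  smallest cohorts at which the per-level signal and the null calibration
  are stable; everything is seeded and regenerable.

## Known limitations

Real reconstructions have irregular topology, heteroscedastic radius
noise and soma geometry that a complete binary tree does not capture; the
per-branch mean radius weights samples, not arc length; the image-level
accuracy depends on the junction-score threshold 0.5 without calibration;
and the DeLong CI treats junctions within a cell as independent, which
overstates the effective sample size when junctions are correlated — the
cell-wise split protects the train/test boundary but not the CI width.
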