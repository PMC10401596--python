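# Methods

## Aperture model and feature definitions

A dynamic IMRT field is an ordered list of control points, each with a
cumulative meterset fraction in [0, 1], per-pair leaf tip positions for
both banks (mm at isocenter, IEC 61217: x toward the right bank, leaf
pair *i* on `y ∈ [edge[i], edge[i+1])`, bank centred about y = 0) and a
jaw rectangle. The default leaf geometry is a Millennium-120-style
projection (10 × 10 mm, 40 × 5 mm, 10 × 10 mm pairs); any geometry can
be supplied.

The aperture at a control point is the union of axis-aligned rectangles
of the *open* pairs. A pair is open when its jaw-clipped tip gap
exceeds the closure tolerance (default 0.5 mm — sliding-window plans
park closed pairs with a small dosimetric gap, so exact closure cannot
be required). Jaw clipping is on by default because physical fluence is
jaw-limited; it can be disabled for geometry cross-checks.

Per-snapshot quantities are exact polygon arithmetic, not
rasterization: area = Σ gap × row height; perimeter decomposes into
leaf-tip edges (2 × row height per open row) plus leaf-side edges (the
caps of each maximal run of open rows and the symmetric difference of
adjacent-row intervals). The edge metric uses only the leaf-side part,
following the original intent of penalising MLC side-edge exposure; the
tip contribution is excluded.

**MU attribution.** Beam-level features aggregate snapshots with
weights from trapezoidal attribution of the meterset fraction: interior
control point *k* carries `(mu[k+1] − mu[k−1])/2`, the ends carry their
half-intervals. The attribution is symmetric, sums to 1, and treats
the aperture *at* the control point as representative of the dose
delivered around it. NS counts MU-carrying control points — for
sliding-window delivery the control point is the only segment-like
unit, so "number of segments" is read as this count and MUCP = MU/NS.

Conventions fixed where the formulas have removable singularities: an
LSV bank factor is 1 when all open-pair positions coincide (the limit
of the formula, avoiding 0/0); CVA uses the unweighted population
standard deviation over MU-carrying control points; AAV's denominator
is the per-pair maximal envelope `Σ (max right − min left)₊ × width`
over pairs that ever open; UAA is the per-pair *union* of open
intervals times width (≥ any single-snapshot area, hence BM ∈ [0, 1]).
SAS thresholds are strict (`gap < x mm`). MAXJ is the maximum
*absolute* jaw position. A zero-area aperture at an MU-carrying
control point is an error, not a skip: ratio metrics (BI, AAV, EM) are
undefined there and the condition indicates corrupt input.

The column header spelling `AVV` for the aperture-area-variability
feature is kept in all tabular output for continuity with the
customary feature table of this 21-feature set.

## Synthetic cohort

The generator emulates sliding-window delivery: both banks sweep
left→right with the aperture centre travelling from `−(w−g)/2` to
`+(w−g)/2` (so the zero-jitter limit is a translating rectangle of
constant area — CVA = 0 while BM > 0), per-pair static envelope offsets
(edge roughness) roughen the aperture sides, and per-control-point gap
jitter varies the local opening. Cohort heterogeneity comes from
per-field draws: 20–120 control points, field widths 60–160 mm, mean
gaps 6–45 mm, jitter 0.5–6 mm, roughness 0–6 mm, 8–32 open pairs,
60–350 MU. These ranges were chosen once to span lightly modulated
wide-field deliveries through heavily modulated narrow-gap sweeps, and
produce non-degenerate variance in all 21 features.

GPR is simulated as a linear response on cohort-standardized features,
`GPR = clip(β₀ + Σ βⱼ zⱼ + ε, 0, 100)` with ε ~ N(0, σ²). The planted
coefficients are negative on NS (−1.0), BI (−0.7), CVA (−0.4), MU
(−0.3) and EM (−0.25) — the directions reported consistently in the
clinical literature — and zero elsewhere; correlations among features
arise naturally from the shared geometry rather than an imposed copula.
β₀ = 96.1 and σ = 1.1 were calibrated once against the two cohort
anchors the model is meant to reproduce (≈ 71.5 % of fields passing the
GPR > 95 % rule; the bulk of GPR values in the low-90s to high-90s) and
then frozen. What passing recovery tests shows: the pipeline can
detect planted monotone effects of this size under realistic feature
correlation. What it does not show: anything about the *mechanism*
linking complexity to measured dose agreement on a real accelerator —
the response here is linear by construction, the noise is homoscedastic
and Gaussian, and delivery-error sources (leaf positional noise, output
drift, detector response) are deliberately out of scope.

The boundary of the pass rule reads "greater than 95 %" strictly: GPR
exactly 95.0 is a fail. Continuous data never exercises the boundary;
the convention is fixed once here.

## Models and tuning

ANN = single-hidden-layer feed-forward perceptron (L-BFGS, tuned hidden
nodes 3–25 and weight decay {0, 0.01, 0.1}); SVM = RBF kernel (tuned
cost {0.25…16}, gamma {0.02…0.5}); RF = random forest (tuned mtry 2–21,
ntree 100–500). ANN/SVM inputs are standardized on the training set;
RF uses raw features. Regression tuning minimises ten-fold CV RMSE;
classification tuning maximises ten-fold CV AUC (AUC is the study's
evaluation metric, so it is also the tuning criterion; the SVM uses its
margin during CV, where only ranks matter, and Platt-scaled
probabilities in the final model so that scores live in [0, 1] with the
hard label at 0.5). RF tunes in two stages — mtry by out-of-bag error
at 300 trees, then ntree by CV — mirroring the customary randomForest
workflow. Ties break toward the earlier grid point. The
`COMPACT_GRIDS` preset spans the same hyperparameter region with ~10×
fewer fits and is the default for single-CPU study-scale runs; every
tuning trace records all evaluated points and their stage, so grid
coverage and stage order are checkable after the fact.

RF feature importance is permutation importance on out-of-bag samples:
per-tree OOB membership is reconstructed from the trees' bootstrap
seeds, each feature column is permuted once, and the importance is the
increase in OOB MSE (regression) or decrease in OOB accuracy
(classification). If the per-tree bootstrap reconstruction is
unavailable the implementation falls back to training-set permutation
importance (5 repeats), which preserves ranking on the tested cohorts.

Class imbalance (~28 % fails) is left unhandled, matching standard
practice for this cohort size; resampling is a possible extension, not
a default. The 8:2 split is unstratified at field level;
`|test| = round(0.2 n)` (468 of 2340).

The learning curve holds out a fixed 20 % test set and, for each of the
20 training fractions (5 %…100 % in 5 % steps), averages train/test
scores over random subsets. Re-tuning the full grid at every fraction
is supported but the pipeline default re-uses the hyperparameters
chosen on the full training set — the curve then isolates the effect of
sample size rather than tuning noise.

## Reproducibility and problem sizes

Every stochastic step (cohort draw, split, CV folds, forest seeds,
subsampling) derives from the single study seed; `report.json` contains
no timestamps, so two runs of the same config are byte-identical. The
acceptance script runs the study at the emulated cohort size of 2340
fields with the compact grids and a 2-replicate learning curve; the
test suite uses 2000 fields for parameter recovery and smaller cohorts
for protocol checks — sizes chosen to keep a full run in minutes on one
CPU while leaving all statistical assertions comfortably powered.

## Verification strategy

The analytic geometry is cross-checked against an independent
brute-force reimplementation that rasterizes apertures on a 0.1 mm
pixel grid (tests/raster_oracle.py); test fields have all positions
snapped to that grid, making the raster measurement exact, and 200
random fields agree on all 21 features to machine precision (the
acceptance tolerance is 1 % relative). AUC is checked against explicit
enumeration of all fail/pass score pairs with half-credit ties.
Closed forms pin the degenerate cases: a static square (BM = 0,
AVV = 1, BI = 4/π, UAA = area), a three-gap snapshot (SAS5 = 1/3,
SAS20 = 2/3) and a two-area sweep (CVA = 0.5).

## Known limitations

* The DICOM-RT reader handles the standard single-MLC Varian-style
  layout; dual-layer MLCs and jaw-tracking exotica are untested.
* Leaf-motion physicality (maximum leaf speed, interdigitation rules)
  is not validated — the package analyses sequences, it does not vet
  deliverability.
* The simulated GPR model is a testing instrument, not a claim about
  clinical GPR distributions; conclusions about real QA cohorts require
  real measurements ingested via `fields_path`/`gpr_csv`.
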