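# Methods

## Generative model of the trial

One simulated trait realization for plot j in replication k, block l(j),
genotype g(j) at field position (row_j, col_j) is

    y_j = mu + rep_k + t_{g(j)} + b_{kl(j)} + e_j,

where `t` is a family effect drawn once per family from N(0, Vg) (shared by
the family's three plots) for the 86 full-sib families and a fixed deviation
(default 0) for the 24 checks/genitors; `b ~ N(0, Vb)` per block within
replication; and `e` is one draw of a matrix-normal field with separable
AR1(rho_row) ⊗ AR1(rho_col) correlation scaled by Ve, sampled exactly through
the Kronecker Cholesky identity (L_row Z L_colᵀ). Negative assembled yields
are truncated at zero — a biological floor; at the default parameters
(mu = 2000 kg/ha, Vg = 44258, Vb = 20000, Ve = 100000 (kg/ha)²,
rho = 0.3/0.3) truncation is rare (~0 plots per trial, the count is logged).

Defaults follow the guineagrass trial the package emulates: 330 plots in a
22 × 15 grid (the real field geometry is not published; a rectangular grid
with row-major numbering is assumed, serpentine is available), 11 blocks of
10 plots per replication, 4.5 m² plots. The alpha-lattice internals are
simplified to randomized equal-size blocks within replications: the
downstream mixed model consumes only rep/block/genotype labels, so the
specific lattice generator is immaterial here.

Each plot's total dry matter is split into leaf / sheath+stem / dead
fractions drawn per plot (leaf ~ N(0.55, 0.05) clipped, dead ~ N(0.05, 0.02)
clipped, stem the remainder), making TDMY = LDMY + SSDMY + DMDMY exact by
construction. A per-plot moisture fraction m ~ U(0.70, 0.78) implies the
fresh ("green") weight TGMW = dry/(1 − m). The field-sample generator inverts
the weighing arithmetic: it draws the sample green weight SGW ~ U(300, 500) g
and emits component dry weights SGW·d_c/TGMW so that the standard equations
recover the true yields to floating-point accuracy — the round trip is an
identity, which is exactly what makes it a useful invariant test.

The moisture band (0.70–0.78) is a deliberate calibration: the plot image
encodes *green* matter, so moisture variation is the irreducible noise
between what the camera can see and the dry-matter ground truth. This band
attenuates the image ↔ TDMY correlation to roughly 0.85 at the canopy-cover
level, which after CNN estimation error lands the out-of-fold correlation in
the 0.6–0.8 region reported for UAV-RGB phenotyping of forage DMY. A much
wider band would make the ceiling unreachable; a degenerate one would make
the task trivially easy.

## Plot rendering

Plots are drawn as ten plant canopies (two rows of five, as planted) on a
noisy soil background. Expected canopy cover is strictly increasing and
saturating in green matter g: cover = 0.85·(1 − exp(−0.25·g)), mimicking
canopy closure — the regime where image-based biomass estimation degrades.
Per-plant radius jitter (texture noise) and per-pixel Gaussian color noise
(hue noise, sd 10 of 255) perturb the signal. The renderer is deliberately
not photorealistic: it provides a learnable, monotone, noisy signal with a
controllable ceiling, nothing more. Consequently, a passing CNN criterion
here demonstrates that the pipeline (augmentation, fold hygiene, training,
out-of-fold assembly) extracts an attainable signal — it says nothing about
how a given architecture ranks on real UAV imagery, and no such claim is
made.

The orthomosaic is the patches placed on the grid with a fixed soil-colored
gap; extraction inverts the placement exactly (pixel-copy windows, 0-based
half-open coordinates), so mosaic → patches is pixel-identical — tested as
such. Numbering convention (row-major vs serpentine) is configurable because
the real extraction script's convention is unknown.

## CNN regression

The image regressors are trained with Adam (lr 0.001, beta1 0.9, beta2 0.999,
eps 1e-8) on an MSE loss, with the three axis-flips as augmentation —
"rotation (horizontally and vertically)" is read as flips, which preserve the
patch geometry; 90° rotations would too but add nothing for this signal. The
default 4-conv network (batch norm, average pooling, dropout head) is scaled
to ~74 k parameters: ample for a 64-px canopy-cover signal and trainable on
one CPU; a ~1 M-parameter wide preset exists for parameter-count comparisons,
and a multi-stream late-fusion variant and a deeper 5-conv/3-dense stack are
available. ImageNet-pretrained variants are out of scope (external weights).

Targets are z-scored on the training split (restored at prediction) — purely
a conditioning device for Adam; a zero-variance target degenerates to
predicting its mean exactly. Early stopping evaluates a 10 % validation slice
of the training fold every `early_stop_interval` epochs (protocol default
100; short desk runs simply never trigger it) and restores the best weights.
Cross-validation is a random (unstratified) k-fold partition; augmentation
happens inside `fit` on training images only, so augmented copies of a plot
can never appear in the fold where that plot is tested. At the test scale
(330 plots, 64 px, 10 folds, 10 epochs) the full cross-validation runs in
about 6–7 CPU-minutes and reaches out-of-fold r ≈ 0.8.

## Evaluation metrics

MAE/RMSE in trait units and standard Pearson r (the printed form of the
correlation formula in the source material omits the square root over the
denominator; values in [−1, 1] imply the standard definition, which is what
is implemented). Degenerate variance makes r undefined and is flagged, never
silently zeroed. Fold aggregation reports mean ± sample sd (ddof = 1; sd is
undefined and reported absent for a single fold).

Histogram intersection compares proportion histograms (so unequal lengths are
admissible) over shared bin edges spanning the union range — the symmetric
convention; `edges="real_only"` reproduces the alternative of binning from
the observed values alone. The elbow rule scores candidate bin counts by
within-bin sum of squares and picks the maximum of the discrete second
difference of the (first-candidate-normalized) score curve; this is stable
under extending the candidate range, and a fixed bin count (20 by default in
the pipeline) can always be forced by configuration.

## REML, BLUP and heritability

The mixed model is y = XB + Z1 b + Z2 g + e with X = intercept +
(n_reps − 1) replication contrasts + one indicator per check/genitor
genotype — checks are fixed and contribute to residual/spatial estimation but
not to Vg — and R_ij = rho_row^|Δrow| · rho_col^|Δcol| built on occupied plot
coordinates only (missing grid cells need no phantom plots because the AR1
power form is an exact function of coordinate distance).

The REML criterion is

    l_R = −1/2 [ (n−p) log 2π + log|V| + log|X'V⁻¹X| − log|X'X| + y'Py ],

evaluated through the Henderson mixed-model-equation factorization
(log|V| = log|Ve·R| + log|G| + log|M| with M the random-effect block of the
MME coefficient matrix) rather than by inverting V; the `log|X'X|` term makes
the value invariant to the fixed-effect parameterization. An independent
brute-force dense evaluation (direct inversion of the full n × n V) lives in
the test suite and agrees to 1e-8 on small instances.

Optimization: Average-Information Newton steps (score and AI matrix from the
dense P at the current point) with step-halving and projection onto the box
(variances ≥ 1e-8·var(y), |rho| ≤ 0.99), initialized at Vb = Vg = Ve =
var(y)/3, rho = 0; convergence at |Δl_R| < 1e-6 and relative parameter change
< 1e-4. When an AI step cannot improve the criterion, a Nelder-Mead polish on
(log-variance, atanh-correlation) scale takes over; non-convergence returns a
flagged fit rather than raising. The likelihood trace is monotone by
construction and asserted in tests.

BLUPs and the family prediction-error covariance come from the inverse MME
coefficient matrix at the optimum. Heritability uses the pairwise (Cullis)
PEV statistic — the mean over unordered family pairs of
var(ĝ_i − ĝ_j) — giving H = 1 − PEV̄ /(2 Vg). The alternative diagonal-PEV
variant is exposed by `pev_mode="diagonal"`. Negative H is reported as is
(it is informative: family prediction worse than useless); H is undefined and
flagged when Vg pins at the floor. The "approximate genetic correlation" is
the Pearson correlation of the two traits' family BLUP vectors from separate
single-trait fits — an attenuated estimate of the genetic correlation, which
is precisely the quantity the validation uses. For the 86-family balanced
design with independent residuals the attenuation factor is approximately
Vg/(Vg + (Vb + Ve)/n_reps), which the recovery test uses as its oracle.

## Selection response

i(p) = φ(Φ⁻¹(1−p))/p is the standardized mean of the selected upper tail;
DR = i·√H_real·√Vg_real and CR = i·√H_HTP·r·√Vg_real. Negative heritability
has no square root: responses are refused, not imputed. Reporting convention:
classical tables list i to three decimals (1.755, 2.063, 2.665) and reports
round those half-up to 1.76, 2.06, 2.67 — `printed_intensity` reproduces
this; internals keep full precision, and CR/DR ratios are formed from
unrounded responses. Scenario sizes (660/3300 plots) are metadata only: the
genetic parameters are held fixed across scenarios by assumption, so scaling
claims inherit that assumption.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed and is reproducible
bit-for-bit (single-threaded). The test suite runs the Monte-Carlo checks at
sizes chosen for a single-CPU workstation: 250 replicate draws for
variance-targeting, 100 field draws for autocorrelation recovery, 50
replicate 330-plot REML fits for parameter recovery and 50 twin-trait pairs
for correlation recovery, and one 10-fold cross-validation at 10 epochs for
the CNN criterion. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances.

## Known limitations

- The renderer omits radiometric, perspective and stitching artifacts of real
  orthomosaics; rotated or keystoned mosaics must be rectified before
  extraction.
- The mixed model is single-trait (correlating BLUPs across fits), not a
  bivariate REML; no pedigree/genomic relationship structure.
- Listwise-complete data are required (no missing-plot handling beyond
  refusing NaNs).
- Selection intensities are infinite-population values; no finite-population
  correction.
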