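# Methods

This note documents the models implemented in `fossilclim`, their
assumptions, the defaults that matter, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Compositional conventions

Pollen percentages use the sum of all terrestrial pollen and spores as the
denominator. Aquatic taxa and other non-pollen palynomorphs are expressed
relative to the same sum, so a sample's full row may exceed 100%; exotic
marker grains (added in the laboratory to estimate absolute concentrations)
are excluded from every downstream computation. Counts are non-negative
reals — half grains (e.g. 220.5) are legal. The AP/NAP ratio treats NAP as
terrestrial pollen outside the user-supplied arboreal list; spores are
excluded from NAP by default (configurable), and the arboreal list is a
required input because conventions differ on whether shrubs (e.g. dwarf
birch) count as AP. A sample with zero NAP reports `+inf` with a flag rather
than an error.

Fossil and calibration tables are harmonised by exact taxon-name match after
case folding; unmatched fossil taxa are dropped with a warning and
percentages are *not* renormalised (a `renormalise` flag restores closure
when wanted).

## Calibration models

All six models consume the samples × taxa percentage matrix (0–100 scale)
and a climate variable in °C. Proportions (row-normalised) are used
internally for squared chord distances and MLRC.

* **WA** — taxon optima are abundance-weighted means of the climate
  variable; raw estimates are abundance-weighted means of the optima.
  Deshrinking is inverse by default (regress observed climate on raw
  estimates); classical deshrinking inverts the reverse regression. Raw
  estimates are invariant to scaling a sample's counts. Degenerate constant
  targets fall back to a constant prediction.
* **WA-PLS** — components are extracted from abundance-weighted residuals
  with a final regression weighted by sample pollen totals. On
  percentage data (constant row sums) one component reproduces WA with
  inverse deshrinking to machine precision; this equivalence is asserted in
  the test suite at 1e-8 over 50 random synthetic calibrations. The
  component count defaults to the leave-one-out RMSEP minimum over 1–5.
* **MAT** — k = 5 nearest analogues under squared chord distance with
  inverse-distance weighting (ties at the k-th distance are all included;
  exact matches take all the weight). MAT predictions cannot leave the
  calibration climate range; WA after inverse deshrinking can extrapolate.
  Both properties are asserted.
* **MLRC** — per-taxon Gaussian-logit curves (logit p = b₀ + b₁x + b₂x²)
  fitted by binomial GLM on observed proportions. Curves with b₂ ≥ 0 are
  retained but flagged monotone; taxa whose GLM fails are excluded. The
  fossil estimate maximises the summed Bernoulli log-likelihood over a
  501-point grid spanning the calibration climate range, with response
  probabilities clipped to [1e-6, 1 − 1e-6].
* **BRT** — gradient boosting with learning rate 0.01, interaction depth 3
  and bag fraction 0.75. The tree count is selected by validation-loss early
  stopping (20% validation split, patience 20, cap 2000 trees) — chosen over
  an inner CV loop as a cheaper estimator of the stopping point with
  indistinguishable held-out skill at these data sizes.
* **RF** — 500 trees with the conventional regression feature subsampling
  mtry = p/3.

Cross-validation reports RMSEP, R² and maximum bias (largest absolute mean
residual over 10 equal-width climate intervals). Leave-one-out is used where
refits are cheap (WA, WA-PLS, MAT) and seeded 10-fold where a fit is
expensive (MLRC, BRT, RF).

The ensemble reconstruction is the pointwise median of the six member
reconstructions, smoothed along the depth axis by LOESS — tricube weights,
local quadratic, span 0.03 of the sample count, one bisquare robustifying
iteration. (The smoother is implemented in-package because the installed
lowess routines are local-linear and non-robust-by-default; the local window
never falls below degree + 2 points.) Mapping the smoothed curve from depth
to age is a post-step through the chronology module.

## Zonation

The multivariate regression tree uses core depth as the sole predictor and
the percentage matrix as multivariate response, so splits are depth
thresholds and leaves are contiguous zones. Splits are found best-first:
each step takes the boundary (anywhere in the current partition) that
maximally reduces the total within-zone sum of squares over all taxa, with
exact ties resolved to the shallowest depth. This yields a nested sequence
of candidate trees indexed by size; tree size is chosen by repeated k-fold
cross-validation (10 folds × 50 repetitions, seeded, SE of the relative
error taken across repetitions) and the 1-SE rule — the smallest tree whose
CV error is within one standard error of the minimum. The size-indexed CV
convention replaces the cost-complexity alpha sequence of classic recursive
partitioning; with a single ordered predictor the two prune the same nested
family. The response is untransformed percentages by default with a
square-root option. On clearly blocked data the greedy segmentation attains
the exhaustive optimum (asserted against a brute-force oracle at n = 12); on
arbitrary data greedy is an upper bound on the attainable within-zone SS.

## Analogue diagnostics

Nearest-analogue squared chord distances are computed by full scan. A fossil
sample has a "good" modern analogue when its minimum distance is below twice
the mean analogue distance of a user-supplied reference population (standing
in for late-Holocene samples from a nearby core, which have good analogues
by construction); exact matches are always good, which keeps the rule
sensible when the reference distances are all zero. Analogue geography
averages the coordinates of the five most similar modern samples with
weights 1/d ("weighted by analogue quality"; a 1 − d/2 alternative is
available by flag since the weighting convention is not standardised);
zero-distance analogues take all the weight, and longitudes are averaged
arithmetically (no antimeridian crossing in scope).

## Significance testing

The test statistic is the fraction of variance in the (column-centred)
fossil percentage matrix explained by a single-variable redundancy analysis
on the reconstruction. Null reconstructions retrain the same calibration
method on environmental variables drawn uniformly over the observed climate
range; p = (1 + #{VE_null ≥ VE_obs}) / (1 + n_perm), so p ∈ [1/(n_perm+1), 1]
and the test is deterministic under a seed. Species data are centred but not
scaled, with an optional square-root transform. Subset tests (e.g. a zone
range) recompute VE on the subset rows with taxa re-centred within the
subset. The default method is MAT (the method used is configurable); n_perm
defaults to 99 and must be at least 99.

Two properties are verified by simulation. *Power*: on the default synthetic
scenario the July reconstruction is called significant (p ≤ 0.05) in ≥ 90%
of replicate studies. *Type-I error*: the test's null hypothesis is that the
real environmental variable is no better than a random one, so the type-I
simulation severs the composition–climate link — calibration compositions
from the generator carry random climate labels, and the fossil samples are
compositional noise. Under that null the rejection rate at α = 0.05 sits
inside the 95% binomial envelope over 200 datasets. Note that a noise fossil
tested against an *intact* calibration set is not a null case for this
statistic: the real transfer function still maps fossil compositions to
climate-correlated predictions, and VE_obs then reflects the calibration
set's genuine structure, inflating rejection far above α. The test answers
"is this variable better than a random one", not "is the fossil data
noise".

## Age–depth model

Deposition is modelled as a Poisson process with event rate `k_rate` per
centimetre. Each Monte-Carlo draw samples tie-point ages from their Normal
priors (2σ given; draws with stratigraphic inversions are rejected, and tie
priors implying an inversion probability above 50% are rejected outright),
then allocates each inter-tie time span across the depth increments with a
Dirichlet bridge — gamma weights with shape `k_rate` × Δdepth(cm) — giving
strictly monotone age–depth functions whose uncertainty grows away from the
tie points. Ages are in ka before present on a default 1-cm grid; depths
outside the tie span either raise an error, are linearly extrapolated at the
adjacent segment's per-draw mean rate (flagged), or are handled by
`fixed_duration_section`, which maps a rapidly deposited section (e.g.
glacio-lacustrine beds) linearly onto a prescribed total duration anchored
at the adjacent tie age.

`k_rate` defaults to 1 event/cm. The rate controls the interior uncertainty:
with the standard tie points (130.9 ± 1 ka and 117.5 ± 0.5 ka, 2σ, 10 m
apart) the interior 2σ maximum is ≈ 0.7 ka at k = 1/cm and ≈ 1.5 ka at
k = 0.1/cm, converging to linear interpolation between the sampled tie ages
as k → ∞ (asserted at k = 10⁶ to within 1% of the span). The acceptance
checks run at the moderate value k = 0.1/cm, where the interior-peaked
millennial-scale uncertainty profile matches the behaviour expected of
slowly accumulating lake sediment with coarse depositional events; in real
applications k should be estimated from an independently dated analogue
sequence, which is out of scope here.

## The synthetic-data generator

The generator is first-class, tested code that defines the study conditions
for every end-to-end check. Each taxon has a bivariate Gaussian response
over (T_jul, T_jan) — independent seasonal terms with optimum, tolerance and
maximum abundance; expected proportions are the normalised response
intensities and counts are multinomial at a fixed pollen sum (optional
Dirichlet-multinomial overdispersion). Calibration climates are drawn from a
correlated bivariate normal (defaults: T_jul 13 ± 3 °C, T_jan −6 ± 5 °C,
r = 0.7), sketching a subarctic-to-temperate lake-surface-sample gradient;
coordinates are a smooth, jittered map of climate sufficient for analogue
geography. January tolerances are deliberately broad (5–9 °C vs 1.5–3.5 °C
for July), so — together with the climate correlation — the winter signal is
realistically weak and confounded with summer.

The fossil truth trajectory spans 26–16 m with 200 samples: July
temperature declines linearly by 3 °C bottom-to-top while January
temperature rises by 5 °C (decoupled seasonal trends), and two boxcar
cooling events are subtracted from July temperature — a broad mid-sequence
event (23.40–22.51 m, 2.7 °C) and a short late spike (17.45–17.30 m,
1.8 °C). The default study size is 300 calibration samples, 25 taxa and
pollen sum 400.

What the generator does *not* emulate: pollen dispersal and basin-size
effects, taphonomy and differential preservation, secular changes in pollen
productivity, non-analogue communities, spatial autocorrelation among
calibration sites, and age uncertainty in the fossil ordering. Passing the
recovery tests therefore demonstrates the correctness and internal
consistency of the inference chain under its own assumptions — not the
field accuracy of any particular reconstruction.

## Event magnitudes

An event report compares two closed depth windows on the ensemble: per
method, ΔT = mean(estimate over the reference window) − mean(estimate over
the event window), summarised by the across-method mean and min–max range.
The reference for a synthetic event defaults to the adjacent deeper
(stratigraphically preceding) half-metre. Recovery is judged against the
*truth-trajectory contrast over the same two windows* rather than the raw
injected magnitude, so the background trend inside the windows does not
contaminate the comparison. Both adjacency conventions for the reference
window are supported (the window is explicit config, not a hard-coded
direction).

## Problem sizes and determinism

End-to-end checks run the default scenario once (six models × two
variables with cross-validation, a few minutes on one CPU); the
significance simulations use 200 small null datasets and 50 full-size
signal datasets with MAT, and the age model uses 1000–2000 draws on a ~1-cm
grid — sizes chosen so the whole suite validates every claim in minutes
while keeping Monte-Carlo error well below the asserted margins. Every
stochastic component takes an explicit seed; child seeds are spawned via
`numpy.random.SeedSequence`, and identical configs produce byte-identical
pipeline outputs.

## Known limitations

* MLRC assumes binomial sampling of proportions and fits taxa
  independently; strongly bimodal or extremely rare taxa are dropped or
  flagged rather than modelled.
* The BRT stopping rule (single validation split) adds seed-to-seed
  variance relative to a full inner CV; at these data sizes the effect is
  well inside the member spread absorbed by the ensemble median.
* The January reconstruction is structurally harder than July in the
  synthetic scenario (broad winter tolerances, correlated gradients,
  decoupled fossil trends): its RMSE is consistently larger, its recovered
  trend is compressed towards the July signal, and subset significance tests
  on T_jan frequently fail to reach α = 0.05. This is the intended,
  documented behaviour of a weak winter signal, not a defect.
* The P-sequence implementation has no outlier model and no radiocarbon
  calibration; tie-point ages enter as Normal priors on a calendar scale.
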