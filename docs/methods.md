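# Methods

## The predictive model

strokecpm implements connectome-based predictive modeling for post-stroke
recovery: a univariate linear regression of a later-stage functional
assessment score (mRS or BI) on a single network-strength summary of an
earlier-stage functional connectome. The procedure has four stages — edge-wise
Pearson correlation of connectivity with behavior, significance
thresholding into pos- and neg-polarity edge masks, summation of the
selected edges' connectivity into a per-subject pooled score s_k, and
ordinary least squares of behavior on s_k. The two polarities are always
modeled separately as two univariate regressions, never combined into one
two-predictor model. Behavior scores are treated as continuous in the
Pearson correlations even though mRS is ordinal; that is a deliberate
property of the method being implemented, not an oversight.

Assumptions worth stating: edges enter the model only through their sum,
so the method presumes a diffuse, sign-coherent association rather than a
structured multivariate pattern; the Pearson edge test assumes roughly
linear edge–behavior relations; and the LOOCV inference assumes
exchangeable subjects.

### Numerical conventions

- **Edge canonical form.** All edge sets live on the upper triangle
  (i < j, 0-based); symmetric M×M matrices are the I/O representation.
  An M-node brain allows (M² − M)/2 edges (6670 for M = 116).
- **Single counting.** s_k sums each undirected edge once. A full inner
  product of the symmetric mask with the symmetric connectome would count
  every edge twice; that halving only rescales the regression slope and
  changes no correlation, p-value, or prediction, so the cleaner contract
  was chosen and is documented here prominently.
- **Edge p-values** come from the exact t transform of r with N − 2 df
  (two-sided). Zero-variance edges get r = 0, p = 1; a zero-variance
  behavior vector is an error. The minimum cohort for edge statistics is
  N = 3 (df = 1); LOOCV requires N ≥ 5.
- **Edge-selection α** defaults to 0.05 and is configurable everywhere
  (`--edge-alpha`); no universal value exists for this threshold in the
  CPM literature.
- **Fisher z** of the connectivity values is available (`fisher_z=True`)
  but OFF by default: raw Pearson r is the literal quantity the procedure
  correlates, and the z transform is a strictly monotone reparameterization
  that rarely changes selections.
- **Degenerate fits.** An empty mask (or constant pooled scores) flags the
  model degenerate; it predicts the training mean with a warning rather
  than failing, so batch runs survive sparse cells.

## Cross-validation and significance

LOOCV holds out each subject once and reruns the *entire* procedure —
edge correlation, mask selection, regression — on the remaining N − 1,
yielding exactly N held-out predictions. (Reports in this literature
sometimes count N − 1 leave-one-out models; a compatibility flag
`n_minus_one` reproduces that count by dropping the final fold, but
standard N-fold LOOCV is the statistically motivated default.) Model
significance is `R > 0 and p < 0.05` on the Pearson correlation between
predictions and truth; the explicit positive-R condition encodes that an
anticorrelated predictor has no clinical value regardless of p. When the
full 48-cell study grid is evaluated, p-values are reported raw and a log
line notes the number of cells tested; no multiplicity correction is
applied, matching standard practice for this design.

The numerical core vectorises all N folds simultaneously via leave-one-out
updates of the per-edge sums, so one LOOCV costs a few matrix products;
this is what makes permutation testing and Monte-Carlo calibration cheap
(a 199-iteration permutation test on N = 20, M = 10 runs in ~0.1 s).

### Permutation test

Behavior labels are shuffled (equivalent to permuting connectomes under
exchangeability, and cheaper) and the full LOOCV is rerun per iteration;
the default is 10,000 iterations where runtime allows. The p-value is
one-sided in the direction of positive prediction:

    perm_p = (1 + #{valid null R ≥ observed R}) / (n_valid + 1).

"Valid" matters: under the null with small M, a nontrivial fraction of
LOOCV runs select no edge in any fold. Such a run produces only
training-mean fallback predictions, and because the held-out training mean
is an exactly decreasing function of the held-out score, its "R" is the
artifact value −1 rather than a measurement of anything. These no-model
iterations are therefore discarded and the count divides by the number of
valid draws. By exchangeability among the valid draws, perm_p is exactly
uniform under the null conditional on the observed run being a real model
— a property the package verifies by Monte-Carlo (KS test against
uniformity over 200 replicate null cohorts). Counting degenerate draws
against a fixed denominator would instead pile mass near 1 and destroy
calibration. An observed run that is itself invalid propagates invalidity:
no permutation p is reported for a model that does not exist.

## Synthetic cohorts

Real post-stroke rs-fMRI with repeated staged assessments is not publicly
shareable, so validation rests on synthetic cohorts with planted ground
truth. Default dimensions emulate the target study design: groups of
38/26/12/17 subjects, M = 116 AAL-style nodes, T = 155 volumes at
TR = 2 s.

Generative model: one scalar latent recovery strength z_k ~ N(0,1) per
subject, shared by all planted edges — the simplest structure making the
planted edges jointly informative. Planted edge connectivity is
`0.3·z_k + N(0, 0.3)` (loading and background sd both configurable,
defaults chosen to put planted edge–behavior correlations near 0.6, i.e.
detectable but not trivial at N ≈ 40); background edges are i.i.d.
N(0, 0.3) clipped to valid correlation range. Behavior is linear in the
latent on a standardized scale, `b = center + spread·(effect·z + ε)`, then
mapped to the clinical scale: mRS center 3, spread 1, rounded to integers
in [0, 6]; BI center 60, spread 15, rounded to multiples of 5 in [0, 100].
Effect size and noise sd are thus in standardized units for both measures
(defaults 1.0 and 0.5). Behavior defaults to a stage-2 score because
predictive cells always regress a later-stage score on earlier
connectivity; stage-1 mRS cohorts are additionally clamped to {2, 3, 4},
mirroring recruitment restricted to moderate disability. The sign of the
effect sets the expected edge polarity.

The time-series route realises the same targets in signal space: a
per-subject target correlation matrix (identity plus planted entries,
eigenvalue-clipped back to a valid correlation matrix) is Cholesky-mixed
into white noise, band-limited to 0.005–0.1 Hz (slightly wider than the
analysis band so filtering does not erase the structure), then
contaminated with six slow motion random walks, three global/WM/CSF
proxies with random node loadings, and per-node linear drift. The full
multi-group generator (`generate_study`) adds stage-drifting behavior
centers (mRS falls, BI rises across stages) and a per-subject trait that
couples a subject's scores across stages without touching connectivity,
and can confine the planted effect to a single group × measure ×
stage-pair cell.

What the generator does **not** emulate: hemodynamic response shapes,
scanner artifacts, motion spikes, spatial autocorrelation between
neighbouring ROIs, heavy-tailed score distributions, or multivariate edge
patterns beyond the single shared latent. Passing tests therefore
demonstrate the correctness and calibration of the *procedure*, not its
effect size on real stroke cohorts.

## Signal conditioning

Only the numerically defined ROI-level steps are implemented: linear
detrending, 0.01–0.08 Hz band-pass at TR = 2 s, and OLS nuisance
regression on an intercept plus the six motion parameters and
global/WM/CSF signals. Volume-space preprocessing (slice timing,
realignment, normalisation, smoothing) is out of scope; inputs are already
ROI time series. The band-pass defaults to a sharp frequency-domain filter
(DFT bins outside the band zeroed), the convention of classic resting-state
toolboxes; a zero-phase 4th-order Butterworth is available via
`method="butter"`. Order of operations: detrend → band-pass → nuisance
regression, with the covariates themselves detrended and filtered
identically before the regression so that removed frequencies are not
reintroduced; residuals are then exactly orthogonal to every (filtered)
covariate. Detrending is linear only. Rank-deficient nuisance designs drop
dependent columns with a logged warning.

## Consensus networks and export

Across LOOCV folds the selected masks vary; the consensus network keeps
edges selected in at least a fold-frequency threshold (default 0.9), with
an alternative top-k mode (default k = 20) since "the few most frequent
edges" has no canonical quantification. Export follows the BrainNet Viewer
text dialects: `.node` rows are `x y z color size label` for nodes
incident to retained edges (color 1, size = consensus degree — the format
requires the columns but no convention fixes their meaning), and `.edge`
is the full M×M adjacency with fold-frequency (or binary) weights. The
bundled 116-label AAL-style atlas carries synthetic placeholder
coordinates for layout only; they are not measured parcellation centroids,
and users plotting real data should supply their own atlas.

## Problem sizes in the test suite

The suite validates on deliberately small cohorts: oracle-equivalence
checks on 50 random cohorts with N ≤ 20, M ≤ 15; planted-edge recovery on
N = 40, M = 20 with 5 planted edges; null calibration on 200 replicate
N = 20, M = 10 cohorts with 199-iteration permutation tests. These sizes
give stable Monte-Carlo estimates in seconds-to-minutes while exercising
every code path; all scale parameters are ordinary function arguments if
larger runs are wanted.

## Known limitations

- The pooled-sum model cannot represent mixed-sign or interaction
  structure among edges; that is inherent to the method.
- Permutation and LOOCV assume exchangeable subjects; longitudinal
  dependence between stages is not modeled in inference (each cell is
  analysed marginally).
- The Wilcoxon stage-comparison summary uses the zero-difference-dropping
  convention and scipy's exact/normal switching; it is descriptive
  reporting, not part of the predictive method.
- Ordinal mRS treated as continuous compresses variance at the scale ends;
  the generator's clamping reproduces this, which slightly attenuates
  planted correlations near the boundaries.
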