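# strokecpm

Connectome-based predictive modeling (CPM) of functional recovery after
ischemic stroke, from resting-state functional connectivity.

After an acute stroke, clinicians track disability with the modified Rankin
Scale (mRS, integers 0–6) and independence with the Barthel Index (BI,
0–100 in steps of 5) at successive stages of recovery. CPM asks whether a
patient's whole-brain functional connectome at an early stage predicts
their assessment score at a later stage. This package implements the full
procedure — ROI-signal conditioning, Pearson connectomes, edge selection,
pooled-connectivity regression, leave-one-out cross-validation (LOOCV),
permutation significance, and consensus brain-net export — for researchers
who work with ROI-level BOLD time series or precomputed connectivity
matrices, plus a synthetic-cohort generator with planted ground truth for
validation.

## The method

For N subjects with M-node connectomes (c<sub>ij</sub> = Pearson
correlation of the BOLD signals of regions i and j) and behavior array
b<sub>k</sub>:

1. **Edge-wise correlation.** For every edge, r<sub>ij</sub> = Pearson
   correlation of {c<sub>ij</sub>(k)} with {b<sub>k</sub>} across subjects;
   p<sub>ij</sub> from the two-sided t-test with N−2 df.
2. **Edge selection.** Pos-edge mask: r<sub>ij</sub> > 0 and
   p<sub>ij</sub> ≤ α; neg-edge mask: r<sub>ij</sub> < 0 and
   p<sub>ij</sub> ≤ α (default α = 0.05).
3. **Pooling.** Network strength s<sub>k</sub> = Σ c<sub>ij</sub>(k) over
   the selected edges (each undirected edge counted once).
4. **Regression.** Ordinary least squares b = β₀ + β₁·s, fitted per
   polarity; out-of-sample prediction applies the frozen mask and line to a
   new connectome.

Model validity is judged by LOOCV: refit everything on N−1 subjects,
predict the held-out one, and correlate predictions with truth (R, p). A
model with R > 0 and p < 0.05 is called significant, and a permutation
test (behavior shuffled, full LOOCV rerun; default 10,000 iterations)
reconfirms it. Edges selected in ≥ 90% of folds form the consensus network
exported in BrainNet Viewer `.node`/`.edge` format.

## Worked example

```python
from strokecpm import (SyntheticSpec, generate_connectomes_direct,
                       CPMRegressor, loocv, permutation_test,
                       classify_significance)

spec = SyntheticSpec(n_subjects=40, n_nodes=20, n_planted=5,
                     effect_size=1.0, noise_sd=0.5, seed=7)
connectomes, behavior, truth = generate_connectomes_direct(spec)

cpm = CPMRegressor(alpha=0.05, polarity="pos").fit(connectomes, behavior)
cv = loocv(connectomes, behavior, alpha=0.05, polarity="pos")
perm = permutation_test(connectomes, behavior, alpha=0.05,
                        polarity="pos", n_perm=199, seed=1)
```

Printing the fitted quantities gives:

```
selected edges: 7 (planted: 5, recovered: 5)
fit: b = 2.924 + 0.440 * s, training r = 0.740
LOOCV: R = 0.5741, p = 1.07e-04, perm_p = 0.0100
significant: True
```

All five planted edges are recovered (two false positives at α = 0.05 among
190 candidate edges), the fitted line maps network strength s to the mRS
score, and the cross-validated correlation R = 0.57 beats all but one of
199 permutation nulls (perm_p = 2/200).

`CPMRegressor` is a scikit-learn estimator: it composes with `Pipeline`
(see `ConnectivityTransformer` for going straight from raw time series),
`GridSearchCV`, and friends.

## Command line

```bash
strokecpm simulate --mode study --out study/ --seed 1   # synthetic 4-group study
strokecpm run --config study/study.yaml --out results/ --n-perm 1000
strokecpm report --behavior study/ST/behavior.csv
```

`simulate` writes per-group behavior CSVs and per-stage connectivity
matrices plus a YAML config; `run` evaluates the full grid — 4 groups × 2
measures × 3 stage predictions (1→2, 1→3, 2→3) × 2 polarities = 48 model
cells — and exports scatter data and consensus brain nets for significant
cells. `prep` and `connect` cover signal conditioning (0.01–0.08 Hz
band-pass, detrending, nuisance regression) and connectome construction
for your own ROI time series.

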