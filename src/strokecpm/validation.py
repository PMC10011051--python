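"""Leave-one-out cross-validation and permutation significance for CPM.

LOOCV refits the entire procedure — edge-wise correlation, mask selection,
pooled-connectivity regression — on N-1 subjects and predicts the held-out
subject, once per subject.  Model significance is the Pearson correlation R
between true and cross-validated predicted scores, with the usual t-test
p-value; because the null distribution of a cross-validated R is not the
textbook one, a permutation test (behavior labels shuffled, the *full*
LOOCV rerun) reconfirms it.

The numerical core is vectorised across folds using leave-one-out update
formulas on the edge-statistic sums, so a permutation test with hundreds of
iterations costs a few matrix products per iteration rather than N full
refits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import matrix_from_edges
from .cpm import BehaviorArray, EdgeMask, _stack_connectomes

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "PermutationResult",
    "loocv",
    "permutation_test",
    "classify_significance",
]

_TINY = 1e-300


@dataclass
class CVResult:
    """Cross-validated predictions and their significance for one model cell.

    ``valid`` is False when every fold had an empty edge mask (so all
    predictions are mean fallbacks and R is meaningless).
    """

    true_scores: np.ndarray
    predicted_scores: np.ndarray
    polarity: str
    R: float
    p: float
    valid: bool
    fold_masks: list[EdgeMask] = field(default_factory=list)
    empty_folds: np.ndarray | None = None
    measure: str | None = None
    stage: int | None = None

    @property
    def n_folds(self) -> int:
        return self.predicted_scores.size


@dataclass
class PermutationResult:
    """Null distribution of the cross-validated R under shuffled behavior."""

    observed_R: float
    null_Rs: np.ndarray
    perm_p: float
    n_perm: int
    n_valid: int
    valid: bool = True


def _loocv_core(x: np.ndarray, y: np.ndarray, alpha: float, polarity: str):
    """All LOOCV folds at once on an (n, E) edge matrix.

    Returns (predictions, fold_mask (n, E) bool, empty_fold (n,) bool).
    Row k of ``fold_mask`` is the edge mask fitted with subject k held out.
    Folds whose mask is empty (or whose pooled scores are constant) predict
    the training mean.
    """
    n, n_edges = x.shape
    if n < 5:
        raise ValueError("leave-one-out cross-validation needs at least 5 subjects")
    df = n - 3  # (n - 1) training subjects, Pearson df = n_tr - 2

    sx = x.sum(axis=0)
    sy = float(y.sum())
    sxx = (x * x).sum(axis=0)
    sxy = (x * y[:, None]).sum(axis=0)
    syy = float(y @ y)
    n_tr = n - 1

    # training-fold sums with subject k removed, one row per fold
    sx_k = sx[None, :] - x
    sy_k = sy - y
    sxx_k = sxx[None, :] - x * x
    sxy_k = sxy[None, :] - x * y[:, None]
    syy_k = syy - y * y

    cov = sxy_k - sx_k * sy_k[:, None] / n_tr
    varx = np.maximum(sxx_k - sx_k ** 2 / n_tr, 0.0)
    vary = np.maximum(syy_k - sy_k ** 2 / n_tr, 0.0)

    denom = np.sqrt(varx * vary[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.maximum(denom, _TINY)
    r = np.clip(np.where(denom <= 0, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, _TINY))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(denom <= 0, 1.0, p)

    if polarity == "pos":
        fold_mask = (r > 0) & (p <= alpha)
    elif polarity == "neg":
        fold_mask = (r < 0) & (p <= alpha)
    else:
        raise ValueError(f"unknown polarity: {polarity!r}")

    # pooled[j, k] = network strength of subject j under fold k's mask
    pooled = x @ fold_mask.T.astype(float)
    diag = np.diag(pooled)
    s_sum = pooled.sum(axis=0) - diag
    s_sum2 = (pooled ** 2).sum(axis=0) - diag ** 2
    sy_sum = (pooled * y[:, None]).sum(axis=0) - diag * y

    var_s = n_tr * s_sum2 - s_sum ** 2
    empty = ~fold_mask.any(axis=1)
    degenerate = empty | (var_s <= 1e-12 * np.maximum(s_sum2, 1.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n_tr * sy_sum - s_sum * sy_k) / np.maximum(var_s, _TINY)
    intercept = (sy_k - slope * s_sum) / n_tr
    preds = intercept + slope * diag
    preds = np.where(degenerate, sy_k / n_tr, preds)
    return preds, fold_mask, empty


def _cv_correlation(y: np.ndarray, preds: np.ndarray) -> tuple[float, float]:
    if np.ptp(preds) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(y, preds)
    return float(r), float(p)


def loocv(connectomes, behavior, alpha: float = 0.05, polarity: str = "pos",
          keep_fold_masks: bool = True, n_minus_one: bool = False) -> CVResult:
    """Leave-one-out cross-validation of the full CPM procedure.

    Each fold holds out one subject, reruns edge selection and the pooled
    regression on the remaining N-1, and predicts the held-out score.  R
    and p are the Pearson correlation (and its test) between the held-out
    predictions and the true scores.

    ``n_minus_one`` drops the final fold, yielding N-1 predictions instead
    of N — a compatibility mode for reports that count N-1 leave-one-out
    models; standard LOOCV (the default) predicts every subject.
    """
    x = _stack_connectomes(connectomes)
    y = np.asarray(getattr(behavior, "scores", behavior), dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("connectomes and behavior length mismatch")
    measure = getattr(behavior, "measure", None)
    stage = getattr(behavior, "stage", None)

    preds, fold_mask, empty = _loocv_core(x, y, alpha, polarity)
    if n_minus_one:
        preds, fold_mask, empty, y_used = (preds[:-1], fold_mask[:-1],
                                           empty[:-1], y[:-1])
    else:
        y_used = y

    valid = bool(~empty.all())
    if not valid:
        logger.warning("all %d LOOCV folds had empty %s-edge masks; "
                       "result marked invalid", empty.size, polarity)
        R, p = float("nan"), float("nan")
    else:
        if empty.any():
            logger.info("%d of %d folds had empty masks (mean fallback)",
                        int(empty.sum()), empty.size)
        R, p = _cv_correlation(y_used, preds)
        if np.isnan(R):
            valid = False

    masks: list[EdgeMask] = []
    if keep_fold_masks:
        m = int(round((1 + np.sqrt(1 + 8 * x.shape[1])) / 2))
        masks = [
            EdgeMask(mask=matrix_from_edges(row.astype(float), m),
                     polarity=polarity, alpha=alpha)
            for row in fold_mask
        ]
    return CVResult(true_scores=y_used, predicted_scores=preds,
                    polarity=polarity, R=R, p=p, valid=valid,
                    fold_masks=masks, empty_folds=empty,
                    measure=measure, stage=stage)


def permutation_test(connectomes, behavior, alpha: float = 0.05,
                     polarity: str = "pos", n_perm: int = 10_000,
                     seed: int | np.random.Generator | None = None) -> PermutationResult:
    """Permutation null for the cross-validated R.

    Behavior labels are shuffled ``n_perm`` times and the full LOOCV is
    rerun each time (permuting behavior rather than connectomes — the two
    are equivalent under exchangeability and this is cheaper).  Iterations
    whose LOOCV is invalid (every fold mask empty, so no model exists) are
    discarded, and

        perm_p = (1 + #{valid null R >= observed R}) / (n_valid + 1),

    the one-sided rule matching the positive-R significance direction.
    Counting only valid draws keeps the p-value exactly uniform under the
    null, where the observed statistic is itself conditioned on being a
    real (non-degenerate) model.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; permutation p-values are "
                      "coarse below a few hundred iterations", UserWarning,
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    x = _stack_connectomes(connectomes)
    y = np.asarray(getattr(behavior, "scores", behavior), dtype=float).ravel()

    preds, _, empty = _loocv_core(x, y, alpha, polarity)
    if empty.all():
        logger.warning("observed LOOCV invalid; permutation test propagates "
                       "invalidity")
        return PermutationResult(observed_R=float("nan"),
                                 null_Rs=np.empty(0), perm_p=float("nan"),
                                 n_perm=n_perm, n_valid=0, valid=False)
    observed_R, _ = _cv_correlation(y, preds)

    null_rs = np.full(n_perm, np.nan)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        preds_b, _, empty_b = _loocv_core(x, y_perm, alpha, polarity)
        if empty_b.all():
            continue
        r_b, _ = _cv_correlation(y_perm, preds_b)
        null_rs[b] = r_b
    valid_nulls = null_rs[~np.isnan(null_rs)]
    n_valid = valid_nulls.size
    perm_p = (1.0 + float((valid_nulls >= observed_R).sum())) / (n_valid + 1.0)
    return PermutationResult(observed_R=observed_R, null_Rs=valid_nulls,
                             perm_p=perm_p, n_perm=n_perm, n_valid=n_valid,
                             valid=True)


def classify_significance(cv: CVResult, p_threshold: float = 0.05) -> bool:
    """A model is significant iff it is valid, R > 0 and p < threshold.

    The explicit positive-R requirement encodes "a relatively high
    correlation coefficient": a model whose predictions anticorrelate with
    the truth has no predictive value regardless of its p-value.
    """
    if not cv.valid or np.isnan(cv.R):
        return False
    return bool(cv.R > 0 and cv.p < p_threshold)
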