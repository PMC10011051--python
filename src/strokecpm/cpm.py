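"""Connectome-based predictive modeling: edge selection and pooled regression.

The procedure, for N subjects with M-node connectomes and a behavior score
b_k per subject:

1. For every edge (i, j), correlate its connectivity c_ij across subjects
   with the behavior array, giving r_ij and the two-sided p-value p_ij of
   the standard Pearson t-test with N - 2 degrees of freedom.
2. Build a binary pos-edge mask (r_ij > 0 and p_ij <= alpha) and a neg-edge
   mask (r_ij < 0 and p_ij <= alpha); everything else is 0.
3. Pool each subject's connectivity over the masked edges into a single
   network-strength score s_k (each undirected edge counted once).
4. Fit ordinary least squares of behavior on pooled connectivity, per
   polarity, giving a one-predictor linear model usable for out-of-sample
   prediction.

The scikit-learn estimator :class:`CPMRegressor` packages steps 1-4 as a
single fit/predict regressor; the module-level functions expose each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .connectome import (
    SubjectConnectome,
    matrix_from_edges,
    vectorize_edges,
)
from .preprocess import FilterSpec, clean
from .connectome import compute_connectivity

__all__ = [
    "BehaviorArray",
    "EdgeStatMaps",
    "EdgeMask",
    "CPMModel",
    "CPMRegressor",
    "ConnectivityTransformer",
    "edgewise_correlation",
    "select_edges",
    "pool_connectivity",
    "fit_model",
    "predict",
]

MEASURE_RANGES = {"mRS": (0, 6), "BI": (0, 100)}


@dataclass
class BehaviorArray:
    """Functional assessment scores b_k for one measure at one stage."""

    subject_ids: list[str]
    scores: np.ndarray
    measure: Literal["mRS", "BI"] = "mRS"
    stage: int = 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if len(self.subject_ids) != self.scores.size:
            raise ValueError("subject_ids and scores length mismatch")
        lo, hi = MEASURE_RANGES[self.measure]
        if self.scores.size and (self.scores.min() < lo or self.scores.max() > hi):
            raise ValueError(
                f"{self.measure} scores must lie in [{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class EdgeStatMaps:
    """Edge-wise behavior correlations r_ij and p-values p_ij (both M x M)."""

    r: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.shape != self.p.shape or self.r.ndim != 2:
            raise ValueError("r and p must be equal-shaped square matrices")
        np.fill_diagonal(self.r, 0.0)
        np.fill_diagonal(self.p, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class EdgeMask:
    """Binary M x M matrix labeling the selected edges of one polarity."""

    mask: np.ndarray
    polarity: Literal["pos", "neg"]
    alpha: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("mask must be symmetric")
        m = (m != 0).astype(np.uint8)
        np.fill_diagonal(m, 0)
        self.mask = m
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.mask.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of selected undirected edges (upper-triangle count)."""
        return int(vectorize_edges(self.mask).sum())

    @property
    def is_empty(self) -> bool:
        return self.n_edges == 0

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.mask, k=1))
        return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class CPMModel:
    """Fitted per-polarity linear model: behavior ~ intercept + slope * s_k.

    ``degenerate`` is set when the mask was empty or the pooled scores were
    constant; such a model predicts the training mean.
    """

    slope: float
    intercept: float
    polarity: Literal["pos", "neg"]
    mask: EdgeMask
    training_r: float
    training_mean: float
    degenerate: bool = False

    def predict(self, connectome: SubjectConnectome | np.ndarray) -> float:
        matrix = getattr(connectome, "matrix", connectome)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != self.mask.mask.shape:
            raise ValueError(
                f"connectome shape {matrix.shape} does not match mask "
                f"{self.mask.mask.shape}"
            )
        if self.degenerate:
            warnings.warn("degenerate CPM model: returning training mean",
                          RuntimeWarning, stacklevel=2)
            return float(self.training_mean)
        return float(self.intercept + self.slope * pool_connectivity(matrix, self.mask))


# --------------------------------------------------------------------------
# Vectorised Pearson over columns -- shared with the cross-validation core.

def pearson_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of each column of ``x`` against ``y``.

    Zero-variance columns get (r=0, p=1).  p comes from the exact t
    transform with n - 2 degrees of freedom; |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if x.shape[0] != n:
        raise ValueError("x rows must match y length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("behavior array is constant; correlation undefined")

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / denom
    r = np.where(denom == 0, 0.0, r)
    r = np.clip(r, -1.0, 1.0)

    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(denom == 0, 1.0, p)
    return r, p


def _stack_connectomes(connectomes) -> np.ndarray:
    """(N, E) upper-triangle edge matrix from a list/stack of connectomes."""
    if isinstance(connectomes, np.ndarray) and connectomes.ndim == 2:
        return connectomes
    mats = [np.asarray(getattr(c, "matrix", c), dtype=float) for c in connectomes]
    return np.stack([vectorize_edges(m) for m in mats])


def edgewise_correlation(
    connectomes: Sequence[SubjectConnectome], behavior: BehaviorArray
) -> EdgeStatMaps:
    """Correlate every edge's connectivity with behavior across subjects.

    Subject order must be aligned between ``connectomes`` and ``behavior``.
    """
    scores = np.asarray(getattr(behavior, "scores", behavior), dtype=float)
    mats = [np.asarray(getattr(c, "matrix", c), dtype=float) for c in connectomes]
    if len(mats) != scores.size:
        raise ValueError("number of connectomes must match behavior length")
    n_nodes = mats[0].shape[0]
    x = np.stack([vectorize_edges(m) for m in mats])
    r, p = pearson_columns(x, scores)
    return EdgeStatMaps(r=matrix_from_edges(r, n_nodes),
                        p=matrix_from_edges(p, n_nodes) + np.eye(n_nodes))


def select_edges(stats_: EdgeStatMaps, alpha: float = 0.05,
                 polarity: Literal["pos", "neg"] = "pos") -> EdgeMask:
    """Threshold the stat maps into a binary mask of one polarity.

    pos: r_ij > 0 and p_ij <= alpha; neg: r_ij < 0 and p_ij <= alpha.
    An empty mask is legal output.
    """
    if not (0 < alpha < 1):
        # alpha == 1 selects every non-tied edge; allow it only via EdgeMask
        if alpha != 1.0:
            raise ValueError("alpha must lie in (0, 1]")
    if polarity == "pos":
        sel = (stats_.r > 0) & (stats_.p <= alpha)
    elif polarity == "neg":
        sel = (stats_.r < 0) & (stats_.p <= alpha)
    else:
        raise ValueError(f"unknown polarity: {polarity!r}")
    return EdgeMask(mask=sel.astype(np.uint8), polarity=polarity, alpha=alpha)


def pool_connectivity(connectome, mask: EdgeMask) -> float:
    """Network strength s_k: sum of c_ij over the selected edges.

    Each undirected edge contributes once (upper-triangle summation).  A
    full symmetric inner product would count every edge twice and simply
    halve the regression slope; single counting is the cleaner contract and
    leaves correlations, p-values and predictions identical.
    """
    matrix = np.asarray(getattr(connectome, "matrix", connectome), dtype=float)
    if matrix.shape != mask.mask.shape:
        raise ValueError("connectome and mask shapes differ")
    triu = np.triu(mask.mask, k=1).astype(bool)
    return float(matrix[triu].sum())


def fit_model(pooled: np.ndarray, behavior, mask: EdgeMask,
              polarity: Literal["pos", "neg"] | None = None) -> CPMModel:
    """OLS of behavior on pooled connectivity (one slope, one intercept)."""
    s = np.asarray(pooled, dtype=float).ravel()
    b = np.asarray(getattr(behavior, "scores", behavior), dtype=float).ravel()
    if s.size != b.size:
        raise ValueError("pooled and behavior lengths differ")
    if s.size < 3:
        raise ValueError("need at least 3 subjects to fit")
    polarity = polarity or mask.polarity
    mean_b = float(b.mean())
    if mask.is_empty or np.ptp(s) == 0:
        warnings.warn("constant pooled connectivity: degenerate CPM model",
                      RuntimeWarning, stacklevel=2)
        return CPMModel(slope=0.0, intercept=mean_b, polarity=polarity,
                        mask=mask, training_r=0.0, training_mean=mean_b,
                        degenerate=True)
    slope, intercept, r, _, _ = stats.linregress(s, b)
    return CPMModel(slope=float(slope), intercept=float(intercept),
                    polarity=polarity, mask=mask, training_r=float(r),
                    training_mean=mean_b, degenerate=False)


def predict(model: CPMModel, connectome) -> float:
    """Raw regression prediction for one subject (not clamped to the scale)."""
    return model.predict(connectome)


# --------------------------------------------------------------------------
# scikit-learn estimators


class CPMRegressor(RegressorMixin, BaseEstimator):
    """Connectome-based predictive model as a scikit-learn regressor.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level of the edge-selection Pearson test.
    polarity : {"pos", "neg"}, default "pos"
        Keep edges whose connectivity correlates positively (negatively)
        with the behavior score.

    The design matrix ``X`` may be an (N, M, M) stack of symmetric
    connectivity matrices, a list of :class:`SubjectConnectome`, or an
    (N, E) matrix of upper-triangle edge values (E = M(M-1)/2).

    Attributes
    ----------
    r_, p_ : ndarray of shape (E,)
        Edge-wise behavior correlations and p-values on the training data.
    mask_edges_ : ndarray of bool, shape (E,)
        Selected edges in upper-triangle order.
    slope_, intercept_, training_r_ : float
        The fitted one-predictor linear model and its training correlation.
    degenerate_ : bool
        True when no edge survived selection; prediction then falls back to
        the training mean.
    """

    def __init__(self, alpha: float = 0.05, polarity: str = "pos"):
        self.alpha = alpha
        self.polarity = polarity

    def _validate_X(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            x = np.stack([vectorize_edges(m) for m in X])
            self._n_nodes = X.shape[1]
        elif isinstance(X, (list, tuple)):
            mats = [np.asarray(getattr(c, "matrix", c), dtype=float) for c in X]
            if mats and mats[0].ndim == 2 and mats[0].shape[0] == mats[0].shape[1]:
                self._n_nodes = mats[0].shape[0]
                x = np.stack([vectorize_edges(m) for m in mats])
            else:
                x = np.stack([m.ravel() for m in mats])
                self._n_nodes = None
        else:
            x = np.asarray(X, dtype=float)
            if x.ndim != 2:
                raise ValueError("X must be (N, E) or (N, M, M)")
            self._n_nodes = None
        if not np.isfinite(x).all():
            raise ValueError("X contains non-finite values")
        return x

    def fit(self, X, y):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.polarity not in ("pos", "neg"):
            raise ValueError("polarity must be 'pos' or 'neg'")
        x = self._validate_X(X)
        y = np.asarray(getattr(y, "scores", y), dtype=float).ravel()
        if y.size != x.shape[0]:
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = x.shape[1]
        self.n_nodes_ = self._n_nodes

        self.r_, self.p_ = pearson_columns(x, y)
        if self.polarity == "pos":
            self.mask_edges_ = (self.r_ > 0) & (self.p_ <= self.alpha)
        else:
            self.mask_edges_ = (self.r_ < 0) & (self.p_ <= self.alpha)

        pooled = x[:, self.mask_edges_].sum(axis=1)
        self.training_mean_ = float(y.mean())
        if not self.mask_edges_.any() or np.ptp(pooled) == 0:
            self.degenerate_ = True
            self.slope_, self.intercept_ = 0.0, self.training_mean_
            self.training_r_ = 0.0
        else:
            self.degenerate_ = False
            slope, intercept, r, _, _ = stats.linregress(pooled, y)
            self.slope_ = float(slope)
            self.intercept_ = float(intercept)
            self.training_r_ = float(r)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "mask_edges_"):
            raise AttributeError("CPMRegressor is not fitted yet")
        x = self._validate_X(X)
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {x.shape[1]} edges, model was fitted with "
                f"{self.n_features_in_}"
            )
        if self.degenerate_:
            return np.full(x.shape[0], self.training_mean_)
        pooled = x[:, self.mask_edges_].sum(axis=1)
        return self.intercept_ + self.slope_ * pooled

    @property
    def edge_mask_(self) -> EdgeMask:
        """The selected edges as a symmetric :class:`EdgeMask` matrix."""
        if self.n_nodes_ is None:
            m = int(round((1 + np.sqrt(1 + 8 * self.n_features_in_)) / 2))
        else:
            m = self.n_nodes_
        return EdgeMask(mask=matrix_from_edges(self.mask_edges_.astype(float), m),
                        polarity=self.polarity, alpha=self.alpha)

    def to_model(self) -> CPMModel:
        """Export the fit as a standalone :class:`CPMModel`."""
        return CPMModel(slope=self.slope_, intercept=self.intercept_,
                        polarity=self.polarity, mask=self.edge_mask_,
                        training_r=self.training_r_,
                        training_mean=self.training_mean_,
                        degenerate=self.degenerate_)


class ConnectivityTransformer(TransformerMixin, BaseEstimator):
    """Turn raw ROI time series into the (N, E) edge matrix CPM consumes.

    Each sample is one subject's T x M time-series array (optionally a
    :class:`~strokecpm.timeseries.SubjectTimeseries` carrying its nuisance
    design).  ``transform`` applies the conditioning chain (detrend,
    band-pass, nuisance regression) when ``preprocess=True``, computes the
    Pearson connectome and vectorises its upper triangle, so that
    ``Pipeline([("edges", ConnectivityTransformer()), ("cpm", CPMRegressor())])``
    maps time series straight to behavior predictions.
    """

    def __init__(self, preprocess: bool = True,
                 filter_spec: FilterSpec | None = None,
                 fisher_z: bool = False):
        self.preprocess = preprocess
        self.filter_spec = filter_spec
        self.fisher_z = fisher_z

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        from .timeseries import SubjectTimeseries

        spec = self.filter_spec or FilterSpec()
        rows = []
        for sample in X:
            ts = sample if isinstance(sample, SubjectTimeseries) else \
                SubjectTimeseries("subject", np.asarray(sample, dtype=float))
            if self.preprocess:
                ts = clean(ts, spec)
            conn = compute_connectivity(ts, fisher_z=self.fisher_z)
            rows.append(vectorize_edges(conn.matrix))
        return np.stack(rows)
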