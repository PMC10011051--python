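"""Subject-level functional connectivity matrices and edge bookkeeping.

A connectome here is the M x M matrix of pairwise Pearson correlations
between ROI BOLD time series (element ``c_ij`` = functional connectivity of
nodes i and j).  Edge sets are canonically stored over the upper triangle
(i < j, 0-based); symmetric matrices are the I/O representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectConnectome",
    "compute_connectivity",
    "edge_count",
    "edge_list",
    "vectorize_edges",
    "matrix_from_edges",
    "read_matrix",
    "write_matrix",
]


@dataclass
class SubjectConnectome:
    """One subject's symmetric functional-connectivity matrix, zero diagonal."""

    subject_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {m.shape}")
        if not np.isfinite(m).all():
            raise ValueError("connectivity matrix contains non-finite values")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def edge_count(m: int) -> int:
    """Number of distinct undirected edges among m nodes: (m^2 - m) / 2."""
    if m < 1:
        raise ValueError("need at least one node")
    return (m * m - m) // 2


def edge_list(m: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle edge ordering: (0,1), (0,2), ..., (m-2,m-1)."""
    if m < 2:
        raise ValueError("need at least two nodes to have edges")
    iu, ju = np.triu_indices(m, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize_edges(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle entries of a square matrix in edge_list order."""
    m = np.asarray(matrix)
    iu, ju = np.triu_indices(m.shape[-1], k=1)
    return m[..., iu, ju]


def matrix_from_edges(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from edge-ordered values."""
    values = np.asarray(values)
    if values.shape[-1] != edge_count(n_nodes):
        raise ValueError(
            f"expected {edge_count(n_nodes)} edge values, got {values.shape[-1]}"
        )
    iu, ju = np.triu_indices(n_nodes, k=1)
    out = np.zeros(values.shape[:-1] + (n_nodes, n_nodes), dtype=float)
    out[..., iu, ju] = values
    out[..., ju, iu] = values
    return out


def compute_connectivity(
    ts, fisher_z: bool = False, subject_id: str | None = None
) -> SubjectConnectome:
    """Pearson-correlation connectome of one subject's T x M time series.

    Zero-variance node series would make correlations undefined; their edges
    are set to 0 (with a warning) rather than propagating NaN.  With
    ``fisher_z`` the off-diagonal correlations are atanh-transformed
    (clipped at |r| = 1 - 1e-7 to stay finite).
    """
    data = np.asarray(getattr(ts, "data", ts), dtype=float)
    if subject_id is None:
        subject_id = getattr(ts, "subject_id", "subject")
    if data.ndim != 2:
        raise ValueError("time series must be a T x M matrix")
    t, m = data.shape
    if t < 3:
        raise ValueError("need at least 3 time points for correlation")

    sd = data.std(axis=0)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    if dead.any():
        cols = np.flatnonzero(dead).tolist()
        logger.warning(
            "subject %s: zero-variance node columns %s; their edges set to 0",
            subject_id, cols,
        )
        warnings.warn(
            f"subject {subject_id}: zero-variance node columns {cols}; "
            "edges set to 0", RuntimeWarning, stacklevel=2,
        )
        corr[dead, :] = 0.0
        corr[:, dead] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    if fisher_z:
        corr = np.arctanh(np.clip(corr, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(corr, 0.0)
    return SubjectConnectome(subject_id=subject_id, matrix=corr)


def write_matrix(matrix: np.ndarray, path: str | Path, delimiter: str = "\t") -> None:
    """Write an M x M matrix as headerless delimited text.

    The format doubles as the BrainNet Viewer ``.edge`` dialect when the
    delimiter is whitespace.
    """
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g",
               delimiter=delimiter)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a headerless whitespace- or comma-delimited square matrix."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    m = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {m.shape}")
    return m
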