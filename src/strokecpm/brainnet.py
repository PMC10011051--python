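"""Consensus edges across CV folds and BrainNet Viewer ball-and-stick export.

Each LOOCV fold selects its own edge mask; the edges worth drawing are the
ones selected in most folds.  The consensus set is exported in the BrainNet
Viewer text dialects: a ``.node`` file (one row per ball: x y z color size
label) and a ``.edge`` file (the full M x M adjacency, whitespace-delimited).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atlas import Atlas
from .connectome import vectorize_edges, matrix_from_edges
from .cpm import EdgeMask

__all__ = ["ConsensusEdgeSet", "edge_consensus", "write_brainnet",
           "read_edge_matrix"]


@dataclass
class ConsensusEdgeSet:
    """Edges retained across folds with their fold frequency.

    ``edges`` is sorted by frequency (descending), ties broken by (i, j);
    every retained edge satisfies frequency >= threshold_used (or ranks in
    the top-k when built in top-k mode).
    """

    edges: list[tuple[int, int, float]]
    threshold_used: float
    n_nodes: int
    polarity: str | None = None
    atlas: Atlas | None = None

    def __len__(self) -> int:
        return len(self.edges)

    def adjacency(self, weighted: bool = True) -> np.ndarray:
        """Symmetric M x M matrix of fold frequencies (or 0/1 if unweighted)."""
        out = np.zeros((self.n_nodes, self.n_nodes))
        for i, j, freq in self.edges:
            w = freq if weighted else 1.0
            out[i, j] = out[j, i] = w
        return out

    def nodes(self) -> list[int]:
        """Sorted node indices incident to at least one retained edge."""
        seen: set[int] = set()
        for i, j, _ in self.edges:
            seen.update((i, j))
        return sorted(seen)


def _fold_frequencies(fold_masks: list[EdgeMask]) -> tuple[np.ndarray, int]:
    if len(fold_masks) < 2:
        raise ValueError("need at least 2 fold masks for a consensus")
    shapes = {m.mask.shape for m in fold_masks}
    if len(shapes) != 1:
        raise ValueError("fold masks differ in shape")
    pols = {m.polarity for m in fold_masks}
    if len(pols) != 1:
        raise ValueError("fold masks differ in polarity")
    n_nodes = fold_masks[0].n_nodes
    stack = np.stack([vectorize_edges(m.mask) for m in fold_masks])
    return stack.mean(axis=0), n_nodes


def _build(freq: np.ndarray, keep: np.ndarray, n_nodes: int,
           threshold: float, polarity: str | None,
           atlas: Atlas | None) -> ConsensusEdgeSet:
    iu, ju = np.triu_indices(n_nodes, k=1)
    rows = [(int(i), int(j), float(f))
            for i, j, f, k in zip(iu, ju, freq, keep) if k]
    rows.sort(key=lambda e: (-e[2], e[0], e[1]))
    return ConsensusEdgeSet(edges=rows, threshold_used=threshold,
                            n_nodes=n_nodes, polarity=polarity, atlas=atlas)


def edge_consensus(fold_masks: list[EdgeMask], threshold: float = 0.9,
                   atlas: Atlas | None = None) -> ConsensusEdgeSet:
    """Edges selected in at least ``threshold`` fraction of folds."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    freq, n_nodes = _fold_frequencies(fold_masks)
    return _build(freq, freq >= threshold, n_nodes, threshold,
                  fold_masks[0].polarity, atlas)


def top_k_consensus(fold_masks: list[EdgeMask], k: int = 20,
                    atlas: Atlas | None = None) -> ConsensusEdgeSet:
    """The k most frequently selected edges (fewer if fewer ever appear)."""
    if k < 1:
        raise ValueError("k must be positive")
    freq, n_nodes = _fold_frequencies(fold_masks)
    present = freq > 0
    order = np.argsort(-freq, kind="stable")
    keep = np.zeros_like(present)
    keep[order[:k]] = True
    keep &= present
    threshold = float(freq[keep].min()) if keep.any() else 1.0
    return _build(freq, keep, n_nodes, threshold,
                  fold_masks[0].polarity, atlas)


def write_brainnet(consensus: ConsensusEdgeSet, node_path: str | Path,
                   edge_path: str | Path, weighted: bool = True) -> None:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files.

    The ``.node`` file lists only nodes incident to a retained edge, six
    whitespace-delimited columns per row: x y z color size label.  Color is
    1 for every node; size is the node's degree within the consensus.  The
    ``.edge`` file is the full M x M adjacency (fold frequencies, or 0/1
    when ``weighted=False``).
    """
    atlas = consensus.atlas
    incident = consensus.nodes()
    if incident:
        if atlas is None or atlas.coordinates is None:
            raise ValueError("consensus atlas with coordinates required for export")
        for node in incident:
            if node >= atlas.n_nodes:
                raise ValueError(f"node {node} has no atlas coordinates")

    adjacency = consensus.adjacency(weighted=weighted)
    degree = (adjacency > 0).sum(axis=0)

    lines = []
    for node in incident:
        x, y, z = atlas.coordinates[node]
        label = atlas.abbreviation(node)
        lines.append(f"{x:g}\t{y:g}\t{z:g}\t1\t{int(degree[node])}\t{label}")
    Path(node_path).write_text("\n".join(lines) + ("\n" if lines else ""))

    np.savetxt(edge_path, adjacency, fmt="%.6g", delimiter="\t")


def read_edge_matrix(path: str | Path) -> np.ndarray:
    """Read a BrainNet ``.edge`` file back into a symmetric matrix."""
    m = np.loadtxt(path, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: .edge matrix must be square, got {m.shape}")
    return m
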