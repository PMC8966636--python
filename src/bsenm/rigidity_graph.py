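"""Residue rigidity graphs: aggregate site springs into k_IJ coupling matrices.

Each spring whose two sites lie in different residues I ≠ J contributes its
spring constant to exactly one of three category matrices, depending on the
site kinds it connects: backbone–backbone (BB), backbone–side chain (BS, both
orientations summed into one symmetric matrix), or side chain–side chain (SS).
To keep the graphs non-covalent, BB couplings between peptide-bond neighbours
(sequence separation ≤ 1 by default) and SS couplings across declared
disulfide bonds are forced to zero.  The degree of residue I is the row sum
d_I = Σ_J k_IJ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluctuation_matching import SpringNetwork

CATEGORIES = ("BB", "BS", "SS")


@dataclass
class RigidityGraph:
    """Symmetric, non-negative, zero-diagonal residue coupling matrix."""

    category: str
    k_matrix: np.ndarray
    window_index: int | str = "mean"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        self.k_matrix = np.asarray(self.k_matrix, dtype=float)
        n = self.k_matrix.shape[0]
        if self.k_matrix.shape != (n, n):
            raise ValueError("k_matrix must be square")
        if not np.allclose(self.k_matrix, self.k_matrix.T):
            raise ValueError("k_matrix must be symmetric")
        if np.any(self.k_matrix < 0):
            raise ValueError("couplings must be non-negative")
        if np.any(np.diagonal(self.k_matrix) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_residues(self) -> int:
        return self.k_matrix.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return graph_degrees(self)


def graph_degrees(graph: RigidityGraph) -> np.ndarray:
    """Per-residue degree d_I = Σ_J k_IJ (row sums)."""
    return graph.k_matrix.sum(axis=1)


def residue_coupling_matrix(
    network: SpringNetwork,
    category: str,
    window_index: int | str = 0,
    bb_exclusion_sep: int = 1,
) -> RigidityGraph:
    """Aggregate a spring network into the residue coupling matrix of one category.

    ``bb_exclusion_sep`` zeroes BB couplings up to that sequence separation
    (default 1: peptide-bond neighbours, the covalent inter-residue link of a
    two-bead model).  SS couplings across the topology's disulfide pairs are
    always zeroed.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r} (expected one of {CATEGORIES})")
    topo = network.topology
    n = topo.n_residues
    K = np.zeros((n, n))
    res = topo.site_residue[network.pairs]
    bb = topo.site_is_backbone[network.pairs]
    inter = res[:, 0] != res[:, 1]
    if category == "BB":
        match = bb[:, 0] & bb[:, 1]
    elif category == "SS":
        match = ~bb[:, 0] & ~bb[:, 1]
    else:  # BS — either orientation
        match = bb[:, 0] ^ bb[:, 1]
    sel = inter & match
    np.add.at(K, (res[sel, 0], res[sel, 1]), network.k[sel])
    K = K + K.T

    if category == "BB" and bb_exclusion_sep >= 1:
        for sep in range(1, bb_exclusion_sep + 1):
            idx = np.arange(n - sep)
            K[idx, idx + sep] = 0.0
            K[idx + sep, idx] = 0.0
    if category == "SS":
        for i, j in topo.disulfide_pairs:
            K[i, j] = 0.0
            K[j, i] = 0.0
    return RigidityGraph(category=category, k_matrix=K, window_index=window_index)


def mean_rigidity_graph(graphs: list[RigidityGraph]) -> RigidityGraph:
    """Elementwise arithmetic mean over window graphs of one category."""
    if not graphs:
        raise ValueError("need at least one graph")
    cat = graphs[0].category
    n = graphs[0].n_residues
    for g in graphs[1:]:
        if g.category != cat:
            raise ValueError("cannot average graphs of different categories")
        if g.n_residues != n:
            raise ValueError("cannot average graphs of different dimensions")
    mean = np.mean([g.k_matrix for g in graphs], axis=0)
    return RigidityGraph(category=cat, k_matrix=mean, window_index="mean")
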