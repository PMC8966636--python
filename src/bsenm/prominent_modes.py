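"""Spectral analysis of mean rigidity graphs: prominent modes and coupled pairs.

The mean rigidity graph of a category is eigendecomposed, and each mean mode
α is scored for persistence through thermal noise by its *mean-mode content*
in every window n,

    r_nα = max_β |ν_nβ · ν_α| ,

the largest absolute overlap with any eigenvector of window n's graph;
averaging over windows gives ⟨r_α⟩.  A mode is *prominent* when it is both
mechanically strong — its eigenvalue is a statistical outlier of the λ
distribution (Tukey rule, λ > Q3 + 1.5·IQR) — and persistent — ⟨r_α⟩ exceeds
the quantile, at a CDF cutoff, of a normal distribution fitted to the ⟨r_α⟩
values.  Residues carrying squared eigenvector weight ≥ ν_c² (default 0.1) in
a prominent mode, and directly coupled in the mean graph, form the list of
strongly coupled residue pairs {IJ}_Π.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .rigidity_graph import RigidityGraph

NU_C_SQ_DEFAULT = 0.1  # squared eigenvector weight cutoff ν_c²


def eigendecompose(matrix: np.ndarray, sym_tol: float = 1e-8):
    """Eigenvalues (descending) and orthonormal eigenvectors (columns).

    Sign convention: the largest-magnitude component of each eigenvector is
    made positive (first such index on ties), so repeated runs and different
    LAPACK paths yield identical output.
    """
    matrix = np.asarray(matrix, dtype=float)
    scale = max(1.0, np.abs(matrix).max())
    if np.abs(matrix - matrix.T).max() > sym_tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    w, V = np.linalg.eigh((matrix + matrix.T) / 2.0)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    for c in range(V.shape[1]):
        lead = np.argmax(np.abs(V[:, c]))
        if V[lead, c] < 0:
            V[:, c] = -V[:, c]
    return w, V


def mean_mode_content(window_eigenvectors: list[np.ndarray], mean_eigenvectors: np.ndarray):
    """(r_nα, ⟨r_α⟩): per-window and window-averaged mean-mode contents.

    Invariant to sign flips and reordering of the window eigenvectors (the
    max over β absorbs both).
    """
    M = np.asarray(mean_eigenvectors, dtype=float)
    r = np.empty((len(window_eigenvectors), M.shape[1]))
    for n, W in enumerate(window_eigenvectors):
        W = np.asarray(W, dtype=float)
        if W.shape != M.shape:
            raise ValueError("window eigenvector set has mismatched dimensions")
        r[n] = np.abs(W.T @ M).max(axis=0)
    r = np.clip(r, 0.0, 1.0)
    return r, r.mean(axis=0)


@dataclass
class ModeSet:
    """Eigenpairs of a mean rigidity graph plus per-window persistence scores."""

    category: str
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, orthonormal
    window_eigenvalues: list[np.ndarray] = field(default_factory=list)
    window_eigenvectors: list[np.ndarray] = field(default_factory=list)
    content: np.ndarray | None = None  # r_nα, (n_windows, n_modes)
    avg_content: np.ndarray | None = None  # ⟨r_α⟩

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def build_mode_set(
    mean_graph: RigidityGraph, window_graphs: list[RigidityGraph]
) -> ModeSet:
    """Decompose the mean graph and score each mean mode's persistence."""
    w, V = eigendecompose(mean_graph.k_matrix)
    wws, wvs = [], []
    for g in window_graphs:
        ww, wv = eigendecompose(g.k_matrix)
        wws.append(ww)
        wvs.append(wv)
    ms = ModeSet(
        category=mean_graph.category,
        eigenvalues=w,
        eigenvectors=V,
        window_eigenvalues=wws,
        window_eigenvectors=wvs,
    )
    if wvs:
        ms.content, ms.avg_content = mean_mode_content(wvs, V)
    return ms


@dataclass
class ProminentModeSelection:
    """The prominent set Π = strong ∩ persistent, with the thresholds used."""

    mode_indices: list[int]
    eigenvalue_threshold: float
    content_threshold: float
    strong: list[int]
    persistent: list[int]

    def __post_init__(self):
        assert set(self.mode_indices) == set(self.strong) & set(self.persistent)


def select_prominent_modes(
    mode_set: ModeSet, cdf_cutoff: float = 0.8
) -> ProminentModeSelection:
    """Intersect eigenvalue outliers with highly persistent modes.

    Strong: λ_α > Q3 + 1.5·IQR of the eigenvalue distribution.  Persistent:
    ⟨r_α⟩ > the ``cdf_cutoff`` quantile of a normal distribution fitted
    (mean, sd) to the ⟨r_α⟩ values.  Degenerate distributions (zero IQR and
    zero sd) yield an empty Π with a warning.
    """
    if mode_set.n_modes < 3:
        raise ValueError("need at least 3 modes")
    if mode_set.avg_content is None:
        raise ValueError("mode set carries no persistence scores (no windows)")
    lam = mode_set.eigenvalues
    q1, q3 = np.percentile(lam, [25, 75])
    lam_thr = q3 + 1.5 * (q3 - q1)
    strong = np.flatnonzero(lam > lam_thr)

    avg = mode_set.avg_content
    mu, sd = float(avg.mean()), float(avg.std())
    if sd > 0:
        r_thr = float(norm.ppf(cdf_cutoff, loc=mu, scale=sd))
    else:
        r_thr = mu  # all equal: nothing exceeds strictly
    persistent = np.flatnonzero(avg > r_thr)

    if (q3 - q1) == 0 and sd == 0:
        warnings.warn(
            "degenerate eigenvalue and persistence distributions: empty Π",
            stacklevel=2,
        )
    prominent = sorted(set(strong.tolist()) & set(persistent.tolist()))
    return ProminentModeSelection(
        mode_indices=prominent,
        eigenvalue_threshold=float(lam_thr),
        content_threshold=r_thr,
        strong=strong.tolist(),
        persistent=persistent.tolist(),
    )


@dataclass
class CoupledPairList:
    """Strongly coupled residue pairs {IJ}_Π of one category and state."""

    pairs: list[tuple[int, int]]  # I < J, sorted
    source_modes: dict  # pair -> list of contributing mode indices
    category: str
    state_label: str = ""
    nu_c_sq: float = NU_C_SQ_DEFAULT


def strongly_coupled_pairs(
    selection: ProminentModeSelection,
    mode_set: ModeSet,
    mean_graph: RigidityGraph,
    nu_c_sq: float = NU_C_SQ_DEFAULT,
    state_label: str = "",
) -> CoupledPairList:
    """Residue pairs with weight ν²_α ≥ ν_c² in some α ∈ Π and k̄_IJ > 0."""
    if not 0 < nu_c_sq < 1:
        raise ValueError("nu_c_sq must lie in (0, 1)")
    K = mean_graph.k_matrix
    source: dict[tuple[int, int], list[int]] = {}
    for a in selection.mode_indices:
        wsq = mode_set.eigenvectors[:, a] ** 2
        residues = np.flatnonzero(wsq >= nu_c_sq)
        for x in range(len(residues)):
            for y in range(x + 1, len(residues)):
                I, J = int(residues[x]), int(residues[y])
                if K[I, J] > 0:
                    source.setdefault((I, J), []).append(a)
    pairs = sorted(source)
    return CoupledPairList(
        pairs=pairs,
        source_modes=source,
        category=mean_graph.category,
        state_label=state_label,
        nu_c_sq=nu_c_sq,
    )
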