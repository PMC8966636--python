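"""Self-consistent fluctuation matching: learn spring constants per window.

The ensemble is split into overlapping windows.  Within a window, each spring
(i, j) gets an equilibrium length l0 equal to the window-mean inter-site
distance, and a spring constant k_ij adjusted iteratively so that the
bond-length variance predicted by normal-mode analysis of the elastic network,
⟨δl²⟩_NMA, matches the variance observed in the ensemble, ⟨δl²⟩_AA.

The predicted variance comes from the equilibrium covariance of the harmonic
network, C = k_B·T·H⁺ (pseudo-inverse over non-rigid-body modes), projected on
the reference bond direction — the equipartition result k_B·T/k for an
isolated spring.  The update is multiplicative,

    k′ = k · (⟨δl²⟩_NMA / ⟨δl²⟩_AA)^α ,

whose fixed point is exact variance match; for an isolated spring one step at
α = 1 lands on k = k_B·T/⟨δl²⟩_AA exactly.

Units: kcal mol⁻¹, Å, K; k_B = 0.0019872 kcal mol⁻¹ K⁻¹.  Masses never enter:
the equal-time covariance of a harmonic system is mass-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .cg_model import CGEnsemble, CGTopology, check_connected, pair_distances

KB = 0.0019872  # kcal mol^-1 K^-1

#: eigenvalues below RIGID_TOL × (largest eigenvalue) are treated as the
#: rigid-body null space of the Hessian
RIGID_TOL = 1e-8


@dataclass
class SpringNetwork:
    """A fitted (or ground-truth) backbone/side-chain elastic network."""

    topology: CGTopology
    pairs: np.ndarray  # (m, 2) int, i < j, sorted, duplicate-free
    k: np.ndarray  # (m,) kcal mol^-1 Å^-2, ≥ 0
    l0: np.ndarray  # (m,) Å, > 0
    reference_positions: np.ndarray  # (n_sites, 3) Å
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.k = np.asarray(self.k, dtype=float)
        self.l0 = np.asarray(self.l0, dtype=float)
        self.reference_positions = np.asarray(self.reference_positions, dtype=float)
        m = self.pairs.shape[0]
        if self.k.shape != (m,) or self.l0.shape != (m,):
            raise ValueError("k and l0 must have one entry per pair")
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        if len({tuple(p) for p in self.pairs.tolist()}) != m:
            raise ValueError("duplicate pairs")
        if np.any(self.k < 0):
            raise ValueError("spring constants must be non-negative")
        if np.any(self.l0 <= 0):
            raise ValueError("equilibrium lengths must be positive")
        if self.reference_positions.shape != (self.topology.n_sites, 3):
            raise ValueError("reference_positions shape mismatch")

    @property
    def n_sites(self) -> int:
        return self.topology.n_sites

    def reference_lengths(self) -> np.ndarray:
        d = (
            self.reference_positions[self.pairs[:, 0]]
            - self.reference_positions[self.pairs[:, 1]]
        )
        return np.linalg.norm(d, axis=1)


@dataclass
class WindowStats:
    """Per-pair distance statistics of one trajectory window."""

    window_index: int
    pairs: np.ndarray
    mean_length: np.ndarray  # ⟨l_ij⟩, Å — the window's l0
    var_aa: np.ndarray  # ⟨δl_ij²⟩ observed, Å²  (population variance)
    n_frames: int


@dataclass
class FitSettings:
    """Knobs of the self-consistent iteration."""

    alpha: float = 0.3  # learning rate, (0, 1]
    tol: float = 1e-3  # max relative variance mismatch at convergence
    max_iter: int = 200
    temperature: float = 300.0  # K
    k_init: float = 1.0  # kcal mol^-1 Å^-2
    k_min: float = 1e-6  # floor keeping k positive
    zero_var_k: float | None = 1e3  # k assigned to zero-variance pairs; None → error

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tol <= 0 or self.temperature <= 0 or self.k_min <= 0:
            raise ValueError("tol, temperature and k_min must be positive")


# ---------------------------------------------------------------------------
# Windowing and observed statistics
# ---------------------------------------------------------------------------


def split_windows(
    ensemble: CGEnsemble, window_frames: int, stride_frames: int
) -> list[CGEnsemble]:
    """Overlapping windows; a trailing partial window is dropped."""
    if not 0 < stride_frames <= window_frames:
        raise ValueError("need 0 < stride_frames <= window_frames")
    if ensemble.n_frames < window_frames:
        raise ValueError(
            f"ensemble has {ensemble.n_frames} frames < window of {window_frames}"
        )
    out = []
    for lo in range(0, ensemble.n_frames - window_frames + 1, stride_frames):
        out.append(
            CGEnsemble(
                ensemble.topology,
                ensemble.frames[lo : lo + window_frames],
                frame_spacing=ensemble.frame_spacing,
            )
        )
    return out


def window_stats(window: CGEnsemble, pairs, window_index: int = 0) -> WindowStats:
    """Mean length and population variance of every pair's distance series."""
    if window.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuation statistics")
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    d = pair_distances(window.frames, pairs)
    return WindowStats(
        window_index=window_index,
        pairs=pairs,
        mean_length=d.mean(axis=0),
        var_aa=d.var(axis=0),  # population variance (ddof=0)
        n_frames=window.n_frames,
    )


# ---------------------------------------------------------------------------
# Normal-mode covariance of the elastic network
# ---------------------------------------------------------------------------


def enm_hessian(positions: np.ndarray, pairs: np.ndarray, k: np.ndarray) -> np.ndarray:
    """3N×3N Hessian of Σ ½k_ij(l_ij − l0_ij)² at the reference geometry.

    At the reference geometry each spring contributes k·êêᵀ blocks along its
    unit separation vector ê (the transverse terms vanish when l = l0).
    """
    n = positions.shape[0]
    H = np.zeros((3 * n, 3 * n))
    d = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    lengths = np.linalg.norm(d, axis=1)
    if np.any(lengths == 0):
        raise ValueError("coincident sites give an undefined spring direction")
    e = d / lengths[:, None]
    for (i, j), kij, eij in zip(pairs, k, e):
        blk = kij * np.outer(eij, eij)
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += blk
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += blk
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= blk
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= blk
    return H


def _mode_decomposition(H: np.ndarray):
    """Eigenmodes of the Hessian split into rigid-body null space and the rest."""
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite Hessian")
    w, V = eigh(H)
    wmax = max(w.max(), 0.0)
    null = w <= RIGID_TOL * max(wmax, 1e-300)
    return w, V, null


def nma_pair_variances(
    network: SpringNetwork, temperature: float, warn_floppy: bool = True
) -> np.ndarray:
    """Linearized bond-length variances ⟨δl²⟩ from C = k_B·T·H⁺.

    For each spring the variance of the separation fluctuation projected on
    the reference bond direction ê is êᵀ(C_ii + C_jj − 2C_ij)ê.
    """
    if network.n_sites < 2:
        raise ValueError("need at least 2 sites")
    pos = network.reference_positions
    H = enm_hessian(pos, network.pairs, network.k)
    w, V, null = _mode_decomposition(H)
    if warn_floppy and null.sum() > 6:
        warnings.warn(
            f"{int(null.sum())} near-zero modes (> 6): floppy or disconnected network",
            stacklevel=2,
        )
    keep = ~null
    Vk = V[:, keep]
    wk = w[keep]

    d = pos[network.pairs[:, 0]] - pos[network.pairs[:, 1]]
    e = d / np.linalg.norm(d, axis=1)[:, None]
    # per-mode displacement difference across each spring, projected on ê
    Vr = Vk.reshape(network.n_sites, 3, -1)
    diff = Vr[network.pairs[:, 0]] - Vr[network.pairs[:, 1]]  # (m, 3, M)
    proj = np.einsum("pc,pcm->pm", e, diff)
    return KB * temperature * (proj**2 / wk[None, :]).sum(axis=1)


# ---------------------------------------------------------------------------
# The statistical-learning update and the per-window fit
# ---------------------------------------------------------------------------


def update_spring_constants(
    k: np.ndarray, var_nma: np.ndarray, var_aa: np.ndarray, settings: FitSettings
) -> np.ndarray:
    """One multiplicative update k′ = k·(var_NMA/var_AA)^α, clipped to ≥ k_min."""
    k = np.asarray(k, dtype=float)
    var_nma = np.asarray(var_nma, dtype=float)
    var_aa = np.asarray(var_aa, dtype=float)
    if np.any(var_aa <= 0):
        raise ValueError(
            "non-positive observed variance; zero-variance pairs must be handled "
            "by the fitting policy (FitSettings.zero_var_k)"
        )
    return np.maximum(k * (var_nma / var_aa) ** settings.alpha, settings.k_min)


def fit_window(
    window: CGEnsemble,
    pairs,
    settings: FitSettings | None = None,
    window_index: int = 0,
) -> SpringNetwork:
    """Learn spring constants for one window by self-consistent NMA matching.

    Returns a :class:`SpringNetwork` whose ``fit_info`` records convergence
    (``converged``, ``n_iter``, ``final_mismatch``, ``zero_variance_pairs``).
    Non-convergence at ``max_iter`` is reported through the flag, never
    silently.
    """
    settings = settings or FitSettings()
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    if not check_connected(window.topology.n_sites, pairs):
        raise ValueError("spring pairs do not form a connected graph over all sites")
    stats = window_stats(window, pairs, window_index=window_index)

    zero_var = stats.var_aa <= 0
    if zero_var.any() and settings.zero_var_k is None:
        raise ValueError(
            f"{int(zero_var.sum())} pairs have zero observed variance and no "
            "zero-variance policy is set"
        )
    active = ~zero_var
    if not active.any():
        raise ValueError("all pairs have zero observed variance: no finite fit")

    k = np.full(pairs.shape[0], float(settings.k_init))
    if zero_var.any():
        k[zero_var] = settings.zero_var_k

    ref_pos = window.frames.mean(axis=0)
    net = SpringNetwork(window.topology, pairs, k, stats.mean_length, ref_pos)
    converged = False
    mismatch = np.inf
    it = 0
    for it in range(1, settings.max_iter + 1):
        var_nma = nma_pair_variances(net, settings.temperature, warn_floppy=False)
        mismatch = float(
            np.max(np.abs(var_nma[active] - stats.var_aa[active]) / stats.var_aa[active])
        )
        if mismatch < settings.tol:
            converged = True
            break
        k = net.k.copy()
        k[active] = update_spring_constants(
            net.k[active], var_nma[active], stats.var_aa[active], settings
        )
        net = SpringNetwork(window.topology, pairs, k, stats.mean_length, ref_pos)

    net.fit_info = {
        "converged": converged,
        "n_iter": it,
        "final_mismatch": mismatch,
        "zero_variance_pairs": [tuple(p) for p in pairs[zero_var].tolist()],
        "settings": {
            "alpha": settings.alpha,
            "tol": settings.tol,
            "max_iter": settings.max_iter,
            "temperature": settings.temperature,
            "k_init": settings.k_init,
            "k_min": settings.k_min,
        },
        "window_index": window_index,
    }
    return net
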