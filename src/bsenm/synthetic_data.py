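"""Ground-truth spring networks and Gaussian ensembles for every pipeline stage.

The generator builds a toy backbone/side-chain elastic network over a compact
self-avoiding chain (3.8 Å backbone spacing, side-chain sites offset ~2 Å),
puts springs on all site pairs within a distance cutoff plus a sampled set of
longer-range contacts, and samples equilibrium configurational ensembles from
the exact harmonic distribution at a stated temperature — the multivariate
normal with covariance k_B·T·H⁺ over the non-rigid-body modes.  Because the
learning stage consumes only distance-fluctuation statistics, this Gaussian
ensemble makes parameter recovery a well-posed oracle without any molecular
dynamics.

The two-state benchmark emulates a reference/response binding pair on shared
geometry: the springs along a contiguous residue chain are multiplied by a
factor in the response network (the planted relay route), a few stiff "anchor"
couplings are left unchanged in both states so each state has prominent modes
of its own, and one spring is pruned and one added to exercise the on/off
machinery.  Ground truth (Δk, route, switches) is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_model import BACKBONE, SIDECHAIN, CGEnsemble, CGSite, CGTopology
from .fluctuation_matching import (
    KB,
    SpringNetwork,
    _mode_decomposition,
    enm_hessian,
)

BACKBONE_SPACING = 3.8  # Å, consecutive backbone sites
SIDECHAIN_OFFSET = 2.0  # Å, side-chain site from its backbone site
MIN_SEPARATION = 3.0  # Å, self-avoidance during chain growth
ROUTE_K_FACTOR = 12.0  # planted/anchor springs at this multiple of k_range max
ENV_K_FACTOR = 4.0  # springs around route side chains, both states (no Δk)


@dataclass
class ToyNetworkSpec:
    """Conditions of the synthetic ground-truth network."""

    n_residues: int = 30
    sidechain_fraction: float = 0.9  # probability a residue has a side chain
    contact_density: float = 2.0  # expected long-range contacts per residue
    k_range: tuple[float, float] = (0.2, 1.0)  # kcal mol^-1 Å^-2
    cutoff: float = 10.0  # Å, springs on all pairs within this distance
    seed: int = 0


@dataclass
class TwoStateBenchmark:
    """Reference/response networks with planted coupling changes and ensembles."""

    network_ref: SpringNetwork
    network_resp: SpringNetwork
    planted_changes: list  # [((I, J), factor)] residue pairs, k multiplied
    planted_route: list[int]  # ordered contiguous residue chain
    switch_off: list[tuple[int, int]] = field(default_factory=list)  # pruned in resp
    switch_on: list[tuple[int, int]] = field(default_factory=list)  # added in resp
    ensemble_ref: CGEnsemble | None = None
    ensemble_resp: CGEnsemble | None = None


def _grow_chain(n: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding walk with fixed 3.8 Å steps."""
    pos = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3) - 0.12 * pos[i - 1]
            step *= BACKBONE_SPACING / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) >= MIN_SEPARATION:
                pos[i] = cand
                break
        else:
            raise RuntimeError("chain growth failed; geometry too dense")
    return pos


def make_toy_topology(spec: ToyNetworkSpec, rng: np.random.Generator | None = None):
    """Toy CG topology plus reference site positions."""
    if spec.n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = rng or np.random.default_rng(spec.seed)
    bb = _grow_chain(spec.n_residues, rng)
    has_sc = rng.random(spec.n_residues) < spec.sidechain_fraction
    sites: list[CGSite] = []
    for r in range(spec.n_residues):
        name = "ALA" if has_sc[r] else "GLY"
        sites.append(CGSite(len(sites), r, name, BACKBONE, bb[r]))
        if has_sc[r]:
            off = rng.normal(size=3)
            off *= SIDECHAIN_OFFSET / np.linalg.norm(off)
            sites.append(CGSite(len(sites), r, name, SIDECHAIN, bb[r] + off))
    topo = CGTopology(sites=sites)
    return topo, topo.reference_positions()


def make_toy_bsenm(spec: ToyNetworkSpec) -> SpringNetwork:
    """Ground-truth network: cutoff springs + sampled long-range contacts.

    Backbone chain springs are always present, so the network is connected by
    construction; all spring constants are drawn uniformly from ``k_range``.
    Bit-reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    topo, pos = make_toy_topology(spec, rng)
    n = topo.n_sites
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    within = dist[iu, ju] <= spec.cutoff
    pair_set = {(int(i), int(j)) for i, j in zip(iu[within], ju[within])}
    # chain springs guaranteed (they are within cutoff anyway: 3.8 Å)
    for r in range(topo.n_residues - 1):
        a, b = topo.backbone_site[r], topo.backbone_site[r + 1]
        pair_set.add((min(a, b), max(a, b)))
    # sampled long-range contacts beyond the cutoff
    beyond = [
        (int(i), int(j))
        for i, j in zip(iu[~within], ju[~within])
    ]
    n_extra = int(round(spec.contact_density * spec.n_residues / 2))
    if n_extra > len(beyond):
        raise ValueError(
            f"contact_density {spec.contact_density} demands {n_extra} extra "
            f"contacts but only {len(beyond)} pairs lie beyond the cutoff"
        )
    if n_extra > 0:
        pick = rng.choice(len(beyond), size=n_extra, replace=False)
        pair_set.update(beyond[p] for p in sorted(pick))
    pairs = np.array(sorted(pair_set), dtype=int)
    k = rng.uniform(spec.k_range[0], spec.k_range[1], size=len(pairs))
    l0 = dist[pairs[:, 0], pairs[:, 1]]
    return SpringNetwork(topo, pairs, k, l0, pos)


def sample_gaussian_ensemble(
    network: SpringNetwork,
    temperature: float,
    n_frames: int,
    seed: int | np.random.SeedSequence,
) -> CGEnsemble:
    """Frames from the harmonic equilibrium distribution exp(−ΔxᵀHΔx/2k_BT).

    Displacements are drawn mode-wise with variance k_B·T/λ over the
    non-rigid-body modes and added to the reference positions; rigid-body
    modes carry no displacement.  Errors on floppy networks (> 6 null modes).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    H = enm_hessian(network.reference_positions, network.pairs, network.k)
    w, V, null = _mode_decomposition(H)
    if null.sum() > 6:
        raise ValueError(
            f"floppy network: {int(null.sum())} near-zero modes (> 6)"
        )
    Vk = V[:, ~null]
    sigma = np.sqrt(KB * temperature / w[~null])
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_frames, Vk.shape[1]))
    disp = (z * sigma) @ Vk.T
    frames = network.reference_positions[None] + disp.reshape(n_frames, -1, 3)
    return CGEnsemble(network.topology, frames)


def _ss_pair(topo: CGTopology, I: int, J: int) -> tuple[int, int]:
    a, b = int(topo.sidechain_site[I]), int(topo.sidechain_site[J])
    return (min(a, b), max(a, b))


def make_two_state_benchmark(
    spec: ToyNetworkSpec | None = None,
    route_length: int = 5,
    change_factor: float = 4.0,
    n_frames: int = 10_000,
    temperature: float = 300.0,
    seed: int | None = None,
    n_anchor: int = 4,
    with_switches: bool = True,
    sample: bool = True,
) -> TwoStateBenchmark:
    """Reference/response networks with a planted contiguous relay route.

    The side-chain springs linking consecutive residues of a contiguous chain
    are set to a stiff baseline (2 × k_range max) in the reference network and
    multiplied by ``change_factor`` in the response network; ``n_anchor``
    equally stiff side-chain springs are planted unchanged in both states, and
    (optionally) one stiff spring is pruned from and one added to the response
    network as on/off switches.  One Gaussian ensemble per state is sampled
    when ``sample`` is true.
    """
    spec = spec or ToyNetworkSpec()
    if seed is None:
        seed = spec.seed
    if not (0 < route_length < spec.n_residues):
        raise ValueError("route_length must lie in (0, n_residues)")
    if change_factor <= 0:
        raise ValueError("change_factor must be positive")
    base = make_toy_bsenm(spec)
    topo = base.topology
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2_0001]))

    pair_index = {tuple(p): i for i, p in enumerate(base.pairs.tolist())}

    # contiguous residue runs whose members all carry side chains, whose
    # consecutive SS springs all exist, and whose side-chain separations sit
    # in the typical contact range (nearly coincident sites make the spring
    # direction degenerate and the constant unidentifiable)
    pos = base.reference_positions
    candidates = []
    for sep_lo, sep_hi in ((3.5, 8.0), (3.0, 9.0)):  # relax once if needed
        for start in range(topo.n_residues - route_length + 1):
            chain = list(range(start, start + route_length))
            if any(topo.sidechain_site[r] == -1 for r in chain):
                continue
            links = [_ss_pair(topo, a, b) for a, b in zip(chain, chain[1:])]
            if not all(p in pair_index for p in links):
                continue
            seps = [float(np.linalg.norm(pos[i] - pos[j])) for i, j in links]
            if all(sep_lo <= s <= sep_hi for s in seps):
                candidates.append((chain, links))
        if candidates:
            break
    if not candidates:
        raise ValueError(
            f"no contiguous chain of {route_length} side-chain-bearing residues "
            "with consecutive side-chain springs at contact separations"
        )
    chain, links = candidates[rng.integers(len(candidates))]

    k_strong = ROUTE_K_FACTOR * spec.k_range[1]
    k_env = ENV_K_FACTOR * spec.k_range[1]
    k_ref = base.k.copy()
    for p in links:
        k_ref[pair_index[p]] = k_strong
    # Rigidify the local environment of the route side chains identically in
    # both states (no Δk signal): transversely floppy partners bias the
    # linearized variance of a stiff spring and make its constant
    # under-identifiable, which is a property of the estimator, not of the
    # comparison machinery this benchmark probes.
    route_ss_sites = {int(topo.sidechain_site[r]) for r in chain}
    link_set = set(links)
    for idx, (i, j) in enumerate(base.pairs.tolist()):
        if (i in route_ss_sites or j in route_ss_sites) and (i, j) not in link_set:
            k_ref[idx] = max(k_ref[idx], k_env)
    k_resp = k_ref.copy()
    for p in links:
        k_resp[pair_index[p]] *= change_factor
    planted_changes = [
        (
            (int(topo.site_residue[p[0]]), int(topo.site_residue[p[1]])),
            float(change_factor),
        )
        for p in links
    ]

    # stiff anchors, unchanged between states, on residues off the route
    route_set = set(chain)
    ss_pairs = [
        i
        for i, (a, b) in enumerate(base.pairs.tolist())
        if not topo.site_is_backbone[a]
        and not topo.site_is_backbone[b]
        and topo.site_residue[a] not in route_set
        and topo.site_residue[b] not in route_set
        and tuple((a, b)) not in links
    ]
    rng.shuffle(ss_pairs)
    anchor_idx = ss_pairs[:n_anchor]
    for i in anchor_idx:
        k_ref[i] = k_strong
        k_resp[i] = k_strong
    rest = ss_pairs[n_anchor:]

    pairs_ref = base.pairs.copy()
    pairs_resp = base.pairs.copy()
    l0_ref = base.l0.copy()
    l0_resp = base.l0.copy()
    switch_off: list[tuple[int, int]] = []
    switch_on: list[tuple[int, int]] = []
    if with_switches:
        if len(rest) < 2:
            raise ValueError("not enough side-chain springs to plant switches")
        off_i, on_i = rest[0], rest[1]
        k_ref[off_i] = k_strong  # pruned from the response network
        keep_resp = np.ones(len(pairs_resp), dtype=bool)
        keep_resp[off_i] = False
        keep_ref = np.ones(len(pairs_ref), dtype=bool)
        keep_ref[on_i] = False  # absent from the reference network
        k_resp[on_i] = k_strong
        a, b = base.pairs[off_i]
        switch_off.append(
            (int(topo.site_residue[a]), int(topo.site_residue[b]))
        )
        a, b = base.pairs[on_i]
        switch_on.append(
            (int(topo.site_residue[a]), int(topo.site_residue[b]))
        )
        net_ref = SpringNetwork(
            topo, pairs_ref[keep_ref], k_ref[keep_ref], l0_ref[keep_ref],
            base.reference_positions,
        )
        net_resp = SpringNetwork(
            topo, pairs_resp[keep_resp], k_resp[keep_resp], l0_resp[keep_resp],
            base.reference_positions,
        )
    else:
        net_ref = SpringNetwork(topo, pairs_ref, k_ref, l0_ref, base.reference_positions)
        net_resp = SpringNetwork(
            topo, pairs_resp, k_resp, l0_resp, base.reference_positions
        )

    bench = TwoStateBenchmark(
        network_ref=net_ref,
        network_resp=net_resp,
        planted_changes=planted_changes,
        planted_route=chain,
        switch_off=switch_off,
        switch_on=switch_on,
    )
    if sample:
        ss = np.random.SeedSequence([int(seed), 77])
        s_ref, s_resp = ss.spawn(2)
        bench.ensemble_ref = sample_gaussian_ensemble(
            net_ref, temperature, n_frames, s_ref
        )
        bench.ensemble_resp = sample_gaussian_ensemble(
            net_resp, temperature, n_frames, s_resp
        )
    return bench
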