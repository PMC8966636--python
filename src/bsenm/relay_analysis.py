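"""Two-state comparison: Δk responses, on/off switches, and relay routes.

The strongly coupled pair lists of a reference and a response state are
unioned per category; for every union pair the coupling change is

    Δk_IJ = k_resp,IJ − k_ref,IJ

from the two mean rigidity graphs.  Pairs within the top quartile of |Δk|
(percentile configurable, ties at the threshold included) are *prominent*
responses, labelled softening (Δk < 0) or stiffening (Δk > 0); the rest are
neutral.  A coupling present in exactly one state is an on/off switch.
Prominent and on/off pairs pooled across the BB/BS/SS categories are then
linked whenever two pairs share a residue or have residues within ``seq_gap``
sequence positions; connected components with at least two members are the
routes of mechanical relay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .prominent_modes import CoupledPairList
from .rigidity_graph import RigidityGraph

SOFTENING = "softening"
STIFFENING = "stiffening"
NEUTRAL = "neutral"
ON = "on"
OFF = "off"
NONE = "none"

MAX_SEQ_GAP = 4  # hard upper bound on the contiguity gap


@dataclass
class ResponseSet:
    """Union pair list of one category with Δk values, classes and switches."""

    category: str
    pairs: list[tuple[int, int]]
    k_ref: np.ndarray
    k_resp: np.ndarray
    delta_k: np.ndarray
    klass: list[str] = field(default_factory=list)
    switch: list[str] = field(default_factory=list)
    percentile_threshold: float | None = None  # the |Δk| cut actually used

    def __post_init__(self):
        m = len(self.pairs)
        self.k_ref = np.asarray(self.k_ref, dtype=float)
        self.k_resp = np.asarray(self.k_resp, dtype=float)
        self.delta_k = np.asarray(self.delta_k, dtype=float)
        if not self.klass:
            self.klass = [NEUTRAL] * m
        if not self.switch:
            self.switch = [NONE] * m
        for arr in (self.k_ref, self.k_resp, self.delta_k):
            if arr.shape != (m,):
                raise ValueError("per-pair arrays must match the pair list")


@dataclass
class RelayRoute:
    """One connected chain of prominent/on-off response pairs."""

    route_id: int
    members: list[tuple]  # (category, I, J, delta_k, klass, switch)
    residues: list[int]  # sorted participating residue indices


def union_pair_list(
    list_ref: CoupledPairList, list_resp: CoupledPairList
) -> list[tuple[int, int]]:
    """Deduplicated, sorted union of the two states' strongly coupled pairs."""
    if list_ref.category != list_resp.category:
        raise ValueError("cannot union pair lists of different categories")
    return sorted(set(list_ref.pairs) | set(list_resp.pairs))


def delta_couplings(
    mean_ref: RigidityGraph,
    mean_resp: RigidityGraph,
    union_pairs: list[tuple[int, int]],
) -> ResponseSet:
    """Δk_IJ = k_resp − k_ref over the union pairs (unclassified).

    Sign convention: response minus reference.  Pairs absent from both graphs
    are retained with Δk = 0 and a warning.
    """
    if mean_ref.category != mean_resp.category:
        raise ValueError("mean graphs have different categories")
    if mean_ref.n_residues != mean_resp.n_residues:
        raise ValueError("mean graphs have different dimensions")
    pairs = list(union_pairs)
    I = np.array([p[0] for p in pairs], dtype=int)
    J = np.array([p[1] for p in pairs], dtype=int)
    k_ref = mean_ref.k_matrix[I, J] if pairs else np.empty(0)
    k_resp = mean_resp.k_matrix[I, J] if pairs else np.empty(0)
    absent = (k_ref == 0) & (k_resp == 0)
    if absent.any():
        warnings.warn(
            f"{int(absent.sum())} union pairs absent from both graphs (Δk = 0)",
            stacklevel=2,
        )
    return ResponseSet(
        category=mean_ref.category,
        pairs=pairs,
        k_ref=k_ref,
        k_resp=k_resp,
        delta_k=k_resp - k_ref,
    )


def classify_prominent_responses(
    response: ResponseSet, percentile: float = 25.0
) -> ResponseSet:
    """Label the top-|Δk| quartile softening/stiffening; the rest neutral.

    The threshold is the m-th largest |Δk| with m = ceil(percentile/100 · N);
    ties at the threshold are included.  Pairs with Δk = 0 are always neutral.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    if not response.pairs:
        raise ValueError("need at least one union pair")
    abs_dk = np.abs(response.delta_k)
    m = math.ceil(percentile / 100.0 * len(response.pairs))
    threshold = float(np.sort(abs_dk)[::-1][m - 1])
    if threshold == 0:
        warnings.warn("all Δk at or below zero threshold: all pairs neutral",
                      stacklevel=2)
    klass = []
    for dk in response.delta_k:
        if abs(dk) >= threshold and dk != 0:
            klass.append(SOFTENING if dk < 0 else STIFFENING)
        else:
            klass.append(NEUTRAL)
    response.klass = klass
    response.percentile_threshold = threshold
    return response


def label_on_off(response: ResponseSet, zero_tol: float = 0.0) -> ResponseSet:
    """Mark couplings present in exactly one state as on/off switches."""
    switch = []
    for kr, kp in zip(response.k_ref, response.k_resp):
        if kp <= zero_tol < kr:
            switch.append(OFF)
        elif kr <= zero_tol < kp:
            switch.append(ON)
        else:
            switch.append(NONE)
    response.switch = switch
    return response


def _pair_contiguous(p: tuple[int, int], q: tuple[int, int], seq_gap: int) -> bool:
    return min(abs(a - b) for a in p for b in q) <= seq_gap


def build_relay_routes(
    responses: list[ResponseSet], seq_gap: int = 2
) -> list[RelayRoute]:
    """Connected components of prominent/on-off pairs under residue contiguity.

    Nodes are all non-neutral or on/off pairs pooled across categories; two
    nodes are linked when any residue of one lies within ``seq_gap`` sequence
    positions of any residue of the other (a shared residue is distance 0).
    Components with ≥ 2 members are routes, ordered by their smallest residue.
    """
    if not 0 <= seq_gap <= MAX_SEQ_GAP:
        raise ValueError(f"seq_gap must lie in [0, {MAX_SEQ_GAP}]")
    nodes = []
    for resp in responses:
        for idx, (I, J) in enumerate(resp.pairs):
            if resp.klass[idx] != NEUTRAL or resp.switch[idx] != NONE:
                nodes.append(
                    (
                        resp.category,
                        int(I),
                        int(J),
                        float(resp.delta_k[idx]),
                        resp.klass[idx],
                        resp.switch[idx],
                    )
                )
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for a in range(len(nodes)):
        pa = (nodes[a][1], nodes[a][2])
        for b in range(a + 1, len(nodes)):
            if _pair_contiguous(pa, (nodes[b][1], nodes[b][2]), seq_gap):
                g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: min(min(nodes[i][1], nodes[i][2]) for i in c))
    routes = []
    for rid, comp in enumerate(comps):
        members = [nodes[i] for i in comp]
        residues = sorted({r for m in members for r in (m[1], m[2])})
        routes.append(RelayRoute(route_id=rid, members=members, residues=residues))
    return routes
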