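"""Coarse-grained mapping of protein structures onto backbone/side-chain sites.

A residue is represented by one *backbone* site (centroid of the N, CA, C, O
heavy atoms) and, when the residue carries at least one side-chain heavy atom,
one *sidechain* site (centroid of the side-chain heavy atoms).  Glycine has a
backbone site only.  Hydrogens are ignored throughout.  Springs of the
elastic-network model connect site pairs whose ensemble-averaged distance lies
within a cutoff; pairs bridged by a disulfide bond are recorded on the
topology so the rigidity-graph stage can exclude them.

All positions are in Å.  Residue indices are 0-based and sequential along the
chain; original PDB residue numbers are kept on the topology for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: atoms never counted as side chain even though they are heavy
_NON_SIDECHAIN = set(BACKBONE_ATOMS) | {"OXT"}
DISULFIDE_CUTOFF = 2.5  # Å, SG-SG distance declaring a disulfide bond

BACKBONE = "backbone"
SIDECHAIN = "sidechain"


@dataclass(frozen=True)
class CGSite:
    """One coarse-grained interaction site."""

    site_index: int
    residue_index: int
    residue_name: str
    kind: str  # BACKBONE or SIDECHAIN
    position: np.ndarray  # (3,) Å

    def __post_init__(self):
        if self.kind not in (BACKBONE, SIDECHAIN):
            raise ValueError(f"unknown site kind {self.kind!r}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class CGTopology:
    """Ordered site list plus chain metadata.

    ``atom_site_map`` (optional) assigns every atom of the source structure to
    a site index (−1 for atoms that map to no site, e.g. hydrogens); it is what
    :func:`map_to_cg` uses to reduce atomistic frames.
    """

    sites: list[CGSite]
    chain_id: str = ""
    disulfide_pairs: list[tuple[int, int]] = field(default_factory=list)
    res_ids: list[int] = field(default_factory=list)  # original PDB numbers
    atom_site_map: np.ndarray | None = None

    def __post_init__(self):
        idx = [s.site_index for s in self.sites]
        if idx != list(range(len(self.sites))):
            raise ValueError("site_index values must be dense and ordered")
        self.site_residue = np.array([s.residue_index for s in self.sites], dtype=int)
        self.site_is_backbone = np.array(
            [s.kind == BACKBONE for s in self.sites], dtype=bool
        )
        n_res = int(self.site_residue.max()) + 1 if self.sites else 0
        if np.count_nonzero(self.site_is_backbone) != n_res:
            raise ValueError("every residue needs exactly one backbone site")
        self.backbone_site = np.full(n_res, -1, dtype=int)
        self.sidechain_site = np.full(n_res, -1, dtype=int)
        for s in self.sites:
            if s.kind == BACKBONE:
                if self.backbone_site[s.residue_index] != -1:
                    raise ValueError(
                        f"residue {s.residue_index} has two backbone sites"
                    )
                self.backbone_site[s.residue_index] = s.site_index
            else:
                self.sidechain_site[s.residue_index] = s.site_index
        if not self.res_ids:
            self.res_ids = list(range(1, n_res + 1))
        for i, j in self.disulfide_pairs:
            if not (0 <= i < n_res and 0 <= j < n_res):
                raise ValueError(f"disulfide pair ({i}, {j}) out of range")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_residues(self) -> int:
        return len(self.backbone_site)

    @property
    def residue_names(self) -> list[str]:
        names = [""] * self.n_residues
        for s in self.sites:
            if s.kind == BACKBONE:
                names[s.residue_index] = s.residue_name
        return names

    def reference_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float)


@dataclass
class CGEnsemble:
    """A stack of CG-site coordinate frames (n_frames, n_sites, 3) in Å."""

    topology: CGTopology
    frames: np.ndarray
    frame_spacing: float = 1.0  # metadata only (time units per frame)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_sites,
            3,
        ):
            raise ValueError(
                f"frames must have shape (n_frames, {self.topology.n_sites}, 3), "
                f"got {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Topology construction from an atomistic structure
# ---------------------------------------------------------------------------


def build_cg_topology(
    structure,
    chain_id: str | None = None,
    altloc_policy: str | None = None,
    allow_insertion_codes: bool = False,
) -> CGTopology:
    """Build the two-bead CG topology from a biotite ``AtomArray``.

    Parameters
    ----------
    structure
        ``biotite.structure.AtomArray`` (or a stack, in which case the first
        model defines the topology).
    chain_id
        Chain to map.  Required when the structure has several chains.
    altloc_policy
        ``None`` errors on duplicate (residue, atom) records; ``"first"``
        keeps the first occurrence.
    allow_insertion_codes
        When False, any insertion code raises; when True, inserted residues
        are kept in file order as additional sequence positions.
    """
    import biotite.structure as struc

    if hasattr(structure, "stack_depth"):
        structure = structure[0]
    amino = structure[struc.filter_amino_acids(structure)]
    if amino.array_length() == 0:
        raise ValueError("structure contains no amino-acid residues")

    chains = np.unique(amino.chain_id)
    if chain_id is None:
        if len(chains) > 1:
            raise ValueError(
                f"structure has chains {list(chains)}; pass chain_id to select one"
            )
        chain_id = str(chains[0])
    mask = amino.chain_id == chain_id
    if not mask.any():
        raise ValueError(f"chain {chain_id!r} not found (available: {list(chains)})")

    if hasattr(amino, "ins_code"):
        ins = amino.ins_code[mask]
        if not allow_insertion_codes and np.any(ins != ""):
            raise ValueError(
                "insertion codes present; pass allow_insertion_codes=True to keep "
                "inserted residues as extra sequence positions"
            )

    # Global atom indices (into the original structure) for the selected chain
    amino_idx = np.flatnonzero(struc.filter_amino_acids(structure))
    chain_idx = amino_idx[mask]
    sub = structure[chain_idx]

    # Group into residues by order of appearance of (res_id, ins_code)
    ins_code = sub.ins_code if hasattr(sub, "ins_code") else np.full(
        sub.array_length(), "", dtype="U1"
    )
    keys = list(zip(sub.res_id.tolist(), ins_code.tolist()))
    residue_of_atom = np.empty(sub.array_length(), dtype=int)
    res_keys: list[tuple[int, str]] = []
    for a, key in enumerate(keys):
        if not res_keys or key != res_keys[-1]:
            res_keys.append(key)
        residue_of_atom[a] = len(res_keys) - 1
    n_res = len(res_keys)
    if n_res < 2:
        raise ValueError("need at least 2 residues to build a CG topology")

    heavy = sub.element != "H"
    atom_site_map = np.full(structure.array_length(), -1, dtype=int)

    sites: list[CGSite] = []
    res_ids: list[int] = []
    cys_sg: list[tuple[int, np.ndarray]] = []
    for r in range(n_res):
        sel = (residue_of_atom == r) & heavy
        names = sub.atom_name[sel]
        res_name = str(sub.res_name[sel][0])
        res_ids.append(int(res_keys[r][0]))
        # altloc duplicates: same atom name appearing more than once
        uniq, counts = np.unique(names, return_counts=True)
        keep = np.flatnonzero(sel)
        if np.any(counts > 1):
            if altloc_policy == "first":
                seen: set[str] = set()
                keep_list = []
                for a in keep:
                    nm = str(sub.atom_name[a])
                    if nm not in seen:
                        seen.add(nm)
                        keep_list.append(a)
                keep = np.array(keep_list)
                names = sub.atom_name[keep]
            else:
                dup = uniq[counts > 1]
                raise ValueError(
                    f"residue {res_name} {res_keys[r][0]} has duplicate atoms "
                    f"{list(dup)} (altloc?); pass altloc_policy='first'"
                )
        name_list = [str(n) for n in names]
        missing = [a for a in BACKBONE_ATOMS if a not in name_list]
        if missing:
            raise ValueError(
                f"residue {res_name} {res_keys[r][0]} is missing backbone "
                f"atom(s) {missing}"
            )
        bb_atoms = [a for a, nm in zip(keep, name_list) if nm in BACKBONE_ATOMS]
        sc_atoms = [a for a, nm in zip(keep, name_list) if nm not in _NON_SIDECHAIN]

        bb_pos = sub.coord[bb_atoms].mean(axis=0)
        sites.append(CGSite(len(sites), r, res_name, BACKBONE, bb_pos))
        atom_site_map[chain_idx[bb_atoms]] = sites[-1].site_index
        if sc_atoms:
            sc_pos = sub.coord[sc_atoms].mean(axis=0)
            sites.append(CGSite(len(sites), r, res_name, SIDECHAIN, sc_pos))
            atom_site_map[chain_idx[sc_atoms]] = sites[-1].site_index
        if res_name == "CYS" and "SG" in name_list:
            sg = keep[name_list.index("SG")]
            cys_sg.append((r, sub.coord[sg]))

    disulfides = []
    for a in range(len(cys_sg)):
        for b in range(a + 1, len(cys_sg)):
            d = np.linalg.norm(cys_sg[a][1] - cys_sg[b][1])
            if d < DISULFIDE_CUTOFF:
                disulfides.append((cys_sg[a][0], cys_sg[b][0]))

    return CGTopology(
        sites=sites,
        chain_id=chain_id,
        disulfide_pairs=disulfides,
        res_ids=res_ids,
        atom_site_map=atom_site_map,
    )


def map_to_cg(atom_frames, topology: CGTopology, frame_spacing: float = 1.0) -> CGEnsemble:
    """Reduce atomistic coordinate frames to CG-site centroids.

    ``atom_frames`` has shape (n_frames, n_atoms, 3) with the atom order of the
    structure the topology was built from.  Frames containing non-finite
    coordinates on mapped atoms are rejected with the frame index.
    """
    if topology.atom_site_map is None:
        raise ValueError("topology carries no atom-site map; rebuild from a structure")
    frames = np.asarray(atom_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    amap = topology.atom_site_map
    if frames.shape[1] != amap.shape[0]:
        raise ValueError(
            f"expected {amap.shape[0]} atoms per frame, got {frames.shape[1]}"
        )
    mapped = amap >= 0
    bad = ~np.isfinite(frames[:, mapped, :]).all(axis=(1, 2))
    if bad.any():
        raise ValueError(f"frame {int(np.flatnonzero(bad)[0])} has missing atoms")

    n_sites = topology.n_sites
    counts = np.bincount(amap[mapped], minlength=n_sites).astype(float)
    # averaging matrix (n_sites, n_atoms_mapped)
    M = csr_matrix(
        (1.0 / counts[amap[mapped]], (amap[mapped], np.arange(mapped.sum()))),
        shape=(n_sites, int(mapped.sum())),
    )
    sub = frames[:, mapped, :]
    out = np.empty((frames.shape[0], n_sites, 3))
    for f in range(frames.shape[0]):
        out[f] = M @ sub[f]
    return CGEnsemble(topology, out, frame_spacing=frame_spacing)


# ---------------------------------------------------------------------------
# Spring-pair selection
# ---------------------------------------------------------------------------


def mean_distance_matrix(frames: np.ndarray, chunk: int = 2000) -> np.ndarray:
    """Frame-averaged pairwise site-distance matrix."""
    n_frames, n_sites, _ = frames.shape
    acc = np.zeros((n_sites, n_sites))
    for lo in range(0, n_frames, chunk):
        blk = frames[lo : lo + chunk]
        diff = blk[:, :, None, :] - blk[:, None, :, :]
        acc += np.sqrt((diff**2).sum(axis=-1)).sum(axis=0)
    return acc / n_frames


def pair_distances(frames: np.ndarray, pairs: np.ndarray, chunk: int = 5000) -> np.ndarray:
    """Distance series, shape (n_frames, n_pairs)."""
    pairs = np.asarray(pairs, dtype=int)
    out = np.empty((frames.shape[0], pairs.shape[0]))
    for lo in range(0, frames.shape[0], chunk):
        blk = frames[lo : lo + chunk]
        d = blk[:, pairs[:, 0], :] - blk[:, pairs[:, 1], :]
        out[lo : lo + blk.shape[0]] = np.linalg.norm(d, axis=-1)
    return out


def select_spring_pairs(ensemble: CGEnsemble, cutoff: float) -> list[tuple[int, int]]:
    """Site pairs (i, j), i<j, whose ensemble-mean distance is ≤ cutoff.

    Warns when the resulting spring graph is disconnected (the normal-mode
    covariance will then have more than 6 near-zero modes).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dmean = mean_distance_matrix(ensemble.frames)
    n = ensemble.topology.n_sites
    iu, ju = np.triu_indices(n, k=1)
    keep = dmean[iu, ju] <= cutoff
    pairs = sorted(zip(iu[keep].tolist(), ju[keep].tolist()))
    check_connected(n, pairs, warn_only=True)
    return pairs


def check_connected(
    n_sites: int, pairs, warn_only: bool = False
) -> bool:
    """True when the spring graph spans all sites in one component."""
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    if len(pairs) == 0:
        ok = n_sites <= 1
    else:
        data = np.ones(len(pairs))
        adj = csr_matrix(
            (data, (pairs[:, 0], pairs[:, 1])), shape=(n_sites, n_sites)
        )
        n_comp, _ = connected_components(adj, directed=False)
        ok = n_comp == 1
    if not ok and warn_only:
        warnings.warn(
            "spring graph is disconnected; expect more than 6 near-zero modes",
            stacklevel=2,
        )
    return ok
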