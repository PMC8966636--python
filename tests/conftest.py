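import numpy as np
import pytest

from bsenm.cg_model import BACKBONE, SIDECHAIN, CGEnsemble, CGSite, CGTopology


def make_atom_array(residues, chain_id="A"):
    """Build a biotite AtomArray from [(res_name, {atom_name: xyz}), ...]."""
    import biotite.structure as struc

    n_atoms = sum(len(atoms) for _, atoms in residues)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for r, (res_name, atoms) in enumerate(residues):
        for name, xyz in atoms.items():
            arr.chain_id[i] = chain_id
            arr.res_id[i] = r + 1
            arr.res_name[i] = res_name
            arr.atom_name[i] = name
            arr.element[i] = name[0]  # good enough for N/C/O/S heavy atoms
            arr.coord[i] = xyz
            arr.hetero[i] = False
            i += 1
    return arr


def simple_residue(res_name, origin, sidechain_atoms=()):
    """Backbone N/CA/C/O around ``origin`` plus optional side-chain atoms."""
    origin = np.asarray(origin, dtype=float)
    atoms = {
        "N": origin + (0.0, 0.0, 0.0),
        "CA": origin + (1.5, 0.0, 0.0),
        "C": origin + (2.3, 1.2, 0.0),
        "O": origin + (2.0, 2.3, 0.3),
    }
    for name, off in sidechain_atoms:
        atoms[name] = origin + np.asarray(off, dtype=float)
    return (res_name, atoms)


@pytest.fixture
def tripeptide_structure():
    """ALA-GLY-ALA: 3 backbone sites + 2 side-chain sites."""
    return make_atom_array(
        [
            simple_residue("ALA", (0, 0, 0), [("CB", (1.5, -1.4, 0.6))]),
            simple_residue("GLY", (3.8, 0, 0)),
            simple_residue("ALA", (7.6, 0, 0), [("CB", (9.1, -1.4, 0.6))]),
        ]
    )


@pytest.fixture
def tripeptide_pdb(tripeptide_structure, tmp_path):
    import biotite.structure.io.pdb as pdb

    path = tmp_path / "tripeptide.pdb"
    pfile = pdb.PDBFile()
    pfile.set_structure(tripeptide_structure)
    pfile.write(str(path))
    return path


def two_site_topology(l0=4.0):
    return CGTopology(
        sites=[
            CGSite(0, 0, "ALA", BACKBONE, np.zeros(3)),
            CGSite(1, 1, "ALA", BACKBONE, np.array([l0, 0.0, 0.0])),
        ]
    )


@pytest.fixture
def two_site_net():
    from bsenm.fluctuation_matching import SpringNetwork

    topo = two_site_topology()
    return SpringNetwork(
        topo, [[0, 1]], [1.0], [4.0], topo.reference_positions()
    )


def toy_topology(n_residues, sidechains, rng=None):
    """Hand-built CG topology: residue r has a side-chain site iff r in sidechains."""
    rng = rng or np.random.default_rng(0)
    sites = []
    for r in range(n_residues):
        base = np.array([3.8 * r, 0.0, 0.0]) + rng.normal(scale=0.2, size=3)
        sites.append(CGSite(len(sites), r, "ALA", BACKBONE, base))
        if r in sidechains:
            sites.append(
                CGSite(len(sites), r, "ALA", SIDECHAIN, base + (0.3, 2.0, 0.2))
            )
    return CGTopology(sites=sites)


@pytest.fixture
def union_find_oracle():
    """Independent connected-components oracle on the pair-contiguity relation."""

    def components(pairs, seq_gap):
        parent = list(range(len(pairs)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                if min(abs(x - y) for x in pairs[a] for y in pairs[b]) <= seq_gap:
                    union(a, b)
        groups = {}
        for i in range(len(pairs)):
            groups.setdefault(find(i), []).append(i)
        return sorted(
            [sorted(g) for g in groups.values() if len(g) >= 2],
            key=lambda g: g[0],
        )

    return components
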