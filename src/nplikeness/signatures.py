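"""Canonical atom signatures: circular descriptors of atom environments.

An *atom signature* of height ``h`` encodes, as a canonical string, the
subgraph induced by all atoms within graph distance ``h`` of a root atom
(its "ball"), with the root distinguished.  Two atoms receive the same
canonical string if and only if their height-``h`` neighbourhoods are
isomorphic as rooted, atom- and bond-labelled graphs — regardless of input
atom numbering.  The *molecular signature* of a molecule is the multiset of
the atom signatures of all its atoms (hydrogens included), i.e. a mapping
``canonical string -> multiplicity``.

Canonicality is obtained by exact canonical labelling (BLISS, via igraph) of
the vertex-coloured ball graph; bond labels are carried by subdividing each
bond into an extra coloured vertex, the standard reduction of edge-coloured
to vertex-coloured graph isomorphism.

Serialisation grammar (versioned, stable across runs; persisted strings must
never change meaning):

    "<VERSION>/h<height>/<atom tokens>/<edge list>"

where atom tokens are comma-separated SMILES-like element tokens (lowercase
for aromatic atoms, trailing ``+``/``-`` repeated for formal charge), the
root atom always first and remaining atoms in canonical order, and the edge
list is a comma-separated, lexicographically sorted sequence of
``<i><bond><j>`` entries over atom positions ``i < j`` with bond characters
``-``, ``=``, ``#``, ``:`` and ``~`` (other).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Tuple

import igraph
from rdkit import Chem

SIGNATURE_FORMAT_VERSION = "sig1"

DEFAULT_HEIGHT = 2

_BOND_CHARS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass(frozen=True)
class AtomSignature:
    """Canonical string form of one atom's height-``h`` environment."""

    canonical_string: str
    height: int
    center_element: str


@dataclass(frozen=True)
class MolecularSignature:
    """Multiset of a molecule's atom signatures.

    ``counts`` maps each canonical signature string to its multiplicity;
    the sum of multiplicities equals the number of atoms (explicit
    hydrogens included) for which signatures were computed.
    """

    counts: Dict[str, int]
    height: int

    def total(self) -> int:
        return sum(self.counts.values())


def _atom_token(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    tok = sym.lower() if atom.GetIsAromatic() else sym
    q = atom.GetFormalCharge()
    if q > 0:
        tok += "+" * q
    elif q < 0:
        tok += "-" * (-q)
    return tok


def _bond_char(bond: Chem.Bond) -> str:
    return _BOND_CHARS.get(bond.GetBondType(), "~")


def _ball(mol: Chem.Mol, root: int, height: int) -> Tuple[List[int], List[Tuple[int, int, str]]]:
    """Atoms within distance <= height of root, and all bonds among them."""
    dist = {root: 0}
    queue = deque([root])
    while queue:
        i = queue.popleft()
        if dist[i] == height:
            continue
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nb.GetIdx()
            if j not in dist:
                dist[j] = dist[i] + 1
                queue.append(j)
    atoms = sorted(dist)
    member = set(atoms)
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in member and j in member:
            edges.append((i, j, _bond_char(bond)))
    return atoms, edges


def atom_signature(mol: Chem.Mol, atom_index: int, height: int = DEFAULT_HEIGHT) -> AtomSignature:
    """Compute the canonical height-``height`` signature of one atom.

    The molecule is traversed as given: hydrogens participate only if they
    are explicit atoms of ``mol`` (see :func:`molecular_signature`, which
    makes them explicit).  Raises ``ValueError`` for an invalid atom index
    or negative height.
    """
    if height < 0:
        raise ValueError(f"height must be >= 0, got {height}")
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise ValueError(f"atom index {atom_index} out of range for molecule with {mol.GetNumAtoms()} atoms")

    atoms, edges = _ball(mol, atom_index, height)
    pos = {a: k for k, a in enumerate(atoms)}
    n = len(atoms)

    tokens = [_atom_token(mol.GetAtomWithIdx(a)) for a in atoms]
    root_pos = pos[atom_index]

    # Vertex-coloured graph: one vertex per ball atom (root gets a colour of
    # its own), plus one vertex per bond carrying the bond label.  Colour
    # integers come from the sorted key set: BLISS canonical forms depend on
    # colour values, not just the partition, so ids must be derivable from
    # the labels alone.
    keys = [("ROOT:" if k == root_pos else "ATOM:") + t for k, t in enumerate(tokens)]
    keys.extend("BOND:" + bc for _, _, bc in edges)
    cid = {key: c for c, key in enumerate(sorted(set(keys)))}

    colours = [cid[key] for key in keys[:n]]
    g_edges = []
    for e, (i, j, bc) in enumerate(edges):
        mid = n + e
        colours.append(cid["BOND:" + bc])
        g_edges.append((pos[i], mid))
        g_edges.append((pos[j], mid))

    g = igraph.Graph(n=len(colours), edges=g_edges)
    perm = g.canonical_permutation(color=colours)

    # Canonical order of the real atoms: root first, the rest by canonical
    # label.  Both criteria are colour-determined, hence invariant.
    order = sorted(range(n), key=lambda k: (k != root_pos, perm[k]))
    rank = {k: r for r, k in enumerate(order)}

    atom_part = ",".join(tokens[k] for k in order)
    edge_entries = []
    for i, j, bc in edges:
        a, b = sorted((rank[pos[i]], rank[pos[j]]))
        edge_entries.append(f"{a}{bc}{b}")
    edge_part = ",".join(sorted(edge_entries))

    canonical = f"{SIGNATURE_FORMAT_VERSION}/h{height}/{atom_part}/{edge_part}"
    return AtomSignature(canonical, height, mol.GetAtomWithIdx(atom_index).GetSymbol())


def center_element(canonical_string: str) -> str:
    """Recover the root atom's element symbol from a canonical string."""
    atom_part = canonical_string.split("/", 3)[2]
    root = atom_part.split(",", 1)[0].rstrip("+-")
    return root.capitalize() if len(root) <= 2 else root


def molecular_signature(mol: Chem.Mol, height: int = DEFAULT_HEIGHT) -> MolecularSignature:
    """Signature multiset over every atom of ``mol``, hydrogens made explicit.

    Each fragment contributes once per occurrence: if the same environment
    occurs three times in the molecule its multiplicity is 3.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot compute a molecular signature of an empty molecule")
    molh = Chem.AddHs(mol)
    counts: Dict[str, int] = {}
    for idx in range(molh.GetNumAtoms()):
        sig = atom_signature(molh, idx, height)
        counts[sig.canonical_string] = counts.get(sig.canonical_string, 0) + 1
    return MolecularSignature(counts, height)
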