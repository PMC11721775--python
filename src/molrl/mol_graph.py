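"""Molecular graph data model and cheminformatics primitives.

The generator operates on heavy-atom graphs with explicit kekulé bond
orders (1, 2, 3).  Aromatic systems are stored in their kekulé form so
that the bond-order-partitioned adjacency slices used by the graph
convolution are well defined; aromaticity is re-perceived (via RDKit
sanitization) whenever a molecule is scored, canonicalized or matched
against structural-alert patterns.

Everything here is 2-D: no conformers, no stereochemistry annotations,
no explicit hydrogens.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: Element vocabulary (drug-like heavy atoms) in one-hot order.
VOCABULARY: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")

#: Maximal valence per element used by the generation environment.
MAX_VALENCE: dict[str, int] = {
    "C": 4, "N": 3, "O": 2, "S": 6, "P": 5,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

HALOGENS: frozenset[str] = frozenset({"F", "Cl", "Br", "I"})

#: Ring sizes that receive a membership bit in the atom featurization.
RING_SIZES: tuple[int, ...] = (3, 4, 5, 6, 7)

#: Atom feature layout: element one-hot + degree one-hot (0-5) + ring bits.
N_ELEMENT_BITS = len(VOCABULARY)
N_DEGREE_BITS = 6
N_RING_BITS = len(RING_SIZES)
N_ATOM_FEATURES = N_ELEMENT_BITS + N_DEGREE_BITS + N_RING_BITS  # 20

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


class MolGraphError(ValueError):
    """Raised for malformed molecular-graph inputs."""


def _edge(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise MolGraphError(f"self-bond on atom {i}")
    return (i, j) if i < j else (j, i)


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with typed (kekulé) bonds.

    ``elements[i]`` is the symbol of atom *i*; ``bonds`` maps an ordered
    pair ``(i, j)`` with ``i < j`` to a bond order in {1, 2, 3}.
    """

    elements: list[str] = field(default_factory=list)
    bonds: dict[tuple[int, int], int] = field(default_factory=dict)
    # incrementally maintained caches (degree / Σ bond order per atom)
    _deg: list[int] = field(default_factory=list, repr=False, compare=False)
    _val: list[int] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        if len(self._deg) != len(self.elements):
            self._deg = [0] * len(self.elements)
            self._val = [0] * len(self.elements)
            for (i, j), o in self.bonds.items():
                self._deg[i] += 1
                self._deg[j] += 1
                self._val[i] += o
                self._val[j] += o

    # -- construction -------------------------------------------------

    def add_atom(self, element: str) -> int:
        if element not in MAX_VALENCE:
            raise MolGraphError(f"element {element!r} not in vocabulary")
        self.elements.append(element)
        self._deg.append(0)
        self._val.append(0)
        return len(self.elements) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        if order not in (1, 2, 3):
            raise MolGraphError(f"bond order must be 1, 2 or 3, got {order}")
        key = _edge(i, j)
        if key in self.bonds:
            raise MolGraphError(f"bond {key} already present")
        if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
            raise MolGraphError(f"bond {key} references missing atom")
        self.bonds[key] = order
        self._deg[i] += 1
        self._deg[j] += 1
        self._val[i] += order
        self._val[j] += order

    def copy(self) -> "MolGraph":
        return MolGraph(list(self.elements), dict(self.bonds),
                        list(self._deg), list(self._val))

    # -- queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def heavy_degree(self, i: int) -> int:
        return self._deg[i]

    def valence_used(self, i: int) -> int:
        """Sum of bond orders incident to atom *i*."""
        return self._val[i]

    def has_bond(self, i: int, j: int) -> bool:
        return _edge(i, j) in self.bonds

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return True
        seen = {0}
        frontier = [0]
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for (a, b) in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        while frontier:
            u = frontier.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        return len(seen) == self.n_atoms

    # -- RDKit bridge -------------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Build an RDKit molecule; sanitization perceives aromaticity."""
        rw = Chem.RWMol()
        for sym in self.elements:
            rw.AddAtom(Chem.Atom(sym))
        for (i, j), order in self.bonds.items():
            rw.AddBond(i, j, _BOND_TYPES[order])
        mol = rw.GetMol()
        if sanitize:
            try:
                Chem.SanitizeMol(mol)
            except Exception as exc:  # pragma: no cover - defensive
                raise MolGraphError(f"unsanitizable graph: {exc}") from exc
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolGraph":
        mol = Chem.Mol(mol)
        mol = Chem.RemoveHs(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        g = cls()
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            if sym not in MAX_VALENCE:
                raise MolGraphError(f"element {sym!r} not in vocabulary")
            g.add_atom(sym)
        for bond in mol.GetBonds():
            order = int(round(bond.GetBondTypeAsDouble()))
            if order not in (1, 2, 3):
                raise MolGraphError(f"unsupported bond type {bond.GetBondType()}")
            g.add_bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order)
        return g


# ---------------------------------------------------------------------------
# Line-notation I/O
# ---------------------------------------------------------------------------

def parse_smiles(text: str) -> MolGraph:
    """Parse a SMILES string into a kekulized heavy-atom graph."""
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MolGraphError(f"cannot parse SMILES: {text!r}")
    return MolGraph.from_rdkit(mol)


def to_canonical(g: MolGraph) -> str:
    """Canonical (aromatic-form) SMILES; invariant under atom reordering."""
    return Chem.MolToSmiles(g.to_rdkit())


def read_smiles_file(path) -> list[MolGraph]:
    """Read a one-molecule-per-line SMILES file (gzip transparent).

    Lines may carry a tab-separated name which is ignored here.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(parse_smiles(line.split("\t")[0].split()[0]))
    return out


def write_smiles_file(path, graphs: Iterable[MolGraph]) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for g in graphs:
            fh.write(to_canonical(g) + "\n")


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def atom_ring_sizes(g: MolGraph) -> list[set[int]]:
    """Per-atom set of SSSR ring sizes within RING_SIZES the atom is in."""
    sizes: list[set[int]] = [set() for _ in range(g.n_atoms)]
    if not g.bonds:
        return sizes
    mol = g.to_rdkit(sanitize=False)
    Chem.GetSymmSSSR(mol)
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) in RING_SIZES:
            for idx in ring:
                sizes[idx].add(len(ring))
    return sizes


def encode_atoms(g: MolGraph) -> np.ndarray:
    """One-hot atom features: element (9) + heavy degree (6) + ring bits (5).

    Each row is a 20-dimensional binary vector with exactly one element
    bit, one degree bit and zero to five ring-membership bits.
    """
    X = np.zeros((g.n_atoms, N_ATOM_FEATURES))
    ring_sizes = atom_ring_sizes(g)
    for i, sym in enumerate(g.elements):
        if sym not in VOCABULARY:
            raise MolGraphError(f"element {sym!r} not in vocabulary")
        X[i, VOCABULARY.index(sym)] = 1.0
        deg = min(g.heavy_degree(i), N_DEGREE_BITS - 1)
        X[i, N_ELEMENT_BITS + deg] = 1.0
        for size in ring_sizes[i]:
            X[i, N_ELEMENT_BITS + N_DEGREE_BITS + RING_SIZES.index(size)] = 1.0
    return X


@dataclass
class BondSliceAdjacency:
    """Bond-order-partitioned adjacency with symmetric normalization.

    ``raw[k]`` is the adjacency of bond order ``k+1``; ``normalized[k]``
    is D̃^(-1/2) (A + I) D̃^(-1/2) where D̃ is the degree matrix of the
    self-loop-augmented slice.
    """

    raw: list[np.ndarray]
    normalized: list[np.ndarray]


def bond_slices(g: MolGraph) -> BondSliceAdjacency:
    """Split the graph into three single-bond-order adjacency slices."""
    if g.n_atoms == 0:
        raise MolGraphError("empty graph has no adjacency")
    n = g.n_atoms
    raw, normalized = [], []
    for order in (1, 2, 3):
        A = np.zeros((n, n))
        for (i, j), o in g.bonds.items():
            if o == order:
                A[i, j] = A[j, i] = 1.0
        A_tilde = A + np.eye(n)
        d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
        normalized.append(A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :])
        raw.append(A)
    return BondSliceAdjacency(raw=raw, normalized=normalized)


# ---------------------------------------------------------------------------
# Fingerprints and similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length circular (ECFP4, radius 2) fingerprint bit vector."""

    bits: np.ndarray  # boolean array

    @property
    def nbits(self) -> int:
        return self.bits.size


def ecfp4(g: MolGraph, nbits: int = 2048) -> Fingerprint:
    """Radius-2 Morgan (ECFP4) fingerprint hashed to ``nbits`` bits."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    fp = gen.GetFingerprint(g.to_rdkit())
    bits = np.zeros(nbits, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return Fingerprint(bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b|.

    Two all-zero vectors are defined to have similarity 1.0 (identical
    empty environments).
    """
    if a.nbits != b.nbits:
        raise MolGraphError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    union = np.logical_or(a.bits, b.bits).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a.bits, b.bits).sum() / union)


# ---------------------------------------------------------------------------
# Scaffolds and structural edits
# ---------------------------------------------------------------------------

def murcko_scaffold(g: MolGraph) -> MolGraph:
    """Bemis–Murcko scaffold: ring systems plus linkers, side chains removed.

    An acyclic molecule yields an empty scaffold graph.
    """
    scaffold = MurckoScaffold.GetScaffoldForMol(g.to_rdkit())
    if scaffold.GetNumAtoms() == 0:
        return MolGraph()
    return MolGraph.from_rdkit(scaffold)


def strip_halogens(g: MolGraph) -> MolGraph:
    """Remove F/Cl/Br/I atoms (treated as hydrogens) from the graph."""
    keep = [i for i, sym in enumerate(g.elements) if sym not in HALOGENS]
    remap = {old: new for new, old in enumerate(keep)}
    out = MolGraph()
    for i in keep:
        out.add_atom(g.elements[i])
    for (i, j), order in g.bonds.items():
        if i in remap and j in remap:
            out.add_bond(remap[i], remap[j], order)
    return out


def heavy_atom_count(g: MolGraph) -> int:
    return g.n_atoms


def count_chiral_centers(g: MolGraph) -> int:
    """Number of potential stereocenters, counting unassigned ones.

    Generated graphs carry no stereo annotations, so assigned and
    unassigned centers are counted alike.
    """
    if g.n_atoms == 0:
        return 0
    return len(
        Chem.FindMolChiralCenters(
            g.to_rdkit(), includeUnassigned=True, useLegacyImplementation=False
        )
    )


def sssr_ring_sizes(g: MolGraph) -> list[int]:
    """Sizes of the smallest set of smallest rings."""
    if not g.bonds:
        return []
    mol = g.to_rdkit(sanitize=False)
    Chem.GetSymmSSSR(mol)
    return [len(r) for r in mol.GetRingInfo().AtomRings()]
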