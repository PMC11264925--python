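"""Molecule parsing, pharmacophore-labelled graphs and circular fingerprints.

Molecules are parsed with RDKit and stored with their canonical SMILES so
that every downstream artefact (graphs, fingerprints, descriptors) is
invariant to the atom ordering of the input string.  The labelled graph is
the substrate of the distance-signature features: heavy atoms are nodes,
covalent bonds are edges, and each atom carries a *set* of pharmacophore
classes assigned by an ordered, user-overridable SMARTS rule table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

RDLogger.DisableLog("rdApp.*")

#: The default pharmacophore class vocabulary, in canonical order.
PHARMACOPHORE_CLASSES = (
    "Acceptor",
    "Aromatic",
    "Donor",
    "Hydrophobe",
    "NegativeIonizable",
    "Neutral",
    "PositiveIonizable",
    "Sulfur",
)

FALLBACK_CLASS = "Neutral"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the input."""

    def __init__(self, smiles: str, reason: str = "invalid SMILES"):
        self.smiles = smiles
        super().__init__(f"cannot parse SMILES {smiles!r}: {reason}")


@dataclass(frozen=True)
class Molecule:
    """A parsed small molecule (heavy atoms only, implicit hydrogens)."""

    smiles: str  # canonical form
    atoms: tuple  # (element, formal_charge, is_aromatic, in_ring) per atom
    bonds: tuple  # (i, j, bond_order) per bond, i < j
    rdmol: Chem.Mol = field(compare=False, repr=False, hash=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises :class:`SmilesParseError` on empty or unparsable input.  The
    stored SMILES is RDKit-canonical, so ``parse_smiles(m.smiles).smiles ==
    m.smiles`` for every valid molecule.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty input")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(smiles)
    canonical = Chem.MolToSmiles(rdmol)
    # re-parse from the canonical form so atom indices are order-invariant
    rdmol = Chem.MolFromSmiles(canonical)
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(), a.IsInRing())
        for a in rdmol.GetAtoms()
    )
    bonds = tuple(
        sorted(
            (
                min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                b.GetBondTypeAsDouble(),
            )
            for b in rdmol.GetBonds()
        )
    )
    return Molecule(smiles=canonical, atoms=atoms, bonds=bonds, rdmol=rdmol)


def read_smiles_file(path) -> list:
    """Read a SMILES file: one molecule per line, optional tab-separated id."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        name = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
        out.append((name, parse_smiles(smi)))
    return out


def read_sdf(path) -> list:
    """Read an SDF file into (name, Molecule) pairs."""
    out = []
    for i, rdmol in enumerate(Chem.SDMolSupplier(str(path))):
        if rdmol is None:
            raise SmilesParseError(f"<SDF record {i}>", "unreadable record")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"mol{i}"
        out.append((name, parse_smiles(Chem.MolToSmiles(rdmol))))
    return out


# ---------------------------------------------------------------------------
# Pharmacophore rule table


@dataclass(frozen=True)
class PharmacophoreRule:
    cls: str
    smarts: str
    priority: int
    pattern: Chem.Mol = field(compare=False, repr=False, hash=False, default=None)


def load_pharmacophore_rules(path=None) -> tuple:
    """Load the (class, SMARTS, priority) rule table.

    ``path=None`` loads the table shipped with the package.  Rules are
    returned sorted by (class, priority); an atom gets a class when it is
    the first atom of any match of that class's patterns.
    """
    if path is None:
        text = (
            resources.files("combosyn.data").joinpath("pharmacophores.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, smarts, prio = line.split("\t")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule table: {smarts!r}")
        rules.append(PharmacophoreRule(cls, smarts, int(prio), patt))
    return tuple(sorted(rules, key=lambda r: (r.cls, r.priority)))


@dataclass(frozen=True)
class LabeledMolGraph:
    """A molecule as a pharmacophore-labelled graph.

    ``labels[i]`` is the frozenset of pharmacophore classes of atom ``i``
    (never empty: ``Neutral`` is the fallback).  ``dist`` is the all-pairs
    shortest-path length in bonds, ``inf`` across disconnected components.
    """

    n_atoms: int
    labels: tuple  # frozenset per atom
    edges: tuple  # (i, j) per bond
    dist: np.ndarray = field(compare=False, repr=False, hash=False, default=None)


def build_labeled_graph(mol: Molecule, rules=None) -> LabeledMolGraph:
    """Assign pharmacophore labels and compute bond-topology distances.

    Distances are breadth-first shortest paths over the covalent-bond
    graph (every bond counts 1, regardless of order); disconnected
    fragments are allowed and get infinite cross-component distance.
    """
    if rules is None:
        rules = load_pharmacophore_rules()
    rdmol = mol.rdmol if mol.rdmol is not None else Chem.MolFromSmiles(mol.smiles)
    n = mol.n_atoms
    label_sets = [set() for _ in range(n)]
    for rule in rules:
        for match in rdmol.GetSubstructMatches(rule.pattern, uniquify=True):
            label_sets[match[0]].add(rule.cls)
    for s in label_sets:
        if not s:
            s.add(FALLBACK_CLASS)

    edges = tuple((i, j) for (i, j, _order) in mol.bonds)
    if edges:
        rows = [e[0] for e in edges] + [e[1] for e in edges]
        cols = [e[1] for e in edges] + [e[0] for e in edges]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        dist = shortest_path(adj, method="BF", unweighted=True, directed=False)
    else:
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0.0)
    return LabeledMolGraph(
        n_atoms=n,
        labels=tuple(frozenset(s) for s in label_sets),
        edges=edges,
        dist=dist,
    )


# ---------------------------------------------------------------------------
# Fingerprints


@dataclass(frozen=True)
class Fingerprint:
    """A Morgan/circular fingerprint as a set of on-bits."""

    bits: frozenset
    nbits: int
    radius: int

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.nbits:
            raise ValueError("bit index out of range")


def morgan_fingerprint(mol: Molecule, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Hashed circular fingerprint of radius ``radius`` folded to ``nbits``."""
    if radius < 0 or nbits < 1:
        raise ValueError("radius must be >= 0 and nbits >= 1")
    rdmol = mol.rdmol if mol.rdmol is not None else Chem.MolFromSmiles(mol.smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(rdmol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B|; 0.0 when both bit sets are empty."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def is_finite_dist(d: float) -> bool:
    return math.isfinite(d)
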