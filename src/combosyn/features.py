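"""Per-drug feature vectors and pair assembly.

Each drug is represented by the concatenation of two blocks:

* a **graph-based signature**: for every unordered pair of pharmacophore
  classes and every bond-distance cutoff, the cumulative count of atom
  pairs of those classes within that many bonds of each other;
* a block of **physicochemical descriptors** (ring counts, rotatable
  bonds, LogP, kappa shape and connectivity indices, MOE-style surface
  area bins, functional-group counts) computed with RDKit and listed in a
  versioned manifest.

Pair feature vectors are the concatenation ``[drug A block | drug B
block]`` with names suffixed ``_drug_A`` / ``_drug_B``; the default
``canonical`` policy orders the two drugs by canonical SMILES so the
vector is invariant to the order the pair is written in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem import (
    FALLBACK_CLASS,
    LabeledMolGraph,
    Molecule,
    build_labeled_graph,
    load_pharmacophore_rules,
    parse_smiles,
)

DEFAULT_CUTOFFS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

# custom descriptors not provided by RDKit's Descriptors registry:
# name -> SMARTS whose unique-match count is the descriptor value
_SMARTS_DESCRIPTORS = {
    "pyrimidine_rings": "c1cncnc1",
}
_SMARTS_CACHE = {k: Chem.MolFromSmarts(v) for k, v in _SMARTS_DESCRIPTORS.items()}


class UnknownDescriptorError(KeyError):
    pass


def load_descriptor_manifest(path=None) -> tuple:
    """Ordered descriptor names; ``None`` loads the shipped manifest."""
    if path is None:
        text = resources.files("combosyn.data").joinpath("descriptors.tsv").read_text()
    else:
        text = Path(path).read_text()
    names = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if len(set(names)) != len(names):
        raise ValueError("duplicate descriptor names in manifest")
    return tuple(names)


def _descriptor_fn(name: str):
    if name in _SMARTS_CACHE:
        patt = _SMARTS_CACHE[name]
        return lambda m: float(len(m.GetSubstructMatches(patt, uniquify=True)))
    fn = getattr(Descriptors, name, None)
    if fn is None:
        raise UnknownDescriptorError(
            f"descriptor {name!r} is neither an RDKit descriptor nor a "
            f"registered SMARTS count"
        )
    return fn


@dataclass(frozen=True)
class FeatureConfig:
    """Everything that determines the feature space.

    The config hash is embedded in trained models so that a model can
    refuse feature matrices produced under a different configuration.
    """

    cutoffs: tuple = DEFAULT_CUTOFFS
    classes: tuple = None  # derived from the rule table when None
    rules_path: str = None
    descriptors: tuple = None  # shipped manifest when None
    descriptors_path: str = None
    fp_radius: int = 2
    fp_nbits: int = 2048
    pair_policy: str = "canonical"  # or "symmetric-augment"

    def __post_init__(self):
        cut = tuple(float(c) for c in self.cutoffs)
        if any(c <= 0 for c in cut) or any(
            b <= a for a, b in zip(cut, cut[1:])
        ):
            raise ValueError("cutoffs must be strictly ascending and positive")
        object.__setattr__(self, "cutoffs", cut)
        if self.pair_policy not in ("canonical", "symmetric-augment"):
            raise ValueError(f"unknown pair policy {self.pair_policy!r}")
        if self.classes is None:
            rules = load_pharmacophore_rules(self.rules_path)
            classes = sorted({r.cls for r in rules} | {FALLBACK_CLASS})
            object.__setattr__(self, "classes", tuple(classes))
        else:
            object.__setattr__(self, "classes", tuple(self.classes))
        if self.descriptors is None:
            object.__setattr__(
                self, "descriptors", load_descriptor_manifest(self.descriptors_path)
            )
        else:
            object.__setattr__(self, "descriptors", tuple(self.descriptors))

    @property
    def class_pairs(self) -> tuple:
        return tuple(combinations_with_replacement(self.classes, 2))

    def signature_names(self) -> list:
        return [
            f"{a}:{b}-{c:.2f}" for (a, b) in self.class_pairs for c in self.cutoffs
        ]

    def drug_feature_names(self) -> list:
        return self.signature_names() + list(self.descriptors)

    def pair_feature_names(self) -> list:
        per = self.drug_feature_names()
        return [f"{n}_drug_A" for n in per] + [f"{n}_drug_B" for n in per]

    @property
    def n_drug_features(self) -> int:
        return len(self.class_pairs) * len(self.cutoffs) + len(self.descriptors)

    def to_dict(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "classes": list(self.classes),
            "rules_path": self.rules_path,
            "descriptors": list(self.descriptors),
            "fp_radius": self.fp_radius,
            "fp_nbits": self.fp_nbits,
            "pair_policy": self.pair_policy,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Signature block


def signature_vector(g: LabeledMolGraph, cutoffs=DEFAULT_CUTOFFS, classes=None):
    """Cumulative pharmacophore-pair distance counts.

    Entry ``(P, Q, c)`` counts unordered atom pairs ``{i, j}`` with ``P``
    among atom i's labels, ``Q`` among atom j's (or vice versa) and graph
    distance ``<= c`` bonds.  An atom pair contributes at most once per
    class pair, however many of its label combinations match.  Counts are
    non-decreasing in the cutoff by construction.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if classes is None:
        classes = sorted({c for s in g.labels for c in s})
    pair_index = {
        p: k for k, p in enumerate(combinations_with_replacement(tuple(classes), 2))
    }
    counts = np.zeros((len(pair_index), len(cutoffs)), dtype=np.int64)
    cut_arr = np.asarray(cutoffs)
    for i in range(g.n_atoms):
        for j in range(i + 1, g.n_atoms):
            d = g.dist[i, j]
            if not np.isfinite(d) or d > cut_arr[-1]:
                continue
            first = int(np.searchsorted(cut_arr, d, side="left"))
            seen = {
                (p, q) if p <= q else (q, p)
                for p in g.labels[i]
                for q in g.labels[j]
            }
            for key in seen:
                if key in pair_index:
                    counts[pair_index[key], first:] += 1
    return counts.reshape(-1)


def descriptor_vector(mol: Molecule, manifest=None) -> np.ndarray:
    """Evaluate the descriptor manifest on a molecule, in manifest order.

    Unknown names raise :class:`UnknownDescriptorError`; a descriptor that
    evaluates to a non-finite value raises rather than silently emitting
    zero.
    """
    if manifest is None:
        manifest = load_descriptor_manifest()
    rdmol = mol.rdmol if mol.rdmol is not None else Chem.MolFromSmiles(mol.smiles)
    values = np.empty(len(manifest), dtype=float)
    for k, name in enumerate(manifest):
        v = float(_descriptor_fn(name)(rdmol))
        if not np.isfinite(v):
            raise ValueError(f"descriptor {name!r} evaluated non-finite on {mol.smiles}")
        values[k] = v
    return values


def drug_feature_vector(mol: Molecule, config: FeatureConfig) -> np.ndarray:
    """Concatenated [signature | descriptor] block for one drug."""
    rules = load_pharmacophore_rules(config.rules_path)
    g = build_labeled_graph(mol, rules)
    sig = signature_vector(g, config.cutoffs, config.classes)
    desc = descriptor_vector(mol, config.descriptors)
    return np.concatenate([sig.astype(float), desc])


def pair_feature_vector(vec_a, vec_b, smiles_a, smiles_b, policy="canonical"):
    """Assemble the pair vector ``[drug A block | drug B block]``.

    Under the ``canonical`` policy the two drugs are first ordered by
    canonical SMILES, so (X, Y) and (Y, X) map to the same vector.  Under
    ``symmetric-augment`` the caller is expected to emit both orderings at
    training time and average the two at prediction time; this function
    then concatenates in the order given.
    """
    if len(vec_a) != len(vec_b):
        raise ValueError("per-drug feature blocks differ in length")
    if policy == "canonical" and smiles_b < smiles_a:
        vec_a, vec_b = vec_b, vec_a
    return np.concatenate([vec_a, vec_b])


class Featurizer:
    """Caches per-drug vectors and builds pair feature matrices.

    Feature computation is per unique canonical SMILES, so a dataset with
    thousands of pair instances over a few dozen drugs featurizes in the
    time of the drug library, not the instance table.
    """

    def __init__(self, config: FeatureConfig = None):
        self.config = config if config is not None else FeatureConfig()
        self._cache = {}
        self._rules = load_pharmacophore_rules(self.config.rules_path)

    @property
    def feature_names(self) -> list:
        return self.config.pair_feature_names()

    def drug_vector(self, smiles: str) -> np.ndarray:
        mol = parse_smiles(smiles)
        key = mol.smiles
        if key not in self._cache:
            g = build_labeled_graph(mol, self._rules)
            sig = signature_vector(g, self.config.cutoffs, self.config.classes)
            desc = descriptor_vector(mol, self.config.descriptors)
            self._cache[key] = np.concatenate([sig.astype(float), desc])
        return self._cache[key]

    def pair_vector(self, smiles_a: str, smiles_b: str) -> np.ndarray:
        a = parse_smiles(smiles_a).smiles
        b = parse_smiles(smiles_b).smiles
        return pair_feature_vector(
            self.drug_vector(a), self.drug_vector(b), a, b, self.config.pair_policy
        )

    def pair_matrix(self, df, augment: bool = None):
        """Feature matrix for a pair table (drug_a_smiles / drug_b_smiles).

        With the ``symmetric-augment`` policy and ``augment=True`` (the
        default at training time for that policy), each row is emitted in
        both orderings and the returned row index maps matrix rows back to
        input rows.
        """
        if augment is None:
            augment = self.config.pair_policy == "symmetric-augment"
        rows, origin = [], []
        for idx, rec in df.iterrows():
            a = parse_smiles(rec["drug_a_smiles"]).smiles
            b = parse_smiles(rec["drug_b_smiles"]).smiles
            va, vb = self.drug_vector(a), self.drug_vector(b)
            rows.append(
                pair_feature_vector(va, vb, a, b, self.config.pair_policy)
            )
            origin.append(idx)
            if augment and self.config.pair_policy == "symmetric-augment":
                rows.append(np.concatenate([vb, va]))
                origin.append(idx)
        return np.asarray(rows, dtype=float), list(origin)

    def pair_matrix_both_orders(self, df):
        """(X_ab, X_ba) for prediction-time averaging under symmetric-augment."""
        fwd, rev = [], []
        for _, rec in df.iterrows():
            a = parse_smiles(rec["drug_a_smiles"]).smiles
            b = parse_smiles(rec["drug_b_smiles"]).smiles
            va, vb = self.drug_vector(a), self.drug_vector(b)
            fwd.append(np.concatenate([va, vb]))
            rev.append(np.concatenate([vb, va]))
        return np.asarray(fwd, dtype=float), np.asarray(rev, dtype=float)
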