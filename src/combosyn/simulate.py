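"""Seeded synthetic molecule libraries and synergy screens.

The generator emulates the shape of a large pairwise oncology combination
screen — a few dozen drug-like molecules, pair x cell-line instances over
several tissue types, continuous Loewe-style synergy scores in [-60, 60]
— with a *planted* structure-synergy rule (by default: the pair carries
at least one methoxy group and at least two rings in total, echoing the
motifs enriched among synergistic combinations in real screens).  Labels
are the rule's output flipped with probability ``label_noise``; scores
are then drawn strictly on the matching side of the binarization
threshold, so curation round-trips the observed labels exactly.

Molecules are assembled by concatenating self-contained SMILES fragments
(each with balanced ring closures), which always yields parseable
drug-like strings; every generated molecule is re-parsed and
canonicalized before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import parse_smiles
from .curation import SYNERGY_THRESHOLD

# Fragment pools: each entry is a valid standalone SMILES whose first atom
# can bond to the previous fragment's tail and whose tail can accept the
# next fragment (multi-valent ends only, so any concatenation parses).
CHAIN_FRAGMENTS = (
    "C", "CC", "CCC", "C(C)C", "CCN", "CN(C)C", "C(=O)C",
    "C(=O)N", "CS", "CNC", "C(F)(F)C", "CC(C)C", "CCCN", "C(C)N",
)
RING_FRAGMENTS = (
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1cncnc1", "C1CCNCC1",
    "C1CCOC1", "c1ccc2ccccc2c1", "c1ccsc1", "C1CN(C)CCN1C",
)
# Appended as a tail: previous atom bonds the first C, giving R-CH2-O-CH3;
# the chain pool is kept free of O-CH3 sources so the planted tail is the
# only way a methoxy group can occur (its frequency is exactly p_methoxy).
METHOXY_FRAGMENT = "COC"

DEFAULT_TISSUES = ("breast", "colon", "lung", "melanoma", "ovarian", "prostate")


def default_rule(methoxy_total: float, ring_total: float) -> int:
    """Planted structure-synergy rule: methoxy_total>=1 and ring_total>=2."""
    return int(methoxy_total >= 1 and ring_total >= 2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic screen (seed-determined)."""

    n_molecules: int = 36
    n_instances: int = 2000
    tissues: tuple = DEFAULT_TISSUES
    n_cell_lines_per_tissue: int = 5
    label_noise: float = 0.05
    p_methoxy: float = 0.4
    ring_count_weights: tuple = (0.3, 0.5, 0.2)  # P(0), P(1), P(2) ring fragments
    n_chain_fragments: tuple = (1, 3)  # inclusive range
    seed: int = 0
    chain_fragments: tuple = CHAIN_FRAGMENTS
    ring_fragments: tuple = RING_FRAGMENTS

    def __post_init__(self):
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not self.chain_fragments:
            raise ValueError("fragment grammar must be non-empty")


def generate_molecule_library(cfg: SyntheticConfig) -> list:
    """``cfg.n_molecules`` unique, parseable, canonical SMILES.

    Each molecule is a seeded draw: 1-3 chain fragments, 0-2 ring
    fragments (weighted), and a methoxy tail with probability
    ``p_methoxy``, shuffled (first fragment kept multi-valent) and
    concatenated.  Raises if the grammar cannot produce enough unique
    molecules within a generous resampling budget.
    """
    rng = np.random.default_rng(cfg.seed)
    seen, library = set(), []
    # The methoxy-tail decision is drawn once per molecule, before body
    # resampling, so uniqueness rejections cannot bias the motif rate.
    for _ in range(cfg.n_molecules):
        has_methoxy = rng.random() < cfg.p_methoxy
        for _attempt in range(500):
            lo, hi = cfg.n_chain_fragments
            parts = list(
                rng.choice(cfg.chain_fragments, size=rng.integers(lo, hi + 1))
            )
            n_rings = rng.choice(len(cfg.ring_count_weights), p=cfg.ring_count_weights)
            parts += list(rng.choice(cfg.ring_fragments, size=n_rings))
            rng.shuffle(parts)
            if has_methoxy:
                parts.append(METHOXY_FRAGMENT)
            try:
                canonical = parse_smiles("".join(parts)).smiles
            except ValueError:
                continue
            if canonical in seen:
                continue
            seen.add(canonical)
            library.append(canonical)
            break
        else:
            raise RuntimeError(
                f"fragment grammar produced only {len(library)} unique "
                f"molecules of the requested {cfg.n_molecules}"
            )
    return library


def _pair_rule_inputs(library, featurizer=None):
    """Per-molecule (methoxy count, ring count) used by the planted rule."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    out = {}
    for smi in library:
        m = Chem.MolFromSmiles(smi)
        out[smi] = (Descriptors.fr_methoxy(m), Descriptors.RingCount(m))
    return out


def plant_synergy_dataset(
    library, cfg: SyntheticConfig, rule=default_rule
) -> pd.DataFrame:
    """Sample a synergy table with a planted structure-synergy rule.

    Returns the curation-schema table (drug_a_smiles, drug_b_smiles,
    cell_line, tissue, synergy_score, label) plus truth-sidecar columns
    ``true_label``, ``methoxy_total`` and ``ring_total`` for recovery
    tests.  Scores land strictly on the observed label's side of the
    binarization threshold (synergistic: uniform [10, 60]; antagonistic:
    uniform [-60, 10)).
    """
    if len(library) < 2:
        raise ValueError("need at least two molecules")
    rng = np.random.default_rng(cfg.seed + 1)
    cell_lines = [
        (f"{t[:3].upper()}-{i:02d}", t)
        for t in cfg.tissues
        for i in range(cfg.n_cell_lines_per_tissue)
    ]
    motifs = _pair_rule_inputs(library)
    pairs = [
        (library[i], library[j])
        for i in range(len(library))
        for j in range(i + 1, len(library))
    ]
    capacity = len(pairs) * len(cell_lines)
    if cfg.n_instances > capacity:
        raise ValueError(
            f"requested {cfg.n_instances} instances but only {capacity} "
            f"(pair, cell line) combinations exist"
        )
    chosen = rng.choice(capacity, size=cfg.n_instances, replace=False)
    rows = []
    for c in chosen:
        (a, b) = pairs[c // len(cell_lines)]
        cell, tissue = cell_lines[c % len(cell_lines)]
        if b < a:
            a, b = b, a
        methoxy_total = motifs[a][0] + motifs[b][0]
        ring_total = motifs[a][1] + motifs[b][1]
        true_label = int(rule(methoxy_total, ring_total))
        observed = true_label ^ int(rng.random() < cfg.label_noise)
        if observed:
            score = rng.uniform(SYNERGY_THRESHOLD, 60.0)
        else:
            score = rng.uniform(-60.0, SYNERGY_THRESHOLD - 1e-9)
        rows.append(
            {
                "drug_a_smiles": a,
                "drug_b_smiles": b,
                "cell_line": cell,
                "tissue": tissue,
                "synergy_score": score,
                "label": observed,
                "true_label": true_label,
                "methoxy_total": methoxy_total,
                "ring_total": ring_total,
            }
        )
    return pd.DataFrame(rows)


def simulate_screen(cfg: SyntheticConfig = None, rule=default_rule):
    """Library + planted dataset in one call (the common entry point)."""
    if cfg is None:
        cfg = SyntheticConfig()
    library = generate_molecule_library(cfg)
    df = plant_synergy_dataset(library, cfg, rule)
    return library, df
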