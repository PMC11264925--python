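"""Dataset curation: synergy binarization, redundancy-aware splitting, CV.

The unit of training and evaluation is a (drug pair, cell line) instance
with a Loewe-style synergy score, binarized at a threshold (default 10,
inclusive) into synergistic (1) vs antagonistic (0).  To keep chemically
similar pairs from straddling the train/test boundary, drugs are clustered
by Butina sphere exclusion on Morgan-fingerprint Tanimoto similarity and
whole *pair-cluster* groups are assigned to one side of the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .chem import Fingerprint, morgan_fingerprint, parse_smiles, tanimoto

SYNERGY_THRESHOLD = 10.0  # Loewe scale

REQUIRED_COLUMNS = ("drug_a_smiles", "drug_b_smiles", "cell_line", "tissue")


class CurationError(ValueError):
    pass


def binarize_synergy(score: float, threshold: float = SYNERGY_THRESHOLD) -> int:
    """1 (synergistic) if ``score >= threshold`` else 0 (antagonistic)."""
    if not np.isfinite(score):
        raise CurationError(f"non-finite synergy score: {score!r}")
    return int(score >= threshold)


def curate_table(
    df: pd.DataFrame,
    threshold: float = SYNERGY_THRESHOLD,
    aggregate: str = "none",
) -> pd.DataFrame:
    """Validate and binarize a synergy table.

    The input needs columns ``drug_a_smiles, drug_b_smiles, cell_line,
    tissue`` and at least one of ``synergy_score`` / ``label``.  Drug
    SMILES are canonicalized and each pair put in canonical (sorted)
    order, making (A, B) and (B, A) the same instance.  ``aggregate``
    controls replicate rows sharing a (pair, cell line) key: ``"none"``
    requires uniqueness, ``"mean"`` averages their scores before
    binarization.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurationError(f"synergy table missing columns: {missing}")
    if "synergy_score" not in df.columns and "label" not in df.columns:
        raise CurationError("synergy table needs synergy_score and/or label")
    out = df.copy()
    canon = {
        s: parse_smiles(s).smiles
        for s in pd.unique(out[["drug_a_smiles", "drug_b_smiles"]].values.ravel())
    }
    a = out["drug_a_smiles"].map(canon)
    b = out["drug_b_smiles"].map(canon)
    swap = b < a
    out["drug_a_smiles"] = a.where(~swap, b)
    out["drug_b_smiles"] = b.where(~swap, a)

    key_cols = ["drug_a_smiles", "drug_b_smiles", "cell_line"]
    if out.duplicated(key_cols).any():
        if aggregate == "mean" and "synergy_score" in out.columns:
            out = (
                out.groupby(key_cols + ["tissue"], as_index=False, sort=False)
                .agg(synergy_score=("synergy_score", "mean"))
            )
        else:
            dup = out[out.duplicated(key_cols, keep=False)]
            raise CurationError(
                f"{len(dup)} replicate (pair, cell line) rows; "
                f"pass aggregate='mean' to average them"
            )
    if "synergy_score" in out.columns:
        out["label"] = [binarize_synergy(s, threshold) for s in out["synergy_score"]]
    out["label"] = out["label"].astype(int)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Butina clustering


@dataclass(frozen=True)
class ClusterAssignment:
    """drug index -> cluster id; singleton clusters allowed."""

    cluster_of: tuple
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_of))

    def sizes(self) -> dict:
        sizes = {}
        for c in self.cluster_of:
            sizes[c] = sizes.get(c, 0) + 1
        return sizes


def butina_cluster(fps, sim_threshold: float = 0.6) -> ClusterAssignment:
    """Butina sphere-exclusion clustering on fingerprint Tanimoto similarity.

    Neighbor lists are built at similarity >= threshold; the unassigned
    item with the most unassigned neighbors (ties -> lowest input index)
    seeds a cluster that absorbs its unassigned neighbors; this repeats
    until everything left is a singleton.
    """
    if len(fps) == 0:
        raise ValueError("need at least one fingerprint")
    if not (0 < sim_threshold <= 1):
        raise ValueError("similarity threshold must be in (0, 1]")
    n = len(fps)
    if isinstance(fps[0], Fingerprint):
        sim = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                sim[i, j] = sim[j, i] = tanimoto(fps[i], fps[j])
    else:  # precomputed similarity matrix (used by the test oracle path)
        sim = np.asarray(fps, dtype=float)
    neighbors = [
        {j for j in range(n) if j != i and sim[i, j] >= sim_threshold}
        for i in range(n)
    ]
    cluster_of = [-1] * n
    unassigned = set(range(n))
    cid = 0
    while unassigned:
        best = max(
            sorted(unassigned),
            key=lambda i: (len(neighbors[i] & unassigned), -i),
        )
        members = {best} | (neighbors[best] & unassigned)
        for m in members:
            cluster_of[m] = cid
        unassigned -= members
        cid += 1
    return ClusterAssignment(cluster_of=tuple(cluster_of), threshold=sim_threshold)


def cluster_drugs(
    smiles_list, sim_threshold: float = 0.6, radius: int = 2, nbits: int = 2048
) -> dict:
    """Butina-cluster a drug library; returns canonical SMILES -> cluster id."""
    canon = [parse_smiles(s).smiles for s in smiles_list]
    uniq = sorted(set(canon))
    fps = [morgan_fingerprint(parse_smiles(s), radius, nbits) for s in uniq]
    ca = butina_cluster(fps, sim_threshold)
    return {s: c for s, c in zip(uniq, ca.cluster_of)}


def pair_cluster_key(smiles_a: str, smiles_b: str, clusters: dict) -> tuple:
    """Unordered (cluster(A), cluster(B)); same for (A,B) and (B,A)."""
    a = parse_smiles(smiles_a).smiles
    b = parse_smiles(smiles_b).smiles
    try:
        ca, cb = clusters[a], clusters[b]
    except KeyError as e:
        raise CurationError(f"drug not clustered: {e.args[0]}") from e
    return (ca, cb) if ca <= cb else (cb, ca)


# ---------------------------------------------------------------------------
# Non-redundant split


@dataclass
class DatasetSplit:
    train_idx: list
    test_idx: list
    fraction: float
    achieved_fraction: float
    leakage: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def nonredundant_split(
    df: pd.DataFrame, clusters: dict, test_fraction: float = 0.2, seed: int = 0
) -> DatasetSplit:
    """Group instances by pair-cluster key; assign whole groups to test.

    Groups are shuffled by ``seed`` and greedily moved to the test side
    until its share first reaches ``test_fraction``; everything else
    trains.  The leakage report proves no pair-cluster key straddles the
    split.  A single group larger than the test budget is forced to train
    with a warning.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    keys = [
        pair_cluster_key(a, b, clusters)
        for a, b in zip(df["drug_a_smiles"], df["drug_b_smiles"])
    ]
    groups = {}
    for idx, k in zip(df.index, keys):
        groups.setdefault(k, []).append(idx)
    rng = np.random.default_rng(seed)
    order = sorted(groups)
    rng.shuffle(order)
    n = len(df)
    budget = test_fraction * n
    test_idx, warnings = [], []
    for k in order:
        if len(test_idx) >= budget:
            break
        if len(groups[k]) > budget:
            warnings.append(
                f"pair-cluster group {k} ({len(groups[k])} instances) exceeds "
                f"the test budget; forced to train"
            )
            continue
        test_idx.extend(groups[k])
    test_set = set(test_idx)
    train_idx = [i for i in df.index if i not in test_set]
    leakage = audit_leakage(keys, df.index, train_idx, test_idx)
    return DatasetSplit(
        train_idx=train_idx,
        test_idx=test_idx,
        fraction=test_fraction,
        achieved_fraction=len(test_idx) / n,
        leakage=leakage,
        warnings=warnings,
    )


def audit_leakage(keys, index, train_idx, test_idx) -> dict:
    key_of = dict(zip(index, keys))
    train_keys = {key_of[i] for i in train_idx}
    test_keys = {key_of[i] for i in test_idx}
    shared = train_keys & test_keys
    return {
        "n_train_keys": len(train_keys),
        "n_test_keys": len(test_keys),
        "shared_keys": sorted(shared),
        "ok": not shared,
    }


# ---------------------------------------------------------------------------
# Cross-validation schemes


@dataclass(frozen=True)
class CVScheme:
    kind: str  # stratified_kfold | leave_pair_out | leave_drug_out | leave_tissue_out
    k: int = 5
    seed: int = 0

    KINDS = ("stratified_kfold", "leave_pair_out", "leave_drug_out", "leave_tissue_out")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown CV scheme {self.kind!r}")

    @property
    def is_partition(self) -> bool:
        # leave_drug_out test folds overlap (a pair has two drugs)
        return self.kind != "leave_drug_out"


def make_cv_folds(df: pd.DataFrame, scheme: CVScheme):
    """Build (train indices, test indices, fold id) triples for a scheme.

    * ``stratified_kfold``: label-stratified k folds (shuffled by seed);
    * ``leave_pair_out``: one fold per distinct unordered drug pair, its
      test set being all cell-line instances of that pair;
    * ``leave_drug_out``: one fold per distinct drug; the test set is all
      instances containing it and the train set all instances containing
      it in neither position (folds overlap; not a partition);
    * ``leave_tissue_out``: one fold per tissue.
    """
    idx = np.asarray(df.index)
    if scheme.kind == "stratified_kfold":
        y = df["label"].to_numpy()
        counts = np.bincount(y, minlength=2)
        if scheme.k > counts.min():
            raise ValueError(
                f"k={scheme.k} exceeds minority class count {counts.min()}"
            )
        skf = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        return [
            (list(idx[tr]), list(idx[te]), f"fold{f}")
            for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y))
        ]
    if scheme.kind == "leave_pair_out":
        pairs = list(zip(df["drug_a_smiles"], df["drug_b_smiles"]))
        folds = []
        for pair in sorted(set(pairs)):
            mask = np.array([p == pair for p in pairs])
            folds.append((list(idx[~mask]), list(idx[mask]), f"pair:{pair[0]}+{pair[1]}"))
        return folds
    if scheme.kind == "leave_drug_out":
        drugs = sorted(set(df["drug_a_smiles"]) | set(df["drug_b_smiles"]))
        folds = []
        for d in drugs:
            mask = ((df["drug_a_smiles"] == d) | (df["drug_b_smiles"] == d)).to_numpy()
            folds.append((list(idx[~mask]), list(idx[mask]), f"drug:{d}"))
        return folds
    if scheme.kind == "leave_tissue_out":
        folds = []
        for t in sorted(df["tissue"].unique()):
            mask = (df["tissue"] == t).to_numpy()
            folds.append((list(idx[~mask]), list(idx[mask]), f"tissue:{t}"))
        return folds
    raise ValueError(f"unknown CV scheme {scheme.kind!r}")
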