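"""Binarization, Butina clustering, leakage-free splits and CV schemes."""

import numpy as np
import pandas as pd
import pytest

from combosyn.curation import (
    CurationError,
    CVScheme,
    binarize_synergy,
    butina_cluster,
    cluster_drugs,
    curate_table,
    make_cv_folds,
    nonredundant_split,
    pair_cluster_key,
)


class TestBinarize:
    @pytest.mark.parametrize("score,label", [(15, 1), (10, 1), (-5, 0), (9.999, 0)])
    def test_threshold_ten_inclusive(self, score, label):
        assert binarize_synergy(score) == label

    def test_nonfinite_score_rejected(self):
        with pytest.raises(CurationError):
            binarize_synergy(float("nan"))

    def test_curate_requires_score_or_label(self):
        df = pd.DataFrame(
            [{"drug_a_smiles": "C", "drug_b_smiles": "CC",
              "cell_line": "x", "tissue": "colon"}]
        )
        with pytest.raises(CurationError):
            curate_table(df)

    def test_curate_canonicalizes_pair_order(self):
        df = pd.DataFrame(
            [
                {"drug_a_smiles": "c1ccccc1", "drug_b_smiles": "CCO",
                 "cell_line": "x", "tissue": "colon", "synergy_score": 20.0},
                {"drug_a_smiles": "OCC", "drug_b_smiles": "c1ccccc1",
                 "cell_line": "y", "tissue": "colon", "synergy_score": -20.0},
            ]
        )
        out = curate_table(df)
        assert out["drug_a_smiles"].nunique() == 1
        assert list(out["label"]) == [1, 0]

    def test_replicate_aggregation(self):
        row = {"drug_a_smiles": "C", "drug_b_smiles": "CC",
               "cell_line": "x", "tissue": "colon"}
        df = pd.DataFrame([dict(row, synergy_score=5.0), dict(row, synergy_score=25.0)])
        with pytest.raises(CurationError):
            curate_table(df)
        out = curate_table(df, aggregate="mean")
        assert len(out) == 1 and out["label"].iloc[0] == 1  # mean 15 >= 10


def butina_reference(sim, threshold):
    """Independent brute-force re-trace of the sphere-exclusion procedure."""
    n = len(sim)
    assigned = {}
    cid = 0
    while len(assigned) < n:
        best, best_count = None, -1
        for i in range(n):
            if i in assigned:
                continue
            count = sum(
                1
                for j in range(n)
                if j != i and j not in assigned and sim[i][j] >= threshold
            )
            if count > best_count:  # strict: ties keep the lowest index
                best, best_count = i, count
        members = [best] + [
            j
            for j in range(n)
            if j != best and j not in assigned and sim[best][j] >= threshold
        ]
        for m in members:
            assigned[m] = cid
        cid += 1
    return [assigned[i] for i in range(n)]


def same_partition(a, b):
    groups_a = {}
    groups_b = {}
    for i, (x, y) in enumerate(zip(a, b)):
        groups_a.setdefault(x, set()).add(i)
        groups_b.setdefault(y, set()).add(i)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


class TestButina:
    def test_identical_items_single_cluster(self):
        sim = np.ones((4, 4))
        ca = butina_cluster(sim, 0.6)
        assert ca.n_clusters == 1

    def test_hand_traced_two_pairs(self):
        sim = np.eye(4)
        sim[0, 1] = sim[1, 0] = 0.8
        sim[2, 3] = sim[3, 2] = 0.7
        sim[0, 2] = sim[2, 0] = sim[0, 3] = sim[3, 0] = 0.1
        sim[1, 2] = sim[2, 1] = sim[1, 3] = sim[3, 1] = 0.1
        ca = butina_cluster(sim, 0.6)
        assert ca.cluster_of[0] == ca.cluster_of[1]
        assert ca.cluster_of[2] == ca.cluster_of[3]
        assert ca.cluster_of[0] != ca.cluster_of[2]

    def test_all_dissimilar_all_singletons(self):
        sim = np.eye(5)
        ca = butina_cluster(sim, 0.6)
        assert ca.n_clusters == 5

    def test_sizes_partition_everything(self):
        rng = np.random.default_rng(0)
        m = rng.random((7, 7))
        sim = (m + m.T) / 2
        np.fill_diagonal(sim, 1)
        ca = butina_cluster(sim, 0.5)
        assert sum(ca.sizes().values()) == 7

    @pytest.mark.parametrize("threshold", [0.4, 0.6, 0.8])
    def test_matches_exhaustive_reference(self, threshold):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            m = rng.random((n, n))
            sim = (m + m.T) / 2
            np.fill_diagonal(sim, 1.0)
            ca = butina_cluster(sim, threshold)
            ref = butina_reference(sim.tolist(), threshold)
            assert same_partition(ca.cluster_of, ref)


def toy_dataset(n_drugs=10, n_rows=60, seed=0):
    """Synthetic pair table over simple alkane/arene drugs."""
    drugs = ["C" * (i + 1) for i in range(n_drugs // 2)] + [
        "c1ccccc1" + "C" * i for i in range(n_drugs - n_drugs // 2)
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_rows):
        i, j = rng.choice(n_drugs, size=2, replace=False)
        rows.append(
            {
                "drug_a_smiles": drugs[i],
                "drug_b_smiles": drugs[j],
                "cell_line": f"cl{rng.integers(6)}",
                "tissue": ["colon", "breast", "lung"][rng.integers(3)],
                "synergy_score": float(rng.uniform(-60, 60)),
            }
        )
    # swapped-order duplicates collide after canonicalization; average them
    return drugs, curate_table(pd.DataFrame(rows), aggregate="mean")


class TestPairKeyAndSplit:
    def test_pair_key_symmetric(self):
        clusters = {"C": 3, "CC": 1}
        assert pair_cluster_key("C", "CC", clusters) == (1, 3)
        assert pair_cluster_key("CC", "C", clusters) == (1, 3)
        assert pair_cluster_key("C", "C", clusters) == (3, 3)

    def test_unclustered_drug_errors(self):
        with pytest.raises(CurationError):
            pair_cluster_key("C", "CCO", {"C": 0})

    def test_split_no_leakage_and_partition(self):
        drugs, df = toy_dataset()
        clusters = cluster_drugs(drugs, 0.6)
        split = nonredundant_split(df, clusters, 0.2, seed=3)
        assert split.leakage["ok"]
        assert set(split.train_idx) | set(split.test_idx) == set(df.index)
        assert not set(split.train_idx) & set(split.test_idx)

    def test_split_deterministic(self):
        drugs, df = toy_dataset()
        clusters = cluster_drugs(drugs, 0.6)
        s1 = nonredundant_split(df, clusters, 0.2, seed=5)
        s2 = nonredundant_split(df, clusters, 0.2, seed=5)
        assert s1.test_idx == s2.test_idx

    def test_greedy_whole_groups(self):
        # 5 groups of sizes [4,3,1,1,1]: whole groups enter test until the
        # 20% budget (2 instances) is first reached
        df = pd.DataFrame(
            [
                {"drug_a_smiles": a, "drug_b_smiles": b, "cell_line": f"c{k}",
                 "tissue": "colon", "synergy_score": 15.0}
                for a, b, reps in [
                    ("C", "CC", 4), ("CCC", "CCCC", 3), ("C", "CCC", 1),
                    ("CC", "CCCC", 1), ("C", "CCCC", 1),
                ]
                for k in range(reps)
            ]
        )
        clusters = {s: i for i, s in enumerate(["C", "CC", "CCC", "CCCC"])}
        split = nonredundant_split(curate_table(df), clusters, 0.2, seed=11)
        keys = {
            pair_cluster_key(a, b, clusters)
            for a, b in zip(
                df.loc[split.test_idx, "drug_a_smiles"],
                df.loc[split.test_idx, "drug_b_smiles"],
            )
        }
        # every selected key contributes all its instances
        for k in keys:
            members = [
                i for i in df.index
                if pair_cluster_key(
                    df.loc[i, "drug_a_smiles"], df.loc[i, "drug_b_smiles"], clusters
                ) == k
            ]
            assert set(members) <= set(split.test_idx)
        assert len(split.test_idx) >= 2
        assert split.leakage["ok"]

    def test_oversized_group_forced_to_train(self):
        df = pd.DataFrame(
            [
                {"drug_a_smiles": "C", "drug_b_smiles": "CC", "cell_line": f"c{k}",
                 "tissue": "colon", "synergy_score": 15.0}
                for k in range(9)
            ]
            + [
                {"drug_a_smiles": "CCC", "drug_b_smiles": "CCCC", "cell_line": "c0",
                 "tissue": "colon", "synergy_score": -15.0}
            ]
        )
        clusters = {"C": 0, "CC": 1, "CCC": 2, "CCCC": 3}
        split = nonredundant_split(curate_table(df), clusters, 0.2, seed=0)
        assert split.warnings  # the 9-instance group exceeds the 2-instance budget
        assert split.leakage["ok"]


class TestCVSchemes:
    def test_leave_drug_out_set_construction(self):
        df = pd.DataFrame(
            [
                {"drug_a_smiles": a, "drug_b_smiles": b, "cell_line": "c",
                 "tissue": "colon", "synergy_score": 15.0}
                for a, b in [("C", "CC"), ("C", "CCC"), ("CC", "CCC")]
            ]
        )
        df = curate_table(df)
        folds = make_cv_folds(df, CVScheme("leave_drug_out"))
        assert len(folds) == 3
        by_drug = {fid.split(":")[1]: (tr, te) for tr, te, fid in folds}
        tr, te = by_drug["C"]
        assert len(te) == 2 and len(tr) == 1

    def test_partition_schemes_cover_disjointly(self, screen):
        _, _, df = screen
        for scheme in [
            CVScheme("stratified_kfold", k=5, seed=1),
            CVScheme("leave_pair_out"),
            CVScheme("leave_tissue_out"),
        ]:
            folds = make_cv_folds(df, scheme)
            all_test = [i for _, te, _ in folds for i in te]
            assert sorted(all_test) == sorted(df.index)

    def test_fold_counts(self, screen):
        _, _, df = screen
        n_drugs = len(set(df["drug_a_smiles"]) | set(df["drug_b_smiles"]))
        n_tissues = df["tissue"].nunique()
        n_pairs = len(set(zip(df["drug_a_smiles"], df["drug_b_smiles"])))
        assert len(make_cv_folds(df, CVScheme("leave_drug_out"))) == n_drugs
        assert len(make_cv_folds(df, CVScheme("leave_tissue_out"))) == n_tissues
        assert len(make_cv_folds(df, CVScheme("leave_pair_out"))) == n_pairs

    def test_stratified_exact_divisibility(self):
        df = pd.DataFrame(
            {
                "drug_a_smiles": ["C"] * 100,
                "drug_b_smiles": ["CC"] * 100,
                "cell_line": [f"c{i}" for i in range(100)],
                "tissue": ["colon"] * 100,
                "label": [0, 1] * 50,
            }
        )
        folds = make_cv_folds(df, CVScheme("stratified_kfold", k=5, seed=0))
        for _, te, _ in folds:
            labels = df.loc[te, "label"]
            assert len(te) == 20 and labels.sum() == 10

    def test_k_exceeding_minority_class_errors(self):
        df = pd.DataFrame(
            {
                "drug_a_smiles": ["C"] * 10,
                "drug_b_smiles": ["CC"] * 10,
                "cell_line": [f"c{i}" for i in range(10)],
                "tissue": ["colon"] * 10,
                "label": [1] + [0] * 9,
            }
        )
        with pytest.raises(ValueError):
            make_cv_folds(df, CVScheme("stratified_kfold", k=5))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            CVScheme("leave_planet_out")

    def test_leave_drug_out_train_excludes_held_out_drug(self, screen):
        _, _, df = screen
        folds = make_cv_folds(df, CVScheme("leave_drug_out"))
        tr, te, fid = folds[0]
        drug = fid.split(":", 1)[1]
        sub = df.loc[tr]
        assert not ((sub["drug_a_smiles"] == drug) | (sub["drug_b_smiles"] == drug)).any()
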