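"""Filters, ARI, K-means protocol, density binning, recovery, few-shot."""

import numpy as np
import pandas as pd
import pytest

from dnaclr.evaluation import (BinningParams, ari, fewshot_eval,
                               filter_balanced, filter_binning,
                               kmeans_cluster_eval, modified_kmedoid,
                               species_recovery, UNBINNED)
from dnaclr.exceptions import InputError
from dnaclr.io import EmbeddingMatrix


from _oracles import textbook_ari


def make_truth(assignments):
    return pd.DataFrame(
        [{"id": i, "species": s} for i, s in assignments.items()],
        columns=["id", "species"])


class TestFilterBalanced:
    def _df(self, counts):
        rows = []
        for sp, n in counts.items():
            rows += [{"id": f"{sp}_{i}", "species": sp} for i in range(n)]
        return pd.DataFrame(rows)

    def test_rule_application(self):
        out = filter_balanced(self._df({"A": 99, "B": 150, "C": 100}))
        sizes = out.groupby("species").size().to_dict()
        assert sizes == {"B": 100, "C": 100}

    def test_all_large_capped(self):
        out = filter_balanced(self._df({"A": 120, "B": 300}))
        assert out.groupby("species").size().to_dict() == {"A": 100, "B": 100}

    def test_seeded_determinism(self):
        df = self._df({"A": 150, "B": 200})
        a = filter_balanced(df, seed=7)
        b = filter_balanced(df, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_result(self):
        out = filter_balanced(self._df({"A": 5}))
        assert len(out) == 0


class TestFilterBinning:
    def _df(self):
        rows = []
        for i in range(12):
            rows.append({"id": f"a{i}", "species": "A", "length": 3000})
        for i in range(12):
            rows.append({"id": f"b{i}", "species": "B",
                         "length": 2500 if i < 3 else 3000})
        for i in range(9):
            rows.append({"id": f"c{i}", "species": "C", "length": 5000})
        return pd.DataFrame(rows)

    def test_strict_length_cutoff(self):
        out = filter_binning(self._df())
        assert not (out["id"].str.startswith("b") & (out["length"] <= 2500)).any()

    def test_species_minimum(self):
        out = filter_binning(self._df())
        sizes = out.groupby("species").size().to_dict()
        # B drops to 9 after the length filter -> removed; C has 9 -> removed
        assert sizes == {"A": 12}

    def test_boundary_species_of_ten_kept(self):
        df = pd.DataFrame([{"id": f"x{i}", "species": "X", "length": 2501}
                           for i in range(10)])
        assert len(filter_binning(df)) == 10


class TestAri:
    def test_trivial_cases(self):
        assert ari([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
        assert ari([1, 1, 1, 1], [0, 1, 2, 1]) == pytest.approx(0.0)

    def test_hand_contingency_example(self):
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        assert ari(a, b) == pytest.approx(textbook_ari(a, b), abs=1e-12)

    def test_matches_textbook_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            assert ari(a, b) == pytest.approx(textbook_ari(a, b), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            ari([0, 1], [0, 1, 2])


class TestKmeansEval:
    def test_separable_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (50, 4)),
                       rng.normal(10, 0.1, (50, 4))])
        labels = ["a"] * 50 + ["b"] * 50
        assert kmeans_cluster_eval(X, labels, seed=0) == pytest.approx(1.0)

    def test_no_signal_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 8))
        labels = list(rng.integers(0, 5, 500))
        assert abs(kmeans_cluster_eval(X, labels, seed=0)) < 0.05

    def test_duplication_invariance(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(5, 1, (30, 3))])
        labels = ["a"] * 30 + ["b"] * 30
        a = kmeans_cluster_eval(X, labels, seed=3)
        b = kmeans_cluster_eval(np.vstack([X, X]), labels * 2, seed=3)
        assert a == pytest.approx(b)


def gaussian_embeddings(n_per=50,
                        centers=((10, 0, 0), (0, 10, 0), (0, 0, 10)),
                        seed=0):
    rng = np.random.default_rng(seed)
    rows, ids, species = [], [], []
    for ci, c in enumerate(centers):
        pts = rng.normal(loc=c, scale=0.05, size=(n_per, len(c)))
        rows.append(pts)
        ids += [f"s{ci}_{i}" for i in range(n_per)]
        species += [f"sp{ci}"] * n_per
    emb = EmbeddingMatrix(ids=ids, rows=np.vstack(rows), source="synthetic")
    truth = make_truth(dict(zip(ids, species)))
    return emb, truth, species


class TestModifiedKmedoid:
    def test_three_separable_clusters(self):
        emb, truth, species = gaussian_embeddings()
        result = modified_kmedoid(emb, BinningParams(seed=0))
        assert len(result.bins) == 3
        pred = result.labels(emb.ids)
        assert ari(pred, species) == pytest.approx(1.0)

    def test_bins_disjoint_and_total(self):
        emb, _, _ = gaussian_embeddings(seed=3)
        result = modified_kmedoid(emb)
        seen = [i for b in result.bins for i in b]
        assert len(seen) == len(set(seen))
        assert set(result.assignment) == set(emb.ids)
        unb = [i for i, b in result.assignment.items() if b == UNBINNED]
        assert len(seen) + len(unb) == len(emb.ids)

    def test_all_identical_points_single_bin(self):
        emb = EmbeddingMatrix(ids=[f"i{k}" for k in range(20)],
                              rows=np.ones((20, 3)), source="synthetic")
        result = modified_kmedoid(emb)
        assert len(result.bins) == 1
        assert len(result.bins[0]) == 20

    def test_too_few_points_all_unbinned(self):
        emb = EmbeddingMatrix(ids=["a", "b"], rows=np.eye(2), source="synthetic")
        result = modified_kmedoid(emb, BinningParams(min_bin_size=5))
        assert result.bins == []
        assert all(v == UNBINNED for v in result.assignment.values())


class TestSpeciesRecovery:
    def test_exact_bin_gives_f1_one(self):
        emb, truth, _ = gaussian_embeddings()
        result = modified_kmedoid(emb, BinningParams(seed=0))
        rec = species_recovery(result, truth)
        assert all(f1 == pytest.approx(1.0) for f1 in rec.best_f1.values())
        assert rec.band_counts[(0.9, 1.0)] == 3
        assert rec.n_identified == 3

    def test_half_species_bin_f1(self):
        ids = [f"x{i}" for i in range(100)]
        truth = make_truth({i: "s" for i in ids})
        from dnaclr.evaluation import BinningResult
        result = BinningResult(
            assignment={**{i: "bin0" for i in ids[:50]},
                        **{i: UNBINNED for i in ids[50:]}},
            bins=[ids[:50]], threshold=0.1)
        rec = species_recovery(result, truth)
        assert rec.best_f1["s"] == pytest.approx(2 / 3)

    def test_zero_bins_zero_bands(self):
        truth = make_truth({"a": "s1", "b": "s2"})
        from dnaclr.evaluation import BinningResult
        result = BinningResult(assignment={"a": UNBINNED, "b": UNBINNED},
                               bins=[], threshold=0.1)
        rec = species_recovery(result, truth)
        assert sum(rec.band_counts.values()) == 0

    def test_band_counts_sum_matches_identified(self):
        emb, truth, _ = gaussian_embeddings(n_per=30, seed=5)
        rec = species_recovery(modified_kmedoid(emb), truth)
        n_ge_half = sum(1 for f1 in rec.best_f1.values() if f1 >= 0.5)
        assert rec.n_identified == n_ge_half

    def test_unknown_id_rejected(self):
        truth = make_truth({"a": "s1"})
        from dnaclr.evaluation import BinningResult
        result = BinningResult(assignment={"zzz": "bin0"}, bins=[["zzz"]],
                               threshold=0.1)
        with pytest.raises(InputError):
            species_recovery(result, truth)


class TestFewshot:
    def test_one_hot_species_perfect_at_one_shot(self):
        n_sp, per = 3, 100
        rows = np.repeat(np.eye(n_sp), per, axis=0)
        labels = np.repeat([f"sp{i}" for i in range(n_sp)], per)
        f1 = fewshot_eval(rows, labels, shots=(1,), n_test=80, n_runs=2, seed=0)
        assert f1[1] == pytest.approx(1.0)

    def test_noise_embeddings_chance_level(self):
        rng = np.random.default_rng(0)
        n_sp, per = 10, 100
        rows = rng.normal(size=(n_sp * per, 16))
        labels = np.repeat([f"sp{i}" for i in range(n_sp)], per)
        f1 = fewshot_eval(rows, labels, shots=(5,), n_test=80, n_runs=3, seed=0)
        assert f1[5] == pytest.approx(0.1, abs=0.05)

    def test_more_shots_never_worse(self, small_community):
        from dnaclr.baselines import tnf_matrix
        com = small_community
        X = tnf_matrix([f.seq for f in com.fragments])
        labels = np.array(com.truth["species"])
        f1 = fewshot_eval(X, labels, shots=(1, 20), n_test=5, n_runs=5, seed=0)
        assert f1[20] >= f1[1]

    def test_insufficient_counts_rejected(self):
        rows = np.ones((30, 4))
        labels = ["a"] * 15 + ["b"] * 15
        with pytest.raises(InputError):
            fewshot_eval(rows, labels, shots=(5,), n_test=80)
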