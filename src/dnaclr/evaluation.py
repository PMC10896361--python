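"""Embedding-agnostic evaluation: clustering ARI, metagenomics binning by a
modified K-medoid density loop, species-recovery F1 bands, few-shot linear
probing, and the dataset filtering rules used before each task.

All evaluations consume an :class:`~dnaclr.io.EmbeddingMatrix` (or a plain
(N, D) array plus ids) and a truth table mapping sequence id to species, so
they apply identically to TNF, TNF-K, and learned embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, f1_score

from .exceptions import InputError
from .io import EmbeddingMatrix

UNBINNED = "unbinned"

F1_BANDS = ((0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0))


# ---------------------------------------------------------------------------
# Dataset filtering rules


def filter_balanced(truth: pd.DataFrame, min_count: int = 100,
                    cap: int = 100, seed: int = 0) -> pd.DataFrame:
    """Drop species with fewer than `min_count` sequences; downsample the
    survivors to exactly `cap` sequences each (seeded)."""
    rng = np.random.default_rng(seed)
    kept = []
    for species, grp in truth.groupby("species", sort=True):
        if len(grp) < min_count:
            continue
        idx = rng.choice(len(grp), size=cap, replace=False)
        kept.append(grp.iloc[np.sort(idx)])
    if not kept:
        return truth.iloc[0:0]
    return pd.concat(kept, ignore_index=True)


def filter_binning(truth: pd.DataFrame, lengths: Optional[dict] = None,
                   min_len: int = 2500, min_species: int = 10) -> pd.DataFrame:
    """Keep sequences strictly longer than `min_len` bp, then drop species
    left with fewer than `min_species` sequences.

    Lengths come from a `length` column or the `lengths` mapping (id → bp).
    """
    df = truth.copy()
    if "length" not in df.columns:
        if lengths is None:
            raise InputError("provide a length column or an id->length mapping")
        df["length"] = df["id"].map(lengths)
    df = df[df["length"] > min_len]
    sizes = df.groupby("species")["id"].transform("size")
    return df[sizes >= min_species].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Clustering


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand Index in [−1, 1] (permutation-model chance correction)."""
    if len(labels_a) != len(labels_b):
        raise InputError("label vectors differ in length")
    if len(labels_a) < 2:
        raise InputError("need at least 2 items")
    return float(adjusted_rand_score(labels_a, labels_b))


def kmeans_cluster_eval(emb: EmbeddingMatrix | np.ndarray,
                        true_labels: Sequence, seed: int = 0) -> float:
    """K-means with k = number of distinct true labels; returns ARI vs truth."""
    X = emb.rows if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)
    true_labels = list(true_labels)
    k = len(set(true_labels))
    if k < 2:
        raise InputError("need at least 2 species")
    if X.shape[0] < k:
        raise InputError(f"{X.shape[0]} points < {k} clusters")
    pred = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    return ari(pred, true_labels)


def kmeans_ari_mean(emb, true_labels, seeds: Sequence[int] = range(5)) -> float:
    """Protocol average: mean ARI over independent K-means seeds."""
    return float(np.mean([kmeans_cluster_eval(emb, true_labels, s)
                          for s in seeds]))


# ---------------------------------------------------------------------------
# Modified K-medoid binning


@dataclass(frozen=True)
class BinningParams:
    """Controls for the density-based binning loop.

    The distance threshold is "learned" from a subsample of the pairwise
    cosine-distance distribution: by default an Otsu split (the threshold
    minimizing intra-class variance), which lands in the valley between
    within-species and between-species distances when the embedding has
    cluster structure; `threshold_method="quantile"` uses the
    `threshold_quantile` quantile instead. `min_bin_size` is the smallest
    region still emitted as a bin; medoid refinement re-centers within the
    candidate set at most `max_refine` times.
    """

    threshold_method: str = "otsu"
    threshold_quantile: float = 0.05
    min_bin_size: int = 5
    max_refine: int = 3
    max_pairs_sample: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.min_bin_size < 1:
            raise InputError("min_bin_size must be >= 1")
        if self.threshold_method not in ("otsu", "quantile"):
            raise InputError("threshold_method must be 'otsu' or 'quantile'")
        if not 0.0 < self.threshold_quantile <= 1.0:
            raise InputError("threshold_quantile must be in (0, 1]")


@dataclass
class BinningResult:
    """Disjoint bins plus an `unbinned` remainder covering all ids."""

    assignment: dict[str, str]   # id -> bin id or UNBINNED
    bins: list[list[str]]
    threshold: float

    def labels(self, ids: Sequence[str]) -> list[str]:
        return [self.assignment[i] for i in ids]


def _otsu_threshold(sample: np.ndarray, n_bins: int = 256) -> float:
    """Two-class variance-minimizing split of a 1-D sample."""
    if np.ptp(sample) < 1e-12:  # degenerate: all points coincide
        return float(sample.max() + 1e-12)
    hist, edges = np.histogram(sample, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    best, best_t = -np.inf, centers[0]
    csum = np.cumsum(w)
    cmean = np.cumsum(w * centers)
    mean_all = cmean[-1] / total
    for i in range(n_bins - 1):
        w0 = csum[i] / total
        w1 = 1.0 - w0
        if w0 == 0.0 or w1 == 0.0:
            continue
        m0 = cmean[i] / csum[i]
        m1 = (cmean[-1] - cmean[i]) / (total - csum[i])
        between = w0 * w1 * (m0 - m1) ** 2
        if between > best:
            best, best_t = between, edges[i + 1]
    return float(best_t)


def learn_threshold(X: np.ndarray, params: BinningParams) -> float:
    """Learn a cosine-distance threshold from the (subsampled) pairwise
    distance distribution, by Otsu split or quantile."""
    n = X.shape[0]
    rng = np.random.default_rng(params.seed)
    if n * (n - 1) // 2 <= params.max_pairs_sample:
        d = 1.0 - X @ X.T
        iu = np.triu_indices(n, k=1)
        sample = d[iu]
    else:
        i = rng.integers(0, n, size=params.max_pairs_sample)
        j = rng.integers(0, n, size=params.max_pairs_sample)
        keep = i != j
        sample = 1.0 - np.einsum("ij,ij->i", X[i[keep]], X[j[keep]])
    if params.threshold_method == "otsu":
        return _otsu_threshold(sample)
    return float(np.quantile(sample, params.threshold_quantile))


def modified_kmedoid(emb: EmbeddingMatrix,
                     params: BinningParams = BinningParams()) -> BinningResult:
    """Iterative density binning over length-normalized embeddings.

    Repeatedly: find the point with the most neighbors within the learned
    cosine-distance threshold (ties to the lowest index), re-center the
    medoid within its candidate set a bounded number of times, emit the
    neighborhood as a bin and remove it. Stops when the densest remaining
    region holds fewer than `min_bin_size` points; leftovers are unbinned.
    """
    ids = list(emb.ids)
    X = np.asarray(emb.rows, float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    X = X / norms
    n = X.shape[0]
    assignment = {i: UNBINNED for i in ids}
    bins: list[list[str]] = []
    if n == 0:
        return BinningResult(assignment, bins, np.nan)
    threshold = learn_threshold(X, params)

    remaining = np.arange(n)
    while remaining.size >= params.min_bin_size:
        Xr = X[remaining]
        D = 1.0 - Xr @ Xr.T
        within = D <= threshold
        counts = within.sum(axis=1)
        medoid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        if counts[medoid] < params.min_bin_size:
            break
        for _ in range(params.max_refine):
            members = np.flatnonzero(within[medoid])
            # re-center: candidate with the most neighbors inside the region
            local = within[np.ix_(members, members)].sum(axis=1)
            new_medoid = int(members[np.argmax(local)])
            if new_medoid == medoid:
                break
            medoid = new_medoid
        members = np.flatnonzero(within[medoid])
        if members.size < params.min_bin_size:
            break
        bin_ids = [ids[remaining[i]] for i in members]
        bin_name = f"bin{len(bins)}"
        for bid in bin_ids:
            assignment[bid] = bin_name
        bins.append(bin_ids)
        keep = np.ones(remaining.size, bool)
        keep[members] = False
        remaining = remaining[keep]
    return BinningResult(assignment, bins, threshold)


# ---------------------------------------------------------------------------
# Species recovery


@dataclass
class SpeciesRecovery:
    """Per-species best F1 under one-to-one bin matching, plus band counts."""

    best_f1: dict[str, float]
    band_counts: dict[tuple[float, float], int]

    @property
    def n_identified(self) -> int:
        return sum(self.band_counts.values())


def species_recovery(result: BinningResult, truth: pd.DataFrame) -> SpeciesRecovery:
    """Match bins to species one-to-one greedily by descending F1.

    For a bin b and species s: precision = |b∩s|/|b|, recall = |b∩s|/|s|,
    F1 their harmonic mean. Each bin may identify at most one species and
    vice versa. Band counts cover matched species with F1 >= 0.5.
    """
    truth_map = dict(zip(truth["id"], truth["species"]))
    for b in result.bins:
        for i in b:
            if i not in truth_map:
                raise InputError(f"binned id {i!r} missing from truth")
    species_members: dict[str, set] = {}
    for i, s in truth_map.items():
        species_members.setdefault(s, set()).add(i)

    scored = []
    for bi, b in enumerate(result.bins):
        bset = set(b)
        for s, members in species_members.items():
            inter = len(bset & members)
            if inter == 0:
                continue
            prec = inter / len(bset)
            rec = inter / len(members)
            scored.append((2 * prec * rec / (prec + rec), bi, s))
    # greedy one-to-one matching, deterministic tie-break
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_bins, best = set(), {s: 0.0 for s in species_members}
    matched = set()
    for f1, bi, s in scored:
        if bi in used_bins or s in matched:
            continue
        used_bins.add(bi)
        matched.add(s)
        best[s] = f1
    bands = {band: 0 for band in F1_BANDS}
    for s, f1 in best.items():
        for lo, hi in F1_BANDS:
            if (lo <= f1 < hi) or (hi == 1.0 and lo <= f1 <= 1.0):
                bands[(lo, hi)] += 1
                break
    return SpeciesRecovery(best_f1=best, band_counts=bands)


# ---------------------------------------------------------------------------
# Few-shot linear probe


def fewshot_eval(emb: EmbeddingMatrix | np.ndarray, labels: Sequence,
                 shots: Sequence[int] = (1, 2, 5, 10, 20),
                 n_test: int = 80, n_runs: int = 5, seed: int = 0) -> dict[int, float]:
    """Few-shot species classification with a logistic-regression probe.

    Per run: 80 embeddings per species are held out as the test set; k
    training embeddings per species are sampled from the remainder; a
    multinomial logistic-regression model (L2, C=1) is fitted and scored by
    macro F1 on the test set. Returns the mean macro F1 over `n_runs` per
    shot count.
    """
    X = emb.rows if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)
    labels = np.asarray(labels)
    species = np.unique(labels)
    max_shot = max(shots)
    for s in species:
        if (labels == s).sum() < n_test + max_shot:
            raise InputError(
                f"species {s!r} has fewer than {n_test + max_shot} embeddings")
    out = {k: [] for k in shots}
    for run in range(n_runs):
        rng = np.random.default_rng(seed + run)
        test_idx, pool_idx = [], {}
        for s in species:
            idx = np.flatnonzero(labels == s)
            idx = rng.permutation(idx)
            test_idx.extend(idx[:n_test])
            pool_idx[s] = idx[n_test:]
        test_idx = np.array(test_idx)
        for k in shots:
            train_idx = np.concatenate([pool_idx[s][:k] for s in species])
            clf = LogisticRegression(C=1.0, max_iter=2000)
            clf.fit(X[train_idx], labels[train_idx])
            pred = clf.predict(X[test_idx])
            out[k].append(f1_score(labels[test_idx], pred, average="macro"))
    return {k: float(np.mean(v)) for k, v in out.items()}
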