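"""K-mer composition of granule-enriched vs background transcripts.

Per-transcript k-mer frequencies use overlapping windows normalized by
the number of valid windows (L - k + 1 for N-free sequences), so each
frequency vector sums to one.  Set-level vectors are unweighted means
over transcripts.  The enriched-vs-invariant log2 fold change per k-mer,
computed per condition, forms a 4^k x conditions matrix that is
partitioned by k-means (three clusters by default, deterministic given a
seed, labels canonicalized by descending cluster mean).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@lru_cache(maxsize=None)
def all_kmers(k: int) -> tuple[str, ...]:
    """All 4^k DNA k-mers in lexicographic order."""
    return tuple("".join(p) for p in product("ACGT", repeat=k))


def kmer_frequencies(sequence: str, k: int = 4) -> pd.Series:
    """Overlapping-window k-mer frequencies of one sequence.

    Windows containing N (or any non-ACGT character) are excluded from
    both numerator and denominator; for an N-free sequence the vector
    sums to exactly one.
    """
    seq = sequence.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    codes = np.fromiter((_BASE_INDEX.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))
    valid = codes >= 0
    # rolling base-4 encoding of windows; invalidate windows touching a bad base
    n_win = len(seq) - k + 1
    window_ok = np.ones(n_win, dtype=bool)
    for off in range(k):
        window_ok &= valid[off: off + n_win]
    idx = np.zeros(n_win, dtype=np.int64)
    for off in range(k):
        idx = idx * 4 + np.where(valid[off: off + n_win], codes[off: off + n_win], 0)
    counts = np.bincount(idx[window_ok], minlength=4**k)
    denom = int(window_ok.sum())
    freqs = counts / denom if denom else np.zeros(4**k)
    return pd.Series(freqs, index=list(all_kmers(k)), name="frequency")


def set_mean_frequency(genes, sequences: dict[str, str], k: int = 4) -> pd.Series:
    """Unweighted mean of per-transcript k-mer frequency vectors.

    Each transcript counts once regardless of its length.  Genes without
    a sequence are skipped; an empty usable set is an error.
    """
    usable = [g for g in genes if g in sequences and len(sequences[g]) >= k]
    if not usable:
        raise ValueError("no usable sequences in gene set")
    acc = np.zeros(4**k)
    for g in usable:
        acc += kmer_frequencies(sequences[g], k).to_numpy()
    return pd.Series(acc / len(usable), index=list(all_kmers(k)))


def kmer_fold_change(enriched_mean: pd.Series, invariant_mean: pd.Series,
                     pseudo: float | None = None) -> pd.Series:
    """Per-k-mer log2 ratio of enriched-set vs background mean frequency.

    ``pseudo`` defaults to half the smallest positive frequency observed
    in either vector, keeping zero-frequency k-mers finite.
    """
    e = enriched_mean.to_numpy(dtype=float)
    b = invariant_mean.reindex(enriched_mean.index).to_numpy(dtype=float)
    if pseudo is None:
        pos = np.concatenate([e[e > 0], b[b > 0]])
        pseudo = float(pos.min() / 2) if len(pos) else 1e-9
    return pd.Series(np.log2((e + pseudo) / (b + pseudo)), index=enriched_mean.index,
                     name="log2FC")


def kmer_fold_change_matrix(enriched_sets: dict[str, set[str]], invariant_genes,
                            sequences: dict[str, str], k: int = 4) -> pd.DataFrame:
    """log2FC matrix: rows all 4^k k-mers, one column per condition label."""
    background = set_mean_frequency(invariant_genes, sequences, k)
    cols = {}
    for label, genes in enriched_sets.items():
        cols[label] = kmer_fold_change(set_mean_frequency(genes, sequences, k), background)
    return pd.DataFrame(cols)


def cluster_kmers(matrix: pd.DataFrame, n_clusters: int = 3, seed: int = 0,
                  n_init: int = 25) -> pd.Series:
    """K-means partition of the k-mer fold-change matrix.

    Lloyd iterations with k-means++ initialization, best of ``n_init``
    restarts by within-cluster sum of squares.  Labels are renumbered by
    descending cluster mean (cluster 1 has the highest mean log2FC) so
    output is stable for a fixed seed.
    """
    X = matrix.to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < n_clusters:
        raise ValueError("fewer distinct rows than clusters")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    means = [X[raw == c].mean() for c in range(n_clusters)]
    order = np.argsort(means)[::-1]  # descending mean
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    return pd.Series([relabel[int(c)] for c in raw], index=matrix.index, name="cluster")
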