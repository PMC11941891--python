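"""Expression-profile clustering of TPM matrices.

Expression values are log2(TPM+1)-transformed and row z-scored, then
clustered by agglomerative hierarchical clustering with Euclidean
distance and complete linkage (inter-cluster distance = maximum pairwise
distance). Cutting the dendrogram at k clusters, per-cluster mean raw
TPM profiles summarize each cluster, and cells with TPM strictly above
20 are flagged abundant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

ABUNDANT_TPM = 20.0  # strict ">" per the abundance convention


@dataclass
class ExpressionMatrix:
    """Non-negative TPM values, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape inconsistent with ids")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains missing or non-finite cells")
        if (self.values < 0).any():
            raise ValueError("TPM values must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClusterResult:
    assignment: dict[str, int]
    merge_history: list[tuple[int, int, float]]
    profiles: pd.DataFrame  # cluster x sample mean raw TPM
    abundant: set[tuple[str, str]]


def normalize_matrix(M: ExpressionMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """log2(TPM + pseudocount), then per-row z-score with population sd.

    Rows with zero variance map to all-zeros.
    """
    v = np.log2(M.values + pseudocount)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)  # population (n) denominator
    out = np.zeros_like(v)
    np.divide(v - mean, sd, out=out, where=sd > 0)
    return out


def hclust_complete(X: np.ndarray) -> list[tuple[int, int, float]]:
    """Complete-linkage agglomeration on Euclidean row distances.

    Returns the merge history as (a, b, height) triples over cluster
    indices: rows are clusters 0..n-1 and the merge at step t creates
    cluster n+t (the SciPy numbering convention). Ties are broken by the
    lexicographically smallest index pair; heights are non-decreasing
    because complete linkage cannot invert.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    # current clusters: id -> member row indices; distances via Lance-Williams
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    dist = {
        (i, j): d[i, j] for idx, i in enumerate(active) for j in active[idx + 1:]
    }
    history: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        history.append((a, b, h))
        merged = next_id
        next_id += 1
        active.remove(a)
        active.remove(b)
        for c in active:
            dac = dist.pop((min(a, c), max(a, c)))
            dbc = dist.pop((min(b, c), max(b, c)))
            dist[(c, merged)] = max(dac, dbc)  # complete linkage
        del dist[(a, b)]
        active.append(merged)
    return history


def cut_k(merge_history: list[tuple[int, int, float]], k: int) -> list[int]:
    """Cluster labels 1..k from a merge history.

    Merging stops when k clusters remain; clusters are renumbered by the
    order in which their first row appears.
    """
    n = len(merge_history) + 1
    if not (1 <= k <= n):
        raise ValueError("k must be in [1, n]")
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while x in parent:
            x = parent[x]
        return x

    for t, (a, b, _h) in enumerate(merge_history[: n - k]):
        parent[find(a)] = n + t
        parent[find(b)] = n + t
    labels_raw = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    out = []
    for lab in labels_raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out.append(remap[lab])
    return out


def cluster_profiles(
    M: ExpressionMatrix, assignment: dict[str, int]
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Per-cluster per-sample mean raw TPM, and the abundant-cell set.

    A cell is abundant when its raw TPM is strictly above 20.
    """
    missing = set(M.gene_ids) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing genes: {sorted(missing)[:5]}")
    df = M.to_frame()
    labels = pd.Series({g: assignment[g] for g in M.gene_ids})
    profiles = df.groupby(labels).mean()
    profiles.index.name = "cluster"
    abundant = {
        (M.gene_ids[i], M.sample_ids[j])
        for i, j in zip(*np.where(M.values > ABUNDANT_TPM))
    }
    return profiles, abundant


def cluster_expression(
    M: ExpressionMatrix,
    k: int,
    on: str = "normalized",
    pseudocount: float = 1.0,
) -> ClusterResult:
    """Full clustering workflow: normalize, agglomerate, cut, profile.

    ``on="normalized"`` (default) clusters the log/z-scored matrix;
    ``on="raw"`` clusters raw TPM rows.
    """
    X = normalize_matrix(M, pseudocount) if on == "normalized" else M.values
    history = hclust_complete(X)
    labels = cut_k(history, k)
    assignment = {g: lab for g, lab in zip(M.gene_ids, labels)}
    profiles, abundant = cluster_profiles(M, assignment)
    return ClusterResult(assignment, history, profiles, abundant)
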