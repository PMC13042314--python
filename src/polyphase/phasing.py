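"""Subgenome assignment by differential k-mer enrichment and clustering.

Chromosomes of an allopolyploid are painted by ancestry using k-mers whose
normalized abundance is strongly enriched in one chromosome cluster
("differential" k-mers). Starting from a provisional clustering on the
highest-variance k-mers, the procedure alternates (a) centroid clustering
of chromosomes on the differential-k-mer submatrix and (b) recomputation
of the differential set from the current clusters, until the partition
stabilizes. The output carries cluster labels, an average-linkage
dendrogram on Jaccard distance of differential-k-mer presence/absence, a
2-axis principal-component ordination, and per-chromosome silhouettes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .kmers import KmerMatrix, count_kmers, kmer_to_str  # noqa: F401  (re-export)

#: cap on the dense differential submatrix used for clustering/ordination
MAX_DIFF_COLUMNS = 50_000


@dataclass
class DifferentialKmers:
    """Differential k-mer set: codes, winning cluster, enrichment scores."""

    codes: np.ndarray  # int64 k-mer codes
    columns: np.ndarray  # column indices into the source KmerMatrix
    labels: np.ndarray  # winning cluster id per k-mer
    scores: np.ndarray  # top mean / second mean (inf when second is 0)

    @property
    def n(self) -> int:
        return self.codes.size


def find_differential_kmers(
    matrix: KmerMatrix,
    groups: dict[str, int],
    fold_q: float = 2.0,
    min_count: float = 2.0,
) -> DifferentialKmers:
    """k-mers enriched in one cluster of chromosomes.

    A k-mer is differential iff its highest cluster-mean per-Mb count is at
    least ``fold_q`` times the second highest and at least ``min_count``.
    """
    if fold_q <= 1:
        raise ValueError("fold_q must be > 1")
    labels = np.array([groups[cid] for cid in matrix.ids])
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    permb = matrix.per_mb()
    means = np.zeros((uniq.size, matrix.n_kmers))
    for i, g in enumerate(uniq):
        rows = np.nonzero(labels == g)[0]
        if rows.size == 0:
            raise ValueError(f"cluster {g} has no chromosomes")
        means[i] = np.asarray(permb[rows].mean(axis=0)).ravel()
    order = np.argsort(means, axis=0)
    top = means[order[-1], np.arange(means.shape[1])]
    second = means[order[-2], np.arange(means.shape[1])]
    mask = (top >= fold_q * second) & (top >= min_count)
    cols = np.nonzero(mask)[0]
    with np.errstate(divide="ignore"):
        scores = np.where(second[cols] > 0, top[cols] / np.maximum(second[cols], 1e-300), np.inf)
    return DifferentialKmers(
        codes=matrix.kmer_codes[cols],
        columns=cols,
        labels=uniq[order[-1, cols]],
        scores=scores,
    )


@dataclass
class SubgenomeAssignment:
    """Chromosome -> subgenome labels plus the evidence behind them."""

    labels: dict[str, str]
    differential: DifferentialKmers
    dendrogram: np.ndarray  # scipy linkage matrix over chromosomes (matrix order)
    chromosome_order: list[str]
    ordination: pd.DataFrame  # index chromosome, columns PC1/PC2
    silhouette: pd.Series
    n_iterations: int
    converged: bool
    heatmap: pd.DataFrame = field(repr=False, default=None)

    def label_set(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def partition(self) -> list[int]:
        """Integer cluster ids in chromosome order (label-name independent)."""
        lut = {lab: i for i, lab in enumerate(dict.fromkeys(self.labels.values()))}
        return [lut[self.labels[c]] for c in self.chromosome_order]


def _letters(n: int) -> list[str]:
    alpha = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return [alpha[i % 26] + ("" if i < 26 else str(i // 26)) for i in range(n)]


def _relabel_by_first_appearance(ids: list[str], raw: np.ndarray) -> dict[str, str]:
    """Assign letters A, B, C... to clusters by first appearance over
    lexicographically sorted chromosome ids (deterministic)."""
    letters = _letters(np.unique(raw).size)
    mapping: dict[int, str] = {}
    for cid in sorted(ids):
        g = int(raw[ids.index(cid)])
        if g not in mapping:
            mapping[g] = letters[len(mapping)]
    return {cid: mapping[int(raw[ids.index(cid)])] for cid in ids}


def _top_variance_columns(
    matrix: KmerMatrix, n: int, min_presence: float = 0.2
) -> np.ndarray:
    """Highest-variance k-mer columns among those present in at least
    ``min_presence`` of the chromosomes.

    The presence filter biases initialization toward genome-wide
    (subgenome-scale) signal such as ancestry-specific repeats, away from
    k-mers private to one homologous chromosome group; it is relaxed when
    it would leave fewer than ``n`` candidates.
    """
    permb = matrix.per_mb()
    mean = np.asarray(permb.mean(axis=0)).ravel()
    mean_sq = np.asarray(permb.multiply(permb).mean(axis=0)).ravel()
    var = mean_sq - mean**2
    pres = np.asarray((permb > 0).mean(axis=0)).ravel()
    cand = np.nonzero(pres >= min_presence)[0]
    if cand.size < min(n, var.size):
        cand = np.arange(var.size)
    if cand.size <= n:
        return cand
    return np.sort(cand[np.argpartition(var[cand], -n)[-n:]])


def _dense(matrix: KmerMatrix, cols: np.ndarray) -> np.ndarray:
    return np.asarray(matrix.per_mb()[:, cols].todense())


def phase_subgenomes(
    matrix: KmerMatrix,
    K: int = 3,
    seed: int = 0,
    max_iter: int = 10,
    fold_q: float = 2.0,
    min_count: float = 2.0,
    n_init_kmers: int = 10_000,
) -> SubgenomeAssignment:
    """Cluster chromosomes into K subgenomes on differential k-mers.

    Initializes on the ``n_init_kmers`` highest-variance k-mers (no
    homologous groups are known a priori), then alternates differential
    k-mer detection and seeded k-means (10 restarts) until the partition
    stabilizes or ``max_iter`` is reached; non-convergence is reported via
    ``converged=False`` with the last labels.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if matrix.n_chromosomes < K:
        raise ValueError("fewer chromosomes than clusters")

    init_cols = _top_variance_columns(matrix, n_init_kmers)
    X = _dense(matrix, init_cols)
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    if np.unique(raw).size < K:
        raise ValueError(
            "chromosomes are indistinguishable at this k: no differential "
            "k-mers can be found; lower fold_q/min_count or use a larger k"
        )

    diff = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        groups = {cid: int(g) for cid, g in zip(matrix.ids, raw)}
        diff = find_differential_kmers(matrix, groups, fold_q=fold_q, min_count=min_count)
        if diff.n == 0:
            raise ValueError(
                "no differential k-mers found; lower fold_q or min_count"
            )
        cols = diff.columns
        if cols.size > MAX_DIFF_COLUMNS:
            keep = np.argsort(diff.scores)[-MAX_DIFF_COLUMNS:]
            cols = np.sort(cols[keep])
        X = _dense(matrix, cols)
        new_raw = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(X)
        if _same_partition(raw, new_raw):
            raw = new_raw
            converged = True
            break
        raw = new_raw

    labels = _relabel_by_first_appearance(matrix.ids, raw)

    presence = X > 0
    if presence.shape[0] > 1:
        dist = pdist(presence, metric="jaccard")
        dist = np.nan_to_num(dist, nan=0.0)  # all-empty rows compare equal
        Z = linkage(dist, method="average")
    else:  # pragma: no cover - degenerate single chromosome
        Z = np.empty((0, 4))
    n_pc = min(2, X.shape[0] - 1, X.shape[1])
    coords = PCA(n_components=n_pc, random_state=seed).fit_transform(X)
    if n_pc < 2:  # pad for a stable two-column contract
        coords = np.column_stack([coords, np.zeros(X.shape[0])])
    ordination = pd.DataFrame(coords[:, :2], index=matrix.ids, columns=["PC1", "PC2"])
    try:
        sil = silhouette_samples(X, raw)
    except ValueError:  # a singleton/empty cluster edge case
        sil = np.zeros(len(matrix.ids))
    silhouette = pd.Series(sil, index=matrix.ids, name="silhouette")

    heat = pd.DataFrame(X, index=matrix.ids)
    return SubgenomeAssignment(
        labels=labels,
        differential=diff,
        dendrogram=Z,
        chromosome_order=list(matrix.ids),
        ordination=ordination,
        silhouette=silhouette,
        n_iterations=iterations,
        converged=converged,
        heatmap=heat,
    )


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label vectors induce the same partition."""
    pair_map: dict[int, int] = {}
    seen: set[int] = set()
    for x, y in zip(a.tolist(), b.tolist()):
        if x in pair_map:
            if pair_map[x] != y:
                return False
        else:
            if y in seen:
                return False
            pair_map[x] = y
            seen.add(y)
    return True


def assignment_report(
    assignment: SubgenomeAssignment,
    out_prefix: str,
    k: int | None = None,
    plot: bool = False,
) -> dict[str, str]:
    """Write labels, ordination, differential k-mers, and the heatmap
    matrix as TSVs (plus optional PNG figures). Returns written paths."""
    paths: dict[str, str] = {}
    labels = pd.DataFrame(
        {
            "chromosome": assignment.chromosome_order,
            "subgenome": [assignment.labels[c] for c in assignment.chromosome_order],
            "silhouette": assignment.silhouette.values,
        }
    )
    paths["labels"] = f"{out_prefix}.labels.tsv"
    labels.to_csv(paths["labels"], sep="\t", index=False)

    paths["ordination"] = f"{out_prefix}.ordination.tsv"
    assignment.ordination.rename_axis("chromosome").to_csv(paths["ordination"], sep="\t")

    diff = assignment.differential
    kmers = pd.DataFrame(
        {
            "kmer": [kmer_to_str(c, k) for c in diff.codes] if k else diff.codes,
            "cluster": diff.labels,
            "enrichment": diff.scores,
        }
    )
    paths["differential"] = f"{out_prefix}.differential_kmers.tsv"
    kmers.to_csv(paths["differential"], sep="\t", index=False)

    paths["heatmap"] = f"{out_prefix}.heatmap.tsv"
    assignment.heatmap.rename_axis("chromosome").to_csv(paths["heatmap"], sep="\t")

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

        fig, axes = plt.subplots(1, 2, figsize=(12, 5))
        scipy_dendrogram(
            assignment.dendrogram,
            labels=assignment.chromosome_order,
            ax=axes[0],
            leaf_rotation=90,
            leaf_font_size=6,
        )
        axes[0].set_title("average linkage, Jaccard on differential k-mers")
        for lab in assignment.label_set():
            rows = [c for c in assignment.chromosome_order if assignment.labels[c] == lab]
            sub = assignment.ordination.loc[rows]
            axes[1].scatter(sub["PC1"], sub["PC2"], label=lab, s=18)
        axes[1].legend(title="subgenome")
        axes[1].set_xlabel("PC1")
        axes[1].set_ylabel("PC2")
        fig.tight_layout()
        paths["plot"] = f"{out_prefix}.phasing.png"
        fig.savefig(paths["plot"], dpi=120)
        plt.close(fig)
    return paths
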