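"""Co-expression module detection.

Genes are clustered by Ward's method on the Spearman distance d = 1 - rho,
the dendrogram is cut at every K in a scan range, and the number of modules
is chosen from the percentage of variance explained,

    R^2(K) = BSS / (WSS + BSS),

via the elbow criterion and/or the pseudo F-index (Calinski-Harabasz form).
Because only a distance matrix exists (no Euclidean coordinates), within-
group dispersion is computed through the pairwise identity

    WSS_c = (1 / n_c) * sum_{i<j in c} d_ij^2,

which reduces to the usual centroid sum of squares whenever the distances
are Euclidean-embeddable.  Module activity is summarized per sample by the
module eigengene (first principal component of the standardized module
expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import ExpressionMatrix, GeneSetCollection


@dataclass
class GeneDistanceMatrix:
    """Symmetric pairwise Spearman-distance matrix, d_ij = 1 - rho_ij."""

    gene_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.gene_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match gene ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < -1e-10) or np.any(self.d > 2 + 1e-10):
            raise ValueError("Spearman distances must lie in [0, 2]")


def rank_standardize(values: np.ndarray) -> np.ndarray:
    """Rank each row (average ties), then center and scale to unit norm, so
    that R @ R.T gives the full Spearman correlation matrix."""
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant row encountered during rank standardization")
    return ranks / norms


def spearman_distance(expr: ExpressionMatrix) -> GeneDistanceMatrix:
    """Pairwise 1 - Spearman correlation with average-rank tie handling."""
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    ranks = stats.rankdata(expr.values, axis=1)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        gene = expr.gene_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {gene!r} is constant across samples")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    centered /= np.linalg.norm(centered, axis=1, keepdims=True)
    rho = centered @ centered.T
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return GeneDistanceMatrix(list(expr.gene_ids), d)


def ward_cluster(dist: GeneDistanceMatrix) -> np.ndarray:
    """Agglomerative Ward merge tree on the precomputed distances
    (Lance-Williams recurrence).  Returns a SciPy linkage matrix."""
    if len(dist.gene_ids) < 2:
        raise ValueError("need at least 2 genes to cluster")
    return linkage(squareform(dist.d, checks=False), method="ward")


@dataclass
class PartitionScore:
    K: int
    R2: float
    BSS: float
    WSS: float
    pseudoF: float


@dataclass
class ModulePartition:
    """Hard assignment of genes to modules; labels are ``M1..MK`` ordered by
    decreasing module size."""

    assignment: dict[str, str]
    K: int

    @property
    def modules(self) -> GeneSetCollection:
        sets: dict[str, set[str]] = {}
        for gene, label in self.assignment.items():
            sets.setdefault(label, set()).add(gene)
        return GeneSetCollection({k: frozenset(v) for k, v in sets.items()})


def _within_sums(d2: np.ndarray, labels: np.ndarray) -> float:
    wss = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size > 1:
            wss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return wss


def scan_partitions(tree: np.ndarray, dist: GeneDistanceMatrix,
                    k_min: int = 2, k_max: int = 30) -> list[PartitionScore]:
    """Score every cut K in [k_min, k_max] by R^2 and the pseudo F-index."""
    n = len(dist.gene_ids)
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max > n:
        raise ValueError(f"k_max {k_max} exceeds number of genes {n}")
    d2 = dist.d ** 2
    tss = d2.sum() / (2.0 * n)
    scores = []
    for k in range(k_min, k_max + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        wss = _within_sums(d2, labels)
        bss = tss - wss
        r2 = bss / tss if tss > 0 else 0.0
        pf = (bss / (k - 1)) / (wss / (n - k)) if wss > 0 and k < n else np.inf
        scores.append(PartitionScore(K=k, R2=r2, BSS=bss, WSS=wss, pseudoF=pf))
    return scores


def cut_tree(tree: np.ndarray, dist: GeneDistanceMatrix, k: int) -> ModulePartition:
    labels = fcluster(tree, t=k, criterion="maxclust")
    by_label: dict[int, list[str]] = {}
    for gene, lab in zip(dist.gene_ids, labels):
        by_label.setdefault(int(lab), []).append(gene)
    # deterministic relabeling: M1 is the largest module
    ordered = sorted(by_label.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    assignment = {}
    for i, (_, genes) in enumerate(ordered, start=1):
        for g in genes:
            assignment[g] = f"M{i}"
    return ModulePartition(assignment=assignment, K=len(ordered))


def relabel_small_modules(partition: ModulePartition, min_size: int,
                          label: str = "unclustered") -> ModulePartition:
    """Optional post-hoc step: pool genes from modules below ``min_size``
    into a single catch-all set of un-clustered genes."""
    sizes: dict[str, int] = {}
    for lab in partition.assignment.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    assignment = {
        g: (label if sizes[lab] < min_size else lab)
        for g, lab in partition.assignment.items()
    }
    return ModulePartition(assignment=assignment, K=len(set(assignment.values())))


class KSelectionError(ValueError):
    """Raised when elbow and pseudo-F disagree in consensus mode."""

    def __init__(self, k_elbow: int, k_pseudof: int):
        self.k_elbow = k_elbow
        self.k_pseudof = k_pseudof
        super().__init__(
            f"elbow selects K={k_elbow} but pseudo-F selects K={k_pseudof}; "
            "outside the consensus tolerance")


def select_k(scores: list[PartitionScore], method: str = "consensus",
             elbow_fraction: float = 0.01, elbow_window: int = 3,
             consensus_tolerance: int = 2, force: bool = False) -> int:
    """Choose the module count from a partition-score scan.

    ``pseudoF``: argmax of the pseudo F-index.  ``elbow``: smallest K after
    which every marginal R^2 gain over the next ``elbow_window`` steps stays
    below ``elbow_fraction`` of the scanned R^2 range.  ``consensus``:
    require the two criteria to agree within ``consensus_tolerance`` and
    return the pseudo-F choice; otherwise raise carrying both candidates
    (or return the pseudo-F choice when ``force``).
    """
    if not scores:
        raise ValueError("empty score list")
    ks = [s.K for s in scores]
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("scores must cover a contiguous K range")
    if len(scores) == 1:
        warnings.warn("degenerate scan range: a single K was scored", stacklevel=2)
        return ks[0]

    if method == "pseudoF":
        return _select_pseudof(scores)
    if method == "elbow":
        return _select_elbow(scores, elbow_fraction, elbow_window)
    if method == "consensus":
        k_e = _select_elbow(scores, elbow_fraction, elbow_window)
        k_f = _select_pseudof(scores)
        if abs(k_e - k_f) <= consensus_tolerance or force:
            return k_f
        raise KSelectionError(k_e, k_f)
    raise ValueError(f"unknown selection method {method!r}")


def _select_pseudof(scores: list[PartitionScore]) -> int:
    finite = [s for s in scores if np.isfinite(s.pseudoF)]
    pool = finite if finite else scores
    best = max(pool, key=lambda s: s.pseudoF)
    if best.K == scores[0].K:
        warnings.warn(
            "pseudo-F maximum sits at the scan boundary; "
            "the selection may be unstable", stacklevel=3)
    return best.K


def _select_elbow(scores: list[PartitionScore], fraction: float, window: int) -> int:
    r2 = np.array([s.R2 for s in scores])
    ks = [s.K for s in scores]
    r2_range = float(r2.max() - r2.min())
    if r2_range <= 0:
        return ks[0]
    gains = np.diff(r2)  # gains[i] = R2(K_i -> K_{i+1})
    thresh = fraction * r2_range
    for i in range(len(gains)):
        window_gains = gains[i:i + window]
        if len(window_gains) > 0 and np.all(window_gains < thresh):
            return ks[i]
    return ks[-1]


@dataclass
class Eigengene:
    """First principal component of the standardized module expression.

    ``values`` holds one score per sample (unit norm, zero mean), oriented
    so the eigengene correlates non-negatively with the module's mean
    standardized expression profile.
    """

    label: str
    sample_ids: list[str]
    values: np.ndarray
    variance_explained: float


def module_eigengene(expr: ExpressionMatrix, genes, label: str = "") -> Eigengene:
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a module needs at least 2 genes for an eigengene")
    sub = expr.subset_genes(genes)
    sd = sub.values.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = genes[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {bad!r} is constant within the module")
    z = (sub.values - sub.values.mean(axis=1, keepdims=True)) / sd[:, None]
    # rows are zero-mean, so right singular vectors are orthogonal to 1 and
    # the eigengene is automatically centered
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    mean_profile = z.mean(axis=0)
    orient = float(scores @ mean_profile)
    if orient < 0:
        scores = -scores
    var_exp = float(s[0] ** 2 / np.sum(s ** 2))
    return Eigengene(label=label, sample_ids=list(expr.sample_ids),
                     values=scores, variance_explained=var_exp)
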