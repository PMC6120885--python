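"""Differential co-expression testing and the subsampling power framework.

For a module, the statistic is the Euclidean distance D between the vectors
of pairwise Spearman correlations computed in each condition separately.
Significance is assessed against a competitive null built by redrawing
random gene sets of the same size from the expressed-gene pool and
recomputing D, with the add-one empirical estimator

    p = (1 + #{D_null >= D_obs}) / (B + 1).

A label-shuffling variant (permute the condition labels of the pooled
samples) is available behind ``null="shuffle"`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix, adjust_bh  # noqa: F401  (re-exported)
from .coexpression import rank_standardize


@dataclass
class DiffCoexprResult:
    label: str
    D: float
    p_emp: float
    q: float  # NaN until BH-adjusted across a module family
    B: int


@dataclass
class PowerGrid:
    """Empirical p-values from stratified subsampling: one row per sampling
    fraction, one column per repetition.  NaN marks skipped cells."""

    fractions: list[float]
    reps: int
    p_values: np.ndarray

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.p_values.shape != (len(self.fractions), self.reps):
            raise ValueError("power grid shape mismatch")


def _pair_upper(corr: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(corr.shape[0], k=1)
    return corr[iu]


def coexpr_profile(expr: ExpressionMatrix, genes) -> np.ndarray:
    """Spearman correlations for all gene pairs i<j of ``genes``, in
    row-major upper-triangle order of the given gene list."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a co-expression profile")
    sub = expr.subset_genes(genes)
    r = rank_standardize(sub.values)
    return _pair_upper(r @ r.T)


def diffcoexpr_stat(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix, genes) -> float:
    """Euclidean distance between the two condition-wise correlation
    profiles, using identical pair ordering."""
    pa = coexpr_profile(expr_a, genes)
    pb = coexpr_profile(expr_b, genes)
    return float(np.linalg.norm(pa - pb))


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def diffcoexpr_test(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix,
                    genes, B: int = 1000, seed=None, pool=None,
                    null: str = "redraw", label: str = "") -> DiffCoexprResult:
    """Permutation test for differential co-expression of one module.

    ``pool`` is the list of eligible (expressed) genes the competitive null
    redraws from; it defaults to all genes present in both matrices and must
    be strictly larger than the module.
    """
    genes = list(genes)
    m = len(genes)
    if B < 1:
        raise ValueError("B must be >= 1")
    if pool is None:
        pool = [g for g in expr_a.gene_ids if g in expr_b]
    pool = list(pool)
    if len(pool) <= m:
        raise ValueError(
            f"expressed-gene pool ({len(pool)}) must be strictly larger "
            f"than the module ({m})")
    rng = _as_generator(seed)

    ra = rank_standardize(expr_a.subset_genes(pool).values)
    rb = rank_standardize(expr_b.subset_genes(pool).values)
    pos = {g: i for i, g in enumerate(pool)}
    try:
        midx = np.array([pos[g] for g in genes])
    except KeyError as exc:
        raise KeyError(f"module gene {exc.args[0]!r} absent from the pool") from None

    def stat_at(idx_a: np.ndarray, mat_a: np.ndarray, idx_b: np.ndarray,
                mat_b: np.ndarray) -> float:
        ca = _pair_upper(mat_a[idx_a] @ mat_a[idx_a].T)
        cb = _pair_upper(mat_b[idx_b] @ mat_b[idx_b].T)
        return float(np.linalg.norm(ca - cb))

    d_obs = stat_at(midx, ra, midx, rb)

    exceed = 0
    if null == "redraw":
        for _ in range(B):
            idx = rng.choice(len(pool), size=m, replace=False)
            if stat_at(idx, ra, idx, rb) >= d_obs:
                exceed += 1
    elif null == "shuffle":
        joint = np.hstack([expr_a.subset_genes(genes).values,
                           expr_b.subset_genes(genes).values])
        na = expr_a.n_samples
        cols = np.arange(joint.shape[1])
        for _ in range(B):
            perm = rng.permutation(cols)
            sa = rank_standardize(joint[:, perm[:na]])
            sb = rank_standardize(joint[:, perm[na:]])
            d_null = float(np.linalg.norm(
                _pair_upper(sa @ sa.T) - _pair_upper(sb @ sb.T)))
            if d_null >= d_obs:
                exceed += 1
    else:
        raise ValueError(f"unknown null construction {null!r}")

    p_emp = (1 + exceed) / (B + 1)
    return DiffCoexprResult(label=label, D=d_obs, p_emp=p_emp, q=np.nan, B=B)


def diffcoexpr_family(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix,
                      modules, B: int = 1000, seed=None, pool=None) -> list[DiffCoexprResult]:
    """Run the differential co-expression test for every module in a
    collection and BH-adjust the empirical p-values across modules."""
    rng = _as_generator(seed)
    results = [
        diffcoexpr_test(expr_a, expr_b, genes, B=B, seed=rng, pool=pool, label=name)
        for name, genes in modules.items()
    ]
    qs = adjust_bh(np.array([r.p_emp for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def conservation_test(genes, external_expr: ExpressionMatrix, omap=None,
                      B: int = 1000, seed=None) -> tuple[float, float]:
    """Module-coherence (conservation) test in an external dataset.

    Maps the module through the ortholog map (identity when ``omap`` is
    None), computes the mean absolute pairwise Spearman correlation of the
    mapped genes, and compares it against B random equal-size gene sets from
    the external expressed genes.  Returns (statistic, one-sided p_emp).
    """
    genes = set(genes)
    if omap is not None:
        mapped = {omap[g] for g in genes if g in omap}
    else:
        mapped = genes
    present = [g for g in sorted(mapped) if g in external_expr]
    if len(present) < 2:
        raise ValueError(
            f"fewer than 2 mapped module genes present in the external data "
            f"({len(present)} of {len(genes)} module genes mapped)")
    rng = _as_generator(seed)
    r = rank_standardize(external_expr.values)
    pos = {g: i for i, g in enumerate(external_expr.gene_ids)}
    idx = np.array([pos[g] for g in present])

    def mean_abs_corr(ix: np.ndarray) -> float:
        return float(np.mean(np.abs(_pair_upper(r[ix] @ r[ix].T))))

    stat = mean_abs_corr(idx)
    exceed = 0
    n_ext = external_expr.n_genes
    for _ in range(B):
        rix = rng.choice(n_ext, size=len(present), replace=False)
        if mean_abs_corr(rix) >= stat:
            exceed += 1
    return stat, (1 + exceed) / (B + 1)


def _power_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def subsample_power(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix, genes,
                    fractions, reps: int = 50, B: int = 1000, seed=None,
                    pool=None) -> PowerGrid:
    """Rejection behaviour under stratified subsampling of the samples.

    For each (fraction, repetition) a random subset of columns is drawn per
    condition (preserving the case/control ratio) and the differential
    co-expression test is rerun.  One master seed spawns an independent
    stream per cell, so the grid is reproducible cell by cell.
    """
    fractions = [float(f) for f in fractions]
    seeds = _power_seeds(seed, len(fractions) * reps)
    p = np.full((len(fractions), reps), np.nan)
    for i, frac in enumerate(fractions):
        na = int(round(frac * expr_a.n_samples))
        nb = int(round(frac * expr_b.n_samples))
        if na < 4 or nb < 4:
            warnings.warn(
                f"fraction {frac} leaves fewer than 4 samples per condition; skipped",
                stacklevel=2)
            continue
        for j in range(reps):
            rng = np.random.default_rng(seeds[i * reps + j])
            cols_a = rng.choice(expr_a.n_samples, size=na, replace=False)
            cols_b = rng.choice(expr_b.n_samples, size=nb, replace=False)
            sub_a = ExpressionMatrix(list(expr_a.gene_ids),
                                     [expr_a.sample_ids[c] for c in cols_a],
                                     expr_a.values[:, cols_a])
            sub_b = ExpressionMatrix(list(expr_b.gene_ids),
                                     [expr_b.sample_ids[c] for c in cols_b],
                                     expr_b.values[:, cols_b])
            res = diffcoexpr_test(sub_a, sub_b, genes, B=B, seed=rng, pool=pool)
            p[i, j] = res.p_emp
    return PowerGrid(fractions=fractions, reps=reps, p_values=p)
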