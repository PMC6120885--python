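"""Module-trait association.

Relates co-expression modules to a quantitative phenotype (here, daily
seizure frequency) in three ways: Spearman correlation of each module
eigengene with the trait, per-gene quantitative trait transcript (QTT)
correlation genome-wide, and hypergeometric enrichment of each module for
QTT genes.  Trait association uses case samples by default, since the
phenotype is undefined (zero by construction) in controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, SampleTable, adjust_bh
from .coexpression import Eigengene, rank_standardize


@dataclass
class ModuleTraitResult:
    label: str
    rho: float
    p: float
    q: float
    R2_trait: float  # linear-fit coefficient of determination
    rho_squared: float  # squared rank correlation, reported alongside


@dataclass
class QTTResult:
    table: pd.DataFrame  # columns: gene_id, rho, p, q
    qtt_genes: frozenset[str]
    threshold: float


def _trait_vector(samples: SampleTable, sample_ids, case_only: bool) -> np.ndarray:
    if case_only:
        cases = set(samples.samples_of("case"))
        sample_ids = [s for s in sample_ids if s in cases]
    trait = samples.trait_of(sample_ids)
    if np.any(np.isnan(trait)):
        raise ValueError("trait missing for a sample used in trait association")
    if len(trait) < 4:
        raise ValueError("need at least 4 samples with trait values")
    if np.all(trait == trait[0]):
        raise ValueError("trait is constant across the samples used")
    return trait


def eigengene_trait(eigengenes: list[Eigengene], samples: SampleTable,
                    case_only: bool = True) -> list[ModuleTraitResult]:
    """Spearman correlation of each module eigengene with the trait, with a
    BH family across modules and the linear-fit R^2 of trait on eigengene."""
    results = []
    for eg in eigengenes:
        ids = eg.sample_ids
        if case_only:
            cases = set(samples.samples_of("case"))
            mask = np.array([s in cases for s in ids])
        else:
            mask = np.ones(len(ids), dtype=bool)
        used = [s for s, m in zip(ids, mask) if m]
        trait = _trait_vector(samples, used, case_only=False)
        vals = eg.values[mask]
        rho, p = stats.spearmanr(vals, trait)
        fit = stats.linregress(vals, trait)
        results.append(ModuleTraitResult(
            label=eg.label, rho=float(rho), p=float(p), q=np.nan,
            R2_trait=float(fit.rvalue ** 2), rho_squared=float(rho ** 2)))
    qs = adjust_bh(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def qtt(expr: ExpressionMatrix, samples: SampleTable, threshold: float = 0.05,
        case_only: bool = True) -> QTTResult:
    """Per-gene Spearman correlation with the trait (QTT analysis).

    The BH family spans all genes in ``expr``; QTT genes are those with
    q below ``threshold``.
    """
    if case_only:
        cases = [s for s in expr.sample_ids if samples._index.get(s) is not None
                 and samples.conditions[samples._index[s]] == "case"]
        sub = expr.subset_samples(cases)
    else:
        sub = expr
    trait = _trait_vector(samples, sub.sample_ids, case_only=False)
    n = sub.n_samples
    gene_r = rank_standardize(sub.values)
    t_rank = stats.rankdata(trait)
    t_rank = t_rank - t_rank.mean()
    t_rank /= np.linalg.norm(t_rank)
    rho = np.clip(gene_r @ t_rank, -1.0, 1.0)
    # two-sided p from the t approximation (matches scipy's spearmanr)
    with np.errstate(divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    q = adjust_bh(p)
    table = pd.DataFrame({"gene_id": sub.gene_ids, "rho": rho, "p": p, "q": q})
    qtt_genes = frozenset(table.loc[table["q"] < threshold, "gene_id"])
    return QTTResult(table=table, qtt_genes=qtt_genes, threshold=threshold)


def qtt_enrichment(module_genes, qtt_genes, universe,
                   rho_by_gene: dict[str, float] | None = None) -> tuple[float, float]:
    """One-sided hypergeometric enrichment of a module for QTT genes, plus
    the mean gene-level trait correlation of the module.

    Returns ``(enrich_p, mean_rho)``; ``mean_rho`` is NaN when no gene-level
    correlations are supplied.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    qset = set(qtt_genes) & universe
    k = len(module & qset)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(qset), len(module)))
    if rho_by_gene is None:
        mean_rho = float("nan")
    else:
        vals = [rho_by_gene[g] for g in module if g in rho_by_gene]
        mean_rho = float(np.mean(vals)) if vals else float("nan")
    return p, mean_rho


def module_qtt_table(modules, qtt_result: QTTResult, universe) -> pd.DataFrame:
    """Per-module QTT summary: mean gene-trait correlation, enrichment p and
    BH q across modules (the volcano-plot table)."""
    rho_by_gene = dict(zip(qtt_result.table["gene_id"], qtt_result.table["rho"]))
    rows = []
    for name, genes in modules.items():
        p, mean_rho = qtt_enrichment(genes, qtt_result.qtt_genes, universe, rho_by_gene)
        rows.append({"module": name, "mean_rho": mean_rho, "enrich_p": p})
    df = pd.DataFrame(rows)
    df["enrich_q"] = adjust_bh(df["enrich_p"].to_numpy())
    return df
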