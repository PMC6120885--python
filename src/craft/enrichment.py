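"""Gene-set enrichment machinery.

Two families: one-sided Fisher's exact enrichment of a query set against a
collection of annotations (cell-type marker signatures), and the literature
co-citation route — a per-gene hypergeometric test on abstract counts to
call disease-associated genes, followed by per-module enrichment for those
genes.  All p-values are upper-tail; BH adjustment is applied within each
query family.  Hypergeometric numerics go through SciPy's survival
function, which works in log space internally and is stable for corpus
sizes in the millions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CitationTable, GeneSetCollection, adjust_bh


@dataclass
class EnrichmentRow:
    query: str
    annotation: str
    k: int  # overlap
    n: int  # query size in universe
    K: int  # annotation size in universe
    N: int  # universe size
    odds_ratio: float
    p: float
    q: float


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2x2 table")
    if 0 in (a, b, c, d):
        # 0.5 continuity for the reported ratio only, never for the p-value
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c))


def fisher_enrich(query, annotations: GeneSetCollection, universe,
                  query_name: str = "query") -> list[EnrichmentRow]:
    """One-sided (enrichment) Fisher exact test of a query gene set against
    each annotation, restricted to the universe; BH across annotations."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    q_set = set(query) & universe
    rows = []
    for name, anno in annotations.items():
        a_set = set(anno) & universe
        k = len(q_set & a_set)
        p = hypergeom_upper(k, len(universe), len(a_set), len(q_set))
        rows.append(EnrichmentRow(
            query=query_name, annotation=name, k=k, n=len(q_set),
            K=len(a_set), N=len(universe),
            odds_ratio=_odds_ratio(k, len(q_set), len(a_set), len(universe)),
            p=p, q=np.nan))
    qs = adjust_bh(np.array([r.p for r in rows]))
    for r, qv in zip(rows, qs):
        r.q = float(qv)
    return rows


def literature_gene_test(cites: CitationTable,
                         threshold: float = 0.05) -> tuple[frozenset[str], pd.DataFrame]:
    """Call disease-associated genes from co-citation counts.

    For each gene, the number of disease co-citing abstracts k_gene is
    tested as an upper-tail hypergeometric draw of n_gene abstracts from a
    corpus of N_total with K_disease disease-linked abstracts; BH across
    genes.  Returns the gene set at q < threshold and the full table.
    """
    df = cites.table.copy()
    n = df["n_gene"].to_numpy(int)
    k = df["k_gene"].to_numpy(int)
    p = stats.hypergeom.sf(k - 1, cites.N_total, cites.K_disease, n)
    df["p"] = p
    df["q"] = adjust_bh(p)
    genes = frozenset(df.loc[df["q"] < threshold, "gene_id"])
    return genes, df


def literature_module_enrichment(modules: GeneSetCollection, disease_genes,
                                 universe) -> list[EnrichmentRow]:
    """Rank modules by their enrichment for disease-associated genes
    (hypergeometric upper tail, BH across modules)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    d_set = set(disease_genes) & universe
    rows = []
    for name, genes in modules.items():
        m_set = set(genes) & universe
        k = len(m_set & d_set)
        p = hypergeom_upper(k, len(universe), len(d_set), len(m_set))
        rows.append(EnrichmentRow(
            query=name, annotation="disease_genes", k=k, n=len(m_set),
            K=len(d_set), N=len(universe),
            odds_ratio=_odds_ratio(k, len(m_set), len(d_set), len(universe)),
            p=p, q=np.nan))
    qs = adjust_bh(np.array([r.p for r in rows]))
    for r, qv in zip(rows, qs):
        r.q = float(qv)
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
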