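"""Data model and validated readers/writers for the expression-analysis pipeline.

All tabular formats are plain TSV; gene and sample identifiers are opaque,
case-sensitive strings.  Expression values are assumed to arrive already
normalized and log-transformed (e.g. log2 FPKM); no quantification or
normalization is performed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Invariants: unique gene ids, unique sample ids, all values finite,
    and ``values.shape == (len(gene_ids), len(sample_ids))``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value for gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in expression matrix") from None

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing[:5]}")
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[idx])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in expression matrix: {missing[:5]}")
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), samples, self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


def read_expression(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes-as-rows expression TSV (header row = sample ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                i = int(np.argmax(bad.isna().to_numpy()))
                raise FormatError(
                    f"non-numeric value {df[col].iloc[i]!r} at gene "
                    f"{df.index[i]!r}, sample {col!r} in {path}"
                ) from None
        raise
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def filter_expressed(expr: ExpressionMatrix, threshold: float = 0.0,
                     min_fraction: float = 0.05) -> ExpressionMatrix:
    """Keep genes with value > ``threshold`` in at least
    ``ceil(min_fraction * n_samples)`` samples.

    The inequality is strict (a log2 FPKM of exactly 0 does not count as
    expressed at threshold 0) and the sample requirement uses "at least"
    semantics on the ceiling of the fraction.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    need = math.ceil(min_fraction * expr.n_samples)
    keep = (expr.values > threshold).sum(axis=1) >= need
    if not keep.any():
        warnings.warn("no gene passed the expression filter", stacklevel=2)
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), expr.values[keep])


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

CONDITIONS = ("case", "control")


@dataclass
class SampleTable:
    """Per-sample metadata: condition label and an optional non-negative
    quantitative trait (e.g. daily seizure frequency).  Trait is NaN when
    unavailable."""

    sample_ids: list[str]
    conditions: list[str]
    traits: np.ndarray  # float, NaN where missing

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample id")
        self.conditions = [str(c) for c in self.conditions]
        for c in self.conditions:
            if c not in CONDITIONS:
                raise FormatError(
                    f"unknown condition {c!r}; allowed: {CONDITIONS}")
        self.traits = np.asarray(self.traits, dtype=float)
        if len(self.conditions) != len(self.sample_ids) or len(self.traits) != len(self.sample_ids):
            raise FormatError("sample table columns have mismatched lengths")
        with np.errstate(invalid="ignore"):
            if np.any(self.traits[~np.isnan(self.traits)] < 0):
                raise FormatError("trait values must be non-negative")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.conditions) if c == condition]

    def trait_of(self, samples) -> np.ndarray:
        return np.array([self.traits[self._index[s]] for s in samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "condition": self.conditions,
            "trait": self.traits,
        })


def read_samples(path, sep: str = "\t") -> SampleTable:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    required = {"sample_id", "condition"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample table needs columns {sorted(required)}")
    traits = df["trait"].to_numpy(float) if "trait" in df.columns else np.full(len(df), np.nan)
    return SampleTable(list(df["sample_id"]), list(df["condition"]), traits)


def write_samples(samples: SampleTable, path, sep: str = "\t") -> None:
    samples.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (modules, marker signatures, ...)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            fs = frozenset(str(g) for g in genes)
            if not fs:
                raise FormatError(f"gene set {name!r} is empty")
            if name in clean:
                raise FormatError(f"duplicate gene set name {name!r}")
            clean[str(name)] = fs
        self.sets = clean

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{ln}: GMT rows need name, description and >=1 gene")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate gene set name {name!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{ln}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Differential expression table
# ---------------------------------------------------------------------------

DE_DIRECTIONS = ("over", "under", "none")


@dataclass
class DETable:
    """Per-gene differential-expression call: direction in
    {over, under, none}, BH-adjusted q in [0, 1], optional signed effect."""

    table: pd.DataFrame  # columns: gene_id, direction, q, effect

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("gene_id", "direction", "q"):
            if col not in df.columns:
                raise FormatError(f"DE table needs column {col!r}")
        if "effect" not in df.columns:
            df["effect"] = np.nan
        df["gene_id"] = df["gene_id"].astype(str)
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"gene {dup!r} appears more than once in DE table")
        bad = ~df["direction"].isin(DE_DIRECTIONS)
        if bad.any():
            raise FormatError(
                f"unknown DE direction {df.loc[bad, 'direction'].iloc[0]!r}; "
                f"allowed: {DE_DIRECTIONS}")
        q = df["q"].to_numpy(float)
        if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
            raise FormatError("DE q-values must lie in [0, 1]")
        self.table = df.reset_index(drop=True)
        self._direction = dict(zip(df["gene_id"], df["direction"]))

    def direction_of(self, gene: str) -> str:
        return self._direction.get(gene, "none")

    def genes_with_direction(self, direction: str) -> frozenset[str]:
        df = self.table
        return frozenset(df.loc[df["direction"] == direction, "gene_id"])


def read_de_table(path, sep: str = "\t") -> DETable:
    return DETable(pd.read_csv(path, sep=sep, dtype={"gene_id": str}))


def write_de_table(de: DETable, path, sep: str = "\t") -> None:
    de.table.to_csv(path, sep=sep, index=False)


def rank_sum_de(case: ExpressionMatrix, control: ExpressionMatrix,
                alpha: float = 0.05) -> DETable:
    """Simple nonparametric differential-expression stand-in.

    Two-sided Wilcoxon rank-sum per gene on log expression, BH-adjusted
    across genes; direction from the sign of the case-minus-control mean.
    This is a documented substitute for count-model DE fitting and is only
    meant to supply (direction, q) labels to downstream stages.
    """
    common = [g for g in case.gene_ids if g in control]
    a = case.subset_genes(common).values
    b = control.subset_genes(common).values
    stat_p = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    q = adjust_bh(stat_p.pvalue)
    effect = a.mean(axis=1) - b.mean(axis=1)
    direction = np.where(q < alpha, np.where(effect > 0, "over", "under"), "none")
    return DETable(pd.DataFrame({
        "gene_id": common,
        "direction": direction,
        "q": q,
        "effect": effect,
    }))


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone enforced)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """One-to-one gene-id mapping (e.g. mouse -> human orthologs)."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        pairs = {str(k): str(v) for k, v in self.pairs.items()}
        targets: set[str] = set()
        for src, tgt in pairs.items():
            if tgt in targets:
                raise FormatError(
                    f"ortholog target {tgt!r} mapped from more than one source")
            targets.add(tgt)
        self.pairs = pairs

    def __contains__(self, gene: str) -> bool:
        return gene in self.pairs

    def __getitem__(self, gene: str) -> str:
        return self.pairs[gene]

    def __len__(self) -> int:
        return len(self.pairs)


def read_ortholog_map(path, sep: str = "\t") -> OrthologMap:
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError("ortholog map needs two columns: source, target")
    if df[0].duplicated().any():
        dup = df.loc[df[0].duplicated(), 0].iloc[0]
        raise FormatError(f"ortholog source {dup!r} appears more than once")
    return OrthologMap(dict(zip(df[0], df[1])))


@dataclass
class MappingReport:
    mapped: int
    dropped: int


def apply_ortholog_map(genes, omap: OrthologMap) -> tuple[frozenset[str], MappingReport]:
    """Map a gene-id set through the ortholog map; unmapped genes are
    dropped and counted in the report."""
    genes = set(genes)
    mapped = {omap[g] for g in genes if g in omap}
    return frozenset(mapped), MappingReport(len(mapped), len(genes) - len(mapped))


# ---------------------------------------------------------------------------
# Citation counts (literature mining output, consumed as a table)
# ---------------------------------------------------------------------------

@dataclass
class CitationTable:
    """Per-gene abstract counts plus corpus-level totals.

    ``n_gene`` = abstracts citing the gene, ``k_gene`` = abstracts co-citing
    the gene and the disease; ``N_total`` / ``K_disease`` are the corpus
    totals the hypergeometric test draws from.
    """

    table: pd.DataFrame  # columns: gene_id, n_gene, k_gene
    N_total: int
    K_disease: int

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("gene_id", "n_gene", "k_gene"):
            if col not in df.columns:
                raise FormatError(f"citation table needs column {col!r}")
        df["gene_id"] = df["gene_id"].astype(str)
        if df["gene_id"].duplicated().any():
            raise FormatError("duplicate gene in citation table")
        n = df["n_gene"].to_numpy(int)
        k = df["k_gene"].to_numpy(int)
        if self.K_disease > self.N_total:
            raise FormatError("K_disease exceeds N_total")
        if np.any(k < 0) or np.any(k > n):
            raise FormatError("need 0 <= k_gene <= n_gene for every gene")
        if np.any(n > self.N_total):
            raise FormatError("n_gene exceeds N_total")
        self.table = df.reset_index(drop=True)


def read_citations(path, sep: str = "\t") -> CitationTable:
    """Read a citation-count TSV whose first two comment lines carry the
    corpus totals: ``#N_total=<int>`` and ``#K_disease=<int>``."""
    totals: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if line.startswith("#") and "=" in line:
            key, val = line[1:].strip().split("=", 1)
            totals[key] = int(val)
            n_header += 1
        else:
            break
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines[n_header:])), sep=sep,
                     dtype={"gene_id": str})
    if "N_total" not in totals or "K_disease" not in totals:
        raise FormatError("citation file must start with #N_total= and #K_disease=")
    return CitationTable(df, totals["N_total"], totals["K_disease"])


def write_citations(cites: CitationTable, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"#N_total={cites.N_total}\n#K_disease={cites.K_disease}\n")
        cites.table.to_csv(fh, sep=sep, index=False)
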