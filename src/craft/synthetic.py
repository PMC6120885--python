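"""Seeded generators with known ground truth for every pipeline stage.

Expression follows a latent-factor model: gene g in module m has

    x_gs = lambda_cond(m) * f_ms + delta_g * 1[case] + baseline + eps_gs

with one standard-normal factor per module and sample, Gaussian noise of
standard deviation ``noise_sd``, and an additive mean shift delta planting
differential expression on the log scale.  Within one condition the
expected correlation of two same-module genes is the classic factor-model
closed form lambda^2 / (lambda^2 + noise_sd^2).  Trait counts for case
samples are Poisson with log-rate ``intercept + sum_m beta_m f_ms``,
mimicking seizure counts driven by module activity.  The regulome generator
plants a driver receptor whose activating two-hop paths cover a configured
fraction of an over-expressed sub-module, among decoy receptors with random
targets.  Each component (expression / regulome / citations) draws from its
own stream spawned from the master seed, so regenerating one leaves the
others unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DETable, ExpressionMatrix, SampleTable
from .causal import Regulome


@dataclass
class ModuleSpec:
    size: int
    loading_case: float
    loading_control: float
    trait_effect: float = 0.0
    de_fraction: float = 0.0
    de_direction: str = "over"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("module size must be positive")
        for lam in (self.loading_case, self.loading_control):
            if not 0.0 <= lam <= 1.0:
                raise ValueError("loadings must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_direction not in ("over", "under"):
            raise ValueError("de_direction must be 'over' or 'under'")


@dataclass
class RegulomeSpec:
    n_targets: int = 1000
    driver_coverage: float = 0.6
    n_decoys: int = 20
    unk_fraction: float = 0.0
    driver_tfs: int = 5
    driver_extra_targets: int = 16
    decoy_tfs: int = 3
    decoy_targets_per_tf: int = 13

    def __post_init__(self) -> None:
        if not 0.0 < self.driver_coverage <= 1.0:
            raise ValueError("driver_coverage must lie in (0, 1]")
        if not 0.0 <= self.unk_fraction <= 1.0:
            raise ValueError("unk_fraction must lie in [0, 1]")


@dataclass
class SimulationConfig:
    n_genes: int
    n_case: int
    n_control: int
    module_specs: list[ModuleSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline: float = 5.0
    trait_intercept: float = 1.0
    trait_model: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 5.0
    de_shift: float = 1.0
    regulome_spec: RegulomeSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.trait_model not in ("poisson", "negative_binomial"):
            raise ValueError("trait_model must be poisson or negative_binomial")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    module_members: dict[str, frozenset[str]]
    diff_coexpressed: dict[str, bool]
    trait_associated: dict[str, bool]
    de_direction: dict[str, str]  # gene -> over | under (absent = none)
    driver_receptor: str | None = None
    driver_submodule: str | None = None  # e.g. "SM1.o"
    driver_class: str | None = None
    decoy_receptors: list[str] = field(default_factory=list)

    def de_table(self, q_de: float = 1e-3) -> DETable:
        genes = sorted(set().union(*self.module_members.values())) if self.module_members else []
        rows = []
        for g in genes:
            direction = self.de_direction.get(g, "none")
            rows.append({
                "gene_id": g, "direction": direction,
                "q": q_de if direction != "none" else 1.0,
                "effect": {"over": 1.0, "under": -1.0}.get(direction, 0.0),
            })
        return DETable(pd.DataFrame(rows))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "expression": np.random.default_rng(children[0]),
        "regulome": np.random.default_rng(children[1]),
        "citations": np.random.default_rng(children[2]),
    }


def simulate_expression(cfg: SimulationConfig
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleTable, SyntheticTruth]:
    rng = _streams(cfg.seed)["expression"]
    n_total = cfg.n_case + cfg.n_control
    gene_ids = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    case_ids = [f"case_{i:03d}" for i in range(1, cfg.n_case + 1)]
    ctrl_ids = [f"ctrl_{i:03d}" for i in range(1, cfg.n_control + 1)]

    values = cfg.baseline + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_total))
    is_case = np.zeros(n_total, dtype=bool)
    is_case[:cfg.n_case] = True

    members: dict[str, frozenset[str]] = {}
    diff: dict[str, bool] = {}
    assoc: dict[str, bool] = {}
    de_dir: dict[str, str] = {}
    log_rate = np.full(cfg.n_case, cfg.trait_intercept)

    start = 0
    for mi, spec in enumerate(cfg.module_specs, start=1):
        label = f"SM{mi}"
        rows = np.arange(start, start + spec.size)
        start += spec.size
        members[label] = frozenset(gene_ids[r] for r in rows)
        diff[label] = spec.loading_case != spec.loading_control
        assoc[label] = spec.trait_effect != 0.0

        factor = rng.normal(size=n_total)
        lam = np.where(is_case, spec.loading_case, spec.loading_control)
        values[np.ix_(rows, np.arange(n_total))] += np.outer(
            np.ones(spec.size), lam * factor)

        n_de = int(round(spec.de_fraction * spec.size))
        if n_de:
            de_rows = rng.choice(rows, size=n_de, replace=False)
            shift = cfg.de_shift if spec.de_direction == "over" else -cfg.de_shift
            values[np.ix_(de_rows, np.flatnonzero(is_case))] += shift
            for r in de_rows:
                de_dir[gene_ids[r]] = spec.de_direction

        log_rate = log_rate + spec.trait_effect * factor[is_case]

    rate = np.exp(log_rate)
    if cfg.trait_model == "poisson":
        counts = rng.poisson(rate)
    else:
        r = cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + rate))
    traits = np.concatenate([counts.astype(float), np.full(cfg.n_control, np.nan)])

    case_expr = ExpressionMatrix(gene_ids, case_ids, values[:, is_case])
    ctrl_expr = ExpressionMatrix(gene_ids, ctrl_ids, values[:, ~is_case])
    samples = SampleTable(case_ids + ctrl_ids,
                          ["case"] * cfg.n_case + ["control"] * cfg.n_control,
                          traits)
    truth = SyntheticTruth(module_members=members, diff_coexpressed=diff,
                           trait_associated=assoc, de_direction=de_dir)
    return case_expr, ctrl_expr, samples, truth


def simulate_regulome(cfg: SimulationConfig, truth: SyntheticTruth
                      ) -> tuple[Regulome, SyntheticTruth]:
    """Plant a driver receptor whose activating paths cover a fraction of an
    over-expressed sub-module, among decoy receptors with random targets."""
    spec = cfg.regulome_spec
    if spec is None:
        raise ValueError("cfg.regulome_spec is not set")
    rng = _streams(cfg.seed)["regulome"]

    sub_label, sub_genes = None, None
    for label, genes in truth.module_members.items():
        over = frozenset(g for g in genes if truth.de_direction.get(g) == "over")
        if over:
            sub_label, sub_genes = label, over
            break
    if sub_genes is None:
        raise ValueError("no over-expressed sub-module in the truth to plant a driver on")

    n_cov = int(round(spec.driver_coverage * len(sub_genes)))
    if n_cov < 1:
        raise ValueError(
            f"driver coverage {spec.driver_coverage} of a {len(sub_genes)}-gene "
            "sub-module covers no gene")

    all_genes = sorted(set().union(*truth.module_members.values()))
    background = [f"BG{i:05d}" for i in range(1, max(0, spec.n_targets - len(all_genes)) + 1)]
    pool = (all_genes + background)[:spec.n_targets]
    pool_set = set(pool)
    missing_sub = [g for g in sorted(sub_genes) if g not in pool_set]
    if missing_sub:
        raise ValueError("target pool does not contain the planted sub-module")

    rt_edges: set[tuple[str, str, str]] = set()
    tt_edges: set[tuple[str, str, str]] = set()

    driver = "R_driver"
    covered = rng.choice(sorted(sub_genes), size=n_cov, replace=False)
    non_sub = sorted(pool_set - sub_genes)
    extras = rng.choice(non_sub, size=min(spec.driver_extra_targets, len(non_sub)),
                        replace=False)
    driver_targets = list(covered) + list(extras)
    tf_names = [f"TF_drv{i:02d}" for i in range(1, spec.driver_tfs + 1)]
    for tf in tf_names:
        rt_edges.add((driver, tf, "act"))
    for i, gene in enumerate(driver_targets):
        tt_edges.add((tf_names[i % len(tf_names)], gene, "act"))

    decoys = [f"R_decoy{i:02d}" for i in range(1, spec.n_decoys + 1)]
    for di, decoy in enumerate(decoys, start=1):
        for ti in range(1, spec.decoy_tfs + 1):
            tf = f"TF_d{di:02d}_{ti}"
            rt_edges.add((decoy, tf, str(rng.choice(["act", "inh"]))))
            tgts = rng.choice(pool, size=min(spec.decoy_targets_per_tf, len(pool)),
                              replace=False)
            for gene in tgts:
                tt_edges.add((tf, gene, str(rng.choice(["act", "inh"]))))

    # a hub TF pins the regulome target universe to the full pool
    for gene in pool:
        tt_edges.add(("TF_hub", gene, "unk"))

    if spec.unk_fraction > 0:
        def degrade(edges: set[tuple[str, str, str]]) -> set[tuple[str, str, str]]:
            edges = sorted(edges)
            n_unk = int(round(spec.unk_fraction * len(edges)))
            idx = set(rng.choice(len(edges), size=n_unk, replace=False).tolist())
            return {(s, t, "unk") if i in idx else e
                    for i, (e, (s, t, _)) in enumerate(zip(edges, edges))}
        rt_edges = degrade(rt_edges)
        tt_edges = {e for e in tt_edges if e[0] == "TF_hub"} | degrade(
            {e for e in tt_edges if e[0] != "TF_hub"})

    truth.driver_receptor = driver
    truth.driver_submodule = f"{sub_label}.o"
    truth.driver_class = "act" if spec.unk_fraction < 1.0 else "ns"
    truth.decoy_receptors = decoys
    return Regulome(frozenset(rt_edges), frozenset(tt_edges)), truth


def simulate_citations(gene_ids, disease_genes, seed: int = 0,
                       mean_abstracts: float = 100.0, enrichment: float = 10.0,
                       N_total: int = 1_000_000, K_disease: int = 6_000):
    """Citation counts with planted disease genes at an elevated
    co-citation rate; background genes sit at the corpus base rate."""
    from .core_io import CitationTable

    rng = _streams(seed)["citations"]
    disease = set(disease_genes)
    base = K_disease / N_total
    rows = []
    for g in gene_ids:
        n = int(rng.poisson(mean_abstracts)) + 1
        rate = min(base * (enrichment if g in disease else 1.0), 1.0)
        k = int(rng.binomial(n, rate))
        rows.append({"gene_id": g, "n_gene": n, "k_gene": k})
    return CitationTable(pd.DataFrame(rows), N_total, K_disease)
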