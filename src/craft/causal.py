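"""Signed causal reasoning from membrane receptors to disease sub-modules.

The regulome is a two-layer signed directed graph: receptor -> transcription
factor (TF) edges derived from linear canonical pathways, and TF -> target
edges, each carrying a sign in {act, inh, unk}.  For every receptor, the
sign of each two-hop path is composed and the receptor's direction-specified
target sets (activated / inhibited / unknown) are assembled.  Each set is
tested for overlap with a disease sub-module — the over-expressed ("o") or
under-expressed ("u") genes of a co-expression module — by an upper-tail
hypergeometric test, BH-adjusted across the whole run.  Receptors are then
classified as activators (act), inhibitors (inh), unspecified (uns) or
non-significant (ns) of each sub-module, scored by

    activity = k / n   (fraction of the direction-specified targets that
                        fall in the sub-module)
    weight   = k / K   (fraction of the sub-module under the regulator's
                        direction-specified control)

and ranked.  Under the signature-reversion paradigm, an activator of an
over-expressed sub-module (or an inhibitor of an under-expressed one) is a
blockade candidate, and conversely for activation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import DETable, FormatError, adjust_bh
from .coexpression import ModulePartition
from .enrichment import hypergeom_upper

SIGNS = ("act", "inh", "unk")
LAYERS = ("receptor_tf", "tf_target")


@dataclass
class Regulome:
    """Two signed edge layers; entities are opaque gene ids and an entity
    may play several roles (a receptor may itself be a TF's target)."""

    receptor_tf_edges: frozenset[tuple[str, str, str]]
    tf_target_edges: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for src, tgt, sign in itertools.chain(self.receptor_tf_edges,
                                              self.tf_target_edges):
            if sign not in SIGNS:
                raise FormatError(
                    f"unknown sign {sign!r} on edge {src}->{tgt}; allowed: {SIGNS}")

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(r for r, _, _ in self.receptor_tf_edges)

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(t for _, t, _ in self.receptor_tf_edges) | \
            frozenset(t for t, _, _ in self.tf_target_edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(g for _, g, _ in self.tf_target_edges)


def read_regulome(path, sep: str = "\t") -> Regulome:
    """Read a 4-column signed edge list (source, target, layer, sign).

    Exact duplicate rows collapse to one edge; a (source, target, layer)
    pair annotated with both act and inh keeps both signed edges, so the
    causal engine sees the conflicting paths.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["source", "target", "layer", "sign"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"regulome needs columns {required}")
    bad_layer = ~df["layer"].isin(LAYERS)
    if bad_layer.any():
        raise FormatError(
            f"unknown layer {df.loc[bad_layer, 'layer'].iloc[0]!r}; allowed: {LAYERS}")
    bad_sign = ~df["sign"].isin(SIGNS)
    if bad_sign.any():
        raise FormatError(
            f"unknown sign {df.loc[bad_sign, 'sign'].iloc[0]!r}; allowed: {SIGNS}")
    rt = frozenset((r.source, r.target, r.sign)
                   for r in df[df["layer"] == "receptor_tf"].itertuples())
    tt = frozenset((r.source, r.target, r.sign)
                   for r in df[df["layer"] == "tf_target"].itertuples())
    return Regulome(rt, tt)


def write_regulome(reg: Regulome, path, sep: str = "\t") -> None:
    rows = [(s, t, "receptor_tf", sg) for s, t, sg in sorted(reg.receptor_tf_edges)]
    rows += [(s, t, "tf_target", sg) for s, t, sg in sorted(reg.tf_target_edges)]
    pd.DataFrame(rows, columns=["source", "target", "layer", "sign"]).to_csv(
        path, sep=sep, index=False)


def filter_to_expressed(reg: Regulome, expressed) -> Regulome:
    """Restrict every edge to endpoints in the expressed gene set."""
    expressed = set(expressed)
    if not expressed:
        warnings.warn("empty expressed set: the filtered regulome is empty",
                      stacklevel=2)
    rt = frozenset((r, t, s) for r, t, s in reg.receptor_tf_edges
                   if r in expressed and t in expressed)
    tt = frozenset((t, g, s) for t, g, s in reg.tf_target_edges
                   if t in expressed and g in expressed)
    return Regulome(rt, tt)


def regulome_counts(reg: Regulome) -> dict[str, int]:
    return {
        "receptors": len(reg.receptors),
        "tfs": len(reg.tfs),
        "targets": len(reg.targets),
        "receptor_tf_edges": len(reg.receptor_tf_edges),
        "tf_target_edges": len(reg.tf_target_edges),
    }


# ---------------------------------------------------------------------------
# Sign algebra
# ---------------------------------------------------------------------------

_MULTIPLICATIVE = {
    ("act", "act"): "act", ("act", "inh"): "inh",
    ("inh", "act"): "inh", ("inh", "inh"): "act",
}
# The published rule table differs from sign multiplication in exactly one
# cell: an inhibitory receptor->TF edge composed with an activating
# TF->target edge is printed as "Activated".  Both behaviours are
# selectable; multiplicative is the default.
_AS_PRINTED = {
    ("act", "act"): "act", ("act", "inh"): "inh",
    ("inh", "act"): "act", ("inh", "inh"): "act",
}


def compose_signs(s1: str, s2: str, mode: str = "multiplicative") -> str:
    """Compose a receptor->TF sign with a TF->target sign; unk absorbs."""
    if s1 not in SIGNS or s2 not in SIGNS:
        raise ValueError(f"signs must be in {SIGNS}, got ({s1!r}, {s2!r})")
    if s1 == "unk" or s2 == "unk":
        return "unk"
    if mode == "multiplicative":
        return _MULTIPLICATIVE[(s1, s2)]
    if mode == "as_printed":
        return _AS_PRINTED[(s1, s2)]
    raise ValueError(f"unknown sign mode {mode!r}")


# ---------------------------------------------------------------------------
# Direction-specified target sets
# ---------------------------------------------------------------------------

@dataclass
class DirectedTargetSets:
    """Genes a regulator is predicted to influence, by composed direction.

    ``activated`` and ``inhibited`` may intersect (conflicting paths are
    preserved); ``unknown`` holds genes reachable only through unk-composed
    paths.
    """

    regulator: str
    activated: frozenset[str]
    inhibited: frozenset[str]
    unknown: frozenset[str]


def receptor_target_sets(reg: Regulome, receptor: str,
                         mode: str = "multiplicative") -> DirectedTargetSets:
    """Compose all two-hop receptor -> TF -> gene paths for one receptor."""
    if receptor not in reg.receptors:
        raise KeyError(f"receptor {receptor!r} absent from the regulome")
    tf_edges: dict[str, list[tuple[str, str]]] = {}
    for tf, gene, sign in reg.tf_target_edges:
        tf_edges.setdefault(tf, []).append((gene, sign))
    act: set[str] = set()
    inh: set[str] = set()
    unk: set[str] = set()
    for r, tf, s1 in reg.receptor_tf_edges:
        if r != receptor:
            continue
        for gene, s2 in tf_edges.get(tf, ()):
            composed = compose_signs(s1, s2, mode=mode)
            if composed == "act":
                act.add(gene)
            elif composed == "inh":
                inh.add(gene)
            else:
                unk.add(gene)
    unk -= act | inh
    return DirectedTargetSets(receptor, frozenset(act), frozenset(inh), frozenset(unk))


def tf_target_sets(reg: Regulome, tf: str) -> DirectedTargetSets:
    """Direction-specified targets of a TF from its direct edges."""
    act = frozenset(g for t, g, s in reg.tf_target_edges if t == tf and s == "act")
    inh = frozenset(g for t, g, s in reg.tf_target_edges if t == tf and s == "inh")
    unk = frozenset(g for t, g, s in reg.tf_target_edges if t == tf and s == "unk")
    if not (act or inh or unk):
        raise KeyError(f"TF {tf!r} has no target edges in the regulome")
    return DirectedTargetSets(tf, act, inh, unk - act - inh)


# ---------------------------------------------------------------------------
# Sub-modules
# ---------------------------------------------------------------------------

@dataclass
class SubModule:
    """The over- ("o") or under-expressed ("u") genes of a module."""

    label: str
    direction: str  # "o" | "u"
    genes: frozenset[str]

    @property
    def name(self) -> str:
        return f"{self.label}.{self.direction}"


def build_submodules(partition: ModulePartition, de: DETable) -> list[SubModule]:
    """Split each module into its o/u sub-modules; empty ones are dropped."""
    subs = []
    for label, genes in partition.modules.items():
        over = frozenset(g for g in genes if de.direction_of(g) == "over")
        under = frozenset(g for g in genes if de.direction_of(g) == "under")
        if over:
            subs.append(SubModule(label=label, direction="o", genes=over))
        if under:
            subs.append(SubModule(label=label, direction="u", genes=under))
        if not over and not under:
            warnings.warn(f"module {label} has no DE genes; no sub-modules",
                          stacklevel=2)
    return subs


# ---------------------------------------------------------------------------
# Effect tests
# ---------------------------------------------------------------------------

@dataclass
class EffectTest:
    regulator: str
    submodule: str
    effect_sign: str  # "positive" | "negative"
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float  # NaN until the family-wise BH pass
    conflicted: frozenset[str] = frozenset()  # genes in both directed sets


def resolve_universe(reg: Regulome, expressed, universe: str) -> frozenset[str]:
    """Resolve the hypergeometric population for effect tests.

    ``regulome_targets`` (default): expressed genes appearing as targets
    anywhere in the filtered regulome.  ``expressed_genes``: every expressed
    gene.  (``regulator_targets`` is resolved per regulator inside
    :func:`effect_enrichment`.)
    """
    if universe == "regulome_targets":
        return frozenset(reg.targets) & frozenset(expressed)
    if universe == "expressed_genes":
        return frozenset(expressed)
    raise ValueError(f"unknown universe {universe!r}")


def effect_enrichment(targets: DirectedTargetSets, sub: SubModule,
                      universe) -> tuple[EffectTest | None, EffectTest | None]:
    """Paired positive/negative hypergeometric tests of a regulator's
    direction-specified target sets against one sub-module.

    An empty (universe-restricted) target set yields None — recorded as
    untested, never as p = 1.
    """
    universe = frozenset(universe)
    sub_u = sub.genes & universe
    if not sub_u:
        return None, None
    conflicted = targets.activated & targets.inhibited
    out = []
    for effect_sign, tset in (("positive", targets.activated),
                              ("negative", targets.inhibited)):
        t_u = tset & universe
        if not t_u:
            out.append(None)
            continue
        k = len(t_u & sub_u)
        out.append(EffectTest(
            regulator=targets.regulator, submodule=sub.name,
            effect_sign=effect_sign, k=k, n=len(t_u), K=len(sub_u),
            N=len(universe), p=hypergeom_upper(k, len(universe), len(sub_u), len(t_u)),
            q=float("nan"), conflicted=frozenset(conflicted & universe)))
    return out[0], out[1]


def run_effect_tests(reg: Regulome, submodules: list[SubModule], universe,
                     regulators=None, kind: str = "receptor",
                     mode: str = "multiplicative") -> list[EffectTest]:
    """All (regulator x sub-module x sign) tests of one family, BH-adjusted
    together.  Receptors and TFs form separate families, mirroring how they
    are reported separately."""
    if kind == "receptor":
        regulators = sorted(regulators if regulators is not None else reg.receptors)
        get_sets = lambda r: receptor_target_sets(reg, r, mode=mode)  # noqa: E731
    elif kind == "tf":
        regulators = sorted(regulators if regulators is not None else
                            {t for t, _, _ in reg.tf_target_edges})
        get_sets = lambda r: tf_target_sets(reg, r)  # noqa: E731
    else:
        raise ValueError(f"unknown regulator kind {kind!r}")
    universe = frozenset(universe)
    tests: list[EffectTest] = []
    for r in regulators:
        tsets = get_sets(r)
        for sub in submodules:
            pos, neg = effect_enrichment(tsets, sub, universe)
            tests.extend(t for t in (pos, neg) if t is not None)
    if tests:
        qs = adjust_bh(np.array([t.p for t in tests]))
        for t, qv in zip(tests, qs):
            t.q = float(qv)
    return tests


# ---------------------------------------------------------------------------
# Classification and ranking
# ---------------------------------------------------------------------------

@dataclass
class RegulatorCall:
    regulator: str
    submodule: str
    clazz: str  # act | inh | uns | ns
    activity: float
    weight: float
    q: float  # q of the classifying test (min q for uns/ns)
    absolute_rank: int | None = None
    relative_rank: int | None = None


def classify_regulator(pos: EffectTest | None, neg: EffectTest | None,
                       alpha: float = 0.05) -> str:
    """act: significant positive effect, no significant negative one;
    inh symmetric; uns: both significant; ns otherwise."""
    pos_sig = pos is not None and pos.q < alpha
    neg_sig = neg is not None and neg.q < alpha
    if pos_sig and neg_sig:
        return "uns"
    if pos_sig:
        return "act"
    if neg_sig:
        return "inh"
    return "ns"


def make_calls(tests: list[EffectTest], alpha: float = 0.05) -> list[RegulatorCall]:
    """Fold paired effect tests into one classified call per
    (regulator, sub-module).

    Activity and weight come from the classifying test; for uns (and for ns
    reporting) the more significant of the two tests is used.
    """
    grouped: dict[tuple[str, str], dict[str, EffectTest]] = {}
    for t in tests:
        grouped.setdefault((t.regulator, t.submodule), {})[t.effect_sign] = t
    calls = []
    for (regulator, submodule), pair in sorted(grouped.items()):
        pos = pair.get("positive")
        neg = pair.get("negative")
        clazz = classify_regulator(pos, neg, alpha=alpha)
        chooser = {"act": pos, "inh": neg}.get(clazz)
        if chooser is None:  # uns / ns: take the stronger evidence
            cands = [t for t in (pos, neg) if t is not None]
            chooser = min(cands, key=lambda t: t.q)
        calls.append(RegulatorCall(
            regulator=regulator, submodule=submodule, clazz=clazz,
            activity=chooser.k / chooser.n if chooser.n else 0.0,
            weight=chooser.k / chooser.K if chooser.K else 0.0,
            q=chooser.q))
    return calls


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """Competition-free average ranks, rank 1 = largest value."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    # average ranks for ties
    sorted_vals = values[order]
    i = 0
    pos = 1
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (pos + pos + (j - i)) / 2.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        pos += j - i + 1
        i = j + 1
    return ranks


def absolute_ranking(calls: list[RegulatorCall]) -> list[RegulatorCall]:
    """Rank the regulators called on one sub-module.

    Regulators with a defined direction (act/inh) take priority over uns;
    ns calls are excluded.  Within a stratum, regulators are ordered by the
    sum of their activity and weight ranks (both descending), ties broken by
    smaller classifying q, then regulator id.
    """
    ranked: list[RegulatorCall] = []
    for stratum_classes in (("act", "inh"), ("uns",)):
        stratum = [c for c in calls if c.clazz in stratum_classes]
        if not stratum:
            continue
        act_r = _rank_desc(np.array([c.activity for c in stratum]))
        wt_r = _rank_desc(np.array([c.weight for c in stratum]))
        keyed = sorted(
            zip(stratum, act_r + wt_r),
            key=lambda cw: (cw[1], cw[0].q, cw[0].regulator))
        ranked.extend(c for c, _ in keyed)
    out = []
    for i, c in enumerate(ranked, start=1):
        out.append(replace(c, absolute_rank=i))
    return out


@dataclass
class RelativeRankEntry:
    call: RegulatorCall
    relative_rank: int
    new_genes: int  # residual sub-module genes this pick covers
    cumulative_coverage: int


def _covering_set(call: RegulatorCall, tsets: DirectedTargetSets) -> frozenset[str]:
    if call.clazz == "act":
        return tsets.activated
    if call.clazz == "inh":
        return tsets.inhibited
    return tsets.activated | tsets.inhibited  # uns: either direction


def relative_ranking(calls: list[RegulatorCall],
                     target_sets: dict[str, DirectedTargetSets],
                     sub: SubModule) -> list[RelativeRankEntry]:
    """Greedy re-ranking that maximizes sub-module coverage.

    Starting from the absolute ranking, repeatedly pick the top regulator,
    remove the sub-module genes it covers, recompute activity (residual
    overlap / target-set size) and weight (residual overlap / residual
    size) for the rest, and re-rank.  Regulators contributing no residual
    coverage are listed last, in absolute-rank order.
    """
    ranked = absolute_ranking(calls)
    residual = set(sub.genes)
    remaining = list(ranked)
    entries: list[RelativeRankEntry] = []
    covered = 0
    while remaining and residual:
        scored = []
        for c in remaining:
            cov = _covering_set(c, target_sets[c.regulator])
            k_res = len(cov & residual)
            n = len(cov)
            scored.append(replace(
                c,
                activity=k_res / n if n else 0.0,
                weight=k_res / len(residual) if residual else 0.0))
        if all(len(_covering_set(c, target_sets[c.regulator]) & residual) == 0
               for c in remaining):
            break
        order = absolute_ranking(scored)
        pick = order[0]
        original = next(c for c in remaining if c.regulator == pick.regulator)
        cov = _covering_set(original, target_sets[original.regulator])
        new = len(cov & residual)
        covered += new
        entries.append(RelativeRankEntry(
            call=replace(original, relative_rank=len(entries) + 1),
            relative_rank=len(entries) + 1, new_genes=new,
            cumulative_coverage=covered))
        residual -= cov
        remaining = [c for c in remaining if c.regulator != pick.regulator]
    for c in remaining:  # zero-contribution stragglers, listed last
        entries.append(RelativeRankEntry(
            call=replace(c, relative_rank=len(entries) + 1),
            relative_rank=len(entries) + 1, new_genes=0,
            cumulative_coverage=covered))
    return entries


# ---------------------------------------------------------------------------
# Therapeutic direction
# ---------------------------------------------------------------------------

_THERAPY = {
    ("act", "o"): "blockade",
    ("inh", "o"): "activation",
    ("act", "u"): "activation",
    ("inh", "u"): "blockade",
}


def therapeutic_direction(clazz: str, direction: str) -> str:
    """Map a (regulator class, sub-module direction) pair to the predicted
    therapeutic intervention under signature reversion.

    An activator of over-expressed disease genes (or an inhibitor of
    under-expressed ones) is a disease activator: blockade should restore
    the signature toward health.  The mirrored cases call for activation.
    uns/ns calls give no recommendation.
    """
    if direction not in ("o", "u"):
        raise ValueError(f"sub-module direction must be 'o' or 'u', got {direction!r}")
    return _THERAPY.get((clazz, direction), "undetermined")


def calls_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        direction = c.submodule.rsplit(".", 1)[-1]
        rows.append({
            "regulator": c.regulator, "submodule": c.submodule,
            "class": c.clazz, "activity": c.activity, "weight": c.weight,
            "q": c.q, "absolute_rank": c.absolute_rank,
            "intervention": therapeutic_direction(c.clazz, direction)
            if direction in ("o", "u") else "undetermined",
        })
    return pd.DataFrame(rows)
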