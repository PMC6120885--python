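"""End-to-end pipeline: filter -> modules -> differential co-expression ->
trait association -> causal reasoning -> rankings.

Each stage writes its outputs (TSV/JSON) into its own subdirectory before
the next stage begins, and a JSON run manifest (config snapshot, input
digests, seed, per-stage parameters, counts) is written last.  Module
prioritization gates (differential co-expression, trait correlation) mirror
the staged analysis cascade and can be disabled individually.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, causal, coexpression, core_io, diffcoexpr

DEFAULTS = {
    "filter": {"threshold": 0.0, "min_fraction": 0.05},
    "modules": {"k_min": 2, "k_max": 30, "select": "consensus",
                "elbow_fraction": 0.01, "elbow_window": 3,
                "consensus_tolerance": 2, "min_module_size": 0},
    "diffcoexpr": {"B": 1000, "alpha": 0.05, "gate": True},
    "associate": {"alpha": 0.05, "gate": True, "qtt_threshold": 0.05},
    "causal": {"universe": "regulome_targets", "sign_mode": "multiplicative",
               "alpha": 0.05, "de_alpha": 0.05},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _merge(defaults: dict, override: dict | None) -> dict:
    out = dict(defaults)
    out.update(override or {})
    return out


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full analysis described by ``config`` (see DEFAULTS for the
    per-stage knobs).  Required config keys: inputs.case, inputs.control,
    inputs.samples, inputs.regulome; optional: inputs.de, seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    for key in ("case", "control", "samples", "regulome"):
        if key not in inputs:
            raise ValueError(f"config inputs.{key} is required")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"inputs.{key}: no such file {inputs[key]}")
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "tool": "craft",
        "version": _pkg_version("craft"),
        "seed": seed,
        "config": config,
        "input_digests": {k: _digest(v) for k, v in inputs.items()},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    stage = "filter"
    try:
        p = _merge(DEFAULTS["filter"], config.get("filter"))
        case = core_io.read_expression(inputs["case"])
        control = core_io.read_expression(inputs["control"])
        samples = core_io.read_samples(inputs["samples"])
        common = [g for g in case.gene_ids if g in control]
        joint = core_io.ExpressionMatrix(
            common, case.sample_ids + control.sample_ids,
            np.hstack([case.subset_genes(common).values,
                       control.subset_genes(common).values]))
        expressed = core_io.filter_expressed(joint, p["threshold"], p["min_fraction"])
        case = case.subset_genes(expressed.gene_ids)
        control = control.subset_genes(expressed.gene_ids)
        d = outdir / "filter"
        d.mkdir(exist_ok=True)
        (d / "expressed_genes.txt").write_text("\n".join(expressed.gene_ids) + "\n")
        manifest["stages"][stage] = {"params": p, "n_expressed": expressed.n_genes}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "modules"
    try:
        p = _merge(DEFAULTS["modules"], config.get("modules"))
        dist = coexpression.spearman_distance(case)
        tree = coexpression.ward_cluster(dist)
        k_max = min(p["k_max"], case.n_genes)
        scores = coexpression.scan_partitions(tree, dist, p["k_min"], k_max)
        try:
            k = coexpression.select_k(
                scores, method=p["select"], elbow_fraction=p["elbow_fraction"],
                elbow_window=p["elbow_window"],
                consensus_tolerance=p["consensus_tolerance"])
        except coexpression.KSelectionError as err:
            warnings.warn(f"{err}; falling back to the pseudo-F choice",
                          stacklevel=2)
            k = err.k_pseudof
        partition = coexpression.cut_tree(tree, dist, k)
        if p["min_module_size"]:
            partition = coexpression.relabel_small_modules(partition, p["min_module_size"])
        d = outdir / "modules"
        d.mkdir(exist_ok=True)
        pd.DataFrame([s.__dict__ for s in scores]).to_csv(
            d / "scores.tsv", sep="\t", index=False)
        core_io.write_gmt(partition.modules, d / "modules.gmt")
        pd.DataFrame(sorted(partition.assignment.items()),
                     columns=["gene_id", "module"]).to_csv(
            d / "assignment.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"params": p, "selected_k": k}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "diffcoexpr"
    try:
        p = _merge(DEFAULTS["diffcoexpr"], config.get("diffcoexpr"))
        results = diffcoexpr.diffcoexpr_family(
            case, control, partition.modules, B=p["B"], seed=seed)
        d = outdir / "diffcoexpr"
        d.mkdir(exist_ok=True)
        dce = pd.DataFrame([r.__dict__ for r in results])
        dce.to_csv(d / "dce.tsv", sep="\t", index=False)
        dce_pass = {r.label for r in results if r.q < p["alpha"]}
        manifest["stages"][stage] = {"params": p, "n_significant": len(dce_pass)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "associate"
    trait_pass = set(partition.modules)
    try:
        p = _merge(DEFAULTS["associate"], config.get("associate"))
        have_trait = not np.all(np.isnan(samples.trait_of(samples.samples_of("case"))))
        d = outdir / "associate"
        d.mkdir(exist_ok=True)
        if have_trait:
            eigengenes = [
                coexpression.module_eigengene(case, genes, label=name)
                for name, genes in partition.modules.items()
                if len(genes) >= 2]
            mt = association.eigengene_trait(eigengenes, samples)
            pd.DataFrame([r.__dict__ for r in mt]).to_csv(
                d / "module_trait.tsv", sep="\t", index=False)
            qres = association.qtt(case, samples, threshold=p["qtt_threshold"])
            qres.table.to_csv(d / "qtt.tsv", sep="\t", index=False)
            association.module_qtt_table(
                partition.modules, qres, case.gene_ids).to_csv(
                d / "module_qtt.tsv", sep="\t", index=False)
            trait_pass = {r.label for r in mt if r.q < p["alpha"]}
            manifest["stages"][stage] = {
                "params": p, "n_trait_modules": len(trait_pass),
                "n_qtt_genes": len(qres.qtt_genes)}
        else:
            manifest["stages"][stage] = {"params": p, "skipped": "no trait values"}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "causal"
    try:
        p = _merge(DEFAULTS["causal"], config.get("causal"))
        gates = set(partition.modules)
        if _merge(DEFAULTS["diffcoexpr"], config.get("diffcoexpr"))["gate"]:
            gates &= dce_pass
        if _merge(DEFAULTS["associate"], config.get("associate"))["gate"]:
            gates &= trait_pass
        if "de" in inputs:
            de = core_io.read_de_table(inputs["de"])
        else:
            de = core_io.rank_sum_de(case, control, alpha=p["de_alpha"])
        reg = causal.read_regulome(inputs["regulome"])
        # an entity counts as expressed if it passed the filter, or was never
        # measured at all (its expression status is unknown, not negative)
        measured = set(common)
        exp_set = set(expressed.gene_ids)
        keep = exp_set | {e for e in (reg.receptors | reg.tfs | reg.targets)
                          if e not in measured}
        reg = causal.filter_to_expressed(reg, keep)
        gated = coexpression.ModulePartition(
            assignment={g: m for g, m in partition.assignment.items() if m in gates},
            K=len(gates))
        submodules = causal.build_submodules(gated, de) if gates else []
        universe = causal.resolve_universe(reg, expressed.gene_ids, p["universe"])
        rec_tests = causal.run_effect_tests(
            reg, submodules, universe, kind="receptor", mode=p["sign_mode"])
        tf_tests = causal.run_effect_tests(
            reg, submodules, universe, kind="tf")
        calls = causal.make_calls(rec_tests, alpha=p["alpha"])
        d = outdir / "causal"
        d.mkdir(exist_ok=True)
        for name, tests in (("receptor_tests", rec_tests), ("tf_tests", tf_tests)):
            pd.DataFrame([{**t.__dict__, "conflicted": len(t.conflicted)}
                          for t in tests]).to_csv(d / f"{name}.tsv", sep="\t", index=False)
        abs_rows, rel_rows = [], []
        for sub in submodules:
            sub_calls = [c for c in calls if c.submodule == sub.name]
            ranked = causal.absolute_ranking(sub_calls)
            abs_rows.extend(causal.calls_frame(ranked).to_dict("records"))
            tsets = {c.regulator: causal.receptor_target_sets(reg, c.regulator,
                                                              mode=p["sign_mode"])
                     for c in ranked}
            for entry in causal.relative_ranking(sub_calls, tsets, sub):
                rel_rows.append({
                    "regulator": entry.call.regulator, "submodule": sub.name,
                    "relative_rank": entry.relative_rank,
                    "new_genes": entry.new_genes,
                    "cumulative_coverage": entry.cumulative_coverage})
        causal.calls_frame(calls).to_csv(d / "calls.tsv", sep="\t", index=False)
        pd.DataFrame(abs_rows).to_csv(d / "absolute_ranking.tsv", sep="\t", index=False)
        pd.DataFrame(rel_rows).to_csv(d / "relative_ranking.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "params": p, "universe_size": len(universe),
            "gated_modules": sorted(gates),
            "counts": causal.regulome_counts(reg),
            "n_submodules": len(submodules)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
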