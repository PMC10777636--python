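"""End-to-end pipeline: simulate/load -> core taxa -> EMF -> ordination ->
network -> drivers, with a machine-readable JSON run report.

A run is configured by a plain dict (usually loaded from YAML). One
global seed is fanned out deterministically to every stochastic stage,
so re-running the same config reproduces every number bitwise.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import numpy as np

from . import __version__
from .community import anosim, bray_curtis, pcoa
from .core import identify_core
from .drivers import (compare_cluster_abundance_by_zone, compare_core_importance,
                      ols_cluster_emf, rf_importance, trophic_ratio)
from .emf import compare_emf_groups, emf_index
from .network import NetworkParams, build_network, edge_list
from .simulate import SyntheticConfig, generate
from .tables import (align_tables, ensure_relative, read_function_table,
                     read_otu_table, read_sample_metadata, read_taxonomy_table,
                     write_otu_table)

logger = logging.getLogger(__name__)

STAGES = ("inputs", "core", "emf", "ordination", "network", "drivers")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "ordination", "drivers")
    return {n: int(s.generate_state(1)[0] % 2**31)
            for n, s in zip(names, ss.spawn(len(names)))}


def _comparison_block(comp) -> dict:
    return {
        "kruskal_h": comp.kruskal_h,
        "kruskal_p": comp.kruskal_p,
        "group_means": comp.group_means,
        "pairwise": {
            f"{a}_vs_{b}": {"p": r.p_value, "method": r.method,
                            "percent_change": comp.percent_change[(a, b)]}
            for (a, b), r in comp.pairwise.items()},
    }


def run_pipeline(config: dict) -> dict:
    """Execute all stages in dependency order and return the run report.

    On a stage failure the report records the stage and error and the
    remaining stages are skipped.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "coremf_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    report: dict = {"version": __version__, "seed": seed,
                    "stage_seeds": seeds, "stages": {}, "warnings": []}

    state: dict = {}
    for stage in STAGES:
        try:
            block = _run_stage(stage, config, state, seeds, outdir)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            logger.error("stage %s failed: %s\n%s", stage, exc,
                         traceback.format_exc())
            break
        report["stages"][stage] = {"status": "ok", **block}

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1,
                                                       default=float))
    return report


def _run_stage(stage: str, config: dict, state: dict, seeds: dict,
               outdir: Path) -> dict:
    if stage == "inputs":
        return _stage_inputs(config, state, seeds, outdir)
    if stage == "core":
        return _stage_core(config, state, outdir)
    if stage == "emf":
        return _stage_emf(config, state, outdir)
    if stage == "ordination":
        return _stage_ordination(config, state, seeds, outdir)
    if stage == "network":
        return _stage_network(config, state, outdir)
    if stage == "drivers":
        return _stage_drivers(config, state, seeds, outdir)
    raise ValueError(f"unknown stage {stage}")


def _stage_inputs(config, state, seeds, outdir):
    if "simulate" in config:
        sim_cfg = SyntheticConfig(**{**config["simulate"],
                                     "seed": seeds["simulate"]})
        otu, tax, meta, fx, truth = generate(sim_cfg)
        state["truth"] = truth
        mode = "simulate"
    elif "inputs" in config:
        paths = config["inputs"]
        otu = read_otu_table(paths["otu"], kind=paths.get("kind", "counts"))
        tax = read_taxonomy_table(paths["taxonomy"])
        meta = read_sample_metadata(paths["metadata"])
        fx = read_function_table(paths["functions"]) if "functions" in paths \
            else None
        mode = "load"
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")
    otu, meta, fx = align_tables(otu, meta, fx)
    state.update(otu=otu, tax=tax, meta=meta, fx=fx)
    return {"mode": mode, "n_taxa": otu.n_taxa, "n_samples": otu.n_samples,
            "zones": sorted(set(meta.zones.values()))}


def _stage_core(config, state, outdir):
    opts = config.get("core", {})
    assignment = identify_core(state["otu"],
                               top_frac=opts.get("top_frac", 0.10),
                               occ_frac=opts.get("occ_frac", 0.95))
    state["core"] = assignment
    assignment.to_frame().to_csv(outdir / "core_assignment.tsv", sep="\t")
    core_table = ensure_relative(state["otu"]).subset_taxa(
        sorted(assignment.core_set))
    write_otu_table(core_table, outdir / "core_subset.tsv")
    state["core_table"] = core_table
    by_kingdom = assignment.core_counts_by_kingdom(state["tax"])
    return {"n_core": len(assignment.core_set), "by_kingdom": by_kingdom}


def _stage_emf(config, state, outdir):
    if state["fx"] is None:
        raise ValueError("the EMF stage requires a function table")
    res = emf_index(state["fx"])
    state["emf"] = res
    res.to_frame().to_csv(outdir / "emf.tsv", sep="\t", index_label="sample_id")
    comp = compare_emf_groups(res, state["meta"])
    state["emf_comparison"] = comp
    return {"transforms": {k: v.transform for k, v in res.transform_log.items()},
            "excluded_functions": res.excluded_functions,
            "comparison": _comparison_block(comp)}


def _stage_ordination(config, state, seeds, outdir):
    opts = config.get("ordination", {})
    d = bray_curtis(state["core_table"])
    ord_res = pcoa(d)
    np.savetxt(outdir / "pcoa_coordinates.tsv", ord_res.coordinates,
               delimiter="\t")
    groups = state["meta"].zone_vector(d.sample_ids)
    res = anosim(d, groups, n_permutations=opts.get("n_permutations", 9999),
                 seed=seeds["ordination"])
    block = {"anosim_r": res.r, "anosim_p": res.p,
             "exhaustive": res.exhaustive,
             "explained": ord_res.explained[:2].tolist()}
    # pairwise zone contrasts mirror the global test
    zones = sorted(set(groups))
    pairwise = {}
    for i, a in enumerate(zones):
        for b in zones[i + 1:]:
            keep = [j for j, z in enumerate(groups) if z in (a, b)]
            sub = d.values[np.ix_(keep, keep)]
            ids = [d.sample_ids[j] for j in keep]
            from .community import DistanceMatrix
            r2 = anosim(DistanceMatrix(ids, sub),
                        [groups[j] for j in keep],
                        n_permutations=opts.get("n_permutations", 9999),
                        seed=seeds["ordination"])
            pairwise[f"{a}_vs_{b}"] = {"r": r2.r, "p": r2.p}
    block["pairwise"] = pairwise
    state["anosim"] = res
    return block


def _stage_network(config, state, outdir):
    opts = dict(config.get("network", {}))
    subset_mode = opts.pop("subset", "core")
    params = NetworkParams(**opts)
    subset = None
    if subset_mode == "core":
        subset = sorted(state["core"].core_set)
    net = build_network(state["otu"], subset=subset, params=params)
    state["network"] = net
    net.labels_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t")
    net.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    net.kme.to_csv(outdir / "kme.tsv", sep="\t")
    net.cluster_abundance.to_csv(outdir / "cluster_abundance.tsv", sep="\t")
    edge_list(net, min_weight=0.01).to_csv(outdir / "edges.tsv", sep="\t",
                                           index=False)
    return {"beta": net.threshold_report.chosen_power,
            "scale_free_target_reached": net.threshold_report.reached_target,
            "n_clusters": net.n_clusters,
            "cluster_sizes": np.bincount(net.cluster_label)[1:].tolist(),
            "n_hub_taxa": {q: len(h) for q, h in net.hub_taxa.items()}}


def _stage_drivers(config, state, seeds, outdir):
    opts = config.get("drivers", {})
    net = state["network"]
    emf_res = state["emf"]
    rel = ensure_relative(state["otu"])
    x = rel.to_frame().T  # samples x taxa
    x = x.loc[emf_res.sample_ids]
    x = x.loc[:, x.var(axis=0) > 0]
    imp = rf_importance(x, emf_res.emf, core_set=state["core"].core_set,
                        n_trees=opts.get("n_trees", 1000),
                        n_repeats=opts.get("rf_repeats", 5),
                        n_permutations=opts.get("rf_permutations", 0),
                        seed=seeds["drivers"])
    imp.to_frame().to_csv(outdir / "rf_importance.tsv", sep="\t")
    contrast = compare_core_importance(imp)
    reg = ols_cluster_emf(net.cluster_abundance, emf_res.emf)
    reg.table.to_csv(outdir / "cluster_emf_regression.tsv", sep="\t")
    trophic = trophic_ratio(net.cluster_label, net.taxon_ids, state["tax"],
                            basis=opts.get("trophic_basis", "count"))
    trophic.table.to_csv(outdir / "trophic.tsv", sep="\t")
    zone_tests = compare_cluster_abundance_by_zone(net.cluster_abundance,
                                                   state["meta"])
    return {
        "core_vs_other_importance": {"p": contrast.p_value,
                                     "method": contrast.method,
                                     "median_diff": contrast.median_diff},
        "regressions": {int(q): {"slope": float(reg.table.loc[q, "slope"]),
                                 "r2": float(reg.table.loc[q, "r2"]),
                                 "p": float(reg.table.loc[q, "p"])}
                        for q in reg.table.index},
        "trophic_percent_copiotroph": {
            int(q): float(trophic.table.loc[q, "percent_copiotroph"])
            for q in trophic.table.index},
        "cluster_zone_tests": {q: _comparison_block(c)
                               for q, c in zone_tests.items()},
    }
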