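"""End-to-end orchestration from a single YAML config.

Each stage consumes the in-memory outputs of its predecessors, writes its
tabular results under the output directory, and contributes headline
numbers to a JSON run report. Per-stage seeds are derived
deterministically from the global seed and the stage name, so a rerun
with the same config reproduces every stochastic stage.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import decore, enrichment, io, netcore, preservation, scsig, screen, \
    synthdata, xspecies

log = logging.getLogger("gliasig")

STAGES = ("simulate", "de", "screen", "network", "preserve", "enrich",
          "scsig", "xspecies")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "gliasig_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    bulk: dict[str, Any] = field(default_factory=dict)
    de: dict[str, Any] = field(default_factory=dict)
    screen_rules: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)
    preserve: dict[str, Any] = field(default_factory=dict)
    enrich: dict[str, Any] = field(default_factory=dict)
    single_cell: dict[str, Any] = field(default_factory=dict)
    species: dict[str, Any] = field(default_factory=dict)

    _KEYS = ("seed", "outdir", "stages", "bulk", "de", "screen_rules",
             "network", "preserve", "enrich", "single_cell", "species")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self._KEYS}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONTRASTS = [
    ("WT_E13.5_vs_WT_E12.5", ("group", "WT_E13.5", "WT_E12.5")),
    ("WT_E14.5_vs_WT_E13.5", ("group", "WT_E14.5", "WT_E13.5")),
    ("cKO_E14.5_vs_WT_E14.5", ("group", "cKO_E14.5", "WT_E14.5")),
    ("rescue_E14.5_vs_WT_E14.5", ("group", "rescue_E14.5", "WT_E14.5")),
]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order and return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {},
                              "config": config.to_dict()}
    state: dict[str, Any] = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            seed = stage_seed(config.seed, stage)
            log.info("stage %s (seed %d)", stage, seed)
            _RUNNERS[stage](config, state, report, outdir, seed)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    io.write_json(report, outdir / "run_report.json")
    return report


def _run_simulate(config, state, report, outdir, seed):
    params = dict(config.bulk)
    params.setdefault("seed", seed)
    if "planted_modules" in params:
        params["planted_modules"] = [
            synthdata.PlantedModule(**m) for m in params["planted_modules"]]
    sim_cfg = synthdata.BulkSimConfig(**params)
    counts, meta, truth = synthdata.simulate_bulk_experiment(sim_cfg)
    io.write_counts_tsv(counts, outdir / "counts.tsv")
    io.write_metadata_tsv(meta, outdir / "metadata.tsv")
    io.write_json({"module_membership": truth.module_membership},
                  outdir / "ground_truth.json")
    state.update(counts=counts, meta=meta, truth=truth)
    report["stages"]["simulate"] = {
        "seed": seed, "n_genes": counts.shape[0], "n_samples": counts.shape[1]}


def _run_de(config, state, report, outdir, seed):
    counts, meta = state["counts"], state["meta"]
    meta = meta.assign(group=screen.group_column(meta))
    specs = config.de.get("contrasts") or DEFAULT_CONTRASTS
    specs = [(n, tuple(c)) for n, c in specs]
    results = screen.run_contrast_set(counts, meta, specs)
    for cname, res in results.items():
        res.to_tsv(outdir / f"de_{cname}.tsv")
    state["contrasts"] = results
    report["stages"]["de"] = {
        "seed": seed,
        "n_significant": {n: int((r.table["padj"] < 0.05).sum())
                          for n, r in results.items()}}


def _run_screen(config, state, report, outdir, seed):
    rules = screen.default_rules(**config.screen_rules)
    cand = screen.intersect_candidates(state["contrasts"], rules)
    io.write_gmt({"screen_candidates": cand.genes},
                 outdir / "candidates.gmt")
    cand.audit.to_csv(outdir / "screen_audit.tsv", sep="\t")
    state["candidates"] = cand
    report["stages"]["screen"] = {"seed": seed,
                                  "n_candidates": len(cand.genes)}


def _run_network(config, state, report, outdir, seed):
    counts, meta = state["counts"], state["meta"]
    params = netcore.NetworkParams(**config.network)
    sf = decore.size_factors(counts)
    expr = decore.shifted_log_transform(counts, sf)
    if meta["batch"].nunique() > 1:
        expr = decore.center_batches(expr, meta["batch"])
    expr = expr[expr.var(axis=1) > 0]
    kept, zk = netcore.remove_outlier_samples(expr)
    expr = expr[kept]
    power = netcore.pick_soft_power(expr, params=params)
    params.power = power.chosen
    adj = netcore.adjacency(expr, params)
    tom = netcore.tom_similarity(adj)
    assignment = netcore.cut_modules(tom, params)
    assignment = netcore.merge_modules(expr, assignment, params)
    mes = netcore.eigengene_matrix(expr, assignment)
    kme_table = netcore.kme(expr, mes)
    assignment.to_frame().to_csv(outdir / "modules.tsv", sep="\t")
    mes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    kme_table.to_csv(outdir / "kme.tsv", sep="\t")
    state.update(expr=expr, params=params, assignment=assignment,
                 eigengenes=mes, kme=kme_table, kept_samples=kept)

    module_sizes = assignment[assignment != netcore.UNASSIGNED] \
        .value_counts().to_dict()
    info = {"seed": seed, "power": params.power,
            "n_modules": len(module_sizes), "module_sizes": module_sizes,
            "outliers_removed": sorted(set(zk.index) - set(kept))}
    truth = state.get("truth")
    if truth is not None:
        planted = {g for g, m in truth.module_membership.items()
                   if m != "background"}
        universe = set(assignment.index)
        best = None
        for m in module_sizes:
            genes = set(assignment.index[assignment == m])
            p = enrichment.hypergeom_overlap(genes, planted & universe,
                                             universe)
            if best is None or p < best[1]:
                best = (m, p)
        if best:
            info["recovered_module"] = best[0]
            info["recovery_hypergeom_p"] = best[1]
            state["recovered_module"] = best[0]
            anova = netcore.eigengene_anova(
                state["eigengenes"], state["meta"].loc[kept], best[0],
                "genotype")
            info["eigengene_anova_p"] = anova.p_value
    report["stages"]["network"] = info


def _run_preserve(config, state, report, outdir, seed):
    expr = state["expr"]
    rng = np.random.default_rng(seed)
    n_perm = config.preserve.get("n_perm", 200)
    half = expr.shape[1] // 2
    cols = list(expr.columns)
    rng.shuffle(cols)
    ref, test = expr[cols[:half]], expr[cols[half:]]
    rep = preservation.module_preservation(
        ref, test, state["assignment"], state["params"],
        n_perm=n_perm, seed=seed)
    rep.to_tsv(outdir / "preservation.tsv")
    report["stages"]["preserve"] = {
        "seed": seed,
        "Zsummary": dict(zip(rep.table["module"], rep.table["Zsummary"]))}


def _run_enrich(config, state, report, outdir, seed):
    truth = state["truth"]
    planted = {g for g, m in truth.module_membership.items()
               if m != "background"}
    ish_cfg = synthdata.IshSimConfig(
        true_positive_set=frozenset(planted),
        score_distribution_positive=tuple(
            config.enrich.get("score_dist_positive", (0.2, 0.1, 0.2, 0.5))),
        score_distribution_negative=tuple(
            config.enrich.get("score_dist_negative", (0.7, 0.15, 0.13, 0.02))),
        n_genes_scored=config.enrich.get("n_genes_scored",
                                         max(200, 2 * len(planted))),
        seed=seed)
    scores = synthdata.simulate_ish_scores(ish_cfg)
    scores.to_csv(outdir / "ish_scores.tsv", sep="\t")
    cand = state.get("candidates")
    cand_genes = [g for g in (cand.genes if cand else sorted(planted))
                  if g in scores.index]
    ctrl = enrichment.random_set_control(scores, cand_genes, seed=seed)
    n_perm = config.enrich.get("n_perm", 1000)
    # rank genes by evidence of loss in the knockout (down -> top)
    cko = state["contrasts"]["cKO_E14.5_vs_WT_E14.5"].table
    ranked_scores = (-cko.dropna(subset=["waldZ"])["waldZ"]) \
        .sort_values(ascending=False)
    ranked = list(ranked_scores.items())
    gres = enrichment.gsea(ranked, sorted(planted), n_perm=n_perm, seed=seed)
    enrichment.gsea_results_to_tsv([gres], outdir / "gsea.tsv", seed)
    report["stages"]["enrich"] = {
        "seed": seed,
        "candidate_positive_fraction": ctrl.candidate_fraction,
        "random_positive_fractions": ctrl.random_fractions,
        "fisher_p": [t.p_value for t in ctrl.fisher],
        "gsea_nes": gres.nes, "gsea_p": gres.p_value}


def _run_scsig(config, state, report, outdir, seed):
    truth = state["truth"]
    planted = sorted(g for g, m in truth.module_membership.items()
                     if m != "background")
    sc = dict(config.single_cell)
    n_genes = sc.get("n_genes", 500)
    shift = sc.get("signature_log2_shift", 2.0)
    sig = tuple(planted[: sc.get("signature_size", 40)]) or \
        tuple(f"g{i:05d}" for i in range(40))
    cfg = synthdata.SingleCellSimConfig(
        cell_types=[
            synthdata.CellTypeSpec("bRG", sc.get("n_brg", 200), sig, shift),
            synthdata.CellTypeSpec("aRG", sc.get("n_arg", 400)),
            synthdata.CellTypeSpec("IPC", sc.get("n_ipc", 400)),
        ],
        n_genes=n_genes, seed=seed)
    matrix, labels = synthdata.simulate_single_cells(cfg)
    io.write_mtx(matrix, outdir / "single_cell")
    res = scsig.geneset_overdispersion(
        matrix, {"planted_signature": list(sig)},
        n_null_sets=sc.get("n_null_sets", 200), seed=seed)
    scsig.scores_to_tsv(res, outdir / "scsig_scores.tsv")
    flagged = scsig.flag_cells(res[0])
    true_cells = set(labels.index[labels == "bRG"])
    recall = len(set(flagged) & true_cells) / max(len(true_cells), 1)
    fp = len(set(flagged) - true_cells) / max(len(flagged), 1)
    report["stages"]["scsig"] = {
        "seed": seed, "adjusted_z": res[0].adjusted_z,
        "flag_recall": recall, "flag_false_positive_rate": fp}


def _run_xspecies(config, state, report, outdir, seed):
    sp = dict(config.species)
    n_genes = sp.get("n_genes", 600)
    n_orth = sp.get("n_orthologs", 500)
    design = [synthdata.DesignCell("WT", s, sp.get("n_replicates", 4))
              for s in synthdata.STAGES]
    base = dict(n_genes=n_genes, design=design,
                effect_size_log2=sp.get("effect_size_log2", 2.0))
    cfg_a = synthdata.BulkSimConfig(**base, seed=seed)
    cfg_b = synthdata.BulkSimConfig(**base, seed=seed + 1)
    shared = [synthdata.PlantedModule("shared", sp.get("module_size", 50))]
    counts_a, counts_b, omap = synthdata.simulate_species_pair(
        cfg_a, cfg_b, shared, n_orth,
        many2many_frac=sp.get("many2many_frac", 0.05),
        rrna_frac=sp.get("rrna_frac", 0.05),
        mito_frac=sp.get("mito_frac", 0.02), seed=seed)
    omap.records.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    pair = xspecies.harmonize_orthologs(counts_a, counts_b, omap)
    contrast = xspecies.species_de(pair)
    contrast.to_tsv(outdir / "species_de.tsv")
    mean_a, mean_b = xspecies.species_mean_expression(pair)
    rho, p = xspecies.rank_correlation(mean_a, mean_b)
    report["stages"]["xspecies"] = {
        "seed": seed, "kept": pair.dropped.get("kept"),
        "dropped": {k: v for k, v in pair.dropped.items() if k != "kept"},
        "spearman_r": rho, "spearman_p": p,
        "fractions": xspecies.de_fractions(contrast)}


_RUNNERS = {
    "simulate": _run_simulate, "de": _run_de, "screen": _run_screen,
    "network": _run_network, "preserve": _run_preserve,
    "enrich": _run_enrich, "scsig": _run_scsig, "xspecies": _run_xspecies,
}
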