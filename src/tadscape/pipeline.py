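"""End-to-end orchestration: simulate -> differential analyses -> TAD
enrichment -> Hi-C topology -> report.

The pipeline is deterministic given its config (one root seed drives the
simulators and every permutation test) and idempotent: re-running with
the same config rewrites byte-identical tables. Each report carries a
provenance block with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hic as hic_mod
from . import methylation as meth
from . import sites as sites_mod
from . import tads as tads_mod
from .io import write_bed, write_coo, write_counts
from .simulate import (HISTONE_MARKS, SimulationParams, SimulatedDataset,
                       simulate)

log = logging.getLogger("tadscape")

ALL_STAGES = ("simulate", "methylation", "sites", "tads", "hic")


@dataclass
class RunConfig:
    """Thresholds, seed, stage toggles and simulation parameters."""

    seed: int = 0
    outdir: str = "tadscape_run"
    stages: tuple = ALL_STAGES
    p_threshold: float = 1e-6
    fdr: float = 0.05
    chip_p: float = 0.001
    delta: float = 25.0
    window: int = 20_000
    min_sites: int = 5
    draws: int = 1000
    tss_window: int = 2500
    bin_size: int = 100_000
    wt_quantile: float = 0.25
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("p_threshold", "fdr", "chip_p", "delta", "window",
                     "min_sites", "draws", "tss_window", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_params(self) -> SimulationParams:
        d = dict(self.sim)
        d.setdefault("seed", self.seed)
        d.setdefault("hic_bin_size", self.bin_size)
        return SimulationParams.from_dict(d)

    def hash(self) -> str:
        payload = asdict(self)
        payload["stages"] = list(payload["stages"])
        payload.pop("outdir")  # fingerprint the analysis, not the destination
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    tables: dict
    provenance: dict


def _write_simulation(ds: SimulatedDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    g = ds.genome
    write_bed(g.tads.assign(name=g.tads["tad_id"]), outdir / "tads.bed")
    write_bed(g.genes[["chrom", "start", "end", "name", "tss", "strand"]]
              .rename(columns={"tss": "score"}), outdir / "genes.bed")
    write_bed(g.states, outdir / "states.bed")
    meth_df = ds.methylation
    tidy = []
    for cond in ("wt", "tko"):
        for enzyme in ("hpaii", "mspi"):
            tidy.append(pd.DataFrame({
                "site_id": meth_df["site_id"], "chrom": meth_df["chrom"],
                "start": meth_df["start"], "end": meth_df["end"],
                "condition": cond, "replicate": enzyme,
                "count": meth_df[f"{enzyme}_{cond}"]}))
    write_counts(pd.concat(tidy, ignore_index=True), outdir / "methylation_counts.tsv")
    meth_df.to_csv(outdir / "methylation_table.tsv", sep="\t", index=False)
    for mark, tab in ds.signal.items():
        tab.to_csv(outdir / f"signal_{mark}.tsv", sep="\t", index=False)
    ds.de_genes.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
    for cond, mats in ds.hic.items():
        coo = []
        for chrom, m in mats.items():
            cm = hic_mod.ContactMatrix(chrom, ds.params.hic_bin_size, m)
            coo.append(hic_mod.matrix_to_coo(cm))
        if coo:
            write_coo(pd.concat(coo, ignore_index=True), outdir / f"hic_{cond}.coo")


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in dependency order."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {}
    params = config.sim_params()
    if "simulate" not in config.stages:
        raise ValueError("the pipeline currently requires the simulate stage "
                         "(user-supplied input mode is per-command via the CLI)")
    with_hic = "hic" in config.stages
    ds = simulate(params, with_hic=with_hic)
    _write_simulation(ds, outdir / "fixtures")
    log.info("stage=simulate n_sites=%d n_regions=%d elapsed=%.1fs",
             len(ds.methylation), len(ds.signal["dhs"]), time.time() - t0)

    genome = ds.genome
    gene_counts = tads_mod.assign_genes_to_tads(genome.genes, genome.tads)
    change_counts = {"genes": gene_counts}

    meth_table = None
    if "methylation" in config.stages:
        t = time.time()
        meth_table = meth.test_differential_methylation(
            ds.methylation, p_threshold=config.p_threshold)
        meth_table = meth.classify_stringent(meth_table, config.delta,
                                             config.p_threshold)
        tables["methylation"] = meth_table
        dmr = meth_table[meth_table["direction"] != "none"]
        cluster = meth.window_cluster_test(
            dmr, meth_table, window=config.window, min_sites=config.min_sites,
            draws=config.draws, seed=config.seed)
        tables["methylation_cluster"] = pd.DataFrame([{
            "window": cluster.window, "min_sites": cluster.min_sites,
            "observed": cluster.observed, "n_draws": cluster.n_draws,
            "p": cluster.p_value}])
        comp = meth.state_composition(dmr, genome.states, meth_table,
                                      seed=config.seed)
        tables["methylation_states"] = comp.reset_index(names="state")
        for direction in ("hypo", "hyper"):
            change_counts[f"meth_{direction}"] = tads_mod.assign_sites_to_tads(
                meth_table[meth_table["direction"] == direction], genome.tads)
        log.info("stage=methylation n_dmr=%d elapsed=%.1fs", len(dmr),
                 time.time() - t)

    labelled = {}
    if "sites" in config.stages:
        t = time.time()
        for mark, tab in ds.signal.items():
            tested = sites_mod.test_regions(tab)
            mode = "dhs" if mark == "dhs" else "chip"
            labelled[mark] = sites_mod.call_changes(
                tested, mode=mode, q_threshold=config.fdr,
                p_threshold=config.chip_p)
            tables[f"sites_{mark}"] = labelled[mark]
            for lab in ("gain", "loss"):
                change_counts[f"{mark}_{lab}"] = tads_mod.assign_sites_to_tads(
                    labelled[mark][labelled[mark]["label"] == lab], genome.tads)
        denovo = sites_mod.call_denovo_dhs(
            labelled["dhs"][labelled["dhs"]["label"] == "gain"],
            labelled["dhs"][labelled["dhs"]["wt_active"]],
            labelled["h3k4me1"], labelled["h3k4me1"][labelled["h3k4me1"]["wt_active"]],
            labelled["h3k4me3"], labelled["h3k4me3"][labelled["h3k4me3"]["wt_active"]],
            config.wt_quantile)
        tables["denovo_dhs"] = denovo
        conc = sites_mod.concordance(labelled["dhs"], labelled["h3k4me1"])
        if conc is not None:
            tables["concordance_dhs_k4me1"] = conc.table.reset_index()
        log.info("stage=sites n_denovo_dhs=%d elapsed=%.1fs", len(denovo),
                 time.time() - t)

    if "tads" in config.stages:
        t = time.time()
        features = {k: v for k, v in change_counts.items()}
        tables["tad_quintiles_by_genes"] = tads_mod.quintile_table(
            genome.tads, gene_counts.drop(index="unassigned"), features,
            reference="genes")
        de_counts = tads_mod.assign_genes_to_tads(ds.de_genes, genome.tads) \
            if len(ds.de_genes) else None
        if de_counts is not None:
            change_counts["de_genes"] = de_counts
        if meth_table is not None and "dhs" in labelled:
            for direction in ("up", "down"):
                genes_dir = ds.de_genes[ds.de_genes["direction"] == direction]
                res = tads_mod.tss_proximal_changes(
                    genes_dir, labelled["dhs"], window=config.tss_window)
                tables[f"tss_dhs_{direction}"] = pd.DataFrame([res.__dict__])
        log.info("stage=tads elapsed=%.1fs", time.time() - t)

    if "hic" in config.stages:
        t = time.time()
        balanced = {}
        for cond in ("wt", "tko"):
            balanced[cond] = {}
            for chrom, m in ds.hic[cond].items():
                cm = hic_mod.ContactMatrix(chrom, params.hic_bin_size, m)
                balanced[cond][chrom] = hic_mod.balance(cm)
        scores = {cond: hic_mod.domain_scores(balanced[cond], genome.tads, cond)
                  for cond in ("wt", "tko")}
        comparison = hic_mod.compare_domain_scores(scores["wt"], scores["tko"])
        tables["domain_scores"] = comparison.deltas
        tables["domain_score_test"] = pd.DataFrame([{
            "statistic": comparison.statistic, "p": comparison.p_value,
            "fraction_decreased": comparison.fraction_decreased}])
        quints = hic_mod.delta_score_quintiles(
            genome.tads, comparison.deltas,
            {k: v for k, v in change_counts.items()})
        for rank_name, tab in quints.items():
            tables[f"delta_quintiles_by_{rank_name}"] = tab
        decay = {cond: hic_mod.fit_decay_exponent(
            next(iter(balanced[cond].values()))) for cond in ("wt", "tko")}
        tables["decay_exponent"] = pd.DataFrame([decay])
        log.info("stage=hic wilcoxon_p=%.3g elapsed=%.1fs",
                 comparison.p_value, time.time() - t)

    log.info("pipeline done elapsed=%.1fs", time.time() - t0)
    provenance = {"config_hash": config.hash(), "seed": config.seed,
                  "version": __import__("tadscape").__version__}
    for name, tab in tables.items():
        tab.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                   float_format="%.10g")
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True))
    return ReportBundle(tables=tables, provenance=provenance)
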