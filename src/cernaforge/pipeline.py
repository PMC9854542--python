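"""End-to-end orchestration: simulate -> DE -> targets -> co-expression ->
ceRNA assembly -> interaction modules -> enrichment, under one config.

A run writes every stage artifact into one directory plus a JSON manifest
(seed, thresholds, per-stage row counts). Reruns with the same config and
seed reproduce byte-identical files: the single global seed is fanned out to
per-stage child seeds through numpy's SeedSequence spawning.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import cerna as ce
from . import coexpression as cx
from . import diffexpr as de
from . import enrichment as en
from . import io as cio
from . import netmodules as nm
from . import synthetic as syn
from . import targets as tp

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage thresholds and flags of one pipeline run."""

    seed: int = 42
    alpha: float = 0.05
    lfc: float = 2.0
    s_min: float = 150.0
    g_max: float = -30.0
    top_k: int = 100
    score_min: float = 5.0
    node_score_cutoff: float = 0.2
    positive_only: bool = True
    antagonistic: bool = False
    circular_scan: bool = True
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.lfc < 0:
            raise ValueError("lfc must be >= 0")
        if not (0.0 <= self.node_score_cutoff <= 1.0):
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.top_k < 0:
            raise ValueError("top_k must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        d = dict(d)
        sim = d.pop("sim", {})
        cfg = cls(**d)
        sim = dict(sim)
        sim.setdefault("seed", cfg.seed)
        cfg.sim = syn.SimConfig.from_dict(sim)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in dependency order; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "lfc": config.lfc,
            "s_min": config.s_min,
            "g_max": config.g_max,
            "top_k": config.top_k,
            "score_min": config.score_min,
            "node_score_cutoff": config.node_score_cutoff,
        },
        "stages": {},
    }

    def _stage(name: str):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        # --- simulate -------------------------------------------------
        rec = _stage("simulate")
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        bundle = syn.generate_bundle(sim_cfg)
        syn.write_bundle(bundle, outdir / "bundle")
        rec["n_features"] = {cls: len(bundle.counts[cls]) for cls in syn.RNA_CLASSES}

        # --- differential expression ---------------------------------
        rec = _stage("diffexpr")
        de_tables: dict[str, pd.DataFrame] = {}
        for cls in syn.RNA_CLASSES:
            table = de.nb_wald_test(
                bundle.counts[cls], bundle.samples, alpha=config.alpha, lfc=config.lfc
            )
            de_tables[cls] = table
            cio.write_counts(table, outdir / f"de_{cls}.tsv")
            rec[cls] = de.summarize_de(table)

        # --- target prediction ----------------------------------------
        rec = _stage("targets")
        mirna_seqs = bundle.sequences["miRNA"]
        hits: dict[str, pd.DataFrame] = {}
        for cls in ("mRNA", "lncRNA", "circRNA"):
            hits[cls] = tp.scan_transcriptome(
                mirna_seqs,
                bundle.sequences[cls],
                cls,
                s_min=config.s_min,
                g_max=config.g_max,
                circular=(cls == "circRNA" and config.circular_scan),
            )
            cio.write_table(hits[cls], outdir / f"targets_{cls}.tsv")
            rec[cls] = int(len(hits[cls]))

        # --- co-expression --------------------------------------------
        rec = _stage("coexpression")
        logn: dict[str, pd.DataFrame] = {
            cls: cx.log_transform(de.normalize_counts(bundle.counts[cls]))
            for cls in ("mRNA", "lncRNA", "circRNA")
        }
        sig = {
            cls: de_tables[cls].index[de_tables[cls]["significant"]]
            for cls in ("mRNA", "lncRNA", "circRNA")
        }
        coexpr: dict[str, pd.DataFrame] = {}
        for cls in ("lncRNA", "circRNA"):
            if config.alpha <= 0 or len(sig["mRNA"]) == 0 or len(sig[cls]) == 0:
                coexpr[cls] = pd.DataFrame(
                    columns=["feature_a", "feature_b", "r", "p_value", "n", "rank"]
                )
            else:
                coexpr[cls] = cx.screen_pairs(
                    logn["mRNA"].loc[sig["mRNA"]],
                    logn[cls].loc[sig[cls]],
                    alpha=config.alpha,
                    top_k=config.top_k,
                    positive_only=config.positive_only,
                )
            cio.write_table(coexpr[cls], outdir / f"coexpr_{cls}.tsv")
            rec[cls] = int(len(coexpr[cls]))

        # --- ceRNA assembly -------------------------------------------
        rec = _stage("cerna")
        triads: dict[str, list[ce.CeRNATriad]] = {}
        for cls in ("lncRNA", "circRNA"):
            triads[cls] = ce.build_sponge_network(
                coexpr[cls],
                hits["mRNA"],
                hits[cls],
                de_tables["mRNA"],
                de_tables[cls],
                de_tables["miRNA"],
                sponge_class=cls,
                antagonistic=config.antagonistic,
            )
            cio.write_table(ce.triads_table(triads[cls]), outdir / f"triads_{cls}.tsv")
            rec[cls] = len(triads[cls])
        network = ce.integrate_networks(triads["lncRNA"], triads["circRNA"])
        cio.write_table(ce.triads_table(network.triads), outdir / "cerna_triads.tsv")
        cio.write_sif(ce.network_to_sif(network), outdir / "cerna_network.sif")
        cio.write_table(ce.node_attributes_table(network), outdir / "cerna_nodes.tsv")
        summary = ce.network_summary(network)
        cio.write_json(summary, outdir / "cerna_summary.json")
        rec["integrated"] = summary["n_triads"]

        # --- interaction modules and hubs ------------------------------
        rec = _stage("netmodules")
        graph = nx.Graph(bundle.interactions)
        modules = nm.mcode_find_modules(
            graph, node_score_cutoff=config.node_score_cutoff, score_min=config.score_min
        )
        cio.write_table(nm.modules_table(modules), outdir / "modules.tsv")
        cio.write_table(nm.degree_ranking(graph, top=20), outdir / "hubs.tsv")
        rec["n_modules"] = len(modules)

        # --- enrichment ------------------------------------------------
        rec = _stage("enrichment")
        universe = list(bundle.counts["mRNA"].index)
        de_list = list(sig["mRNA"])
        result = en.enrich(de_list, bundle.gene_sets, universe)
        cio.write_table(result, outdir / "enrichment.tsv")
        rec["n_sets_tested"] = int(len(result))
    except Exception as exc:  # noqa: BLE001 - halt with stage name and cause
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    cio.write_json(manifest, outdir / "manifest.json")
    return manifest


def evaluate_run(outdir: str | Path) -> dict:
    """Planted-truth evaluation of a finished run: per-stage recall/precision."""
    outdir = Path(outdir)
    truth = syn.TruthLedger.from_json(outdir / "bundle" / "truth.json")
    report: dict = {}

    # DE recall per class
    for cls in syn.RNA_CLASSES:
        table = cio.read_counts(outdir / f"de_{cls}.tsv")
        called = set(table.index[table["significant"].astype(bool)])
        planted = set(truth.de_features.get(cls, {}))
        report[f"de_recall_{cls}"] = (
            len(called & planted) / len(planted) if planted else float("nan")
        )

    # target recall
    found = set()
    for cls in ("mRNA", "lncRNA", "circRNA"):
        t = cio.read_table(outdir / f"targets_{cls}.tsv")
        found |= {
            (str(r.mirna_id), str(r.transcript_id), str(r.transcript_class))
            for r in t.itertuples()
        }
    planted_targets = set(truth.true_targets)
    report["target_recall"] = (
        len(found & planted_targets) / len(planted_targets) if planted_targets else float("nan")
    )

    # triad recall/precision (per sponge class, pre-integration)
    recovered = set()
    for cls in ("lncRNA", "circRNA"):
        t = cio.read_table(outdir / f"triads_{cls}.tsv")
        recovered |= {
            (str(r.sponge_id), str(r.mirna_id), str(r.mrna_id)) for r in t.itertuples()
        }
    planted_triads = {
        (t["sponge_id"], t["mirna_id"], t["mrna_id"]) for t in truth.true_triads
    }
    report["triad_recall"] = (
        len(recovered & planted_triads) / len(planted_triads) if planted_triads else float("nan")
    )
    report["triad_precision"] = (
        len(recovered & planted_triads) / len(recovered) if recovered else float("nan")
    )

    # module recovery (best Jaccard per planted module)
    mods = cio.read_table(outdir / "modules.tsv")
    detected = [set(str(m).split(",")) for m in mods["members"]] if len(mods) else []
    jaccards = []
    for planted in truth.true_modules:
        p = set(planted)
        jaccards.append(
            max((len(p & d) / len(p | d) for d in detected), default=0.0)
        )
    report["module_jaccards"] = jaccards

    # enrichment: rank of the planted enriched set
    enr = cio.read_table(outdir / "enrichment.tsv")
    if truth.enriched_set is not None and len(enr):
        ranks = {s: i + 1 for i, s in enumerate(enr["set_id"])}
        report["enriched_set_rank"] = ranks.get(truth.enriched_set)
        row = enr[enr["set_id"] == truth.enriched_set]
        report["enriched_set_q"] = float(row["q_value"].iloc[0]) if len(row) else None
    return report
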