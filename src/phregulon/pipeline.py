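"""End-to-end orchestration: simulate -> differential expression ->
clustering -> target inference -> motif enrichment -> genomic scan ->
report.

The run is fully described by a config mapping (YAML/JSON-friendly) and a
seed; identical configs produce byte-identical summary JSON.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import clustering, diffexpr, genomic, motifs, paci, reporting, synthetic
from .io_formats import read_catalog, read_expression, read_genome

log = logging.getLogger("phregulon")

DEFAULT_CONFIG = {
    "simulate": True,
    "simulation": {},          # SimulationConfig overrides
    "expression": None,        # paths, used when simulate is false
    "design": None,
    "genome": None,
    "catalog": None,
    "thresholds": {},          # SelectionThresholds overrides
    "clustering": {"c": 50, "m": None, "n_restarts": 3},
    "motif": {"pattern": "GCCARG", "both_strands": True, "length": 1500},
    "seed": 0,
    "out": "phregulon_out",
    "write_heatmap": False,
}


def _merged_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in ("simulation", "thresholds", "clustering", "motif"):
        cfg[key] = {**DEFAULT_CONFIG[key], **(cfg.get(key) or {})}
    return cfg


def run_pipeline(config: dict) -> dict:
    """Execute every stage and write all outputs under ``config['out']``.

    Returns the run summary (also written as ``summary.json``): per-stage
    counts, the Venn partition of pH-responsive vs deletion-strain DE
    genes, motif-enrichment results for the candidate target sets, and the
    genomic region calls.
    """
    cfg = _merged_config(config)
    outdir = cfg["out"]
    os.makedirs(outdir, exist_ok=True)
    stage = "load"
    try:
        if cfg["simulate"]:
            stage = "simulate"
            sim_cfg = synthetic.SimulationConfig(
                **{"seed": cfg["seed"], **cfg["simulation"]}
            )
            bundle = synthetic.simulate_study(sim_cfg)
            synthetic.write_simulation(bundle, outdir)
            matrix, design = bundle["matrix"], bundle["design"]
            catalog, genome = bundle["catalog"], bundle["genome"]
            parent, deletion = sim_cfg.parent_name, sim_cfg.deletion_name
        else:
            for key in ("expression", "design", "genome", "catalog"):
                if not cfg.get(key):
                    raise ValueError(
                        f"config field {key!r} is required when simulate is disabled"
                    )
            matrix, design = read_expression(
                cfg["expression"], cfg["design"],
                linear_input=bool(cfg.get("linear_input", False)),
            )
            genome = read_genome(cfg["genome"])
            catalog = read_catalog(cfg["catalog"], genome=genome)
            parent = cfg.get("parent", "parent")
            deletion = cfg.get("deletion", "deletion")

        stage = "de"
        thresholds = diffexpr.SelectionThresholds(**cfg["thresholds"])
        de = diffexpr.run_ph_analysis(
            matrix, design, parent=parent, deletion=deletion, thresholds=thresholds
        )
        _write_de_table(de, os.path.join(outdir, "de.tsv"))

        stage = "cluster"
        profiles, n_dropped = clustering.standardize_profiles(matrix, design)
        ccfg = cfg["clustering"]
        c = min(int(ccfg["c"]), max(2, len(profiles) // 2))
        model = clustering.fuzzy_cmeans(
            profiles, c=c, m=ccfg["m"], seed=cfg["seed"],
            n_restarts=int(ccfg["n_restarts"]),
        )
        hard = clustering.assign_clusters(model)
        hard.rename_axis("gene_id").to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
        pd.DataFrame(
            model.centroids, columns=model.condition_labels
        ).to_csv(os.path.join(outdir, "centroids.tsv"), sep="\t", index=False)

        stage = "paci"
        regulon = paci.infer_paci_targets(
            de["decisions"]["6v3"],
            de["decisions"]["del_v_parent_ph6"],
            ph_category=de["ph_category"],
        )
        induced_set = regulon.index[regulon["paci_status"] == "induced"]
        # co-clustering annotation: does a gene sit in the modal cluster of
        # the induced candidates? (reported, never used for calling)
        if len(induced_set) and induced_set.isin(hard.index).any():
            modal = hard.loc[hard.index.intersection(induced_set), "cluster"].mode()
            modal = int(modal.iloc[0]) if len(modal) else -1
        else:
            modal = -1
        regulon["coclustering_flag"] = (
            hard["cluster"].reindex(regulon.index).eq(modal).fillna(False)
        )
        regulon.rename_axis("gene_id").to_csv(
            os.path.join(outdir, "regulon.tsv"), sep="\t"
        )

        stage = "motif"
        mcfg = cfg["motif"]
        spec = motifs.MotifSpec(mcfg["pattern"], bool(mcfg["both_strands"]))
        promoters = motifs.extract_promoters(catalog, genome, length=int(mcfg["length"]))
        presence = motifs.motif_presence_table(promoters, spec)
        presence.rename_axis("gene_id").to_csv(
            os.path.join(outdir, "motif.tsv"), sep="\t"
        )
        background = motifs.genome_background_rate(promoters, spec)
        enrichment = {}
        for set_name, genes in {
            "paci_induced": regulon.index[regulon["paci_status"] == "induced"],
            "paci_repressed": regulon.index[regulon["paci_status"] == "repressed"],
            "paci_all": regulon.index[regulon["paci_status"] != "none"],
        }.items():
            if len(genes) == 0:
                continue
            enrichment[set_name] = motifs.gene_set_enrichment(promoters, genes, spec)

        stage = "scan"
        ph_responsive = (de["ph_category"] != "flat").to_dict()
        labels = hard["cluster"].to_dict()
        calls = genomic.scan_coexpressed_regions(catalog, labels, ph_responsive)
        genomic.calls_to_frame(calls).to_csv(
            os.path.join(outdir, "regions.tsv"), sep="\t", index=False
        )
        bed = genomic.calls_to_bed(calls, catalog)
        bed.to_csv(os.path.join(outdir, "regions.bed"), sep="\t", index=False, header=False)

        stage = "report"
        responsive_set = set(de["ph_category"].index[de["ph_category"] != "flat"])
        deletion_set = set(
            de["decisions"]["del_v_parent_ph6"].index[
                de["decisions"]["del_v_parent_ph6"] != "not_de"
            ]
        )
        venn = paci.venn_partition(responsive_set, deletion_set)
        tally = reporting.tally_classes(regulon)
        tally.to_csv(os.path.join(outdir, "class_tally.tsv"), sep="\t", index=False)
        if cfg["write_heatmap"] and responsive_set:
            subset = sorted(responsive_set)
            hm, _ = reporting.heatmap_matrix(de["fits"], subset)
            hm.rename_axis("gene_id").to_csv(
                os.path.join(outdir, "heatmap.tsv"), sep="\t"
            )
            reporting.plot_heatmap(hm, os.path.join(outdir, "heatmap.png"))

        category_counts = de["ph_category"].value_counts().to_dict()
        summary = {
            "seed": cfg["seed"],
            "thresholds": asdict(thresholds),
            "n_genes": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "ph_category_counts": {
                k: int(category_counts.get(k, 0)) for k in diffexpr.PH_CATEGORIES
            },
            "n_ph_responsive": int(len(responsive_set)),
            "n_deletion_de": int(len(deletion_set)),
            "venn": venn,
            "n_paci_induced": int((regulon["paci_status"] == "induced").sum()),
            "n_paci_repressed": int((regulon["paci_status"] == "repressed").sum()),
            "motif_background_rate": round(background, 6),
            "motif_enrichment": {
                k: {
                    "set_size": v["set_size"],
                    "hits": v["hits"],
                    "background_rate": round(v["background_rate"], 6),
                    "p_value": round(v["p_value"], 8),
                }
                for k, v in enrichment.items()
            },
            "clustering": {
                "c": int(model.n_clusters),
                "m": round(model.fuzzifier, 6),
                "n_dropped_zero_variance": int(n_dropped),
            },
            "n_genomic_region_calls": len(calls),
        }
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_de_table(de: dict, path) -> None:
    rows = []
    for (name, tp), frame in sorted(de["fits"].items()):
        block = frame[["log2fc", "t_mod", "p", "q"]].copy()
        block.insert(0, "contrast", name)
        block.insert(1, "time_point", tp)
        block["decision"] = de["decisions"][name].reindex(frame.index)
        block["ph_category"] = de["ph_category"].reindex(frame.index)
        rows.append(block)
    pd.concat(rows).rename_axis("gene_id").to_csv(path, sep="\t")
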