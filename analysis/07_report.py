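#!/usr/bin/env python
"""Summarize the run: category counts, Venn partition, class tallies and
the clustered fold-change heatmap of the pH-responsive genes."""

import json
import sys

import pandas as pd

from phregulon.io_formats import read_expression
from phregulon.diffexpr import run_ph_analysis
from phregulon.paci import venn_partition
from phregulon.reporting import heatmap_matrix, plot_heatmap, tally_classes

OUTDIR = "results/analysis"


def main():
    matrix, design = read_expression(f"{OUTDIR}/expression.tsv", f"{OUTDIR}/design.tsv")
    de = run_ph_analysis(matrix, design)
    regulon = pd.read_csv(f"{OUTDIR}/regulon.tsv", sep="\t", index_col=0)

    tally = tally_classes(regulon)
    tally.to_csv(f"{OUTDIR}/class_tally.tsv", sep="\t", index=False)

    responsive = sorted(de["ph_category"].index[de["ph_category"] != "flat"])
    deletion_de = set(regulon.index[regulon["deletion_decision"] != "not_de"])
    summary = {
        "ph_category_counts": de["ph_category"].value_counts().to_dict(),
        "venn": venn_partition(set(responsive), deletion_de),
        "n_paci_induced": int((regulon["paci_status"] == "induced").sum()),
        "n_paci_repressed": int((regulon["paci_status"] == "repressed").sum()),
    }
    with open(f"{OUTDIR}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(json.dumps(summary, indent=2, sort_keys=True))

    hm, _ = heatmap_matrix(de["fits"], responsive)
    hm.rename_axis("gene_id").to_csv(f"{OUTDIR}/heatmap.tsv", sep="\t")
    plot_heatmap(hm, f"{OUTDIR}/heatmap.png")
    print(f"heatmap: {hm.shape[0]} pH-responsive genes x {hm.shape[1]} comparisons")
    return 0


if __name__ == "__main__":
    sys.exit(main())
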