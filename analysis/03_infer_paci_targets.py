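#!/usr/bin/env python
"""Call candidate direct regulator (PACI) targets.

Combines the parent-strain pH6-vs-3 decision with the deletion-vs-parent
decision at pH 6: induced targets are up at alkaline pH and drop in the
deletion strain; repressed targets the mirror image. Writes
results/analysis/regulon.tsv and scores the calls against the planted
truth.
"""

import sys

import pandas as pd

from phregulon.paci import infer_paci_targets, venn_partition

OUTDIR = "results/analysis"


def main():
    de = pd.read_csv(f"{OUTDIR}/de.tsv", sep="\t")
    tp1 = sorted(de["time_point"].unique())[0]
    sub = de[de["time_point"] == tp1]

    def dec(name):
        return sub[sub["contrast"] == name].set_index("gene_id")["decision"]

    cat = sub[sub["contrast"] == "6v3"].set_index("gene_id")["ph_category"]
    regulon = infer_paci_targets(dec("6v3"), dec("del_v_parent_ph6"), ph_category=cat)
    regulon.rename_axis("gene_id").to_csv(f"{OUTDIR}/regulon.tsv", sep="\t")

    n_ind = (regulon["paci_status"] == "induced").sum()
    n_rep = (regulon["paci_status"] == "repressed").sum()
    print(f"candidate targets: {n_ind} induced, {n_rep} repressed")

    responsive = set(cat.index[cat != "flat"])
    deletion_de = set(regulon.index[regulon["deletion_decision"] != "not_de"])
    print("Venn partition (pH-responsive vs deletion-strain DE):",
          venn_partition(responsive, deletion_de))

    truth = pd.read_csv(f"{OUTDIR}/truth.tsv", sep="\t", index_col=0)
    for status in ("induced", "repressed"):
        t = truth["paci_status"] == status
        c = regulon["paci_status"].reindex(truth.index) == status
        prec = (t & c).sum() / max(c.sum(), 1)
        rec = (t & c).sum() / max(t.sum(), 1)
        print(f"{status}: precision {prec:.3f}, recall {rec:.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
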