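"""Scan gene order for co-regulated genomic regions.

A window of 4 consecutive genes on a scaffold *fires* for cluster label L
when at least 3 of its genes carry L. Fired windows with equal label and
overlapping (or abutting) rank spans merge into one region call, whose
members are the L-labelled genes inside the merged span; regions without at
least one pH-responsive member are discarded. Windows are rank-based (gene
adjacency), not base-pair based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

WINDOW = 4
MIN_SHARED = 3

#: sentinel for genes without a usable cluster label; never matches itself
NO_LABEL = object()


@dataclass
class GenomicClusterCall:
    scaffold: str
    member_gene_ids: list
    span_ranks: tuple
    shared_cluster_label: object
    n_ph_responsive: int
    interrupting_genes: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.member_gene_ids) < MIN_SHARED:
            raise ValueError("a region call needs >= 3 member genes")


def scan_coexpressed_regions(
    catalog: pd.DataFrame,
    labels: dict,
    ph_responsive: dict,
) -> list[GenomicClusterCall]:
    """Find co-regulated genomic regions on every scaffold.

    ``labels`` maps gene_id -> hard cluster label (genes missing from the
    map get a sentinel that matches nothing); ``ph_responsive`` maps
    gene_id -> bool. Calls are sorted by (scaffold, first rank).
    """
    if "rank" not in catalog.columns or catalog["rank"].isna().any():
        raise ValueError("catalog genes must carry dense ranks")
    calls = []
    for scaffold, block in catalog.groupby("scaffold", sort=True):
        block = block.sort_values("rank")
        genes = block["gene_id"].tolist()
        labs = [labels.get(g, NO_LABEL) for g in genes]
        # fired windows: (start_index, label)
        fired = []
        for i in range(len(genes) - WINDOW + 1):
            window = labs[i : i + WINDOW]
            counts = {}
            for lab in window:
                if lab is NO_LABEL:
                    continue
                counts[lab] = counts.get(lab, 0) + 1
            for lab, cnt in counts.items():
                if cnt >= MIN_SHARED:
                    fired.append((i, lab))
        # merge overlapping/abutting windows with equal label
        merged = {}
        for i, lab in sorted(fired, key=lambda t: t[0]):
            spans = merged.setdefault(lab, [])
            if spans and i <= spans[-1][1] + 1:
                spans[-1] = (spans[-1][0], max(spans[-1][1], i + WINDOW - 1))
            else:
                spans.append((i, i + WINDOW - 1))
        for lab, spans in merged.items():
            for lo, hi in spans:
                hi = min(hi, len(genes) - 1)
                members = [genes[j] for j in range(lo, hi + 1) if labs[j] == lab]
                interrupting = [genes[j] for j in range(lo, hi + 1) if labs[j] != lab]
                n_resp = sum(bool(ph_responsive.get(g, False)) for g in members)
                if n_resp < 1:
                    continue
                first = int(block.iloc[lo]["rank"])
                last = int(block.iloc[hi]["rank"])
                calls.append(
                    GenomicClusterCall(
                        scaffold=scaffold,
                        member_gene_ids=members,
                        span_ranks=(first, last),
                        shared_cluster_label=lab,
                        n_ph_responsive=n_resp,
                        interrupting_genes=interrupting,
                    )
                )
    calls.sort(key=lambda c: (str(c.scaffold), c.span_ranks[0]))
    return calls


def calls_to_frame(calls: list[GenomicClusterCall]) -> pd.DataFrame:
    """Tabulate region calls for TSV output."""
    return pd.DataFrame(
        [
            {
                "scaffold": c.scaffold,
                "first_rank": c.span_ranks[0],
                "last_rank": c.span_ranks[1],
                "shared_cluster": c.shared_cluster_label,
                "n_members": len(c.member_gene_ids),
                "n_ph_responsive": c.n_ph_responsive,
                "member_gene_ids": ",".join(map(str, c.member_gene_ids)),
                "interrupting_genes": ",".join(map(str, c.interrupting_genes)),
            }
            for c in calls
        ]
    )


def calls_to_bed(calls: list[GenomicClusterCall], catalog: pd.DataFrame) -> pd.DataFrame:
    """Half-open 0-based BED intervals spanning each region call."""
    coords = catalog.set_index("gene_id")
    rows = []
    for c in calls:
        starts = coords.loc[c.member_gene_ids, "start"]
        ends = coords.loc[c.member_gene_ids, "end"]
        rows.append(
            {
                "chrom": c.scaffold,
                "chromStart": int(starts.min()) - 1,
                "chromEnd": int(ends.max()),
                "name": str(c.shared_cluster_label),
                "score": c.n_ph_responsive,
                "strand": ".",
            }
        )
    return pd.DataFrame(rows)
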