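"""Functional-class tallies and the fold-change heatmap matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def tally_classes(regulon: pd.DataFrame, annotations: pd.Series | None = None) -> pd.DataFrame:
    """Count regulon categories per functional class.

    ``regulon`` carries per-gene ``ph_category``, ``deletion_decision`` and
    ``paci_status`` (as from the target-inference step); ``annotations``
    maps gene_id -> class label (KOG class or CAZy family). Unannotated
    genes fall into ``unclassified``. Percentages are kept at full
    precision; display rounding is the caller's concern.
    """
    if annotations is None:
        annotations = pd.Series("unclassified", index=regulon.index)
    cls = annotations.reindex(regulon.index).fillna("unclassified")
    out = []
    for label, idx in regulon.groupby(cls).groups.items():
        sub = regulon.loc[idx]
        responsive = (sub["ph_category"] != "flat").sum()
        paci = (sub["paci_status"] != "none").sum()
        out.append(
            {
                "class_label": label,
                "n_genes": len(sub),
                "n_high_up": int((sub["ph_category"] == "high_up").sum()),
                "n_low_up": int((sub["ph_category"] == "low_up").sum()),
                "n_peak": int((sub["ph_category"] == "peak").sum()),
                "n_dip": int((sub["ph_category"] == "dip").sum()),
                "n_deletion_up": int((sub["deletion_decision"] == "up_in_a").sum()),
                "n_deletion_down": int((sub["deletion_decision"] == "up_in_b").sum()),
                "n_paci_candidates": int(paci),
                "pct_paci_of_responsive": (
                    100.0 * paci / responsive if responsive else 0.0
                ),
            }
        )
    return (
        pd.DataFrame(out)
        .sort_values("class_label", kind="mergesort")
        .reset_index(drop=True)
    )


def heatmap_matrix(
    fits: dict, gene_subset, time_points=None
) -> tuple[pd.DataFrame, list]:
    """Genes x comparisons log2 fold-change matrix with a clustered row order.

    ``fits`` maps ``(contrast_name, time_point)`` -> fitted frame; one
    column per key, values taken bit-for-bit from the fitted log2fc. Rows
    are ordered by average-linkage hierarchical clustering on
    1 - Pearson correlation distance (genes with zero variance across
    comparisons keep their input position at the end).

    Returns ``(matrix_in_clustered_order, row_order)``.
    """
    gene_subset = list(gene_subset)
    cols = {}
    for (name, tp), frame in sorted(fits.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if time_points is not None and tp not in time_points:
            continue
        cols[f"{name}@{tp}"] = frame["log2fc"].reindex(gene_subset)
    mat = pd.DataFrame(cols, index=gene_subset)
    if len(gene_subset) < 2:
        return mat, gene_subset
    values = mat.to_numpy(dtype=float)
    sd = values.std(axis=1)
    ok = sd > 0
    order_ok = np.where(ok)[0]
    if ok.sum() >= 2:
        corr = np.corrcoef(values[ok])
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        leaf_order = hierarchy.leaves_list(link)
        order_ok = order_ok[leaf_order]
    order = list(order_ok) + list(np.where(~ok)[0])
    ordered = mat.iloc[order]
    return ordered, ordered.index.tolist()


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Write the heatmap image with a symmetric color scale about 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.nanmax(np.abs(matrix.to_numpy()))) or 1.0
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * matrix.shape[1], max(2.0, 0.08 * matrix.shape[0]))
    )
    im = ax.imshow(
        matrix.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax
    )
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} genes")
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
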