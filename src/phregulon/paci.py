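"""Inference of candidate direct PacC/PAC1 targets.

The regulator is proteolytically activated at alkaline ambient pH, where it
induces alkaline-expressed genes and represses acid-expressed genes;
deleting it mimics acidic conditions. Candidate direct targets are
therefore called from two decisions made under identical thresholds:

* **induced** — up at pH 6 vs pH 3 in the parent strain AND down in the
  deletion strain vs the parent at pH 6;
* **repressed** — up at pH 3 vs pH 6 in the parent strain AND up in the
  deletion strain vs the parent at pH 6;
* **none** otherwise.
"""

from __future__ import annotations

import pandas as pd

PACI_STATUSES = ("induced", "repressed", "none")


def infer_paci_targets(
    ph6v3_decision: pd.Series,
    deletion_decision: pd.Series,
    ph_category: pd.Series | None = None,
    dec_6v45: pd.Series | None = None,
    *,
    accept_any_high_low_pair: bool = False,
) -> pd.DataFrame:
    """Call candidate regulator targets per gene.

    ``ph6v3_decision`` is oriented pH6-vs-pH3 in the parent strain
    (``up_in_a`` = up at pH 6); ``deletion_decision`` is oriented
    deletion-vs-parent at pH 6 (``up_in_a`` = up in the deletion strain).
    With ``accept_any_high_low_pair`` the pH criterion also accepts the
    6-vs-4.5 comparison (``dec_6v45`` required).

    Returns a frame with columns ``deletion_decision`` and ``paci_status``;
    ``ph_category`` is carried through when given.
    """
    if not ph6v3_decision.index.equals(deletion_decision.index):
        raise ValueError("gene universes differ between pH and deletion decisions")
    up_high = ph6v3_decision == "up_in_a"
    up_low = ph6v3_decision == "up_in_b"
    if accept_any_high_low_pair:
        if dec_6v45 is None:
            raise ValueError("accept_any_high_low_pair requires the 6v4.5 decision")
        up_high |= dec_6v45 == "up_in_a"
        up_low |= dec_6v45 == "up_in_b"
    down_in_del = deletion_decision == "up_in_b"
    up_in_del = deletion_decision == "up_in_a"

    induced = up_high & down_in_del
    repressed = up_low & up_in_del
    status = pd.Series("none", index=ph6v3_decision.index, name="paci_status")
    status[induced] = "induced"
    status[repressed] = "repressed"
    out = pd.DataFrame(
        {"deletion_decision": deletion_decision, "paci_status": status}
    )
    if ph_category is not None:
        out.insert(0, "ph_category", ph_category)
    return out


def venn_partition(ph_responsive: set, deletion_de: set) -> dict:
    """Partition counts of the pH-responsive and deletion-strain DE sets."""
    ph_responsive = set(ph_responsive)
    deletion_de = set(deletion_de)
    both = ph_responsive & deletion_de
    return {
        "ph_only": len(ph_responsive - both),
        "deletion_only": len(deletion_de - both),
        "both": len(both),
    }
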