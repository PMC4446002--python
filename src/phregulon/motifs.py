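"""Strand-aware promoter extraction, IUPAC motif scanning and enrichment.

The motif of interest is the regulator's core binding site GCCARG (R = A
or G, i.e. the 6-mers GCCAAG and GCCAGG). Promoters are the up-to-1500
bases immediately upstream of the annotated gene start, taken in the
gene's coding-strand orientation; windows truncated by a scaffold edge
keep their effective length. Enrichment of motif *presence* in a gene set
against the genome-wide presence rate is tested with a one-sided exact
binomial upper tail (hypergeometric alternative available).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifSpec:
    pattern: str = "GCCARG"
    scan_both_strands: bool = True

    def __post_init__(self):
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("empty motif pattern")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in motif: {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)

    def regex(self) -> re.Pattern:
        # character classes over concrete bases: N in the sequence never matches
        body = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.pattern
        )
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches

    def reverse_complement(self) -> "MotifSpec":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}
        rc = "".join(comp[c] for c in reversed(self.pattern))
        return MotifSpec(rc, self.scan_both_strands)


def scan_motif(sequence: str, motif: MotifSpec = MotifSpec()) -> int:
    """Count all (possibly overlapping) motif matches in a sequence.

    Forward-strand matches plus, when ``scan_both_strands``, matches of the
    motif's reverse complement on the same string (equivalent to scanning
    the complementary strand). ``N`` never matches.
    """
    seq = sequence.upper()
    hits = len(motif.regex().findall(seq))
    if motif.scan_both_strands:
        hits += len(motif.reverse_complement().regex().findall(seq))
    return hits


def has_motif(sequence: str, motif: MotifSpec = MotifSpec()) -> bool:
    return scan_motif(sequence, motif) >= 1


def extract_promoters(
    catalog: pd.DataFrame, genome: dict, length: int = 1500
) -> pd.DataFrame:
    """Extract up-to-``length``-bp upstream windows in coding orientation.

    For a + strand gene starting at 1-based position ``s`` the promoter is
    bases ``[max(1, s-length), s-1]``; for a - strand gene ending at ``e``
    it is the reverse complement of ``[e+1, min(L, e+length)]``. Windows
    truncated at scaffold edges keep their effective length; a gene flush
    against the edge gets an empty promoter (not an error).

    Returns a frame indexed by gene id with columns ``sequence`` and
    ``effective_length``.
    """
    rows = {}
    for _, g in catalog.iterrows():
        seq = genome.get(g["scaffold"])
        if seq is None:
            raise ValueError(f"scaffold {g['scaffold']} absent from genome")
        L = len(seq)
        if g["strand"] == "+":
            lo = max(1, g["start"] - length)
            hi = g["start"] - 1
            promoter = seq[lo - 1 : hi] if hi >= lo else ""
        else:
            lo = g["end"] + 1
            hi = min(L, g["end"] + length)
            promoter = (
                str(Seq(seq[lo - 1 : hi]).reverse_complement()) if hi >= lo else ""
            )
        rows[g["gene_id"]] = {
            "sequence": promoter.upper(),
            "effective_length": len(promoter),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def genome_background_rate(
    promoters: pd.DataFrame, motif: MotifSpec = MotifSpec()
) -> float:
    """Fraction of genes (with non-empty promoters) whose promoter contains
    the motif."""
    nonempty = promoters[promoters["effective_length"] > 0]
    if nonempty.empty:
        raise ValueError("all promoters are empty")
    present = nonempty["sequence"].map(lambda s: has_motif(s, motif))
    return float(present.mean())


def enrichment_test(
    k: int,
    n: int,
    p0: float | None = None,
    method: str = "binomial",
    population: tuple[int, int] | None = None,
) -> dict:
    """One-sided enrichment test of motif presence in a gene set.

    ``binomial``: exact upper tail P(X >= k), X ~ Binomial(n, p0), against
    the genome presence rate ``p0``. ``hypergeometric``: ``population`` is
    ``(population_size, population_hits)`` and the tail is over draws of
    ``n`` genes without replacement.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if method == "binomial":
        if p0 is None or not (0 < p0 < 1):
            raise ValueError("binomial test needs background rate p0 in (0, 1)")
        p_value = float(stats.binom.sf(k - 1, n, p0))
    elif method == "hypergeometric":
        if population is None:
            raise ValueError("hypergeometric test needs (population_size, population_hits)")
        N, K = population
        p_value = float(stats.hypergeom.sf(k - 1, N, K, n))
        p0 = K / N
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "set_size": n,
        "hits": k,
        "background_rate": float(p0),
        "p_value": min(p_value, 1.0),
        "method": method,
    }


def motif_presence_table(
    promoters: pd.DataFrame, motif: MotifSpec = MotifSpec()
) -> pd.DataFrame:
    """Per-gene hit counts and presence calls over a promoter set."""
    hits = promoters["sequence"].map(lambda s: scan_motif(s, motif))
    return pd.DataFrame(
        {
            "promoter_length": promoters["effective_length"],
            "hits": hits,
            "presence": hits >= 1,
        }
    )


def gene_set_enrichment(
    promoters: pd.DataFrame,
    gene_set,
    motif: MotifSpec = MotifSpec(),
    method: str = "binomial",
) -> dict:
    """Test motif-presence enrichment of ``gene_set`` against all promoters."""
    table = motif_presence_table(promoters, motif)
    gene_set = [g for g in gene_set if g in table.index]
    in_set = table.loc[gene_set]
    in_set = in_set[in_set["promoter_length"] > 0]
    k = int(in_set["presence"].sum())
    n = int(len(in_set))
    nonempty = table[table["promoter_length"] > 0]
    if method == "hypergeometric":
        return enrichment_test(
            k, n, method=method,
            population=(len(nonempty), int(nonempty["presence"].sum())),
        )
    p0 = float(nonempty["presence"].mean())
    return enrichment_test(k, n, p0=p0, method=method)
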