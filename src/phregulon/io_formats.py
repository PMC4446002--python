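"""Readers/writers for the standard formats the pipeline touches.

Internal conventions
--------------------
* Coordinates are 1-based inclusive (GFF3-native). BED input is converted at
  the boundary and back on output.
* Expression values are log2-scale throughout; a ``linear_input`` flag on
  :func:`read_expression` converts linear signals on the way in.
* A gene catalog is a :class:`pandas.DataFrame` with columns
  ``gene_id, scaffold, start, end, strand, rank`` (plus optional annotation
  columns); ``rank`` is the dense 1-based ordinal of the gene on its
  scaffold, ordered by ``start``.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ["sample_id", "strain", "ph", "time_point", "replicate"]
CATALOG_COLUMNS = ["gene_id", "scaffold", "start", "end", "strand", "rank"]


def _open_text(path, mode: str = "rt"):
    """Open a path, transparently handling gzip."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample design table.

    Requires the canonical columns and unique sample ids. Returns the frame
    with ``ph`` coerced to float and ``replicate`` to int.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in design: {dups}")
    out = design.copy()
    out["ph"] = out["ph"].astype(float)
    out["replicate"] = out["replicate"].astype(int)
    return out.reset_index(drop=True)


def read_design(path) -> pd.DataFrame:
    with _open_text(path) as fh:
        design = pd.read_csv(fh, sep="\t")
    return validate_design(design)


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design)[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression(path, design_path, *, linear_input: bool = False):
    """Read an expression TSV and its design table.

    The matrix TSV has ``gene_id`` as its first column and one column per
    sample. Columns are reordered to design order. With ``linear_input`` the
    values are log2-transformed on read.

    Returns ``(matrix, design)`` where ``matrix`` is a genes x samples
    :class:`pandas.DataFrame` indexed by gene id.
    """
    design = read_design(design_path)
    with _open_text(path) as fh:
        matrix = pd.read_csv(fh, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dups}")
    wanted = design["sample_id"].tolist()
    absent = [s for s in wanted if s not in matrix.columns]
    if absent:
        raise ValueError(
            f"samples present in design but absent from expression matrix: {absent}"
        )
    extra = [s for s in matrix.columns if s not in set(wanted)]
    if extra:
        raise ValueError(
            f"samples present in expression matrix but absent from design: {extra}"
        )
    matrix = matrix.loc[:, wanted]
    values = matrix.to_numpy(dtype=float)
    if linear_input:
        if (values <= 0).any():
            raise ValueError("linear_input requires strictly positive signals")
        matrix = pd.DataFrame(
            np.log2(values), index=matrix.index, columns=matrix.columns
        )
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    matrix.index.name = "gene_id"
    return matrix, design


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------

def _assign_ranks(catalog: pd.DataFrame) -> pd.DataFrame:
    catalog = catalog.sort_values(["scaffold", "start"], kind="mergesort")
    catalog["rank"] = catalog.groupby("scaffold", sort=False).cumcount() + 1
    return catalog.reset_index(drop=True)


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("gene_id", "scaffold", "start", "end", "strand") if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    if catalog["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in catalog")
    bad_strand = set(catalog["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValueError(f"unknown strand characters: {sorted(bad_strand)}")
    if (catalog["start"] > catalog["end"]).any():
        bad = catalog.loc[catalog["start"] > catalog["end"], "gene_id"].tolist()
        raise ValueError(f"start > end for genes: {bad}")
    if (catalog["start"] < 1).any():
        raise ValueError("coordinates must be 1-based positive")
    return _assign_ranks(catalog.copy())


def read_catalog(path, fasta_path=None, *, genome: dict | None = None) -> pd.DataFrame:
    """Read a gene catalog from GFF3 or BED6.

    BED half-open 0-based intervals are converted to the internal 1-based
    inclusive convention. When a genome (FASTA path or id->sequence dict) is
    supplied, coordinates are checked against scaffold lengths.
    """
    path = os.fspath(path)
    if path.endswith((".bed", ".bed.gz")):
        catalog = _read_bed(path)
    else:
        catalog = _read_gff3(path)
    catalog = validate_catalog(catalog)
    lengths = None
    if genome is not None:
        lengths = {name: len(seq) for name, seq in genome.items()}
    elif fasta_path is not None:
        lengths = {rec.id: len(rec.seq) for rec in _iter_fasta(fasta_path)}
    if lengths is not None:
        for _, row in catalog.iterrows():
            if row["scaffold"] not in lengths:
                raise ValueError(f"gene {row['gene_id']}: unknown scaffold {row['scaffold']}")
            if row["end"] > lengths[row["scaffold"]]:
                raise ValueError(
                    f"gene {row['gene_id']} extends beyond scaffold "
                    f"{row['scaffold']} (len {lengths[row['scaffold']]})"
                )
    return catalog


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED6 line with {len(parts)} fields: {line!r}")
            scaffold, start0, end0, name, _score, strand = parts[:6]
            rows.append(
                {
                    "gene_id": name,
                    "scaffold": scaffold,
                    "start": int(start0) + 1,  # half-open 0-based -> 1-based inclusive
                    "end": int(end0),
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows)


def _read_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "scaffold": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    return pd.DataFrame(rows)


def write_gff3(catalog: pd.DataFrame, path) -> None:
    catalog = validate_catalog(catalog)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in catalog.iterrows():
            fh.write(
                f"{row['scaffold']}\tphregulon\tgene\t{row['start']}\t{row['end']}"
                f"\t.\t{row['strand']}\t.\tID={row['gene_id']}\n"
            )


def write_bed(catalog: pd.DataFrame, path) -> None:
    catalog = validate_catalog(catalog)
    with open(path, "w") as fh:
        for _, row in catalog.iterrows():
            fh.write(
                f"{row['scaffold']}\t{row['start'] - 1}\t{row['end']}"
                f"\t{row['gene_id']}\t.\t{row['strand']}\n"
            )


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

def _iter_fasta(path):
    from Bio import SeqIO

    with _open_text(path) as fh:
        yield from SeqIO.parse(fh, "fasta")


def read_genome(path) -> dict:
    """Read a FASTA into an ordered ``{scaffold: sequence}`` dict (uppercase)."""
    genome = {}
    for rec in _iter_fasta(path):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no sequences in {path}")
    return genome


def write_genome(genome: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
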