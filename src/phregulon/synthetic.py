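"""Synthetic study generator with full ground truth.

Emulates the design of the ambient-pH transcriptome study: a compact
genome with ordered gene models, a parent strain profiled at three ambient
pH levels (3, 4.5, 6) and a regulator-deletion strain at pH 6, two time
points, three biological replicates per condition, on a log2 expression
scale. Planted features — pH-responsive genes of each category, regulator
(PACI) induced/repressed targets, promoter motif instances, and runs of
consecutive co-expressed genes — are recorded in a truth table so every
downstream stage can be scored against known answers.

Defaults mirror the study scale: ~10,000 genes, ~9.4% pH-responsive
(within which 38 induced and 30 repressed regulator targets per 10,000),
an up/down split of roughly 35/63 with a small non-monotonic remainder,
1 log2-unit effect steps, and 0.25 log2-unit replicate noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import validate_catalog, validate_design
from .motifs import IUPAC

PH_CATEGORY_ORDER = ("high_up", "low_up", "peak", "dip", "flat")

#: split of the generically pH-responsive genes (after removing regulator
#: targets) into categories, approximating the study's observed proportions
GENERIC_CATEGORY_PROPS = {"high_up": 0.35, "low_up": 0.625, "peak": 0.015, "dip": 0.01}


@dataclass
class SimulationConfig:
    """Study-design constants and generator knobs.

    Fractions are of ``n_genes``; effects and noise are log2 units. The
    regulator-target fractions must fit inside the pH-responsive fraction
    (targets are pH-responsive by definition).
    """

    n_genes: int = 10_000
    n_scaffolds: int = 20
    intergenic_len: int = 1500
    gene_len: int = 1500
    promoter_motif: str = "GCCARG"
    background_gc: float = 0.5
    frac_ph_responsive: float = 0.094
    frac_paci_induced: float = 0.0038
    frac_paci_repressed: float = 0.0030
    effect_log2fc: float = 1.0
    noise_sd: float = 0.25
    n_replicates: int = 3
    time_points: tuple = ("t1", "t2")
    ph_levels: tuple = (3.0, 4.5, 6.0)
    motif_prob_target: float = 0.9
    motif_prob_background: float = 0.0
    n_planted_genomic_clusters: int = 8
    planted_cluster_size: int = 6
    seed: int = 0
    # optional realism knobs
    gene_specific_variance: bool = False
    variance_prior_df: float = 10.0
    time_attenuation: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    parent_name: str = "parent"
    deletion_name: str = "deletion"

    def __post_init__(self):
        for name in ("n_genes", "n_scaffolds", "gene_len", "n_replicates",
                     "planted_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.intergenic_len < 0:
            raise ValueError("intergenic_len must be >= 0")
        if self.n_planted_genomic_clusters < 0:
            raise ValueError("n_planted_genomic_clusters must be >= 0")
        for name in ("background_gc", "frac_ph_responsive", "frac_paci_induced",
                     "frac_paci_repressed", "motif_prob_target",
                     "motif_prob_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_paci_induced + self.frac_paci_repressed > self.frac_ph_responsive:
            raise ValueError(
                "regulator-target fractions exceed the pH-responsive fraction"
            )
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.ph_levels) != 3:
            raise ValueError("exactly three pH levels expected")
        if len(self.time_points) != 2:
            raise ValueError("exactly two time points expected")
        bad = set(self.promoter_motif.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in motif: {sorted(bad)}")
        self.promoter_motif = self.promoter_motif.upper()
        self.time_points = tuple(str(t) for t in self.time_points)
        self.ph_levels = tuple(sorted(float(p) for p in self.ph_levels))


def largest_remainder(fractions, total: int) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``fractions``.

    Floors the quotas, then hands the remaining units to the largest
    fractional parts (ties to the earlier entry). Exactly conserves the
    total when fractions sum to 1.
    """
    fractions = np.asarray(list(fractions), dtype=float)
    quotas = fractions * total
    counts = np.floor(quotas).astype(int)
    short = int(round(quotas.sum())) - int(counts.sum())
    if short > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        for i in order[:short]:
            counts[i] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# Planted co-expression templates
# ---------------------------------------------------------------------------
# Each planted genomic cluster shares one non-flat profile template:
# (category, parent-strain effect multiples of effect_log2fc at (pH low,
#  mid, high), time-point-2 scale). Shapes are chosen to be pairwise
# distinct after per-gene standardization so the soft clustering can give
# each planted run its own label.
CLUSTER_TEMPLATES = [
    ("high_up", (0.0, 0.0, 2.0), 1.0),
    ("low_up", (2.0, 0.0, 0.0), 1.0),
    ("high_up", (0.0, 2.0, 2.0), 1.0),
    ("low_up", (2.0, 2.0, 0.0), 1.0),
    ("peak", (0.0, 2.0, 1.0), 1.0),
    ("dip", (2.0, 0.0, 1.0), 1.0),
    ("high_up", (0.0, 1.0, 2.0), 0.6),
    ("low_up", (2.0, 1.0, 0.0), 0.6),
]


def _template_for(cluster_index: int):
    return CLUSTER_TEMPLATES[cluster_index % len(CLUSTER_TEMPLATES)]


# ---------------------------------------------------------------------------
# Genome + truth
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig):
    """Build the toy genome, gene catalog and truth table.

    Returns ``(genome, catalog, truth)`` where ``genome`` is an ordered
    ``{scaffold: sequence}`` dict, ``catalog`` a validated gene table and
    ``truth`` a frame indexed by gene id with columns ``ph_category,
    paci_status, has_planted_motif, planted_genomic_cluster_id``.
    Deterministic under ``config.seed``.
    """
    window = min(1500, config.intergenic_len)
    if len(config.promoter_motif) > window:
        raise ValueError(
            f"motif ({len(config.promoter_motif)} bp) longer than the "
            f"promoter window ({window} bp)"
        )
    rng = np.random.default_rng([config.seed, 0])
    catalog = _layout_genes(config, rng)
    truth = _assign_truth(config, catalog, rng)
    genome = _synthesize_sequences(config, catalog, truth, rng)
    return genome, catalog, truth


def _layout_genes(config: SimulationConfig, rng) -> pd.DataFrame:
    per_scaffold = largest_remainder(
        [1.0 / config.n_scaffolds] * config.n_scaffolds, config.n_genes
    )
    rows = []
    gid = 0
    for s, count in enumerate(per_scaffold, start=1):
        pos = config.intergenic_len + 1
        for _ in range(count):
            gid += 1
            rows.append(
                {
                    "gene_id": f"g{gid:05d}",
                    "scaffold": f"scaffold_{s}",
                    "start": pos,
                    "end": pos + config.gene_len - 1,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            pos += config.gene_len + config.intergenic_len
    return validate_catalog(pd.DataFrame(rows))


def _assign_truth(config: SimulationConfig, catalog: pd.DataFrame, rng) -> pd.DataFrame:
    n = config.n_genes
    frac_other = (
        config.frac_ph_responsive
        - config.frac_paci_induced
        - config.frac_paci_repressed
    )
    n_ind, n_rep, n_other, n_flat = largest_remainder(
        [
            config.frac_paci_induced,
            config.frac_paci_repressed,
            frac_other,
            1.0 - config.frac_ph_responsive,
        ],
        n,
    )
    other_counts = dict(
        zip(
            GENERIC_CATEGORY_PROPS,
            largest_remainder(GENERIC_CATEGORY_PROPS.values(), n_other),
        )
    )

    gene_ids = catalog["gene_id"].tolist()
    truth = pd.DataFrame(
        {
            "ph_category": "flat",
            "paci_status": "none",
            "has_planted_motif": False,
            "planted_genomic_cluster_id": pd.array([pd.NA] * n, dtype="string"),
            "planted_template": pd.array([pd.NA] * n, dtype="Int64"),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # 1) planted genomic clusters: non-overlapping runs of consecutive genes,
    #    each consuming quota from its template's category
    cluster_members: dict[str, list] = {}
    by_scaffold = {
        s: block.sort_values("rank")["gene_id"].tolist()
        for s, block in catalog.groupby("scaffold")
    }
    scaffolds = sorted(by_scaffold)
    taken = set()
    size = config.planted_cluster_size
    for j in range(config.n_planted_genomic_clusters):
        # prefer template j; fall back to the next template whose category
        # still has quota (small simulations lack peak/dip budget)
        for probe in range(len(CLUSTER_TEMPLATES)):
            cat, _, _ = _template_for(j + probe)
            if other_counts.get(cat, 0) >= size:
                template_index = (j + probe) % len(CLUSTER_TEMPLATES)
                break
        else:
            raise ValueError(
                f"no pH-responsive category has quota for a planted cluster "
                f"of size {size}"
            )
        placed = False
        for _ in range(1000):
            scaf = scaffolds[int(rng.integers(len(scaffolds)))]
            genes = by_scaffold[scaf]
            if len(genes) < size:
                continue
            start = int(rng.integers(len(genes) - size + 1))
            run = genes[start : start + size]
            if any(g in taken for g in run):
                continue
            cid = f"pc{j + 1}"
            cluster_members[cid] = run
            for g in run:
                truth.loc[g, "ph_category"] = cat
                truth.loc[g, "planted_genomic_cluster_id"] = cid
                truth.loc[g, "planted_template"] = template_index
            taken.update(run)
            other_counts[cat] -= size
            placed = True
            break
        if not placed:
            raise ValueError("could not place planted genomic clusters without overlap")

    # 2) remaining quotas scattered over the untaken genes
    free = [g for g in gene_ids if g not in taken]
    free = list(rng.permutation(free))
    cursor = 0

    def _take(count):
        nonlocal cursor
        chunk = free[cursor : cursor + count]
        cursor += count
        return chunk

    for g in _take(n_ind):
        truth.loc[g, "ph_category"] = "high_up"
        truth.loc[g, "paci_status"] = "induced"
    for g in _take(n_rep):
        truth.loc[g, "ph_category"] = "low_up"
        truth.loc[g, "paci_status"] = "repressed"
    for cat, count in other_counts.items():
        for g in _take(count):
            truth.loc[g, "ph_category"] = cat

    # 3) promoter-motif plants
    is_target = truth["paci_status"] != "none"
    prob = np.where(is_target, config.motif_prob_target, config.motif_prob_background)
    truth["has_planted_motif"] = rng.random(n) < prob
    return truth


def _concrete_motif(pattern: str, rng) -> str:
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in pattern)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _synthesize_sequences(config, catalog, truth, rng) -> dict:
    gc = config.background_gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {}
    lengths = catalog.groupby("scaffold")["end"].max() + config.intergenic_len
    for scaf in sorted(lengths.index):
        L = int(lengths[scaf])
        seq = rng.choice(bases, size=L, p=base_p)
        genome[scaf] = seq
    # plant one motif instance per flagged gene, on the coding strand,
    # at a random offset inside the upstream window
    window = min(1500, config.intergenic_len)
    mlen = len(config.promoter_motif)
    for _, g in catalog.iterrows():
        if not truth.loc[g["gene_id"], "has_planted_motif"]:
            continue
        seq = genome[g["scaffold"]]
        instance = _concrete_motif(config.promoter_motif, rng)
        if g["strand"] == "+":
            lo = max(1, g["start"] - window)
            hi = g["start"] - 1
        else:
            lo = g["end"] + 1
            hi = min(len(seq), g["end"] + window)
            instance = instance.translate(_COMPLEMENT)[::-1]
        if hi - lo + 1 < mlen:
            raise ValueError(f"promoter window of {g['gene_id']} shorter than motif")
        offset = int(rng.integers(lo, hi - mlen + 2))  # 1-based start of instance
        seq[offset - 1 : offset - 1 + mlen] = np.frombuffer(
            instance.encode(), dtype="S1"
        )
    return {s: arr.tobytes().decode() for s, arr in genome.items()}


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Replicated design: parent at every pH, deletion strain at the highest
    pH only, both time points."""
    rows = []
    cells = [(config.parent_name, ph) for ph in config.ph_levels]
    cells.append((config.deletion_name, config.ph_levels[-1]))
    for strain, ph in cells:
        for tp in config.time_points:
            for r in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_pH{ph:g}_{tp}_r{r}",
                        "strain": strain,
                        "ph": ph,
                        "time_point": tp,
                        "replicate": r,
                    }
                )
    return validate_design(pd.DataFrame(rows))


def expected_offsets(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected log2 offsets from baseline, genes x design cells.

    Columns are labelled ``strain:pH:time`` as in the fitted design. The
    planted effect structure: ``high_up`` gains one effect step per pH
    level upward, ``low_up`` the negative; ``peak``/``dip`` move only at
    the middle pH; regulator targets additionally lose (induced) or gain
    (repressed) one effect in the deletion strain; planted-run genes follow
    their shared template instead.
    """
    e = config.effect_log2fc
    levels = list(config.ph_levels)
    cells = []
    for strain, ph in [(config.parent_name, p) for p in levels] + [
        (config.deletion_name, levels[-1])
    ]:
        for tp in config.time_points:
            cells.append((strain, ph, tp))
    labels = [f"{s}:{p:g}:{t}" for s, p, t in cells]
    out = np.zeros((len(truth), len(cells)))
    cat = truth["ph_category"].to_numpy()
    paci = truth["paci_status"].to_numpy()
    template = truth["planted_template"]
    for j, (strain, ph, tp) in enumerate(cells):
        idx = levels.index(ph)
        tp_idx = config.time_points.index(tp)
        tp_scale = config.time_attenuation if tp_idx == 1 else 1.0
        col = np.zeros(len(truth))
        col[cat == "high_up"] = e * idx
        col[cat == "low_up"] = -e * idx
        if idx == 1:
            col[cat == "peak"] = e
            col[cat == "dip"] = -e
        if strain == config.deletion_name:
            col[paci == "induced"] -= e
            col[paci == "repressed"] += e
        col *= tp_scale
        # planted runs override the generic patterns
        for k, t in enumerate(template):
            if pd.isna(t):
                continue
            _, shape, tp2_scale = _template_for(int(t))
            scale = tp2_scale if tp_idx == 1 else 1.0
            col[k] = e * shape[idx] * scale
        out[:, j] = col
    return pd.DataFrame(out, index=truth.index, columns=labels)


def generate_expression(
    catalog: pd.DataFrame, truth: pd.DataFrame, config: SimulationConfig
):
    """Simulate the replicated log2 expression matrix.

    Per-gene baselines are drawn once; expected offsets follow
    :func:`expected_offsets`; i.i.d. Gaussian noise of sd ``noise_sd`` (or
    per-gene sds from a scaled inverse-chi-squared prior when
    ``gene_specific_variance`` is set) is added per sample. Returns
    ``(matrix, design)``; deterministic under ``config.seed``.
    """
    if not catalog["gene_id"].isin(truth.index).all():
        raise ValueError("catalog and truth gene sets differ")
    design = build_design(config)
    if design.empty:
        raise ValueError("empty design")
    rng = np.random.default_rng([config.seed, 1])
    truth = truth.loc[catalog["gene_id"]]
    n = len(truth)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    offsets = expected_offsets(config, truth)
    if config.gene_specific_variance:
        d0 = config.variance_prior_df
        sd = np.sqrt(d0 * config.noise_sd**2 / rng.chisquare(d0, size=n))
    else:
        sd = np.full(n, config.noise_sd)
    cols = {}
    for _, s in design.iterrows():
        cell = f"{s['strain']}:{s['ph']:g}:{s['time_point']}"
        noise = rng.normal(0.0, 1.0, size=n) * sd
        cols[s["sample_id"]] = baseline + offsets[cell].to_numpy() + noise
    matrix = pd.DataFrame(cols, index=truth.index)
    matrix.index.name = "gene_id"
    return matrix, design


def simulate_study(config: SimulationConfig):
    """Run the full generator; returns a dict bundle with ``genome``,
    ``catalog``, ``truth``, ``matrix`` and ``design``."""
    genome, catalog, truth = generate_genome(config)
    matrix, design = generate_expression(catalog, truth, config)
    return {
        "config": config,
        "genome": genome,
        "catalog": catalog,
        "truth": truth,
        "matrix": matrix,
        "design": design,
    }


def write_simulation(bundle: dict, outdir) -> dict:
    """Write FASTA/GFF3/TSV outputs with deterministic ordering; returns the
    path map."""
    import os

    from .io_formats import write_design, write_expression, write_genome, write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "catalog": os.path.join(outdir, "genes.gff3"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "design": os.path.join(outdir, "design.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_genome(bundle["genome"], paths["genome"])
    write_gff3(bundle["catalog"], paths["catalog"])
    write_expression(bundle["matrix"], paths["expression"])
    write_design(bundle["design"], paths["design"])
    bundle["truth"].to_csv(paths["truth"], sep="\t")
    return paths
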