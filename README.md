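# phregulon

Analysis pipeline for ambient-pH gene regulation in fungal transcriptomes.

Filamentous fungi sense ambient pH through the pal/PacC pathway: at
alkaline pH the zinc-finger factor PacC (PACI in *Trichoderma reesei*) is
proteolytically activated, induces alkaline-expressed genes and represses
acid-expressed genes. Given a replicated expression matrix from a parent
strain grown at several pH levels and a regulator-deletion strain, plus
the genome and gene catalog, this package identifies pH-responsive genes,
calls candidate direct regulator targets, tests their promoters for the
core binding site GCCARG, clusters expression profiles, and scans the gene
order for co-regulated genomic regions. A synthetic-data generator with
full ground truth makes every stage testable end to end.

## The statistics at the core

* **Moderated t** — per-gene pooled variances s²_g (df = n_a+n_b−2) are
  shrunk toward a prior: s̃²_g = (d₀s₀² + df·s²_g)/(d₀+df), with (d₀, s₀²)
  estimated across genes by method of moments on log s²; t̃_g =
  Δ_g/(s̃_g√(1/n_a+1/n_b)) on d₀+df degrees of freedom. Selection requires
  |log2 FC| > 0.4 and p < 0.01 at **both** sampled time points.
* **Target inference** — induced: up at pH 6 vs 3 in the parent AND down
  in the deletion strain at pH 6; repressed: the mirror image.
* **Motif enrichment** — presence of GCCARG (both strands) in ≤1500-bp
  coding-orientation promoters, tested with the exact one-sided binomial
  tail P(X ≥ k), X ~ Bin(n, p₀), against the genome presence rate p₀.
* **Fuzzy c-means** — soft clustering of standardized condition-mean
  profiles, u_ij = 1/Σ_k(d_ij/d_kj)^(2/(m−1)).
* **Genomic regions** — ≥3 of 4 consecutive genes sharing a cluster
  label, with ≥1 pH-responsive member.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a
2,000-gene synthetic study (written to `results/analysis/`):

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_infer_paci_targets.py
python analysis/04_motif_enrichment.py
python analysis/05_cluster_profiles.py
python analysis/06_genomic_regions.py
python analysis/07_report.py
```

Output of the first four steps:

```
planted pH categories: {'flat': 1812, 'low_up': 115, 'high_up': 69, 'peak': 2, 'dip': 2}
planted regulator targets: {'none': 1986, 'induced': 8, 'repressed': 6}
pH-response calls: {'flat': 1812, 'low_up': 115, 'high_up': 70, 'dip': 2, 'peak': 1}
recovery of planted pH-responsive set: sensitivity 1.000, false-discovery proportion 0.000
candidate targets: 8 induced, 6 repressed
induced: precision 1.000, recall 1.000
repressed: precision 1.000, recall 1.000
genome background: 76.8% of promoters carry GCCARG
induced candidates: 8/8 with motif, binomial p = 0.121
printed-counts check (33/38 vs 0.65): p = 0.0024 (< 0.0025)
```

Reading this: of 2,000 simulated genes, 188 were planted as
pH-responsive; the dual-threshold moderated-t selection recovers them all
with no false positives (one planted `peak` gene is recalled as `high_up`
— its mid-pH step happens to miss significance at one time point). All 14
planted regulator targets are recovered exactly. In a GC-0.5 genome the
6-bp site GCCARG occurs spontaneously in ~77% of 1500-bp promoters, so an
8-gene set with 8 hits is unremarkable (p = 0.12), while 33 hits in 38
genes against a 65% background is strongly enriched (p = 0.0024). Steps
05–07 then cluster the profiles (all 8 induced candidates land in one
cluster), recover all 8 planted co-expressed gene runs as exactly one
genomic-region call each, and write the summary and fold-change heatmap.

The same chain is available as a CLI (`phregulon simulate/de/cluster/
paci/motif/scan/run`) and as one call, `phregulon.pipeline.run_pipeline`,
which writes a deterministic `summary.json` for a given config and seed.

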