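# acetylome

Downstream analysis of multi-organ lysine-acetylation (Kac) site catalogs,
of the kind produced by antibody-enrichment LC-MS/MS surveys of plant
organs.  The package is aimed at proteomics analysts who have a validated
site table (protein, position, organ, replicate, abundance), a proteome
FASTA, and auxiliary inputs (expression matrix, annotation tables, ortholog
alignments), and want the standard battery of acetylome questions answered
reproducibly:

* **Catalog structure** — sites-per-protein distribution, within-organ
  replicate overlap (both |A∩B|/min(|A|,|B|) and Jaccard |A∩B|/|A∪B|),
  organ Venn partitions with organ-specific fractions, within-replicate
  spectral-area normalization, and deterministic hierarchical ordering for
  abundance heatmaps.
* **Expression specificity** — per-gene Shannon entropy
  H = −Σ pᵢ log₂ pᵢ over n samples (H = log₂ n for uniform expression,
  0 for single-sample expression), contrasted between acetylated and
  non-acetylated genes with a Mann–Whitney rank test and a median-split
  hypergeometric test.
* **Flanking motifs** — pLogo-style signed −log₁₀ binomial tail scores for
  every (flank position, residue) cell of the ±15-residue windows, against
  an all-lysine-window or proteome-global background, plus motif-x-style
  greedy motif extraction.
* **Conservation** — per-lysine conservation calls on ortholog alignments
  (K in all aligned species, or a fractional rule), the acK vs non-acK 2×2
  Pearson chi-square contrast, and the substitution spectrum (K→Q
  acetyl-mimic vs K→R non-acetyl-mimic).
* **PTM crosstalk** — hypergeometric protein-overlap tests with
  phospho/ubiquitin/SUMO catalogs, exact shared-site counts, an
  anchor-centric positional profile of phosphorylation around acetylated vs
  non-acetylated lysines with percentile-bootstrap CIs, and dual-modification
  domain enrichment.
* **Generic enrichment** — one hypergeometric + Benjamini–Hochberg engine
  for every term-enrichment panel, plus set tallies.

Because raw MS data are not needed for any of these statistics, the package
ships a seeded synthetic-data generator (`acetylome.synthetic`) that
emulates a five-organ acetylome — geometric sites-per-protein counts,
per-replicate detection probability q, +1 R/K/N/H flank bias with Cys
depletion, Dirichlet expression profiles, distance-decaying phosphorylation
p₀ + a·e^(−d/λ) around acetyl-lysines, and conservation-toggled ortholog
columns — so every stage is verifiable end to end against known ground
truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
catalog (seed 1, 800 proteins) and write their tables under `results/`.
For example:

```sh
python analysis/02_catalog_structure.py
```

prints

```
distinct acetyl sites: 809 on 393 proteins (mean 2.06 sites/protein)
sites-per-protein histogram (exponential decay): {1: 189, 2: 101, 3: 52, 4: 20, 5: 19, 6: 6, 7: 1, 8: 2, 9: 2, 10: 1}
mean replicate overlap (min denominator): 76.4% (Jaccard 0.596)
sites present in all five organs: 143
organ-specific site fractions: flower 49%, leaf 47%, root 43%, seed 42%, stem 49%
```

— the histogram decays geometrically (~2 sites per acetylated protein), and
with detection probability q = 0.75 the replicate overlap lands in the
mid-70% range (min-denominator convention; the expected Jaccard is
q/(2−q) ≈ 0.6).  Likewise:

```sh
python analysis/05_conservation.py
```

```
lysines classified: 816 acetylated, 5976 non-acetylated (72 gap-heavy columns excluded)
conserved fraction: acK 22.3% vs non-acK 10.6%
chi-square = 94.0, p = 3.17e-22
substitution spectrum at acK columns: {'Q': 1487, 'R': 1531}
```

— acetylated lysines are conserved twice as often as the other lysines of
the same proteins (the generator's column-toggle rates are 0.22 and 0.11),
and only Q/R substitutions appear at acetylated positions.

The same stages are available as a CLI (`acetylome all --seed 1 --out-dir
results/run`, or per-stage subcommands `catalog`, `entropy`, `motif`,
`conserve`, `crosstalk`, `enrich` operating on TSV/FASTA inputs) and as
library functions (`acetylome.pipeline.stage_*`).

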