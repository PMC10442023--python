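# Methods

This note documents the models and procedures implemented in `acetylome`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Data model

The unit of every site-level statistic is the **site key** (protein id,
1-based residue position).  Coordinates are 1-based inclusive throughout —
the field writes K56, H4K5 — and validation enforces that every site's
residue matches the proteome at that position (K for acetyl/ubiquitin/SUMO,
S/T/Y for phospho; the unknown residue X never matches).  Validation reports
*all* offending rows, not just the first, and duplicate
(site, PTM, organ, replicate) rows are rejected.  Absent abundances are
missing, never 0.

## Synthetic study generator

The generator produces, from one seed, a mutually consistent proteome, acetyl
catalog, co-occurring PTM catalog, expression matrix, ortholog alignments and
annotation table.  One global seed drives fixed-offset substreams per table,
so regenerating one table never shifts the others; identical config + seed is
byte-identical.

**Proteome.** `n_proteins` (default 800) i.i.d. sequences from Swiss-Prot
average amino-acid frequencies; lengths from a gamma law (mean 300 residues,
shape 4, floor 31 so a full ±15 window always fits).  A mean below 10 is
rejected as degenerate.

**Acetylome.** A protein is acetylated with probability `frac_acetylated`
(0.5); acetylated proteins carry Geometric(π) sites (π = 0.5, support
1, 2, …, mean 1/π = 2 sites/protein), placed on distinct lysines.  The
geometric law makes the sites-per-protein histogram decay exponentially and
the "acetylated" label truthful (≥ 1 site).  Flanks of chosen sites are
re-drawn with multipliers on the base frequencies (+1: R×3, K×2, N×2, H×2;
C×0.3 at every redrawn offset) and written back into the proteome copy, so
catalog and sequences stay consistent; redrawing edits offsets within ±5
(the explicit keys of the boost map plus a local window — wide enough to
carry the Cys depletion, narrow enough not to erase the background
composition) and never touches another chosen site.  Each true site lives in
all five organs with probability `core_site_fraction` (0.2) or in one random
organ; each (organ, replicate) observation is emitted independently with
detection probability q (0.75, 3 replicates/organ), with log-normal
abundance.  Under this thinning the expected min-denominator replicate
overlap is ≈ q and the expected Jaccard is q/(2−q), which puts the default
run in the low-to-high-70% overlap range typical of reproducible PTM
surveys; core 0.2 yields organ-specific site fractions around 40–50%.

**Expression.** Per-gene profiles over `n_samples` (158) are symmetric
Dirichlet draws — concentration `entropy_alpha_kac` = 5 for acetylated
genes, `entropy_alpha_non` = 0.5 otherwise — scaled by a log-normal library
size.  High concentration → near-uniform profile → entropy near log₂ n;
low concentration → spiky, sample-specific profiles.  The two alphas are the
generator's device for an entropy contrast of realistic effect size, not an
estimate of any real atlas.

**Co-occurring PTMs.** Each S/T/Y is phosphorylated with probability
p₀ + a·e^(−d/λ), d the distance to the nearest acetyl-lysine (p₀ alone if
none); defaults p₀ = 0.05, a = 0.3, λ = 3 residues, so the rate adjacent to
an acK is p₀ + a·e^(−1/3) ≈ 0.265 and decays to ≈ p₀ by d = 15.  Each K is
ubiquitinated/SUMOylated at 0.02/0.01 per residue, multiplied by
`ack_exclusion` = 0.1 at acetylated lysines — K-targeted PTMs rarely share a
lysine with acetylation.

**Ortholog alignments.** Ten species rows per acetylated protein.  Each
reference lysine column is toggled conserved — K in every species — with
probability ρ_ac = 0.22 (acetylated) or ρ_non = 0.11 (other); otherwise each
species independently shows K (probability 0.5) or a residue from the
substitution alphabet {Q, R}.  Column-level toggling makes ρ directly
recoverable as the conserved fraction.  Non-K columns match the reference
with probability 0.7 (mismatches drawn uniformly from the 19 other
residues); cells gap out at rate 0.05.  The 0.5 within-column K probability
and the ±5 redraw window above are this package's own choices where no
convention exists; both are exposed in the config.

**What the generator does not emulate:** spectra, digestion, missed
cleavages, intensity models, FDR filtering of identifications, real
phylogenetic covariance between species, compositional biases of real
proteomes, or annotation structure correlated with function.  Passing tests
therefore demonstrate that the *statistics* recover known structure under
their stated assumptions — not that any biological conclusion transfers to a
particular real dataset.

## Analysis conventions

**Replicate overlap.** The literature's "overlap ratio" denominator is
ambiguous; the headline number defaults to intersection over the smaller
set, with Jaccard always computed alongside.  Two empty sets give undefined
(None) ratios, never 0.

**Organ Venn.** An element observed in organ X by any replicate counts as
present in X; each distinct element falls in exactly one power-set region,
so region counts always sum to the element total.  Rows without an organ
label are excluded and counted.

**Abundance.** Within each (organ, replicate) the site abundances are
divided by the replicate total (proportions of total spectral area, robust
to loading differences); the per-organ value is the mean of replicate
proportions.  Heatmap ordering uses average-linkage Euclidean clustering of
row-wise z-scores (missing treated as 0 for ordering only, constant rows
z-scored to 0 with a warning); scipy's linkage on a fixed input order is
deterministic, which we prefer over fidelity to any particular tool's
unstated choice.

**Entropy.** Base-2 logarithm, so the 158-sample maximum is
log₂ 158 = 7.30 bits.  Genes with zero total expression are excluded rather
than assigned H = 0, since 0 means maximal specificity — wrong for an
unexpressed gene.  The group contrast uses a two-sided Mann–Whitney test as
the primary statistic; a hypergeometric test on a continuous quantity needs
a binarization, so the secondary test counts acetylated genes in the
above-global-median-entropy half (upper tail).  The median split is a
documented default, not a claim about any particular published threshold.

**Motif scores.** Windows are 31-mers (w = 15); `-` padding beyond termini
is excluded from both foreground counts and background frequencies.  For a
cell with foreground count k of n and background frequency p, the score is
−log₁₀ P(X ≥ k) when k/n ≥ p and −(−log₁₀ P(X ≤ k)) otherwise,
X ~ Binomial(n, p).  p = 0 with k > 0 (and symmetrically p = 1 with k < n)
is flagged degenerate with infinite score.  Significance is Bonferroni
α/(20 residues × 2w positions), α = 0.05.  The default background is
windows on *all* proteome lysines — the standard conditional background for
centered PTM logos, which avoids trivially rediscovering the central K — with
a proteome-global frequency vector as the alternative.  Motif extraction is
greedy: fix the (position, residue) cell with the smallest upper-tail p if
p < 1e−6 and k ≥ 20 (ties broken by position, then residue, so extraction is
deterministic), filter both window sets to matches, recurse; on emission the
motif's foreground matches are removed and the search restarts.

**Conservation.** "Conserved" defaults to K in every aligned species; a
fractional rule (≥ ⌈0.8·aligned⌉) is available since the strict threshold is
a convention, not a law.  A gap counts as not-K and removes that species
from the aligned count; columns with < 80% species coverage are excluded
(flagged) rather than called unconserved.  The contrast is a Pearson
chi-square without continuity correction on the 2×2 table (1 df); a zero
margin yields NaN, flagged, rather than a fabricated p.

**Crosstalk.** Protein-overlap p-values are upper hypergeometric tails over
a caller-supplied universe (default: the full proteome; configurable to the
union of PTM-detected proteins).  The positional profile is anchor-centric:
every (anchor, S/T/Y-at-distance-d) pair contributes to the denominator at
d, and to the numerator if that residue is phosphorylated; distance is
unsigned sequence separation.  Non-acK anchors default to the unmodified
lysines of acetylated proteins — lysines of comparable detectability —
configurable to all proteome lysines.  CIs are percentile bootstrap over
proteins (B = 1000 by default, seeded, bit-reproducible).

**Enrichment.** One engine — hypergeometric upper tail (equal to one-sided
Fisher) with Benjamini–Hochberg step-up q-values — serves the term,
compartment, kingdom and dual-modification panels.  Terms with zero
foreground hits are omitted; universes are caller-supplied, never fetched.

## Numerical and testing notes

Problem sizes in the test suite are chosen so each check is decisive at desk
scale: parameter-recovery runs use ~1200–2000 proteins (≥ 2000 lysines per
conservation class, ±0.03 recovery at 3 binomial SEs), repeated-seed checks
use 100 seeds at ~250–400 proteins each.  The sites-per-protein monotonicity
check is asserted over counts 1–6, where expected bin counts at 10⁴ proteins
exceed ~150 and an inversion would be a real defect; deeper bins have
Poisson-level counts where adjacent inversions are sampling noise, not a
violation of the geometric law.  The a = 0 crosstalk null is judged at the
(seed, distance) level — ≥ 90% of marginal 95% CIs overlapping — because a
joint all-distances requirement compounds the per-distance type-I error and
fails even for a perfect implementation when the two anchor classes differ
10× in size.

Known limitations: the binary core-vs-single-organ site model is coarser
than real organ sharing patterns; alignment columns are independent (no
phylogeny); the bootstrap treats proteins as exchangeable units; and the
motif extractor, like motif-x, is greedy and order-dependent by design.
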