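# fgscreen

A forward-genomics screen for convergent gene loss.  Mammals that
independently stopped relying on a trait — here, vision — let the genes
serving that trait decay under relaxed selection.  `fgscreen` finds such
genes genome-wide: it detects gene-inactivating mutations
(frameshifting indels, premature stops, splice-site lesions, exon and
gene deletions) in codon alignments, summarises them into the maximum
percentage of the reading frame left intact (**%intact**) per gene and
species, associates %intact with a phenotype across a phylogeny, and
maps the inferred loss events onto the tree.

It is written for comparative genomicists who have (or can simulate)
a species tree, per-species coding alignments or a precomputed %intact
matrix, and a phenotype table — and who want candidates that are
*convergently* lost, not just lost once.

## The statistic at the core

For each gene, %intact per species is regressed on the binary
poor-vision indicator x by phylogenetic generalized least squares:

y = α + βx + ε,  ε ~ N(0, σ²V),  V_ij = shared root-to-tip path length

under Brownian motion, so shared ancestry cannot masquerade as
convergence.  The one-sided p-value (alternative β < 0: losses depress
%intact in the foreground) is Benjamini–Hochberg corrected over the
post-filter gene universe, and a candidate must satisfy q < 0.05 *and*
be lost (%intact < 60) in at least three independent foreground
lineages — the maximal all-foreground clades of the tree.  Loss events
are then counted by Dollo parsimony (loss is irreversible), with
lesions shared identically across a clade assigned to its stem branch.

## Worked example

Simulate a benchmark with known truth, screen it, and map the top
candidate's losses:

```bash
fgscreen simulate --n-species 20 --n-genes 60 --n-associated 6 \
    --seed 7 --out-dir run/
fgscreen screen --matrix run/matrix.tsv --tree run/tree.nwk \
    --acuity run/acuity.tsv --out run/results.tsv
```

The screen log prints:

```
INFO fgscreen: 10 foreground species in 7 lineages
INFO fgscreen.screen: filter_genes: dropped 47 of 60 genes (0 missing-heavy, 47 constant)
INFO fgscreen: 13 genes tested, 6 candidates
```

meaning: of 60 simulated genes, 47 never mutated anywhere (constant
%intact = 100) and are excluded; 13 are tested; 6 pass FDR 0.05 with
losses in at least three of the seven poor-vision lineages.
`run/results.tsv` has one row per tested gene:

```
gene_id  n_species_used  slope     t_stat    p_value      q_value      n_lost_lineages  candidate
g27      20              -63.6443  -21.0563  1.97717e-14  2.57032e-13  7                true
g59      20              -55.3972  -17.6631  4.06618e-13  2.64302e-12  7                true
g32      20              -53.7236  -10.9567  1.07531e-09  4.65966e-09  6                true
```

The slope is the GLS-estimated %intact deficit of poor-vision species:
gene `g27` has lost ~64 percentage points of reading-frame intactness
in the foreground relative to the background, p = 2.0e-14, and is lost
in all seven poor-vision lineages.  All six candidates here are truly
associated genes of the simulation.

The numbered scripts under `analysis/` run the same pipeline at the
full study scale (49 species, 7 poor-vision lineages, 2,000 genes) and
write their tables under `results/`: `01_simulate_benchmark.py`,
`02_scan_alignments.py` (alignment-level mutation detection, zero
discrepancies against the implanted truth), `03_run_screen.py`
(sensitivity 1.00, false-discovery proportion 0.00 on the default
seed, control screen flags nothing), `04_map_losses.py` (Dollo events
for the top candidate; 70 inactivated species in 18 independent
lineages on the curated extended panel), `05_enrichment.py`.

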