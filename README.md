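# intronevo

Tools for studying the evolution of spliceosomal introns across a phylogeny:
where introns were gained, where they were lost, and what the losses and
gains say about mechanism.

Spliceosomal introns are removed from pre-mRNA by the spliceosome and are
bounded almost universally by `GT…AG`. Over evolutionary time genomes both
lose introns — most plausibly when a reverse-transcribed, spliced cDNA
recombines back into the gene (cDNA-mediated loss) — and gain new ones, for
instance during double-strand-break repair, which leaves short direct
repeats (microhomology) straddling the new boundaries. The cDNA model makes
sharp predictions: losses should be *precise* (no junction indels), biased
toward the 3′ ends of genes, clustered in *adjacent* positions, and enriched
in highly expressed genes. This package implements the full analysis chain
needed to test those predictions, together with a simulator that generates
data with a known gain/loss history so every stage can be validated against
ground truth.

## What it does

- **`intronevo.synthetic_data`** — evolves intron presence/absence along a
  rooted tree (per branch of length *t*: loss with probability
  `1 − exp(−λt)`, gain per free site slot with `1 − exp(−γt)`), then emits
  genomes (FASTA), annotations (GFF3), true codon alignments, and an FPKM
  expression table, with configurable precise/imprecise losses, planted
  boundary repeats and expression shifts.
- **`intronevo.mapping`** — projects intron positions onto ortholog
  alignments (a site is an alignment column + phase), screens absence calls
  with 45-bp flank filters (gaps < 10, identity > 0.5 per side), builds the
  sites × species `{0,1,?}` matrix (rows with more than 11 ambiguous cells
  dropped), and classifies each loss as precise or imprecise from junction
  gap columns.
- **`intronevo.ancestral`** — Dollo parsimony (single origin at the MRCA of
  presences, minimal losses) and a two-state pruning likelihood with global
  gain/loss rates, optional two-category loss-rate variation
  (`Δ = −2(L₁ − L₂)` against χ²₁), observability conditioning, per-branch
  event posteriors thresholded at 0.99, and density scaling
  `N × 3.65 ÷ 373` against the *C. elegans* reference.
- **`intronevo.adjacency`** — the exact per-gene adjacent-loss law
  `Pr{d|l,r} = C(l−1,d)·C(r+1,l−d)/C(r+l,l)`, an exact aggregate tail by
  convolution, and the seeded 100,000-round resampling null.
- **`intronevo.evidence`** — representative intron lengths via the closest
  retaining relative, relative 3′ distances, loss/gain co-occurrence
  chi-square, Mann–Whitney / Wilcoxon contrasts with Benjamini–Hochberg
  correction, microhomology scans (k = 3…8 over the 10-bp boundary
  windows), splice-signal checks (GT–AG, polypyrimidine tract, GC), and
  RNA-junction confirmation of putative gains.
- **`intronevo.pipeline` / the `intronevo` CLI** — orchestrates
  simulate → map → infer → adjacency → evidence with one YAML config,
  writing per-stage manifests with checksums; runs are deterministic under a
  fixed seed.

## Worked example

```python
from intronevo import (SimConfig, simulate_history, emit_genes,
                       map_introns, classify_site, build_matrix,
                       dollo_events, fit_rates, lrt, cooccurrence_test)
from intronevo.phylo import TreeIndex

cfg = SimConfig(tree="((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);",
                root_site_count=200, n_groups=40,
                loss_rate=0.5, gain_rate=0.01, seed=1)
history = simulate_history(cfg)
data = emit_genes(history, cfg)

sites = []
for aln in data.alignments.values():
    for site in map_introns(aln):
        classify_site(site, aln)
        sites.append(site)
matrix = build_matrix(sites, species=history.tree.leaf_labels)
events = dollo_events(matrix, history.tree)
print(matrix.n_sites, events.total_losses, events.total_gains)
# 207 77 51

res = cooccurrence_test(4892, 1534, 118, 80)
print(round(res.expected_both), f"{100*res.expected_fraction:.2f}%", f"{res.p_value:.0e}")
# 37 0.76% 6e-18
```

The first line says 207 sites are recovered in the matrix (the 200
simulated ancestral sites minus those lost in every species, plus a handful
of gained ones); Dollo parsimony then explains the leaf patterns with 77
losses and 51 gains. The second block is the gene-class
worked example: given 4892 ortholog groups of which 1534 lost and 118
gained introns, independence predicts ≈ 37 genes (0.76%) in both classes —
the observed 80 rejects independence at p ≈ 6×10⁻¹⁸.

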