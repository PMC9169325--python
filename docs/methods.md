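# Methods

## The model

Each intron site is a binary character (absent = 0, present = 1) evolving
independently down a rooted tree with branch lengths. On a branch of length
*t* the transition probabilities are

    P(1 → 0) = 1 − exp(−λ t)        P(0 → 1) = 1 − exp(−γ t)

with a global loss rate λ and gain rate γ (per site, per unit branch
length). Two reconstruction routes consume the observed sites × species
matrix of `{0, 1, ?}` cells:

**Dollo parsimony.** Each site is gained exactly once — at the most recent
common ancestor of the species carrying it — and lost on the minimal set of
branches explaining every confirmed absence. Given the fixed origin, that
minimal set is unique: each loss sits on the highest branch whose subtree
contains confirmed absences and no presence. Ambiguous (`?`) cells impose
no constraint and are never charged a loss. A site whose origin is below
the root contributes one gain on the origin's stem branch; note that this
convention also reports "gains" for genuinely ancestral sites lost in one
of the root's two child clades — outgroups in the input tree are the
standard remedy, exactly as in parsimony tools for this problem.

**Maximum likelihood.** Per-site likelihoods come from Felsenstein pruning
with the 2 × 2 transition matrices above. The root state prior is the chain's
stationary distribution (π₁ = γ/(γ+λ)) by default, or an explicit presence
probability: `fit_rates(..., root="free")` optimizes the root intron content
as a free parameter, which matters whenever the data were not generated at
stationarity (see below). Every site in a real matrix is present in at
least one species, so site likelihoods are conditioned on observability by
dividing by 1 − P(all leaves absent). The *rate-variation* flavour mixes
two equal-prior loss-rate categories with multipliers (m, 2 − m), m ∈ (0,2)
— the mean-1 constraint keeps λ identifiable — over a single gain category.
Setting m = 1 recovers the constant model exactly, which the tests assert
to 10⁻⁹. Models are compared with Δ = −2(L₁ − L₂) against χ² (df = 1);
p-values below 10⁻³⁰⁰ are reported as 0 with an underflow flag.

Optimization is bounded L-BFGS-B on log-rates (floor 10⁻⁹, ceiling 10²)
with three starts (two fixed, one seeded); convergence is reported, never
raised. Per-branch event posteriors — P(parent = 1, child = 0 | data) for a
loss, P(parent = 0, child = 1 | data) for a gain — come from an up–down
(inside–outside) pass, mixed over loss categories; events at posterior
≥ 0.99 (default) are retained. Only the best-supported gain branch per site
enters the per-branch tallies, so branch totals always equal per-site sums.
Ancestral node counts are summed posterior presence probabilities (ML) or
replayed presence (Dollo), and are scaled to introns/kbp by
`N × 3.65 ÷ 373`, anchored on the *C. elegans* reference values.

## Site mapping and filters

Two introns from different species are the same site iff they project to
the same alignment column (the column of the first aligned base 3′ of the
junction) with the same phase. An absence call survives only if, against
*every* intron-bearing species, both 45-column flank windows show fewer
than 10 gap characters and identity above 0.5 — gaps counted over both
sequences of the pair, identity over columns ungapped in both, each side
independently (the thresholds are strict: 10 gaps or identity 0.50 fail).
Windows truncated at alignment ends need ≥ 20 usable columns, else the cell
is ambiguous. Rows with more than 11 ambiguous cells are dropped from the
matrix. Loss precision inspects 15 columns on each side of the junction in
the (loser, retainer) pair: gap-free means precise; otherwise the loss is
imprecise with the indel size equal to the count of columns gapped in
exactly one of the two sequences — columns gapped in both are padding
introduced by third species and are ignored.

## Adjacent-loss statistics

For a gene with l lost and r conserved sites, the number d of adjacent lost
pairs under uniform random placement has the exact law
Pr{d|l,r} = C(l−1,d)·C(r+1,l−d)/C(r+l,l) (runs-of-losses combinatorics).
Aggregation across genes uses the total pair count: exactly, by convolving
per-gene mass functions (genes with l ≤ 1 are point masses at 0 and are
retained); and by Monte-Carlo resampling of l-subsets per gene (uniform via
random-key selection), p = #{resampled total ≥ observed}/n. Both paths are
reported side by side because published per-species probabilities do not
pin down the aggregation; the observed total of 0 yields p = 1 in both.

## The simulator

`simulate_history` is the generative counterpart of the inference model,
restricted to the Dollo-compatible regime: losses are irreversible, a site
slot is gained at most once (first gaining branch in preorder wins), and
per-branch event probabilities follow the exponential form above. Sites
occupy nucleotide junction offsets ≥ 50 nt from the CDS ends and ≥ 45 nt
apart, so flank windows and junction-indel windows never overlap
neighbouring sites. Gains draw from the free offsets, making the expected
gain count proportional to gene length — genes default to 20·(sites + 2)
codons. Because the root composition is a parameter (all root sites
present) rather than the stationary distribution, fitting this output with
the stationary root prior badly inflates the gain rate; `root="free"`
restores sensible estimates and is what the pipeline uses.
`simulate_matrix` is the exact reversible-chain generator (stationary root,
regains allowed, unobservable columns redrawn) and is the matched source
for ML rate-recovery checks.

Emission writes, per species, a single-chromosome genome FASTA with
100-nt spacers, GFF3 (1-based, gene/mRNA/exon/CDS), and per-group true
codon alignments that are gap-consistent with the ancestral CDS. Ancestral
coding sequence is uniform over the 61 sense codons; substitutions hit each
branch at a configurable per-nt rate (default 0.01 per unit length) without
indels. Intron sequences are `GT … AG` with a 10-nt pyrimidine tract ending
3 nt before the terminal `AG`; lengths are log-normal (default log-mean 4.0,
log-sd 0.6 ≈ median 55 nt) floored at 30 nt, with small per-leaf
multiplicative jitter so orthologous lengths correlate without being equal.
Imprecise losses plant an insertion or deletion (50/50) of the configured
size at the junction, shared by every leaf below the losing branch; a 2-nt
indel therefore leaves a frame-shifted CDS, which is why a non-codon-multiple
CDS length is a logged warning rather than an error. Planted microhomologies
write the repeat k-mer into the exonic window on both sides of the intron
(spanning into the intron for k > 5, with the constrained positions matching
`GT`/`AG`). Expression baselines are log-normal (log-mean 1.6, log-sd 1.5,
median ≈ 5 — a realistic FPKM spread); intron-lost genes are multiplied by
the configured effect.

What the simulator does **not** emulate: realistic substitution processes,
codon usage bias, UTRs and alternative splicing, alignment error (true
alignments are emitted), orthology error, and intron length evolution
beyond i.i.d. jitter. Passing round-trip tests therefore demonstrate that
the mapping/matrix/inference chain is internally correct, not that it is
robust to aligner artifacts or annotation noise in real genomes.

## Evidence statistics

Representative length of a lost intron = length of the orthologous intron
in the relative at minimal patristic distance that retains it, averaging
exact ties; genes with no retaining relative are excluded. Relative 3′
distance = (CDS length − junction offset)/CDS length. Class co-occurrence
uses expected = n_lost·n_gained/n_total and Pearson chi-square without
continuity correction on the 2 × 2 table (this reproduces published p-values
from published counts). Group contrasts are two-sided Mann–Whitney U
(unpaired) or Wilcoxon signed-rank (paired, after averaging within genes);
p-values are Benjamini–Hochberg adjusted. Microhomology windows are 5
exonic + 5 intronic nt at each boundary; a repeat of size k is called when
any exact k-mer occurs in both windows, at any offsets (binary per k,
k = 3…8). The polypyrimidine-tract rule — unavoidably a design choice — is:
any 10-nt window within the final 30 nt upstream of the terminal `AG`
containing ≥ 8 pyrimidines; all thresholds configurable. Putative gains are
confirmed only by an exactly matching RNA splice junction (species,
chromosome, start, end); off-by-one junctions do not confirm. FPKM values
of exactly 0 are removed before expression contrasts.

## Numerical and scale choices

Pruning partials are rescaled per internal node, keeping 100-species
matrices finite in log space. Posterior ratios skip rescaling (they cancel
per site) and are safe at the tree sizes the package targets. Test and
acceptance problem sizes — 10-taxon trees, 2000-site matrices for rate
recovery, 500-group round trips, 100,000-round resampling — were chosen as
the smallest scales at which the statistical criteria are sharp
(binomial/3-SE bounds, ±15% recovery, power ≥ 0.9), and run in seconds to
a couple of minutes on one CPU. Full published-scale analyses (104 genomes,
10,469 sites) use the same code paths unchanged.

## Known limitations

- The Dollo gain convention needs outgroups to distinguish basal losses
  from gains (see above).
- The ML machinery fits global rates with optional loss-rate categories; it
  does not fit fully branch-specific rates (over-parameterized at desk
  scale), though per-branch event *counts* come from the posteriors.
- Frame-shifting junction indels change downstream intron phases in the
  affected species; site identity is column + phase, so a heavily
  frame-shifted species can split a site. At the simulator's spacing and
  indel sizes this does not occur in practice, but it is a real-data caveat.
- `confirm_gains` requires exact junction matches and will reject support
  from slightly misaligned RNA-seq junctions.
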