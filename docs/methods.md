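# Methods

Models, conventions and defaults used by primerscope. Defaults encode the
standard design regime for group-specific degenerate 16S primers; every one
can be overridden from the library API and the CLI.

## Sequence model

Nucleotides are the 15 IUPAC codes plus `-` (gap). `U` is silently mapped to
`T`; any other letter is a hard error that names the offending position
(silent acceptance hides corrupt input). `.` in alignments is normalized to
`-`. A degenerate letter denotes a base set (Y = {C,T}, D = {A,G,T}, …);
*fold degeneracy* is the product of set sizes, and brute-force expansion is
capped at 1024 concrete sequences so the expansion oracle stays bounded.

## Multiple alignment

`align_progressive` builds a guide tree from k-mer (k = 6) profile distances
by UPGMA (scipy average linkage), then merges profiles along the tree with an
affine-gap global profile–profile aligner (Gotoh three-state recurrence,
vectorized row-wise). Scores: match +1, mismatch −1, gap open −4, gap extend
−1; the first gapped column therefore costs −5. Ties are broken
deterministically (match > delete > insert, input order), so the alignment is
reproducible. The pairwise kernel is checked in the tests against an
exhaustive recursive oracle on short sequences and against Biopython's
`PairwiseAligner` scores. This is a desk-scale aligner (≲500 sequences of
≲2 kb), not a replacement for production MSA tools.

## Conserved windows and degenerate consensus

A column's consensus is the *smallest* IUPAC code covering every concrete
base whose non-gap frequency is ≥ `min_fraction` (default 0: cover all
observed bases). Any gap observation disqualifies the column. A window
qualifies as a primer site when every column has a consensus, its length is
within [17, 24] and it contains ≤2 degenerate positions. Candidates are the
window consensus (forward) and its reverse complement (reverse); each must
match every target with zero mismatches (coverage 1.0 by default). Pairs
require the forward site strictly upstream of the reverse site and a
predicted product >400 bp, measured on an ungapped reference sequence when
one is named, otherwise by gap-corrected alignment columns. Melting
temperature is reported with the Wallace rule (<14 nt) or the GC-fraction
formula 64.9 + 41·(GC − 16.4/N)/N, using expected GC for degenerate
positions; it is descriptive output, not a design constraint.

## In-silico PCR

Primer matching is ungapped scanning of every template offset on both
strands, scoring mismatches with IUPAC-aware base-set intersection. The
`MatchPolicy` defaults allow ≤2 mismatches overall but **zero** within the 3
3′-terminal bases (the 3′ anchor), because polymerase extension is abolished
by terminal mismatches. A template amplifies when a forward site and a
downstream reverse-complement site yield a product inside (100, 3000) bp; the
*primary* hit per template is chosen by fewest total mismatches, then
shortest product, then leftmost position. Coverage is the fraction of target
templates with a primary hit; specificity is the count of non-target
templates with any hit. Matching is validated against a brute-force
degenerate-expansion oracle.

## Discriminability

Pairwise identity is computed from an affine-gap global alignment with
terminal-gap columns excluded from the denominator, so length differences at
the ends do not dilute identity. Distance models: p-distance, Jukes–Cantor
(d = −¾ ln(1 − 4p/3)) and Kimura 2-parameter
(d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)); saturated distances are capped at 5.0
with a warning rather than returned as infinities. Trees are built by
Saitou–Nei neighbor joining (own implementation: lexicographic tie-breaks
for determinism, negative branch lengths clamped to zero with a warning),
returned as scikit-bio `TreeNode`s; the test suite cross-checks topologies
against scikit-bio's independent NJ and verifies exact recovery of additive
matrices. The headline resolution statistic is the *indistinguishable-pair
fraction*: the share of unordered sequence pairs with identity ≥ a threshold
(default 0.98, the conventional species boundary), optionally excluding
conspecific pairs when species labels are supplied. `compare_resolution`
contrasts this fraction for full-length sequences versus the inter-primer
region alone.

## Diversity

Samples are standardized to a common depth by seeded uniform subsampling
without replacement (`depth="auto"` = smallest sample). OTUs are exact
100%-identity clusters (dereplication), the strictest possible clustering —
appropriate for error-free or denoised reads, and a deliberate simplification
versus threshold clustering. Taxonomy is best-hit assignment against a
labeled reference at ≥97% identity by default, with ties flagged and resolved
to the first reference. Target-read proportion is reported with survey
rounding conventions: integer percent at ≥1%, one decimal below. Shannon
index uses natural log by default; rarefaction reports seeded subsampling
means/SDs and is validated against the hypergeometric closed form
E[S_d] = Σ_i (1 − C(N − n_i, d)/C(N, d)).

## Synthetic fixtures

`generate_clade` plants a forward site (18 nt, degeneracy 4) and a reverse
site (20 nt, degeneracy 6) in every target, separated by a 712-nt insert
(product 750 bp), flanked by 40 nt, with substitution-only divergence (~0.10
expected pairwise) so the true alignment is ungapped and fully recoverable.
Degenerate site positions are realized so that *every* allowed base occurs in
some target — consensus calling must re-derive the code, not copy one
realization. Non-targets share no 17-mer with either site, guaranteeing zero
false amplification at zero mismatches. `generate_reads` emits reads from a
specified taxon mixture with a truth sidecar; `generate_insert_panel` builds
panels with an exact, known number of ≥98%-identity pairs. The generator
emulates the *geometry* of a 16S design problem (conserved sites, divergent
inserts, off-target templates); it does not emulate real 16S secondary
structure, indels, chimeras or sequencing error profiles beyond a uniform
substitution rate.

## Numerical and design notes

- All stochastic steps take explicit seeds (`numpy.random.default_rng`);
  nothing reads global RNG state.
- Alignment traceback compares floating-point scores with a 1e-6 tolerance.
- The bundled reference panel includes one primer pair whose forward
  sequence duplicates another pair's; it is kept verbatim and flagged
  `suspect_duplicate` in the data table rather than silently corrected.
- Limitations: no thermodynamic (nearest-neighbor) Tm or dimer/hairpin
  screening; no gapped primer matching; exact-identity OTUs only; NJ is the
  only tree method. These are out of scope for the design-evaluation loop
  this package targets.
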