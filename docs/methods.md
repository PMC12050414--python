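# Methods

## The CpG-content statistic

CpG content is defined as `#CpG / (#CpG + #GpC)` over a stretch of DNA.
Both dinucleotides have one C and one G, and each is its own reverse
complement, so the statistic is invariant to strand choice and, to first
order, to GC fraction and to the strand bias `G/(G+C)`. Under base
independence P(CG) = P(GC) = P(C)·P(G), hence the neutral expectation is
0.5 regardless of composition; methylation-driven CpG loss pushes it below.
`expected_cpg_frequency` returns the per-window CpG probability
`gc² · s · (1−s)` for GC fraction `gc` and strand bias `s`, together with
that neutral 0.5.

Counting conventions (fixed so that counts are reproducible bit-exactly):

* overlapping dinucleotide windows, step 1;
* case-insensitive; soft-masked lowercase counts normally (no repeat-masking
  semantics are attached to case);
* a window containing any non-ACGT base is voided: it contributes to neither
  the CG/GC counts nor the valid-window total. Assemblies contain N runs and
  the statistic must not be distorted by them;
* a record with `#CpG + #GpC = 0` has undefined content and is excluded
  (flagged, never silently dropped).

GC content *excluding CpG and GpC sites* is computed by base masking: every
base inside an overlapping CG or GC window is removed, and the GC fraction is
taken over the remaining ACGT bases (undefined if none remain). Masking is
one of several defensible readings of "excluding CpG/GpC sites"
(alternatives: subtracting dinucleotide counts, or excluding CpG only); the
convention is stated here and carried in the output schema so results are
interpretable.

Genomes are analysed in consecutive non-overlapping 5-kb tiles anchored at
scaffold coordinate 0; a trailing partial tile is retained (scaffolds shorter
than the tile width yield a single short tile). Terminal windows are the
first and last 99 coding bases (33 codons); a CDS must be at least
2·99 + 2 = 200 nt so the two windows are distinct.

## Genetic-code combinatorics

All enumerations run over the standard code (Biopython table 1, DNA
alphabet, 61 sense + 3 stop codons). The within-codon CpG classes are the
four CGN codons (arginine) and the four NCG codons (S, P, T, A being the
second-position-C amino acids with a G-ending synonym); 16 codons end in C
(15 amino acids) and 16 start with G (V, A, D, E, G — five amino acids,
although six is sometimes quoted; the enumeration is authoritative here).

The CpG-free repertoire removes the 8 CG-containing codons and then the 15
remaining C-ending codons. Removing C-enders rather than G-starters is the
only consistent choice: valine is encodable exclusively by GTN, so G-starting
codons cannot all be discarded, while every amino acid with a C-ending codon
has a non-C-ending synonym. The result — 38 codons, junction-safe by
construction (verified exhaustively over all 38² concatenations), covering
all 20 amino acids — shrinks the ordered dicodon space from 3721 to 1444
(−61.2%).

A consequence of the same junction rule worth stating explicitly: **four**
amino acids can never occur in a CpG context — K, M, Q, W. Lysine is the
easily-overlooked member: AAA and AAG contain no cytosine, and the G of AAG
sits behind an A, so no reading frame can place lysine's bases inside a CpG.
Published treatments sometimes list only M, Q, W; `never_cpg_amino_acids`
returns the rule-derived set.

Minimal synonymous escape (`min_synonymous_steps_to_cpg_free`) is a
breadth-first search over single-nucleotide substitutions constrained to
sense codons of the same amino acid, ignoring junction-formed CpG (the
question is codon-internal). Only CGT/CGC need two steps; CGA/CGG and all
NCG codons escape in one.

## Dicodon enrichment

Observed counts slide by one codon within each CDS (maximizing data; pairs
never span CDS boundaries); pairs touching a stop codon or an ambiguous base
are excluded. Expected counts are `N·f(c1)·f(c2)` with pooled sense-codon
frequencies from the same CDS set, stops excluded. Pooling across all
retained genes matches a per-species analysis; per-gene frequencies and
start/stop handling are the main alternative conventions, and the pooled,
stop-free choice is recorded in the output metadata. Records with expected
count below 5 (configurable) are flagged low-confidence, the standard
small-expected-count practice, and the top-k extraction skips them by
default. CpG placement flags (within codon 1, within codon 2, junction) are
read directly off the hexamer.

## Statistical comparisons

* Coding vs genomic: two-sided Mann–Whitney U between per-gene and
  per-fragment CpG contents.
* CpG content vs GC content (excluding CpG/GpC): Kendall τ plus an OLS line,
  restricted to genes of 150–2000 nt — extreme lengths make the per-gene
  ratio unstable at one end and average away heterogeneity at the other.
* 5′ vs 3′: paired two-sided Wilcoxon signed-rank on (first-99, last-99)
  contents; all-zero difference vectors are reported as p = 1 rather than an
  error.

Each comparison's length filter applies only to that comparison; global
analyses use every retained gene. Retention requires an informative gene
symbol (headers matching `LOC\d+` or lacking a symbol are treated as
unnamed — a proxy that filters unnamed/predicted models) and a defined CpG
content. No multiple-testing correction is applied across this small fixed
set of named tests; p-values are reported per comparison. The exclusion
ledger plus the retained set exactly partition the input.

`run_species` writes TSV/JSON outputs with sorted keys, fixed float
formatting and no timestamps, so reruns are byte-identical.

## Region-overlap permutation test

Overlap between merged interval sets is computed per chromosome with
prefix-sum interval arithmetic, in bases (symmetric) or as the count of
query regions hitting the subject. The null re-places each query region
uniformly on its own chromosome, preserving length; permuted regions may
overlap each other (no rejection), matching the usual random-placement
convention of region-randomization tools, and cross-chromosome placement is
available by flag. The empirical p uses the add-one rule
`(1 + #{null ≥ obs}) / (1 + n_perm)`, so the smallest attainable value is
`1/(n_perm+1)`; a z-score against the null mean/sd is reported when the null
is non-degenerate.

A calibration subtlety: the add-one p counts ties as extreme, so when
overlap totals live on a coarse lattice (identical region lengths) the
p-value is conservative — with 200-bp queries on a 10%-covered genome about
one permutation in eight ties the observed total exactly. Calibration
studies therefore use region fixtures with varied query lengths, which
removes the tie mass; applications with real data rarely sit on such a
lattice.

## Synthetic generators

**Genome.** First-order Markov chain: i.i.d. draws from
π = ((1−gc)/2, gc(1−s), gc·s, (1−gc)/2) for (A, C, G, T), except that the
transition row leaving C multiplies the G probability by λ and renormalizes.
This is the minimal generator that decouples CpG depletion from GC content
and strand bias. Its stationary CpG content is exactly

    content(λ) = λ / (λ + 1 − π_GC(1 − λ)),

derived from the stationary distribution (only the C row is perturbed, so
the chain's stationary vector is an affine function of the C-row) and
confirmed against the transition-matrix eigenvector and brute-force
simulation at several (λ, gc, s) combinations. Note the dependence is on the
*total* GC fraction, not on π_G alone. Inversion gives
λ̂ = r(1−g)/(1−r(1+g)) for measured content r, with a delta-method standard
error used by the recovery tests. A and T are symmetric (no AT skew).

**CDS sets.** Codons are drawn sequentially from usage weights (uniform over
the 61 sense codons by default); each CG a candidate codon would create —
internally, or across the junction with the previous codon — multiplies its
weight by λ. Separate λ values may apply to the first and last 33 codons
(terminal-window effects are injected through codon choice, never by
post-hoc sequence editing, so every output is a valid CDS: ATG start, single
terminal stop, no internal stop, length ≥ 201 nt). Per-dicodon factors
multiply the transition weight of a specific hexamer; because the transition
row renormalizes, an injected factor f on dicodon (c1, c2) appears in
measurements as enrichment f/Z with Z = 1 − w(c2)(1 − f), a correction of
about 1.5% at uniform weights — `dicodon_factor_normalization` returns it,
and a simulation test verifies it. A configurable fraction of genes receives
LOC-style headers to exercise the symbol filter.

**Region fixtures.** Subject blocks tile a chosen fraction of each
chromosome at regular spacing; each query region lands fully inside the
subject with the chosen enrichment probability, else fully outside (both
conditionally uniform). Enrichment equal to the coverage is the calibration
null up to edge effects of order (query length)/(chromosome length); query
lengths may be fixed or drawn from a range (see above).

All generators are byte-deterministic given (spec, seed) and return a truth
record alongside the sequences.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks compare measurements to expectations within 3 standard
errors. Generator calibration uses 10⁶-base genomes and ~10⁶-codon CDS sets;
pipeline direction-recovery uses 2000 genes vs 2000 fragments (Mann–Whitney)
and 1000 genes (Wilcoxon) with the injected contrasts λ = 0.8 vs 0.3 and
λ₅′ = 0.9 vs λ₃′ = 0.4; permutation calibration uses 200 seeds at 99
permutations and the power check 500 permutations. Oracle-equivalence tests
compare against independent brute-force implementations (naive window scans,
naive reframing, an independent shortest-path search, bitmap interval
intersection) on 100+ randomized small instances each.

One caveat the suite states honestly rather than hides: requiring *all* 3721
dicodon enrichments of a neutral 10⁶-codon set to sit within 3 per-dicodon
standard errors of 1.0 ignores multiplicity — the expected number of >3·SE
excursions among 3721 ratios is ~10, so that check fails for any correct
generator (the family-wise-sound version, max |z| against the Šidák bound,
passes and is the property the suite relies on).

## Limitations

The generators emulate composition, not biology: no isochore structure, CpG
islands, repeats, introns, or codon-usage realism beyond the supplied
weights. Passing tests demonstrate that the statistics and tests behave
correctly on data with known structure; they do not validate biological
conclusions on real genomes. The pipeline's genomic fragments are not
CDS-masked by default (the coding-vs-genomic contrast compares genes to the
whole genome including genic regions); masking can be layered on via the
region utilities. BED handling is minimal (first three columns, strand
ignored — CpG overlap is strand-symmetric).
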