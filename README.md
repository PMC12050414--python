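# cpg-landscape

Tools for analysing the CpG dinucleotide landscape of protein-coding DNA.

In vertebrates, methylated CpG dinucleotides deaminate at high rates
(CpG → TpG on one strand, CpG → CpA on the other), depleting CpG genome-wide.
Coding DNA is a special battleground for this process: a CpG can sit inside a
codon (CGN arginine codons; NCG codons of S, P, T, A) or span a codon junction
(a C-ending codon followed by a G-starting one), and the fate of a deamination
— silent, amino-acid-changing, or nonsense — depends entirely on where it
lands. This package provides:

* **Genetic-code combinatorics** — exact enumeration of CpG-bearing codon
  classes, the CpG-free codon repertoire (38 codons that still cover all 20
  amino acids, shrinking the dicodon space from 61² = 3721 to 38² = 1444),
  the six CpG SNP polymorphism classes, minimal synonymous escape paths from
  CpG codons, and non-CpG alternative encodings.
* **CpG content** — the normalized statistic
  `CpG content = #CpG / (#CpG + #GpC)`, bounded in [0, 1] with neutral
  expectation 0.5 under base independence; GpC has the same base content as
  CpG but is not a methylation target, so the ratio is insensitive to GC
  fraction and strand bias `G/(G+C)`. Plus 5-kb genome tiling, 99-bp terminal
  windows, and GC content with CpG/GpC bases masked.
* **Dicodon enrichment** — in-frame codon-pair counts versus the expectation
  from pooled codon frequencies (`expected = N·f(c1)·f(c2)`), with CpG
  placement flags and top-k under/over-representation tables.
* **Analysis pipeline** — gene filtering (informative symbols, defined
  content), coding vs genomic contrast (Mann–Whitney U), CpG-vs-GC
  correlation (Kendall τ + OLS, 150–2000 nt genes), 5′ vs 3′ contrast
  (paired Wilcoxon on the first/last 99 coding bases), with a complete
  exclusion ledger and byte-deterministic outputs.
* **Region-overlap permutation test** — empirical significance of overlap
  between two BED region sets under uniform per-chromosome re-placement,
  with the add-one p-value `p = (1 + #{null ≥ obs}) / (1 + n_perm)`.
* **Synthetic data** — seeded generators for genomes (first-order Markov
  chain with tunable GC fraction, strand bias, and CpG-depletion factor λ),
  CDS sets (codon-usage draws with CpG penalties, terminal-region overrides
  and injectable dicodon factors), and region fixtures with controlled
  overlap enrichment — every generator ships its ground truth.

The Markov genome model has the exact stationary CpG content
`λ / (λ + 1 − π_GC(1 − λ))`, so the depletion factor is recoverable from a
measured content by inversion (`invert_lambda`).

## Worked example

Generate a synthetic species — 300 coding sequences with mild CpG depletion
(λ = 0.8) and a 500-kb genome with strong depletion (λ = 0.3) — and run the
full analysis:

```bash
cpg-landscape simulate cds --n-genes 300 --cpg-lambda 0.8 --seed 7 --out demo
cpg-landscape simulate genome --length 500000 --cpg-depletion 0.3 --seed 8 --out demo
cpg-landscape run --cds demo/cds.fa --genome demo/genome.fa --out demo/out
```

which prints

```
coding_vs_genomic: p=1.120978039005156e-50 direction=coding>genomic
content_gc_correlation: p=0.0031555642104351468 direction=positive
start_vs_end: p=0.1764734584505674 direction=start<end
retained 300 genes -> demo/out
```

The coding set was built less CpG-depleted than the genome, and the pipeline
recovers exactly that: per-gene CpG content is far above the per-5-kb-fragment
content (Mann–Whitney U, p ≈ 10⁻⁵⁰). No 5′/3′ asymmetry was injected, and the
paired Wilcoxon test correspondingly finds none (p ≈ 0.18). `demo/out/`
contains the per-gene and per-fragment tables, the dicodon enrichment table,
the exclusion ledger, and a run manifest; two runs on the same inputs are
byte-identical.

The code-level combinatorics are available directly:

```bash
cpg-landscape code-report          # codon classes, CpG-free set, SNP classes
cpg-landscape dicodon --cds demo/cds.fa --top 3
```

`code-report` prints, among other things, `all_sense_pairs: 3721`,
`cpg_free_pairs: 1444`, and `never_cpg_amino_acids: [K, M, Q, W]` — the four
amino acids whose codons can never touch a CpG (lysine qualifies because
AAA/AAG contain no cytosine and their only guanine follows an A).

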