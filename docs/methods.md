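# Methods

## Scope and model

`oryzadiff` implements the analysis chain for an unreplicated two-condition
bulk RNA-seq comparison: per-gene RPKM from NH-weighted alignment counts,
median-pseudocount fold-change classification, and exact one-sided binomial
over-representation of flat gene categories (GO terms, KEGG pathways,
transcription-factor families). Alignment itself is out of scope: the
pipeline consumes either per-gene weighted count tables or a SAM stream
produced by an aligner that reports NH tags.

With a single library per condition, no per-gene variance is estimable, so
there are no per-gene p-values anywhere in the differential stage; the
statistical statement of the analysis lives entirely in the category-level
binomial test. This is a deliberate restriction, not an omission — methods
that shrink a dispersion estimate across genes (edgeR/DESeq-style) answer a
different question and need a different design.

## Coordinates and gene models

Files (GFF3, the gene-model TSV `location` column, SAM POS) are 1-based
inclusive; all internal interval arithmetic is 0-based half-open, and the
conversion happens only at the I/O boundary. A gene's `exon_length` — the
"kb" in RPKM — is the length of the union of all its exons across all
transcripts, with overlaps merged; the union is invariant to exon order and
to splitting exons into abutting pieces. When exon structure is unknown
(the TSV dialect, synthetic single-exon genes) the gene span acts as the
exon union for read overlap. Strand is carried through but never used in
counting: the library is treated as unstranded.

## Counting rules

- Each mapped alignment record has weight `1/NH`; a missing NH tag means
  weight 1 with a logged warning.
- The record is assigned to a gene only if its aligned reference span
  (from the CIGAR) overlaps the exon union of **exactly one** gene by at
  least one base. Records overlapping two or more genes are discarded from
  gene counts to avoid double counting — but every mapped record, assigned
  or not, contributes its weight to `total_mapped_reads`, the RPKM
  denominator. "Total reads" therefore means mapped reads, the quantity
  observable from the input.
- Paired-end mates are two independent records (read counting, not
  fragment counting).

These rules make weight conservation testable: the summed gene counts never
exceed the mapped total, with equality exactly when every alignment hits
one gene.

## Thresholds and bins

| parameter | default | meaning |
|---|---|---|
| `expressed_rpkm_threshold` | 1 (strict `>`) | gene called expressed |
| level-bin edges | 10 / 100 / 1000 RPKM | low / modest / high / extreme, left-closed |
| `de_fold_threshold` | 2 | enrichment foreground, `max(f, 1/f) ≥ 2` (closed) |
| `class_edges` | 1.5 / 2 / 3 | seven-way regulation classes, left-closed |

All bins are left-closed right-open so they partition: an RPKM of exactly
100 is "high", a symmetric fold of exactly 2 is in the 2–3-fold class, and
exactly 3 is in the ≥3-fold class. Everything in the table is configuration
(`AnalysisConfig`), never a literal in stage code.

## Pseudocount

The pseudocount `m_s` added to both terms of the expression ratio is the
per-sample **median RPKM over genes with nonzero RPKM**. Taking the median
over all annotated genes would give 0 whenever at least half the genes are
silent — which is the normal situation in a single tissue — and would leave
silent-gene ratios undefined; excluding zeros is the reading that yields a
finite adjusted value for every annotated gene. Fold changes are computed
for **all** annotated genes, not only expressed ones; the silent–silent
case lands exactly on `fldchg = m_30/m_25 ≈ 1`. Consequences worth knowing:

- the pseudocount is data-dependent (it grows with sequencing depth for
  fixed composition of detected genes), so fold changes are comparable
  within one analysis, not across libraries of very different depth;
- genes below roughly `m/6` RPKM cannot reach a 2-fold call at all, even
  under a true 8-fold change — the classification is intentionally blind
  to regulation of genes expressed near the detection floor.

## Binomial enrichment

The statistic is `P(X ≥ k)` for `X ~ Binomial(n, R/N)`: `N` universe genes,
`R` regulated, `n` category members in the universe, `k` of them regulated.
The tail is summed exactly in log space (`gammaln` + `logsumexp`), so
values of order 1e-50 are representable; no normal approximation is used.
Defaults: the universe is all annotated genes (switchable to expressed-only),
no multiple-testing adjustment (BH step-up available), no depletion scoring
(a lower-tail option exists). The margin convention is a genuine modelling
choice — `Binomial(n, R/N)` vs `Binomial(R, n/N)` — and both are exposed;
the default reproduces the published transcription-factor table's p-values
to within a factor of ~1.4, which is as close as an unstated convention can
be pinned down. Ranking is by ascending p-value with ties broken by larger
observed count, then category id, so ranks are a deterministic permutation.

Because the binomial treats member draws as independent while the regulated
set is a fixed-size sample without replacement, the test is an
approximation to the hypergeometric one; at `n ≪ N` the difference is
negligible. Exactness of the tail also means **discreteness**: under the
null, `P(p < α)` is at most α and typically below it. Computed exactly over
category sizes 20–200, the achieved size at α = 0.05 is ≈0.030 at a
background rate of 0.0245 and ≈0.039 at 0.15–0.2. The calibration test
therefore uses a background rate of 0.15 and judges the null
false-positive fraction against 0.05 with a ±3·SE band computed on the
number of replicates (not the number of category draws), because category
outcomes within one replicate share a single regulated-set draw and are not
independent. This conservatism is a property of every exact tail test, not
an implementation artefact.

## Synthetic study generator

The generator emulates the structure of the leaf-blade study at a
scaled-down default size, with truth recorded for every draw:

- **10,000 genes** (vs 56,143 annotated in the real genome; the
  `full_scale()` preset restores full size), single-exon, lengths uniform
  500–5000 bp, laid head-to-tail with 200 bp gaps along 12 chromosomes;
- **half the genes expressed**, with true RPKM log-normal
  (`meanlog = ln 3`, `sdlog = 1.86`) — chosen so ~3% of expressed genes
  exceed 100 RPKM and, at full scale, a few tens exceed 1000 RPKM, with the
  bulk below 10 RPKM;
- **146 genes planted up at 25 °C and 99 down** (the published 821/553
  scaled by 10,000/56,143), default planted fold 8, drawn from expressed
  genes with true RPKM ≥ 2 — below that, a 1M-read library yields
  single-digit counts and the pseudocount makes 2-fold calls unreachable
  (see above), so planting there would measure the detection floor, not the
  pipeline;
- **counts** Poisson (default) or negative-binomial with configurable size
  parameter, mean `rpkm · kb · library/10⁶`, library 1,000,000 reads per
  condition; per-condition true RPKMs are rescaled so `Σ rpkm·kb = 10⁶`,
  making expected empirical RPKM equal the recorded truth (real RPKM is
  compositional in exactly this way, so the rescale is fidelity, not
  convenience);
- **categories**: a GO/KEGG/TF panel with sizes spanning 20–200 (TF sizes
  follow the real rice TF-family sizes), one planted per namespace at
  enrichment factor 5 — each member slot of a planted category is filled
  from the regulated set with probability `5·R/N`; planting that demands
  more regulated members than exist is a hard error;
- three independent RNG streams (annotation / counts / SAM fixtures), all
  derived from one seed; identical config + seed reproduces every artifact
  byte for byte.

What the generator does **not** emulate: sequence-level error, positional
or GC bias, isoform structure, overlapping genes (except in hand-built
fixtures), correlated gene programs, or library-composition artefacts
beyond the compositional rescale. Passing recovery tests therefore show the
pipeline's arithmetic and ranking are correct under the stated generative
law, not that the biological conclusions of any real dataset are robust to
alignment or annotation error.

SAM fixtures for the counting oracle are generated separately: reads placed
inside gene spans, a configurable fraction emitted at two loci with NH=2,
a fraction intergenic; the expected count table accompanying the fixture is
computed by a brute-force per-read enumeration that shares no code with the
interval-tree counter it checks.

## Problem sizes in the test suite

The default test run uses the scaled-down study (10,000 genes, 1M reads)
for recovery (100 seeds), 1,000 replicates × 40 categories for null
calibration, 50 replicate count draws at a 10M-read library for the
expectation-match check, and ≤60-gene/≤50-read fixtures for exact oracle
comparisons. These sizes make the suite run in well under a minute while
leaving every statistical margin wide (e.g. recovery sensitivity ≥ 0.99
observed vs 0.95 required).

## Known limitations

- The headline counts of the motivating study (19,766 / 19,350 expressed
  genes, 821/553 regulated) depend on its raw sequencing runs and cannot be
  recomputed from printed inputs; the package validates the method, and the
  worked-example arithmetic of the printed tables, instead.
- Ambiguous alignments (overlapping genes) are discarded rather than
  fractionally shared; for gene-dense genomes this undercounts overlapping
  loci.
- The published source mixes "more than threefold" with "threefold or
  higher" and reports internally inconsistent bin counts; the class edges
  here are closed on the left so the bins partition, and the edges are
  configurable.
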