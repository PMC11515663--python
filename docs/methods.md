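# Methods

## Problem and approach

Differential gene expression analysis for organisms without a reference
genome or transcriptome conventionally starts with de-novo transcriptome
assembly, which is computationally expensive and error-prone. samlite takes
the alternative route of quantifying expression directly against a reference
**protein** database (of the same or a related species): each RNA-seq read is
assigned to candidate proteins by exact-substring *quasi-mapping* of its
six-frame translations, mapped fragments are counted per protein with a
multi-mapping rescue scheme, and the resulting count matrix is exported for
standard DE tools (DESeq2, edgeR, limma). No base-level alignments are
computed.

## Reference index

The reference proteins are concatenated into one text `C`, with a `$`
separator after every protein (including the last, so every protein's
suffixes are well terminated). Three structures are built over `C`:

* **Suffix array `SA`** — all suffix start positions of `C` in lexicographic
  order (`$` sorts before all amino-acid letters). Constructed by a numpy
  prefix-doubling routine (Manber–Myers), O(n log n); at the intended
  reference sizes (10⁵–10⁷ residues) this is not the bottleneck, and memory
  economy is deliberately not a goal of the plain (non-compressed) suffix
  array.
* **k-mer table `HT`** — maps every `$`-free k-mer of `C` to the maximal
  half-open `SA` row interval of suffixes starting with it. Built in one
  left-to-right sweep of `SA` (rows sharing a k-letter prefix are
  contiguous). Its role is purely to replace the first `k` steps of binary
  search with a hash lookup.
* **Separator bit vector `B`** with rank support — `B[p] = 1` iff
  `C[p] = '$'`. An exclusive prefix-sum array gives
  `rank(p)` = number of separators strictly before `p` in O(1), which is
  exactly the ordinal of the protein containing position `p`. The same array
  maps a whole `SA` interval to its set of proteins.

The index is serialized to a single binary file with a versioned header
recording `k` and the alphabet mode; `HT` and the rank array are rebuilt
deterministically on load, and the byte layout contains no timestamps, so
re-indexing the same input reproduces the file exactly. The k-mer length is
a build-time parameter and mapping always uses the index's `k`.

## Quasi-mapping

Each read is translated in all six reading frames (standard genetic code;
stop codons become `*`, codons containing `N` become `X` — neither symbol
occurs in the index alphabet, so matches implicitly terminate at stops and
ambiguous codons rather than spanning them). For one translation `T` the
scan is greedy and left to right: at position `pos`,

1. look up the k-mer `T[pos:pos+k]` in `HT`; on a miss advance `pos` by 1;
2. on a hit, repeatedly extend the match with `T[pos+k]`, `T[pos+k+1]`, … by
   binary search restricted to the current `SA` interval, until the interval
   empties or `T` ends; let `k'` be the final matched length;
3. credit `k'` to every protein in the final (maximal) interval and jump to
   `pos + k'`.

A protein is reported for the read iff in **some** frame its accumulated
coverage exceeds a threshold expressed as a **percentage of that frame's
translation length** (strict inequality). The threshold is interpreted as a
percentage because useful values like 40–60 could not be absolute residue
counts for 100-bp reads, whose translations are at most 33 residues. Because
`pos` jumps past each match, matches within a frame never overlap and
coverage never exceeds the translation length.

Paired-end mates are mapped independently and their protein sets unioned;
the pair counts as a single fragment downstream. Defaults are `k = 7` with
threshold 40 on the full alphabet, and `k = 11` in reduced-alphabet mode.

### Reduced alphabet

Optionally the index (on ingest) and all translations (at map time) are
projected onto an 11-class amino-acid alphabet —
{K,R,E,D,Q,N} {C} {G} {H} {I,L,V} {M} {F} {Y} {W} {P} {S,T,A} — in which
residues of a class compare equal. Reduction preserves equality, so every
full-alphabet match survives reduction and per-frame coverage can only grow;
the cost is specificity (more incorrect mappings at permissive thresholds).
The class representative is the alphabetically first member of each class,
an arbitrary but fixed choice: only equality of symbols matters anywhere.

## Counting

Counting is per sample and two-pass:

1. **Unique pass.** For each protein `P`, `u_P` = number of fragments
   mapping only to `P`, normalized by protein length:
   `n_P = u_P / |P|`.
2. **Rescue pass.** Each fragment mapping to `m > 1` proteins adds
   `n_P / Σ_Q n_Q` to each of its proteins `P` (the sum over its candidate
   set), or `1/m` to each if the denominator is zero. The `n_P` values are
   frozen at their pass-1 values, so the result is independent of stream
   order.

Each multi-mapping fragment therefore distributes exactly one unit of count,
and `Σ r_P` equals the number of multi-mapping fragments to machine
precision. Note the deliberate unit asymmetry, kept as specified by the
counting scheme: pass-1 contributions are per-residue (length-normalized)
while pass-2 increments are fragment fractions. Final exported abundance is
`n_P + r_P`, written as a proteins × samples TSV; values are fractional by
default, with an optional integer rounding for DE tools that require it.

## Synthetic data generator

The generator emulates a small two-condition RNA-seq experiment and exists
so the whole pipeline is testable without downloads:

* **Proteome** — `n_genes` genes, by default 200, each with
  `isoforms_per_gene` products (default 2). Protein lengths are log-normal
  (median 300 aa, σ = 0.35, floor 80 aa); residues are uniform over the 20
  letters. Additional isoforms are copies of the base protein with 20% of
  positions substituted, so isoforms share ≈80% identity and reads
  multi-map within genes, exercising the rescue pass.
* **Coding sequences** — reverse translation with synonymous codons drawn
  uniformly at random, plus a stop codon; translating frame 0 recovers the
  protein exactly.
* **Expression and DE** — baseline per-transcript means are log-normal
  (σ = 1). A `de_fraction` (default 30%) of genes is differentially
  expressed in condition 2; the fold-change magnitude is drawn from a
  configurable set (default {2, 4}), applied up or down with equal
  probability, and multiplies **only the gene's highest-expressing
  isoform**.
* **Fragments and reads** — a single sequencing-depth scale is calibrated on
  the baseline condition so that a sample yields ≈ `n_fragments` fragments;
  per-transcript fragment counts are then independent Poisson draws around
  expression × length × scale in both conditions. This keeps a DE gene's
  expected count ratio equal to its fold-change (renormalizing per sample
  would compress ratios through the composition effect). Fragment lengths
  are normal (mean 250 bp, sd 25, clipped to the read length and the CDS);
  mate 1 is the fragment's 5' end, mate 2 the reverse complement of its 3'
  end, both 100 bp by default; substitution errors are injected per base
  (default 0.5%). Every fragment's source gene/transcript/protein is
  recorded.

Everything is reproducible byte-for-byte from the config seed.

What the generator does **not** emulate: negative-binomial overdispersion
across replicates (counts are Poisson, so replicate variance is at its
floor), realistic codon usage and amino-acid composition, homology between
different genes, sequence-dependent error and coverage biases, introns/UTRs,
and cross-species references. Passing tests on this fixture therefore show
algorithmic correctness and parameter recovery under the model's own
assumptions, not mapping accuracy against real, diverged proteomes.

## Evaluation metrics

A fragment from gene `g` with product set `M_g` is **correct** if its
reported protein set intersects `M_g`, **incorrect** if it was mapped but
misses `M_g`, and **unmapped** (counted in neither tally) otherwise. When an
ortholog table is supplied, intersection is tested on ortholog-group ids
instead of protein ids, so mapping to an ortholog of a source product counts
as correct. For DE, a gene is correctly predicted if at least one of its
products (or their ortholog group) is predicted DE in the true direction;
precision is over predicted DE genes, recall over truly DE genes. With zero
predictions precision is reported as 0 with a degenerate flag rather than
left undefined.

## Numerical and design choices

* Suffix intervals are half-open, giving a uniform empty representation.
* `$` sorts before all letters; any fixed order would do, but the oracle
  tests require one convention.
* Coverage thresholding uses `100·matched > threshold·|T|` on integers
  scaled by floats — no division, no epsilon.
* When a suffix interval narrows to a single row, extension switches from
  binary search to direct text comparison (same result, hot-path speed).
* Counting keeps `n_P` in double precision; conservation of rescued mass
  holds to 1e-9 per fragment in tests.
* Degenerate inputs: translations shorter than `k` map to nothing; empty
  mapping streams give empty count tables; an empty reference is an error.

## Problem sizes in tests and the acceptance script

Test fixtures use proteomes of up to 200 genes and up to 50,000 fragments
per sample (the fold-change-recovery experiment: 50 single-isoform genes ×
6 samples × 50k fragments), sizes chosen so the full suite runs on a laptop
in about a minute while leaving per-gene depth (~1000 fragments) high enough
that a ±30% per-gene ratio bound is meaningful. Single-isoform genes are
used for that experiment because applying the fold-change to the top isoform
of a multi-isoform gene dilutes the gene-level ratio below the nominal
fold-change — with two expressed isoforms the gene-level change is
structurally smaller than the per-transcript one. The self-mapping
sensitivity fixture keeps the default two isoforms per gene.

## Known limitations

* Sensitivity degrades with evolutionary divergence of the reference faster
  than for alignment-based methods: quasi-mapping needs exact (possibly
  reduced-alphabet) k-mer seeds and exact extensions.
* The greedy left-to-right decomposition is not guaranteed to find the
  maximum-coverage decomposition of a frame.
* Counting is a heuristic rescue, not an EM estimator; highly similar
  references (recent duplications, multi-species databases) will blur
  counts across members.
* DE testing itself is out of scope: the exported matrix is the interface
  to DESeq2 and friends.
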