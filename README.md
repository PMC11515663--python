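# samlite

Assembly-free differential-expression front-end for RNA-seq in non-model
organisms: instead of assembling a transcriptome, **quasi-map** reads
directly against a reference **protein** database (of the same or a related
species) and export a protein-level count matrix ready for DESeq2/edgeR.

It is aimed at expression studies where the goal is to find over- and
under-expressed genes, not to reconstruct transcripts, and where the best
available reference is a protein set.

## Method in brief

* **Index.** Reference proteins are concatenated into a text
  `C = P₁$P₂$…Pₙ$`; over it sit the suffix array `SA`, a hash table `HT`
  mapping every `$`-free k-mer to its `SA` interval, and a separator bit
  vector `B` whose rank function converts a text position to a protein
  ordinal in O(1).
* **Quasi-mapping.** Each read is translated in all six reading frames. A
  frame is scanned greedily: a k-mer hit in `HT` opens an `SA` interval that
  is extended one residue at a time by interval-restricted binary search;
  the final match length k′ is credited to every protein in the interval
  and the scan jumps past the match. A protein is reported if, in any
  frame, its coverage (total matched length) exceeds a percentage threshold
  of the frame's translation length. Defaults: `k = 7`, threshold 40%.
  An optional 11-class reduced amino-acid alphabet (`k = 11`) trades
  specificity for sensitivity to diverged references.
* **Counting.** Per sample: unique fragments give length-normalized counts
  `n_P = u_P/|P|`; each multi-mapping fragment is then rescued, adding
  `n_P/Σ n_Q` to every candidate `P` (even split if all candidates lack
  unique evidence). The export is a proteins × samples TSV.
* **Simulation & scoring.** A built-in generator produces a synthetic
  proteome, reverse-translated coding sequences, and paired-end reads for a
  two-condition design with known DE genes, plus scorers for mapping
  correctness (orthology-aware) and DE precision/recall.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```sh
# 1. simulate a small two-condition experiment (writes FASTQ + truth files)
samlite simulate --n-genes 50 --n-fragments 2000 --seed 1 -o demo

# 2. index the (source) proteome
samlite index demo/proteome.fasta -k 7 -o demo/ref.idx

# 3. quasi-map one sample's read pairs
samlite map demo/ref.idx demo/cond1_rep1_1.fastq.gz demo/cond1_rep1_2.fastq.gz \
    -o demo/cond1_rep1.tsv

# 4. score the mappings against the simulation truth
samlite evaluate demo/cond1_rep1.tsv demo --sample cond1_rep1
```

The evaluate step prints, for this seed:

```
correct	2040
incorrect	0
unmapped	0
correct_fraction	1.0000
```

i.e. all 2040 fragments of the sample were assigned to at least one protein
product of their true source gene — expected when mapping error-prone but
same-species reads back to their own proteome. Counting all six samples into
a matrix:

```sh
samlite quant demo/cond*_rep*.tsv --index demo/ref.idx -o demo/counts.tsv
```

writes a 100 × 6 TSV (`protein` column + one column per sample) whose
entries are final abundances `n_P + r_P`; load it into DESeq2 with
`read.delim("counts.tsv", row.names=1)`.

The same pipeline is available as a library (`samlite.build_index`,
`samlite.map_file`, `samlite.count_sample`, `samlite.simulate_reads`, …).

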