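"""Synthetic proteome and RNA-seq read generation, plus mapping and
differential-expression scorers.

The generator emulates a small two-condition expression experiment: a
proteome of a few hundred genes (optionally with multiple isoforms per gene
sharing high identity, so that multi-mapping occurs), coding sequences
obtained by reverse translation with random synonymous codons, and paired-end
reads drawn from fragments of those coding sequences.  Baseline per-transcript
expression is log-normal; in the second condition a configurable fraction of
genes is differentially expressed, with the fold-change applied to the
gene's highest-expressing isoform only.  Per-transcript fragment counts are
Poisson around the expression-and-length-weighted expectation.  Every
fragment's source is recorded so that mappings and downstream DE calls can be
scored against the truth.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from Bio.Data.CodonTable import standard_dna_table

from .alphabet import AA_LETTERS, reverse_complement
from .io_formats import write_fasta, write_fastq, write_tsv

_QUAL_CHAR = "I"  # constant Q40; the error model is explicit, not quality-driven

_CODONS_OF: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_OF[_aa].append(_codon)
for _aa in _CODONS_OF:
    _CODONS_OF[_aa].sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror a scaled-down low-coverage two-condition study: 100 bp
    paired reads, 250 bp mean fragments, three replicates per condition and
    ~30% of genes differentially expressed.
    """

    n_genes: int = 200
    isoforms_per_gene: int = 2
    mean_protein_length: int = 300
    protein_length_sigma: float = 0.35
    min_protein_length: int = 80
    read_length: int = 100
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 25.0
    error_rate: float = 0.005
    n_fragments: int = 5000
    replicates: int = 3
    de_fraction: float = 0.30
    fold_changes: tuple[float, ...] = (2.0, 4.0)
    expression_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "isoforms_per_gene", "mean_protein_length",
                     "read_length", "n_fragments", "replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length > self.fragment_length_mean:
            raise ValueError("read_length must not exceed mean fragment length")
        if any(fc <= 1.0 for fc in self.fold_changes):
            raise ValueError("fold_changes must all be > 1")

    def echo(self) -> str:
        lines = ["# samlite simulation config"]
        for f in fields(self):
            lines.append(f"{f.name}\t{getattr(self, f.name)}")
        return "\n".join(lines) + "\n"


@dataclass
class Proteome:
    """A synthetic reference proteome and its gene/transcript structure."""

    proteins: list[tuple[str, str]]
    table: pd.DataFrame  # columns: gene_id, transcript_id, protein_id

    @property
    def gene_products(self) -> dict[str, set[str]]:
        """M_g: protein products per gene."""
        out: dict[str, set[str]] = defaultdict(set)
        for row in self.table.itertuples(index=False):
            out[row.gene_id].add(row.protein_id)
        return dict(out)

    def sequence_of(self, protein_id: str) -> str:
        for name, seq in self.proteins:
            if name == protein_id:
                return seq
        raise KeyError(protein_id)


@dataclass
class SimTruth:
    """Ground truth for a simulated read set."""

    read_source: dict[str, tuple[str, str, str, str]]  # read -> (sample, gene, transcript, protein)
    gene_products: dict[str, set[str]]  # M_g
    gene_fold_change: dict[str, float]  # condition-2 multiplier for DE genes
    ortholog_group: Optional[dict[str, str]] = None  # protein -> group id

    def genes_up(self) -> set[str]:
        return {g for g, fc in self.gene_fold_change.items() if fc > 1.0}

    def genes_down(self) -> set[str]:
        return {g for g, fc in self.gene_fold_change.items() if fc < 1.0}


@dataclass
class SimResult:
    """Files and truth produced by one simulation run."""

    config: SimConfig
    proteome: Proteome
    truth: SimTruth
    samples: list[tuple[str, Path, Path]]  # (sample name, mate1, mate2)
    transcript_means: dict[str, dict[str, float]]  # condition -> transcript -> mean


def generate_proteome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Proteome:
    """Draw a random proteome: per gene, a base protein with log-normal
    length and, for additional isoforms, variants sharing >= 80% identity
    (so reads from one isoform multi-map across the gene's products)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    letters = np.frombuffer(AA_LETTERS.encode(), dtype=np.uint8)
    proteins: list[tuple[str, str]] = []
    rows = []
    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        length = int(
            np.clip(
                rng.lognormal(math.log(config.mean_protein_length), config.protein_length_sigma),
                config.min_protein_length,
                4 * config.mean_protein_length,
            )
        )
        base = rng.choice(letters, size=length)
        for iso in range(config.isoforms_per_gene):
            seq = base.copy()
            if iso > 0:
                n_mut = max(1, int(0.2 * length))
                sites = rng.choice(length, size=n_mut, replace=False)
                seq[sites] = rng.choice(letters, size=n_mut)
            protein_id = f"{gene_id}_p{iso + 1}"
            transcript_id = f"{gene_id}_t{iso + 1}"
            proteins.append((protein_id, seq.tobytes().decode("ascii")))
            rows.append((gene_id, transcript_id, protein_id))
    table = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "protein_id"])
    return Proteome(proteins=proteins, table=table)


def reverse_translate(protein: str, seed) -> str:
    """A coding sequence for ``protein`` with synonymous codons drawn at
    random, terminated by a stop codon.  ``seed`` may be an int or a numpy
    Generator.  Translating frame 0 of the result recovers the protein."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    for aa in protein:
        codons = _CODONS_OF.get(aa)
        if not codons:
            raise ValueError(f"cannot reverse-translate symbol {aa!r}")
        parts.append(codons[rng.integers(len(codons))])
    parts.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(parts)


def _assign_de(
    config: SimConfig, proteome: Proteome, baseline: dict[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, float], dict[str, float]]:
    """Pick DE genes and build condition-2 means: the fold-change multiplies
    only the highest-expressing isoform of each chosen gene."""
    genes = sorted(proteome.table["gene_id"].unique())
    n_de = int(round(config.de_fraction * len(genes)))
    de_genes = sorted(rng.choice(genes, size=n_de, replace=False).tolist())
    cond2 = dict(baseline)
    gene_fc: dict[str, float] = {}
    tx_of_gene = proteome.table.groupby("gene_id")["transcript_id"].apply(list)
    for gene in de_genes:
        fc = float(rng.choice(config.fold_changes))
        if rng.random() < 0.5:
            fc = 1.0 / fc
        top_tx = max(tx_of_gene[gene], key=lambda t: baseline[t])
        cond2[top_tx] = baseline[top_tx] * fc
        gene_fc[gene] = fc
    return cond2, gene_fc


def simulate_reads(
    config: SimConfig,
    proteome: Proteome,
    outdir,
    compress: bool = True,
) -> SimResult:
    """Generate paired FASTQ files for ``replicates`` samples in each of two
    conditions, plus the ground truth.

    Mate 1 is the fragment's 5' end on the coding strand; mate 2 is the
    reverse complement of its 3' end.  Substitution errors are injected per
    base at ``error_rate``.  Byte-for-byte reproducible from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    tx_rows = list(proteome.table.itertuples(index=False))
    protein_seq = dict(proteome.proteins)
    cds: dict[str, str] = {}
    for row in tx_rows:
        cds[row.transcript_id] = reverse_translate(protein_seq[row.protein_id], rng)

    baseline = {row.transcript_id: float(rng.lognormal(0.0, config.expression_sigma))
                for row in tx_rows}
    cond2_means, gene_fc = _assign_de(config, proteome, baseline, rng)
    means_by_condition = {"cond1": baseline, "cond2": cond2_means}

    truth_reads: dict[str, tuple[str, str, str, str]] = {}
    samples: list[tuple[str, Path, Path]] = []
    tx_ids = [row.transcript_id for row in tx_rows]
    tx_info = {row.transcript_id: (row.gene_id, row.protein_id) for row in tx_rows}
    ext = ".fastq.gz" if compress else ".fastq"

    # One sequencing-depth scale calibrated on the baseline condition, shared
    # by both conditions: per-transcript counts are then independent Poisson
    # draws and a DE gene's expected count ratio equals its fold-change
    # (condition-2 samples may total slightly more or fewer fragments).
    base_weights = np.array([baseline[t] * len(cds[t]) for t in tx_ids])
    depth_scale = config.n_fragments / base_weights.sum()

    for condition in ("cond1", "cond2"):
        means = means_by_condition[condition]
        expect = depth_scale * np.array([means[t] * len(cds[t]) for t in tx_ids])
        for rep in range(1, config.replicates + 1):
            sample = f"{condition}_rep{rep}"
            counts = rng.poisson(expect)
            records1: list[tuple[str, str, str]] = []
            records2: list[tuple[str, str, str]] = []
            serial = 0
            for t, n_frag in zip(tx_ids, counts):
                if n_frag == 0:
                    continue
                seq = cds[t]
                gene_id, protein_id = tx_info[t]
                L = len(seq)
                frag_lens = np.clip(
                    np.rint(rng.normal(config.fragment_length_mean,
                                       config.fragment_length_sd, size=n_frag)),
                    config.read_length, L,
                ).astype(int)
                starts = rng.integers(0, L - frag_lens + 1)
                for fl, start in zip(frag_lens, starts):
                    rid = f"{sample}:f{serial:07d}"
                    serial += 1
                    m1 = seq[start : start + config.read_length]
                    m2 = reverse_complement(seq[start + fl - config.read_length : start + fl])
                    if config.error_rate > 0.0:
                        m1 = _inject_errors(m1, config.error_rate, rng)
                        m2 = _inject_errors(m2, config.error_rate, rng)
                    qual = _QUAL_CHAR * config.read_length
                    records1.append((rid, m1, qual))
                    records2.append((rid, m2, qual))
                    truth_reads[rid] = (sample, gene_id, t, protein_id)
            p1 = outdir / f"{sample}_1{ext}"
            p2 = outdir / f"{sample}_2{ext}"
            write_fastq(records1, p1)
            write_fastq(records2, p2)
            samples.append((sample, p1, p2))

    truth = SimTruth(
        read_source=truth_reads,
        gene_products=proteome.gene_products,
        gene_fold_change=gene_fc,
    )
    _write_truth_files(config, proteome, truth, outdir)
    return SimResult(
        config=config,
        proteome=proteome,
        truth=truth,
        samples=samples,
        transcript_means=means_by_condition,
    )


_DNA = "ACGT"


def _inject_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    sites = rng.choice(len(read), size=n_err, replace=False)
    chars = list(read)
    for s in sites:
        alternatives = _DNA.replace(chars[s], "")
        chars[s] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _write_truth_files(config: SimConfig, proteome: Proteome, truth: SimTruth, outdir: Path) -> None:
    write_fasta(proteome.proteins, outdir / "proteome.fasta")
    write_tsv(
        [list(row) for row in proteome.table.itertuples(index=False)],
        ["gene_id", "transcript_id", "protein_id"],
        outdir / "gene_to_protein.tsv",
    )
    write_tsv(
        [[rid, *src] for rid, src in sorted(truth.read_source.items())],
        ["read_id", "sample", "gene_id", "transcript_id", "protein_id"],
        outdir / "truth.tsv",
    )
    write_tsv(
        sorted(truth.gene_fold_change.items()),
        ["gene_id", "fold_change"],
        outdir / "de_genes.tsv",
    )
    (outdir / "config.txt").write_text(config.echo(), encoding="utf-8")


def write_ortholog_map(proteome: Proteome, path) -> dict[str, str]:
    """Emit a protein -> ortholog-group table grouping each gene's products
    into one group (a stand-in for a cross-species orthology map)."""
    mapping = {
        row.protein_id: f"OG_{row.gene_id}"
        for row in proteome.table.itertuples(index=False)
    }
    write_tsv(sorted(mapping.items()), ["protein_id", "group_id"], path)
    return mapping


def load_truth(truth_path, gene_table_path, de_path=None) -> SimTruth:
    """Reload a SimTruth from the TSVs written by :func:`simulate_reads`."""
    truth_df = pd.read_csv(truth_path, sep="\t", dtype=str)
    table = pd.read_csv(gene_table_path, sep="\t", dtype=str)
    gene_products: dict[str, set[str]] = defaultdict(set)
    for row in table.itertuples(index=False):
        gene_products[row.gene_id].add(row.protein_id)
    fold_change: dict[str, float] = {}
    if de_path is not None and Path(de_path).exists():
        de = pd.read_csv(de_path, sep="\t")
        fold_change = dict(zip(de["gene_id"].astype(str), de["fold_change"].astype(float)))
    return SimTruth(
        read_source={
            r.read_id: (r.sample, r.gene_id, r.transcript_id, r.protein_id)
            for r in truth_df.itertuples(index=False)
        },
        gene_products=dict(gene_products),
        gene_fold_change=fold_change,
    )


# ----- scoring --------------------------------------------------------------


@dataclass
class MappingScore:
    correct: int
    incorrect: int
    unmapped: int

    @property
    def total(self) -> int:
        return self.correct + self.incorrect + self.unmapped

    @property
    def correct_fraction(self) -> float:
        return self.correct / self.total if self.total else 0.0

    @property
    def incorrect_fraction(self) -> float:
        return self.incorrect / self.total if self.total else 0.0


def _group_sets(
    proteins: Iterable[str], orthologs: Optional[Mapping[str, str]]
) -> set[str]:
    """Protein names, or their ortholog-group ids when a map is supplied."""
    if orthologs is None:
        return set(proteins)
    return {orthologs.get(p, p) for p in proteins}


def score_mappings(
    mappings: Iterable[tuple[str, Sequence[str]]],
    truth: SimTruth,
    orthologs: Optional[Mapping[str, str]] = None,
    read_ids: Optional[Iterable[str]] = None,
) -> MappingScore:
    """Classify each fragment as correctly mapped (reported set intersects
    the source gene's products M_g, or their ortholog groups), incorrectly
    mapped, or unmapped (no mapping reported; counted in neither tally's
    accuracy but reported).

    ``read_ids`` restricts the universe (e.g. to one sample); by default all
    reads in the truth are considered, and any read without a mapping record
    counts as unmapped.
    """
    universe = set(read_ids) if read_ids is not None else set(truth.read_source)
    correct = incorrect = 0
    seen: set[str] = set()
    for read_id, proteins in mappings:
        if read_id not in truth.read_source:
            raise ValueError(f"unknown read id {read_id!r}")
        if read_id in seen:
            raise ValueError(f"duplicate mapping record for {read_id!r}")
        seen.add(read_id)
        if not proteins:
            continue
        gene = truth.read_source[read_id][1]
        target = _group_sets(truth.gene_products[gene], orthologs)
        if _group_sets(proteins, orthologs) & target:
            correct += 1
        else:
            incorrect += 1
    outside = seen - universe
    if outside:
        raise ValueError(
            f"mapping stream contains reads outside the stated universe, "
            f"e.g. {sorted(outside)[0]!r}"
        )
    unmapped = len(universe) - (correct + incorrect)
    return MappingScore(correct=correct, incorrect=incorrect, unmapped=unmapped)


@dataclass
class DEScore:
    precision: float
    recall: float
    n_true: int
    n_predicted: int
    degenerate: bool = False  # no predictions at all; precision reported as 0


def score_de(
    predicted_up: Iterable[str],
    predicted_down: Iterable[str],
    truth: SimTruth,
    orthologs: Optional[Mapping[str, str]] = None,
) -> DEScore:
    """Gene-level precision and recall of direction-labelled DE predictions
    over proteins.

    A gene is predicted up (down) if at least one of its products — or a
    member of their ortholog groups — is in the corresponding predicted set;
    a true DE gene is recovered if it is predicted in its true direction.
    """
    up_groups = _group_sets(predicted_up, orthologs)
    down_groups = _group_sets(predicted_down, orthologs)
    true_up = truth.genes_up()
    true_down = truth.genes_down()
    predicted_genes: dict[str, set[str]] = {}
    for gene, products in truth.gene_products.items():
        target = _group_sets(products, orthologs)
        directions = set()
        if target & up_groups:
            directions.add("up")
        if target & down_groups:
            directions.add("down")
        if directions:
            predicted_genes[gene] = directions
    tp = sum(
        1
        for gene, dirs in predicted_genes.items()
        if (gene in true_up and "up" in dirs) or (gene in true_down and "down" in dirs)
    )
    n_pred = len(predicted_genes)
    n_true = len(true_up) + len(true_down)
    if n_pred == 0:
        return DEScore(precision=0.0, recall=0.0, n_true=n_true, n_predicted=0,
                       degenerate=True)
    return DEScore(
        precision=tp / n_pred,
        recall=tp / n_true if n_true else 0.0,
        n_true=n_true,
        n_predicted=n_pred,
    )
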