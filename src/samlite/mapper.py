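"""Quasi-mapping of reads against the protein index.

Each read is translated in all six frames.  Within a frame, positions are
scanned left to right: a k-mer hash hit yields a suffix-array interval that
is extended one residue at a time by interval-restricted binary search until
it empties or the translation ends.  The final match length k' is credited to
every protein in the maximal interval and the scan jumps ahead by k' (or by 1
on a hash miss).  A protein is reported for the read if, in at least one
frame, its accumulated coverage exceeds a percentage threshold of that
frame's translation length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .alphabet import FrameTranslation, six_frames
from .index import ReferenceIndex
from .io_formats import read_fastq


@dataclass(frozen=True)
class ReadMapping:
    """The set of protein ordinals a read (or fragment) was mapped to."""

    read_id: str
    proteins: frozenset[int]

    def names(self, index: ReferenceIndex) -> list[str]:
        return sorted(index.protein_names[p] for p in self.proteins)


@dataclass
class MappingSummary:
    """Tallies accumulated over a mapping run."""

    mapped: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.mapped + self.unmapped


def quasimap_translation(
    T: FrameTranslation | str, index: ReferenceIndex
) -> dict[int, int]:
    """Coverage of one frame translation: protein ordinal -> total matched
    length (amino acids).

    Implements the greedy scan described above.  The translation must already
    be in the index alphabet (reduced if the index is reduced); translations
    shorter than k yield an empty map.
    """
    seq = T.sequence if isinstance(T, FrameTranslation) else T
    k = index.k
    n = len(seq)
    table = index.kmer_table
    tb = index._text_bytes
    sa = index.sa
    coverage: dict[int, int] = {}
    pos = 0
    while pos + k <= n:
        hit = table.get(seq[pos : pos + k])
        if hit is None:
            pos += 1
            continue
        lo, hi = hit
        depth = k
        while pos + depth < n:
            if hi - lo == 1:
                # single suffix left: extend by direct text comparison
                base = sa[lo]
                while pos + depth < n and tb[base + depth] == ord(seq[pos + depth]):
                    depth += 1
                break
            c = ord(seq[pos + depth])
            a, b = lo, hi
            while a < b:
                m = (a + b) // 2
                if tb[sa[m] + depth] < c:
                    a = m + 1
                else:
                    b = m
            start = a
            b = hi
            while a < b:
                m = (a + b) // 2
                if tb[sa[m] + depth] <= c:
                    a = m + 1
                else:
                    b = m
            if start == a:
                break
            lo, hi = start, a
            depth += 1
        for p in index.proteins_of_interval_raw(lo, hi):
            coverage[p] = coverage.get(p, 0) + depth
        pos += depth
    return coverage


def frame_coverages(
    read: str, index: ReferenceIndex, read_id: str = ""
) -> list[tuple[int, dict[int, int]]]:
    """Per-frame ``(translation_length, coverage_map)`` for all six frames,
    reducing translations first when the index alphabet is reduced."""
    reduce = index.alphabet.reduce if index.alphabet.mode == "reduced" else None
    out = []
    for frame in six_frames(read, read_id=read_id):
        seq = reduce(frame.sequence) if reduce else frame.sequence
        out.append((len(seq), quasimap_translation(seq, index)))
    return out


def map_read(
    read: str, index: ReferenceIndex, threshold_pct: float = 40.0, read_id: str = ""
) -> ReadMapping:
    """Map a single read: a protein is reported iff for some frame its
    coverage exceeds ``threshold_pct`` percent of the frame translation
    length (strict inequality)."""
    if not 0 <= threshold_pct <= 100:
        raise ValueError(f"threshold_pct must be in [0, 100], got {threshold_pct}")
    hits: set[int] = set()
    for tlen, cov in frame_coverages(read, index, read_id=read_id):
        if tlen == 0:
            continue
        bound = threshold_pct * tlen
        for p, matched in cov.items():
            if 100.0 * matched > bound:
                hits.add(p)
    return ReadMapping(read_id=read_id, proteins=frozenset(hits))


def map_pair(
    read1: str,
    read2: str,
    index: ReferenceIndex,
    threshold_pct: float = 40.0,
    read_id: str = "",
) -> ReadMapping:
    """Map a read pair as one fragment: the union of the mates' mappings."""
    m1 = map_read(read1, index, threshold_pct, read_id=read_id)
    m2 = map_read(read2, index, threshold_pct, read_id=read_id)
    return ReadMapping(read_id=read_id, proteins=m1.proteins | m2.proteins)


def map_file(
    index: ReferenceIndex,
    reads1,
    reads2=None,
    threshold_pct: float = 40.0,
    summary: Optional[MappingSummary] = None,
) -> Iterator[ReadMapping]:
    """Map a FASTQ file (or a pair of mate files) in input order.

    Yields one :class:`ReadMapping` per mapped fragment; unmapped fragments
    are tallied in ``summary`` but not yielded.  Deterministic given the
    inputs.
    """
    if summary is None:
        summary = MappingSummary()
    if reads2 is None:
        stream: Iterable = ((r.id, r.sequence, None) for r in read_fastq(reads1))
    else:
        def _paired():
            it1 = read_fastq(reads1)
            it2 = read_fastq(reads2)
            for r1, r2 in zip(it1, it2, strict=True):
                yield r1.id, r1.sequence, r2.sequence
        stream = _paired()
    for read_id, seq1, seq2 in stream:
        if seq2 is None:
            mapping = map_read(seq1, index, threshold_pct, read_id=read_id)
        else:
            mapping = map_pair(seq1, seq2, index, threshold_pct, read_id=read_id)
        if mapping.proteins:
            summary.mapped += 1
            yield mapping
        else:
            summary.unmapped += 1


def write_mappings(mappings: Iterable[ReadMapping], index: ReferenceIndex, path) -> MappingSummary:
    """Write a mapping TSV: read_id TAB comma-separated protein names, one
    row per mapped fragment (unmapped fragments are omitted)."""
    summary = MappingSummary()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tproteins\n")
        for m in mappings:
            if not m.proteins:
                summary.unmapped += 1
                continue
            summary.mapped += 1
            fh.write(f"{m.read_id}\t{','.join(m.names(index))}\n")
    return summary


def read_mappings_tsv(path) -> Iterator[tuple[str, list[str]]]:
    """Read back a mapping TSV as ``(read_id, [protein names])`` pairs."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: not a samlite mapping file")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            read_id, names = line.split("\t")
            yield read_id, names.split(",")
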