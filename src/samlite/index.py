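"""Reference protein index: suffix array with k-mer hash acceleration.

The reference proteins are concatenated into a single text ``C`` with a ``$``
separator after every protein (``$`` sorts before all amino-acid letters).
Substring search is by binary search over the suffix array of ``C``; a hash
table mapping every ``$``-free k-mer of ``C`` to its suffix-array interval
restricts each search to a small row range.  A bit vector marking the ``$``
positions, augmented with a precomputed rank (prefix popcount) array, turns a
text position into the ordinal of the protein that contains it in constant
time.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .alphabet import AA_LETTERS, AminoAlphabet, alphabet_for_mode

SEPARATOR = "$"

_MAGIC = b"SAMLITEIDX"
_VERSION = 1


class SuffixInterval(NamedTuple):
    """Half-open range ``[lo, hi)`` of suffix-array rows sharing a prefix."""

    lo: int
    hi: int

    @property
    def empty(self) -> bool:
        return self.lo >= self.hi

    def __len__(self) -> int:
        return max(0, self.hi - self.lo)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber-Myers), O(n log n)."""
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    step = 1
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        rank2[: n - step] = rank[step:]
        order = np.lexsort((rank2, rank))
        r1 = rank[order]
        r2 = rank2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            changed[1:] = (np.diff(r1) != 0) | (np.diff(r2) != 0)
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        step *= 2


@dataclass
class ReferenceIndex:
    """Queryable index over a concatenated protein text.

    Attributes
    ----------
    text : str
        The concatenated text ``C`` (reduced if ``alphabet`` is reduced),
        with a ``$`` after every protein including the last.
    sa : np.ndarray
        Suffix array of ``text``.
    kmer_table : dict
        Maps each ``$``-free k-mer of ``text`` to the maximal
        :class:`SuffixInterval` of suffixes starting with it.
    """

    text: str
    sa: np.ndarray
    kmer_table: dict[str, SuffixInterval]
    k: int
    protein_names: list[str]
    protein_lengths: list[int]
    alphabet: AminoAlphabet
    _text_bytes: bytes = field(init=False, repr=False)
    _rank_before: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._text_bytes = self.text.encode("ascii")
        bits = self.separator_bits
        # rank_before[p] = number of separators strictly before position p
        rank = np.zeros(len(self.text) + 1, dtype=np.int64)
        np.cumsum(bits, out=rank[1:])
        self._rank_before = rank

    # ----- structure views -------------------------------------------------

    @property
    def separator_bits(self) -> np.ndarray:
        """The bit vector ``B``: 1 exactly at ``$`` positions."""
        arr = np.frombuffer(self.text.encode("ascii"), dtype=np.uint8)
        return (arr == ord(SEPARATOR)).astype(np.uint8)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_names)

    def rank_separator(self, pos: int) -> int:
        """Number of ``$`` strictly before text position ``pos``."""
        return int(self._rank_before[pos])

    def protein_of_position(self, pos: int) -> int:
        """Ordinal of the protein containing text position ``pos``."""
        return int(self._rank_before[pos])

    # ----- queries ---------------------------------------------------------

    def lookup_kmer(self, kmer: str) -> Optional[SuffixInterval]:
        """The suffix-array interval of ``kmer``, or None if absent."""
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer query must have length {self.k}, got {len(kmer)}"
            )
        return self.kmer_table.get(kmer)

    def extend_interval(
        self, interval: SuffixInterval, prefix_len: int, next_char: str
    ) -> SuffixInterval:
        """Narrow ``interval`` (all suffixes sharing ``prefix_len`` chars) to
        the maximal subinterval whose suffixes have ``next_char`` at position
        ``prefix_len``.  Binary search restricted to the input interval; may
        return an empty interval."""
        lo, hi = interval
        if lo >= hi:
            return SuffixInterval(lo, lo)
        tb = self._text_bytes
        sa = self.sa
        c = ord(next_char)
        # lower bound: first row with char >= c at depth prefix_len
        a, b = lo, hi
        while a < b:
            m = (a + b) // 2
            if tb[sa[m] + prefix_len] < c:
                a = m + 1
            else:
                b = m
        start = a
        # upper bound: first row with char > c
        b = hi
        while a < b:
            m = (a + b) // 2
            if tb[sa[m] + prefix_len] <= c:
                a = m + 1
            else:
                b = m
        return SuffixInterval(start, a)

    def proteins_of_interval(self, interval: SuffixInterval) -> set[int]:
        """Set of protein ordinals whose substrings occupy ``interval``."""
        lo, hi = interval
        if lo >= hi:
            return set()
        return self.proteins_of_interval_raw(lo, hi)

    def proteins_of_interval_raw(self, lo: int, hi: int) -> set[int]:
        """As :meth:`proteins_of_interval` but on raw bounds (hot path)."""
        rb = self._rank_before
        sa = self.sa
        if hi - lo <= 8:
            return {int(rb[sa[r]]) for r in range(lo, hi)}
        return set(np.unique(rb[sa[lo:hi]]).tolist())

    # ----- serialization ---------------------------------------------------

    def save(self, path) -> None:
        """Write the index to a single binary file (versioned header, name
        table, lengths, text, suffix array).  Deterministic byte layout; the
        k-mer table and rank array are rebuilt on load."""
        names_blob = "\n".join(self.protein_names).encode("utf-8")
        mode_flag = 0 if self.alphabet.mode == "full" else 1
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<HHB", _VERSION, self.k, mode_flag))
            fh.write(struct.pack("<Q", len(self.protein_names)))
            fh.write(struct.pack("<Q", len(names_blob)))
            fh.write(names_blob)
            fh.write(np.asarray(self.protein_lengths, dtype="<u4").tobytes())
            fh.write(struct.pack("<Q", len(self.text)))
            fh.write(self._text_bytes)
            fh.write(self.sa.astype("<i8").tobytes())

    @classmethod
    def load(cls, path) -> "ReferenceIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a samlite index file")
            version, k, mode_flag = struct.unpack("<HHB", fh.read(5))
            if version != _VERSION:
                raise ValueError(f"{path}: unsupported index version {version}")
            (n_prot,) = struct.unpack("<Q", fh.read(8))
            (nb_len,) = struct.unpack("<Q", fh.read(8))
            names = fh.read(nb_len).decode("utf-8").split("\n") if nb_len else []
            lengths = np.frombuffer(fh.read(4 * n_prot), dtype="<u4").tolist()
            (text_len,) = struct.unpack("<Q", fh.read(8))
            text = fh.read(text_len).decode("ascii")
            sa = np.frombuffer(fh.read(8 * text_len), dtype="<i8").astype(np.int64)
        alphabet = alphabet_for_mode("full" if mode_flag == 0 else "reduced")
        kmer_table = _build_kmer_table(text, sa, k)
        return cls(
            text=text,
            sa=sa,
            kmer_table=kmer_table,
            k=k,
            protein_names=names,
            protein_lengths=[int(x) for x in lengths],
            alphabet=alphabet,
        )


def _next_separator(text: str) -> np.ndarray:
    """nd[i] = smallest j >= i with text[j] == '$' (text ends with '$')."""
    codes = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    dollars = np.flatnonzero(codes == ord(SEPARATOR))
    idx = np.searchsorted(dollars, np.arange(len(text)), side="left")
    return dollars[idx]


def _build_kmer_table(text: str, sa: np.ndarray, k: int) -> dict[str, SuffixInterval]:
    """One left-to-right sweep of SA grouping rows by their first k chars,
    skipping suffixes whose k-prefix crosses a separator."""
    nd = _next_separator(text)
    n = len(text)
    table: dict[str, SuffixInterval] = {}
    r = 0
    while r < n:
        i = int(sa[r])
        if nd[i] < i + k:
            r += 1
            continue
        key = text[i : i + k]
        start = r
        r += 1
        while r < n:
            j = int(sa[r])
            if nd[j] >= j + k and text[j : j + k] == key:
                r += 1
            else:
                break
        table[key] = SuffixInterval(start, r)
    return table


def build_index(
    proteins: Iterable[tuple[str, str]],
    k: int = 7,
    alphabet: Optional[AminoAlphabet] = None,
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from ``(name, sequence)`` pairs.

    Sequences are validated against the 20 standard letters and, if
    ``alphabet`` is reduced, reduced on ingest so that all downstream matching
    happens in the reduced space.
    """
    from .alphabet import full_alphabet

    if alphabet is None:
        alphabet = full_alphabet()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    names: list[str] = []
    lengths: list[int] = []
    parts: list[str] = []
    valid = set(AA_LETTERS)
    seen: set[str] = set()
    for name, seq in proteins:
        if name in seen:
            raise ValueError(f"duplicate protein name: {name!r}")
        seen.add(name)
        if not seq:
            raise ValueError(f"protein {name!r} has an empty sequence")
        bad = set(seq.upper()) - valid
        if bad:
            raise ValueError(
                f"protein {name!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )
        names.append(name)
        lengths.append(len(seq))
        parts.append(alphabet.reduce(seq.upper()))
        parts.append(SEPARATOR)
    if not names:
        raise ValueError("empty protein list")
    text = "".join(parts)
    codes = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    sa = _suffix_array(codes)
    kmer_table = _build_kmer_table(text, sa, k)
    return ReferenceIndex(
        text=text,
        sa=sa,
        kmer_table=kmer_table,
        k=k,
        protein_names=names,
        protein_lengths=lengths,
        alphabet=alphabet,
    )
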