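"""Six-frame translation and amino-acid alphabet handling.

Reads are nucleotide sequences but the reference is a protein database, so
every read is rendered in all six reading frames (three forward offsets and
three on the reverse complement) before matching.  Matching can optionally be
done on a reduced amino-acid alphabet in which biochemically similar residues
are collapsed into equivalence classes, trading specificity for seed
sensitivity against diverged references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data.CodonTable import standard_dna_table

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
UNKNOWN = "X"

#: The 11 equivalence classes of the reduced alphabet (as used by DIAMOND's
#: seed alphabet): residues within a class are treated as equal.
REDUCED_CLASSES = (
    "KREDQN",
    "C",
    "G",
    "H",
    "ILV",
    "M",
    "F",
    "Y",
    "W",
    "P",
    "STA",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codon_map() -> dict[str, str]:
    table = dict(standard_dna_table.forward_table)
    for codon in standard_dna_table.stop_codons:
        table[codon] = STOP
    return table


_CODONS = _codon_map()


@dataclass(frozen=True)
class AminoAlphabet:
    """An amino-acid alphabet, either the full 20 letters or the 11-class
    reduced one.

    ``class_of`` maps each of the 20 standard letters to the canonical
    representative of its class (the alphabetically first member); in full
    mode it is the identity.  ``*`` and ``X`` are never class members and
    always map to themselves.
    """

    mode: str
    class_of: Mapping[str, str]
    _table: dict[int, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("full", "reduced"):
            raise ValueError(f"unknown alphabet mode: {self.mode!r}")
        if set(self.class_of) != set(AA_LETTERS):
            raise ValueError("class_of must cover exactly the 20 standard letters")
        object.__setattr__(self, "_table", str.maketrans(dict(self.class_of)))

    def reduce(self, seq: str) -> str:
        """Map every letter of ``seq`` to its class representative.

        ``*`` (stop) and ``X`` (unknown) pass through unchanged.  Idempotent
        and length-preserving.
        """
        return seq.translate(self._table)

    @property
    def letters(self) -> frozenset[str]:
        """The canonical symbols of this alphabet."""
        return frozenset(self.class_of.values())


def full_alphabet() -> AminoAlphabet:
    """The identity alphabet over the 20 standard amino-acid letters."""
    return AminoAlphabet(mode="full", class_of={a: a for a in AA_LETTERS})


def reduced_alphabet() -> AminoAlphabet:
    """The 11-class reduced alphabet.

    Each letter maps to the alphabetically first member of its class, e.g.
    I, L and V all map to I, and S, T and A all map to A.
    """
    class_of: dict[str, str] = {}
    for cls in REDUCED_CLASSES:
        rep = min(cls)
        for letter in cls:
            class_of[letter] = rep
    return AminoAlphabet(mode="reduced", class_of=class_of)


def alphabet_for_mode(mode: str) -> AminoAlphabet:
    if mode == "full":
        return full_alphabet()
    if mode == "reduced":
        return reduced_alphabet()
    raise ValueError(f"unknown alphabet mode: {mode!r}")


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six reading-frame translations of a read.

    Frames 0-2 are the forward strand at offsets 0, 1, 2; frames 3-5 are the
    reverse complement at offsets 0, 1, 2.  ``sequence`` is over the 20
    amino-acid letters plus ``*`` (stop codon) and ``X`` (codon containing an
    ambiguous base).
    """

    frame_id: int
    sequence: str
    read_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_dna(dna: str) -> str:
    up = dna.upper()
    for pos, ch in enumerate(up):
        if ch not in "ACGTN":
            raise ValueError(
                f"non-IUPAC nucleotide {dna[pos]!r} at position {pos}"
            )
    return up


def reverse_complement(dna: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (case-folded)."""
    return _validate_dna(dna).translate(_COMPLEMENT)[::-1]


def translate_frame(dna: str, frame_id: int, read_id: str = "") -> FrameTranslation:
    """Translate one reading frame of ``dna`` with the standard genetic code.

    Stop codons become ``*``; any codon containing N becomes ``X``.  Frames
    3-5 translate the reverse complement at offsets 0-2.
    """
    if not 0 <= frame_id <= 5:
        raise ValueError(f"frame_id must be in 0..5, got {frame_id}")
    seq = _validate_dna(dna)
    if frame_id >= 3:
        seq = seq.translate(_COMPLEMENT)[::-1]
    offset = frame_id % 3
    codons = _CODONS
    aa = []
    for i in range(offset, len(seq) - 2, 3):
        aa.append(codons.get(seq[i : i + 3], UNKNOWN))
    return FrameTranslation(frame_id=frame_id, sequence="".join(aa), read_id=read_id)


def six_frames(dna: str, read_id: str = "") -> list[FrameTranslation]:
    """All six frame translations, frame_ids 0..5 in order."""
    seq = _validate_dna(dna)
    rc = seq.translate(_COMPLEMENT)[::-1]
    codons = _CODONS
    out = []
    for frame_id in range(6):
        strand = seq if frame_id < 3 else rc
        offset = frame_id % 3
        aa = "".join(
            codons.get(strand[i : i + 3], UNKNOWN)
            for i in range(offset, len(strand) - 2, 3)
        )
        out.append(FrameTranslation(frame_id=frame_id, sequence=aa, read_id=read_id))
    return out


def reduce_sequence(seq: str, alphabet: AminoAlphabet) -> str:
    """Replace each residue of ``seq`` by its class representative under
    ``alphabet``; ``*`` and ``X`` are passed through."""
    return alphabet.reduce(seq)
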