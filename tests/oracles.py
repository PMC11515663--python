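"""Brute-force reference implementations used only to check the real ones.

Everything here is deliberately naive (quadratic sorts, linear scans) and
shares no code with the package.
"""

from __future__ import annotations

SEP = "$"


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_kmer_intervals(text: str, k: int) -> dict[str, tuple[int, int]]:
    """k-mer -> (lo, hi) over the naive suffix array, excluding separator-
    crossing k-mers."""
    sa = naive_suffix_array(text)
    table: dict[str, tuple[int, int]] = {}
    for row, pos in enumerate(sa):
        kmer = text[pos : pos + k]
        if len(kmer) < k or SEP in kmer:
            continue
        lo, hi = table.get(kmer, (row, row))
        table[kmer] = (min(lo, row), max(hi, row + 1))
    return table


def naive_rank(text: str, pos: int) -> int:
    """Separators strictly before position pos."""
    return text[:pos].count(SEP)


def naive_occurrences(proteins: list[str], query: str) -> set[int]:
    """Ordinals of proteins containing query as a substring."""
    return {i for i, p in enumerate(proteins) if query in p}


def longest_occurring_prefix(proteins: list[str], query: str) -> int:
    """Length of the longest prefix of query occurring in some protein."""
    length = 0
    for end in range(1, len(query) + 1):
        if naive_occurrences(proteins, query[:end]):
            length = end
        else:
            break
    return length


def greedy_mem_coverage(proteins: list[str], T: str, k: int) -> dict[int, int]:
    """Greedy left-to-right decomposition: at each position take the longest
    prefix (>= k) of the remaining translation occurring in the reference,
    credit its length to every protein containing it, and jump past it;
    otherwise advance one position."""
    coverage: dict[int, int] = {}
    pos = 0
    while pos + k <= len(T):
        length = longest_occurring_prefix(proteins, T[pos:])
        if length >= k:
            for p in naive_occurrences(proteins, T[pos : pos + length]):
                coverage[p] = coverage.get(p, 0) + length
            pos += length
        else:
            pos += 1
    return coverage
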