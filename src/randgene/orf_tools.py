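"""ORF discovery and mutational designs for protein-vs-RNA dissection.

A random gene can act through its protein product or through its RNA.
Three designs tease the two apart:

* knocking out a start codon with the fewest possible nucleotide changes
  (protein gone, RNA almost untouched);
* maximal synonymous recoding of an ORF (protein identical, RNA-level
  features maximally disrupted);
* deleting a 3' fraction of the sequence.

ORF discovery is forward-strand only (library inserts are
orientation-fixed by the expression cassette) and admits the bacterial
alternative starts TTG and GTG, which initiate with Met regardless of the
codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import FrozenSet

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "DEFAULT_STARTS",
    "Orf",
    "find_orfs",
    "translate_orf",
    "design_start_mutation",
    "synonymous_recode",
    "truncate_3prime",
]

DEFAULT_STARTS: FrozenSet[str] = frozenset({"ATG", "TTG", "GTG"})
_STOPS = frozenset(standard_dna_table.stop_codons)
_FORWARD = standard_dna_table.forward_table

#: synonymous codon families of the standard genetic code
_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _FORWARD.items():
    _SYNONYMS.setdefault(_aa, ())
for _codon, _aa in sorted(_FORWARD.items()):
    _SYNONYMS[_aa] = _SYNONYMS[_aa] + (_codon,)

_PURINES = frozenset("AG")
_ALL_CODONS = tuple("".join(b) for b in product("ACGT", repeat=3))


def _is_transition(x: str, y: str) -> bool:
    return x != y and (x in _PURINES) == (y in _PURINES)


@dataclass(frozen=True)
class Orf:
    """A located open reading frame (0-based half-open coordinates).

    ``end`` points one past the stop codon; ``protein`` excludes the stop
    and begins with Met regardless of the start codon used.
    """

    start: int
    end: int
    start_codon: str
    protein: str

    def __post_init__(self) -> None:
        length = self.end - self.start
        if length % 3 != 0 or length < 6:
            raise ValueError("ORF span must be a multiple of 3 and >= 6 nt")
        if len(self.protein) != length // 3 - 1:
            raise ValueError("protein length inconsistent with coordinates")
        if not self.protein.startswith("M"):
            raise ValueError("translation must initiate as Met")


def translate_orf(seq: str, start: int, end: int) -> str:
    """Translate codons in [start, end), initiator as Met, stop dropped."""
    residues = ["M"]
    for i in range(start + 3, end - 3, 3):
        residues.append(_FORWARD[seq[i: i + 3]])
    return "".join(residues)


def find_orfs(
    seq: str,
    starts: FrozenSet[str] = DEFAULT_STARTS,
    min_aa: int = 0,
) -> list[Orf]:
    """All forward-strand ORFs from an allowed start to the first in-frame stop.

    All three frames are scanned; nested ORFs sharing a stop are each
    reported. Proteins shorter than ``min_aa`` residues are dropped.
    Result is sorted by start position (ties by end).
    """
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must contain only A/C/G/T")
    if min_aa < 0:
        raise ValueError("min_aa must be >= 0")
    orfs: list[Orf] = []
    for frame in range(3):
        stop_after: dict[int, int] = {}
        next_stop = None
        # scan right-to-left so each position knows its first in-frame stop
        for pos in range(frame + 3 * ((len(seq) - frame) // 3) - 3, frame - 1, -3):
            codon = seq[pos: pos + 3]
            if codon in _STOPS:
                next_stop = pos
            stop_after[pos] = next_stop
        for pos, stop in stop_after.items():
            codon = seq[pos: pos + 3]
            if codon in starts and stop is not None and stop > pos:
                protein = translate_orf(seq, pos, stop + 3)
                if len(protein) >= min_aa:
                    orfs.append(
                        Orf(start=pos, end=stop + 3, start_codon=codon, protein=protein)
                    )
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def design_start_mutation(
    seq: str, orf: Orf, starts: FrozenSet[str] = DEFAULT_STARTS
) -> str:
    """Knock out an ORF's start codon with the minimal nucleotide edit.

    The replacement codon (a) is not in the allowed start set, (b) differs
    from the original by the fewest possible nucleotides, and (c) is not a
    stop codon. Ties are broken deterministically: prefer fewer
    transversions (transitions are the milder edit), then the
    lexicographically smallest codon.
    """
    _check_orf_in_seq(seq, orf)
    original = seq[orf.start: orf.start + 3]
    candidates = []
    for codon in _ALL_CODONS:
        if codon == original or codon in starts or codon in _STOPS:
            continue
        subs = sum(x != y for x, y in zip(original, codon))
        transversions = sum(
            1 for x, y in zip(original, codon) if x != y and not _is_transition(x, y)
        )
        candidates.append((subs, transversions, codon))
    if not candidates:
        raise ValueError("no qualifying replacement codon")
    _, _, best = min(candidates)
    return seq[: orf.start] + best + seq[orf.start + 3:]


def _check_orf_in_seq(seq: str, orf: Orf) -> None:
    if orf.end > len(seq) or orf.start < 0:
        raise ValueError("ORF coordinates outside the sequence")
    if (orf.end - orf.start) % 3 != 0:
        raise ValueError("frame-broken ORF")
    if seq[orf.start: orf.start + 3] != orf.start_codon:
        raise ValueError("ORF start codon does not match the sequence")
    if seq[orf.end - 3: orf.end] not in _STOPS:
        raise ValueError("ORF does not end in a stop codon")


def _max_diff_synonym(codon: str) -> str:
    """The synonymous codon maximizing nucleotide differences (tie: smallest)."""
    aa = _FORWARD[codon]
    best = max(
        _SYNONYMS[aa],
        key=lambda c: (sum(x != y for x, y in zip(codon, c)), *[-ord(ch) for ch in c]),
    )
    return best


def _max_diff_stop(codon: str) -> str:
    return max(
        _STOPS,
        key=lambda c: (sum(x != y for x, y in zip(codon, c)), *[-ord(ch) for ch in c]),
    )


def synonymous_recode(
    seq: str, orf: Orf, recode_stop: bool = False
) -> tuple[str, int]:
    """Maximally recode an ORF without changing its protein.

    Every codon after the start is replaced by the synonymous codon with
    the most nucleotide differences from the original (ties break to the
    lexicographically smallest). The start codon is left untouched (it
    sets initiation), Met and Trp codons are necessarily unchanged, and
    the stop is recoded to another stop only when ``recode_stop`` is set.
    Returns the recoded sequence and the total substitution count.
    """
    _check_orf_in_seq(seq, orf)
    pieces = [seq[: orf.start], seq[orf.start: orf.start + 3]]
    n_subs = 0
    for i in range(orf.start + 3, orf.end - 3, 3):
        codon = seq[i: i + 3]
        new = _max_diff_synonym(codon)
        n_subs += sum(x != y for x, y in zip(codon, new))
        pieces.append(new)
    stop = seq[orf.end - 3: orf.end]
    if recode_stop:
        new_stop = _max_diff_stop(stop)
        n_subs += sum(x != y for x, y in zip(stop, new_stop))
        pieces.append(new_stop)
    else:
        pieces.append(stop)
    pieces.append(seq[orf.end:])
    return "".join(pieces), n_subs


def truncate_3prime(seq: str, fraction: float) -> str:
    """Remove the trailing ``floor(fraction * len(seq))`` nucleotides."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0,1)")
    drop = int(fraction * len(seq))
    if drop >= len(seq):
        raise ValueError("truncation would remove the whole sequence")
    return seq[: len(seq) - drop] if drop else seq
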