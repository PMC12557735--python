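"""Exact combinatorics of degenerate-codon library designs.

A degenerate codon is written as three IUPAC nucleotide codes (e.g. ``NNB``,
``NYN``). Synthesis with equimolar base mixes at each position makes every
concrete codon in the expansion equally likely, so the amino-acid composition
of a library, its stop-codon load, and the probability that an insert of
``n_codons`` random codons stays in frame are all closed-form quantities.
This module computes them exactly under the standard genetic code (the host
is *E. coli*; translation tables 1 and 11 agree for this purpose).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "IUPAC_DNA",
    "KYTE_DOOLITTLE",
    "STOP",
    "DegenerateScheme",
    "AminoAcidDistribution",
    "expand_degenerate_codon",
    "scheme_amino_acid_distribution",
    "encodable_amino_acids",
    "intact_orf_probability",
    "expected_mean_hydrophobicity",
]

#: IUPAC nucleotide codes mapped to the concrete bases they stand for.
IUPAC_DNA: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Symbol used for translational stop in distributions.
STOP = "*"

_STOP_CODONS = frozenset(standard_dna_table.stop_codons)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _translate_codon(codon: str) -> str:
    if codon in _STOP_CODONS:
        return STOP
    return standard_dna_table.forward_table[codon]


def expand_degenerate_codon(pattern: str) -> tuple[str, ...]:
    """Expand a 3-symbol IUPAC pattern into its concrete codons, sorted.

    Raises ``ValueError`` naming the offending symbol if the pattern
    contains anything outside the 15 IUPAC nucleotide codes, or is not
    exactly three symbols long.
    """
    pattern = str(pattern)
    if len(pattern) != 3:
        raise ValueError(f"degenerate codon must have 3 symbols, got {pattern!r}")
    for sym in pattern:
        if sym.upper() not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC nucleotide symbol {sym!r} in {pattern!r}")
    sets = [IUPAC_DNA[s.upper()] for s in pattern]
    return tuple(sorted("".join(bases) for bases in product(*sets)))


@dataclass(frozen=True)
class DegenerateScheme:
    """A library design: one degenerate codon pattern repeated ``n_codons`` times.

    Parameters
    ----------
    name : short label, e.g. ``"NNB"``.
    pattern : three IUPAC symbols, one per codon position.
    n_codons : number of random codons per insert (default 50, i.e. a
        150-nt random region).
    """

    name: str
    pattern: str
    n_codons: int = 50

    def __post_init__(self) -> None:
        codons = expand_degenerate_codon(self.pattern)  # validates symbols
        degeneracy = 1
        for sym in self.pattern:
            degeneracy *= len(IUPAC_DNA[sym.upper()])
        if len(codons) != degeneracy:
            raise AssertionError("codon expansion size mismatch")  # pragma: no cover
        if self.n_codons < 1:
            raise ValueError(f"n_codons must be >= 1, got {self.n_codons}")

    @property
    def codons(self) -> tuple[str, ...]:
        return expand_degenerate_codon(self.pattern)

    @property
    def insert_length(self) -> int:
        """Length of the random region in nucleotides."""
        return 3 * self.n_codons


@dataclass(frozen=True)
class AminoAcidDistribution:
    """Probabilities of the 20 amino acids plus stop (``*``) under a scheme."""

    probabilities: Mapping[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        for aa, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability of {aa!r} out of [0,1]: {p}")

    @property
    def stop_probability(self) -> float:
        return self.probabilities.get(STOP, 0.0)

    def conditioned_on_nonstop(self) -> "AminoAcidDistribution":
        """Distribution over amino acids only, renormalized."""
        p_stop = self.stop_probability
        if p_stop >= 1.0:
            raise ValueError("scheme encodes only stop codons")
        probs = {
            aa: p / (1.0 - p_stop)
            for aa, p in self.probabilities.items()
            if aa != STOP
        }
        return AminoAcidDistribution(probs)

    def to_tsv(self, path) -> None:
        """Write (amino_acid, probability) rows as TSV."""
        with open(path, "w") as fh:
            fh.write("amino_acid\tprobability\n")
            for aa in sorted(self.probabilities):
                fh.write(f"{aa}\t{self.probabilities[aa]:.12g}\n")


def scheme_amino_acid_distribution(scheme: DegenerateScheme) -> AminoAcidDistribution:
    """Amino-acid (and stop) probabilities under uniform codon sampling.

    Each concrete codon in the expansion has probability equal to the
    product of the per-position base probabilities (equimolar degenerate
    synthesis), which for IUPAC patterns is uniform over the expanded set.
    """
    codons = scheme.codons
    per_position = [1.0 / len(IUPAC_DNA[s.upper()]) for s in scheme.pattern]
    p_codon = per_position[0] * per_position[1] * per_position[2]
    probs: dict[str, float] = {aa: 0.0 for aa in AMINO_ACIDS}
    probs[STOP] = 0.0
    for codon in codons:
        probs[_translate_codon(codon)] += p_codon
    return AminoAcidDistribution(probs)


def encodable_amino_acids(scheme: DegenerateScheme) -> frozenset[str]:
    """Amino acids with nonzero probability under the scheme; stop excluded."""
    dist = scheme_amino_acid_distribution(scheme)
    return frozenset(aa for aa, p in dist.probabilities.items() if p > 0 and aa != STOP)


def intact_orf_probability(scheme: DegenerateScheme, n_codons: int | None = None) -> float:
    """Probability that ``n_codons`` independent draws contain no stop codon.

    Defaults to the scheme's own ``n_codons``; equals
    ``(1 - P(stop)) ** n_codons``, with the n=0 empty product being 1.
    """
    if n_codons is None:
        n_codons = scheme.n_codons
    if n_codons < 0:
        raise ValueError("n_codons must be >= 0")
    p_stop = scheme_amino_acid_distribution(scheme).stop_probability
    return (1.0 - p_stop) ** n_codons


def expected_mean_hydrophobicity(scheme: DegenerateScheme) -> float:
    """Expected Kyte-Doolittle index of a residue drawn from the scheme.

    The expectation is over the amino-acid distribution conditioned on
    non-stop codons. Rejects schemes that encode only stops.
    """
    dist = scheme_amino_acid_distribution(scheme).conditioned_on_nonstop()
    return sum(p * KYTE_DOOLITTLE[aa] for aa, p in dist.probabilities.items())


def schemes_from_config(entries: Iterable[Mapping]) -> list[DegenerateScheme]:
    """Build schemes from config mappings with keys name/pattern/n_codons."""
    return [
        DegenerateScheme(
            name=e["name"], pattern=e["pattern"], n_codons=int(e.get("n_codons", 50))
        )
        for e in entries
    ]
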