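"""Synthetic-data generator for random-gene selection experiments.

Emulates the three stages of the experimental pipeline that produce the
data the analysis modules consume:

1. **Library synthesis** — inserts of ``ATG`` + *n* degenerate codons +
   ``TAA`` behind constant flanks, with log-normally skewed variant
   abundances and a small fraction of variants carrying 1-2 nt synthesis
   indels inside the random region.
2. **Selection** — a configurable number of rounds (two in the modeled
   screen) in which clones are multinomially sampled from the current
   population, survive phage challenge as a clone-level Bernoulli event
   (functional variants with probability ``p_survive_functional``,
   the rest with the background escape probability ``p_escape``), and the
   surviving plasmids reseed the next round.
3. **Amplicon sequencing** — paired-end reads drawn multinomially from the
   population, with per-base substitution errors and constant quality
   strings, returned with the ground-truth counts so recovery can be
   scored against the planted functional set.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_model import DegenerateScheme

__all__ = [
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
    "LibraryConfig",
    "SelectionConfig",
    "Variant",
    "Library",
    "SelectionExperiment",
    "ReadSet",
    "generate_library",
    "simulate_selection",
    "sequence_reads",
]

# Constant priming regions around the insert (arbitrary fixed sequences
# standing in for the vector context of the expression cassette).
DEFAULT_FLANK5 = "GGAGGTACTAGT"
DEFAULT_FLANK3 = "GGATCCAAACTC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass(frozen=True)
class LibraryConfig:
    """Parameters of library synthesis.

    abundance_skew is the sigma of the log-normal pre-selection abundance
    distribution (0 = equimolar); indel_rate is the per-variant probability
    of carrying one 1-2 nt insertion or deletion inside the random region.
    """

    scheme: DegenerateScheme
    n_variants: int = 5000
    abundance_skew: float = 1.0
    indel_rate: float = 0.05
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0,1]")
        if self.abundance_skew < 0:
            raise ValueError("abundance_skew must be >= 0")
        for label, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if not flank or set(flank) - set("ACGT"):
                raise ValueError(f"{label} must be a nonempty A/C/G/T string")


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the phage-challenge selection.

    Survival is a clone-level Bernoulli event: in the structured-medium
    screen each plated clone either founds a surviving microcolony or not.
    """

    p_survive_functional: float = 0.5
    p_escape: float = 1e-4
    fraction_functional: float = 0.01
    rounds: int = 2
    bottleneck: int = 1_000_000

    def __post_init__(self) -> None:
        for label, p in (
            ("p_survive_functional", self.p_survive_functional),
            ("p_escape", self.p_escape),
            ("fraction_functional", self.fraction_functional),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0,1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")
        # equality is allowed (a neutral, no-enrichment experiment);
        # an escape rate above the functional survival rate is nonsense
        if self.p_survive_functional < self.p_escape:
            raise ValueError(
                "p_survive_functional must be >= p_escape"
            )


@dataclass(frozen=True)
class Variant:
    variant_id: str
    insert: str  # ATG + random region + TAA, possibly indel-bearing
    abundance: float
    has_indel: bool


@dataclass
class Library:
    config: LibraryConfig
    variants: list[Variant]

    def amplicon(self, variant: Variant) -> str:
        return self.config.flank5 + variant.insert + self.config.flank3

    @property
    def abundances(self) -> np.ndarray:
        return np.array([v.abundance for v in self.variants])

    @property
    def inserts(self) -> list[str]:
        return [v.insert for v in self.variants]


@dataclass
class SelectionExperiment:
    """Paired pre/post populations plus the planted ground truth."""

    pre: "VariantTable"
    post: "VariantTable"
    truth: frozenset[str]  # variant_ids planted as functional
    library: Library
    functional_ids: frozenset[str] = field(default=frozenset())
    extinct: bool = False  # no survivors after some round

    def __post_init__(self) -> None:
        if not self.functional_ids:
            self.functional_ids = self.truth


def _draw_insert(rng: np.random.Generator, scheme: DegenerateScheme) -> str:
    codons = scheme.codons
    idx = rng.integers(0, len(codons), size=scheme.n_codons)
    return "ATG" + "".join(codons[i] for i in idx) + "TAA"


def _apply_indel(rng: np.random.Generator, insert: str) -> str:
    """One 1-2 nt insertion or deletion at a random spot in the random region."""
    body = insert[3:-3]
    size = int(rng.integers(1, 3))
    if rng.random() < 0.5 and len(body) > size:  # deletion
        pos = int(rng.integers(0, len(body) - size + 1))
        body = body[:pos] + body[pos + size:]
    else:  # insertion
        pos = int(rng.integers(0, len(body) + 1))
        extra = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
        body = body[:pos] + extra + body[pos:]
    return insert[:3] + body + insert[-3:]


def generate_library(config: LibraryConfig) -> Library:
    """Synthesize a library of unique variant inserts with true abundances.

    Abundances are log-normal draws normalized to sum to 1; reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    inserts: list[str] = []
    indel_flags: list[bool] = []
    while len(inserts) < config.n_variants:
        ins = _draw_insert(rng, config.scheme)
        has_indel = rng.random() < config.indel_rate
        if has_indel:
            ins = _apply_indel(rng, ins)
        if ins in seen:  # vanishingly unlikely; keeps sequences unique
            continue
        seen.add(ins)
        inserts.append(ins)
        indel_flags.append(has_indel)
    if config.abundance_skew > 0:
        weights = rng.lognormal(mean=0.0, sigma=config.abundance_skew, size=config.n_variants)
    else:
        weights = np.ones(config.n_variants)
    abundances = weights / weights.sum()
    width = len(str(config.n_variants))
    variants = [
        Variant(f"v{i:0{width}d}", ins, float(a), flag)
        for i, (ins, a, flag) in enumerate(zip(inserts, abundances, indel_flags))
    ]
    return Library(config=config, variants=variants)


def simulate_selection(
    library: Library,
    sel: SelectionConfig,
    seed: int | None = None,
) -> SelectionExperiment:
    """Run the multi-round clone-sampling / Bernoulli-survival selection.

    Per round, ``bottleneck`` clones are multinomially sampled from the
    current abundance vector; each survives with its variant's survival
    probability; survivors are renormalized to reseed the next round.
    A round with zero survivors yields an explicit empty post table with
    the ``extinct`` flag set.
    """
    from .amplicon_pipeline import VariantTable  # local import avoids a cycle

    cfg = library.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n = len(library.variants)
    n_functional = int(round(sel.fraction_functional * n))
    functional_idx = rng.choice(n, size=n_functional, replace=False)
    is_functional = np.zeros(n, dtype=bool)
    is_functional[functional_idx] = True
    p_survive = np.where(is_functional, sel.p_survive_functional, sel.p_escape)

    freqs = library.abundances
    pre_counts = rng.multinomial(sel.bottleneck, freqs)
    counts = pre_counts
    extinct = False
    for rnd in range(sel.rounds):
        if rnd > 0:
            counts = rng.multinomial(sel.bottleneck, freqs)
        survivors = rng.binomial(counts, p_survive)
        total = int(survivors.sum())
        if total == 0:
            extinct = True
            survivors = np.zeros(n, dtype=int)
            break
        freqs = survivors / total

    post_counts = survivors
    ids = [v.variant_id for v in library.variants]
    truth = frozenset(ids[i] for i in functional_idx)

    def _table(cnts: np.ndarray, label: str) -> VariantTable:
        entries = [
            (library.variants[i].insert, int(c)) for i, c in enumerate(cnts) if c > 0
        ]
        return VariantTable(entries=entries, label=label)

    return SelectionExperiment(
        pre=_table(pre_counts, "pre"),
        post=_table(post_counts, "post"),
        truth=truth,
        library=library,
        extinct=extinct,
    )


@dataclass
class ReadSet:
    """Paired reads with multiplicities, plus ground-truth variant counts.

    ``pairs`` holds unique ``(read1, read2, count)`` triples (identical
    error-free pairs are collapsed); ``true_counts[i]`` is the number of
    read pairs drawn from amplicon ``i``.
    """

    pairs: list[tuple[str, str, int]]
    true_counts: np.ndarray
    read_len: int
    base_quality: int = 35

    @property
    def depth(self) -> int:
        return int(sum(c for _, _, c in self.pairs))

    def quality_string(self) -> str:
        return chr(self.base_quality + 33) * self.read_len

    def write_fastq(self, path1, path2) -> None:
        """Expand to standard paired FASTQ (phred+33, constant quality)."""
        qual = self.quality_string()
        with open(path1, "w") as f1, open(path2, "w") as f2:
            serial = 0
            for r1, r2, count in self.pairs:
                for _ in range(count):
                    name = f"read{serial}"
                    serial += 1
                    f1.write(f"@{name}/1\n{r1}\n+\n{qual[:len(r1)]}\n")
                    f2.write(f"@{name}/2\n{r2}\n+\n{qual[:len(r2)]}\n")

    def true_counts_table(self, library: Library | None = None):
        import pandas as pd

        df = pd.DataFrame({"true_count": self.true_counts})
        if library is not None:
            df.insert(0, "variant_id", [v.variant_id for v in library.variants])
            df.insert(1, "sequence", [v.insert for v in library.variants])
        return df


def sequence_reads(
    amplicons: list[str],
    abundances: np.ndarray,
    depth: int,
    read_len: int = 120,
    substitution_rate: float = 1e-3,
    seed: int = 0,
    base_quality: int = 35,
) -> ReadSet:
    """Simulate paired-end amplicon sequencing.

    Read 1 is the first ``read_len`` bases of the amplicon, read 2 the
    reverse complement of the last ``read_len`` bases, so the pair covers
    the fragment from opposite ends. Pairs are drawn multinomially from
    ``abundances``; substitutions are scattered per base at
    ``substitution_rate``. Rejects geometries in which the mates could not
    overlap by at least 10 nt.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(amplicons) != len(abundances):
        raise ValueError("amplicons and abundances length mismatch")
    max_len = max(len(a) for a in amplicons)
    if 2 * read_len < max_len + 10:
        raise ValueError(
            f"read_len {read_len} too short to merge a {max_len}-nt amplicon "
            "(mates must overlap by >= 10 nt)"
        )
    if read_len > min(len(a) for a in amplicons):
        raise ValueError("read_len exceeds the shortest amplicon")

    rng = np.random.default_rng(seed)
    probs = np.asarray(abundances, dtype=float)
    probs = probs / probs.sum()
    true_counts = rng.multinomial(depth, probs)

    pairs: list[tuple[str, str, int]] = []
    for i, n_i in enumerate(true_counts):
        if n_i == 0:
            continue
        amp = amplicons[i]
        r1_ref = amp[:read_len]
        r2_ref = reverse_complement(amp[-read_len:])
        if substitution_rate <= 0:
            pairs.append((r1_ref, r2_ref, int(n_i)))
            continue
        # choose which reads carry >=1 error by thinning a global error count
        n_err1 = rng.binomial(n_i * read_len, substitution_rate)
        n_err2 = rng.binomial(n_i * read_len, substitution_rate)
        hit1 = rng.integers(0, n_i, size=n_err1)
        hit2 = rng.integers(0, n_i, size=n_err2)
        dirty = np.union1d(hit1, hit2)
        n_clean = int(n_i - len(dirty))
        if n_clean > 0:
            pairs.append((r1_ref, r2_ref, n_clean))
        if len(dirty) == 0:
            continue
        remap = {int(r): j for j, r in enumerate(dirty)}
        a1 = np.tile(np.frombuffer(r1_ref.encode(), dtype=np.uint8), (len(dirty), 1)).copy()
        a2 = np.tile(np.frombuffer(r2_ref.encode(), dtype=np.uint8), (len(dirty), 1)).copy()
        for hits, arr in ((hit1, a1), (hit2, a2)):
            if len(hits) == 0:
                continue
            rows = np.array([remap[int(r)] for r in hits])
            cols = rng.integers(0, read_len, size=len(hits))
            current = arr[rows, cols]
            offsets = rng.integers(1, 4, size=len(hits))
            base_idx = np.searchsorted(_BASES, current)
            arr[rows, cols] = _BASES[(base_idx + offsets) % 4]
        for j in range(len(dirty)):
            pairs.append(
                (a1[j].tobytes().decode(), a2[j].tobytes().decode(), 1)
            )
    return ReadSet(
        pairs=pairs,
        true_counts=true_counts,
        read_len=read_len,
        base_quality=base_quality,
    )


def sequence_experiment_post(
    experiment: SelectionExperiment,
    depth: int = 3_000_000,
    read_len: int = 120,
    substitution_rate: float = 1e-3,
    seed: int = 0,
) -> ReadSet:
    """Sequence the post-selection population of a simulated experiment."""
    lib = experiment.library
    post = experiment.post
    if post.total_reads == 0:
        raise ValueError("post-selection population is empty (selection extinct)")
    amplicons = [lib.config.flank5 + seq + lib.config.flank3 for seq, _ in post.entries]
    abund = np.array([c for _, c in post.entries], dtype=float)
    return sequence_reads(
        amplicons, abund / abund.sum(), depth,
        read_len=read_len, substitution_rate=substitution_rate, seed=seed,
    )
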