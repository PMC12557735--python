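# Methods

## The modeled system

A random-gene selection screen: plasmid libraries express a constant
leader ORF followed by an insert of `ATG` + 50 degenerate codons + `TAA`.
Cells are mixed with phage in structured medium so that each clone
founds a microcolony that either survives infection or does not;
plasmids from survivors are retransformed into naive cells and selected
a second time to purge chromosomal-mutation false positives. Survivor
pools are amplicon-sequenced, and variants whose post-selection
frequency reaches 5×10⁻⁵ are called functional. The package implements
the codon-level combinatorics of the library designs, a generative model
of the screen, the read-analysis pipeline, the mutational designs used
to dissect protein- versus RNA-level function, pool-level protein
characterization, and the two assay readouts.

## Codon model

Degenerate codons are three IUPAC symbols; equimolar degenerate
synthesis makes every concrete codon in the expansion equally likely
(per-position equimolarity implies per-codon uniformity for IUPAC
patterns, which is why the closed-form position-product distribution
equals brute-force enumeration — a relation the tests verify over all
15³ patterns). Translation uses the standard genetic code only: the host
is *E. coli*, and tables 1 and 11 agree codon-by-codon. The stop symbol
`*` is carried inside `AminoAcidDistribution` so conditioning on
non-stop draws is explicit rather than implicit. Expected hydrophobicity
is the Kyte–Doolittle expectation under the non-stop-conditioned
distribution.

## Synthetic-data generator

The generator's defaults are the study conditions the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_codons` | 50 | 150-nt random region |
| `indel_rate` | 0.05 | ~5% of variants carry one 1–2-nt synthesis indel |
| `abundance_skew` | 1.0 | σ of log-normal pre-selection abundances |
| `rounds` | 2 | selection rounds |
| `p_survive_functional` / `p_escape` | 0.5 / 1e-4 | clone-level Bernoulli survival |
| `fraction_functional` | 0.01 | planted functional variants |
| `bottleneck` | 1e6 | clones sampled per round |
| `depth` | 3e6 | merged read pairs (makes the 5×10⁻⁵ cutoff ≈ 150 reads) |
| `read_len` | 120 | per mate; 12-nt constant flanks |
| `substitution_rate` | 1e-3 | per-base sequencing error (typical MiSeq) |

Survival is clone-level Bernoulli, not a continuous growth-rate model:
in the structured-medium screen a plated clone either founds a surviving
microcolony or it does not. Indels are restricted to 1–2 nt inside the
random region — enough to emulate frame-disrupting synthesis errors
without modeling synthesis chemistry. Log-normal abundances are the
standard model for amplification skew. Qualities are constant by
default; the pipeline uses them only to break ties during merge
consensus.

What the generator does **not** emulate: PCR-cycle-explicit
amplification bias, chimeras, quality degradation along reads,
adapter read-through, demultiplexing artifacts, or phage
counter-evolution. Passing recovery tests therefore show that the
pipeline is correct under multinomial sampling with substitution noise
and planted enrichment — not that it is robust to every artifact of
real libraries.

## Read pipeline

Merging reverse-complements read 2 and accepts the longest overlap
≥ `min_overlap` (default 20 nt) whose mismatch fraction is ≤ 0.1; the
consensus takes the higher-quality base, ties favoring read 1. This is a
deliberate simplification of statistical merge tests used by dedicated
mergers; at amplicon geometries (true overlap ≥ 60 nt) false overlap
acceptance is negligible. Flanks are located by best-scoring ungapped
match with ≤ 2 mismatches each; an exact `str.find` hit short-circuits
the Hamming scan.

Identity between sequences is matches / alignment columns of an optimal
end-to-end alignment scored match +1, mismatch −1, gap −2 (open = extend).
This is a documented dialect — centroid-clustering tools differ in edge
handling — and both the threshold and scores are configurable. Greedy
clustering visits sequences in decreasing count order (ties
lexicographic, making runs deterministic) and joins the first centroid
within threshold. Two provably safe fast paths keep clustering exact but
fast:

* *reject*: any alignment has ≥ `ed` non-match columns (unit edit
  distance) and ≤ `len(a)+len(b)` columns, so identity ≤
  1 − ed/(len(a)+len(b)); a k-bounded edit-distance query can reject
  without aligning.
* *accept* (equal lengths `L`, Hamming distance `h`): the ungapped
  alignment is feasible with score `L − 2h`, and for any alignment with
  `g` gap columns and `m` mismatches, score = L + g/2 − 2m − 3g, so
  optimality forces `m + g/2 ≤ h`, hence the optimal alignment's
  identity is ≥ 1 − h/L. If the Hamming bound already clears the
  threshold, the exact aligner would too.

Borderline pairs fall through to the exact aligner, so the clustering
decision always equals the pure-aligner greedy replay (tested).

Hit calling operates on clusters (summed member counts) by default,
making it robust to sequencing errors; a raw-per-sequence mode is
available. The threshold comparison is **inclusive** (≥): at a depth
where threshold × depth is integral, this reproduces an "at least N
reads" cutoff exactly, with N = ⌈threshold × depth⌉. Enrichment tables
floor absent-in-pre frequencies at 1/(pre_total+1) and flag such
clusters as de novo appearances.

## ORF designs

ORF discovery is forward-strand only (inserts are orientation-fixed by
the cassette) over the starts {ATG, TTG, GTG}; rarer initiators
(ATT, CTG) are ignored. Initiation is always Met. Nested ORFs sharing a
stop are each reported.

Start-codon knockout is the package's codification of an otherwise
unspecified mutagenesis: the replacement codon must not be a start or a
stop, must differ by the fewest possible nucleotides, and ties prefer
transitions over transversions, then the lexicographically smallest
codon. This yields the canonical ATG→ACG knockout.

Synonymous recoding replaces every non-start codon with the synonym
maximizing nucleotide differences (ties: lexicographically smallest);
Met and Trp are immutable by synonymy, and the start codon is left
untouched because changing it would alter initiation. Maximal
substitution count is the design objective because the experiment's
intent is to disrupt putative RNA-level features as much as possible
while preserving the protein; rare-codon avoidance is deliberately not
attempted.

## Pool comparison

Residue classes are fixed as nonpolar {A,V,L,I,M,F,W,P,G}, charged
{D,E,K,R} (His counted polar-uncharged), polar-uncharged the remainder.
Cohen's d uses the pooled-SD formula with sample variances and the sign
convention (post − pre)/pooled SD; p-values come from Welch's unequal-
variance t-test, appropriate because pool sizes differ ~66-fold (151 vs
10,000). No multiple-testing correction is applied by default (raw
p-values are the reporting convention); Benjamini–Hochberg is available
behind a flag. The windowed hydrophobicity profile defaults to a 9-residue
window — suited to 51-residue proteins — with the 1.0/1.6 thresholds
marking moderately/strongly hydrophobic stretches; the window is a flag
because no single choice is canonical.

A neutral control draws both pools from the same scheme distribution at
the study's sizes (151 vs 10,000): the sampling SD of d̂ is
√(1/151 + 1/10000) ≈ 0.085, so requiring |d| < 0.2 for all three
(correlated) metrics passes a ~96–97% fraction of replicates; the
validation suite requires ≥ 95/100.

## Assay metrics

Plaque/lawn ratio uses mean (not median) intensity within
caller-supplied masks, matching the default region measurement of
standard image-analysis tools; images may be PNG/TIFF or plain-text
grids. Replicate aggregation reports mean ± sample SD, returning exactly
0 for identical replicates. Adsorption efficiency is exactly
(PFU_control − PFU_sample)/PFU_control × 100; negative values (sample
above control) are reported as-is and flagged, and percent remaining is
defined as 100 − adsorbed. The module is timepoint-agnostic.

## Problem sizes and numerical choices

The full-scale recovery experiment uses 5,000 variants, 1% planted
functional, two rounds at p_survive 0.5 / p_escape 10⁻⁴, and 3×10⁶
reads — roughly 25 s per seed — and the validation suite takes its
median over 5 seeds. Identical reads are collapsed before merging
(multiplicities carried), and merging/extraction are vectorized over
byte matrices; the scalar rules are the reference semantics and the bulk
path is tested against them read-by-read. Coordinates are 0-based
half-open throughout. All RNG flows through `numpy.random.default_rng`
seeds; identical seeds give byte-identical FASTQ output.

## Known limitations

* The identity definition is a dialect; results near the 0.95 boundary
  can differ from other clustering tools.
* The merge rule has no statistical significance test; very short or
  highly repetitive amplicons could merge at a spurious overlap.
* The generator's selection model has no clone-to-clone variance in
  survival probability beyond the functional/escape dichotomy.
* Secondary/tertiary structure prediction, RNA-seq analysis, and phage
  genome variant calling are out of scope.
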