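"""End-to-end study workflows built from the library modules.

Two composite experiments used throughout the docs and the validation
suite:

* :func:`run_recovery` — simulate a full screen (library synthesis, two
  selection rounds with planted functional variants, deep sequencing of
  the survivors) and push the reads through the analysis pipeline,
  scoring the called hit set against the planted ground truth.
* :func:`neutral_control` — draw pre/post protein pools from the *same*
  compositional distribution and check that the pool comparison reports
  no spurious effect sizes at the study's pool sizes (151 vs 10,000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amplicon_pipeline import process_read_set
from .codon_model import DegenerateScheme, scheme_amino_acid_distribution
from .library_synth import (
    LibraryConfig,
    SelectionConfig,
    generate_library,
    sequence_experiment_post,
    simulate_selection,
)
from .protein_props import METRICS, ProteinPool, compare_pools

__all__ = ["RecoveryResult", "run_recovery", "sample_scheme_proteins", "neutral_control"]


@dataclass
class RecoveryResult:
    """Hit-calling performance against the planted functional set."""

    sensitivity: float
    false_discovery_proportion: float
    n_planted: int
    n_hits: int
    n_true_positive: int
    summary: dict


def run_recovery(
    seed: int,
    scheme: DegenerateScheme | None = None,
    n_variants: int = 5000,
    fraction_functional: float = 0.01,
    p_survive_functional: float = 0.5,
    p_escape: float = 1e-4,
    depth: int = 3_000_000,
    identity_threshold: float = 0.95,
    frequency_threshold: float = 5e-5,
) -> RecoveryResult:
    """Simulate one screen and score recovery of the planted variants.

    A called cluster counts as a true positive when its centroid is
    exactly the insert of a planted functional variant (sequencing-error
    sequences collapse into the variant's cluster, so true centroids are
    the unmutated inserts). Sensitivity is over all planted variants;
    the false-discovery proportion is over called hits.
    """
    if scheme is None:
        scheme = DegenerateScheme("NNB", "NNB", n_codons=50)
    lib_cfg = LibraryConfig(
        scheme=scheme, n_variants=n_variants, seed=seed,
    )
    library = generate_library(lib_cfg)
    sel = SelectionConfig(
        p_survive_functional=p_survive_functional,
        p_escape=p_escape,
        fraction_functional=fraction_functional,
    )
    experiment = simulate_selection(library, sel, seed=seed + 10_000)
    read_set = sequence_experiment_post(
        experiment, depth=depth, seed=seed + 20_000
    )
    _, clusters, hit_call, summary = process_read_set(
        read_set,
        flank5=lib_cfg.flank5,
        flank3=lib_cfg.flank3,
        identity_threshold=identity_threshold,
        frequency_threshold=frequency_threshold,
    )
    planted_inserts = {
        v.insert for v in library.variants if v.variant_id in experiment.truth
    }
    hit_centroids = hit_call.hit_centroids
    true_positives = hit_centroids & planted_inserts
    n_hits = len(hit_centroids)
    sensitivity = len(true_positives) / len(planted_inserts)
    fdp = (n_hits - len(true_positives)) / n_hits if n_hits else 0.0
    return RecoveryResult(
        sensitivity=sensitivity,
        false_discovery_proportion=fdp,
        n_planted=len(planted_inserts),
        n_hits=n_hits,
        n_true_positive=len(true_positives),
        summary=summary.as_dict(),
    )


def sample_scheme_proteins(
    scheme: DegenerateScheme,
    n_proteins: int,
    rng: np.random.Generator,
    length: int | None = None,
) -> list[str]:
    """Draw proteins with residues i.i.d. from the scheme's non-stop distribution."""
    if length is None:
        length = scheme.n_codons + 1  # initiator + random codons
    dist = scheme_amino_acid_distribution(scheme).conditioned_on_nonstop()
    residues = sorted(dist.probabilities)
    probs = np.array([dist.probabilities[r] for r in residues])
    probs = probs / probs.sum()
    matrix = rng.choice(len(residues), size=(n_proteins, length), p=probs)
    alphabet = np.frombuffer("".join(residues).encode(), dtype=np.uint8)
    return [alphabet[row].tobytes().decode() for row in matrix]


def neutral_control(
    n_replicates: int = 100,
    seed: int = 0,
    pre_n: int = 10_000,
    post_n: int = 151,
    scheme: DegenerateScheme | None = None,
    effect_threshold: float = 0.2,
) -> dict:
    """Pool comparisons between identically distributed pools.

    Both pools are drawn from the same scheme distribution (no planted
    compositional bias), so every |Cohen's d| should stay below the flag
    threshold in nearly all replicates. Returns the pass fraction and the
    per-replicate maximal |d|.
    """
    if scheme is None:
        scheme = DegenerateScheme("NNB", "NNB", n_codons=50)
    rng = np.random.default_rng(seed)
    max_abs_d = []
    passed = 0
    for _ in range(n_replicates):
        pre = ProteinPool(
            sample_scheme_proteins(scheme, pre_n, rng), label="pre"
        )
        post = ProteinPool(
            sample_scheme_proteins(scheme, post_n, rng), label="post"
        )
        report = compare_pools(pre, post)
        worst = max(abs(report.metrics[m].cohens_d) for m in METRICS)
        max_abs_d.append(worst)
        if worst < effect_threshold:
            passed += 1
    return {
        "n_replicates": n_replicates,
        "passed": passed,
        "pass_fraction": passed / n_replicates,
        "max_abs_d": max_abs_d,
    }
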