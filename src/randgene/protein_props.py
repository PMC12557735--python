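"""Protein-pool characterization: composition, hydrophobicity, effect sizes.

Functional (post-selection) and ancestral (pre-selection) protein pools
are contrasted on three per-protein metrics — nonpolar residue fraction,
charged residue fraction, and mean Kyte-Doolittle hydrophobicity (GRAVY)
— with Cohen's d effect sizes and Welch two-sided t-tests, plus pooled
amino-acid frequency vectors for each pool.

Residue classes (the classification is fixed and documented here):
nonpolar {A,V,L,I,M,F,W,P,G}, charged {D,E,K,R}, polar-uncharged
{S,T,N,Q,C,Y,H}. Histidine is counted polar-uncharged, not charged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .codon_model import AMINO_ACIDS, KYTE_DOOLITTLE

__all__ = [
    "NONPOLAR",
    "CHARGED",
    "POLAR_UNCHARGED",
    "ProteinPool",
    "PoolComparisonReport",
    "pooled_aa_frequencies",
    "residue_class_fractions",
    "gravy",
    "kd_profile",
    "cohens_d",
    "compare_pools",
]

NONPOLAR = frozenset("AVLIMFWPG")
CHARGED = frozenset("DEKR")
POLAR_UNCHARGED = frozenset("STNQCYH")

_AA_SET = frozenset(AMINO_ACIDS)
_KD_BY_CODE = np.zeros(128)
for _aa, _v in KYTE_DOOLITTLE.items():
    _KD_BY_CODE[ord(_aa)] = _v
_NONPOLAR_BY_CODE = np.zeros(128, dtype=bool)
_CHARGED_BY_CODE = np.zeros(128, dtype=bool)
for _aa in NONPOLAR:
    _NONPOLAR_BY_CODE[ord(_aa)] = True
for _aa in CHARGED:
    _CHARGED_BY_CODE[ord(_aa)] = True


def _validate_protein(protein: str) -> None:
    if not protein:
        raise ValueError("protein must be nonempty")
    bad = set(protein) - _AA_SET
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")


@dataclass
class ProteinPool:
    """A pool of protein sequences with an inclusion length floor.

    Proteins shorter than ``min_len`` (default 30 residues, the analysis
    floor for library ORFs) are rejected at construction; use
    :meth:`filtered` to build a pool by dropping them instead.
    """

    proteins: list[str]
    label: str = ""
    min_len: int = 30

    def __post_init__(self) -> None:
        for p in self.proteins:
            _validate_protein(p)
            if len(p) < self.min_len:
                raise ValueError(
                    f"protein of length {len(p)} below min_len={self.min_len}"
                )

    @classmethod
    def filtered(
        cls, proteins: Iterable[str], label: str = "", min_len: int = 30
    ) -> "ProteinPool":
        kept = [p for p in proteins if len(p) >= min_len]
        return cls(proteins=kept, label=label, min_len=min_len)

    def __len__(self) -> int:
        return len(self.proteins)

    def _byte_matrix_rows(self) -> list[np.ndarray]:
        return [np.frombuffer(p.encode(), dtype=np.uint8) for p in self.proteins]

    def metric_values(self, metric: str) -> np.ndarray:
        """Per-protein values of one of the comparison metrics."""
        rows = self._byte_matrix_rows()
        if metric == "nonpolar_fraction":
            return np.array([_NONPOLAR_BY_CODE[r].mean() for r in rows])
        if metric == "charged_fraction":
            return np.array([_CHARGED_BY_CODE[r].mean() for r in rows])
        if metric == "mean_hydrophobicity":
            return np.array([_KD_BY_CODE[r].mean() for r in rows])
        raise ValueError(f"unknown metric {metric!r}")


METRICS = ("nonpolar_fraction", "charged_fraction", "mean_hydrophobicity")


def pooled_aa_frequencies(pool: ProteinPool) -> dict[str, float]:
    """Residue frequencies over all residues of all proteins in the pool."""
    if not pool.proteins:
        raise ValueError("empty pool")
    concat = np.frombuffer("".join(pool.proteins).encode(), dtype=np.uint8)
    counts = np.bincount(concat, minlength=128)
    total = len(concat)
    return {aa: counts[ord(aa)] / total for aa in AMINO_ACIDS}


def residue_class_fractions(protein: str) -> tuple[float, float, float]:
    """(nonpolar, charged, polar-uncharged) fractions; they sum to 1."""
    _validate_protein(protein)
    n = len(protein)
    nonpolar = sum(1 for r in protein if r in NONPOLAR) / n
    charged = sum(1 for r in protein if r in CHARGED) / n
    return nonpolar, charged, 1.0 - nonpolar - charged


def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    _validate_protein(protein)
    return float(np.mean([KYTE_DOOLITTLE[r] for r in protein]))


@dataclass
class KdProfile:
    """Windowed Kyte-Doolittle profile with flagged hydrophobic stretches."""

    values: np.ndarray
    window: int
    moderate_threshold: float = 1.0
    strong_threshold: float = 1.6
    #: window-center indices (0-based, in profile coordinates)
    over_moderate: np.ndarray = field(default=None)
    over_strong: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.over_moderate = np.flatnonzero(self.values > self.moderate_threshold)
        self.over_strong = np.flatnonzero(self.values > self.strong_threshold)


def kd_profile(protein: str, window: int = 9) -> KdProfile:
    """Centered sliding-window mean hydrophobicity.

    Output length is ``len(protein) - window + 1``; positions whose value
    exceeds 1.0 (moderately hydrophobic) and 1.6 (strongly hydrophobic)
    are reported alongside. The window must be odd and no longer than the
    protein.
    """
    _validate_protein(protein)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window > len(protein):
        raise ValueError("window exceeds protein length")
    per_residue = _KD_BY_CODE[np.frombuffer(protein.encode(), dtype=np.uint8)]
    kernel = np.ones(window) / window
    values = np.convolve(per_residue, kernel, mode="valid")
    return KdProfile(values=values, window=window)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d, (mean_a - mean_b) / pooled SD with sample variances."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class MetricComparison:
    metric: str
    pre_mean: float
    post_mean: float
    cohens_d: float  # sign convention: (post - pre) / pooled SD
    p_value: float
    flagged: bool  # |d| > 0.2


@dataclass
class PoolComparisonReport:
    metrics: dict[str, MetricComparison]
    pre_frequencies: Mapping[str, float]
    post_frequencies: Mapping[str, float]
    pre_n: int
    post_n: int
    effect_flag_threshold: float = 0.2

    def as_dict(self) -> dict:
        return {
            "pre_n": self.pre_n,
            "post_n": self.post_n,
            "metrics": {
                m.metric: {
                    "pre_mean": m.pre_mean,
                    "post_mean": m.post_mean,
                    "cohens_d": m.cohens_d,
                    "p_value": m.p_value,
                    "flagged": m.flagged,
                }
                for m in self.metrics.values()
            },
            "pre_frequencies": dict(self.pre_frequencies),
            "post_frequencies": dict(self.post_frequencies),
        }


def compare_pools(
    pre: ProteinPool,
    post: ProteinPool,
    effect_flag_threshold: float = 0.2,
    bh_correct: bool = False,
) -> PoolComparisonReport:
    """Contrast two pools on composition and hydrophobicity metrics.

    For each metric: per-protein values, group means, Cohen's d with sign
    (post - pre) / pooled SD, and a two-sided Welch t-test p-value.
    Metrics with |d| above ``effect_flag_threshold`` are flagged.
    ``bh_correct`` applies a Benjamini-Hochberg adjustment across the
    three p-values (off by default; raw p-values are the convention).
    """
    if not pre.proteins or not post.proteins:
        raise ValueError(
            f"pools must be nonempty after the length filter "
            f"(pre n={len(pre)}, post n={len(post)})"
        )
    comparisons: dict[str, MetricComparison] = {}
    pvals = []
    for metric in METRICS:
        a = post.metric_values(metric)
        b = pre.metric_values(metric)
        d = cohens_d(a, b)
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        comparisons[metric] = MetricComparison(
            metric=metric,
            pre_mean=float(b.mean()),
            post_mean=float(a.mean()),
            cohens_d=d,
            p_value=p,
            flagged=abs(d) > effect_flag_threshold,
        )
        pvals.append(p)
    if bh_correct:
        order = np.argsort(pvals)
        m = len(pvals)
        adjusted = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, pvals[i] * m / (rank_idx + 1))
            adjusted[i] = prev
        for i, metric in enumerate(METRICS):
            comparisons[metric].p_value = float(adjusted[i])
    return PoolComparisonReport(
        metrics=comparisons,
        pre_frequencies=pooled_aa_frequencies(pre),
        post_frequencies=pooled_aa_frequencies(post),
        pre_n=len(pre),
        post_n=len(post),
        effect_flag_threshold=effect_flag_threshold,
    )
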