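"""Read processing and functional-hit calling for selection amplicons.

The analysis mirrors the standard amplicon workflow for selection screens:
paired reads are merged by overlap consensus, inserts are cut out between
the constant flanks, unique inserts are greedily clustered at 95%
identity (highest-count sequence seeds each cluster), and a cluster is
called *functional* when its post-selection frequency reaches the
threshold (default 5e-5, the frequency at which a variant is considered
reproducibly enriched after two selection rounds).

Identity between two sequences is matches / alignment columns of an
end-to-end alignment scored match +1, mismatch -1, gap -2 (a documented
dialect of the greedy-centroid tools it replaces; the threshold and the
scores are configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VariantTable",
    "Cluster",
    "HitCall",
    "sequence_identity",
    "merge_pairs",
    "extract_insert",
    "cluster_sequences",
    "call_functional",
    "enrichment_table",
    "process_read_set",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class VariantTable:
    """Unique sequences with read counts for one population."""

    entries: list[tuple[str, int]]
    label: str = ""
    total_reads: int = 0

    def __post_init__(self) -> None:
        seqs = [s for s, _ in self.entries]
        if len(seqs) != len(set(seqs)):
            raise ValueError("sequences must be unique within a table")
        if any(c < 1 for _, c in self.entries):
            raise ValueError("counts must be >= 1")
        computed = sum(c for _, c in self.entries)
        if self.total_reads and self.total_reads != computed:
            raise ValueError(
                f"total_reads {self.total_reads} != sum of counts {computed}"
            )
        self.total_reads = computed

    @classmethod
    def from_counts(cls, counts: dict[str, int], label: str = "") -> "VariantTable":
        return cls(entries=sorted(counts.items()), label=label)

    def frequencies(self) -> dict[str, float]:
        return {s: c / self.total_reads for s, c in self.entries}


@dataclass
class Cluster:
    """A greedy identity cluster; the centroid is its highest-count member."""

    centroid: str
    members: list[tuple[str, int]]
    total_count: int = 0

    def __post_init__(self) -> None:
        self.total_count = sum(c for _, c in self.members)


@dataclass
class HitCall:
    """Result of frequency-threshold hit calling on clustered counts."""

    hits: list[dict]  # centroid, count, frequency
    total_reads: int
    frequency_threshold: float
    min_reads: int  # implied minimum read count at this depth

    @property
    def hit_centroids(self) -> frozenset[str]:
        return frozenset(h["centroid"] for h in self.hits)


# ---------------------------------------------------------------------------
# pairwise identity

_ALIGNER = None


def _get_aligner(match: float, mismatch: float, gap: float):
    from Bio import Align

    global _ALIGNER
    key = (match, mismatch, gap)
    if _ALIGNER is None or _ALIGNER[0] != key:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap
        aligner.extend_gap_score = gap
        _ALIGNER = (key, aligner)
    return _ALIGNER[1]


def sequence_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Matches / alignment columns under an optimal end-to-end alignment."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aligner = _get_aligner(match, mismatch, gap)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _identity_at_least(a: str, b: str, threshold: float) -> bool:
    """Exact decision ``sequence_identity(a,b) >= threshold`` with fast paths.

    Reject path: unit edit distance ``ed`` bounds identity above by
    ``1 - ed/(len(a)+len(b))`` (any alignment has >= ed non-match columns
    and <= len(a)+len(b) columns). Accept path: for equal lengths the
    optimal alignment's identity is >= the ungapped identity ``1 - h/L``
    (see methods note), so a Hamming distance within budget suffices.
    Borderline cases fall through to the exact aligner.
    """
    import edlib

    la, lb = len(a), len(b)
    max_ed = int(math.floor((1.0 - threshold) * (la + lb)))
    res = edlib.align(a, b, mode="NW", task="distance", k=max_ed)
    if res["editDistance"] == -1:
        return False
    if la == lb and 1.0 - _hamming(a, b) / la >= threshold:
        return True
    return sequence_identity(a, b) >= threshold


# ---------------------------------------------------------------------------
# merging and extraction

def merge_pairs(
    read1: str,
    read2: str,
    qual1: Sequence[int] | None = None,
    qual2: Sequence[int] | None = None,
    min_overlap: int = 20,
    max_mismatch_fraction: float = 0.1,
) -> str | None:
    """Merge a read pair by overlap consensus; ``None`` on failure.

    Read 2 is reverse-complemented, all overlaps >= ``min_overlap`` are
    scanned from longest to shortest, and the longest overlap whose
    mismatch fraction is <= ``max_mismatch_fraction`` is accepted. At
    mismatching positions the consensus takes the base with the higher
    quality score (ties, or no qualities, favor read 1).
    """
    if not read1 or not read2:
        raise ValueError("reads must be nonempty")
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    from .library_synth import reverse_complement

    rc2 = reverse_complement(read2)
    q2r = list(qual2)[::-1] if qual2 is not None else None
    l1, l2 = len(read1), len(rc2)
    for k in range(min(l1, l2), min_overlap - 1, -1):
        tail = read1[l1 - k:]
        head = rc2[:k]
        mismatches = _hamming(tail, head)
        if mismatches / k > max_mismatch_fraction:
            continue
        if mismatches == 0:
            overlap = tail
        else:
            consensus = []
            for i, (x, y) in enumerate(zip(tail, head)):
                if x == y:
                    consensus.append(x)
                else:
                    qx = qual1[l1 - k + i] if qual1 is not None else 0
                    qy = q2r[i] if q2r is not None else 0
                    consensus.append(y if qy > qx else x)
            overlap = "".join(consensus)
        return read1[: l1 - k] + overlap + rc2[k:]
    return None


def _best_ungapped_match(seq: str, probe: str, start: int = 0) -> tuple[int, int]:
    """(position, mismatches) of the best ungapped probe match at >= start.

    Ties go to the leftmost position. An exact hit (0 mismatches) is
    necessarily best, so ``str.find`` serves as a fast path; the general
    Hamming scan is vectorized for long sequences.
    """
    exact = seq.find(probe, start)
    if exact >= 0:
        return exact, 0
    n_pos = len(seq) - len(probe) + 1 - start
    if n_pos <= 0:
        return -1, len(probe) + 1
    if n_pos > 24:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr[start:], len(probe))
        mm = (windows != np.frombuffer(probe.encode(), dtype=np.uint8)).sum(axis=1)
        best = int(mm.argmin())
        return start + best, int(mm[best])
    best_pos, best_mm = -1, len(probe) + 1
    for pos in range(start, len(seq) - len(probe) + 1):
        mm = _hamming(seq[pos: pos + len(probe)], probe)
        if mm < best_mm:
            best_pos, best_mm = pos, mm
    return best_pos, best_mm


def extract_insert(
    merged_read: str,
    flank5: str,
    flank3: str,
    max_flank_mismatches: int = 2,
) -> str | None:
    """Cut the insert (start codon through stop) out of a merged amplicon.

    Both flanks are located by best-scoring ungapped match with at most
    ``max_flank_mismatches`` mismatches each; the enclosed substring is
    returned (0-based half-open coordinates). ``None`` when either flank
    is not found within tolerance or the insert is empty.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be nonempty")
    p5, mm5 = _best_ungapped_match(merged_read, flank5)
    if p5 < 0 or mm5 > max_flank_mismatches:
        return None
    insert_start = p5 + len(flank5)
    p3, mm3 = _best_ungapped_match(merged_read, flank3, start=insert_start)
    if p3 < 0 or mm3 > max_flank_mismatches:
        return None
    insert = merged_read[insert_start:p3]
    return insert or None


# ---------------------------------------------------------------------------
# clustering and calling

def cluster_sequences(
    table: VariantTable, identity_threshold: float = 0.95
) -> list[Cluster]:
    """Greedy centroid clustering in decreasing count order.

    Sequences are visited by decreasing count (ties lexicographic); each
    joins the first existing centroid whose identity to it reaches the
    threshold, otherwise it founds a new cluster. Centroids are therefore
    always the highest-count member of their cluster.
    """
    if not table.entries:
        raise ValueError("cannot cluster an empty table")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0,1]")
    ordered = sorted(table.entries, key=lambda e: (-e[1], e[0]))
    clusters: list[Cluster] = []
    for seq, count in ordered:
        for cluster in clusters:
            if _identity_at_least(seq, cluster.centroid, identity_threshold):
                cluster.members.append((seq, count))
                cluster.total_count += count
                break
        else:
            clusters.append(Cluster(centroid=seq, members=[(seq, count)]))
    return clusters


def call_functional(
    clusters: Iterable[Cluster],
    total_reads: int,
    frequency_threshold: float = 5e-5,
) -> HitCall:
    """Call clusters functional at a post-selection frequency threshold.

    The comparison is inclusive (count/total >= threshold), so at a depth
    where threshold x total is integral the implied "at least N reads"
    cutoff, ``ceil(threshold x total)``, is reproduced exactly.
    """
    clusters = list(clusters)
    if total_reads < 1:
        if clusters:
            raise ValueError("total_reads must be >= 1")
        return HitCall([], 0, frequency_threshold, 0)
    if not 0.0 < frequency_threshold <= 1.0:
        raise ValueError("frequency_threshold must be in (0,1]")
    min_reads = math.ceil(frequency_threshold * total_reads)
    hits = [
        {
            "centroid": c.centroid,
            "count": c.total_count,
            "frequency": c.total_count / total_reads,
        }
        for c in clusters
        if c.total_count / total_reads >= frequency_threshold
    ]
    hits.sort(key=lambda h: (-h["count"], h["centroid"]))
    return HitCall(hits, total_reads, frequency_threshold, min_reads)


def enrichment_table(
    pre_clusters: Sequence[Cluster],
    post_clusters: Sequence[Cluster],
    pre_total: int,
    post_total: int,
    identity_threshold: float = 0.95,
):
    """Per-cluster pre/post frequencies and fold change (post / pre).

    Post clusters are matched to the first pre cluster whose centroid
    identity reaches the threshold. Clusters absent pre-selection get the
    frequency floor 1/(pre_total+1) and are flagged as de novo
    appearances so fold changes stay finite.
    """
    import pandas as pd

    floor = 1.0 / (pre_total + 1)
    rows = []
    for post in post_clusters:
        post_freq = post.total_count / post_total
        pre_freq = None
        for pre in pre_clusters:
            if _identity_at_least(post.centroid, pre.centroid, identity_threshold):
                pre_freq = pre.total_count / pre_total
                break
        de_novo = pre_freq is None
        if de_novo:
            pre_freq = floor
        rows.append(
            {
                "centroid": post.centroid,
                "pre_frequency": pre_freq,
                "post_frequency": post_freq,
                "fold_change": post_freq / pre_freq,
                "de_novo": de_novo,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["centroid", "pre_frequency", "post_frequency", "fold_change", "de_novo"],
    )


# ---------------------------------------------------------------------------
# bulk read processing (vectorized over unique read pairs)

@dataclass
class RunSummary:
    reads_in: int = 0
    merged: int = 0
    merge_failures: int = 0
    flank_failures: int = 0
    inserts: int = 0
    clusters: int = 0
    hits: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "reads_in": self.reads_in,
            "merged": self.merged,
            "merge_failures": self.merge_failures,
            "flank_failures": self.flank_failures,
            "inserts": self.inserts,
            "clusters": self.clusters,
            "hits": self.hits,
        }
        d.update(self.extra)
        return d


def _merge_block(
    r1: np.ndarray,
    rc2: np.ndarray,
    min_overlap: int,
    max_mismatch_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized longest-acceptable-overlap merge for equal-length blocks.

    Returns (overlap length per row, 0 = failure; consensus byte matrix of
    merged reads padded per-row). Consensus at mismatches takes read 1's
    base (constant-quality reads: ties favor the forward read).
    """
    n, l1 = r1.shape
    l2 = rc2.shape[1]
    best_k = np.zeros(n, dtype=np.int32)
    unresolved = np.arange(n)
    for k in range(min(l1, l2), min_overlap - 1, -1):
        if unresolved.size == 0:
            break
        mism = (r1[unresolved, l1 - k:] != rc2[unresolved, :k]).sum(axis=1)
        ok = mism <= max_mismatch_fraction * k
        best_k[unresolved[ok]] = k
        unresolved = unresolved[~ok]
    return best_k, unresolved


def process_read_set(
    read_set,
    flank5: str,
    flank3: str,
    min_overlap: int = 20,
    max_mismatch_fraction: float = 0.1,
    max_flank_mismatches: int = 2,
    identity_threshold: float = 0.95,
    frequency_threshold: float = 5e-5,
    cluster: bool = True,
    label: str = "post",
) -> tuple[VariantTable, list[Cluster], HitCall, RunSummary]:
    """Full pipeline on a simulated :class:`~randgene.library_synth.ReadSet`.

    merge pairs -> extract inserts -> cluster -> call hits. Merging is
    vectorized over the unique read pairs (multiplicities are carried, not
    re-merged); the scalar :func:`merge_pairs` rule is identical. Set
    ``cluster=False`` to call hits on raw unique inserts instead of
    clusters.
    """
    from .library_synth import reverse_complement

    summary = RunSummary(reads_in=read_set.depth)
    pairs = read_set.pairs
    by_len: dict[tuple[int, int], list[int]] = {}
    for i, (a, b, _) in enumerate(pairs):
        by_len.setdefault((len(a), len(b)), []).append(i)

    insert_counts: dict[str, int] = {}
    for (l1, l2), idxs in by_len.items():
        r1 = np.frombuffer(
            "".join(pairs[i][0] for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), l1)
        rc2 = np.frombuffer(
            "".join(reverse_complement(pairs[i][1]) for i in idxs).encode(),
            dtype=np.uint8,
        ).reshape(len(idxs), l2)
        best_k, failed = _merge_block(r1, rc2, min_overlap, max_mismatch_fraction)
        summary.merge_failures += int(sum(pairs[idxs[j]][2] for j in failed))
        for j, k in enumerate(best_k):
            k = int(k)
            if k == 0:
                continue
            count = pairs[idxs[j]][2]
            summary.merged += count
            head = r1[j].tobytes().decode()
            tail = rc2[j, k:].tobytes().decode()
            merged = head + tail  # consensus = read1 bases over the overlap
            insert = extract_insert(merged, flank5, flank3, max_flank_mismatches)
            if insert is None:
                summary.flank_failures += count
                continue
            insert_counts[insert] = insert_counts.get(insert, 0) + count

    if not insert_counts:
        table = VariantTable(entries=[], label=label)
        summary.inserts = 0
        return table, [], HitCall([], 0, frequency_threshold, 0), summary

    table = VariantTable.from_counts(insert_counts, label=label)
    summary.inserts = table.total_reads
    if cluster:
        clusters = cluster_sequences(table, identity_threshold)
    else:
        clusters = [Cluster(centroid=s, members=[(s, c)]) for s, c in table.entries]
    summary.clusters = len(clusters)
    hit_call = call_functional(clusters, table.total_reads, frequency_threshold)
    summary.hits = len(hit_call.hits)
    return table, clusters, hit_call, summary
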