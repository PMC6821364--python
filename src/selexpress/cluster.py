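"""Coverage filtering, greedy identity clustering and rank-size analysis.

After selection, unique operator sequences are coverage-filtered, clustered
at a sequence-identity threshold (greedy incremental clustering with the
most-abundant/longest sequence founding each cluster, the classic
CD-HIT-style strategy), and the descending cluster-size curve is fit with an
exponential: successful affinity enrichment shows a characteristic
exponential rank-size decay, while unselected controls do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def coverage_filter(seq_counts: dict[str, int], min_coverage: int = 10) -> dict[str, int]:
    """Drop unique sequences observed fewer than ``min_coverage`` times."""
    return {s: c for s, c in seq_counts.items() if c >= min_coverage}


def sequence_identity(a: str, b: str) -> float:
    """Best ungapped-offset identity: matches / max(length).

    The shorter sequence slides over the longer at every overlapping offset;
    the denominator is the longer length (conservative for the 16-19 bp
    mixed-length libraries).
    """
    if not a or not b:
        return 0.0
    if len(a) < len(b):
        a, b = b, a
    best = 0
    for shift in range(-(len(b) - 1), len(a)):
        m = 0
        for i, c in enumerate(b):
            j = shift + i
            if 0 <= j < len(a) and a[j] == c:
                m += 1
        best = max(best, m)
    return best / len(a)


@dataclass
class Cluster:
    representative: str
    members: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        """Total member count (reads, not unique sequences)."""
        return int(sum(self.members.values()))


def greedy_cluster(
    seq_counts: dict[str, int],
    identity_threshold: float = 0.90,
    min_cluster_size: int = 5,
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are visited by descending count, then descending length, then
    lexicographically (deterministic).  Each sequence joins the first
    existing cluster whose representative it matches at >= threshold
    identity, else founds a new cluster.  Clusters smaller than
    ``min_cluster_size`` total count are dropped; output is sorted by size
    descending.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    if not seq_counts:
        raise ValueError("no sequences to cluster")
    order = sorted(seq_counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))
    clusters: list[Cluster] = []
    for seq, cnt in order:
        for cl in clusters:
            if sequence_identity(seq, cl.representative) >= identity_threshold:
                cl.members[seq] = cl.members.get(seq, 0) + cnt
                break
        else:
            clusters.append(Cluster(seq, {seq: cnt}))
    clusters = [c for c in clusters if c.size >= min_cluster_size]
    clusters.sort(key=lambda c: (-c.size, c.representative))
    return clusters


@dataclass
class RankSizeFit:
    """Exponential fit size(rank) = amplitude * exp(-decay * rank)."""

    amplitude: float
    decay: float
    r_squared: float
    n_clusters: int

    def predict(self, ranks) -> np.ndarray:
        return self.amplitude * np.exp(-self.decay * np.asarray(ranks, dtype=float))

    def summary(self) -> str:
        return (
            f"Rank-size exponential fit over {self.n_clusters} clusters\n"
            f"  amplitude a = {self.amplitude:.4g}\n"
            f"  decay     b = {self.decay:.4g} per rank\n"
            f"  R^2         = {self.r_squared:.4f}"
        )


def rank_size_fit(cluster_sizes) -> RankSizeFit:
    """Least-squares fit of log(size) = log(a) - b * rank (1-based ranks)."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if len(sizes) < 3:
        raise ValueError("need at least 3 clusters for a rank-size fit")
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    ranks = np.arange(1, len(sizes) + 1, dtype=float)
    logs = np.log(sizes)
    slope, intercept = np.polyfit(ranks, logs, 1)
    resid = logs - (slope * ranks + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((logs - logs.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RankSizeFit(
        amplitude=float(np.exp(intercept)),
        decay=float(-slope),
        r_squared=r2,
        n_clusters=len(sizes),
    )


__all__ = [
    "Cluster",
    "RankSizeFit",
    "coverage_filter",
    "greedy_cluster",
    "rank_size_fit",
    "sequence_identity",
]
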