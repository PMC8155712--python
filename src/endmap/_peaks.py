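"""Shared peak clustering and replicate-grouping primitives.

Clustering follows the end-mapping rule set: positions with nonzero depth
are single-linkage clustered when the gap between neighbours is below
``max_gap``; within a cluster, a greedy left-to-right sweep grows a
sub-cluster while the population standard deviation of its positions stays
below ``sd_threshold``, and each sub-cluster is represented by its
highest-depth position (ties broken toward the smaller coordinate).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class Peak:
    seq_id: str
    position: int
    strand: str
    depth: float
    replicate_id: str = ""
    tap_ratio: Optional[float] = None
    replicate_support: int = 1


def _pstd(positions: Sequence[int]) -> float:
    return float(np.std(np.asarray(positions, dtype=float)))


def subcluster(positions: Sequence[int], sd_threshold: float) -> List[List[int]]:
    """Greedy partition of sorted positions into runs with population SD
    below ``sd_threshold``."""
    groups: List[List[int]] = []
    current: List[int] = []
    for p in positions:
        if not current:
            current = [p]
        elif _pstd(current + [p]) < sd_threshold:
            current.append(p)
        else:
            groups.append(current)
            current = [p]
    if current:
        groups.append(current)
    return groups


def cluster_positions(
    positions: Sequence[int],
    depths: Dict[int, float],
    max_gap: int,
    sd_threshold: float,
) -> List[int]:
    """Representative positions after clustering and sub-clustering."""
    reps: List[int] = []
    cluster: List[int] = []
    prev = None
    for p in list(positions) + [None]:  # sentinel flush
        if p is not None and (prev is None or p - prev < max_gap):
            cluster.append(p)
        else:
            for sub in subcluster(cluster, sd_threshold):
                best = max(sub, key=lambda q: (depths[q], -q))
                reps.append(best)
            cluster = [p] if p is not None else []
        prev = p
    return sorted(reps)


def group_across_replicates(
    peak_sets: Sequence[Sequence[Peak]], tolerance: int
) -> List[List[Peak]]:
    """Chain peaks from several replicates whose positions lie within
    ``tolerance`` nt of their neighbour, per (seq_id, strand)."""
    by_key: Dict[Tuple[str, str], List[Peak]] = {}
    for peaks in peak_sets:
        for pk in peaks:
            by_key.setdefault((pk.seq_id, pk.strand), []).append(pk)
    groups: List[List[Peak]] = []
    for key in sorted(by_key):
        peaks = sorted(by_key[key], key=lambda pk: pk.position)
        current: List[Peak] = []
        for pk in peaks:
            if current and pk.position - current[-1].position <= tolerance:
                current.append(pk)
            else:
                if current:
                    groups.append(current)
                current = [pk]
        if current:
            groups.append(current)
    return groups


def merge_group(group: Sequence[Peak]) -> Peak:
    """Merged peak: position of the deepest member (ties toward smaller
    coordinate), depth = mean over one best peak per replicate."""
    per_rep: Dict[str, Peak] = {}
    for pk in group:
        cur = per_rep.get(pk.replicate_id)
        if cur is None or (pk.depth, -pk.position) > (cur.depth, -cur.position):
            per_rep[pk.replicate_id] = pk
    best = max(per_rep.values(), key=lambda pk: (pk.depth, -pk.position))
    depth = float(np.mean([pk.depth for pk in per_rep.values()]))
    return Peak(
        seq_id=best.seq_id,
        position=best.position,
        strand=best.strand,
        depth=depth,
        replicate_id=best.replicate_id,
        tap_ratio=best.tap_ratio,
        replicate_support=len(per_rep),
    )
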