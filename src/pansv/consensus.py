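"""Multi-caller SV call-set filtering and consensus merging.

Short-read SV callers disagree on breakpoints by tens of bases.  The
consensus pipeline mirrors the SURVIVOR-style merge used for cohort
call sets: size-filter raw calls, single-linkage cluster them within a
breakpoint distance (type-aware), drop clusters observed fewer than a
recurrence threshold of (sample, tool) times, and emit one record per
cluster at the most frequently reported exact coordinates.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SVTYPES = ("DEL", "INS", "INV", "DUP")


@dataclass(frozen=True)
class SVCall:
    """One raw call from one tool on one sample (0-based half-open)."""

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    sample_id: str
    tool_id: str
    alt_seq: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for call at {self.chrom}:{self.start}")
        if self.length < 1:
            raise ValueError("SV length must be >= 1")
        if self.svtype == "INS" and self.end != self.start:
            raise ValueError("insertions must have end == start")


@dataclass(frozen=True)
class SVRecord:
    """Consensus record: representative coordinates of one cluster."""

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    support: int  # observations of the representative coordinates
    cluster_size: int
    seq: str | None = None
    member_ids: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_calls(
    calls: Sequence[SVCall],
    min_size: int = 50,
    max_size: int = 100_000,
    min_recurrence: int = 3,
    max_dist: int = 50,
    recurrence_mode: str = "clustered",
) -> list[SVCall]:
    """Keep calls with ``min_size <= length <= max_size`` whose breakpoint
    recurs at least ``min_recurrence`` times across all samples and tools.

    Recurrence is counted on clustered breakpoints at the merge distance
    by default (``recurrence_mode="clustered"``); ``"exact"`` counts
    identical coordinates only.
    """
    if min_size < 0 or max_size < 0:
        raise ValueError("size thresholds must be non-negative")
    sized = [c for c in calls if min_size <= c.length <= max_size]
    if min_recurrence <= 1:
        return sized
    if recurrence_mode == "exact":
        counts = Counter((c.chrom, c.start, c.end, c.svtype) for c in sized)
        return [c for c in sized if counts[(c.chrom, c.start, c.end, c.svtype)] >= min_recurrence]
    if recurrence_mode != "clustered":
        raise ValueError(f"unknown recurrence_mode {recurrence_mode!r}")
    keep = []
    for cluster in cluster_calls(sized, max_dist=max_dist):
        if len(cluster) >= min_recurrence:
            keep.extend(cluster)
    return keep


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_calls(
    calls: Sequence[SVCall],
    max_dist: int = 50,
    type_aware: bool = True,
) -> list[list[SVCall]]:
    """Single-linkage clusters: two calls link iff same chromosome, same
    type (when ``type_aware``), and both breakpoints within ``max_dist``.

    Clusters are disjoint, cover all calls, and come out in deterministic
    (chrom, type, position) order regardless of input order.
    """
    groups: dict[tuple, list[tuple[int, SVCall]]] = defaultdict(list)
    for idx, c in enumerate(calls):
        key = (c.chrom, c.svtype) if type_aware else (c.chrom,)
        groups[key].append((idx, c))
    clusters: list[list[SVCall]] = []
    for key in sorted(groups, key=lambda k: tuple(map(str, k))):
        members = sorted(groups[key], key=lambda t: (t[1].start, t[1].end, t[1].sample_id, t[1].tool_id))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            ci = members[i][1]
            for j in range(i + 1, len(members)):
                cj = members[j][1]
                if cj.start - ci.start > max_dist:
                    break  # sorted by start
                if abs(ci.end - cj.end) <= max_dist:
                    uf.union(i, j)
        by_root: dict[int, list[SVCall]] = defaultdict(list)
        for i, (_, c) in enumerate(members):
            by_root[uf.find(i)].append(c)
        for root in sorted(by_root):
            clusters.append(by_root[root])
    return clusters


# ---------------------------------------------------------------------------
# Representative selection
# ---------------------------------------------------------------------------


def select_representative(
    cluster: Sequence[SVCall],
    reference: Mapping[str, str] | None = None,
    record_id: str = "sv",
) -> SVRecord:
    """Pick the most frequently observed exact (start, end) pair as the
    representative; ties break to the pair seen by more distinct tools,
    then to the smaller start.

    Deletion sequence is read from the reference span when a reference
    is given; insertion sequence is taken from a sequence-reporting
    member, preferring one at the representative coordinates.
    """
    if not cluster:
        raise ValueError("empty cluster")
    counts: Counter[tuple[int, int]] = Counter()
    tools: dict[tuple[int, int], set[str]] = defaultdict(set)
    for c in cluster:
        key = (c.start, c.end)
        counts[key] += 1
        tools[key].add(c.tool_id)
    best = max(counts, key=lambda k: (counts[k], len(tools[k]), -k[0]))
    first = cluster[0]
    length = next(
        c.length for c in cluster if (c.start, c.end) == best
    )
    seq = None
    if first.svtype == "DEL" and reference is not None:
        seq = reference[first.chrom][best[0] : best[1]]
    elif first.svtype == "INS":
        with_seq = [c for c in cluster if c.alt_seq]
        at_rep = [c for c in with_seq if (c.start, c.end) == best]
        chosen = at_rep[0] if at_rep else (with_seq[0] if with_seq else None)
        if chosen is not None:
            seq = chosen.alt_seq
    return SVRecord(
        id=record_id,
        chrom=first.chrom,
        start=best[0],
        end=best[1],
        svtype=first.svtype,
        length=length,
        support=counts[best],
        cluster_size=len(cluster),
        seq=seq,
    )


# ---------------------------------------------------------------------------
# Cohort merge
# ---------------------------------------------------------------------------


def merge_cohort(
    callsets: Mapping[tuple[str, str], Sequence[SVCall]] | Sequence[SVCall],
    reference: Mapping[str, str] | None = None,
    min_size: int = 50,
    max_size: int = 100_000,
    min_recurrence: int = 3,
    max_dist: int = 50,
) -> list[SVRecord]:
    """filter -> cluster (per type) -> representative, sorted by position.

    ``callsets`` is either a flat call list or a mapping keyed by
    (sample, tool).  Chromosome names must be consistent; offenders are
    listed in the error.
    """
    if isinstance(callsets, Mapping):
        calls = [c for cs in callsets.values() for c in cs]
    else:
        calls = list(callsets)
    if reference is not None:
        unknown = sorted({c.chrom for c in calls} - set(reference))
        if unknown:
            raise ValueError(f"calls on chromosomes absent from reference: {unknown}")
    kept = filter_calls(
        calls,
        min_size=min_size,
        max_size=max_size,
        min_recurrence=min_recurrence,
        max_dist=max_dist,
    )
    records = [
        select_representative(cluster, reference=reference)
        for cluster in cluster_calls(kept, max_dist=max_dist)
    ]
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.svtype))
    return [replace(r, id=f"sv_{i}") for i, r in enumerate(records)]


def records_to_frame(records: Sequence[SVRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "svtype": r.svtype,
                "length": r.length,
                "seq": r.seq,
                "support": r.support,
                "cluster_size": r.cluster_size,
            }
            for r in records
        ],
        columns=[
            "id",
            "chrom",
            "start",
            "end",
            "svtype",
            "length",
            "seq",
            "support",
            "cluster_size",
        ],
    )
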