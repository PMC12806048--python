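"""Permutation-based enrichment of SV sets in annotation region classes.

The observed count of SVs overlapping a region class by >= 1 bp is
compared with the distribution obtained by re-placing every SV
uniformly at random on its own chromosome (length preserved, no
inter-chromosomal moves), in the spirit of regioneR's randomizeRegions
permutation test.  Z = (observed - mean) / sd over permutations and the
empirical p uses the add-one rule p = (1 + #{perm as extreme}) / (N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EnrichmentResult:
    sv_category: str
    region_class: str
    observed: int
    perm_mean: float
    perm_sd: float
    z: float  # NaN when saturated (perm_sd == 0)
    p_empirical: float
    direction: str  # "over" | "under"
    saturated: bool
    n_permutations: int

    @property
    def stars(self) -> str:
        for thresh, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_empirical < thresh:
                return mark
        return ""


def _validate(intervals: pd.DataFrame) -> None:
    if (intervals["end"] < intervals["start"]).any():
        raise ValueError("interval with end < start")


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [], []
    for s, e in zip(starts, ends):
        if m_ends and s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.array(m_starts), np.array(m_ends)


def overlap_count(sv_intervals: pd.DataFrame, region_set: pd.DataFrame) -> int:
    """Number of SV intervals sharing >= 1 bp with any region.

    Regions are merged per chromosome; an SV [s, e) overlaps iff some
    merged region has start < e and end > s (binary search).  Matches
    the all-pairs brute force on every toy we test.
    """
    _validate(sv_intervals)
    _validate(region_set)
    count = 0
    for chrom, regions in region_set.groupby("chrom", sort=False):
        ms, me = _merge_sorted(regions["start"].to_numpy(), regions["end"].to_numpy())
        svs = sv_intervals[sv_intervals["chrom"] == chrom]
        if not len(svs) or not len(ms):
            continue
        s = svs["start"].to_numpy()
        e = svs["end"].to_numpy()
        # candidate region: the last one starting before the SV end
        j = np.searchsorted(ms, e, side="left") - 1
        prev_ok = (j >= 0) & (np.take(me, np.maximum(j, 0)) > s)
        count += int(prev_ok.sum())
    return count


def permutation_enrichment(
    sv_intervals: pd.DataFrame,
    region_set: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_permutations: int = 100,
    seed: int | np.random.Generator = 0,
    sv_category: str = "all",
    region_class: str = "regions",
    direction: str | None = None,
) -> EnrichmentResult:
    """Permutation Z-score of SV/region overlap (fixed seed => identical
    result).  ``direction`` defaults to the side the observation falls
    on relative to the permutation mean."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    _validate(sv_intervals)
    lengths = (sv_intervals["end"] - sv_intervals["start"]).to_numpy()
    chroms = sv_intervals["chrom"].to_numpy()
    for chrom, L in zip(chroms, lengths):
        if L > chrom_lengths[chrom]:
            raise ValueError(f"SV longer than its chromosome {chrom}")
    observed = overlap_count(sv_intervals, region_set)
    perm_counts = np.empty(n_permutations, dtype=int)
    chrom_len = np.array([chrom_lengths[c] for c in chroms])
    for k in range(n_permutations):
        starts = np.floor(rng.random(len(lengths)) * (chrom_len - lengths + 1)).astype(
            np.int64
        )
        perm = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + lengths}
        )
        perm_counts[k] = overlap_count(perm, region_set)
    mean = float(perm_counts.mean())
    sd = float(perm_counts.std(ddof=0))
    saturated = sd == 0
    z = np.nan if saturated else (observed - mean) / sd
    if direction is None:
        direction = "over" if observed >= mean else "under"
    if direction == "over":
        extreme = int((perm_counts >= observed).sum())
    else:
        extreme = int((perm_counts <= observed).sum())
    p = (1 + extreme) / (n_permutations + 1)
    return EnrichmentResult(
        sv_category=sv_category,
        region_class=region_class,
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        z=z,
        p_empirical=p,
        direction=direction,
        saturated=saturated,
        n_permutations=n_permutations,
    )


def enrichment_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sv_category": r.sv_category,
                "region_class": r.region_class,
                "observed": r.observed,
                "perm_mean": r.perm_mean,
                "perm_sd": r.perm_sd,
                "Z": r.z,
                "p": r.p_empirical,
                "direction": r.direction,
                "stars": r.stars,
            }
            for r in results
        ]
    )
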