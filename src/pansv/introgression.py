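"""Windowed ABBA-BABA statistics under the topology (((P1, P2), P3), O).

Sites are polarized by the outgroup (derived = the allele that is minor
in O); per-site pattern weights use derived-allele frequencies:

    ABBA = (1 - p1) * p2 * p3 * (1 - pO)
    BABA = p1 * (1 - p2) * p3 * (1 - pO)

Patterson's D per window is (sum ABBA - sum BABA) / (sum ABBA + sum BABA).
fdM follows the dynamic-donor estimator: for sites with p2 >= p1 the
denominator substitutes the higher of (p2, p3) into both the P2 and P3
slots; for sites with p1 > p2 it substitutes the higher of (p1, p3) into
the P1 and P3 slots.  fdM is bounded in [-1, 1], positive for P3->P2
gene flow, and flips sign exactly under a P1/P2 swap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import GenotypeMatrix


@dataclass(frozen=True)
class PolarizedSites:
    """Per-site derived-allele frequencies for the four groups."""

    chrom: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    pO: np.ndarray
    n_dropped: int  # sites lost to missing or ambiguous outgroup


def _group_freq(gm: GenotypeMatrix, group: str, group_col: str) -> np.ndarray:
    """Derived-side allele frequency per group; phased haplotypes are
    used when present (exact allele counts), genotypes otherwise."""
    idx = gm.sample_indices(group_col, group)
    if idx.size == 0:
        raise ValueError(f"empty group {group!r}")
    if gm.haplotypes is not None:
        h = gm.haplotypes[:, idx].reshape(gm.n_variants, -1)
        called = h >= 0
        alt = np.where(called, h, 0).sum(axis=1).astype(float)
        tot = called.sum(axis=1)
    else:
        g = gm.genotypes[:, idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1).astype(float)
        tot = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)


def polarize_sites(
    gm: GenotypeMatrix,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    group_col: str = "strain",
) -> PolarizedSites:
    """Derived-allele frequencies per group at SNP sites.

    The derived allele is the one minor in the outgroup; sites where the
    outgroup has no called alleles or is at exactly 0.5 (ambiguous
    polarity) are dropped and counted.
    """
    snp = gm.variants["type"].to_numpy() == "SNP"
    freqs = {g: _group_freq(gm, g, group_col) for g in (p1, p2, p3, outgroup)}
    fo = freqs[outgroup]
    usable = snp & ~np.isnan(fo) & (fo != 0.5)
    for g in (p1, p2, p3):
        usable &= ~np.isnan(freqs[g])
    flip = fo > 0.5  # alt is major in O -> ref allele is derived
    out = {}
    for name, f in freqs.items():
        out[name] = np.where(flip, 1 - f, f)[usable]
    return PolarizedSites(
        chrom=gm.variants["chrom"].to_numpy()[usable],
        pos=gm.variants["pos"].to_numpy()[usable],
        p1=out[p1],
        p2=out[p2],
        p3=out[p3],
        pO=out[outgroup],
        n_dropped=int(snp.sum() - usable.sum()),
    )


def site_pattern_weights(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, pO: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


def _fdm_denominators(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, pO: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site dynamic-donor denominators for the two flow directions.

    ``den_p2``: donor = the higher of (P2, P3) substituted into both the
    P2 and P3 slots — the expected numerator under complete P3->P2
    replacement (used when the window numerator is positive).  ``den_p1``
    is the mirror image for P3->P1 flow, sign-flipped so a negative
    window numerator divides by a positive quantity.  Under complete
    donor replacement (p2 = p3 at every site) ``den_p2`` equals the
    numerator site by site, so fdM is exactly 1; the construction is
    antisymmetric under a P1/P2 swap, so the swap flips fdM exactly.
    """
    pd23 = np.maximum(p2, p3)
    a2, b2 = site_pattern_weights(p1, pd23, pd23, pO)
    pd13 = np.maximum(p1, p3)
    a1, b1 = site_pattern_weights(pd13, p2, pd13, pO)
    return a2 - b2, -(a1 - b1)


def windowed_dstat(
    sites: PolarizedSites,
    windows: pd.DataFrame,
    min_sites: int = 20,
) -> pd.DataFrame:
    """Per-window D and fdM from summed site-pattern weights.

    A site is informative when its ABBA or BABA weight is non-zero.
    Windows with fewer than ``min_sites`` informative sites (or a zero
    denominator) report missing values.
    """
    abba, baba = site_pattern_weights(sites.p1, sites.p2, sites.p3, sites.pO)
    den_p2, den_p1 = _fdm_denominators(sites.p1, sites.p2, sites.p3, sites.pO)
    informative = (abba > 0) | (baba > 0)
    rows = []
    for row in windows.itertuples(index=False):
        m = (
            (sites.chrom == row.chrom)
            & (sites.pos >= row.start)
            & (sites.pos < row.end)
        )
        n_inf = int((m & informative).sum())
        s_abba, s_baba = float(abba[m].sum()), float(baba[m].sum())
        num = s_abba - s_baba
        s_denom = float(den_p2[m].sum()) if num >= 0 else float(den_p1[m].sum())
        d = (
            num / (s_abba + s_baba)
            if n_inf >= min_sites and (s_abba + s_baba) > 0
            else np.nan
        )
        fdm = num / s_denom if n_inf >= min_sites and s_denom != 0 else np.nan
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "n_informative_sites": n_inf,
                "sum_ABBA": s_abba,
                "sum_BABA": s_baba,
                "D": d,
                "fdM": fdm,
            }
        )
    return pd.DataFrame(rows)


def genome_wide_d(sites: PolarizedSites) -> float:
    abba, baba = site_pattern_weights(sites.p1, sites.p2, sites.p3, sites.pO)
    s_a, s_b = float(abba.sum()), float(baba.sum())
    return (s_a - s_b) / (s_a + s_b) if (s_a + s_b) > 0 else np.nan


def groupwise_fdm_contrast(
    fdm_groups: dict[str, Sequence[float]],
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between every pair of window
    groups of fdM values (e.g. the expected gene-flow models).

    Exact p for small tie-free samples; otherwise the normal
    approximation with continuity correction.
    """
    names = list(fdm_groups)
    for name in names:
        if len(fdm_groups[name]) == 0:
            raise ValueError(f"empty contrast group {name!r}")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x = np.asarray(fdm_groups[a], dtype=float)
            y = np.asarray(fdm_groups[b], dtype=float)
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = (
                "exact"
                if (max(len(x), len(y)) <= exact_max_n and not ties)
                else "asymptotic"
            )
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method=method, use_continuity=True
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(x),
                    "n_b": len(y),
                    "median_a": float(np.median(x)),
                    "median_b": float(np.median(y)),
                    "statistic": float(res.statistic),
                    "p": float(res.pvalue),
                    "method": method,
                }
            )
    return pd.DataFrame(rows)
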