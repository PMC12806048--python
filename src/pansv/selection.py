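"""Windowed selection statistics and the composite rank score.

Two populations are contrasted in sliding windows (30 kb, 10 kb step by
default) with Weir & Cockerham (1984) F_ST (ratio-of-sums over the SNPs
in each window) and XP-EHH (log-ratio of integrated extended-haplotype
homozygosity, genome-standardized).  Per method m, window scores are
rank-normalized to R_m in [0, 1], scaled to S_m = R_m / (1.001 - R_m)
(so the top window maps to S = 1000 exactly and division by zero is
avoided), and averaged over available methods into a composite value.
Windows in the top fraction (0.1% by default) of composite values are
called as candidate sweep regions.  Per-window scores from external
methods (e.g. XP-CLR) can be imported from a table and enter the
composite the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .popgen import GenotypeMatrix

SCALING_CONSTANT = 1.001


def make_windows(
    chrom_lengths: Mapping[str, int],
    window: int = 30_000,
    step: int = 10_000,
) -> pd.DataFrame:
    """Sliding windows per chromosome; the last window is clipped to the
    chromosome end."""
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append({"chrom": chrom, "start": start, "end": min(start + window, length)})
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_fst_components(
    g_a: np.ndarray, g_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components for two
    populations from genotype matrices (sites x samples, -1 missing).

    Returns (a, a + b + c) arrays; the windowed estimator is
    sum(a) / sum(a + b + c) over the sites in a window.
    """
    comps = []
    for g in (g_a, g_b):
        called = g >= 0
        n_i = called.sum(axis=1).astype(float)  # diploid individuals
        alt = np.where(called, g, 0).sum(axis=1).astype(float)
        het = np.where(called, g == 1, False).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * np.maximum(n_i, 1)), np.nan)
            h_i = np.where(n_i > 0, het / np.maximum(n_i, 1), np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    total = a + b + c
    bad = (n1 < 1) | (n2 < 1) | np.isnan(pbar)
    a = np.where(bad, np.nan, a)
    total = np.where(bad, np.nan, total)
    return a, total


def windowed_fst(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    windows: pd.DataFrame,
    group_col: str = "strain",
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """Ratio-of-sums W&C F_ST per window; negative estimates are floored
    at 0 for ranking while the raw value is retained."""
    ia = gm.sample_indices(group_col, pop_a)
    ib = gm.sample_indices(group_col, pop_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both populations need >= 2 samples")
    snp = gm.variants["type"].to_numpy() == "SNP"
    a, total = wc_fst_components(gm.genotypes[:, ia], gm.genotypes[:, ib])
    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    out = windows.copy()
    raw = np.full(len(windows), np.nan)
    nsites = np.zeros(len(windows), dtype=int)
    for w, row in enumerate(windows.itertuples(index=False)):
        m = snp & (chroms == row.chrom) & (pos >= row.start) & (pos < row.end) & ~np.isnan(total)
        nsites[w] = int(m.sum())
        denom = np.nansum(total[m])
        if nsites[w] and denom > 0:
            raw[w] = np.nansum(a[m]) / denom
    out["fst_raw"] = raw
    out["fst"] = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0)) if floor_at_zero else raw
    out["n_sites"] = nsites
    return out


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------


def _ehh_profile(
    hap: np.ndarray, core: int, direction: int, truncation: float, max_extend: int
) -> tuple[list[float], list[int]]:
    """EHH values and positions-index offsets extending from ``core`` in
    one direction until EHH < truncation.  Haplotypes are partitioned by
    identity over the extended segment; EHH = sum k_c(k_c-1) / (K(K-1))."""
    K = hap.shape[1]
    ids = hap[core].astype(np.int64)  # condition on the core-site allele
    _, counts0 = np.unique(ids, return_counts=True)
    e0 = float((counts0 * (counts0 - 1)).sum()) / (K * (K - 1)) if K > 1 else 1.0
    ehh, idx = [e0], [core]
    j = core
    steps = 0
    n_sites = hap.shape[0]
    while steps < max_extend:
        j += direction
        if j < 0 or j >= n_sites:
            break
        ids = ids * 2 + hap[j]
        if steps % 50 == 49:  # renumber to avoid int64 overflow
            _, ids = np.unique(ids, return_inverse=True)
        _, counts = np.unique(ids, return_counts=True)
        e = float((counts * (counts - 1)).sum()) / (K * (K - 1)) if K > 1 else 1.0
        ehh.append(e)
        idx.append(j)
        if e < truncation:
            break
        steps += 1
    return ehh, idx


def _ihh(
    hap: np.ndarray,
    positions: np.ndarray,
    core: int,
    truncation: float = 0.05,
    max_extend: int = 400,
) -> float:
    """Integrated EHH (trapezoid over physical distance) on both sides."""
    total = 0.0
    for direction in (-1, 1):
        ehh, idx = _ehh_profile(hap, core, direction, truncation, max_extend)
        x = np.abs(positions[idx] - positions[core]).astype(float)
        total += float(np.trapezoid(np.array(ehh), x)) if len(idx) > 1 else 0.0
    return total


def xpehh(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    windows: pd.DataFrame,
    group_col: str = "strain",
    truncation: float = 0.05,
    max_extend: int = 400,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-core-SNP XP-EHH = ln(iHH_A / iHH_B), genome-standardized to
    mean 0 and unit variance; window value = the standardized score of
    largest magnitude among cores in the window (sign retained).

    Requires phased haplotypes; genotype-only matrices raise with a
    pointer to the F_ST-only composite.
    """
    if gm.haplotypes is None:
        raise ValueError(
            "XP-EHH needs phased haplotypes; run the scan in genotype-only "
            "mode (F_ST composite) instead"
        )
    ia = gm.sample_indices(group_col, pop_a)
    ib = gm.sample_indices(group_col, pop_b)
    snp_mask = gm.variants["type"].to_numpy() == "SNP"
    scores_rows = []
    chroms = gm.variants["chrom"].to_numpy()
    for chrom in pd.unique(gm.variants["chrom"]):
        m = snp_mask & (chroms == chrom)
        vidx = np.flatnonzero(m)
        if vidx.size == 0:
            continue
        positions = gm.variants["pos"].to_numpy()[vidx]
        hap_a = gm.haplotypes[vidx][:, ia].reshape(vidx.size, -1)
        hap_b = gm.haplotypes[vidx][:, ib].reshape(vidx.size, -1)
        for c in range(vidx.size):
            ihh_a = _ihh(hap_a, positions, c, truncation, max_extend)
            ihh_b = _ihh(hap_b, positions, c, truncation, max_extend)
            score = (
                np.log(ihh_a / ihh_b) if ihh_a > 0 and ihh_b > 0 else np.nan
            )
            scores_rows.append({"chrom": chrom, "pos": int(positions[c]), "xpehh_raw": score})
    scores = pd.DataFrame(scores_rows, columns=["chrom", "pos", "xpehh_raw"])
    raw = scores["xpehh_raw"].to_numpy()
    mu, sd = np.nanmean(raw), np.nanstd(raw)
    scores["xpehh_std"] = (raw - mu) / sd if sd > 0 else raw - mu
    out = windows.copy()
    vals = np.full(len(windows), np.nan)
    for w, row in enumerate(windows.itertuples(index=False)):
        m = (
            (scores["chrom"] == row.chrom)
            & (scores["pos"] >= row.start)
            & (scores["pos"] < row.end)
        ).to_numpy() & ~np.isnan(scores["xpehh_std"].to_numpy())
        if m.any():
            s = scores["xpehh_std"].to_numpy()[m]
            vals[w] = s[np.argmax(np.abs(s))]
    out["xpehh"] = vals
    return out, scores


# ---------------------------------------------------------------------------
# Composite rank score
# ---------------------------------------------------------------------------


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """R = (rank - 1) / (n - 1), ascending, average ranks for ties, over
    non-missing values; missing stays missing."""
    r = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n == 1:
        raise ValueError("rank undefined for a single window")
    if n:
        r[ok] = (rankdata(values[ok], method="average") - 1) / (n - 1)
    return r


def scale_rank(r: np.ndarray, constant: float = SCALING_CONSTANT) -> np.ndarray:
    """S = R / (constant - R); with the 1.001 constant, R=1 -> S=1000."""
    if constant <= 1:
        raise ValueError("scaling constant must exceed 1 (S unbounded otherwise)")
    return r / (constant - r)


def composite_rank(
    window_scores: pd.DataFrame,
    methods: Sequence[str],
    top_fraction: float = 0.001,
    constant: float = SCALING_CONSTANT,
) -> pd.DataFrame:
    """Rank/scale each method column, average available S into the
    composite, and call the top ``top_fraction`` of windows.

    Selection takes the top k = max(1, ceil(n * top_fraction)) windows
    by composite in stable (chrom, start) tie order; a ``degenerate``
    flag marks scans where the selection boundary falls inside a tie.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    out = window_scores.copy()
    s_cols = []
    for m in methods:
        r = rank_normalize(out[m].to_numpy(dtype=float))
        out[f"{m}_R"] = r
        out[f"{m}_S"] = scale_rank(r, constant)
        s_cols.append(f"{m}_S")
    s_matrix = out[s_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        out["composite"] = np.nanmean(s_matrix, axis=1)
    out["n_methods"] = (~np.isnan(s_matrix)).sum(axis=1)
    comp = out["composite"].to_numpy()
    ok = np.flatnonzero(~np.isnan(comp))
    k = max(1, int(np.ceil(ok.size * top_fraction)))
    order = ok[np.argsort(-comp[ok], kind="stable")]
    selected = np.zeros(len(out), dtype=bool)
    selected[order[:k]] = True
    out["selected"] = selected
    out.attrs["degenerate"] = bool(
        ok.size > k and comp[order[k - 1]] == comp[order[k]]
    )
    return out


# ---------------------------------------------------------------------------
# Full scan and power harness
# ---------------------------------------------------------------------------


def selection_scan(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    chrom_lengths: Mapping[str, int],
    window: int = 30_000,
    step: int = 10_000,
    top_fraction: float = 0.001,
    group_col: str = "strain",
    imported_scores: pd.DataFrame | None = None,
    use_xpehh: bool = True,
) -> pd.DataFrame:
    """Windowed F_ST (+ XP-EHH when phased, + imported per-window scores)
    combined by the composite rank score."""
    windows = make_windows(chrom_lengths, window, step)
    ws = windowed_fst(gm, pop_a, pop_b, windows, group_col)
    methods = ["fst"]
    if use_xpehh and gm.haplotypes is not None:
        xw, _ = xpehh(gm, pop_a, pop_b, windows, group_col)
        ws["xpehh"] = np.abs(xw["xpehh"].to_numpy())  # magnitude ranks
        ws["xpehh_signed"] = xw["xpehh"].to_numpy()
        methods.append("xpehh")
    if imported_scores is not None:
        ws = ws.merge(
            imported_scores, on=["chrom", "start", "end"], how="left", validate="1:1"
        )
        methods.extend(
            c for c in imported_scores.columns if c not in ("chrom", "start", "end")
        )
    return composite_rank(ws, methods, top_fraction)


def sweep_detection_power(
    scans: Sequence[pd.DataFrame],
    sweep_window: tuple[str, int, int],
) -> dict:
    """Fraction of replicate scans whose selected set overlaps the
    planted sweep window, plus the sweep window's composite rank."""
    chrom, start, end = sweep_window
    hits, ranks = [], []
    for ws in scans:
        overlap = (
            (ws["chrom"] == chrom) & (ws["start"] < end) & (ws["end"] > start)
        ).to_numpy()
        hits.append(bool((overlap & ws["selected"].to_numpy()).any()))
        comp = ws["composite"].to_numpy()
        order = np.argsort(-comp, kind="stable")
        rank_of = np.empty(len(ws), dtype=int)
        rank_of[order] = np.arange(1, len(ws) + 1)
        ranks.append(int(rank_of[overlap].min()) if overlap.any() else -1)
    return {
        "detection_fraction": float(np.mean(hits)),
        "best_ranks": ranks,
        "n_replicates": len(scans),
    }
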