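"""Genotype-matrix statistics for SV/SNP cohorts.

Covers post-genotyping QC, per-group allele frequencies with the four
frequency classes and deltaAF, SV-vs-SNP LD tagging, identity-by-state
distances, normalized IBD sharing (nIBD), windowed nucleotide diversity,
and case-control association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Frequency-class boundaries: rare <= 0.01 < low <= 0.05 < common <= 0.3 < high
FREQ_CLASS_BOUNDS = (0.01, 0.05, 0.3)


@dataclass
class GenotypeMatrix:
    """Variants x samples genotype container.

    ``variants``: DataFrame (id, chrom, pos, type in {SNP, SV}, length).
    ``samples``: DataFrame (id, strain, optionally population, phenotype).
    ``genotypes``: int8 array (n_variants, n_samples), codes {0, 1, 2},
    -1 for missing.  ``haplotypes``: optional phased int8 array
    (n_variants, n_samples, 2) with alleles in {0, 1}.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        nv, ns = self.genotypes.shape
        if len(self.variants) != nv or len(self.samples) != ns:
            raise ValueError("genotype matrix dimensions inconsistent with tables")
        valid = np.isin(self.genotypes, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("invalid genotype codes")
        if "strain" not in self.samples.columns:
            raise ValueError("every sample needs a strain label")
        if self.haplotypes is not None and self.haplotypes.shape != (nv, ns, 2):
            raise ValueError("haplotype array shape mismatch")

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def dosage(self) -> np.ndarray:
        """Float copy with missing as NaN."""
        d = self.genotypes.astype(float)
        d[self.genotypes < 0] = np.nan
        return d

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants.loc[mask].reset_index(drop=True),
            self.samples,
            self.genotypes[mask],
            None if self.haplotypes is None else self.haplotypes[mask],
        )

    def sample_indices(self, group_col: str, group: str) -> np.ndarray:
        return np.flatnonzero((self.samples[group_col] == group).to_numpy())


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_genotypes(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.3,
    min_mac_exclusive: int = 3,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep variants with call rate > ``min_call_rate`` and minor allele
    count > ``min_mac_exclusive`` (both strict); returns the filtered
    matrix and a removal report (variant id, reason)."""
    called = gm.genotypes >= 0
    call_rate = called.mean(axis=1)
    alt = np.where(called, gm.genotypes, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    mac = np.minimum(alt, total - alt)
    keep = (call_rate > min_call_rate) & (mac > min_mac_exclusive)
    reasons = []
    for i in np.flatnonzero(~keep):
        why = []
        if call_rate[i] <= min_call_rate:
            why.append(f"call_rate={call_rate[i]:.3f}")
        if mac[i] <= min_mac_exclusive:
            why.append(f"mac={mac[i]}")
        reasons.append({"id": gm.variants["id"].iat[i], "reason": ";".join(why)})
    return gm.subset_variants(keep), pd.DataFrame(reasons, columns=["id", "reason"])


# ---------------------------------------------------------------------------
# Frequencies, classes, deltaAF
# ---------------------------------------------------------------------------


def group_frequencies(gm: GenotypeMatrix, group_col: str = "strain") -> pd.DataFrame:
    """Per-group alternate-allele frequencies (NaN when a group has no
    called alleles at a site)."""
    if group_col not in gm.samples.columns:
        raise ValueError(f"no grouping column {group_col!r}")
    out = {}
    for grp in pd.unique(gm.samples[group_col]):
        idx = gm.sample_indices(group_col, grp)
        g = gm.genotypes[:, idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1).astype(float)
        tot = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[grp] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return pd.DataFrame(out, index=gm.variants["id"])


def frequency_class(freq: float) -> str:
    if np.isnan(freq):
        return "missing"
    lo, mid, hi = FREQ_CLASS_BOUNDS
    if freq <= lo:
        return "rare"
    if freq <= mid:
        return "low"
    if freq <= hi:
        return "common"
    return "high"


def frequencies(
    gm: GenotypeMatrix,
    group_col: str = "strain",
    delta_groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """FrequencyRecords: overall frequency and class, per-group
    frequencies, strain sharing, and (optionally) deltaAF between two
    named groups (groupA minus groupB)."""
    per_group = group_frequencies(gm, group_col)
    called = gm.genotypes >= 0
    alt = np.where(called, gm.genotypes, 0).sum(axis=1).astype(float)
    tot = 2 * called.sum(axis=1)
    overall = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    strain_freq = (
        per_group
        if group_col == "strain"
        else group_frequencies(gm, "strain")
    )
    n_strains_with_alt = (strain_freq.to_numpy() > 0).sum(axis=1)
    rec = pd.DataFrame(
        {
            "id": gm.variants["id"].to_numpy(),
            "frequency": overall,
            "frequency_class": [frequency_class(f) for f in overall],
            "strain_sharing": np.where(
                n_strains_with_alt == 1,
                "specific",
                np.where(n_strains_with_alt == 0, "absent", "shared"),
            ),
        }
    )
    for grp in per_group.columns:
        rec[f"freq_{grp}"] = per_group[grp].to_numpy()
    if delta_groups is not None:
        a, b = delta_groups
        rec["deltaAF"] = per_group[a].to_numpy() - per_group[b].to_numpy()
    return rec


# ---------------------------------------------------------------------------
# LD tagging
# ---------------------------------------------------------------------------


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_tagging(
    gm: GenotypeMatrix,
    window_bp: int = 100_000,
    tag_threshold: float = 0.2,
    molqtl_threshold: float = 0.6,
    molqtl_snp_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Best r^2 of each SV against SNPs within +-``window_bp``.

    ``tagged`` iff best r^2 >= ``tag_threshold``; SVs with no SNP in the
    window are ``independent`` with the ``no_snp`` flag; monomorphic SVs
    are flagged ``monomorphic``.  ``molqtl_linked`` marks SVs whose best
    r^2 against a designated molQTL SNP set reaches
    ``molqtl_threshold``.
    """
    dos = gm.dosage()
    is_snp = (gm.variants["type"] == "SNP").to_numpy()
    is_sv = ~is_snp
    molqtl = (
        gm.variants["id"].isin(set(molqtl_snp_ids)).to_numpy()
        if molqtl_snp_ids is not None
        else np.zeros(gm.n_variants, bool)
    )
    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    rows = []
    for i in np.flatnonzero(is_sv):
        near = (
            is_snp
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        best, best_molqtl = np.nan, np.nan
        flag = ""
        sv_dos = dos[i]
        if np.nanstd(sv_dos) == 0 or np.all(np.isnan(sv_dos)):
            flag = "monomorphic"
        elif not near.any():
            flag = "no_snp"
        else:
            r2s = np.array([pairwise_r2(sv_dos, dos[j]) for j in np.flatnonzero(near)])
            if np.all(np.isnan(r2s)):
                flag = "no_informative_snp"
            else:
                best = float(np.nanmax(r2s))
            if molqtl.any():
                jm = np.flatnonzero(near & molqtl)
                if jm.size:
                    r2m = np.array([pairwise_r2(sv_dos, dos[j]) for j in jm])
                    if not np.all(np.isnan(r2m)):
                        best_molqtl = float(np.nanmax(r2m))
        tagged = (not np.isnan(best)) and best >= tag_threshold
        rows.append(
            {
                "id": gm.variants["id"].iat[i],
                "best_r2": best,
                "tag_class": "tagged" if tagged else "independent",
                "molqtl_linked": (not np.isnan(best_molqtl))
                and best_molqtl >= molqtl_threshold,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows, columns=["id", "best_r2", "tag_class", "molqtl_linked", "flag"])


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------


def ibs_matrix(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    group_col: str = "strain",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-by-sample IBS distance and its group-averaged matrix.

    distance(i, j) = mean over variants with MAF >= ``maf_min`` and both
    samples called of |dosage_i - dosage_j| / 2.  The group matrix is
    the mean distance over all cross-group sample pairs (within-group:
    all unordered pairs of distinct samples).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    called = gm.genotypes >= 0
    alt = np.where(called, gm.genotypes, 0).sum(axis=1).astype(float)
    tot = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    dos = gm.dosage()[keep]
    n = gm.n_samples
    dist = np.full((n, n), np.nan)
    for i in range(n):
        di = dos[:, i][:, None]
        dj = dos[:, i + 1 :]
        diff = np.abs(di - dj) / 2.0
        m = np.nanmean(diff, axis=0)
        dist[i, i + 1 :] = m
        dist[i + 1 :, i] = m
        dist[i, i] = 0.0
    ids = gm.samples["id"].tolist()
    sample_df = pd.DataFrame(dist, index=ids, columns=ids)
    groups = pd.unique(gm.samples[group_col])
    gmat = pd.DataFrame(index=groups, columns=groups, dtype=float)
    gidx = {g: gm.sample_indices(group_col, g) for g in groups}
    for a in groups:
        for b in groups:
            ia, ib = gidx[a], gidx[b]
            if a == b:
                if len(ia) < 2:
                    gmat.loc[a, b] = np.nan
                    continue
                vals = [dist[i, j] for k, i in enumerate(ia) for j in ia[k + 1 :]]
            else:
                vals = dist[np.ix_(ia, ib)].ravel()
            gmat.loc[a, b] = float(np.nanmean(vals))
    return sample_df, gmat


# ---------------------------------------------------------------------------
# nIBD
# ---------------------------------------------------------------------------


def nibd(
    ibd_segments: pd.DataFrame,
    samples: pd.DataFrame,
    group_col: str,
    region: tuple[str, int, int],
) -> pd.DataFrame:
    """Normalized IBD sharing per group pair over a region.

    cIBD counts sample pairs with at least one IBD segment overlapping
    the region; tIBD is |A| x |B| for distinct groups and n(n-1)/2
    within a group; nIBD = cIBD / tIBD.
    """
    chrom, start, end = region
    seg = ibd_segments[
        (ibd_segments["chrom"] == chrom)
        & (ibd_segments["start"] < end)
        & (ibd_segments["end"] > start)
    ]
    sharing = {
        frozenset((a, b))
        for a, b in zip(seg["sample_a"], seg["sample_b"])
        if a != b
    }
    strain_of = dict(zip(samples["id"], samples[group_col]))
    groups = list(pd.unique(samples[group_col]))
    members = {g: [s for s in samples["id"] if strain_of[s] == g] for g in groups}
    rows = []
    for gi, a in enumerate(groups):
        for b in groups[gi:]:
            if not members[a] or not members[b]:
                raise ValueError(f"empty group in pair ({a}, {b})")
            if a == b:
                pairs = [
                    frozenset((x, y))
                    for k, x in enumerate(members[a])
                    for y in members[a][k + 1 :]
                ]
            else:
                pairs = [frozenset((x, y)) for x in members[a] for y in members[b]]
            t = len(pairs)
            c = sum(1 for p in pairs if p in sharing)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "cIBD": c,
                    "tIBD": t,
                    "nIBD": c / t if t else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------


def nucleotide_diversity(
    gm: GenotypeMatrix,
    windows: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Per-window pi from SNP sites: sum over sites of
    2 p (1-p) n/(n-1) divided by window length (n = called alleles)."""
    snp = gm.variants["type"].to_numpy() == "SNP"
    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    called = gm.genotypes >= 0
    alt = np.where(called, gm.genotypes, 0).sum(axis=1).astype(float)
    n_alleles = 2 * called.sum(axis=1)
    rows = []
    for chrom, start, end in windows:
        if end <= start:
            raise ValueError("zero-length window")
        m = snp & (chroms == chrom) & (pos >= start) & (pos < end) & (n_alleles > 1)
        p = alt[m] / n_alleles[m]
        n = n_alleles[m]
        pi = float(np.sum(2 * p * (1 - p) * n / (n - 1))) / (end - start)
        rows.append({"chrom": chrom, "start": start, "end": end, "pi": pi, "n_sites": int(m.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Case-control association
# ---------------------------------------------------------------------------


def assoc_case_control(
    gm: GenotypeMatrix,
    phenotype_col: str = "phenotype",
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-variant allelic case-control association with Bonferroni
    correction over the tested variants.

    ``fisher``: two-sided Fisher exact test on the allelic 2x2 table
    (default; robust at strain sample sizes).  ``logistic``: logistic
    regression of phenotype on dosage (Wald p), via statsmodels.
    """
    pheno = gm.samples[phenotype_col].to_numpy()
    if set(np.unique(pheno[~pd.isna(pheno)])) - {0, 1}:
        raise ValueError("phenotype must be binary 0/1")
    cases = pheno == 1
    controls = pheno == 0
    if not cases.any() or not controls.any():
        raise ValueError("need both cases and controls")
    rows = []
    for i in range(gm.n_variants):
        g = gm.genotypes[i]
        res = {"id": gm.variants["id"].iat[i],
               "chrom": gm.variants["chrom"].iat[i],
               "pos": gm.variants["pos"].iat[i]}
        if method == "fisher":
            a_alt = int(np.where((g >= 0) & cases, g, 0).sum())
            a_ref = int(2 * ((g >= 0) & cases).sum() - a_alt)
            b_alt = int(np.where((g >= 0) & controls, g, 0).sum())
            b_ref = int(2 * ((g >= 0) & controls).sum() - b_alt)
            table = [[a_alt, a_ref], [b_alt, b_ref]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            res["OR"], res["p"] = odds, p
        elif method == "logistic":
            import statsmodels.api as sm

            ok = g >= 0
            x = sm.add_constant(g[ok].astype(float))
            try:
                fit = sm.Logit(pheno[ok].astype(float), x).fit(disp=0)
                res["OR"] = float(np.exp(fit.params[1]))
                res["p"] = float(fit.pvalues[1])
            except Exception:
                res["OR"], res["p"] = np.nan, np.nan
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(res)
    df = pd.DataFrame(rows)
    df["p_bonf"] = np.minimum(df["p"] * len(df), 1.0)
    return df.sort_values("p", kind="stable").reset_index(drop=True)
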