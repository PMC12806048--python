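import numpy as np
import pandas as pd
import pytest

from pansv.popgen import GenotypeMatrix
from pansv.selection import (
    composite_rank,
    make_windows,
    rank_normalize,
    scale_rank,
    wc_fst_components,
    windowed_fst,
    xpehh,
)
from tests.test_popgen import make_gm


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def test_window_tiling_covers_each_position_window_over_step_times():
    windows = make_windows({"chr1": 300_000}, window=30_000, step=10_000)
    w1 = windows[windows["chrom"] == "chr1"]
    for pos in (35_000, 100_005, 250_000):
        covering = ((w1["start"] <= pos) & (w1["end"] > pos)).sum()
        assert covering == 3  # window / step


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _two_pop_gm(g_a, g_b, pos=None):
    G = np.hstack([np.asarray(g_a, dtype=np.int8), np.asarray(g_b, dtype=np.int8)])
    na, nb = np.asarray(g_a).shape[1], np.asarray(g_b).shape[1]
    return make_gm(G, strains=["A"] * na + ["B"] * nb, pos=pos)


def test_identical_populations_have_near_zero_fst(rng):
    g = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
    gm = _two_pop_gm(g, g.copy(), pos=np.arange(40) * 100)
    windows = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10_000}])
    res = windowed_fst(gm, "A", "B", windows)
    assert res["fst"].iat[0] == pytest.approx(0.0, abs=0.05)


def test_fixed_difference_gives_fst_near_one():
    g_a = np.full((10, 50), 2, dtype=np.int8)
    g_b = np.zeros((10, 50), dtype=np.int8)
    gm = _two_pop_gm(g_a, g_b, pos=np.arange(10) * 100)
    windows = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10_000}])
    res = windowed_fst(gm, "A", "B", windows)
    assert res["fst"].iat[0] == pytest.approx(1.0, abs=0.02)


def _wc_site_oracle(p1, p2, h1, h2, n1, n2):
    """Scalar per-site Weir & Cockerham (1984) components, written
    independently of the vectorized implementation."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def test_windowed_fst_matches_per_site_oracle(rng):
    g_a = rng.integers(0, 3, size=(5, 12)).astype(np.int8)
    g_b = rng.integers(0, 3, size=(5, 15)).astype(np.int8)
    gm = _two_pop_gm(g_a, g_b, pos=np.arange(5) * 100)
    windows = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10_000}])
    res = windowed_fst(gm, "A", "B", windows, floor_at_zero=False)
    num = den = 0.0
    for i in range(5):
        for g, n in ((g_a[i], 12), (g_b[i], 15)):
            pass
        p1, h1 = g_a[i].mean() / 2, (g_a[i] == 1).mean()
        p2, h2 = g_b[i].mean() / 2, (g_b[i] == 1).mean()
        a, tot = _wc_site_oracle(p1, p2, h1, h2, 12, 15)
        num += a
        den += tot
    assert res["fst_raw"].iat[0] == pytest.approx(num / den, abs=1e-12)


def test_window_without_snps_is_missing():
    gm = _two_pop_gm([[0, 1], [1, 2]], [[2, 0], [0, 1]], pos=[100, 200])
    windows = pd.DataFrame([{"chrom": "chr1", "start": 50_000, "end": 80_000}])
    res = windowed_fst(gm, "A", "B", windows)
    assert np.isnan(res["fst"].iat[0])


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------


def _hap_gm(h_a, h_b, pos):
    H = np.concatenate([h_a, h_b], axis=1)  # sites x haplotypes
    n_samp = H.shape[1] // 2
    Hs = H.reshape(H.shape[0], n_samp, 2)
    G = Hs.sum(axis=2).astype(np.int8)
    na = h_a.shape[1] // 2
    return make_gm(
        G,
        strains=["A"] * na + ["B"] * (n_samp - na),
        pos=pos,
        haplotypes=Hs.astype(np.int8),
    )


def test_identical_haplotype_sets_give_zero_scores(rng):
    h = (rng.random((60, 40)) < 0.5).astype(np.int8)
    gm = _hap_gm(h, h.copy(), pos=np.arange(60) * 500)
    windows = make_windows({"chr1": 30_000}, 30_000, 10_000)
    _, scores = xpehh(gm, "A", "B", windows)
    assert np.allclose(scores["xpehh_raw"].dropna(), 0.0)


def test_extended_haplotype_in_one_population_scores_high(rng):
    n_sites, n_hap = 300, 40
    base = (rng.random((n_sites, n_hap)) < 0.5).astype(np.int8)
    common = (rng.random(n_sites) < 0.5).astype(np.int8)
    h_a = base.copy()
    # 90% of A haplotypes share one extended haplotype over a 40-site core
    h_a[140:180, : int(0.9 * n_hap)] = common[140:180, None]
    h_b = (rng.random((n_sites, n_hap)) < 0.5).astype(np.int8)
    gm = _hap_gm(h_a, h_b, pos=np.arange(n_sites) * 500)
    windows = make_windows({"chr1": n_sites * 500}, 30_000, 10_000)
    _, scores = xpehh(gm, "A", "B", windows)
    core = scores["xpehh_std"].iloc[160]
    assert core > 2


def test_standardized_scores_have_zero_mean_unit_sd(rng):
    h_a = (rng.random((200, 30)) < 0.4).astype(np.int8)
    h_b = (rng.random((200, 30)) < 0.6).astype(np.int8)
    gm = _hap_gm(h_a, h_b, pos=np.arange(200) * 300)
    windows = make_windows({"chr1": 60_000}, 30_000, 10_000)
    _, scores = xpehh(gm, "A", "B", windows)
    s = scores["xpehh_std"].dropna()
    assert abs(s.mean()) < 0.05
    assert abs(s.std(ddof=0) - 1) < 0.05


def test_unphased_matrix_raises_with_guidance():
    gm = make_gm([[0, 1, 2, 1]], strains=["A", "A", "B", "B"])
    with pytest.raises(ValueError, match="genotype-only"):
        xpehh(gm, "A", "B", make_windows({"chr1": 1000}))


# ---------------------------------------------------------------------------
# composite rank score
# ---------------------------------------------------------------------------


def _ws(values):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(len(values)) * 10_000,
            "end": np.arange(len(values)) * 10_000 + 30_000,
            "fst": values,
        }
    )


def test_extreme_ranks_map_to_exact_scaled_values():
    out = composite_rank(_ws(np.linspace(0, 1, 11)), ["fst"], top_fraction=0.1)
    assert out["fst_S"].iloc[-1] == pytest.approx(1 / 0.001)  # R=1 -> 1000
    assert out["fst_S"].iloc[0] == 0.0  # R=0 -> 0


def test_scaled_score_strictly_increasing_in_rank():
    r = np.linspace(0, 1, 101)
    s = scale_rank(r)
    assert np.all(np.diff(s) > 0)
    assert s.max() == pytest.approx(1000.0)


def test_single_method_composite_equals_its_scaled_score():
    out = composite_rank(_ws([0.1, 0.5, 0.3, 0.9]), ["fst"], top_fraction=0.25)
    np.testing.assert_allclose(out["composite"], out["fst_S"])


def test_composite_invariant_to_monotone_transformation():
    vals = np.array([0.1, 0.5, 0.3, 0.9, 0.7])
    a = composite_rank(_ws(vals), ["fst"], top_fraction=0.2)
    b = composite_rank(_ws(np.exp(vals * 5)), ["fst"], top_fraction=0.2)
    np.testing.assert_allclose(a["composite"], b["composite"])
    assert list(a["selected"]) == list(b["selected"])


def test_all_tied_windows_flagged_degenerate():
    out = composite_rank(_ws([0.5] * 10), ["fst"], top_fraction=0.1)
    assert np.allclose(out["fst_R"], 0.5)
    assert out["selected"].sum() == 1  # stable tie order
    assert out.attrs["degenerate"]


def test_average_ranks_for_ties():
    r = rank_normalize(np.array([1.0, 2.0, 2.0, 3.0]))
    np.testing.assert_allclose(r, [0.0, 0.5, 0.5, 1.0])


def test_single_window_rank_is_an_error():
    with pytest.raises(ValueError):
        composite_rank(_ws([0.5]), ["fst"], top_fraction=0.5)


def test_missing_method_scores_average_over_available():
    ws = _ws([0.1, 0.2, 0.3, 0.4])
    ws["xpehh"] = [np.nan, 1.0, 2.0, 3.0]
    out = composite_rank(ws, ["fst", "xpehh"], top_fraction=0.25)
    assert out["n_methods"].iloc[0] == 1
    assert out["composite"].iloc[0] == pytest.approx(out["fst_S"].iloc[0])


def test_scaling_constant_below_one_rejected():
    with pytest.raises(ValueError):
        scale_rank(np.array([0.5]), constant=0.9)
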