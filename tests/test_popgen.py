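import numpy as np
import pandas as pd
import pytest

from pansv.popgen import (
    GenotypeMatrix,
    assoc_case_control,
    frequencies,
    frequency_class,
    ibs_matrix,
    ld_tagging,
    nibd,
    nucleotide_diversity,
    pairwise_r2,
    qc_genotypes,
)


def make_gm(genotypes, strains=None, types=None, pos=None, phenotype=None, haplotypes=None):
    G = np.asarray(genotypes, dtype=np.int8)
    nv, ns = G.shape
    strains = strains or ["a"] * ns
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(nv)],
            "chrom": "chr1",
            "pos": pos if pos is not None else np.arange(nv) * 1000,
            "type": types if types is not None else ["SNP"] * nv,
            "length": 1,
        }
    )
    samples = pd.DataFrame(
        {"id": [f"s{j}" for j in range(ns)], "strain": strains}
    )
    if phenotype is not None:
        samples["phenotype"] = phenotype
    return GenotypeMatrix(variants, samples, G, haplotypes)


# ---------------------------------------------------------------------------
# QC thresholds
# ---------------------------------------------------------------------------


def test_qc_removes_low_call_rate_and_low_mac():
    n = 100
    g_low_cr = np.full(n, -1, dtype=np.int8)
    g_low_cr[:29] = 1  # call rate 0.29 (and MAC 29)
    g_mac3 = np.zeros(n, dtype=np.int8)
    g_mac3[:3] = 1  # MAC exactly 3: strict threshold removes it
    g_mac4 = np.zeros(n, dtype=np.int8)
    g_mac4[:4] = 1
    g_good = np.array([0, 1, 2] * 33 + [1], dtype=np.int8)
    gm = make_gm([g_low_cr, g_mac3, g_mac4, g_good])
    kept, report = qc_genotypes(gm)
    assert list(kept.variants["id"]) == ["v2", "v3"]
    assert set(report["id"]) == {"v0", "v1"}
    assert "call_rate" in report.set_index("id").loc["v0", "reason"]


def test_qc_boundary_call_rate_is_strict():
    n = 10
    g = np.full(n, -1, dtype=np.int8)
    g[:3] = 1  # call rate exactly 0.3 -> removed ("higher than 0.3")
    gm = make_gm([g])
    kept, _ = qc_genotypes(gm)
    assert kept.n_variants == 0


# ---------------------------------------------------------------------------
# frequencies and classes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "freq,cls",
    [(0.005, "rare"), (0.01, "rare"), (0.03, "low"), (0.05, "low"),
     (0.2, "common"), (0.3, "common"), (0.5, "high")],
)
def test_frequency_class_bounds(freq, cls):
    assert frequency_class(freq) == cls


def test_deltaaf_matches_hand_arithmetic():
    # broiler-like group at p=0.100, layer-like at p=0.701
    broiler = [2] * 50 + [0] * 450  # 100 / 1000 alleles
    layer = [2] * 350 + [1] + [0] * 149  # 701 / 1000 alleles
    gm = make_gm([broiler + layer], strains=["broiler"] * 500 + ["layer"] * 500)
    rec = frequencies(gm, delta_groups=("broiler", "layer"))
    assert rec["deltaAF"].iat[0] == pytest.approx(-0.601, abs=1e-12)


def test_strain_specific_allele_detection():
    gm = make_gm(
        [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 0]],
        strains=["a", "a", "b", "b"],
    )
    rec = frequencies(gm)
    assert list(rec["strain_sharing"]) == ["specific", "shared", "absent"]


def test_group_with_no_called_alleles_reports_missing():
    gm = make_gm([[1, 1, -1, -1]], strains=["a", "a", "b", "b"])
    rec = frequencies(gm)
    assert np.isnan(rec["freq_b"].iat[0])
    assert rec["freq_a"].iat[0] == 0.5


# ---------------------------------------------------------------------------
# LD tagging
# ---------------------------------------------------------------------------


def test_identical_dosages_are_perfectly_tagged():
    col = [0, 1, 2, 1, 0, 2, 1, 0]
    gm = make_gm([col, col], types=["SNP", "SV"], pos=[1000, 2000])
    ld = ld_tagging(gm)
    assert ld["best_r2"].iat[0] == pytest.approx(1.0)
    assert ld["tag_class"].iat[0] == "tagged"


def test_sv_without_nearby_snp_is_independent_with_flag():
    col = [0, 1, 2, 1, 0, 2, 1, 0]
    gm = make_gm([col, col], types=["SNP", "SV"], pos=[1000, 500_000])
    ld = ld_tagging(gm, window_bp=100_000)
    assert ld["tag_class"].iat[0] == "independent"
    assert ld["flag"].iat[0] == "no_snp"


def test_monomorphic_sv_flagged():
    gm = make_gm([[0, 1, 2, 1], [0, 0, 0, 0]], types=["SNP", "SV"], pos=[1000, 2000])
    ld = ld_tagging(gm)
    assert ld["flag"].iat[0] == "monomorphic"


def test_planted_r2_recovered_within_tolerance(rng):
    # haplotype pair (A, B) with p=q=0.5 and D chosen so r^2 = 0.4
    D = np.sqrt(0.4) / 4
    probs = {  # P(a, b)
        (1, 1): 0.25 + D, (0, 0): 0.25 + D, (1, 0): 0.25 - D, (0, 1): 0.25 - D,
    }
    keys = list(probs)
    n = 200
    hap_idx = rng.choice(4, size=2 * n, p=[probs[k] for k in keys])
    a = np.array([keys[i][0] for i in hap_idx])
    b = np.array([keys[i][1] for i in hap_idx])
    dos_a = a[:n] + a[n:]
    dos_b = b[:n] + b[n:]
    gm = make_gm([dos_a, dos_b], types=["SNP", "SV"], pos=[1000, 2000])
    ld = ld_tagging(gm)
    assert ld["best_r2"].iat[0] == pytest.approx(0.4, abs=0.1)
    assert ld["tag_class"].iat[0] == "tagged"


def test_r2_matches_direct_correlation_on_random_toys(rng):
    for _ in range(20):
        x = rng.integers(0, 3, size=30).astype(float)
        y = rng.integers(0, 3, size=30).astype(float)
        x[rng.random(30) < 0.1] = np.nan
        y[rng.random(30) < 0.1] = np.nan
        ok = ~(np.isnan(x) | np.isnan(y))
        if x[ok].std() == 0 or y[ok].std() == 0:
            continue
        expected = np.corrcoef(x[ok], y[ok])[0, 1] ** 2
        assert pairwise_r2(x, y) == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------


def test_identical_samples_have_zero_distance():
    gm = make_gm([[1, 1], [2, 2], [0, 0], [1, 1]])
    dist, _ = ibs_matrix(gm, maf_min=0.0)
    assert dist.iloc[0, 1] == 0.0


def test_opposite_homozygotes_have_distance_one():
    gm = make_gm([[0, 2], [2, 0], [0, 2]])
    dist, _ = ibs_matrix(gm, maf_min=0.0)
    assert dist.iloc[0, 1] == 1.0


def test_three_sample_matrix_matches_hand_computation():
    # variants x samples dosages
    G = [[0, 1, 2], [2, 2, 0], [1, 1, 1], [0, 2, 2]]
    gm = make_gm(G, strains=["x", "x", "y"])
    dist, group = ibs_matrix(gm, maf_min=0.0)
    # hand: d(0,1) = (1+0+0+2)/4/2 = 0.375 ; d(0,2)=(2+2+0+2)/8=0.75 ; d(1,2)=(1+2+0+0)/8=0.375
    assert dist.iloc[0, 1] == pytest.approx(0.375)
    assert dist.iloc[0, 2] == pytest.approx(0.75)
    assert dist.iloc[1, 2] == pytest.approx(0.375)
    # group averages: within x = d(0,1); x vs y = mean(d(0,2), d(1,2))
    assert group.loc["x", "x"] == pytest.approx(0.375)
    assert group.loc["x", "y"] == pytest.approx((0.75 + 0.375) / 2)
    np.testing.assert_allclose(dist.to_numpy(), dist.to_numpy().T)
    assert np.all(np.diag(dist.to_numpy()) == 0)


def test_maf_filter_restricts_sites():
    # second variant is rare (maf 0.125 with 4 samples) and must be excluded
    G = [[0, 2, 2, 2], [1, 0, 0, 0]]
    gm = make_gm(G)
    dist_all, _ = ibs_matrix(gm, maf_min=0.0)
    dist_flt, _ = ibs_matrix(gm, maf_min=0.2)
    assert dist_flt.iloc[0, 1] == pytest.approx(1.0)  # only variant 0
    assert dist_all.iloc[0, 1] == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# nIBD
# ---------------------------------------------------------------------------


def _samples(groups):
    ids = [f"s{i}" for i in range(len(groups))]
    return pd.DataFrame({"id": ids, "strain": groups})


def test_nibd_zero_without_segments():
    res = nibd(
        pd.DataFrame(columns=["chrom", "start", "end", "sample_a", "sample_b"]),
        _samples(["A", "A", "B", "B"]),
        "strain",
        ("chr1", 0, 1000),
    )
    assert (res["nIBD"] == 0).all()


def test_nibd_one_when_all_pairs_share():
    samples = _samples(["A", "A", "B", "B"])
    rows = []
    for i in range(4):
        for j in range(i + 1, 4):
            rows.append({"chrom": "chr1", "start": 0, "end": 1000,
                         "sample_a": f"s{i}", "sample_b": f"s{j}"})
    res = nibd(pd.DataFrame(rows), samples, "strain", ("chr1", 0, 1000))
    assert (res["nIBD"] == 1.0).all()


def test_nibd_three_of_four_cross_pairs():
    samples = _samples(["A", "A", "B", "B"])
    rows = [
        {"chrom": "chr1", "start": 0, "end": 500, "sample_a": a, "sample_b": b}
        for a, b in [("s0", "s2"), ("s0", "s3"), ("s1", "s2")]
    ]
    res = nibd(pd.DataFrame(rows), samples, "strain", ("chr1", 0, 1000))
    ab = res[(res["group_a"] == "A") & (res["group_b"] == "B")]
    assert ab["cIBD"].iat[0] == 3 and ab["tIBD"].iat[0] == 4
    assert ab["nIBD"].iat[0] == 0.75


def test_nibd_ignores_segments_outside_region():
    samples = _samples(["A", "B"])
    seg = pd.DataFrame(
        [{"chrom": "chr1", "start": 5000, "end": 6000, "sample_a": "s0", "sample_b": "s1"}]
    )
    res = nibd(seg, samples, "strain", ("chr1", 0, 1000))
    ab = res[(res["group_a"] == "A") & (res["group_b"] == "B")]
    assert ab["nIBD"].iat[0] == 0.0


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def test_monomorphic_window_has_zero_pi():
    gm = make_gm([[0] * 10, [2] * 10])
    res = nucleotide_diversity(gm, [("chr1", 0, 1000)])
    assert res["pi"].iat[0] == 0.0


def test_single_site_closed_form():
    n = 1000  # 2000 alleles, p = 0.5
    gm = make_gm([[2] * (n // 2) + [0] * (n // 2)], pos=[500])
    res = nucleotide_diversity(gm, [("chr1", 0, 1000)])
    expected = 2 * 0.5 * 0.5 * (2 * n) / (2 * n - 1) / 1000
    assert res["pi"].iat[0] == pytest.approx(expected, rel=1e-12)
    assert res["pi"].iat[0] == pytest.approx(0.0005, rel=1e-3)


def test_pi_matches_allele_pair_counting_oracle(rng):
    G = rng.integers(0, 3, size=(10, 12)).astype(np.int8)
    G[rng.random(G.shape) < 0.1] = -1
    gm = make_gm(G, pos=list(range(0, 1000, 100)))
    res = nucleotide_diversity(gm, [("chr1", 0, 1000)])
    total = 0.0
    for row in G:
        alleles = []
        for g in row:
            if g >= 0:
                alleles += [1] * g + [0] * (2 - g)
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            1 for i in range(n) for j in range(i + 1, n) if alleles[i] != alleles[j]
        )
        total += diffs / (n * (n - 1) / 2)
    assert res["pi"].iat[0] == pytest.approx(total / 1000, rel=1e-10)


def test_zero_length_window_rejected():
    gm = make_gm([[0, 1]])
    with pytest.raises(ValueError):
        nucleotide_diversity(gm, [("chr1", 100, 100)])


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


def test_null_variant_has_or_near_one():
    g = [1] * 20 + [1] * 20
    gm = make_gm([g], phenotype=[1] * 20 + [0] * 20)
    res = assoc_case_control(gm)
    assert res["p"].iat[0] == pytest.approx(1.0)


def test_perfect_separation_is_bonferroni_significant():
    n = 100
    causal = [2] * 50 + [0] * 50
    noise = [0, 1] * 50
    gm = make_gm([noise, causal], phenotype=[1] * 50 + [0] * 50)
    res = assoc_case_control(gm)
    assert res["id"].iat[0] == "v1"  # smallest p first
    assert res["p_bonf"].iat[0] <= 0.01


def test_single_class_phenotype_rejected():
    gm = make_gm([[0, 1, 2]], phenotype=[1, 1, 1])
    with pytest.raises(ValueError):
        assoc_case_control(gm)


def test_statistics_invariant_to_sample_order(rng, small_cohort):
    gm = small_cohort.genotypes
    perm = rng.permutation(gm.n_samples)
    gm2 = GenotypeMatrix(
        gm.variants,
        gm.samples.iloc[perm].reset_index(drop=True),
        gm.genotypes[:, perm],
        None if gm.haplotypes is None else gm.haplotypes[:, perm],
    )
    f1 = frequencies(gm)
    f2 = frequencies(gm2)
    pd.testing.assert_frame_equal(f1, f2, check_like=True)
    k1, _ = qc_genotypes(gm)
    k2, _ = qc_genotypes(gm2)
    assert list(k1.variants["id"]) == list(k2.variants["id"])
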