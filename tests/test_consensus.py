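import dataclasses
import itertools

import numpy as np
import pytest

from pansv import simulate
from pansv.consensus import (
    SVCall,
    cluster_calls,
    filter_calls,
    merge_cohort,
    records_to_frame,
    select_representative,
)
from tests.conftest import small_config


def mk(start, end, svtype="DEL", sample="s0", tool="t0", chrom="chr1", length=None):
    if length is None:
        length = end - start if svtype == "DEL" else 100
    return SVCall(chrom, start, end, svtype, length, sample, tool)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def test_size_filter_bounds():
    calls = [
        mk(0, 40),  # 40 bp: below the 50 bp floor
        mk(100, 150),  # exactly 50: kept
        mk(1000, 151_000),  # 150 kb: above the 100 kb ceiling
        mk(200_000, 300_000),  # exactly 100 kb: kept
    ]
    kept = filter_calls(calls, min_recurrence=1)
    assert [(c.start, c.end) for c in kept] == [(100, 150), (200_000, 300_000)]


def test_recurrence_threshold_on_clustered_breakpoints():
    # one breakpoint observed 3x (within merge distance), another only 2x
    trio = [mk(1000, 2000, sample=s) for s in ("s0", "s1")] + [mk(1010, 2010, sample="s2")]
    duo = [mk(50_000, 51_000, sample=s) for s in ("s0", "s1")]
    kept = filter_calls(trio + duo, min_recurrence=3)
    assert sorted({c.start for c in kept}) == [1000, 1010]


def test_exact_recurrence_mode_counts_identical_coordinates():
    trio = [mk(1000, 2000, sample=s) for s in ("s0", "s1")] + [mk(1010, 2010, sample="s2")]
    assert filter_calls(trio, min_recurrence=3, recurrence_mode="exact") == []


def test_negative_sizes_rejected():
    with pytest.raises(ValueError):
        filter_calls([], min_size=-1)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_nearby_same_type_calls_cluster():
    clusters = cluster_calls([mk(1000, 2000), mk(1005, 2003)])
    assert len(clusters) == 1 and len(clusters[0]) == 2


def test_type_aware_clustering_separates_del_and_ins():
    clusters = cluster_calls([mk(1000, 2000), mk(1000, 1000, svtype="INS")])
    assert len(clusters) == 2


def test_single_linkage_chains_transitively():
    # A-B and B-C within 50 bp, A-C 80 bp apart: one cluster of three
    a, b, c = mk(1000, 2000), mk(1040, 2040), mk(1080, 2080)
    clusters = cluster_calls([a, b, c])
    assert len(clusters) == 1 and len(clusters[0]) == 3


def _brute_force_clusters(calls, max_dist=50):
    """Connected components over the explicit pair predicate."""
    n = len(calls)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = calls[i], calls[j]
        if (
            a.chrom == b.chrom
            and a.svtype == b.svtype
            and abs(a.start - b.start) <= max_dist
            and abs(a.end - b.end) <= max_dist
        ):
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset((calls[k].start, calls[k].end) for k in comp))
    return comps


def test_clustering_matches_brute_force_components(rng):
    for _ in range(10):
        calls = [
            mk(int(s), int(s) + int(rng.integers(60, 200)), sample=f"s{i}")
            for i, s in enumerate(rng.integers(0, 3000, size=25))
        ]
        got = {
            frozenset((c.start, c.end) for c in cl) for cl in cluster_calls(calls)
        }
        expected = set(_brute_force_clusters(calls))
        assert got == expected


def test_clusters_cover_all_calls_and_are_disjoint(rng):
    calls = [
        mk(int(s), int(s) + 100, sample=f"s{i}")
        for i, s in enumerate(rng.integers(0, 2000, size=30))
    ]
    clusters = cluster_calls(calls)
    flat = [c for cl in clusters for c in cl]
    assert len(flat) == len(calls)
    assert sorted((c.start, c.sample_id) for c in flat) == sorted(
        (c.start, c.sample_id) for c in calls
    )


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------


def test_most_frequent_coordinates_win():
    cluster = [mk(1000, 2000, sample=f"s{i}") for i in range(4)] + [mk(1005, 2003)]
    rec = select_representative(cluster)
    assert (rec.start, rec.end, rec.support, rec.cluster_size) == (1000, 2000, 4, 5)


def test_singleton_cluster_is_its_own_representative():
    rec = select_representative([mk(42, 142)])
    assert (rec.start, rec.end, rec.support) == (42, 142, 1)


def test_tie_breaks_by_distinct_tool_support():
    cluster = [
        mk(1000, 2000, tool="t0"),
        mk(1000, 2000, tool="t0", sample="s1"),
        mk(1010, 2010, tool="t0"),
        mk(1010, 2010, tool="t1", sample="s1"),
    ]
    rec = select_representative(cluster)
    assert (rec.start, rec.end) == (1010, 2010)  # 2 tools beats 1


def test_final_tie_breaks_to_smaller_start():
    cluster = [mk(1010, 2010, tool="t0"), mk(1000, 2000, tool="t1")]
    rec = select_representative(cluster)
    assert (rec.start, rec.end) == (1000, 2000)


def test_empty_cluster_is_an_error():
    with pytest.raises(ValueError):
        select_representative([])


def test_insertion_sequence_from_sequence_reporting_member():
    calls = [
        SVCall("chr1", 10, 10, "INS", 5, "s0", "t0", alt_seq=None),
        SVCall("chr1", 10, 10, "INS", 5, "s1", "t1", alt_seq="ACGTA"),
    ]
    rec = select_representative(calls)
    assert rec.seq == "ACGTA"


# ---------------------------------------------------------------------------
# cohort merge
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def noise_free_cohort():
    cfg = small_config(breakpoint_jitter_sd=0.0, fnr=0.0, fpr=0.0)
    rng = np.random.default_rng(cfg.seed)
    ref = simulate.generate_reference(cfg, rng)
    truth = simulate.plant_svs(ref, cfg, rng)
    callsets = simulate.simulate_callsets(truth, cfg, rng)
    return cfg, ref, truth, callsets


def test_noise_free_merge_recovers_exact_truth(noise_free_cohort):
    cfg, ref, truth, callsets = noise_free_cohort
    records = merge_cohort(callsets, reference=ref.sequences)
    got = {(r.chrom, r.start, r.end, r.svtype) for r in records}
    want = {
        (row.chrom, row.start, row.end, row.svtype)
        for row in truth.svs.itertuples(index=False)
    }
    assert got == want


def test_merge_is_idempotent(noise_free_cohort):
    cfg, ref, truth, callsets = noise_free_cohort
    records = merge_cohort(callsets, reference=ref.sequences)
    as_calls = [
        SVCall(r.chrom, r.start, r.end, r.svtype, r.length, "merged", "merged", r.seq)
        for r in records
    ]
    again = merge_cohort(as_calls, reference=ref.sequences, min_recurrence=1)
    assert [(r.chrom, r.start, r.end, r.svtype, r.length) for r in again] == [
        (r.chrom, r.start, r.end, r.svtype, r.length) for r in records
    ]


def test_merge_invariant_to_input_order(noise_free_cohort, rng):
    cfg, ref, truth, callsets = noise_free_cohort
    flat = [c for cs in callsets.values() for c in cs]
    records = merge_cohort(flat, reference=ref.sequences)
    shuffled = list(flat)
    rng.shuffle(shuffled)
    assert merge_cohort(shuffled, reference=ref.sequences) == records


def test_representative_coordinates_come_from_input_calls(noise_free_cohort):
    cfg, ref, truth, callsets = noise_free_cohort
    flat = [c for cs in callsets.values() for c in cs]
    coords = {(c.chrom, c.start, c.end) for c in flat}
    for r in merge_cohort(flat, reference=ref.sequences):
        assert (r.chrom, r.start, r.end) in coords


def test_jittered_merge_recovers_most_svs_within_50bp():
    cfg = small_config(breakpoint_jitter_sd=10.0, fnr=0.05, fpr=0.02)
    rng = np.random.default_rng(cfg.seed)
    ref = simulate.generate_reference(cfg, rng)
    truth = simulate.plant_svs(ref, cfg, rng)
    callsets = simulate.simulate_callsets(truth, cfg, rng)
    records = merge_cohort(callsets, reference=ref.sequences)
    recovered = 0
    for row in truth.svs.itertuples(index=False):
        for r in records:
            if (
                r.chrom == row.chrom
                and r.svtype == row.svtype
                and abs(r.start - row.start) <= 50
                and abs(r.end - row.end) <= 50
            ):
                recovered += 1
                break
    assert recovered / len(truth.svs) >= 0.95


def test_empty_input_gives_empty_output():
    assert merge_cohort([]) == []


def test_unknown_chromosome_listed_in_error():
    with pytest.raises(ValueError, match="chrZ"):
        merge_cohort([mk(0, 100, chrom="chrZ")], reference={"chr1": "A" * 200})
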