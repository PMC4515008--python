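import random

import pytest

from nclose.bloom import KmerBloom, build_from_reads
from nclose.connector import (
    BRANCH_LIMIT,
    CONSENSUS,
    LENGTH_LIMIT,
    NO_ANCHOR,
    NO_PATH,
    TOO_MANY_PATHS,
    UNIQUE,
    ConnectionResult,
    SearchParams,
    connect,
    consensus_paths,
    enumerate_paths,
    find_anchor,
)
from nclose.graph import GraphParams, neighbors
from nclose.seq_core import IUPAC_SETS, extract_kmers
from oracle_utils import dfs_paths, exact_solid_set, oracle_find_anchor

from conftest import random_dna

BIG = 1 << 20


def graph_from_reads(reads, k, threshold=2, size_bits=BIG):
    return GraphParams(k=k, bloom=build_from_reads(
        reads, k, threshold=threshold, size_bits=size_bits))


def graph_with_kmers(kmers, k):
    """A graph whose solid set is exactly the given k-mers."""
    filt = KmerBloom(k, BIG, num_levels=1)
    filt.add_sequences(kmers)
    return GraphParams(k=k, bloom=filt)


# --- neighbors -----------------------------------------------------------

def test_neighbors_single_successor():
    g = graph_from_reads(["ACGTAC"] * 2, 5)
    assert neighbors(g, "ACGTA", "right") == [("C", "CGTAC")]
    assert neighbors(g, "CGTAC", "left") == [("A", "ACGTA")]


def test_neighbors_empty_filter():
    g = GraphParams(k=5, bloom=KmerBloom(5, BIG))
    assert neighbors(g, "ACGTA", "right") == []


def test_neighbors_branching_in_base_order():
    reads = ["ACGTA"] * 2 + ["CGTAT"] * 2 + ["CGTAG"] * 2
    g = graph_from_reads(reads, 5)
    got = neighbors(g, "ACGTA", "right")
    # verify against direct membership of each of the four candidates
    expected = [(c, "CGTA" + c) for c in "ACGT" if g.bloom.solid("CGTA" + c)]
    assert got == expected
    assert got == [("G", "CGTAG"), ("T", "CGTAT")]


# --- find_anchor ---------------------------------------------------------

def test_find_anchor_terminal_kmer():
    g = graph_with_kmers(["CGTAC", "GTACG", "TACGT"], 5)
    assert find_anchor("ACGTACGT", "left", g) == ("TACGT", 0)
    # note TACGT and ACGTA are the same canonical k-mer, so the right
    # side's terminal 5' window is solid too
    assert find_anchor("ACGTACGT", "right", g) == ("ACGTA", 0)


def test_find_anchor_scans_inward():
    g = graph_with_kmers(["GTACG"], 5)
    # neither terminal window (TACGT / ACGTA, one canonical k-mer) is
    # present; the first solid window sits one base inward on each side
    assert find_anchor("ACGTACGT", "left", g) == ("GTACG", 1)
    assert find_anchor("ACGTACGT", "right", g) == ("CGTAC", 1)


def test_find_anchor_none_on_empty_filter_or_short_flank():
    g = GraphParams(k=5, bloom=KmerBloom(5, BIG))
    assert find_anchor("ACGTACGT", "left", g) is None
    g2 = graph_with_kmers(["ACGTA"], 5)
    assert find_anchor("ACG", "left", g2) is None


def test_find_anchor_respects_scan_window():
    g = graph_with_kmers(["ACGTA"], 5)
    # solid k-mer sits 3 positions inward of the 3' end
    flank = "ACGTACCC"
    assert find_anchor(flank, "left", g) == ("ACGTA", 3)
    assert find_anchor(flank, "left", g, max_flank_scan=2) is None


# --- enumerate_paths -----------------------------------------------------

def test_single_chain_yields_one_path():
    s = "ACGGTAGCCA"
    g = graph_from_reads([s, s], 5)
    status, paths = enumerate_paths(g, "ACGGT", "AGCCA", 100, 10, 100)
    assert (status, paths) == ("ok", [s])


def test_start_equals_goal_yields_zero_length_path():
    g = graph_from_reads(["ACGGTAGCCA"] * 2, 5)
    status, paths = enumerate_paths(g, "ACGGT", "ACGGT", 100, 10, 100)
    assert (status, paths) == ("ok", ["ACGGT"])


def test_snp_pair_enumerates_both_paths_and_matches_dfs():
    hap1, hap2 = "ACGGTAGCCAT", "ACGGTTGCCAT"  # one substitution apart
    reads = [hap1, hap1, hap2, hap2]
    g = graph_from_reads(reads, 5)
    status, paths = enumerate_paths(g, "ACGGT", "GCCAT", 100, 10, 100)
    assert status == "ok"
    assert paths == sorted([hap1, hap2])
    oracle = dfs_paths(exact_solid_set(reads, 5, 2), "ACGGT", "GCCAT", 100)
    assert paths == oracle


def test_no_path_on_disconnected_graph():
    g = graph_with_kmers(["AAAAA", "CCCCC"], 5)
    status, paths = enumerate_paths(g, "AAAAA", "CCCCC", 100, 10, 100)
    assert (status, paths) == (NO_PATH, [])


def test_depth_cap_reports_length_limit():
    s = "ACGGTAGCCATTG"
    g = graph_from_reads([s, s], 5)
    status, _ = enumerate_paths(g, s[:5], s[-5:], 3, 10, 100)
    assert status == LENGTH_LIMIT


def test_branch_cap_reports_branch_limit(rng):
    # dense graph: many short reads produce a tangled 4-mer graph
    reads = [random_dna(rng, 30) for _ in range(200)] * 2
    g = graph_from_reads(reads, 4)
    status, _ = enumerate_paths(g, reads[0][:4], reads[1][-4:], 200, 1000, 5)
    assert status == BRANCH_LIMIT


# --- consensus -----------------------------------------------------------

def test_consensus_single_path_verbatim():
    assert consensus_paths(["ACGGTAGCCA"]) == "ACGGTAGCCA"


def test_consensus_merges_mismatch_to_iupac():
    assert consensus_paths(["ACGGTAGCCA", "ACGGTTGCCA"]) == "ACGGTWGCCA"


def test_consensus_unequal_lengths_fails():
    assert consensus_paths(["A" * 30, "A" * 32]) is None


def test_consensus_empty_rejected():
    with pytest.raises(ValueError):
        consensus_paths([])


# --- connect -------------------------------------------------------------

def test_connect_reconstructs_unique_sequence():
    s = "ACGGTAGCCATTGCA"
    # all canonical 5-mers of s are distinct, so reconstruction is forced
    kmers = list(extract_kmers(s, 5))
    assert len({min(km, km.translate(str.maketrans('ACGT', 'TGCA'))[::-1])
                for km in kmers}) == len(kmers)
    g = graph_from_reads([s, s], 5)
    p = SearchParams(k=5, max_paths=2, max_branches=100, max_frag=100)
    res = connect(s[0:7], s[8:15], g, p)
    assert res.status == UNIQUE
    assert res.sequence == s
    assert res.num_paths == 1


def test_connect_empty_filter_gives_no_anchor():
    g = GraphParams(k=5, bloom=KmerBloom(5, BIG))
    p = SearchParams(k=5, max_frag=100)
    res = connect("ACGTACG", "TACGTAC", g, p)
    assert res.status == NO_ANCHOR
    assert res.sequence is None


def test_connect_short_flank_gives_no_anchor():
    g = graph_from_reads(["ACGGTAGCCA"] * 2, 5)
    res = connect("ACG", "AGCCA", g, SearchParams(k=5, max_frag=100))
    assert res.status == NO_ANCHOR


def test_connect_snp_pair_consensus_and_path_budget():
    hap1, hap2 = "ACGGTAGCCAT", "ACGGTTGCCAT"
    reads = [hap1, hap1, hap2, hap2]
    g = graph_from_reads(reads, 5)
    # flanks are the sequence the haplotypes share, outside the variant
    res = connect(hap1[:5], hap1[-5:], g,
                  SearchParams(k=5, max_paths=2, max_frag=100))
    assert res.status == CONSENSUS
    assert res.num_paths == 2
    assert res.sequence == "ACGGTWGCCAT"
    res1 = connect(hap1[:5], hap1[-5:], g,
                   SearchParams(k=5, max_paths=1, max_frag=100))
    assert res1.status == TOO_MANY_PATHS
    assert res1.sequence is None


def test_connect_length_cap_is_respected(rng):
    genome = random_dna(rng, 400)
    g = graph_from_reads([genome, genome], 21)
    left, right = genome[:60], genome[-60:]
    # max_frag far below the 400 bp true product: the gap must fail
    res = connect(left, right, g, SearchParams(k=21, max_frag=200))
    assert res.status in (LENGTH_LIMIT, NO_PATH)
    # and with room to spare it must succeed and respect the cap
    res2 = connect(left, right, g, SearchParams(k=21, max_frag=500))
    assert res2.status == UNIQUE
    assert res2.sequence == genome
    assert len(res2.sequence) <= 500


def test_connect_agrees_with_exhaustive_dfs_on_random_genomes(rng):
    """Dual-route check: Bloom-backed bidirectional search vs exact DFS."""
    k, flank_len = 21, 40
    for trial in range(8):
        genome = random_dna(rng, rng.randint(500, 1500))
        reads = [genome, genome]
        solid = exact_solid_set(reads, k, 2)
        g = graph_from_reads(reads, k)
        for _ in range(5):
            a = rng.randint(0, len(genome) - 2 * flank_len - 50)
            b = rng.randint(a + flank_len, min(a + flank_len + 250,
                                               len(genome) - flank_len))
            left, right = genome[a : a + flank_len], genome[b : b + flank_len]
            p = SearchParams(k=k, max_paths=50, max_branches=10_000,
                             max_frag=2 * flank_len + 300)
            res = connect(left, right, g, p)
            la = oracle_find_anchor(left, "left", solid, k)
            ra = oracle_find_anchor(right, "right", solid, k)
            if la is None or ra is None:
                assert res.status == NO_ANCHOR
                continue
            max_interior = (p.max_frag - (flank_len - la[1])
                            - (flank_len - ra[1]) + k)
            oracle = dfs_paths(solid, la[0], ra[0], max_interior)
            if res.status in (UNIQUE, CONSENSUS):
                assert sorted(res.path_seqs) == oracle
            elif res.status == TOO_MANY_PATHS:
                assert len(oracle) > p.max_paths or len(oracle) >= 2
            else:
                assert oracle == []


def test_returned_paths_are_walks_of_solid_kmers(rng):
    genome = random_dna(rng, 800)
    g = graph_from_reads([genome, genome], 15)
    res = connect(genome[:40], genome[-40:], g,
                  SearchParams(k=15, max_frag=900))
    assert res.success
    for path in res.path_seqs:
        for km in extract_kmers(path, 15):
            assert g.bloom.solid(km)


def test_consensus_sequence_present_iff_success():
    r_ok = ConnectionResult(UNIQUE, sequence="ACGT", num_paths=1)
    assert r_ok.success
    for status in (NO_PATH, TOO_MANY_PATHS, BRANCH_LIMIT, LENGTH_LIMIT,
                   NO_ANCHOR):
        assert not ConnectionResult(status).success
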