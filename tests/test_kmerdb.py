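"""k-mer profiling, Jaccard deduplication and genome clustering."""

import pytest
from Bio.Seq import Seq

from strainref.genomes import GenomeRecord
from strainref.kmerdb import (
    KmerProfile,
    build_profile,
    canonical,
    cluster_profiles,
    deduplicate,
    jaccard_similarity,
    quality_filter,
    read_database,
    write_database,
)
from strainref.synthetic import mutate_genome, simulate_genome

from conftest import make_genome, profile_of


def naive_canonical_kmers(seq: str, k: int) -> set[str]:
    """Independent oracle: enumerate windows, canonicalize via Bio.Seq."""
    out = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        rc = str(Seq(window).reverse_complement())
        out.add(min(window, rc))
    return out


class TestQualityFilter:
    def test_bounds(self):
        good = make_genome("good", ["A" * 100] * 10, coverage=50)
        at_coverage = make_genome("cov30", ["A" * 100] * 10, coverage=30.0)
        at_contigs = make_genome("c100", ["A" * 100] * 100, coverage=50)
        mag = GenomeRecord("mag", "sp", tuple(["A" * 100] * 10), coverage=None)
        kept = quality_filter([good, at_coverage, at_contigs, mag])
        assert [g.strain_id for g in kept] == ["good", "mag"]

    def test_order_preserved(self):
        gs = [make_genome(f"g{i}", "ACGT" * 50, coverage=40 + i) for i in range(5)]
        assert [g.strain_id for g in quality_filter(gs)] == [g.strain_id for g in gs]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            quality_filter([])


class TestBuildProfile:
    def test_matches_enumeration_oracle(self, toy_genome):
        prof = build_profile(toy_genome, k=5)
        assert prof.kmers == frozenset(naive_canonical_kmers("ACGTACGTACGT", 5))
        assert len(prof.kmers) <= 8  # 8 windows, deduplicated

    def test_strand_invariance(self):
        g = simulate_genome(2000, seed=7, strain_id="fwd")
        rc = GenomeRecord("rev", g.species, (str(Seq(g.sequences[0]).reverse_complement()),), 100.0)
        assert build_profile(g).kmers == build_profile(rc).kmers

    def test_n_windows_skipped(self):
        g = make_genome("n", "AAANAAA")
        assert build_profile(g, k=3).kmers == frozenset({"AAA"})

    @pytest.mark.parametrize("k", [10, 12, 1, -3])
    def test_invalid_k(self, toy_genome, k):
        with pytest.raises(ValueError):
            build_profile(toy_genome, k=k)

    def test_all_contigs_shorter_than_k(self):
        with pytest.raises(ValueError):
            build_profile(make_genome("short", ["ACGTACG", "ACGT"]), k=11)


class TestJaccard:
    def test_identical_and_disjoint(self):
        a = profile_of("a", "ACGTACGTAC")
        assert jaccard_similarity(a, a) == 1.0
        b = KmerProfile("b", 5, frozenset({"AAAAA"}))
        if not (a.kmers & b.kmers):
            assert jaccard_similarity(a, b) == 0.0

    def test_hand_built_overlap(self):
        # |A|=5, |B|=5, |A∩B|=3 -> 3/7
        shared = {"AAAAA", "AAAAC", "AAAAG"}
        a = KmerProfile("a", 5, frozenset(shared | {"AACAA", "AACAC"}))
        b = KmerProfile("b", 5, frozenset(shared | {"AAGAA", "AAGAC"}))
        assert jaccard_similarity(a, b) == pytest.approx(3 / 7)

    def test_symmetry(self):
        a = profile_of("a", "ACGTACGTACGTAAAA")
        b = profile_of("b", "ACGTACGTACGTTTTT")
        assert jaccard_similarity(a, b) == jaccard_similarity(b, a)

    def test_errors(self):
        a = profile_of("a", "ACGTACGTAC", k=5)
        b = profile_of("b", "ACGTACGTAC", k=7)
        with pytest.raises(ValueError):
            jaccard_similarity(a, b)
        empty = KmerProfile("e", 5, frozenset())
        with pytest.raises(ValueError):
            jaccard_similarity(empty, KmerProfile("f", 5, frozenset()))


class TestDeduplicate:
    def test_identical_pair_keeps_one(self):
        seq = "ACGT" * 30
        g1, g2 = make_genome("g1", seq), make_genome("g2", seq)
        profs = [build_profile(g, k=11) for g in (g1, g2)]
        kept = deduplicate(profs, 0.99, [g1, g2])
        assert [p.strain_id for p in kept] == ["g1"]  # id tie-break

    def test_priority_and_disjoint_survivor(self):
        seq = "ACGT" * 30
        other = "AACC" * 30
        # b has fewer contigs than a, so it wins the duplicate pair
        a = make_genome("a", [seq[:60], seq[60:]])
        b = make_genome("b", seq)
        c = make_genome("c", other)
        profs = {g.strain_id: build_profile(g, k=11) for g in (a, b, c)}
        kept = deduplicate(list(profs.values()), 0.99, [a, b, c])
        assert {p.strain_id for p in kept} == {"b", "c"}

    def test_half_percent_divergence_both_kept(self, ancestor_5kb):
        mutant, n_subs = mutate_genome(ancestor_5kb, 0.005, seed=11, strain_id="mut")
        assert n_subs > 0
        profs = [build_profile(ancestor_5kb), build_profile(mutant)]
        sim = jaccard_similarity(*profs)
        assert sim < 0.99  # expected shared fraction ~0.995^23
        kept = deduplicate(profs, 0.99, [ancestor_5kb, mutant])
        assert len(kept) == 2

    def test_idempotent(self, ancestor_5kb):
        genomes = [ancestor_5kb] + [
            mutate_genome(ancestor_5kb, 0.02, seed=s, strain_id=f"m{s}")[0] for s in range(3)
        ]
        profs = [build_profile(g) for g in genomes]
        once = deduplicate(profs, 0.99, genomes)
        twice = deduplicate(once, 0.99, genomes)
        assert [p.strain_id for p in once] == [p.strain_id for p in twice]

    def test_threshold_validation(self, ancestor_5kb):
        profs = [build_profile(ancestor_5kb)]
        with pytest.raises(ValueError):
            deduplicate(profs, 0.0, [ancestor_5kb])
        with pytest.raises(ValueError):
            deduplicate(profs, 1.5, [ancestor_5kb])


class TestClusterProfiles:
    def test_single_linkage_chain(self):
        # A~B and B~C exceed the 0.90 edge threshold, A~C does not; single
        # linkage must still merge all three through the chain
        pool = sorted(
            {canonical(x + y + z + u + v) for x in "ACGT" for y in "ACGT"
             for z in "ACGT" for u in "ACGT" for v in "ACGT"}
        )
        assert len(pool) >= 110
        b_set = set(pool[:100])
        a_set = (b_set - set(pool[0:5])) | set(pool[100:105])
        c_set = (b_set - set(pool[5:10])) | set(pool[105:110])
        pa = KmerProfile("A", 5, frozenset(a_set))
        pb = KmerProfile("B", 5, frozenset(b_set))
        pc = KmerProfile("C", 5, frozenset(c_set))
        assert jaccard_similarity(pa, pb) == pytest.approx(95 / 105)
        assert jaccard_similarity(pb, pc) == pytest.approx(95 / 105)
        assert jaccard_similarity(pa, pc) == pytest.approx(90 / 110)
        gs = [make_genome(s, "ACGT" * 10) for s in "ABC"]
        clusters = cluster_profiles([pa, pb, pc], 0.90, gs)
        assert len(clusters) == 1 and set(clusters[0].members) == {"A", "B", "C"}

    def test_all_singletons(self, ancestor_5kb):
        genomes = [
            simulate_genome(5000, seed=s, strain_id=f"u{s}") for s in range(3)
        ]
        profs = [build_profile(g) for g in genomes]
        clusters = cluster_profiles(profs, 0.90, genomes)
        assert len(clusters) == 3
        assert all(c.representative == c.members[0] for c in clusters)

    def test_representative_prefers_fewer_contigs(self):
        seq = "ACGT" * 50
        five = make_genome("five", [seq[i * 40 : (i + 1) * 40] for i in range(5)])
        two = make_genome("two", [seq[:100], seq[100:]])
        profs = [build_profile(g, k=11) for g in (five, two)]
        clusters = cluster_profiles(profs, 0.90, [five, two])
        assert len(clusters) == 1
        assert clusters[0].representative == "two"

    def test_partition_invariant(self, ancestor_5kb):
        genomes = [ancestor_5kb] + [
            mutate_genome(ancestor_5kb, d, seed=i, strain_id=f"d{i}")[0]
            for i, d in enumerate([0.001, 0.02, 0.1])
        ]
        profs = [build_profile(g) for g in genomes]
        clusters = cluster_profiles(profs, 0.90, genomes)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(p.strain_id for p in profs)


def test_brute_force_equivalence_small_instance():
    """Dedup and clustering agree with naive set arithmetic on 8 small genomes."""
    genomes = []
    anc1 = simulate_genome(2000, seed=21, strain_id="anc1")
    anc2 = simulate_genome(2000, seed=22, strain_id="anc2")
    genomes.extend([anc1, anc2])
    for i, (anc, d) in enumerate(
        [(anc1, 0.0001), (anc1, 0.003), (anc1, 0.05), (anc2, 0.0001), (anc2, 0.02), (anc2, 0.08)]
    ):
        genomes.append(mutate_genome(anc, d, seed=30 + i, strain_id=f"m{i}")[0])

    profs = [build_profile(g) for g in genomes]
    naive_sets = {g.strain_id: naive_canonical_kmers(g.sequences[0], 23) for g in genomes}
    by_id = {g.strain_id: g for g in genomes}

    for p in profs:
        assert set(p.kmers) == naive_sets[p.strain_id]

    def naive_jaccard(x, y):
        return len(naive_sets[x] & naive_sets[y]) / len(naive_sets[x] | naive_sets[y])

    # naive greedy dedup with the same priority rule
    order = sorted(
        naive_sets, key=lambda s: (by_id[s].n_contigs, -by_id[s].total_length, s)
    )
    naive_kept: list[str] = []
    for sid in order:
        if all(naive_jaccard(sid, other) < 0.99 for other in naive_kept):
            naive_kept.append(sid)
    kept = deduplicate(profs, 0.99, genomes)
    assert [p.strain_id for p in kept] == naive_kept

    # naive single-linkage components over Jaccard > 0.90
    ids = naive_kept
    comps = {sid: {sid} for sid in ids}
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            if naive_jaccard(x, y) > 0.90:
                merged = comps[x] | comps[y]
                for sid in merged:
                    comps[sid] = merged
    naive_clusters = sorted({frozenset(v) for v in comps.values()}, key=min)
    clusters = cluster_profiles(kept, 0.90, genomes)
    assert [set(c.members) for c in clusters] == [set(c) for c in naive_clusters]


def test_database_round_trip(tmp_path, ancestor_5kb):
    mutant, _ = mutate_genome(ancestor_5kb, 0.02, seed=5, strain_id="mutdb")
    profs = [build_profile(ancestor_5kb), build_profile(mutant)]
    path = tmp_path / "db.txt"
    write_database(profs, path)
    back = read_database(path)
    assert {p.strain_id: p.kmers for p in back} == {p.strain_id: p.kmers for p in profs}
    assert all(p.k == 23 for p in back)
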