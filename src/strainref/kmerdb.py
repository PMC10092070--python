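"""Species-specific strain databases built from canonical k-mer profiles.

Each genome is reduced to the set of its canonical k-mers (default k=23;
a k-mer and its reverse complement are the same observation, so the
lexicographically smaller of the two is stored). Near-identical assemblies
are removed by a greedy Jaccard-similarity pass at 0.99, and the survivors
are grouped into single-linkage clusters at Jaccard > 0.90, keeping one
representative per cluster. Representatives are chosen by assembly
contiguity: fewest contigs, then largest total length, then strain id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .genomes import GenomeRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_K = 23


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Return min(kmer, reverse_complement(kmer)) lexicographically."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def iter_canonical_kmers(seq: str, k: int) -> Iterable[str]:
    """Yield canonical k-mers of *seq*, skipping windows that contain N.

    Tracks the position of the most recent N so each window is tested in
    O(1) instead of rescanning its characters.
    """
    last_n = -1
    n = len(seq)
    for i in range(n):
        if seq[i] == "N":
            last_n = i
        if i >= k - 1 and last_n <= i - k:
            yield canonical(seq[i - k + 1 : i + 1])


@dataclass(frozen=True)
class KmerProfile:
    """Canonical k-mer set of one genome."""

    strain_id: str
    k: int
    kmers: frozenset[str]

    def __post_init__(self) -> None:
        if any(len(km) != self.k for km in self.kmers):
            raise ValueError("k-mer length does not match k")


@dataclass(frozen=True)
class GenomeCluster:
    members: tuple[str, ...]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


def quality_filter(
    genomes: Sequence[GenomeRecord],
    min_coverage: float = 30,
    max_contigs: int = 100,
) -> list[GenomeRecord]:
    """Retain genomes with coverage strictly above *min_coverage* (when known)
    and strictly fewer than *max_contigs* contigs. MAGs without a coverage
    estimate are filtered on contig count alone. Input order is preserved."""
    if not genomes:
        raise ValueError("no genomes supplied")
    kept = []
    for g in genomes:
        if g.n_contigs >= max_contigs:
            continue
        if g.coverage is not None and g.coverage <= min_coverage:
            continue
        kept.append(g)
    return kept


def build_profile(genome: GenomeRecord, k: int = DEFAULT_K) -> KmerProfile:
    """Collect the canonical k-mer set over all contigs of *genome*."""
    # odd k so no k-mer is its own reverse complement; 23 is the working
    # default, small odd k remains available for toy examples
    if k % 2 == 0 or k < 3:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    if all(len(s) < k for s in genome.sequences):
        raise ValueError(
            f"genome {genome.strain_id!r}: every contig is shorter than k={k}"
        )
    kmers: set[str] = set()
    for seq in genome.sequences:
        kmers.update(iter_canonical_kmers(seq, k))
    return KmerProfile(strain_id=genome.strain_id, k=k, kmers=frozenset(kmers))


def jaccard_similarity(a: KmerProfile, b: KmerProfile) -> float:
    """|A ∩ B| / |A ∪ B| over the two canonical k-mer sets."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if not a.kmers and not b.kmers:
        raise ValueError("Jaccard similarity of two empty profiles is undefined")
    inter = len(a.kmers & b.kmers)
    union = len(a.kmers) + len(b.kmers) - inter
    return inter / union


def _containment(candidate: KmerProfile, kept: KmerProfile) -> float:
    # fraction of the candidate's k-mers already present in the kept profile
    if not candidate.kmers:
        raise ValueError("empty profile")
    return len(candidate.kmers & kept.kmers) / len(candidate.kmers)


def _priority_key(genome: GenomeRecord) -> tuple:
    return (genome.n_contigs, -genome.total_length, genome.strain_id)


def _genome_map(
    profiles: Sequence[KmerProfile], genomes: Sequence[GenomeRecord]
) -> Mapping[str, GenomeRecord]:
    by_id = {g.strain_id: g for g in genomes}
    missing = [p.strain_id for p in profiles if p.strain_id not in by_id]
    if missing:
        raise ValueError(f"profiles without a genome record: {missing}")
    return by_id


def deduplicate(
    profiles: Sequence[KmerProfile],
    identity_threshold: float = 0.99,
    genomes: Sequence[GenomeRecord] = (),
    mode: Literal["jaccard", "containment"] = "jaccard",
) -> list[KmerProfile]:
    """Greedy redundancy removal: profiles are visited in priority order
    (fewest contigs, largest genome, strain id) and dropped when their
    similarity to any already-kept profile reaches *identity_threshold*.

    ``mode="containment"`` replaces Jaccard with the fraction of the
    candidate's k-mers contained in the kept profile.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    by_id = _genome_map(profiles, genomes)
    ordered = sorted(profiles, key=lambda p: _priority_key(by_id[p.strain_id]))
    kept: list[KmerProfile] = []
    for prof in ordered:
        redundant = False
        for other in kept:
            sim = (
                jaccard_similarity(prof, other)
                if mode == "jaccard"
                else _containment(prof, other)
            )
            if sim >= identity_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(prof)
    return kept


def cluster_profiles(
    profiles: Sequence[KmerProfile],
    cluster_threshold: float = 0.90,
    genomes: Sequence[GenomeRecord] = (),
) -> list[GenomeCluster]:
    """Single-linkage connected components over edges with Jaccard strictly
    above *cluster_threshold*; one representative per cluster by the same
    contiguity priority used in deduplication."""
    by_id = _genome_map(profiles, genomes)
    n = len(profiles)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if jaccard_similarity(profiles[i], profiles[j]) > cluster_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[KmerProfile]] = {}
    for i, prof in enumerate(profiles):
        groups.setdefault(find(i), []).append(prof)

    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda p: _priority_key(by_id[p.strain_id]))
        clusters.append(
            GenomeCluster(
                members=tuple(sorted(p.strain_id for p in members)),
                representative=rep.strain_id,
            )
        )
    clusters.sort(key=lambda c: c.members[0])
    return clusters


# --- database and cluster I/O (plain text, one profile per strain) ---------


def write_database(profiles: Sequence[KmerProfile], path: str | Path) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    ks = {p.k for p in profiles}
    if len(ks) > 1:
        raise ValueError(f"profiles have mixed k: {sorted(ks)}")
    with open(path, "w") as fh:
        fh.write(f"#k\t{profiles[0].k}\n")
        for p in profiles:
            fh.write(f">{p.strain_id}\n")
            for km in sorted(p.kmers):
                fh.write(km + "\n")


def read_database(path: str | Path) -> list[KmerProfile]:
    profiles: list[KmerProfile] = []
    k = None
    strain = None
    kmers: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#k"):
                k = int(line.split("\t")[1])
            elif line.startswith(">"):
                if strain is not None:
                    profiles.append(KmerProfile(strain, k, frozenset(kmers)))
                strain = line[1:]
                kmers = set()
            else:
                kmers.add(line)
    if strain is not None:
        profiles.append(KmerProfile(strain, k, frozenset(kmers)))
    if k is None:
        raise ValueError(f"{path}: missing '#k' header")
    return profiles


def write_clusters(clusters: Sequence[GenomeCluster], path: str | Path) -> None:
    rows = [
        {
            "cluster_id": f"KC{i+1}",
            "representative": c.representative,
            "members": ",".join(c.members),
        }
        for i, c in enumerate(clusters)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
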