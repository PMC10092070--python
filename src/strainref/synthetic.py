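"""Seeded generators for every input the pipeline consumes.

These emulate the study conditions end to end without any download:
ancestral genomes, derived strains at controlled substitution divergence
(so the true nucleotide identity is analytically known), metagenome k-mer
samples with planted strain prevalences and decoy k-mers, toy count
tables with planted up/down-regulated gene fractions, and a full
multi-species strain collection for pipeline-level recovery checks.
All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genomes import GenomeRecord
from .kmerdb import DEFAULT_K, KmerProfile, build_profile, canonical
from .strain_profiler import SampleKmerSet
from .transcriptome import CountTable

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 50_000
    gc_content: float = 0.5
    divergences: tuple[float, ...] = (0.005, 0.02, 0.03, 0.05)
    n_samples: int = 50
    planted_prevalences: tuple[float, ...] = (0.6, 0.15, 0.1, 0.05)
    contamination_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        for p in self.divergences + self.planted_prevalences:
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    strain_id: Optional[str] = None,
    species: str = "sim_species",
) -> GenomeRecord:
    """Single-contig i.i.d. nucleotide sequence with expected GC content
    *gc*; coverage set to a 100x sentinel so quality filters pass."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
    return GenomeRecord(
        strain_id=strain_id or f"sim{seed}",
        species=species,
        sequences=(seq,),
        coverage=100.0,
    )


def mutate_genome(
    g: GenomeRecord,
    substitution_rate: float,
    seed: int = 0,
    strain_id: Optional[str] = None,
) -> tuple[GenomeRecord, int]:
    """Substitute each base independently (to a different base) with the
    given probability; returns the derived genome and the realized
    substitution count, from which the true identity to the ancestor is
    1 - count/length exactly (no indels)."""
    if not (0 <= substitution_rate <= 0.2):
        raise ValueError("substitution_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    new_seqs = []
    n_subs = 0
    for seq in g.sequences:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        mask = rng.random(len(arr)) < substitution_rate
        idx = np.nonzero(mask)[0]
        n_subs += len(idx)
        for i in idx:
            base = arr[i].decode()
            choices = [b for b in "ACGT" if b != base]
            arr[i] = rng.choice(choices).encode()
        new_seqs.append(arr.tobytes().decode())
    derived = GenomeRecord(
        strain_id=strain_id or f"{g.strain_id}_mut",
        species=g.species,
        sequences=tuple(new_seqs),
        coverage=g.coverage,
    )
    return derived, n_subs


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> set[str]:
    kmers: set[str] = set()
    while len(kmers) < n:
        batch = rng.integers(0, 4, size=(max(n - len(kmers), 1), k))
        for row in batch:
            kmers.add(canonical("".join("ACGT"[b] for b in row)))
            if len(kmers) >= n:
                break
    return kmers


def simulate_sample(
    db_strains: Sequence[KmerProfile],
    present: Iterable[str],
    contamination_fraction: float = 0.0,
    seed: int = 0,
    sample_id: str = "sample",
) -> SampleKmerSet:
    """Union of the present strains' k-mer sets plus uniformly random decoy
    canonical k-mers amounting to *contamination_fraction* of the union."""
    if contamination_fraction < 0:
        raise ValueError("contamination_fraction must be >= 0")
    by_id = {p.strain_id: p for p in db_strains}
    present = list(present)
    unknown = [s for s in present if s not in by_id]
    if unknown:
        raise ValueError(f"present strains not in database: {unknown}")
    ks = {p.k for p in db_strains}
    if len(ks) != 1:
        raise ValueError("database profiles have mixed k")
    k = ks.pop()
    kmers: set[str] = set()
    for sid in present:
        kmers |= by_id[sid].kmers
    n_decoys = round(contamination_fraction * len(kmers))
    if n_decoys:
        rng = np.random.default_rng(seed)
        kmers |= _random_kmers(rng, n_decoys, k)
    return SampleKmerSet(sample_id=sample_id, k=k, kmers=frozenset(kmers))


def simulate_count_table(
    n_genes: int,
    n_up: int,
    n_down: int,
    fc_up: float = 8.0,
    fc_down: float = 0.1,
    base_mean: float = 500.0,
    seed: int = 0,
) -> CountTable:
    """Poisson count table with the first *n_up* genes up-regulated by
    *fc_up*, the next *n_down* down-regulated by *fc_down*, the rest flat.
    Gene lengths are uniform in [300, 3000]; library totals are the column
    sums, so realized fold changes carry the resulting normalization factor."""
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    if not fc_up > 5:
        raise ValueError("fc_up must exceed the >5 bin threshold")
    if not fc_down < 0.25:
        raise ValueError("fc_down must lie below the <0.25 bin threshold")
    rng = np.random.default_rng(seed)
    factors = np.ones(n_genes)
    factors[:n_up] = fc_up
    factors[n_up : n_up + n_down] = fc_down
    lengths = rng.integers(300, 3001, size=n_genes)
    count_control = rng.poisson(base_mean, size=n_genes)
    count_test = rng.poisson(base_mean * factors)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i+1:05d}" for i in range(n_genes)],
            "gene_length": lengths,
            "count_test": count_test,
            "count_control": count_control,
        }
    )
    return CountTable(
        genes=genes,
        total_test=int(count_test.sum()),
        total_control=int(count_control.sum()),
    )


@dataclass
class StrainCollection:
    """A planted multi-species strain collection with metagenome samples."""

    genomes: list[GenomeRecord]
    profiles: list[KmerProfile]
    samples: list[SampleKmerSet]
    planted_prevalence: dict[str, float]
    central_strains: dict[str, str]  # species -> the planted "best" strain
    species_of: dict[str, str]

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strain_id": g.strain_id,
                    "species": g.species,
                    "coverage": g.coverage,
                    "n_contigs": g.n_contigs,
                }
                for g in self.genomes
            ]
        )


def simulate_collection(
    n_species: int = 3,
    strains_per_species: int = 4,
    n_samples: int = 50,
    genome_length: int = 15_000,
    k: int = DEFAULT_K,
    divergences: Sequence[float] = (0.005, 0.02, 0.03, 0.05),
    prevalences: Sequence[float] = (0.6, 0.15, 0.1, 0.05),
    contamination_fraction: float = 0.05,
    seed: int = 0,
) -> StrainCollection:
    """Simulate a strain collection with a planted answer.

    Per species, an ancestral genome spawns ``strains_per_species`` derived
    strains; the first ("central") strain sits closest to the ancestor and
    carries the highest planted prevalence, so it is the expected
    reference-strain designation. Each sample carries at most one strain
    per species (the locally dominant strain), drawn according to the
    planted prevalences, plus random decoy k-mers.
    """
    if strains_per_species > len(divergences) or strains_per_species > len(prevalences):
        raise ValueError("need a divergence and prevalence per strain")
    if sum(prevalences[:strains_per_species]) > 1:
        raise ValueError("per-species prevalences must sum to <= 1")
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    planted: dict[str, float] = {}
    central: dict[str, str] = {}
    species_of: dict[str, str] = {}
    for si in range(n_species):
        species = f"species{si+1}"
        ancestor = simulate_genome(
            genome_length, gc=0.5, seed=int(rng.integers(2**31)), species=species
        )
        for ti in range(strains_per_species):
            strain_id = f"sp{si+1}_s{ti+1}"
            derived, _ = mutate_genome(
                ancestor, divergences[ti], seed=int(rng.integers(2**31)), strain_id=strain_id
            )
            genomes.append(derived)
            planted[strain_id] = float(prevalences[ti])
            species_of[strain_id] = species
            if ti == 0:
                central[species] = strain_id
    profiles = [build_profile(g, k=k) for g in genomes]

    samples: list[SampleKmerSet] = []
    cum = np.cumsum(prevalences[:strains_per_species])
    for n in range(n_samples):
        present: list[str] = []
        for si in range(n_species):
            r = rng.random()
            for ti in range(strains_per_species):
                if r < cum[ti]:
                    present.append(f"sp{si+1}_s{ti+1}")
                    break
        samples.append(
            simulate_sample(
                profiles,
                present,
                contamination_fraction=contamination_fraction,
                seed=int(rng.integers(2**31)),
                sample_id=f"sample{n+1:03d}",
            )
        )
    return StrainCollection(
        genomes=genomes,
        profiles=profiles,
        samples=samples,
        planted_prevalence=planted,
        central_strains=central,
        species_of=species_of,
    )
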