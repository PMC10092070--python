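"""Strain detection in metagenomic samples and collection-level filters.

A sample is reduced to a canonical k-mer set and screened against the
strain database with a greedy iterative matcher: at each round the strain
whose k-mers are best covered by the remaining sample k-mers is reported
(if its match fraction clears the detection threshold) and its k-mers are
subtracted before the next round. Prevalence of a strain is the fraction
of collection samples in which it is detected at least once.

The module also hosts the collection-level abundance filters: core-species
selection (prevalence and mean relative abundance cutoffs), selection of
samples rich in a target genus, and the per-cohort summary table of a
metagenome collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .kmerdb import KmerProfile, iter_canonical_kmers


@dataclass(frozen=True)
class SampleKmerSet:
    sample_id: str
    k: int
    kmers: frozenset[str]


@dataclass(frozen=True)
class StrainDetection:
    sample_id: str
    strain_id: str
    iteration: int
    match_fraction: float


def sample_from_sequences(sample_id: str, sequences: Iterable[str], k: int) -> SampleKmerSet:
    """k-merize raw read/contig sequences into a sample k-mer set."""
    kmers: set[str] = set()
    for seq in sequences:
        kmers.update(iter_canonical_kmers(seq.upper(), k))
    return SampleKmerSet(sample_id=sample_id, k=k, kmers=frozenset(kmers))


def detect_strains(
    sample: SampleKmerSet,
    db: Sequence[KmerProfile],
    min_match: float = 0.90,
    max_iterations: int = 5,
) -> list[StrainDetection]:
    """Greedy iterative strain detection against the database.

    Each iteration scores every database strain by the fraction of its
    k-mers present in the *remaining* sample set, reports the best strain
    when that fraction reaches ``min_match`` (ties broken by strain id),
    removes its k-mers and repeats, up to ``max_iterations`` rounds.
    """
    if not db:
        raise ValueError("empty database")
    for prof in db:
        if prof.k != sample.k:
            raise ValueError(
                f"k mismatch: sample k={sample.k}, db strain {prof.strain_id} k={prof.k}"
            )
    remaining = set(sample.kmers)
    detections: list[StrainDetection] = []
    reported: set[str] = set()
    for iteration in range(1, max_iterations + 1):
        best: Optional[KmerProfile] = None
        best_frac = -1.0
        for prof in db:
            if prof.strain_id in reported or not prof.kmers:
                continue
            frac = len(prof.kmers & remaining) / len(prof.kmers)
            if frac > best_frac or (frac == best_frac and best is not None and prof.strain_id < best.strain_id):
                best, best_frac = prof, frac
        if best is None or best_frac < min_match:
            break
        detections.append(
            StrainDetection(sample.sample_id, best.strain_id, iteration, best_frac)
        )
        reported.add(best.strain_id)
        remaining -= best.kmers
    return detections


def compute_prevalence(
    detections: Sequence[StrainDetection],
    n_samples: int,
    min_prevalence: float = 0.001,
    sample_ids: Optional[Iterable[str]] = None,
) -> dict[str, float]:
    """Fraction of samples with at least one detection per strain.

    Strains at or below ``min_prevalence`` are dropped (strict >). If
    ``sample_ids`` is given, detections referencing unknown samples raise.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    known = set(sample_ids) if sample_ids is not None else None
    seen: dict[str, set[str]] = {}
    for det in detections:
        if known is not None and det.sample_id not in known:
            raise ValueError(f"detection references unknown sample {det.sample_id!r}")
        seen.setdefault(det.strain_id, set()).add(det.sample_id)
    table = {
        strain: len(samples) / n_samples
        for strain, samples in sorted(seen.items())
    }
    return {s: p for s, p in table.items() if p > min_prevalence}


def core_species(
    abund: pd.DataFrame,
    min_prevalence_pct: float = 10,
    min_mean_abundance_pct: float = 0.5,
) -> list[str]:
    """Taxa detected (>0) in more than *min_prevalence_pct* percent of samples
    AND with mean relative abundance above *min_mean_abundance_pct* percent;
    both cutoffs strict. Abundances are percentages, samples as rows."""
    if (abund.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    prevalence_pct = (abund > 0).mean(axis=0) * 100
    mean_abund = abund.mean(axis=0)
    keep = (prevalence_pct > min_prevalence_pct) & (mean_abund > min_mean_abundance_pct)
    return [taxon for taxon in abund.columns if keep[taxon]]


def select_high_genus_samples(
    abund: pd.DataFrame, genus: str, min_abundance_pct: float = 10
) -> list[str]:
    """Samples whose relative abundance of *genus* is strictly above the
    cutoff, in input order."""
    if genus not in abund.columns:
        raise ValueError(f"genus {genus!r} not in abundance table")
    mask = abund[genus] > min_abundance_pct
    return [str(s) for s in abund.index[mask]]


def summarize_collection(counts: Sequence[tuple[str, int]]) -> pd.DataFrame:
    """Per-group sample counts with percentages of the collection total.

    Returns a table with columns ``group``, ``n``, ``percent`` (rounded to
    two decimals) and a final ``Total`` row.
    """
    if any(n < 0 for _, n in counts):
        raise ValueError("negative counts")
    total = sum(n for _, n in counts)
    if total == 0:
        raise ValueError("all counts are zero")
    rows = [
        {"group": label, "n": n, "percent": round(100 * n / total, 2)}
        for label, n in counts
    ]
    rows.append({"group": "Total", "n": total, "percent": 100.00})
    return pd.DataFrame(rows)


# --- I/O ---------------------------------------------------------------


def write_sample(sample: SampleKmerSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k\t{sample.k}\n#sample\t{sample.sample_id}\n")
        for km in sorted(sample.kmers):
            fh.write(km + "\n")


def read_sample(path: str | Path) -> SampleKmerSet:
    k = None
    sample_id = Path(path).stem
    kmers: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#k"):
                k = int(line.split("\t")[1])
            elif line.startswith("#sample"):
                sample_id = line.split("\t")[1]
            else:
                kmers.add(line)
    if k is None:
        raise ValueError(f"{path}: missing '#k' header")
    return SampleKmerSet(sample_id=sample_id, k=k, kmers=frozenset(kmers))


def write_detections(detections: Sequence[StrainDetection], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "strain_id": d.strain_id,
                "iteration": d.iteration,
                "match_fraction": d.match_fraction,
            }
            for d in detections
        ],
        columns=["sample_id", "strain_id", "iteration", "match_fraction"],
    ).to_csv(path, sep="\t", index=False)


def write_prevalence(prevalence: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"strain_id": s, "prevalence": p} for s, p in prevalence.items()],
        columns=["strain_id", "prevalence"],
    ).to_csv(path, sep="\t", index=False)


def read_prevalence(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str})
    return dict(zip(df["strain_id"], df["prevalence"].astype(float)))
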