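"""Genome assemblies and their metadata.

A :class:`GenomeRecord` is the unit every downstream step consumes: one
strain, one or more contigs, an optional sequencing fold-coverage (absent
for metagenome-assembled genomes of unknown depth) and a species label.
Genomes are read from per-strain multi-FASTA files accompanied by a
metadata table (TSV with columns ``strain_id``, ``species``, ``coverage``,
``n_contigs``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """One strain's assembly: contig sequences plus assembly metadata."""

    strain_id: str
    species: str
    sequences: tuple[str, ...]
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"genome {self.strain_id!r} has no sequences")
        seqs = tuple(s.upper() for s in self.sequences)
        for s in seqs:
            bad = set(s) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"genome {self.strain_id!r} contains invalid characters: {sorted(bad)}"
                )
        object.__setattr__(self, "sequences", seqs)

    @property
    def n_contigs(self) -> int:
        return len(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the strain metadata table (strain_id, species, coverage, n_contigs)."""
    meta = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "species": str})
    required = {"strain_id", "species"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return meta


def read_genome_fasta(
    path: str | Path, strain_id: str, species: str, coverage: Optional[float] = None
) -> GenomeRecord:
    seqs = tuple(str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
    return GenomeRecord(strain_id=strain_id, species=species, sequences=seqs, coverage=coverage)


def read_genome_dir(genome_dir: str | Path, metadata: pd.DataFrame) -> list[GenomeRecord]:
    """Load one FASTA per strain from *genome_dir*, named ``<strain_id>.fasta``.

    Coverage may be NaN/empty in the metadata, in which case the genome is
    treated as a MAG of unknown depth.
    """
    genome_dir = Path(genome_dir)
    genomes: list[GenomeRecord] = []
    for row in metadata.itertuples(index=False):
        cov = getattr(row, "coverage", None)
        if cov is not None and (cov == "" or (isinstance(cov, float) and math.isnan(cov))):
            cov = None
        path = genome_dir / f"{row.strain_id}.fasta"
        if not path.exists():
            path = genome_dir / f"{row.strain_id}.fa"
        if not path.exists():
            raise FileNotFoundError(f"no FASTA for strain {row.strain_id!r} in {genome_dir}")
        genomes.append(
            read_genome_fasta(path, str(row.strain_id), str(row.species),
                              None if cov is None else float(cov))
        )
    return genomes


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{genome.strain_id}_contig{i+1}", description="")
        for i, s in enumerate(genome.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_collection(
    genomes: Iterable[GenomeRecord], out_dir: str | Path, metadata_name: str = "metadata.tsv"
) -> Path:
    """Write one FASTA per genome plus the metadata TSV; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in genomes:
        write_genome_fasta(g, out_dir / f"{g.strain_id}.fasta")
        rows.append(
            {
                "strain_id": g.strain_id,
                "species": g.species,
                "coverage": g.coverage,
                "n_contigs": g.n_contigs,
            }
        )
    meta_path = out_dir / metadata_name
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    return meta_path
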