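"""Biobank screening against designated reference strains (RefBifSelector).

A local candidate genome is compared to its species' reference on two
axes: nucleotide identity (fragment ANI, percent) and proteome similarity,
summarized as Average_PPOS — the mean percentage of positive-scoring
matches over bidirectional-best-hit protein pairs, where PPOS of one
alignment is 100 * (identical + similar residue pairs) / alignment length
under BLOSUM62 local alignment (gap open 11, extend 1), "similar" meaning
a positive substitution score. The final score is ANI * Average_PPOS with
a default acceptance threshold of 9600; candidates below it are flagged
as unsuitable stand-ins for the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .ani_phylo import compute_ani
from .genomes import GenomeRecord

PASS_THRESHOLD = 9600.0

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ProteinSet:
    strain_id: str
    proteins: tuple[tuple[str, str], ...]  # (protein_id, sequence)

    def __post_init__(self) -> None:
        # an empty tuple is tolerated (a genome may yield no ORFs); operations
        # that require proteins raise at the point of use
        for pid, seq in self.proteins:
            if not seq:
                raise ValueError(f"protein {pid!r} is empty")
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise ValueError(f"protein {pid!r} has invalid residues: {sorted(bad)}")


@dataclass(frozen=True)
class AlignmentSummary:
    query_id: str
    target_id: str
    alignment_length: int  # aligned columns, gaps included
    n_identical: int
    n_similar: int  # positive-scoring non-identical pairs
    score: float

    def __post_init__(self) -> None:
        if self.n_identical + self.n_similar > self.alignment_length:
            raise ValueError("identical + similar pairs exceed alignment length")


@dataclass(frozen=True)
class LocalScore:
    query_strain: str
    reference_strain: str
    ani_pct: float
    avg_ppos_pct: float
    score: float
    passes: bool
    threshold: float = PASS_THRESHOLD

    def __post_init__(self) -> None:
        if abs(self.score - self.ani_pct * self.avg_ppos_pct) > 1e-9:
            raise ValueError("score is inconsistent with ANI * Average_PPOS")
        if self.passes != (self.score >= self.threshold):
            raise ValueError("pass flag is inconsistent with the threshold")


def call_orfs(genome: GenomeRecord, min_len_nt: int = 300) -> ProteinSet:
    """Naive ORF calling: maximal ATG-to-stop open reading frames of at
    least *min_len_nt* nucleotides (stop included) on all six frames,
    translated with the standard code, stop codon excluded. A genome with
    no qualifying ORF yields an empty protein set."""
    proteins: list[tuple[str, str]] = []
    counter = 0
    for contig in genome.sequences:
        for strand_seq in (contig, str(Seq(contig).reverse_complement())):
            for frame in range(3):
                start = None
                for pos in range(frame, len(strand_seq) - 2, 3):
                    codon = strand_seq[pos : pos + 3]
                    if codon in _STOP_CODONS:
                        if start is not None:
                            orf = strand_seq[start : pos + 3]
                            if len(orf) >= min_len_nt:
                                counter += 1
                                aa = str(Seq(orf[:-3]).translate())
                                proteins.append((f"{genome.strain_id}_p{counter}", aa))
                            start = None
                    elif start is None and codon == "ATG":
                        start = pos
    return ProteinSet(strain_id=genome.strain_id, proteins=tuple(proteins))


def _make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    # BLAST-style affine cost: a gap of length L costs 11 + L
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def align_protein_pair(
    q: tuple[str, str], t: tuple[str, str], aligner: Optional[Align.PairwiseAligner] = None
) -> AlignmentSummary:
    """Local BLOSUM62 alignment of two proteins given as (id, sequence)."""
    qid, qseq = q
    tid, tseq = t
    if not qseq or not tseq:
        raise ValueError("cannot align an empty protein sequence")
    if aligner is None:
        aligner = _make_protein_aligner()
    alignments = aligner.align(qseq, tseq)
    aln = alignments[0]
    n_identical = 0
    n_similar = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            a, b = qseq[qi], tseq[ti]
            if a == b:
                n_identical += 1
            elif _BLOSUM62[a, b] > 0:
                n_similar += 1
    return AlignmentSummary(
        query_id=qid,
        target_id=tid,
        alignment_length=int(aln.length),
        n_identical=n_identical,
        n_similar=n_similar,
        score=float(alignments.score),
    )


def ppos(summary: AlignmentSummary) -> float:
    """100 * (identical + similar matches) / alignment length."""
    if summary.alignment_length <= 0:
        raise ValueError("zero-length alignment")
    return 100.0 * (summary.n_identical + summary.n_similar) / summary.alignment_length


def average_ppos(a: ProteinSet, b: ProteinSet) -> Optional[float]:
    """Mean PPOS over bidirectional best hits between two proteomes.

    Best hits are by alignment score with ties broken by target protein id;
    a pair is kept when each member is the other's best hit. Returns None
    when no such pair exists (practically only for degenerate inputs)."""
    if not a.proteins or not b.proteins:
        raise ValueError("cannot compute Average_PPOS for an empty protein set")
    aligner = _make_protein_aligner()
    summaries: dict[tuple[str, str], AlignmentSummary] = {}
    for qp in a.proteins:
        for tp in b.proteins:
            summaries[(qp[0], tp[0])] = align_protein_pair(qp, tp, aligner)

    def best_hits(queries, targets, lookup):
        hits = {}
        for qid in queries:
            hits[qid] = min(targets, key=lambda tid: (-lookup(qid, tid).score, tid))
        return hits

    a_ids = [p[0] for p in a.proteins]
    b_ids = [p[0] for p in b.proteins]
    fwd = best_hits(a_ids, b_ids, lambda q, t: summaries[(q, t)])
    rev = best_hits(b_ids, a_ids, lambda q, t: summaries[(t, q)])
    pairs = [(qid, tid) for qid, tid in fwd.items() if rev[tid] == qid]
    if not pairs:
        return None
    return float(np.mean([ppos(summaries[pair]) for pair in pairs]))


def local_score(
    query_strain: str,
    reference_strain: str,
    ani_pct: float,
    avg_ppos_pct: float,
    threshold: float = PASS_THRESHOLD,
) -> LocalScore:
    """Combine precomputed ANI and Average_PPOS percentages into the final
    screening score and pass/fail flag."""
    score = ani_pct * avg_ppos_pct
    return LocalScore(
        query_strain=query_strain,
        reference_strain=reference_strain,
        ani_pct=ani_pct,
        avg_ppos_pct=avg_ppos_pct,
        score=score,
        passes=score >= threshold,
        threshold=threshold,
    )


def score_local_candidate(
    query: tuple[GenomeRecord, ProteinSet],
    reference: tuple[GenomeRecord, ProteinSet],
    threshold: float = PASS_THRESHOLD,
    **ani_kwargs,
) -> LocalScore:
    """Score one biobank candidate against one reference strain."""
    q_genome, q_prot = query
    r_genome, r_prot = reference
    ani = compute_ani(q_genome, r_genome, **ani_kwargs)
    if ani is None:
        raise ValueError(
            f"genomes {q_genome.strain_id!r} and {r_genome.strain_id!r} are not "
            "comparable (no accepted ANI fragments)"
        )
    avg = average_ppos(q_prot, r_prot)
    if avg is None:
        raise ValueError("no bidirectional best hits between the proteomes")
    return local_score(q_genome.strain_id, r_genome.strain_id, ani, avg, threshold)


@dataclass
class BiobankReport:
    """Per-species candidate rankings; ``designated`` holds the best passing
    candidate per species or None when no strain is suitable."""

    rankings: dict[str, list[LocalScore]]
    designated: dict[str, Optional[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for species in sorted(self.rankings):
            for s in self.rankings[species]:
                rows.append(
                    {
                        "species": species,
                        "query_strain": s.query_strain,
                        "reference_strain": s.reference_strain,
                        "ani_pct": s.ani_pct,
                        "avg_ppos_pct": s.avg_ppos_pct,
                        "score": s.score,
                        "passes": s.passes,
                        "designated": s.query_strain == self.designated[species],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def rank_biobank(
    candidates: Sequence[tuple[GenomeRecord, ProteinSet]],
    references: Mapping[str, tuple[GenomeRecord, ProteinSet]],
    threshold: float = PASS_THRESHOLD,
    **ani_kwargs,
) -> BiobankReport:
    """Score every candidate against its species' reference and rank by
    score (descending, ties by strain id); the best passing candidate per
    species is designated the in vitro stand-in."""
    rankings: dict[str, list[LocalScore]] = {}
    for genome, proteins in candidates:
        species = genome.species
        if species not in references:
            raise ValueError(f"no reference for species {species!r}")
        score = score_local_candidate((genome, proteins), references[species], threshold, **ani_kwargs)
        rankings.setdefault(species, []).append(score)
    designated: dict[str, Optional[str]] = {}
    for species, scores in rankings.items():
        scores.sort(key=lambda s: (-s.score, s.query_strain))
        passing = [s for s in scores if s.passes]
        designated[species] = passing[0].query_strain if passing else None
    return BiobankReport(rankings=rankings, designated=designated)


def read_protein_fasta(path: str | Path, strain_id: str) -> ProteinSet:
    proteins = tuple(
        (rec.id, str(rec.seq).upper().rstrip("*")) for rec in SeqIO.parse(str(path), "fasta")
    )
    return ProteinSet(strain_id=strain_id, proteins=proteins)
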