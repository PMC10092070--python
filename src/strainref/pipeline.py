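"""End-to-end composition: genomes + samples -> designated reference strains.

Runs the full designation flow: quality filtering, k-mer database
construction with deduplication and cluster-representative selection,
greedy strain detection across the sample collection, prevalence
computation, per-species ANI matrices and hierarchical clustering, and
finally A×P scoring and reference-strain designation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .ani_phylo import AniMatrix, build_ani_matrix, build_hcl_tree, cut_clusters
from .axp_selector import SelectionReport, compute_axp_scores, select_refbif_is
from .genomes import GenomeRecord
from .kmerdb import (
    DEFAULT_K,
    build_profile,
    cluster_profiles,
    deduplicate,
    quality_filter,
)
from .strain_profiler import SampleKmerSet, compute_prevalence, detect_strains


@dataclass
class DesignationResult:
    report: SelectionReport
    prevalence: dict[str, float]
    clusters: dict[str, str]  # strain -> species-qualified HCL id
    matrices: dict[str, AniMatrix]  # per species
    database_strains: list[str]


def designate_reference_strains(
    genomes: Sequence[GenomeRecord],
    samples: Sequence[SampleKmerSet],
    k: int = DEFAULT_K,
    min_coverage: float = 30,
    max_contigs: int = 100,
    dedup_threshold: float = 0.99,
    cluster_threshold: float = 0.90,
    min_match: float = 0.90,
    max_iterations: int = 5,
    min_prevalence: float = 0.001,
    linkage: str = "complete",
    distance: str = "one_minus_pearson",
    cut_height: float = 0.05,
    type_strains: Optional[Mapping[str, str]] = None,
) -> DesignationResult:
    """Designate one reference strain per species from a genome collection
    and a metagenome sample collection."""
    retained = quality_filter(genomes, min_coverage=min_coverage, max_contigs=max_contigs)
    profiles = [build_profile(g, k=k) for g in retained]
    profiles = deduplicate(profiles, dedup_threshold, retained)
    kclusters = cluster_profiles(profiles, cluster_threshold, retained)
    reps = {c.representative for c in kclusters}
    db = [p for p in profiles if p.strain_id in reps]

    detections = []
    for sample in samples:
        detections.extend(
            detect_strains(sample, db, min_match=min_match, max_iterations=max_iterations)
        )
    prevalence = compute_prevalence(
        detections,
        n_samples=len(samples),
        min_prevalence=min_prevalence,
        sample_ids=[s.sample_id for s in samples],
    )

    by_id = {g.strain_id: g for g in retained}
    species_of = {sid: by_id[sid].species for sid in sorted(reps)}
    by_species: dict[str, list[str]] = {}
    for sid, sp in species_of.items():
        by_species.setdefault(sp, []).append(sid)

    clusters: dict[str, str] = {}
    matrices: dict[str, AniMatrix] = {}
    scores = []
    for sp in sorted(by_species):
        members = sorted(by_species[sp])
        if len(members) == 1:
            clusters[members[0]] = f"{sp}:HCL1"
            sp_clusters = {members[0]: f"{sp}:HCL1"}
            matrix = AniMatrix([members[0]], [[100.0]])
        else:
            matrix = build_ani_matrix([by_id[sid] for sid in members])
            tree = build_hcl_tree(matrix, linkage=linkage, distance=distance)
            raw = cut_clusters(tree, cut_height)
            sp_clusters = {sid: f"{sp}:{cid}" for sid, cid in raw.items()}
            clusters.update(sp_clusters)
        matrices[sp] = matrix
        scores.extend(
            compute_axp_scores(sp_clusters, matrix, prevalence, species_of)
        )
    report = select_refbif_is(scores, type_strains=type_strains)
    return DesignationResult(
        report=report,
        prevalence=prevalence,
        clusters=clusters,
        matrices=matrices,
        database_strains=sorted(reps),
    )
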