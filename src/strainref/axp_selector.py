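"""The A×P index: cluster-level genomic representativeness times prevalence.

A strain's score is the average ANI (as a fraction) between the strain and
the other members of its hierarchical cluster, multiplied by the strain's
prevalence across the metagenome collection (as a fraction), times 100.
Within each species the strain with the highest A×P is designated the
in-silico reference strain (RefBif-IS in the bifidobacterial setting).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ani_phylo import AniMatrix


@dataclass(frozen=True)
class AxpScore:
    strain_id: str
    species: str
    cluster_id: str
    cluster_mean_ani: float  # fraction in [0, 1]
    prevalence: float  # fraction in [0, 1]
    axp: float  # in [0, 100]

    def __post_init__(self) -> None:
        expected = self.cluster_mean_ani * self.prevalence * 100.0
        if abs(self.axp - expected) > 1e-9:
            raise ValueError("axp is inconsistent with its components")


@dataclass
class SelectionReport:
    """Per-species A×P rankings and the designated reference strain."""

    rankings: dict[str, list[AxpScore]]  # species -> scores, best first
    designated: dict[str, str]  # species -> strain_id
    type_strain_scores: dict[str, AxpScore]  # species -> flagged type strain

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for species in sorted(self.rankings):
            for score in self.rankings[species]:
                rows.append(
                    {
                        "species": species,
                        "strain_id": score.strain_id,
                        "cluster_id": score.cluster_id,
                        "cluster_mean_ani": score.cluster_mean_ani,
                        "prevalence": score.prevalence,
                        "axp": score.axp,
                        "designated": score.strain_id == self.designated[species],
                        "type_strain": (
                            species in self.type_strain_scores
                            and self.type_strain_scores[species].strain_id == score.strain_id
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def cluster_mean_ani(
    strain_id: str,
    clusters: Mapping[str, str],
    m: AniMatrix,
    mode: Literal["strain", "allpairs"] = "strain",
) -> float:
    """Average ANI (fraction) within the strain's cluster.

    ``mode="strain"`` (default) averages the ANI between the strain and each
    other member; ``mode="allpairs"`` averages over all distinct member
    pairs. A singleton cluster scores 1.0 (self-identity)."""
    if strain_id not in clusters:
        raise ValueError(f"strain {strain_id!r} not assigned to a cluster")
    if strain_id not in m.strain_ids:
        raise ValueError(f"strain {strain_id!r} absent from ANI matrix")
    members = sorted(s for s, c in clusters.items() if c == clusters[strain_id])
    if len(members) == 1:
        return 1.0
    if mode == "strain":
        vals = [m.value(strain_id, other) for other in members if other != strain_id]
    elif mode == "allpairs":
        vals = [
            m.value(members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if any(np.isnan(v) for v in vals):
        raise ValueError(f"cluster of {strain_id!r} contains NA ANI pairs")
    return float(np.mean(vals)) / 100.0


def axp_index(cluster_mean_ani: float, prevalence: float) -> float:
    """cluster_mean_ani * prevalence * 100, both operands as fractions."""
    for name, x in (("cluster_mean_ani", cluster_mean_ani), ("prevalence", prevalence)):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {x}")
    return cluster_mean_ani * prevalence * 100.0


def compute_axp_scores(
    clusters: Mapping[str, str],
    m: AniMatrix,
    prevalence: Mapping[str, float],
    species: Mapping[str, str],
    mode: Literal["strain", "allpairs"] = "strain",
    percent_scale: bool = False,
) -> list[AxpScore]:
    """Score every clustered strain. Strains without a prevalence entry
    score a prevalence of 0. ``percent_scale=True`` divides prevalence
    inputs given in percent by 100 on ingest."""
    scores = []
    for strain_id in sorted(clusters):
        prev = float(prevalence.get(strain_id, 0.0))
        if percent_scale:
            prev /= 100.0
        mean_ani = cluster_mean_ani(strain_id, clusters, m, mode=mode)
        scores.append(
            AxpScore(
                strain_id=strain_id,
                species=species[strain_id],
                cluster_id=clusters[strain_id],
                cluster_mean_ani=mean_ani,
                prevalence=prev,
                axp=axp_index(mean_ani, prev),
            )
        )
    return scores


def select_refbif_is(
    scores: Sequence[AxpScore],
    type_strains: Optional[Mapping[str, str]] = None,
) -> SelectionReport:
    """Rank strains by A×P within each species and designate the argmax
    (ties broken by strain id). ``type_strains`` optionally maps species to
    a historical type strain whose score is surfaced for comparison."""
    if not scores:
        raise ValueError("no scores supplied")
    rankings: dict[str, list[AxpScore]] = {}
    for score in scores:
        rankings.setdefault(score.species, []).append(score)
    designated = {}
    for species, sp_scores in rankings.items():
        sp_scores.sort(key=lambda s: (-s.axp, s.strain_id))
        designated[species] = sp_scores[0].strain_id
    type_scores: dict[str, AxpScore] = {}
    if type_strains:
        by_key = {(s.species, s.strain_id): s for s in scores}
        for species, strain_id in type_strains.items():
            if (species, strain_id) in by_key:
                type_scores[species] = by_key[(species, strain_id)]
    return SelectionReport(
        rankings=rankings, designated=designated, type_strain_scores=type_scores
    )
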