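"""Fragment-based average nucleotide identity and ANI hierarchical clustering.

ANI between two genomes follows the fragment convention: the query is cut
into non-overlapping 1,000-bp windows, each window is placed on the target
by exact 15-mer seeding and aligned locally (match +1, mismatch -1, gap
open -5, gap extend -2), and fragments aligning at >= 70% identity over
>= 70% of their length are accepted. The directional ANI is the mean
identity of accepted fragments and the reported ANI is the mean of the
two directions; a pair with no accepted fragment in either direction has
no ANI (NA).

The ANI matrix of a species' strains is turned into a dendrogram by
agglomerative clustering, either on correlation distance between ANI
profiles (1 - Pearson r of matrix rows) or directly on (100 - ANI)/100,
with complete linkage by default. Cutting the tree at a height yields the
hierarchical clusters ("HCLs") used for reference-strain scoring.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genomes import GenomeRecord

logger = logging.getLogger(__name__)

SEED_LEN = 15
_SEED_STEP = 10
_WINDOW_MARGIN = 60


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _fragments(genome: GenomeRecord, fragment_len: int) -> list[str]:
    frags = []
    for seq in genome.sequences:
        for start in range(0, len(seq) - fragment_len + 1, fragment_len):
            frags.append(seq[start : start + fragment_len])
    return frags


def _seed_index(target: str) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for pos in range(len(target) - SEED_LEN + 1):
        seed = target[pos : pos + SEED_LEN]
        if "N" in seed:
            continue
        hits = index.setdefault(seed, [])
        if len(hits) < 8:  # cap repeats to bound work
            hits.append(pos)
    return index


def _anchor_offset(frag: str, index: dict[str, list[int]]) -> Optional[int]:
    votes: Counter[int] = Counter()
    for fpos in range(0, len(frag) - SEED_LEN + 1, _SEED_STEP):
        seed = frag[fpos : fpos + SEED_LEN]
        for tpos in index.get(seed, ()):
            votes[tpos - fpos] += 1
    if not votes:
        return None
    # modal offset; ties resolved toward the smaller offset
    return min(votes, key=lambda off: (-votes[off], off))


def _directional_ani(
    query: GenomeRecord,
    target_concat: str,
    index: dict[str, list[int]],
    aligner: Align.PairwiseAligner,
    fragment_len: int,
    min_identity: float,
    min_coverage: float,
) -> Optional[float]:
    identities: list[float] = []
    for frag in _fragments(query, fragment_len):
        offset = _anchor_offset(frag, index)
        if offset is None:
            continue
        lo = max(0, offset - _WINDOW_MARGIN)
        hi = min(len(target_concat), offset + fragment_len + _WINDOW_MARGIN)
        window = target_concat[lo:hi]
        if not window:
            continue
        alignments = aligner.align(frag, window)
        if alignments.score <= 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        columns = aln.length
        if columns == 0:
            continue
        identity_pct = 100.0 * counts.identities / columns
        span = aln.coordinates[0, -1] - aln.coordinates[0, 0]
        coverage_pct = 100.0 * span / fragment_len
        if identity_pct >= min_identity and coverage_pct >= min_coverage:
            identities.append(identity_pct)
    if not identities:
        return None
    return float(np.mean(identities))


def compute_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_len: int = 1000,
    min_identity: float = 70,
    min_coverage: float = 70,
) -> Optional[float]:
    """Bidirectional fragment ANI in percent, or None when no fragment is
    accepted in either direction (non-comparable genomes)."""
    for g in (a, b):
        if g.total_length < fragment_len:
            raise ValueError(
                f"genome {g.strain_id!r} is shorter than fragment_len={fragment_len}"
            )
    aligner = _make_aligner()
    concat_a = "N".join(a.sequences)
    concat_b = "N".join(b.sequences)
    d_ab = _directional_ani(
        a, concat_b, _seed_index(concat_b), aligner, fragment_len, min_identity, min_coverage
    )
    d_ba = _directional_ani(
        b, concat_a, _seed_index(concat_a), aligner, fragment_len, min_identity, min_coverage
    )
    accepted = [d for d in (d_ab, d_ba) if d is not None]
    if not accepted:
        return None
    return float(np.mean(accepted))


@dataclass
class AniMatrix:
    """Symmetric matrix of pairwise ANI percentages; NaN marks NA pairs."""

    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match strain list")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be exactly 100")
        with np.errstate(invalid="ignore"):
            if np.nanmax(v) > 100 or np.nanmin(v) < 0:
                raise ValueError("ANI values must lie in [0, 100]")
        mask = ~np.isnan(v)
        if not np.array_equal(mask, mask.T) or not np.allclose(v[mask & mask.T], v.T[mask & mask.T]):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def value(self, a: str, b: str) -> float:
        i = self.strain_ids.index(a)
        j = self.strain_ids.index(b)
        return float(self.values[i, j])

    def has_na(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.strain_ids, columns=self.strain_ids).to_csv(
            path, sep="\t", na_rep="NA"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AniMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        return cls(strain_ids=[str(s) for s in df.index], values=df.to_numpy(dtype=float))

    def subset(self, strain_ids: Sequence[str]) -> "AniMatrix":
        idx = [self.strain_ids.index(s) for s in strain_ids]
        return AniMatrix(list(strain_ids), self.values[np.ix_(idx, idx)])


def build_ani_matrix(genomes: Sequence[GenomeRecord], **ani_kwargs) -> AniMatrix:
    """All-vs-all ANI; each pair computed once, symmetric by construction."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.strain_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain_ids")
    n = len(genomes)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ani = compute_ani(genomes[i], genomes[j], **ani_kwargs)
            values[i, j] = values[j, i] = np.nan if ani is None else ani
    return AniMatrix(strain_ids=ids, values=values)


@dataclass
class HclTree:
    """Agglomerative clustering dendrogram over a set of strains.

    ``linkage_matrix`` is in scipy's encoding; ``labels`` are in the leaf
    order used to build it (sorted lexicographically for determinism).
    """

    labels: list[str]
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def root_height(self) -> float:
        return float(self.heights[-1]) if len(self.heights) else 0.0

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            height = 0.0 if node.is_leaf() else node.dist
            branch = parent_height - height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{branch:.6g}"
            inner = ",".join(render(c, height) for c in (node.left, node.right))
            return f"({inner}):{branch:.6g}"

        if root.is_leaf():
            return f"{self.labels[root.id]}:0;"
        inner = ",".join(render(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def _pearson_distance(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    dist = 1.0 - corr
    # zero-variance rows yield NaN correlations: identical rows are at
    # distance 0, anything else at the maximum correlation distance
    if np.isnan(dist).any():
        n = values.shape[0]
        for i in range(n):
            for j in range(n):
                if np.isnan(dist[i, j]):
                    dist[i, j] = 0.0 if np.allclose(values[i], values[j]) else 2.0
    return dist


def build_hcl_tree(
    m: AniMatrix,
    linkage: Literal["complete", "average", "single"] = "complete",
    distance: Literal["one_minus_pearson", "ani_complement"] = "one_minus_pearson",
    impute_na: bool = True,
) -> HclTree:
    """Agglomerative clustering of the ANI matrix.

    NA pairs are imputed to the minimum observed off-diagonal ANI (logged)
    before computing distances; set ``impute_na=False`` to make NA an error.
    """
    order = sorted(m.strain_ids)
    sub = m.subset(order)
    values = sub.values.copy()
    if np.isnan(values).any():
        if not impute_na:
            raise ValueError("ANI matrix contains NA pairs and imputation is disabled")
        off = values[~np.eye(len(order), dtype=bool)]
        finite = off[~np.isnan(off)]
        if finite.size == 0:
            raise ValueError("ANI matrix has no finite off-diagonal values")
        fill = float(finite.min())
        n_imputed = int(np.isnan(values).sum())
        logger.warning("imputing %d NA ANI pairs to minimum observed ANI %.3f", n_imputed, fill)
        values[np.isnan(values)] = fill

    if distance == "one_minus_pearson":
        dist = _pearson_distance(values)
    elif distance == "ani_complement":
        dist = (100.0 - values) / 100.0
    else:
        raise ValueError(f"unknown distance {distance!r}")

    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return HclTree(labels=order, linkage_matrix=Z)


def cut_clusters(tree: HclTree, height: float) -> dict[str, str]:
    """Cut the dendrogram at *height*: strains whose cophenetic distance is
    <= height share a cluster. Cluster ids are ordered by their smallest
    member strain id (HCL1, HCL2, ...)."""
    if height < 0:
        raise ValueError("height must be >= 0")
    if len(tree.labels) == 1:
        return {tree.labels[0]: "HCL1"}
    assignments = hierarchy.fcluster(tree.linkage_matrix, t=height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for label, cl in zip(tree.labels, assignments):
        groups.setdefault(int(cl), []).append(label)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    mapping: dict[str, str] = {}
    for idx, members in enumerate(ordered, start=1):
        for strain in members:
            mapping[strain] = f"HCL{idx}"
    return mapping


def write_hcl_clusters(clusters: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"strain_id": s, "cluster_id": c} for s, c in sorted(clusters.items())]
    ).to_csv(path, sep="\t", index=False)


def read_hcl_clusters(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["strain_id"], df["cluster_id"]))
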