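"""Transcriptome response summaries for host-interaction experiments.

Expression is normalized as RPKM = numReads / (geneLength/1000 *
totalNumReads/1e6). Per-gene fold changes between a test condition (e.g.
growth on a human cell monolayer) and its control are the ratio of
pseudocount-stabilized RPKM values, and the response of a strain is
summarized by how many genes fall into the fold-change bins >3, >5,
<0.25 and <=0.5, together with the up/down ratio n(>5)/n(<0.25).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd


@dataclass
class CountTable:
    """Per-gene read counts for a test/control pair plus library totals.

    ``genes`` holds columns gene_id, gene_length, count_test, count_control;
    totals are the total mapped reads per condition and may exceed the
    column sums (reads mapping outside annotated genes)."""

    genes: pd.DataFrame
    total_test: int
    total_control: int

    def __post_init__(self) -> None:
        required = {"gene_id", "gene_length", "count_test", "count_control"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.genes["gene_length"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.genes[["count_test", "count_control"]] < 0).to_numpy().any():
            raise ValueError("counts must be non-negative")
        if self.total_test < self.genes["count_test"].sum():
            raise ValueError("total_test is smaller than the column sum")
        if self.total_control < self.genes["count_control"].sum():
            raise ValueError("total_control is smaller than the column sum")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_test\t{self.total_test}\n")
            fh.write(f"#total_control\t{self.total_control}\n")
            self.genes.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        import io

        totals = {}
        lines = Path(path).read_text().splitlines(keepends=True)
        n_header = 0
        for line in lines:
            if not line.startswith("#"):
                break
            key, value = line[1:].rstrip("\n").split("\t")
            totals[key] = int(value)
            n_header += 1
        genes = pd.read_csv(io.StringIO("".join(lines[n_header:])), sep="\t")
        if "total_test" not in totals or "total_control" not in totals:
            raise ValueError(f"{path}: missing #total_test/#total_control header lines")
        return cls(genes=genes, total_test=totals["total_test"], total_control=totals["total_control"])


@dataclass(frozen=True)
class ResponseSummary:
    """Fold-change bin counts and the up/down response ratio of one strain."""

    strain_id: str
    n_up3: int
    n_up5: int
    n_down025: int
    n_down05: int
    ratio: Optional[float]

    def __post_init__(self) -> None:
        if self.n_up5 > self.n_up3 or self.n_down025 > self.n_down05:
            raise ValueError("bins must nest: n_up5 <= n_up3 and n_down025 <= n_down05")


def compute_rpkm(count: int, gene_length: int, total_reads: int) -> float:
    """numReads / (geneLength/1000 * totalNumReads/1e6)."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return count / ((gene_length / 1000) * (total_reads / 1_000_000))


def compute_fold_changes(
    table: CountTable, pseudocount_rpkm: float = 0.01
) -> list[tuple[str, float]]:
    """Per-gene test/control RPKM ratio with an additive pseudocount; genes
    with zero reads in both conditions are excluded."""
    if table.total_test <= 0 or table.total_control <= 0:
        raise ValueError("library totals must be positive")
    out: list[tuple[str, float]] = []
    for row in table.genes.itertuples(index=False):
        if row.count_test == 0 and row.count_control == 0:
            continue
        rpkm_t = compute_rpkm(row.count_test, row.gene_length, table.total_test)
        rpkm_c = compute_rpkm(row.count_control, row.gene_length, table.total_control)
        fc = (rpkm_t + pseudocount_rpkm) / (rpkm_c + pseudocount_rpkm)
        out.append((str(row.gene_id), fc))
    return out


def up_down_ratio(n_up5: int, n_down025: int) -> Optional[float]:
    """n(>5)/n(<0.25) to 4 decimals; 0.0 when nothing is up-regulated but
    something is down; None (NA) when the denominator is zero."""
    if n_up5 < 0 or n_down025 < 0:
        raise ValueError("counts must be non-negative")
    if n_down025 == 0:
        return None
    return round(n_up5 / n_down025, 4)


def bin_fold_changes(
    fcs: Sequence[tuple[str, float]], strain_id: str = ""
) -> ResponseSummary:
    """Count genes in the fold-change bins >3, >5 (strict) and <0.25,
    <=0.5 (the half bin inclusive)."""
    values = [fc for _, fc in fcs]
    n_up3 = sum(fc > 3 for fc in values)
    n_up5 = sum(fc > 5 for fc in values)
    n_down025 = sum(fc < 0.25 for fc in values)
    n_down05 = sum(fc <= 0.5 for fc in values)
    return ResponseSummary(
        strain_id=strain_id,
        n_up3=n_up3,
        n_up5=n_up5,
        n_down025=n_down025,
        n_down05=n_down05,
        ratio=up_down_ratio(n_up5, n_down025),
    )


def summarize_response(
    strain_id: str, table: CountTable, pseudocount_rpkm: float = 0.01
) -> ResponseSummary:
    return bin_fold_changes(compute_fold_changes(table, pseudocount_rpkm), strain_id)


def write_gene_report(
    table: CountTable, path: str | Path, pseudocount_rpkm: float = 0.01
) -> None:
    """Per-gene RPKM, fold change and bin flags as TSV."""
    rows = []
    fcs = dict(compute_fold_changes(table, pseudocount_rpkm))
    for row in table.genes.itertuples(index=False):
        gid = str(row.gene_id)
        if gid not in fcs:
            continue
        fc = fcs[gid]
        rows.append(
            {
                "gene_id": gid,
                "rpkm_test": compute_rpkm(row.count_test, row.gene_length, table.total_test),
                "rpkm_control": compute_rpkm(
                    row.count_control, row.gene_length, table.total_control
                ),
                "fold_change": fc,
                "up3": fc > 3,
                "up5": fc > 5,
                "down025": fc < 0.25,
                "down05": fc <= 0.5,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary(summaries: Sequence[ResponseSummary], path: str | Path) -> None:
    """Summary table: strain, responsive-gene bins and up/down ratio."""
    pd.DataFrame(
        [
            {
                "strain_id": s.strain_id,
                "n_up3": s.n_up3,
                "n_up5": s.n_up5,
                "n_down025": s.n_down025,
                "n_down05": s.n_down05,
                "ratio": "NA" if s.ratio is None else f"{s.ratio:.4f}",
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)
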