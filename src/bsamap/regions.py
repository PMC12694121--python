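"""Interval arithmetic on candidate regions and candidate-gene extraction.

Coordinates are 1-based inclusive throughout, with
``length = end - start + 1`` — the convention under which every published
region table row's printed length is exactly reproduced from its printed
start and end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .variant_io import GeneModel


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class CandidateRegion:
    """A called region with its provenance and supporting markers."""

    interval: GenomicInterval
    source: str  # "snp_index" | "ed" | "intersection"
    n_markers: int = 0
    snps: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, pos in self.snps:
            if not self.interval.contains(chrom, pos):
                raise ValueError(f"member SNP {chrom}:{pos} outside {self.interval}")


def region_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    return iv.length


def _intervals(regions: Iterable[GenomicInterval | CandidateRegion]) -> list[GenomicInterval]:
    return [r.interval if isinstance(r, CandidateRegion) else r for r in regions]


def _check_disjoint(ivs: list[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, chrom_ivs in by_chrom.items():
        chrom_ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(chrom_ivs, chrom_ivs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping intervals on {chrom}: {a} / {b}")


def total_length(regions: Sequence[GenomicInterval | CandidateRegion]) -> int:
    """Sum of region lengths; the list must be internally disjoint."""
    ivs = _intervals(regions)
    _check_disjoint(ivs)
    return sum(iv.length for iv in ivs)


def intersect_region_sets(
    a: Sequence[GenomicInterval | CandidateRegion],
    b: Sequence[GenomicInterval | CandidateRegion],
) -> list[CandidateRegion]:
    """Maximal intervals covered by both region sets (commutative).

    Both inputs must be internally disjoint; output is sorted by
    (chrom, start) and labelled ``source="intersection"``.
    """
    ivs_a = _intervals(a)
    ivs_b = _intervals(b)
    _check_disjoint(ivs_a)
    _check_disjoint(ivs_b)
    out: list[CandidateRegion] = []
    for iv_a in sorted(ivs_a, key=lambda iv: (iv.chrom, iv.start)):
        for iv_b in (iv for iv in ivs_b if iv.chrom == iv_a.chrom):
            start = max(iv_a.start, iv_b.start)
            end = min(iv_a.end, iv_b.end)
            if start <= end:
                out.append(
                    CandidateRegion(
                        interval=GenomicInterval(iv_a.chrom, start, end),
                        source="intersection",
                    )
                )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def snps_in_regions(
    loci: pd.DataFrame, regions: Sequence[CandidateRegion]
) -> list[CandidateRegion]:
    """Attach member SNPs (inclusive bounds) to each region.

    *loci* needs chrom/pos columns; returns new regions whose ``snps`` and
    ``n_markers`` reflect the members found.
    """
    out = []
    for reg in regions:
        iv = reg.interval
        mask = (
            (loci["chrom"] == iv.chrom)
            & (loci["pos"] >= iv.start)
            & (loci["pos"] <= iv.end)
        )
        members = list(zip(loci.loc[mask, "chrom"], loci.loc[mask, "pos"].astype(int)))
        out.append(
            CandidateRegion(
                interval=iv, source=reg.source, n_markers=len(members), snps=members
            )
        )
    return out


def genes_in_regions(
    regions: Sequence[CandidateRegion],
    gene_models: Sequence[GeneModel],
    annotated_genes: dict[tuple[str, int], list[str]] | None = None,
) -> list[GeneModel]:
    """Candidate genes: genes containing a member candidate SNP of some
    region, plus genes linked to a member SNP by its effect annotation
    (*annotated_genes*: (chrom, pos) -> gene ids, e.g. flanking-gene calls).
    """
    by_id = {g.gene_id: g for g in gene_models}
    hits: dict[str, GeneModel] = {}
    for reg in regions:
        for chrom, pos in reg.snps:
            for g in gene_models:
                if g.chrom == chrom and g.start <= pos <= g.end:
                    hits[g.gene_id] = g
            if annotated_genes:
                for gid in annotated_genes.get((chrom, pos), []):
                    if gid in by_id:
                        hits[gid] = by_id[gid]
    return sorted(hits.values(), key=lambda g: (g.chrom, g.start))


def prioritize_by_expression(
    genes: Sequence[GeneModel | str],
    expression: pd.DataFrame,
    target_tissue: str = "spike",
    rel_dominance: float = 0.8,
    floor: float = 0.5,
) -> pd.DataFrame:
    """Rank candidate genes by target-tissue predominance.

    A gene is *selected* when its target-tissue expression is at least
    ``rel_dominance`` times the maximum over the other tissues AND above
    ``floor`` expression units. Genes absent from the matrix are flagged
    (``missing`` column) and never selected. Returns a table sorted by
    target-tissue expression, descending.
    """
    if expression.empty:
        raise ConfigurationError("empty expression matrix")
    if target_tissue not in expression.columns:
        raise ConfigurationError(f"tissue {target_tissue!r} not in matrix")
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else g for g in genes]
    rows = []
    others = [c for c in expression.columns if c != target_tissue]
    for gid in gene_ids:
        if gid not in expression.index:
            rows.append((gid, np.nan, np.nan, True, False))
            continue
        tgt = float(expression.loc[gid, target_tissue])
        other_max = float(expression.loc[gid, others].max()) if others else 0.0
        selected = tgt > floor and tgt >= rel_dominance * other_max
        rows.append((gid, tgt, other_max, False, selected))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", target_tissue, "other_max", "missing", "selected"],
    )
    return df.sort_values(target_tissue, ascending=False, ignore_index=True)
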