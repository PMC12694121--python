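"""Variant location and coding-effect annotation against toy gene models.

Location categories follow the ANNOVAR-style closed vocabulary: exonic,
intronic, UTR3, UTR5, upstream, downstream, upstream;downstream, splicing,
exonic;splicing, UTR5;UTR3, intergenic — with 2,000 bp gene flanks and a
2 bp intronic splice window at each exon/intron boundary. Coding effects
for exonic variants: synonymous, nonsynonymous, stopgain, stoploss,
frameshift/nonframeshift insertion/deletion, unknown (any unresolvable
transcript: CDS length not divisible by 3 or a reference mismatch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .variant_io import GeneModel, PooledVariantRecord

logger = logging.getLogger(__name__)

UPSTREAM_BP = 2000
SPLICE_BP = 2

LOCATION_CATEGORIES = (
    "exonic",
    "intronic",
    "UTR3",
    "UTR5",
    "upstream",
    "downstream",
    "upstream;downstream",
    "splicing",
    "exonic;splicing",
    "UTR5;UTR3",
    "intergenic",
)
CODING_EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift insertion",
    "frameshift deletion",
    "nonframeshift insertion",
    "nonframeshift deletion",
    "unknown",
    "n/a",
)

_PRECEDENCE = (
    "exonic",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
)


@dataclass
class EffectCall:
    """Combined location/effect assignment for one variant."""

    chrom: str
    pos: int
    location: str
    effect: str = "n/a"
    gene_ids: list[str] = field(default_factory=list)
    aa_change: str = ""


def _locate_in_gene(pos: int, gene: GeneModel) -> str | None:
    """Category of *pos* relative to one gene, or None when unrelated."""
    start, end = gene.start, gene.end
    if start <= pos <= end:
        in_exon = any(s <= pos <= e for s, e in gene.exons)
        if in_exon:
            if any(s <= pos <= e for s, e in gene.cds):
                return "exonic"
            if not gene.cds:
                return "exonic"
            cds_start, cds_end = gene.cds[0][0], gene.cds[-1][1]
            if pos < cds_start:
                return "UTR5" if gene.strand == "+" else "UTR3"
            if pos > cds_end:
                return "UTR3" if gene.strand == "+" else "UTR5"
            return "exonic"  # between CDS segments but inside an exon
        # intron: splice window = first/last SPLICE_BP intronic bases
        for s, e in gene.exons:
            if 1 <= s - pos <= SPLICE_BP or 1 <= pos - e <= SPLICE_BP:
                return "splicing"
        return "intronic"
    upstream_side = (
        start - UPSTREAM_BP <= pos < start
        if gene.strand == "+"
        else end < pos <= end + UPSTREAM_BP
    )
    downstream_side = (
        end < pos <= end + UPSTREAM_BP
        if gene.strand == "+"
        else start - UPSTREAM_BP <= pos < start
    )
    if upstream_side:
        return "upstream"
    if downstream_side:
        return "downstream"
    return None


def locate_variant(
    record: PooledVariantRecord, gene_models: list[GeneModel]
) -> tuple[str, list[str]]:
    """Location category and the gene ids supporting it.

    A variant touching several genes gets the combined classes where the
    vocabulary defines them (upstream;downstream, exonic;splicing,
    UTR5;UTR3), otherwise the highest-precedence single category.
    """
    per_gene: list[tuple[str, str]] = []
    chrom_genes = [g for g in gene_models if g.chrom == record.chrom]
    if not chrom_genes and not any(g.chrom == record.chrom for g in gene_models):
        logger.warning("chromosome %s absent from gene models", record.chrom)
    for gene in chrom_genes:
        cat = _locate_in_gene(record.pos, gene)
        if cat is not None:
            per_gene.append((gene.gene_id, cat))
    if not per_gene:
        return "intergenic", []
    cats = {c for _, c in per_gene}
    for combo in ("upstream;downstream", "exonic;splicing", "UTR5;UTR3"):
        parts = set(combo.split(";"))
        if parts <= cats:
            genes = [g for g, c in per_gene if c in parts]
            return combo, genes
    for cat in _PRECEDENCE:
        if cat in cats:
            return cat, [g for g, c in per_gene if c == cat]
    return "intergenic", []


def _build_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Coding sequence in translation order (reverse-complemented for -)."""
    chrom_seq = genome[gene.chrom]
    parts = [chrom_seq[s - 1 : e] for s, e in gene.cds]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _cds_offset(pos: int, gene: GeneModel) -> int | None:
    """0-based offset of genomic *pos* within the CDS, in translation order."""
    plus_offset = 0
    found = None
    for s, e in gene.cds:
        if s <= pos <= e:
            found = plus_offset + (pos - s)
            break
        plus_offset += e - s + 1
    if found is None:
        return None
    if gene.strand == "-":
        return gene.cds_length - 1 - found
    return found


def coding_effect(
    record: PooledVariantRecord, gene: GeneModel, genome: dict[str, str]
) -> tuple[str, str]:
    """(effect, amino-acid change) of an exonic variant on *gene*.

    SNPs are classified by translating the reference and mutant codons
    (standard nuclear code); InDels by length mod 3. Unresolvable
    transcripts (CDS not divisible by 3, reference mismatch, variant
    outside the CDS) are bucketed as ``unknown``.
    """
    if record.variant_class == "InDel":
        if not any(s <= record.pos <= e for s, e in gene.cds):
            return "unknown", ""
        shift = len(record.alt) - len(record.ref)
        if shift == 0:
            return "unknown", ""
        kind = "insertion" if shift > 0 else "deletion"
        frame = "nonframeshift" if shift % 3 == 0 else "frameshift"
        return f"{frame} {kind}", ""

    if gene.cds_length % 3 != 0:
        return "unknown", ""
    offset = _cds_offset(record.pos, gene)
    if offset is None:
        return "unknown", ""
    cds = _build_cds(gene, genome)
    ref_base = record.ref if gene.strand == "+" else str(Seq(record.ref).complement())
    alt_base = record.alt if gene.strand == "+" else str(Seq(record.alt).complement())
    if cds[offset] != ref_base:
        logger.warning(
            "reference mismatch at %s:%d in %s (CDS has %s, record ref %s)",
            record.chrom, record.pos, gene.gene_id, cds[offset], record.ref,
        )
        return "unknown", ""
    codon_i = offset // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    mutant = codon[: offset % 3] + alt_base + codon[offset % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    change = f"{aa_ref}{codon_i + 1}{aa_alt}"
    if aa_ref == aa_alt:
        return "synonymous", change
    if aa_alt == "*":
        return "stopgain", change
    if aa_ref == "*":
        return "stoploss", change
    return "nonsynonymous", change


def annotate_records(
    records: list[PooledVariantRecord],
    gene_models: list[GeneModel],
    genome: dict[str, str],
) -> pd.DataFrame:
    """Annotate every record; one row per variant.

    Columns: chrom, pos, ref, alt, variant_class, location, gene_ids
    (comma-joined), effect, aa_change. The coding effect is ``n/a`` unless
    the location includes exonic.
    """
    by_id = {g.gene_id: g for g in gene_models}
    rows = []
    for rec in records:
        location, gene_ids = locate_variant(rec, gene_models)
        effect, aa = "n/a", ""
        if "exonic" in location:
            # one call per gene; report the first exonic gene's effect
            for gid in gene_ids:
                gene = by_id[gid]
                if any(s <= rec.pos <= e for s, e in gene.cds):
                    effect, aa = coding_effect(rec, gene, genome)
                    break
            else:
                effect = "unknown"
        rows.append(
            (
                rec.chrom,
                rec.pos,
                rec.ref,
                rec.alt,
                rec.variant_class,
                location,
                ",".join(gene_ids),
                effect,
                aa,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "variant_class",
            "location", "gene_ids", "effect", "aa_change",
        ],
    )
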