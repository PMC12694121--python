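"""Readers, writers and site-level filters for the pipeline's file formats.

The central container is :class:`PooledVariantRecord`: one biallelic site
with per-sample read depths for the four samples of a bulked-segregant
design — the two parents and the two phenotypic-extreme offspring pools.
Depths are carried both as (ref, alt) allele depths (VCF ``AD``) and, for
SNPs, as full A/C/G/T base-count quadruples (custom ``BD`` FORMAT field)
so that the Euclidean-distance statistic can use complete base frequencies
including sequencing-error bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Sample roles, in canonical column order.
ROLE_WT_PARENT = "P_WT"
ROLE_MUT_PARENT = "P_MUT"
ROLE_POOL_SHORT = "POOL_SHORT"
ROLE_POOL_LONG = "POOL_LONG"
ROLES = (ROLE_WT_PARENT, ROLE_MUT_PARENT, ROLE_POOL_SHORT, ROLE_POOL_LONG)

TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass
class PooledVariantRecord:
    """One variant site with per-sample depths for the four-sample design.

    ``base_depths`` maps role -> length-4 int array (A, C, G, T counts) and
    is ``None`` for InDels, where only ``allele_depths`` (ref, alt counts)
    is meaningful.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str  # "SNP" | "InDel"
    allele_depths: dict[str, tuple[int, int]] = field(default_factory=dict)
    base_depths: dict[str, np.ndarray | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.variant_class == "SNP":
            if self.ref == self.alt:
                raise ValueError("SNP ref and alt must differ")
            if self.ref not in BASES or self.alt not in BASES:
                raise ValueError(f"bad SNP alleles {self.ref}>{self.alt}")

    def total_depth(self, role: str) -> int:
        bd = self.base_depths.get(role)
        if bd is not None:
            return int(np.sum(bd))
        ad = self.allele_depths[role]
        return int(ad[0] + ad[1])

    def quadruple(self, role: str) -> np.ndarray:
        """Base-count quadruple for *role*; InDels are represented on a
        two-allele pseudo-quadruple (ref count, alt count, 0, 0)."""
        bd = self.base_depths.get(role)
        if bd is not None:
            return np.asarray(bd, dtype=float)
        ad = self.allele_depths[role]
        if self.variant_class == "SNP":
            q = np.zeros(4)
            q[BASE_INDEX[self.ref]] = ad[0]
            q[BASE_INDEX[self.alt]] = ad[1]
            return q
        return np.array([ad[0], ad[1], 0.0, 0.0])

    def allele_depth(self, role: str, allele: str) -> int:
        """Depth of reads supporting *allele* ('ref'/'alt') in *role*."""
        if self.variant_class == "SNP" and self.base_depths.get(role) is not None:
            base = self.ref if allele == "ref" else self.alt
            return int(self.base_depths[role][BASE_INDEX[base]])
        ad = self.allele_depths[role]
        return int(ad[0] if allele == "ref" else ad[1])


@dataclass
class GeneModel:
    """A single-transcript gene: exon and CDS segments, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for segs, name in ((self.exons, "exons"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} of {self.gene_id} overlap")
            for s, e in segs:
                if not 1 <= s <= e:
                    raise ValueError(f"bad {name} segment ({s},{e})")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"CDS ({cs},{ce}) outside exons of {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class FilterConfig:
    """Site-level retention rules applied before association scanning.

    min_depth
        Minimum total read depth required in every one of the four samples
        (the published pipelines drop sites under 5x coverage).
    parent_homozygosity
        A parent is treated as homozygous when its major base carries at
        least this fraction of its reads.
    require_parent_divergence
        Keep only sites where the two parents are fixed for different
        alleles (the design is strictly biallelic parent-vs-parent).
    """

    min_depth: int = 5
    parent_homozygosity: float = 0.9
    require_parent_divergence: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ConfigurationError("min_depth must be >= 0")
        if not 0.5 <= self.parent_homozygosity <= 1.0:
            raise ConfigurationError("parent_homozygosity must be in [0.5, 1]")


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a base substitution as ``transition`` or ``transversion``."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"non-base input {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    pair = {ref, alt}
    return "transition" if pair in TRANSITIONS else "transversion"


def _major_allele(record: PooledVariantRecord, role: str) -> tuple[str, float]:
    """(major allele label, its fraction of ALL reads) for *role*.

    For SNPs the fraction is over the full base quadruple, so a parent
    split between any two bases — allele or not — is heterozygous; the
    label is 'ref'/'alt' when the major base is an allele, else the base
    itself.
    """
    q = record.quadruple(role)
    total = q.sum()
    if total == 0:
        return "none", 0.0
    i = int(np.argmax(q))
    frac = float(q[i] / total)
    if record.variant_class == "SNP":
        base = BASES[i]
        label = "ref" if base == record.ref else "alt" if base == record.alt else base
    else:
        label = "ref" if i == 0 else "alt"
    return label, frac


def filter_variants(
    records: Iterable[PooledVariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[PooledVariantRecord], dict[str, int]]:
    """Apply depth and parental-fixation filters.

    Returns the retained records and a per-rule rejection tally. Each
    rejected record is counted once, under the first rule it fails
    (low_depth, heterozygous_parent, parents_not_divergent). The tally plus
    the retained count always equals the input count.
    """
    cfg = cfg or FilterConfig()
    retained: list[PooledVariantRecord] = []
    tally = {"low_depth": 0, "heterozygous_parent": 0, "parents_not_divergent": 0}
    for rec in records:
        if any(rec.total_depth(role) < cfg.min_depth for role in ROLES):
            tally["low_depth"] += 1
            continue
        wt_allele, wt_frac = _major_allele(rec, ROLE_WT_PARENT)
        mut_allele, mut_frac = _major_allele(rec, ROLE_MUT_PARENT)
        if (
            wt_allele == "none"
            or mut_allele == "none"
            or wt_frac < cfg.parent_homozygosity
            or mut_frac < cfg.parent_homozygosity
        ):
            tally["heterozygous_parent"] += 1
            continue
        if cfg.require_parent_divergence and wt_allele == mut_allele:
            tally["parents_not_divergent"] += 1
            continue
        retained.append(rec)
    return retained, tally


@dataclass
class VariantCounts:
    """Bookkeeping of site-class counts with built-in arithmetic checks."""

    snps: int
    indels: int
    transitions: int = 0
    transversions: int = 0

    @property
    def total(self) -> int:
        return self.snps + self.indels

    def consistent(self) -> bool:
        """True when transitions + transversions account for every SNP."""
        return self.transitions + self.transversions == self.snps


def summarize_classes(records: Sequence[PooledVariantRecord]) -> VariantCounts:
    snps = [r for r in records if r.variant_class == "SNP"]
    ts = sum(1 for r in snps if classify_substitution(r.ref, r.alt) == "transition")
    return VariantCounts(
        snps=len(snps),
        indels=len(records) - len(snps),
        transitions=ts,
        transversions=len(snps) - ts,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_pooled_vcf(
    path: str | Path, sample_map: dict[str, str]
) -> list[PooledVariantRecord]:
    """Read a 4-sample VCF into :class:`PooledVariantRecord` objects.

    *sample_map* maps VCF sample names to the four roles in :data:`ROLES`.
    Sites must carry per-sample ``AD``; the optional ``BD`` field (A,C,G,T
    base depths) is used when present. Multiallelic rows are skipped with a
    logged warning — the parent-vs-parent design is strictly biallelic.
    """
    import pysam

    unknown = set(sample_map.values()) - set(ROLES)
    if unknown:
        raise ConfigurationError(f"unknown sample roles: {sorted(unknown)}")
    if set(sample_map.values()) != set(ROLES):
        raise ConfigurationError(
            f"sample_map must cover all roles {ROLES}, got {sorted(sample_map.values())}"
        )

    vf = pysam.VariantFile(str(path))
    try:
        if "AD" not in vf.header.formats:
            raise FormatError(f"{path}: VCF lacks the AD FORMAT field")
        missing = set(sample_map) - set(vf.header.samples)
        if missing:
            raise FormatError(f"{path}: samples absent from VCF: {sorted(missing)}")
        has_bd = "BD" in vf.header.formats

        records: list[PooledVariantRecord] = []
        n_multi = 0
        for row in vf:
            if row.alts is None or len(row.alts) != 1:
                n_multi += 1
                continue
            ref, alt = row.ref, row.alts[0]
            vclass = "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"
            allele_depths: dict[str, tuple[int, int]] = {}
            base_depths: dict[str, np.ndarray | None] = {}
            for name, role in sample_map.items():
                fmt = row.samples[name]
                ad = fmt.get("AD")
                if ad is None or ad[0] is None:
                    raise FormatError(
                        f"{path}: missing AD for sample {name} at {row.chrom}:{row.pos}"
                    )
                allele_depths[role] = (int(ad[0]), int(ad[1]))
                bd = fmt.get("BD") if has_bd else None
                base_depths[role] = (
                    np.array(bd, dtype=int) if bd is not None and bd[0] is not None else None
                )
            records.append(
                PooledVariantRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=ref,
                    alt=alt,
                    variant_class=vclass,
                    allele_depths=allele_depths,
                    base_depths=base_depths,
                )
            )
        if n_multi:
            logger.warning("skipped %d multiallelic rows in %s", n_multi, path)
        return records
    finally:
        vf.close()


# ---------------------------------------------------------------------------
# GFF3 / FASTA / tables
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into single-transcript :class:`GeneModel` objects."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        if not exons:
            exons = [(gene.start, gene.end)]
        annotation = gene.attributes.get("description", [""])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                annotation=annotation,
            )
        )
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (toy-genome-sized) FASTA into a chrom -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the two-column phenotype TSV: plant_id <TAB> spike_length_cm."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "plant_id":
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric spike length {parts[1]!r}"
                ) from exc
            rows.append((parts[0], value))
    return pd.DataFrame(rows, columns=["plant_id", "spike_length_cm"])


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue expression TSV (gene ids in the first column)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse expression matrix ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        raise FormatError(f"{path}: non-numeric columns {list(non_numeric)}")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
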