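"""Independent brute-force oracles and record builders for the test suite.

Everything here deliberately re-derives results by the most literal route
available (per-read tallies, per-bp membership, full protein rebuilds) so
that the package's vectorized/streaming implementations are checked against
logic that shares no code with them.
"""

from __future__ import annotations

import numpy as np

from bsamap.variant_io import BASES, BASE_INDEX, GeneModel, PooledVariantRecord, ROLES


def make_record(
    chrom="chr1",
    pos=100,
    ref="G",
    alt="A",
    variant_class="SNP",
    **depths,
):
    """Build a record from per-role depth specs.

    Each role (P_WT, P_MUT, POOL_SHORT, POOL_LONG) takes either a 4-tuple of
    base counts (A, C, G, T) for SNPs or a (ref, alt) pair for InDels.
    Unspecified roles default to clean homozygous parents / balanced pools.
    """
    defaults = {
        "P_WT": None,
        "P_MUT": None,
        "POOL_SHORT": None,
        "POOL_LONG": None,
    }
    defaults.update(depths)
    allele_depths = {}
    base_depths = {}
    for role in ROLES:
        spec = defaults[role]
        if variant_class == "SNP":
            if spec is None:
                if role == "P_WT":
                    quad = _quad(ref, 50)
                elif role == "P_MUT":
                    quad = _quad(alt, 50)
                else:
                    quad = _quad(ref, 25) + _quad(alt, 25)
            else:
                quad = np.array(spec, dtype=int)
            base_depths[role] = quad
            allele_depths[role] = (
                int(quad[BASE_INDEX[ref]]),
                int(quad[BASE_INDEX[alt]]),
            )
        else:
            pair = spec if spec is not None else (25, 25)
            allele_depths[role] = (int(pair[0]), int(pair[1]))
            base_depths[role] = None
    return PooledVariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        allele_depths=allele_depths,
        base_depths=base_depths,
    )


def _quad(base, n):
    q = np.zeros(4, dtype=int)
    q[BASE_INDEX[base]] = n
    return q


def random_snp_record(rng, max_depth=60):
    ref, alt = rng.choice(list(BASES), size=2, replace=False)
    quads = {
        role: tuple(int(x) for x in rng.integers(0, max_depth, size=4))
        for role in ROLES
    }
    return make_record(pos=int(rng.integers(1, 10**6)), ref=ref, alt=alt, **quads)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def snp_index_oracle(quad, m_base, p_base):
    """Read-by-read tally of M/(M+P); None when undefined."""
    reads = []
    for base, count in zip(BASES, quad):
        reads.extend([base] * int(count))
    m = sum(1 for r in reads if r == m_base)
    p = sum(1 for r in reads if r == p_base)
    return None if m + p == 0 else m / (m + p)


def filter_oracle(record, min_depth, hom_frac):
    """Literal re-application of the three retention rules: per-sample
    depth floor, parental homozygosity (major base over ALL reads), and
    parental divergence (different major bases)."""
    for role in ROLES:
        if sum(record.quadruple(role)) < min_depth:
            return False
    majors = []
    for role in ("P_WT", "P_MUT"):
        quad = list(record.quadruple(role))
        total = sum(quad)
        if total == 0:
            return False
        best = max(range(4), key=lambda i: quad[i])
        if quad[best] / total < hom_frac:
            return False
        majors.append(best)
    return majors[0] != majors[1]


def window_mean_oracle(positions, values, start, width):
    sel = [v for p, v in zip(positions, values) if start <= p < start + width]
    return (len(sel), (sum(sel) / len(sel) if sel else None))


def region_oracle(chroms, positions, values, threshold, max_gap):
    """Run-length scan for above-threshold runs, merging small gaps."""
    regions = []
    cur = None
    for c, p, v in zip(chroms, positions, values):
        if not (v > threshold):
            continue
        if cur and cur[0] == c and p - cur[2] - 1 <= max_gap:
            cur = (c, cur[1], p, cur[3] + 1)
        else:
            if cur:
                regions.append(cur)
            cur = (c, p, p, 1)
    if cur:
        regions.append(cur)
    return regions


def lowess_oracle(x, y, frac):
    """Tricube-weighted local linear regression, evaluated at each x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = int(frac * n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(len(idx))
        xw, yw = x[idx], y[idx]
        sw = w.sum()
        xbar = (w * xw).sum() / sw
        ybar = (w * yw).sum() / sw
        sxx = (w * (xw - xbar) ** 2).sum()
        if sxx <= 1e-12 * (w * xw**2).sum() or sxx == 0:
            out[i] = ybar
        else:
            beta = (w * (xw - xbar) * (yw - ybar)).sum() / sxx
            out[i] = ybar + beta * (x[i] - xbar)
    return out


def intersect_oracle(a, b, span):
    """Per-bp membership intersection over [1, span] for one chromosome.

    a, b: lists of (start, end) 1-based inclusive. Returns merged maximal
    intervals of positions covered by both.
    """
    covered_a = set()
    for s, e in a:
        covered_a.update(range(s, e + 1))
    covered_b = set()
    for s, e in b:
        covered_b.update(range(s, e + 1))
    both = sorted(covered_a & covered_b)
    out = []
    for p in both:
        if out and p == out[-1][1] + 1:
            out[-1][1] = p
        else:
            out.append([p, p])
    return [tuple(iv) for iv in out]


def coding_effect_oracle(gene: GeneModel, genome: dict, pos: int, ref: str, alt: str):
    """Rebuild the full mutant CDS, translate both proteins, compare.

    Independent of the codon-local implementation: applies the SNP to a
    copy of the genome, re-extracts the CDS, translates, and diffs.
    """
    from Bio.Seq import Seq

    def cds_of(seq_by_chrom):
        parts = [seq_by_chrom[gene.chrom][s - 1 : e] for s, e in gene.cds]
        cds = "".join(parts)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    if gene.cds_length % 3 != 0:
        return "unknown"
    if not any(s <= pos <= e for s, e in gene.cds):
        return "unknown"
    if genome[gene.chrom][pos - 1] != ref:
        return "unknown"
    mutant_genome = dict(genome)
    chrom_seq = list(mutant_genome[gene.chrom])
    chrom_seq[pos - 1] = alt
    mutant_genome[gene.chrom] = "".join(chrom_seq)
    prot_ref = str(Seq(cds_of(genome)).translate())
    prot_alt = str(Seq(cds_of(mutant_genome)).translate())
    if prot_ref == prot_alt:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    i = diffs[0]
    if prot_alt[i] == "*":
        return "stopgain"
    if prot_ref[i] == "*":
        return "stoploss"
    return "nonsynonymous"


def indel_effect_oracle(gene: GeneModel, pos: int, ref: str, alt: str):
    if not any(s <= pos <= e for s, e in gene.cds):
        return "unknown"
    shift = len(alt) - len(ref)
    if shift == 0:
        return "unknown"
    kind = "insertion" if shift > 0 else "deletion"
    return ("nonframeshift " if shift % 3 == 0 else "frameshift ") + kind


def random_toy_gene(rng, chrom="chrT", genome_len=3000, gene_id="toy"):
    """Random 1-4 exon gene (either strand) plus a matching random genome."""
    n_exons = int(rng.integers(1, 5))
    exons = []
    cursor = int(rng.integers(100, 300))
    for _ in range(n_exons):
        length = int(rng.integers(30, 120))
        exons.append((cursor, cursor + length - 1))
        cursor += length + int(rng.integers(20, 80))
    total = sum(e - s + 1 for s, e in exons)
    trim = total % 3
    exons[-1] = (exons[-1][0], exons[-1][1] - trim)
    if exons[-1][1] < exons[-1][0]:
        exons.pop()
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel(gene_id, chrom, strand, exons, list(exons))
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=genome_len)])
    return gene, {chrom: seq}
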