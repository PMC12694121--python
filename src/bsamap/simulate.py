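"""Synthetic F2 pooled-sequencing data with known ground truth.

Emulates the study design the scan assumes: an EMS-derived mutant crossed
to its wild-type progenitor, a selfed F2 segregating a dominant major
locus for spike length on a polygenic (Gaussian-residual) background,
trait-ranked tail pools of 30 plants each, and ~50x pooled short-read
depth with a small per-base miscall rate. Everything downstream of read
alignment is generated: a 4-sample VCF with allele and base depths, a toy
reference FASTA, a GFF3 with single-transcript gene models (one spanning
the causal locus), a phenotype table, and a truth JSON for scoring.

Scaling notes: toy chromosomes are a few Mb standing in for ~600 Mb wheat
chromosomes, so the genetic map is scaled up (default 200 cM/Mb, i.e. a
2 Mb toy chromosome spans 4 Morgans). The controlling quantity is the
genetic length per chromosome: two-sided tail selection sustains pooled
allele-frequency contrast proportional to (1 - 2r) around the causal
locus, so the selected signal extends roughly one Morgan to each side;
chromosomes must be several Morgans long for that linked span to remain a
small fraction of the genome, as it is in a real genome-scale experiment.
At the field's customary 1 cM/Mb a 2 Mb toy chromosome would be a single
fully linked block and every genome-wide threshold would degenerate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .variant_io import (
    BASES,
    BASE_INDEX,
    GeneModel,
    PooledVariantRecord,
    ROLE_MUT_PARENT,
    ROLE_POOL_LONG,
    ROLE_POOL_SHORT,
    ROLE_WT_PARENT,
    ROLES,
)

logger = logging.getLogger(__name__)

#: Ordered substitution pairs that are NOT the EMS signature (G:C -> A:T).
_NON_EMS_PAIRS = [
    (r, a) for r in BASES for a in BASES if r != a and (r, a) not in (("G", "A"), ("C", "T"))
]

_ANNOTATIONS = [
    "Protein kinase domain",
    "Leucine-rich repeat domain superfamily",
    "Tubulin",
    "Transcription factor GRAS",
    "RING-type E3 ubiquitin transferase",
    "Aspartic peptidase A1 family",
    "F-box domain-containing protein",
    "ABC transporter-like",
]


@dataclass
class SimConfig:
    """Parameters of the simulated cross, trait model and sequencing.

    Units: positions/lengths in bp, trait values in cm, depth in reads,
    recombination in cM per Mb (Haldane map function).
    """

    n_f2: int = 200
    pool_size: int = 30
    mean_depth: float = 50.0
    n_sites: int = 500
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    ems_fraction: float = 0.9
    indel_fraction: float = 0.05
    # default causal position is generic: mid-chromosome but away from the
    # 500 kb analysis-grid boundaries, which are a measure-zero worst case
    # for fixed-window smoothing (the signal would split across windows)
    causal_chrom: str = "chr2"
    causal_pos: int = 1_200_000
    additive_effect: float = 2.0
    dominance: float = 2.0  # == additive_effect: complete dominance
    env_sd: float = 0.5
    base_mean: float = 7.0
    error_rate: float = 0.001
    recomb_cM_per_Mb: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 <= 0 or self.pool_size <= 0 or self.n_sites <= 0:
            raise ConfigurationError("counts must be positive")
        if self.pool_size > self.n_f2 // 2:
            raise ConfigurationError("pool_size must be <= n_f2/2")
        for frac, name in (
            (self.ems_fraction, "ems_fraction"),
            (self.error_rate, "error_rate"),
            (self.indel_fraction, "indel_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.mean_depth <= 0 or self.env_sd < 0 or self.recomb_cM_per_Mb < 0:
            raise ConfigurationError("mean_depth > 0, env_sd >= 0, recomb >= 0 required")
        if self.causal_chrom not in self.chrom_lengths:
            raise ConfigurationError(f"causal_chrom {self.causal_chrom!r} not simulated")
        if not 1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]:
            raise ConfigurationError("causal_pos outside its chromosome")
        if any(l <= 100 for l in self.chrom_lengths.values()):
            raise ConfigurationError("chromosomes must be > 100 bp")


@dataclass
class TruthSet:
    """Ground truth of one simulated F2 experiment.

    sites
        One row per marker: chrom, pos, ref, alt, variant_class, is_ems,
        is_causal, cM (map position).
    genotypes
        (n_f2, n_markers) mutant-allele dosage (0/1/2).
    traits
        (n_f2,) spike length, cm.
    """

    config: SimConfig
    sites: pd.DataFrame
    genotypes: np.ndarray
    traits: np.ndarray
    causal_index: int


def _sample_positions(
    rng: np.random.Generator, length: int, n: int, exclude_near: int | None = None
) -> np.ndarray:
    # sample on a coarse lattice so neighbouring markers never collide with
    # multi-base InDel reference alleles
    grid = np.arange(10, length - 10, 7)
    if exclude_near is not None:
        grid = grid[np.abs(grid - exclude_near) > 6]
    if n > grid.size:
        raise ConfigurationError(f"n_sites={n} too dense for a {length} bp chromosome")
    return np.sort(rng.choice(grid, size=n, replace=False))


def _draw_alleles(
    rng: np.random.Generator, n: int, cfg: SimConfig
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Draw (ref, alt, is_indel, is_ems) for n marker sites."""
    is_indel = rng.random(n) < cfg.indel_fraction
    is_ems = (~is_indel) & (rng.random(n) < cfg.ems_fraction)
    refs: list[str] = []
    alts: list[str] = []
    for i in range(n):
        if is_indel[i]:
            anchor = BASES[rng.integers(4)]
            tail = "".join(BASES[j] for j in rng.integers(0, 4, size=rng.integers(1, 4)))
            if rng.random() < 0.5:
                refs.append(anchor)
                alts.append(anchor + tail)  # insertion
            else:
                refs.append(anchor + tail)  # deletion
                alts.append(anchor)
        elif is_ems[i]:
            ref = "G" if rng.random() < 0.5 else "C"
            refs.append(ref)
            alts.append("A" if ref == "G" else "T")
        else:
            ref, alt = _NON_EMS_PAIRS[rng.integers(len(_NON_EMS_PAIRS))]
            refs.append(ref)
            alts.append(alt)
    return refs, alts, is_indel, is_ems


def simulate_f2(config: SimConfig) -> TruthSet:
    """Simulate genotypes and trait values for an F2 population.

    Trait model: ``base_mean + additive_effect*[hom mutant] +
    dominance*[het] + Normal(0, env_sd)``. Genotypes arise from two
    independent F1 gametes per plant with Haldane recombination.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    frames = []
    geno_blocks = []
    for chrom, length in config.chrom_lengths.items():
        if chrom == config.causal_chrom:
            # reserve the causal slot so the marker count stays exact
            pos = _sample_positions(
                rng, length, config.n_sites - 1, exclude_near=config.causal_pos
            )
            pos = np.sort(np.append(pos, config.causal_pos))
        else:
            pos = _sample_positions(rng, length, config.n_sites)
        refs, alts, is_indel, is_ems = _draw_alleles(rng, len(pos), config)
        if chrom == config.causal_chrom:
            # the causal lesion itself is an EMS transition SNP
            ci = int(np.searchsorted(pos, config.causal_pos))
            refs[ci], alts[ci] = "G", "A"
            is_indel[ci] = False
            is_ems[ci] = True
        cM = pos / 1e6 * config.recomb_cM_per_Mb
        gam1 = _haldane_gametes(rng, config.n_f2, cM)
        gam2 = _haldane_gametes(rng, config.n_f2, cM)
        geno_blocks.append(gam1.astype(np.int8) + gam2.astype(np.int8))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": refs,
                    "alt": alts,
                    "variant_class": np.where(is_indel, "InDel", "SNP"),
                    "is_ems": is_ems,
                    "is_causal": (chrom == config.causal_chrom) & (pos == config.causal_pos),
                    "cM": cM,
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    genotypes = np.concatenate(geno_blocks, axis=1)
    causal_index = int(np.flatnonzero(sites["is_causal"].to_numpy())[0])

    g_causal = genotypes[:, causal_index]
    traits = (
        config.base_mean
        + config.additive_effect * (g_causal == 2)
        + config.dominance * (g_causal == 1)
        + rng.normal(0.0, config.env_sd, size=config.n_f2)
    )
    return TruthSet(
        config=config,
        sites=sites,
        genotypes=genotypes,
        traits=traits,
        causal_index=causal_index,
    )


def _haldane_gametes(
    rng: np.random.Generator, n: int, cM: np.ndarray
) -> np.ndarray:
    """n gametes (bool array, True = mutant allele) along one chromosome."""
    m = len(cM)
    first = rng.random(n) < 0.5
    if m == 1:
        return first[:, None]
    d = np.diff(cM) / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    switches = rng.random((n, m - 1)) < r[None, :]
    # allele flips wherever an odd number of crossovers has accumulated
    flips = np.cumsum(switches, axis=1) % 2 == 1
    out = np.empty((n, m), dtype=bool)
    out[:, 0] = first
    out[:, 1:] = first[:, None] ^ flips
    return out


def select_tail_pools(
    truth: TruthSet, pool_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the phenotypic-extreme tail pools (plant index arrays).

    Returns ``(long_pool_ids, short_pool_ids)``: the *pool_size* plants with
    the highest and lowest trait values; ties broken by plant id so the
    selection is deterministic.
    """
    n = len(truth.traits)
    if 2 * pool_size > n:
        raise ConfigurationError(f"pool_size {pool_size} too large for {n} plants")
    ids = np.arange(n)
    long_ids = np.sort(np.lexsort((ids, -truth.traits))[:pool_size])
    short_ids = np.sort(np.lexsort((ids, truth.traits))[:pool_size])
    return long_ids, short_ids


def pool_allele_freqs(truth: TruthSet, plant_ids: np.ndarray) -> np.ndarray:
    """Equimolar-pool mutant-allele frequency per marker: mean dosage / 2."""
    return truth.genotypes[plant_ids].mean(axis=0) / 2.0


def _depth_quadruples(
    freqs: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised sequencing model over n sites -> (n, 4) base counts.

    Total depth ~ Poisson(mean_depth); alt reads ~ Binomial(depth, freq);
    each read miscalled with probability error_rate, landing uniformly on
    the two bases that are neither allele (so errors never inflate either
    parental-allele count).
    """
    n = len(freqs)
    depth = rng.poisson(config.mean_depth, size=n)
    alt_true = rng.binomial(depth, freqs)
    ref_true = depth - alt_true
    counts = np.zeros((n, 4), dtype=np.int64)
    rows = np.arange(n)
    err_idx = _error_bases(ref_idx, alt_idx)
    errors_total = np.zeros(n, dtype=np.int64)
    for true_counts, idx in ((ref_true, ref_idx), (alt_true, alt_idx)):
        correct = rng.binomial(true_counts, 1.0 - config.error_rate)
        errors_total += true_counts - correct
        np.add.at(counts, (rows, idx), correct)
    if errors_total.any():
        spread = rng.multinomial(errors_total, [0.5, 0.5])
        np.add.at(counts, (rows[:, None], err_idx), spread)
    return counts


def _error_bases(ref_idx: np.ndarray, alt_idx: np.ndarray) -> np.ndarray:
    """(n, 2) indices of the bases that are neither ref nor alt."""
    n = len(ref_idx)
    mask = np.ones((n, 4), dtype=bool)
    mask[np.arange(n), ref_idx] = False
    mask[np.arange(n), alt_idx] = False
    out = np.argsort(~mask, axis=1, kind="stable")[:, :2]
    out.sort(axis=1)
    return out


def simulate_pool_depths(
    allele_freq: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    ref: str = "G",
    alt: str = "A",
) -> np.ndarray:
    """Draw one base-depth quadruple (A, C, G, T counts) for a pooled sample."""
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError(f"allele_freq must be in [0, 1], got {allele_freq}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return _depth_quadruples(
        np.array([allele_freq]),
        np.array([BASE_INDEX[ref]]),
        np.array([BASE_INDEX[alt]]),
        config,
        rng,
    )[0]


def records_from_truth(
    truth: TruthSet,
    long_ids: np.ndarray,
    short_ids: np.ndarray,
    rng: np.random.Generator | None = None,
) -> list[PooledVariantRecord]:
    """Sequence the four samples at every marker site.

    Parents are fully homozygous and divergent (wild-type parent carries
    ref, mutant parent carries the EMS alt); pool allele frequencies are the
    equimolar mean dosage over pooled plants.
    """
    cfg = truth.config
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 2])
    sites = truth.sites
    n = len(sites)
    role_freqs = {
        ROLE_WT_PARENT: np.zeros(n),
        ROLE_MUT_PARENT: np.ones(n),
        ROLE_POOL_SHORT: pool_allele_freqs(truth, short_ids),
        ROLE_POOL_LONG: pool_allele_freqs(truth, long_ids),
    }
    is_snp = (sites["variant_class"] == "SNP").to_numpy()
    ref_idx = np.array([BASE_INDEX[r[0]] for r in sites["ref"]])
    alt_idx = np.array([BASE_INDEX[a[0]] for a in sites["alt"]])
    # for SNPs the anchors are the actual alleles; for InDels we track only
    # ref/alt-supporting read counts (base quadruples are not meaningful)
    quads: dict[str, np.ndarray] = {}
    allele_counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for role, freqs in role_freqs.items():
        depth = rng.poisson(cfg.mean_depth, size=n)
        alt_reads = rng.binomial(depth, freqs)
        ref_reads = depth - alt_reads
        # per-read miscalls: a miscalled read supports neither allele (SNP
        # miscalls land on the two error bases of the quadruple)
        ref_ok = rng.binomial(ref_reads, 1.0 - cfg.error_rate)
        alt_ok = rng.binomial(alt_reads, 1.0 - cfg.error_rate)
        counts = np.zeros((n, 4), dtype=np.int64)
        rows = np.arange(n)
        np.add.at(counts, (rows, ref_idx), ref_ok)
        np.add.at(counts, (rows, alt_idx), alt_ok)
        errors = (ref_reads - ref_ok) + (alt_reads - alt_ok)
        if errors.any():
            spread = rng.multinomial(errors, [0.5, 0.5])
            np.add.at(counts, (rows[:, None], _error_bases(ref_idx, alt_idx)), spread)
        quads[role] = counts
        allele_counts[role] = (ref_ok, alt_ok)

    records: list[PooledVariantRecord] = []
    for i in range(n):
        allele_depths = {
            role: (int(allele_counts[role][0][i]), int(allele_counts[role][1][i]))
            for role in ROLES
        }
        base_depths = {
            role: (quads[role][i].copy() if is_snp[i] else None) for role in ROLES
        }
        records.append(
            PooledVariantRecord(
                chrom=sites["chrom"].iat[i],
                pos=int(sites["pos"].iat[i]),
                ref=sites["ref"].iat[i],
                alt=sites["alt"].iat[i],
                variant_class=sites["variant_class"].iat[i],
                allele_depths=allele_depths,
                base_depths=base_depths,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Toy gene models and expression profiles
# ---------------------------------------------------------------------------

def build_toy_genes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    genes_per_chrom: int = 8,
) -> list[GeneModel]:
    """Random single-transcript gene models; one always spans the causal
    locus so candidate-gene extraction has a guaranteed hit."""
    rng = rng if rng is not None else np.random.default_rng([config.seed, 3])
    models: list[GeneModel] = []
    counter = 0
    for chrom, length in config.chrom_lengths.items():
        spacing = length // (genes_per_chrom + 1)
        for k in range(genes_per_chrom):
            anchor = spacing * (k + 1) + int(rng.integers(-spacing // 4, spacing // 4))
            if chrom == config.causal_chrom and abs(anchor - config.causal_pos) < spacing:
                anchor = config.causal_pos - int(rng.integers(100, 400))
            counter += 1
            models.append(
                _random_gene(rng, f"gene{counter:03d}", chrom, anchor, length, counter)
            )
    return models


def _random_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, chrom_len: int,
    counter: int,
) -> GeneModel:
    n_exons = int(rng.integers(1, 4))
    exons: list[tuple[int, int]] = []
    cursor = max(start, 1)
    for _ in range(n_exons):
        ex_len = int(rng.integers(150, 400))
        exons.append((cursor, min(cursor + ex_len - 1, chrom_len)))
        cursor += ex_len + int(rng.integers(80, 200))
    utr5 = int(rng.integers(0, 60))
    utr3 = int(rng.integers(0, 60))
    cds = _trim_to_cds(exons, utr5, utr3)
    strand = "+" if rng.random() < 0.5 else "-"
    annotation = _ANNOTATIONS[counter % len(_ANNOTATIONS)]
    return GeneModel(gene_id, chrom, strand, exons, cds, annotation)


def _trim_to_cds(
    exons: list[tuple[int, int]], head_trim: int, tail_trim: int
) -> list[tuple[int, int]]:
    """Trim the exon chain at both ends (UTRs) to a CDS divisible by 3."""
    segs = [list(seg) for seg in exons]
    segs[0][0] += head_trim
    segs[-1][1] -= tail_trim
    segs = [s for s in segs if s[0] <= s[1]]
    total = sum(e - s + 1 for s, e in segs)
    extra = total % 3
    while extra:
        take = min(extra, segs[-1][1] - segs[-1][0] + 1)
        segs[-1][1] -= take
        extra -= take
        if segs[-1][1] < segs[-1][0]:
            segs.pop()
    return [tuple(s) for s in segs]


def simulate_expression_matrix(
    gene_ids: list[str],
    spike_genes: list[str],
    rng: np.random.Generator | None = None,
    tissues: tuple[str, ...] = ("root", "leaf", "stem", "spike", "grain"),
    dominant_level: float = 20.0,
    background_level: float = 2.0,
) -> pd.DataFrame:
    """Gene x tissue expression table with a spike-dominant subset.

    Genes in *spike_genes* are expressed far above background in the spike
    and near background elsewhere; all other genes are constructed
    non-dominant (their spike value is held below their other tissues), so
    the spike-predominance rule selects exactly the intended subset.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    data = rng.gamma(2.0, background_level / 2.0, size=(len(gene_ids), len(tissues)))
    df = pd.DataFrame(data, index=gene_ids, columns=list(tissues))
    spike_set = set(spike_genes)
    for g in gene_ids:
        if g in spike_set:
            df.loc[g, :] = rng.gamma(2.0, background_level / 4.0, size=len(tissues))
            df.loc[g, "spike"] = dominant_level * (1 + 0.2 * rng.random())
        else:
            others = [t for t in tissues if t != "spike"]
            df.loc[g, "spike"] = 0.5 * float(df.loc[g, others].max())
    return df.round(3)


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def _make_genome(
    truth: TruthSet, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Random genome with the marker reference alleles written in."""
    genome: dict[str, np.ndarray] = {}
    base_arr = np.array(list("ACGT"))
    for chrom, length in truth.config.chrom_lengths.items():
        genome[chrom] = base_arr[rng.integers(0, 4, size=length)]
    for _, row in truth.sites.iterrows():
        seq = genome[row["chrom"]]
        ref = row["ref"]
        seq[row["pos"] - 1 : row["pos"] - 1 + len(ref)] = list(ref)
    return genome


def emit_dataset(
    truth: TruthSet,
    out_dir: str | Path,
    genes_per_chrom: int = 8,
) -> dict[str, str]:
    """Write the full dataset and return a file manifest.

    Files: ``variants.vcf`` (4 samples, AD + BD), ``reference.fasta``,
    ``genes.gff3``, ``phenotypes.tsv``, ``truth.json``, ``manifest.json``.
    Byte-identical for identical configs (seed included).
    """
    cfg = truth.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long_ids, short_ids = select_tail_pools(truth, cfg.pool_size)
    records = records_from_truth(
        truth, long_ids, short_ids, np.random.default_rng([cfg.seed, 2])
    )
    genome = _make_genome(truth, np.random.default_rng([cfg.seed, 4]))
    genes = build_toy_genes(cfg, np.random.default_rng([cfg.seed, 3]), genes_per_chrom)

    fasta = out / "reference.fasta"
    _write_fasta(genome, fasta)
    vcf = out / "variants.vcf"
    write_pooled_vcf(records, cfg.chrom_lengths, vcf)
    gff = out / "genes.gff3"
    write_gff(genes, gff)
    pheno = out / "phenotypes.tsv"
    with open(pheno, "w") as fh:
        fh.write("plant_id\tspike_length_cm\n")
        for i, t in enumerate(truth.traits):
            fh.write(f"F2_{i:04d}\t{t:.3f}\n")
    truth_json = out / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(
            {
                "config": {
                    k: (v if not isinstance(v, dict) else dict(v))
                    for k, v in asdict(cfg).items()
                },
                "causal": {"chrom": cfg.causal_chrom, "pos": cfg.causal_pos},
                "long_pool": [f"F2_{i:04d}" for i in long_ids],
                "short_pool": [f"F2_{i:04d}" for i in short_ids],
                "sites": truth.sites.drop(columns=["cM"]).to_dict(orient="list"),
                "long_pool_freq": pool_allele_freqs(truth, long_ids).round(5).tolist(),
                "short_pool_freq": pool_allele_freqs(truth, short_ids).round(5).tolist(),
            },
            fh,
            indent=1,
        )
    manifest = {
        "vcf": str(vcf),
        "fasta": str(fasta),
        "gff": str(gff),
        "phenotypes": str(pheno),
        "truth": str(truth_json),
        "sample_roles": {role: role for role in ROLES},
        "checksums": {
            p.name: hashlib.md5(p.read_bytes()).hexdigest()
            for p in (vcf, fasta, gff, pheno, truth_json)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _write_fasta(genome: dict[str, np.ndarray], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_pooled_vcf(
    records: list[PooledVariantRecord],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write records as a VCF 4.2 with AD (ref,alt) and BD (A,C,G,T) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsamap-simulate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=BD,Number=4,Type=Integer,Description="Base depths A,C,G,T">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ROLES) + "\n")
        for rec in records:
            cols = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS", ".", "AD:BD:DP"]
            for role in ROLES:
                ad = rec.allele_depths[role]
                bd = rec.base_depths.get(role)
                bd_str = ",".join(map(str, bd)) if bd is not None else ".,.,.,."
                cols.append(f"{ad[0]},{ad[1]}:{bd_str}:{rec.total_depth(role)}")
            fh.write("\t".join(cols) + "\n")


def write_gff(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";description={g.annotation}"
            fh.write(
                f"{g.chrom}\tbsamap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tbsamap\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tbsamap\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            cds_order = g.cds if g.strand == "+" else list(reversed(g.cds))
            cum = 0
            for s, e in cds_order:
                phase = (3 - cum % 3) % 3
                fh.write(
                    f"{g.chrom}\tbsamap\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tParent={mrna}\n"
                )
                cum += e - s + 1
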