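"""End-to-end orchestration: simulate -> filter -> scan -> regions -> genes.

Each ``run_*`` function is a thin, deterministic composition of the stage
modules: given a config and a seed it produces the same tables every time.
Output tables carry a ``# seed=`` header line, and ``summary.json`` records
the count chain (variants in -> SNPs/InDels -> retained -> scan points ->
regions -> candidate SNPs -> genes) so a run can be audited stage by stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import effects, kasp, regions as regions_mod, scan as scan_mod, simulate, variant_io
from .kasp import KaspConstraints
from .regions import CandidateRegion
from .scan import ScanConfig
from .simulate import SimConfig
from .variant_io import FilterConfig, ROLES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus stage configs for a full scan run."""

    vcf: str
    gff: str | None = None
    fasta: str | None = None
    phenotypes: str | None = None
    expression: str | None = None
    fluorescence: str | None = None
    out_dir: str = "bsamap_out"
    sample_map: dict[str, str] = field(default_factory=lambda: {r: r for r in ROLES})
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    scan_config: ScanConfig = field(default_factory=ScanConfig)
    kasp_constraints: KaspConstraints = field(default_factory=KaspConstraints)
    target_tissue: str = "spike"
    seed: int = 0


def _write_table(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _region_table(region_list: list[CandidateRegion]) -> pd.DataFrame:
    rows = [
        (
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            r.interval.length,
            r.n_markers,
            r.source,
        )
        for r in region_list
    ]
    return pd.DataFrame(
        rows, columns=["Chrom", "Start", "End", "Length (bp)", "Markers", "Source"]
    )


def run_simulate(config: SimConfig, out_dir: str | Path) -> dict:
    """Drive the simulator end to end and emit the dataset files."""
    truth = simulate.simulate_f2(config)
    return simulate.emit_dataset(truth, out_dir)


def region_score(region: CandidateRegion, points: pd.DataFrame) -> float:
    """Rank score of a region: maximum raw ED among its member sites."""
    iv = region.interval
    mask = (
        (points["chrom"] == iv.chrom)
        & (points["pos"] >= iv.start)
        & (points["pos"] <= iv.end)
    )
    return float(points.loc[mask, "ed"].max()) if mask.any() else float("-inf")


def run_scan(config: PipelineConfig) -> dict:
    """Full association scan: read, filter, both methods, intersect,
    annotate, extract candidate genes. Returns the summary dict (also
    written to ``summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    scfg = config.scan_config

    records = variant_io.read_pooled_vcf(config.vcf, config.sample_map)
    counts = variant_io.summarize_classes(records)
    retained, tally = variant_io.filter_variants(records, config.filter_config)

    points, n_dropped = scan_mod.compute_scan_points(retained, scfg)
    points, n_floor = scan_mod.filter_offspring_index(
        points, scfg.offspring_index_floor, scfg.index_floor_mode
    )

    if len(points):
        points = scan_mod.fit_ed(points, scfg.ed_power, scfg.ed_span)
        ed_regs, ed_thr = scan_mod.ed_regions(points, scfg)
        windows = scan_mod.smooth_delta(
            points, scfg.delta_window_bp, scfg.delta_step_bp, scfg.min_markers_per_window
        )
        delta_regs = scan_mod.delta_regions(windows, scfg, seed=seed)
        intersection = regions_mod.intersect_region_sets(delta_regs, ed_regs)
        candidates = scan_mod.select_candidate_snps(points, ed_regs, scfg)
        intersection = regions_mod.snps_in_regions(candidates, intersection)
    else:
        points = points.assign(fitted_ed=pd.Series(dtype=float))
        ed_regs, ed_thr = [], float("nan")
        windows = pd.DataFrame(
            columns=["chrom", "start", "end", "n_markers", "mean_delta"]
        )
        delta_regs, intersection = [], []
        candidates = points.copy()

    candidate_records = _records_at(records, candidates)
    gene_models = variant_io.read_gff(config.gff) if config.gff else []
    genome = variant_io.read_fasta(config.fasta) if config.fasta else {}
    if gene_models and genome and candidate_records:
        annotations = effects.annotate_records(candidate_records, gene_models, genome)
    else:
        annotations = pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "variant_class",
                "location", "gene_ids", "effect", "aa_change",
            ]
        )

    annotated_genes = {
        (row.chrom, row.pos): row.gene_ids.split(",") if row.gene_ids else []
        for row in annotations.itertuples(index=False)
    }
    candidate_genes = regions_mod.genes_in_regions(
        intersection, gene_models, annotated_genes
    )
    genes_df = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.start, g.end, g.strand, g.annotation)
            for g in candidate_genes
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "annotation"],
    )

    prioritized = None
    if config.expression and len(genes_df):
        expr = variant_io.read_expression_matrix(config.expression)
        prioritized = regions_mod.prioritize_by_expression(
            list(genes_df["gene_id"]), expr, config.target_tissue
        )
        _write_table(prioritized, out / "prioritized_genes.tsv", seed)

    _write_table(points, out / "scan_points.tsv", seed)
    _write_table(windows, out / "delta_windows.tsv", seed)
    _write_table(_region_table(delta_regs), out / "regions_snp_index.tsv", seed)
    _write_table(_region_table(ed_regs), out / "regions_ed.tsv", seed)
    _write_table(_region_table(intersection), out / "regions_intersection.tsv", seed)
    _write_table(candidates, out / "candidate_snps.tsv", seed)
    _write_table(annotations, out / "annotations.tsv", seed)
    _write_table(genes_df, out / "candidate_genes.tsv", seed)

    summary = {
        "seed": seed,
        "input_variants": counts.total,
        "snps": counts.snps,
        "indels": counts.indels,
        "transitions": counts.transitions,
        "transversions": counts.transversions,
        "counts_consistent": counts.consistent(),
        "filter_tally": tally,
        "retained": len(retained),
        "dropped_undefined_index": n_dropped,
        "dropped_offspring_index_floor": n_floor,
        "scan_points": len(points),
        "ed_threshold": ed_thr,
        "n_regions_snp_index": len(delta_regs),
        "n_regions_ed": len(ed_regs),
        "n_regions_intersection": len(intersection),
        "n_candidate_snps": len(candidates),
        "n_candidate_genes": len(genes_df),
        "n_prioritized_genes": int(prioritized["selected"].sum()) if prioritized is not None else None,
    }
    assert sum(tally.values()) + len(retained) == counts.total
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def _records_at(records, points: pd.DataFrame):
    wanted = set(zip(points["chrom"], points["pos"].astype(int)))
    return [r for r in records if (r.chrom, r.pos) in wanted]


def run_kasp(
    fasta: str,
    loci: list[tuple[str, int, str, str]],
    out_dir: str | Path,
    fluorescence: str | None = None,
    phenotypes: str | None = None,
    constraints: KaspConstraints | None = None,
    flank_bp: int = 150,
    seed: int = 0,
) -> dict:
    """Design assays for (chrom, pos, ref, alt) loci; optionally genotype a
    fluorescence table and test the genotype-phenotype association.

    Without a fluorescence file this is design-only mode.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = variant_io.read_fasta(fasta)
    constraints = constraints or KaspConstraints()
    rows = []
    assays = {}
    for chrom, pos, ref, alt in loci:
        snp_id = f"KASP-{chrom}-{pos}"
        seq = genome.get(chrom)
        if seq is None or pos - flank_bp < 1 or pos + flank_bp > len(seq):
            rows.append((snp_id, "failed", "locus too close to a contig end", *[""] * 6))
            continue
        flank = seq[pos - flank_bp - 1 : pos + flank_bp]
        result = kasp.design_kasp(
            flank, (ref, alt), genome, constraints, snp_id=snp_id
        )
        if isinstance(result, kasp.DesignFailure):
            rows.append((snp_id, "failed", "; ".join(result.reasons), *[""] * 6))
            continue
        assays[snp_id] = result
        rows.append(
            (
                snp_id,
                "ok",
                "",
                result.forward_primers[0],
                result.forward_primers[1],
                result.common_primer,
                f"{result.tm['fwd_allele1']:.1f}/{result.tm['fwd_allele2']:.1f}/{result.tm['common']:.1f}",
                f"{result.gc['fwd_allele1']:.2f}/{result.gc['fwd_allele2']:.2f}/{result.gc['common']:.2f}",
                result.product_length,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "marker_id", "status", "failure_reason",
            "fwd_primer_allele1", "fwd_primer_allele2", "common_primer",
            "Tm_C", "GC", "product_bp",
        ],
    )
    _write_table(report, out / "kasp_primers.tsv", seed)

    summary: dict = {
        "seed": seed,
        "n_loci": len(loci),
        "n_designed": len(assays),
        "design_only": fluorescence is None,
    }
    if fluorescence is not None:
        readings = pd.read_csv(fluorescence, sep="\t")
        calls = kasp.call_genotypes(readings, seed=seed)
        calls_df = pd.DataFrame(
            [(c.sample_id, c.call, c.fam, c.hex) for c in calls],
            columns=["sample_id", "call", "fam", "hex"],
        )
        _write_table(calls_df, out / "genotype_calls.tsv", seed)
        if phenotypes is not None:
            pheno = variant_io.read_phenotypes(phenotypes)
            pheno = pheno.rename(columns={"plant_id": "plant_id"})
            assoc = kasp.association_test(calls, pheno)
            summary["association"] = {
                "t": assoc.t_statistic,
                "p": assoc.p_value,
                "group_means": assoc.group_means,
                "group_ns": assoc.group_ns,
                "skipped": assoc.skipped,
            }
    with open(out / "kasp_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


# ---------------------------------------------------------------------------
# Replicated in-memory experiments (method validation)
# ---------------------------------------------------------------------------

def run_recovery_replicate(
    seed: int,
    sim_kwargs: dict | None = None,
    scan_config: ScanConfig | None = None,
) -> dict:
    """One seeded simulate->scan replicate scored against the truth.

    Runs both methods on an in-memory dataset and reports whether the
    causal locus falls inside the top-ranked region of each method and of
    their intersection (regions ranked by maximum raw ED). The Δ arm uses
    the simulation-null quantile threshold: under the complete-dominance
    trait model tail pools cap |Δ| near 2/3, below any fixed threshold
    close to 1.
    """
    cfg = SimConfig(seed=seed, **(sim_kwargs or {}))
    scfg = scan_config or ScanConfig(
        delta_mode="quantile",
        null_cM_per_Mb=cfg.recomb_cM_per_Mb,
        null_pool_size=cfg.pool_size,
        null_depth=cfg.mean_depth,
    )
    truth = simulate.simulate_f2(cfg)
    long_ids, short_ids = simulate.select_tail_pools(truth, cfg.pool_size)
    records = simulate.records_from_truth(truth, long_ids, short_ids)
    retained, _ = variant_io.filter_variants(records, FilterConfig())
    points, _ = scan_mod.compute_scan_points(retained, scfg)
    points, _ = scan_mod.filter_offspring_index(
        points, scfg.offspring_index_floor, scfg.index_floor_mode
    )
    points = scan_mod.fit_ed(points, scfg.ed_power, scfg.ed_span)
    ed_regs, ed_thr = scan_mod.ed_regions(points, scfg)
    windows = scan_mod.smooth_delta(
        points, scfg.delta_window_bp, scfg.delta_step_bp, scfg.min_markers_per_window
    )
    delta_regs = scan_mod.delta_regions(windows, scfg, seed=seed)
    intersection = regions_mod.intersect_region_sets(delta_regs, ed_regs)

    def top_hit(regs: list[CandidateRegion]) -> bool:
        if not regs:
            return False
        top = max(regs, key=lambda r: region_score(r, points))
        return top.interval.contains(cfg.causal_chrom, cfg.causal_pos)

    return {
        "causal_in_top_ed": top_hit(ed_regs),
        "causal_in_top_delta": top_hit(delta_regs),
        "causal_in_top_intersection": top_hit(intersection),
        "n_ed_regions": len(ed_regs),
        "n_delta_regions": len(delta_regs),
        "n_intersection_regions": len(intersection),
        "ed_threshold": ed_thr,
    }


def run_null_replicate(seed: int, sim_kwargs: dict | None = None) -> dict:
    """One no-QTL replicate: Δ regions called at the absolute 0.95
    threshold (the spurious-region control)."""
    base = {"additive_effect": 0.0, "dominance": 0.0}
    base.update(sim_kwargs or {})
    cfg = SimConfig(seed=seed, **base)
    scfg = ScanConfig(delta_mode="absolute")
    truth = simulate.simulate_f2(cfg)
    long_ids, short_ids = simulate.select_tail_pools(truth, cfg.pool_size)
    records = simulate.records_from_truth(truth, long_ids, short_ids)
    retained, _ = variant_io.filter_variants(records, FilterConfig())
    points, _ = scan_mod.compute_scan_points(retained, scfg)
    points, _ = scan_mod.filter_offspring_index(points)
    windows = scan_mod.smooth_delta(
        points, scfg.delta_window_bp, scfg.delta_step_bp, scfg.min_markers_per_window
    )
    delta_regs = scan_mod.delta_regions(windows, scfg, seed=seed)
    return {"n_delta_regions": len(delta_regs)}


def run_kasp_replicate(seed: int, n_plants: int = 91) -> dict:
    """One seeded end-to-end KASP experiment on a synthetic causal SNP.

    Simulates F2 genotypes at one locus (1:2:1), spike lengths from the
    dominant trait model, a designed assay on a random GC-balanced flank,
    fluorescence by genotype, k-means genotype calls, and the homozygote
    association t-test.
    """
    rng = np.random.default_rng([seed, 7])
    flank = kasp.random_feasible_flank(rng, arm=150)
    alleles = ("T", "C")
    flank = flank[:150] + alleles[0] + flank[150 + 1 :]
    assay = kasp.design_kasp(flank, alleles, None, snp_id=f"sim-{seed}")
    assay_ok = isinstance(assay, kasp.KaspAssay)
    if assay_ok:
        assay.validate()

    genotype = rng.choice([0, 1, 2], size=n_plants, p=[0.25, 0.5, 0.25])
    cfg = SimConfig(n_f2=max(n_plants, 60), seed=seed)
    traits = (
        cfg.base_mean
        + cfg.additive_effect * (genotype == 2)
        + cfg.dominance * (genotype == 1)
        + rng.normal(0, cfg.env_sd, size=n_plants)
    )
    labels = np.array([kasp.CALL_ALLELE2, kasp.CALL_HET, kasp.CALL_ALLELE1])[genotype]
    readings = kasp.simulate_fluorescence(list(labels), rng)
    calls = kasp.call_genotypes(readings, seed=seed)
    pheno = pd.DataFrame(
        {"plant_id": readings["sample_id"], "spike_length_cm": traits}
    )
    assoc = kasp.association_test(calls, pheno)
    correct = np.mean([c.call == lab for c, lab in zip(calls, labels)])
    return {
        "assay_designed": assay_ok,
        "p_value": assoc.p_value,
        "genotype_accuracy": float(correct),
        "skipped": assoc.skipped,
    }
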