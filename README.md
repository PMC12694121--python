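# bsamap

BSA-seq trait mapping for biparental crops: locate a major trait locus by
comparing pooled sequencing of phenotypic-extreme offspring bulks, extract
candidate genes, and design KASP genotyping assays for the associated SNPs.

The package is aimed at the standard wheat-style design: a wild-type
parent, an EMS-derived mutant parent, and an F2 population from their
cross, from which the highest- and lowest-trait plants (e.g. 30 each) are
pooled and sequenced to ~50× together with the parents. It consumes a
called multi-sample VCF (with per-sample allele depths), a GFF3
annotation and a FASTA reference; a first-class simulator generates all of
these with known ground truth, so every stage is testable without any
external download.

## Statistics

For each biallelic site that passes the filters (per-sample depth ≥ 5×,
both parents homozygous and fixed for different alleles), with *M* the
read depth supporting one designated parent's allele and *P* the depth of
the other parent's allele in a pool:

- **SNP-index** per pool: `SNP-index = M / (M + P)`;
  **Δ(SNP-index)** `= index(long pool) − index(short pool)`. Δ is averaged
  in fixed 500-kb grid windows and windows with `|Δ̄| > 0.95` (or above a
  simulated no-QTL quantile, `--delta-mode quantile`) merge into
  candidate regions.
- **Euclidean distance**:
  `ED = √[(A_mut−A_wt)² + (C_mut−C_wt)² + (G_mut−G_wt)² + (T_mut−T_wt)²]`
  over the two pools' base-frequency quadruples. ED is smoothed per
  chromosome by tricube local linear regression; sites with fitted ED
  above `median + 3·SD` of all fitted values form regions, and SNPs with
  mutant-pool main-allele frequency > 0.75 and raw ED > 0.50 inside them
  are the candidate SNPs.
- The two methods' regions are **intersected** (1-based inclusive
  coordinates, `length = end − start + 1`), candidate genes are the genes
  containing or annotated to candidate SNPs inside the intersection, and
  an optional gene×tissue expression matrix prioritizes the
  target-tissue-predominant subset.
- **KASP assays**: two allele-specific forward primers differing only at
  the 3′ terminal base plus one common reverse primer, under the standard
  constraints (19–30 nt, Tm 59–65 °C by unified nearest-neighbor
  thermodynamics, product 80–150 bp, flank GC 40–60%, < 3 flank copies in
  the genome). Genotypes are called from two-channel endpoint
  fluorescence by seeded k-means on the channel ratio, and the two
  homozygote classes are compared with Student's t-test.

## Worked example

Simulate an F2 of 200 plants (3 × 2 Mb chromosomes, 500 markers each,
tail pools of 30, ~50× pooled depth, causal locus at chr2:1,200,000 with
incomplete dominance) and scan it:

```python
from bsamap.simulate import SimConfig
from bsamap.pipeline import run_simulate, run_scan, PipelineConfig
from bsamap.scan import ScanConfig

cfg = SimConfig(dominance=1.0, seed=11)
manifest = run_simulate(cfg, "demo/data")
summary = run_scan(PipelineConfig(
    vcf=manifest["vcf"], gff=manifest["gff"], fasta=manifest["fasta"],
    out_dir="demo/scan", seed=11,
    scan_config=ScanConfig(delta_mode="quantile",
                           null_cM_per_Mb=cfg.recomb_cM_per_Mb),
))
```

The summary reports 1,500 input variants (1,420 SNPs — 1,303 transitions,
reflecting the 90% EMS G:C→A:T spectrum — and 80 InDels), all retained by
the filters, an ED threshold of 0.824, one region per method, and one
intersection region with 64 candidate SNPs:

```
Chrom   Start     End  Length (bp)  Markers       Source
 chr2 1027953 1303508       275556       64 intersection
```

The region contains the true locus, and `candidate_genes.tsv` lists the
two toy genes overlapping it (an "Aspartic peptidase A1 family" and an
"F-box domain-containing protein" model). Designing a KASP assay at the
causal SNP from the emitted reference:

```python
from bsamap.pipeline import run_kasp
run_kasp(manifest["fasta"], [("chr2", 1_200_000, "G", "A")], "demo/kasp")
```

yields, in `kasp_primers.tsv`:

```
fwd_primer_allele1  CTGAAAAGGAATGCTTCTGATAAGGGCCCG
fwd_primer_allele2  CTGAAAAGGAATGCTTCTGATAAGGGCCCA
common_primer       GCCGAAGCAACTAGTATTGACAATGCCCT
Tm_C                64.0/63.3/63.9        product_bp  82
```

The end-to-end synthetic KASP experiment (`run_kasp_replicate(seed=11)`:
91 genotyped plants, fluorescence simulated by genotype, k-means calls,
homozygote t-test) gives 100% genotype-call accuracy and p ≈ 7 × 10⁻¹⁵.

The same stages are available from the shell:

```sh
bsamap simulate --out demo/data --seed 11
bsamap scan --vcf demo/data/variants.vcf --gff demo/data/genes.gff3 \
            --fasta demo/data/reference.fasta --out demo/scan --seed 11
bsamap kasp --fasta demo/data/reference.fasta --locus chr2:1200000:G:A \
            --out demo/kasp
bsamap report --run-dir demo/scan
```

## Layout

- `bsamap.simulate` — F2 cross, trait model, tail pools, sequencing model,
  dataset emission (VCF/FASTA/GFF3/phenotypes/truth JSON)
- `bsamap.variant_io` — VCF/GFF3/FASTA/TSV readers, site filters,
  transition/transversion classification
- `bsamap.scan` — SNP-index, Δ, ED, smoothing, thresholds, region calling
- `bsamap.effects` — variant location categories and codon-level effects
- `bsamap.regions` — interval arithmetic, two-method intersection,
  candidate genes, expression prioritization
- `bsamap.kasp` — primer design, Tm/GC, genotype clustering, association
- `bsamap.pipeline`, `bsamap.cli` — orchestration and the `bsamap` command

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
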