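# Methods

This note documents the models behind `bsamap`, the defaults and why they
were chosen, and what the synthetic-data experiments do and do not show.

## The design being modelled

A wild-type parent and an EMS-derived mutant parent are crossed; the F2
segregates a dominant major locus for a quantitative trait (spike length,
cm). Equal-DNA pools of the 30 longest- and 30 shortest-trait plants are
sequenced to ~50× together with both parents, and pooled allele
frequencies are contrasted to locate the locus. The pipeline starts from
the called VCF; read QC, alignment and variant calling are upstream tools'
business and out of scope.

## Simulator

**Genetics.** Parents are fully homozygous and fixed for different alleles
at every marker (the mutant parent carries the EMS allele). Each F2 plant
is two independent F1 gametes; crossovers follow the Haldane map function
`r = (1 − e^(−2d))/2` along each chromosome. Marker positions are drawn on
a 7-bp lattice (so multi-base InDel reference alleles never collide), with
one marker forced at the causal position.

**Trait model.** `y = base_mean + additive·1[g=2] + dominance·1[g=1] +
N(0, env_sd)` with defaults base 7.0 cm, additive 2.0 cm, dominance 2.0 cm
(complete dominance — the heterozygote equals the homozygous mutant, as
the long-spike F1 phenotype implies), env_sd 0.5 cm. The polygenic
background is absorbed into the Gaussian residual; the simulator does not
model transgressive segregation or G×E.

**Pools and sequencing.** Tail pools are the `pool_size` highest/lowest
trait values, ties broken by plant id. A pool's allele frequency at a
marker is the equimolar mean dosage over pooled plants / 2. Per sample and
site: total depth ~ Poisson(50); mutant-allele reads ~ Binomial(depth,
freq); each read is miscalled with probability 0.001, landing uniformly on
the two bases that are neither allele (so errors never inflate either
parental-allele count — which is also what makes the error_rate=1 edge
case well-defined: no reads of either true allele remain).

**Mutation spectrum.** A fraction `ems_fraction = 0.9` of SNPs are
G:C→A:T transitions (the EMS signature); the rest are uniform over the
other ten ordered substitutions; `indel_fraction = 0.05` of sites are
1–3 bp insertions/deletions, carried as a site class only.

**Map scaling — important.** Toy chromosomes (default 3 × 2 Mb) stand in
for ~600 Mb wheat chromosomes, and the recombination default is
200 cM/Mb, i.e. 4 Morgans per toy chromosome. The controlling quantity is
genetic length, not cM-per-Mb realism: two-sided tail selection sustains
pooled allele-frequency contrast proportional to (1 − 2r) around the
causal locus, so the selected signal extends roughly a Morgan to each
side. Chromosomes must be several Morgans long for that linked span to
stay a small fraction of the genome — the situation every genome-wide
threshold (median + 3SD of fitted ED, null quantiles) implicitly assumes.
At a literal 1 cM/Mb a 2 Mb toy chromosome is one fully linked block and
those thresholds degenerate.

**Default causal position** is mid-chromosome at chr2:1,200,000, placed
away from the 500-kb window-grid boundaries. A locus exactly on a grid
boundary is the worst case for fixed-window smoothing — its signal splits
between two windows — which is a real (documented) limitation of grid
windows, not of the locus model; sliding windows (`delta_step_bp` <
`delta_window_bp`) mitigate it on real data.

## Filters

Sites are retained when every sample has total depth ≥ `min_depth` (5×,
applied per sample), both parents are effectively homozygous (major base
≥ 90% of all their reads — the majority is taken over the full base
quadruple, so a parent split between any two bases is heterozygous), and
the parents are fixed for different alleles. The offspring-index floor
(drop sites with SNP-index < 0.30) is applied at scan time, by default
only when **both** pools are below the floor, preserving one-sided
extremes; `index_floor_mode="any"` gives the stricter reading.

## Association scans

**Orientation.** `M` in `M/(M+P)` is the wild-type parent's allele by
default (`index_parent="wt"`, the female parent of the cross); the allele
is inferred from the parents' majority reads rather than trusting ref/alt
assignment. Because the informative sign depends on orientation and on
which pool is fixed, Δ region calling is two-sided on |windowed Δ|.

**Δ windows.** Fixed grid windows `[k·step+1, k·step+window+1]` (adjacent
windows share one boundary base); merged runs of called windows therefore
start and end on round grid boundaries + 1, the convention under which
the published-style region tables' lengths (e.g. 3,500,001 bp for a seven
half-Mb-window run) are exact. Windows with fewer than 3 markers are
masked.

**Δ thresholds.** The default is the absolute 0.95 on |Δ̄|. Under
*complete* dominance that threshold is unreachable by construction: the
long pool is an ~2:1 het:hom mixture, its mutant-allele frequency tends
to 2/3, and |Δ| tops out near 2/3. This is an analytical property of the
trait model, so for dominant traits the scan provides
`delta_mode="quantile"`: per-window thresholds at the 0.995 quantile of a
simulated no-QTL null (binomial pool sampling + Poisson/binomial depth
noise). With `null_cM_per_Mb > 0` the null simulates the pooled plants'
gametes along the window's genetic length with the same Haldane Markov
chain, because physically linked markers share pooled plants and the
independent-marker null is anti-conservative; the default (0) is the
independent null, appropriate when markers are sparse relative to the
map.

**ED.** Raw ED (power 1 by default; 4–5 are conventional alternatives) is
smoothed per chromosome by tricube-weighted local linear regression
(span 0.1 of the chromosome's sites, no robustness iterations); the
genome-wide threshold is `median + 3·SD` of the fitted values, with SD the
population (n-denominator) standard deviation. Chromosomes with fewer
than two sites are skipped. Candidate SNPs inside called ED regions
require mutant-pool main-allele frequency > 0.75 and raw ED > 0.50 (both
strict). Note that under complete dominance the 0.75 gate passes
essentially nothing (the long pool's main allele sits at ~2/3 by the same
argument as above); candidate-SNP extraction is informative for
incompletely dominant loci, where tail selection drives the long pool
toward fixation.

**Regions.** Above-threshold items (sites or windows) merge when
separated by ≤ 1 Mb; each region carries its above-threshold marker
count. ED region intervals run from the first to the last called site;
Δ regions are unions of window intervals. Two-method intersection is
exact interval intersection (1-based inclusive); regions are ranked by
the maximum raw ED among member sites.

## Effect annotation

Location categories use 2,000-bp gene flanks and 2-bp intronic splice
windows; combined classes (upstream;downstream, exonic;splicing,
UTR5;UTR3) arise when several genes or features claim one variant. Coding
effects translate the reference and mutant codon under the standard
nuclear code (minus-strand genes via reverse complement): synonymous /
nonsynonymous / stopgain / stoploss for SNPs; frameshift vs nonframeshift
insertion/deletion by length mod 3 for InDels. Every unresolvable
transcript — CDS length not divisible by 3, reference-base mismatch,
variant outside the CDS of an exonic call — maps to `unknown` rather than
aborting the run. UTRs are exon regions outside the CDS, 5′/3′ resolved
by strand.

## Candidate genes and expression

A gene is a candidate when it contains a candidate SNP inside an
intersection region, or when the effect annotation links such a SNP to it
(flanking categories). "Predominantly expressed" in the target tissue is
operationalized as: target value > 0.5 expression units AND ≥ 0.8 × the
maximum over the other tissues; both thresholds are configurable since no
standard rule exists. Genes missing from the matrix are flagged, never
selected.

## KASP toolkit

Melting temperatures use unified nearest-neighbor ΔH/ΔS with the
SantaLucia entropy salt correction (0.368·(N−1)·ln[Na⁺]), 50 mM
monovalent salt and 200 nM primer by default. Design enumerates all
(forward length, reverse position, reverse length) combinations with the
forward primers ending at the SNP, and returns the feasible assay
minimizing Tm spread across the three primers, ties broken by product
length then primer geometry — fully deterministic. The 40–60% GC rule is
applied to the 301-bp locus flank for retention and (disable-able) to
each primer; "fewer than three copies" is the exact both-strand
occurrence count of the flank in the reference. Fluorophore tail
sequences are not modelled thermodynamically; if configured they are
prepended verbatim and excluded from Tm/GC checks. Secondary structure
and primer-dimer screening are out of scope.

Genotype calling clusters the normalized FAM ratio with seeded k-means
(k = 3, 10 restarts); clusters map to genotypes by center order, samples
below the NTC floor (total signal < 0.2) are no-template controls, and
runs whose cluster centers sit closer than 0.1 yield `undetermined` calls
with a warning. The genotype–phenotype test is Student's two-sample
t-test between the two homozygote classes; heterozygotes are summarized
but excluded, mirroring the two-group comparison such experiments report.

## Validation experiments and their scope

- *Recovery*: 50 seeded datasets at the design scale (3 × 500 markers,
  n_f2 = 200, pools of 30, depth 50); the causal locus must fall in the
  top-ranked region of both methods' intersection in ≥ 95%. The Δ arm
  runs in quantile mode with the linkage-aware null (see above).
- *Null control*: 20 no-QTL datasets; Δ regions at the absolute 0.95
  threshold average ≤ 1 per genome (observed: 0).
- *Formula suites*: SNP-index, ED, and median+3SD agree with brute-force
  read tallies / from-scratch arithmetic on 1,000 random inputs; the
  effect annotator agrees with a rebuild-and-translate oracle on 1,000
  random toy-gene SNPs; the Tm model agrees with an independent
  implementation of the same NN table to ±0.5 °C.
- *KASP end-to-end*: 20 seeded experiments (91 plants, 1:2:1 genotypes,
  fluorescence by genotype) must design constraint-valid assays and give
  homozygote-class p < 0.001 in ≥ 95%.

Problem sizes were chosen to keep the whole validation suite within a few
minutes on one CPU while preserving the design's statistical structure.
Passing these experiments shows the machinery is correct and well-scaled
for the simulated conditions; it does not certify performance on real
data, where alignment artifacts, segmental duplication, uneven coverage,
population structure and polygenic interference — none of which the
generator emulates — all degrade signal.
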