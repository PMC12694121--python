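"""KASP (kompetitive allele-specific PCR) assay design and genotyping.

An assay is two allele-specific forward primers — identical except for the
3' terminal base, which carries the SNP allele — plus one common reverse
primer on the opposite strand. Design constraints: primer lengths 19-30 nt,
melting temperatures 59-65 °C, product 80-150 bp, locus flank GC content
40-60% and fewer than three flank copies in the reference genome. Melting
temperatures come from unified nearest-neighbor thermodynamics with a
monovalent-salt entropy correction.

Genotypes are called from two-channel (FAM/HEX-style) endpoint
fluorescence by seeded k-means on the normalized channel ratio; the
association between the two homozygote classes and the quantitative trait
is tested with Student's two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# Unified nearest-neighbor parameters (kcal/mol, cal/mol/K), 5'->3' dimers.
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# fill in the reverse-complement dimers (identical thermodynamics)
for _dimer, _hs in list(_NN.items()):
    _rc = _dimer.translate(_COMPLEMENT)[::-1]
    _NN.setdefault(_rc, _hs)
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
_R_GAS = 1.987  # cal/mol/K


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(G+C) / length of an A/C/G/T string."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str, salt_mM: float = 50.0, primer_nM: float = 200.0
) -> float:
    """Primer Tm (°C) from unified nearest-neighbor ΔH/ΔS.

    Tm = 1000·ΔH / (ΔS + ΔS_salt + R·ln C) − 273.15, with the SantaLucia
    entropy salt correction ΔS_salt = 0.368·(N−1)·ln[Na+] and C the primer
    concentration (excess over template).
    """
    if len(seq) < 8:
        raise ValueError(f"sequence too short for NN Tm ({len(seq)} nt)")
    if set(seq) - set("ACGT"):
        raise ValueError("non-ACGT characters in primer")
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    conc = primer_nM * 1e-9
    return 1000.0 * dh / (ds + _R_GAS * math.log(conc)) - 273.15


def count_flank_copies(flank_seq: str, genome: dict[str, str]) -> int:
    """Exact occurrence count of *flank_seq* in the genome, both strands
    (overlapping matches counted)."""
    targets = {flank_seq, revcomp(flank_seq)}
    total = 0
    for seq in genome.values():
        for t in targets:
            start = 0
            while True:
                i = seq.find(t, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


@dataclass
class KaspConstraints:
    """Design window for primers, product and locus retention."""

    primer_len_min: int = 19
    primer_len_max: int = 30
    tm_min: float = 59.0
    tm_max: float = 65.0
    product_min: int = 80
    product_max: int = 150
    flank_gc_min: float = 0.40
    flank_gc_max: float = 0.60
    primer_gc_min: float = 0.40
    primer_gc_max: float = 0.60
    check_primer_gc: bool = True
    max_flank_copies: int = 2  # "fewer than three copies"
    salt_mM: float = 50.0
    primer_nM: float = 200.0


@dataclass
class KaspAssay:
    """A designed assay; ``validate`` re-checks every invariant."""

    snp_id: str
    alleles: tuple[str, str]
    forward_primers: tuple[str, str]  # differ only at the 3' terminal base
    common_primer: str
    product_length: int
    tm: dict[str, float]
    gc: dict[str, float]
    flank_copies: int
    tail_sequences: tuple[str, str] | None = None

    def validate(self, constraints: KaspConstraints | None = None) -> None:
        c = constraints or KaspConstraints()
        f1, f2 = self.forward_primers
        if len(f1) != len(f2) or f1[:-1] != f2[:-1] or f1[-1] == f2[-1]:
            raise ValueError("forward primers must differ only at the 3' base")
        if (f1[-1], f2[-1]) != self.alleles:
            raise ValueError("forward primer 3' bases must be the SNP alleles")
        for p in (f1, f2, self.common_primer):
            if not c.primer_len_min <= len(p) <= c.primer_len_max:
                raise ValueError(f"primer length {len(p)} outside window")
        for tm in self.tm.values():
            if not c.tm_min <= tm <= c.tm_max:
                raise ValueError(f"Tm {tm:.2f} outside window")
        if not c.product_min <= self.product_length <= c.product_max:
            raise ValueError(f"product {self.product_length} outside window")
        if self.flank_copies > c.max_flank_copies:
            raise ValueError(f"flank occurs {self.flank_copies} times")

    def tailed_primers(self) -> tuple[str, str]:
        """Forward primers with the optional fluorophore tails prepended
        (tails are excluded from Tm/GC checks)."""
        if self.tail_sequences is None:
            return self.forward_primers
        return (
            self.tail_sequences[0] + self.forward_primers[0],
            self.tail_sequences[1] + self.forward_primers[1],
        )


@dataclass
class DesignFailure:
    """Returned when no primer set satisfies the constraints."""

    snp_id: str
    reasons: list[str]


def design_kasp(
    flank: str,
    alleles: tuple[str, str],
    genome: dict[str, str] | None = None,
    constraints: KaspConstraints | None = None,
    snp_id: str = "snp",
    tails: tuple[str, str] | None = None,
) -> KaspAssay | DesignFailure:
    """Design a KASP assay for the SNP at the center of *flank*.

    *flank* is the reference sequence with the SNP base at its center
    (equal-length arms, e.g. 150 bp each side). All (forward length,
    reverse position, reverse length) combinations in the constraint
    window are enumerated; among feasible sets the one minimizing the Tm
    spread across the three primers is returned, ties broken by shortest
    product then by primer geometry, so the design is deterministic.
    """
    c = constraints or KaspConstraints()
    if len(flank) % 2 == 0:
        return DesignFailure(snp_id, ["flank must have odd length (SNP at center)"])
    center = len(flank) // 2
    reasons: set[str] = set()

    flank_gc = gc_fraction(flank)
    if not c.flank_gc_min <= flank_gc <= c.flank_gc_max:
        reasons.add(f"flank GC {flank_gc:.2f} outside {c.flank_gc_min}-{c.flank_gc_max}")
    copies = count_flank_copies(flank, genome) if genome else 1
    if copies > c.max_flank_copies:
        reasons.add(f"flank copy count {copies} >= 3")
    if reasons:
        return DesignFailure(snp_id, sorted(reasons))

    def primer_ok(seq: str) -> tuple[float, float] | None:
        tm = melting_temperature(seq, c.salt_mM, c.primer_nM)
        gc = gc_fraction(seq)
        if not c.tm_min <= tm <= c.tm_max:
            reasons.add("no primer within the Tm window")
            return None
        if c.check_primer_gc and not c.primer_gc_min <= gc <= c.primer_gc_max:
            reasons.add("no primer within the GC window")
            return None
        return tm, gc

    # forward candidates: end exactly at the SNP, 3' base = allele
    fwd: list[tuple[int, str, str, float, float, float, float]] = []
    for length in range(c.primer_len_min, c.primer_len_max + 1):
        if length - 1 > center:
            break
        stem = flank[center - length + 1 : center]
        p1, p2 = stem + alleles[0], stem + alleles[1]
        r1 = primer_ok(p1)
        r2 = primer_ok(p2)
        if r1 and r2:
            fwd.append((length, p1, p2, r1[0], r1[1], r2[0], r2[1]))
    if not fwd:
        reasons.add("no feasible allele-specific forward primer")
        return DesignFailure(snp_id, sorted(reasons))

    # reverse candidates: top-strand span [j, j+rl-1] downstream of the SNP
    rev_cache: dict[tuple[int, int], tuple[str, float, float] | None] = {}

    def rev_candidate(j: int, rl: int) -> tuple[str, float, float] | None:
        key = (j, rl)
        if key not in rev_cache:
            if j + rl > len(flank):
                rev_cache[key] = None
            else:
                seq = revcomp(flank[j : j + rl])
                r = primer_ok(seq)
                rev_cache[key] = (seq, r[0], r[1]) if r else None
        return rev_cache[key]

    best = None
    for length, p1, p2, tm1, gc1, tm2, gc2 in fwd:
        fwd_start = center - length + 1
        for product in range(c.product_min, c.product_max + 1):
            rev_end = fwd_start + product - 1  # top-strand 3' boundary
            for rl in range(c.primer_len_min, c.primer_len_max + 1):
                j = rev_end - rl + 1
                if j <= center:
                    continue
                cand = rev_candidate(j, rl)
                if cand is None:
                    continue
                seq, tmr, gcr = cand
                tms = (tm1, tm2, tmr)
                key = (max(tms) - min(tms), product, length, rl, j)
                if best is None or key < best[0]:
                    best = (
                        key,
                        KaspAssay(
                            snp_id=snp_id,
                            alleles=alleles,
                            forward_primers=(p1, p2),
                            common_primer=seq,
                            product_length=product,
                            tm={"fwd_allele1": tm1, "fwd_allele2": tm2, "common": tmr},
                            gc={"fwd_allele1": gc1, "fwd_allele2": gc2, "common": gcr},
                            flank_copies=copies,
                            tail_sequences=tails,
                        ),
                    )
    if best is None:
        reasons.add("no feasible forward/reverse combination in the product window")
        return DesignFailure(snp_id, sorted(reasons))
    return best[1]


def random_feasible_flank(
    rng: np.random.Generator, arm: int = 150
) -> str:
    """Random flank that is design-feasible by construction.

    Every adjacent base pair holds one A/T and one G/C base in random
    order, so every primer-sized window sits near 50% GC and the Tm ladder
    over lengths 19-30 crosses the 59-65 °C window.
    """
    at = np.array(list("AT"))
    gc = np.array(list("CG"))
    n = 2 * arm + 2
    out: list[str] = []
    for _ in range(n // 2):
        a = at[rng.integers(2)]
        g = gc[rng.integers(2)]
        out.extend((a, g) if rng.random() < 0.5 else (g, a))
    return "".join(out[: 2 * arm + 1])


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------

CALL_ALLELE1 = "allele1_hom"
CALL_ALLELE2 = "allele2_hom"
CALL_HET = "het"
CALL_NTC = "NTC"
CALL_UNDETERMINED = "undetermined"


@dataclass
class GenotypeCall:
    sample_id: str
    call: str
    fam: float
    hex: float

    @property
    def ratio(self) -> float:
        total = self.fam + self.hex
        return self.fam / total if total > 0 else float("nan")


def call_genotypes(
    readings: pd.DataFrame,
    ntc_floor: float = 0.2,
    min_separation: float = 0.1,
    seed: int = 0,
) -> list[GenotypeCall]:
    """Cluster two-channel fluorescence into genotype calls.

    Samples with total signal below *ntc_floor* are no-template controls;
    the rest are k-means clustered (k=3, seeded) on the normalized FAM
    ratio and mapped by cluster-center order: FAM-dominant -> allele-1
    homozygote, HEX-dominant -> allele-2 homozygote, intermediate ->
    heterozygote. If any two centers are closer than *min_separation*,
    the clusters are not distinguishable and every non-NTC sample is
    called undetermined (with a warning).
    """
    from sklearn.cluster import KMeans

    required = {"sample_id", "fam", "hex"}
    if not required <= set(readings.columns):
        raise ValueError(f"readings must have columns {sorted(required)}")
    total = readings["fam"] + readings["hex"]
    is_ntc = (total < ntc_floor).to_numpy()
    active = readings.loc[~is_ntc]
    if len(active) < 6:
        raise ValueError(f"need >= 6 non-NTC samples, got {len(active)}")
    ratio = (active["fam"] / (active["fam"] + active["hex"])).to_numpy()
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(ratio.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(-centers)  # FAM-dominant first
    sorted_centers = centers[order]
    distinguishable = np.min(-np.diff(sorted_centers)) >= min_separation
    if not distinguishable:
        logger.warning(
            "genotype clusters not separable (centers %s); calls undetermined",
            np.round(sorted_centers, 3),
        )
    label_map = {
        int(order[0]): CALL_ALLELE1,
        int(order[1]): CALL_HET,
        int(order[2]): CALL_ALLELE2,
    }
    calls: list[GenotypeCall] = []
    active_iter = iter(zip(active.itertuples(index=False), km.labels_))
    for row, ntc in zip(readings.itertuples(index=False), is_ntc):
        if ntc:
            calls.append(GenotypeCall(row.sample_id, CALL_NTC, row.fam, row.hex))
            continue
        _, lab = next(active_iter)
        call = label_map[int(lab)] if distinguishable else CALL_UNDETERMINED
        calls.append(GenotypeCall(row.sample_id, call, row.fam, row.hex))
    return calls


def simulate_fluorescence(
    genotype_calls: list[str],
    rng: np.random.Generator | None = None,
    separation: float = 1.0,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Synthetic endpoint fluorescence for known genotype labels.

    Cluster means: allele-1 homozygote (FAM-high), allele-2 homozygote
    (HEX-high), heterozygote (both mid); *noise_sd* is the Gaussian scatter
    as a fraction of *separation*. NTC samples sit at the origin.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    centers = {
        CALL_ALLELE1: (1.0, 0.12),
        CALL_ALLELE2: (0.12, 1.0),
        CALL_HET: (0.62, 0.62),
        CALL_NTC: (0.02, 0.02),
    }
    rows = []
    for i, g in enumerate(genotype_calls):
        cx, cy = centers[g]
        fam = cx * separation + rng.normal(0, noise_sd * separation)
        hx = cy * separation + rng.normal(0, noise_sd * separation)
        rows.append((f"S{i:03d}", max(fam, 0.0), max(hx, 0.0)))
    return pd.DataFrame(rows, columns=["sample_id", "fam", "hex"])


# ---------------------------------------------------------------------------
# Association and phenotype summaries
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    t_statistic: float | None
    p_value: float | None
    group_means: dict[str, float]
    group_ns: dict[str, int]
    skipped: bool = False
    note: str = ""


def association_test(
    calls: list[GenotypeCall], phenotypes: pd.DataFrame
) -> AssociationResult:
    """Student's t-test of the trait between the two homozygote classes.

    Heterozygotes are summarized (mean, n) but excluded from the test.
    *phenotypes* must map sample_id to spike_length_cm. If either
    homozygote class has fewer than 2 phenotyped samples the test is
    skipped with a notice.
    """
    pheno = phenotypes.set_index("plant_id")["spike_length_cm"]
    groups: dict[str, list[float]] = {CALL_ALLELE1: [], CALL_ALLELE2: [], CALL_HET: []}
    for call in calls:
        if call.call in groups and call.sample_id in pheno.index:
            groups[call.call].append(float(pheno[call.sample_id]))
    means = {k: (float(np.mean(v)) if v else float("nan")) for k, v in groups.items()}
    ns = {k: len(v) for k, v in groups.items()}
    if ns[CALL_ALLELE1] < 2 or ns[CALL_ALLELE2] < 2:
        return AssociationResult(
            None, None, means, ns, skipped=True,
            note="a homozygote class has < 2 phenotyped samples",
        )
    t, p = stats.ttest_ind(groups[CALL_ALLELE1], groups[CALL_ALLELE2], equal_var=True)
    return AssociationResult(float(t), float(p), means, ns)


def phenotype_summary(
    groups: dict[str, np.ndarray | list[float]],
    baseline: str | None = None,
    normality_group: str | None = None,
) -> dict:
    """Per-group summary with pairwise Student's t-tests.

    Returns a dict with a per-group table (mean, SD, n), percent change of
    every group against *baseline* ((mean_g - mean_b)/mean_b * 100),
    pairwise t-tests, and a Shapiro-Wilk normality check for
    *normality_group* (e.g. the F2 distribution) when requested.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    table = pd.DataFrame(
        {
            "mean": {k: v.mean() for k, v in arrays.items()},
            "sd": {k: v.std(ddof=1) if len(v) > 1 else np.nan for k, v in arrays.items()},
            "n": {k: len(v) for k, v in arrays.items()},
        }
    )
    result: dict = {"groups": table}
    if baseline is not None:
        base_mean = arrays[baseline].mean()
        result["percent_change"] = {
            k: (v.mean() - base_mean) / base_mean * 100.0
            for k, v in arrays.items()
            if k != baseline
        }
    tests = {}
    keys = list(arrays)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if len(arrays[a]) >= 2 and len(arrays[b]) >= 2:
                t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=True)
                tests[(a, b)] = {"t": float(t), "p": float(p)}
    result["t_tests"] = tests
    if normality_group is not None:
        v = arrays[normality_group]
        if len(v) >= 3:
            w, p = stats.shapiro(v)
            result["normality"] = {"group": normality_group, "W": float(w), "p": float(p)}
    return result
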