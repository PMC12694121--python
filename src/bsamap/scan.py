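"""Per-site association statistics and candidate-region calling.

Two complementary scans over the filtered sites:

* **SNP-index**: per pool, the fraction of reads carrying one designated
  parent's allele, ``M/(M+P)``; the contrast between pools is
  Δ(SNP-index) = index(long pool) − index(short pool). Δ is averaged in
  fixed grid windows along each chromosome and windows above a threshold
  are merged into candidate regions.
* **Euclidean distance (ED)**: per site, the Euclidean distance between the
  two pools' base-frequency quadruples, √Σ_b (f_mut,b − f_wt,b)²; raw ED is
  smoothed by tricube local linear regression along each chromosome and the
  genome-wide threshold is median + k·SD of the fitted values.

Sign convention: with the default orientation (``index_parent="wt"``) M is
the wild-type parent's allele, so a locus fixed in the short pool drives Δ
negative. Region calling is therefore two-sided on |windowed Δ|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError
from .regions import CandidateRegion, GenomicInterval
from .variant_io import (
    BASE_INDEX,
    PooledVariantRecord,
    ROLE_POOL_LONG,
    ROLE_POOL_SHORT,
    ROLE_WT_PARENT,
)

logger = logging.getLogger(__name__)

ED_MAX = math.sqrt(2.0)


@dataclass
class ScanPoint:
    """Per-site association values (also the scan table's row schema)."""

    chrom: str
    pos: int
    index_aa: float  # long pool
    index_ab: float  # short pool
    delta: float
    ed: float
    maf_mut: float
    fitted_ed: float = float("nan")


@dataclass
class ScanConfig:
    """Thresholds and smoothing parameters of both scan methods.

    delta_threshold
        Absolute threshold on |windowed mean Δ| (``delta_mode="absolute"``).
    delta_mode
        ``"absolute"`` or ``"quantile"`` — the latter derives per-window
        thresholds from a simulated no-QTL null (F2 pooling + depth noise)
        at ``null_quantile``; appropriate when dominance caps |Δ| below any
        fixed threshold near 1.
    offspring_index_floor / index_floor_mode
        Drop sites whose SNP-index is below the floor in both pools
        (``"both"``) or in at least one pool (``"any"``).
    ed_power, ed_span
        Exponent applied to raw ED before smoothing, and the local
        regression span (fraction of the chromosome's sites per window).
    ed_k
        Threshold = median + ed_k * SD (population SD) of fitted values.
    """

    delta_threshold: float = 0.95
    delta_mode: str = "absolute"
    offspring_index_floor: float = 0.30
    index_floor_mode: str = "both"
    index_parent: str = "wt"  # which parent's allele is M in M/(M+P)
    ed_power: float = 1.0
    ed_span: float = 0.1
    ed_k: float = 3.0
    delta_window_bp: int = 500_000
    delta_step_bp: int = 500_000
    min_markers_per_window: int = 3
    max_gap_bp: int = 1_000_000
    maf_min: float = 0.75
    ed_min: float = 0.50
    null_quantile: float = 0.995
    null_reps: int = 200
    null_pool_size: int = 30
    null_depth: float = 50.0
    null_cM_per_Mb: float = 0.0  # >0: linkage-aware null (markers correlated)

    def __post_init__(self) -> None:
        if not 0 <= self.offspring_index_floor <= 1:
            raise ConfigurationError("offspring_index_floor must be in [0, 1]")
        if self.delta_mode not in ("absolute", "quantile"):
            raise ConfigurationError("delta_mode must be 'absolute' or 'quantile'")
        if self.index_floor_mode not in ("both", "any"):
            raise ConfigurationError("index_floor_mode must be 'both' or 'any'")
        if self.index_parent not in ("wt", "mut"):
            raise ConfigurationError("index_parent must be 'wt' or 'mut'")
        if not 0 < self.ed_span <= 1:
            raise ConfigurationError("ed_span must be in (0, 1]")
        if self.delta_window_bp <= 0 or self.delta_step_bp <= 0:
            raise ConfigurationError("window/step must be positive")


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def parent_alleles(
    record: PooledVariantRecord, index_parent: str = "wt"
) -> tuple[str, str]:
    """(M, P) alleles for the SNP-index: M belongs to *index_parent*.

    Alleles are inferred from the parents' majority reads, so orientation
    is robust to how ref/alt were assigned upstream.
    """
    wt_ref = record.allele_depth(ROLE_WT_PARENT, "ref") >= record.allele_depth(
        ROLE_WT_PARENT, "alt"
    )
    wt_allele = "ref" if wt_ref else "alt"
    mut_allele = "alt" if wt_ref else "ref"
    if index_parent == "wt":
        return wt_allele, mut_allele
    return mut_allele, wt_allele


def snp_index(
    record: PooledVariantRecord, pool: str, index_parent: str = "wt"
) -> float | None:
    """SNP-index of *pool*: M/(M+P) with M reads carrying the designated
    parent's allele. Reads matching neither parental allele are excluded.
    Returns None (undefined) when M + P = 0.
    """
    m_allele, p_allele = parent_alleles(record, index_parent)
    m = record.allele_depth(pool, m_allele)
    p = record.allele_depth(pool, p_allele)
    if m + p == 0:
        return None
    return m / (m + p)


def delta_snp_index(
    record: PooledVariantRecord, index_parent: str = "wt"
) -> float | None:
    """Δ(SNP-index) = index(long pool) − index(short pool); None if either
    pool's index is undefined."""
    aa = snp_index(record, ROLE_POOL_LONG, index_parent)
    ab = snp_index(record, ROLE_POOL_SHORT, index_parent)
    if aa is None or ab is None:
        return None
    return aa - ab


def euclidean_distance(freqs_mut: np.ndarray, freqs_wt: np.ndarray) -> float:
    """ED between two base-frequency quadruples (each must sum to 1)."""
    fm = np.asarray(freqs_mut, dtype=float)
    fw = np.asarray(freqs_wt, dtype=float)
    for f in (fm, fw):
        if f.min() < 0 or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequency quadruple not normalized: {f}")
    return float(np.sqrt(np.sum((fm - fw) ** 2)))


def _pool_freqs(record: PooledVariantRecord, role: str) -> np.ndarray | None:
    q = record.quadruple(role)
    total = q.sum()
    if total == 0:
        return None
    return q / total


def compute_scan_points(
    records: list[PooledVariantRecord], cfg: ScanConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Per-site scan table (chrom, pos, index_aa, index_ab, delta, ed,
    maf_mut) plus the count of sites dropped for undefined statistics."""
    cfg = cfg or ScanConfig()
    rows = []
    dropped = 0
    for rec in records:
        aa = snp_index(rec, ROLE_POOL_LONG, cfg.index_parent)
        ab = snp_index(rec, ROLE_POOL_SHORT, cfg.index_parent)
        f_mut = _pool_freqs(rec, ROLE_POOL_LONG)
        f_wt = _pool_freqs(rec, ROLE_POOL_SHORT)
        if aa is None or ab is None or f_mut is None or f_wt is None:
            dropped += 1
            continue
        rows.append(
            (
                rec.chrom,
                rec.pos,
                aa,
                ab,
                aa - ab,
                euclidean_distance(f_mut, f_wt),
                float(f_mut.max()),
            )
        )
    if dropped:
        logger.info("dropped %d sites with undefined pool statistics", dropped)
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "index_aa", "index_ab", "delta", "ed", "maf_mut"]
    )
    return df.sort_values(["chrom", "pos"], ignore_index=True), dropped


def filter_offspring_index(
    points: pd.DataFrame, floor: float = 0.30, mode: str = "both"
) -> tuple[pd.DataFrame, int]:
    """Remove low-index sites before association.

    ``mode="both"`` drops a site only when its index is below *floor* in
    both pools (uninformative everywhere); ``"any"`` drops when either pool
    is below the floor.
    """
    below_aa = points["index_aa"] < floor
    below_ab = points["index_ab"] < floor
    drop = (below_aa & below_ab) if mode == "both" else (below_aa | below_ab)
    kept = points.loc[~drop].reset_index(drop=True)
    return kept, int(drop.sum())


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def fit_ed(
    points: pd.DataFrame, power: float = 1.0, span: float = 0.1
) -> pd.DataFrame:
    """Add a ``fitted_ed`` column: tricube local linear regression of
    ED**power on position, per chromosome.

    Chromosomes with fewer than 2 sites are skipped (fitted value NaN).
    """
    out = points.copy()
    out["fitted_ed"] = np.nan
    for chrom, sub in out.groupby("chrom", sort=False):
        if len(sub) < 2:
            logger.warning("chromosome %s has <2 sites; ED fit skipped", chrom)
            continue
        y = sub["ed"].to_numpy() ** power
        x = sub["pos"].to_numpy(dtype=float)
        fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
        out.loc[sub.index, "fitted_ed"] = fitted
    return out


def ed_threshold(fitted_values: np.ndarray, k: float = 3.0) -> float:
    """median + k * SD of the fitted values (population SD, NaNs ignored)."""
    v = np.asarray(fitted_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no fitted values")
    return float(np.median(v) + k * np.std(v))


def smooth_delta(
    points: pd.DataFrame,
    window_bp: int = 500_000,
    step_bp: int = 500_000,
    min_markers: int = 3,
) -> pd.DataFrame:
    """Mean Δ per fixed grid window.

    Windows start at multiples of *step_bp* plus 1 and are reported as the
    closed interval [k*step+1, k*step+window+1] so that merged runs of
    adjacent windows land on the round published-style boundaries. Windows
    with fewer than *min_markers* markers have mean_delta masked (NaN).
    """
    rows = []
    for chrom, sub in points.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        if len(pos) == 0:
            continue
        k_max = int((pos.max() - 1) // step_bp)
        for k in range(0, k_max + 1):
            start = k * step_bp + 1
            in_win = (pos >= start) & (pos < start + window_bp)
            n = int(in_win.sum())
            mean = float(delta[in_win].mean()) if n >= min_markers else np.nan
            rows.append((chrom, start, start + window_bp, n, mean))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_markers", "mean_delta"]
    )


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

def call_regions(
    intervals: pd.DataFrame,
    values: np.ndarray,
    threshold: float,
    max_gap_bp: int = 1_000_000,
    source: str = "scan",
) -> list[CandidateRegion]:
    """Merge above-threshold items into candidate regions.

    *intervals* must hold sorted chrom/start/end rows (for single sites,
    start == end == pos); items with value > threshold are kept and runs
    separated by at most *max_gap_bp* are merged. The supporting-marker
    count of a region is the number of above-threshold markers it absorbs
    (window rows contribute their ``n_markers``).
    """
    values = np.asarray(values, dtype=float)
    above = values > threshold
    regions: list[CandidateRegion] = []
    cur: dict | None = None
    weights = (
        intervals["n_markers"].to_numpy()
        if "n_markers" in intervals.columns
        else np.ones(len(intervals), dtype=int)
    )
    for i in range(len(intervals)):
        if not above[i] or np.isnan(values[i]):
            continue
        chrom = intervals["chrom"].iat[i]
        start = int(intervals["start"].iat[i])
        end = int(intervals["end"].iat[i])
        w = int(weights[i])
        if cur is not None and cur["chrom"] == chrom and start - cur["end"] - 1 <= max_gap_bp:
            cur["end"] = max(cur["end"], end)
            cur["n"] += w
        else:
            if cur is not None:
                regions.append(_close_region(cur, source))
            cur = {"chrom": chrom, "start": start, "end": end, "n": w}
    if cur is not None:
        regions.append(_close_region(cur, source))
    return regions


def _close_region(cur: dict, source: str) -> CandidateRegion:
    return CandidateRegion(
        interval=GenomicInterval(cur["chrom"], cur["start"], cur["end"]),
        source=source,
        n_markers=cur["n"],
    )


def _null_pool_freqs(
    rng: np.random.Generator,
    reps: int,
    n_gametes: int,
    n_markers: int,
    r_adj: float,
) -> np.ndarray:
    """(reps, n_markers) no-QTL pool allele frequencies.

    Each pooled plant contributes two F1 gametes; markers along the window
    are a Markov chain with per-interval recombination fraction *r_adj*
    (r_adj = 0.5 reproduces the unlinked case).
    """
    first = rng.random((reps, n_gametes)) < 0.5
    if n_markers == 1:
        gam = first[:, :, None]
    else:
        switches = rng.random((reps, n_gametes, n_markers - 1)) < r_adj
        flips = np.cumsum(switches, axis=2) % 2 == 1
        gam = np.concatenate(
            [first[:, :, None], first[:, :, None] ^ flips], axis=2
        )
    return gam.mean(axis=1)


@lru_cache(maxsize=256)
def _null_delta_quantile_cached(
    n_markers: int,
    pool_size: int,
    depth: float,
    quantile: float,
    reps: int,
    r_adj: float,
    seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    pools = []
    for _ in range(2):
        p = _null_pool_freqs(rng, reps, 2 * pool_size, n_markers, r_adj)
        d = np.maximum(rng.poisson(depth, size=p.shape), 1)
        pools.append(rng.binomial(d, p) / d)
    means = np.abs((pools[0] - pools[1]).mean(axis=1))
    return float(np.quantile(means, quantile))


def null_delta_quantile(
    n_markers: int, cfg: ScanConfig, seed: int = 0
) -> float:
    """|window-mean Δ| null quantile for a window of *n_markers* markers,
    from a simulated no-QTL F2 (pool sampling + depth noise).

    With ``cfg.null_cM_per_Mb > 0`` the null markers are linked at the
    window's genetic density (evenly spaced over the window), which widens
    the window-mean distribution relative to the independent-marker null —
    physically adjacent markers share the same pooled plants.
    """
    if n_markers <= 0:
        return np.inf
    if cfg.null_cM_per_Mb > 0:
        span_cM = cfg.delta_window_bp / 1e6 * cfg.null_cM_per_Mb
        d_morgan = span_cM / max(n_markers - 1, 1) / 100.0
        r_adj = 0.5 * (1.0 - math.exp(-2.0 * d_morgan))
    else:
        r_adj = 0.5
    return _null_delta_quantile_cached(
        n_markers,
        cfg.null_pool_size,
        cfg.null_depth,
        cfg.null_quantile,
        cfg.null_reps,
        round(r_adj, 4),
        seed,
    )


def delta_regions(
    windows: pd.DataFrame, cfg: ScanConfig | None = None, seed: int = 0
) -> list[CandidateRegion]:
    """Call Δ(SNP-index) candidate regions from the windowed scan.

    Thresholding is two-sided on |mean Δ|: absolute mode uses
    ``cfg.delta_threshold``; quantile mode uses a per-window null quantile.
    """
    cfg = cfg or ScanConfig()
    vals = windows["mean_delta"].abs().to_numpy()
    if cfg.delta_mode == "absolute":
        return call_regions(windows, vals, cfg.delta_threshold, cfg.max_gap_bp, "snp_index")
    thresholds = np.array(
        [null_delta_quantile(int(n), cfg, seed) for n in windows["n_markers"]]
    )
    shifted = vals - thresholds
    return call_regions(windows, shifted, 0.0, cfg.max_gap_bp, "snp_index")


def ed_regions(
    points: pd.DataFrame, cfg: ScanConfig | None = None
) -> tuple[list[CandidateRegion], float]:
    """Call ED candidate regions: sites whose fitted ED exceeds the
    genome-wide median + k*SD threshold, merged over gaps. Returns the
    regions and the threshold used."""
    cfg = cfg or ScanConfig()
    if "fitted_ed" not in points.columns:
        points = fit_ed(points, cfg.ed_power, cfg.ed_span)
    thr = ed_threshold(points["fitted_ed"].to_numpy(), cfg.ed_k)
    site_iv = pd.DataFrame(
        {"chrom": points["chrom"], "start": points["pos"], "end": points["pos"]}
    )
    regions = call_regions(
        site_iv, points["fitted_ed"].to_numpy(), thr, cfg.max_gap_bp, "ed"
    )
    return regions, thr


def select_candidate_snps(
    points: pd.DataFrame,
    regions: list[CandidateRegion],
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Candidate SNPs inside *regions*: main-allele frequency of the mutant
    pool above ``maf_min`` and raw ED above ``ed_min`` (both strict)."""
    cfg = cfg or ScanConfig()
    in_region = np.zeros(len(points), dtype=bool)
    for reg in regions:
        iv = reg.interval
        in_region |= (
            (points["chrom"] == iv.chrom)
            & (points["pos"] >= iv.start)
            & (points["pos"] <= iv.end)
        ).to_numpy()
    sel = in_region & (points["maf_mut"] > cfg.maf_min).to_numpy() & (
        points["ed"] > cfg.ed_min
    ).to_numpy()
    return points.loc[sel].reset_index(drop=True)
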