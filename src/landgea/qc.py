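"""Variant- and individual-level quality control.

Implements the filtering cascade of a hard-filtered resequencing
dataset: depth-mode cutoffs (25% below to 50% above the modal depth),
missingness, biallelic, minor-allele-frequency and Hardy-Weinberg
filters, LD pruning in variant-count windows, and heterozygosity /
missingness outlier removal at the individual level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# depth rule
# ---------------------------------------------------------------------------

def depth_mode_cutoffs(dp, bin_width: float = 0.1):
    """Depth cutoffs from 25% below to 50% above the modal depth.

    The mode is the midpoint of the highest-count bin of a fixed-width
    histogram (bins centered on multiples of ``bin_width``); ties go to
    the lowest bin.  Both cutoffs are rounded to one decimal.

    Returns
    -------
    (low, high) : tuple of float
        ``0.75 * mode`` and ``1.5 * mode``.
    """
    dp = np.asarray(dp, dtype=float)
    dp = dp[np.isfinite(dp)]
    if dp.size == 0:
        raise ValueError("no finite depth values")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    w = bin_width
    first = np.floor(dp.min() / w) * w - w / 2.0
    edges = np.arange(first, dp.max() + w, w)
    counts, edges = np.histogram(dp, bins=edges)
    mode = edges[int(np.argmax(counts))] + w / 2.0
    mode = round(mode, 10)  # kill float fuzz from the edge arithmetic
    return round(0.75 * mode, 1), round(1.5 * mode, 1)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Sums the probabilities of all heterozygote counts (given the fixed
    allele counts) whose probability does not exceed that of the
    observed configuration.  Monomorphic sites return 1.0.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("empty genotype counts")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0

    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)  # feasible het counts, same parity
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        + hets * np.log(2.0)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[np.flatnonzero(hets == n_het)[0]]
    p = float(prob[prob <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# variant filter cascade
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Ordered per-filter removal counts plus thresholds used."""

    steps: list = field(default_factory=list)  # (name, n_removed, threshold)
    n_input: int = 0
    n_output: int = 0

    def add(self, name: str, n_removed: int, threshold) -> None:
        self.steps.append({"step": name, "n_removed": int(n_removed),
                           "threshold": threshold})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def filter_variants(
    gm: GenotypeMatrix,
    dp=None,
    maf_min: float = 0.01,
    max_missing: float = 0.10,
    hwe_min_p: float = 1e-8,
    dp_rule=None,
    site_pass_mask=None,
):
    """Apply the variant filter cascade in fixed order.

    Order: (optional caller-annotation mask) -> depth -> missingness ->
    biallelic -> MAF -> HWE.  ``dp_rule`` may be an explicit
    ``(low, high)`` pair; if ``None`` and ``dp`` is given, the cutoffs
    come from :func:`depth_mode_cutoffs`.

    Returns
    -------
    (gm_filtered, report) : (GenotypeMatrix, QCReport)
    """
    report = QCReport(n_input=gm.n_variants)
    keep = np.ones(gm.n_variants, dtype=bool)

    if site_pass_mask is not None:
        site_pass_mask = np.asarray(site_pass_mask, dtype=bool)
        if site_pass_mask.size != gm.n_variants:
            raise ValueError("site_pass_mask length mismatch")
        removed = keep & ~site_pass_mask
        keep &= site_pass_mask
        report.add("caller_mask", removed.sum(), None)

    if dp is not None:
        dp = np.asarray(dp, dtype=float)
        if dp.size != gm.n_variants:
            raise ValueError("dp vector not aligned to variants")
        low, high = dp_rule if dp_rule is not None else depth_mode_cutoffs(dp[keep])
        bad = (dp < low) | (dp > high)
        removed = keep & bad
        keep &= ~bad
        report.add("depth", removed.sum(), (low, high))
    else:
        report.add("depth", 0, None)

    g = gm.genotypes
    called = g != MISSING
    miss_frac = 1.0 - called.mean(axis=0)
    bad = miss_frac > max_missing
    removed = keep & bad
    keep &= ~bad
    report.add("missingness", removed.sum(), max_missing)

    # matrices are biallelic by construction; flag any multi-allelic ALT field
    multi = gm.variants["alt"].astype(str).str.contains(",").to_numpy()
    removed = keep & multi
    keep &= ~multi
    report.add("biallelic", removed.sum(), None)

    n_called = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    bad = ~(maf >= maf_min)  # NaN (no calls) also removed here
    removed = keep & bad
    keep &= ~bad
    report.add("maf", removed.sum(), maf_min)

    hwe_bad = np.zeros(gm.n_variants, dtype=bool)
    for j in np.flatnonzero(keep):
        col = g[:, j]
        col = col[col != MISSING]
        n_het = int((col == 1).sum())
        p = hwe_exact_test(int((col == 0).sum()), n_het, int((col == 2).sum()))
        hwe_bad[j] = p < hwe_min_p
    removed = keep & hwe_bad
    keep &= ~hwe_bad
    report.add("hwe", removed.sum(), hwe_min_p)

    out = gm.subset(var_idx=np.flatnonzero(keep))
    report.n_output = out.n_variants
    return out, report


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(g_i, g_j) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are pairwise-deleted; returns NaN if either vector
    is monomorphic among complete pairs.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ok = (g_i != MISSING) & (g_j != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 complete pairs")
    x, y = g_i[ok], g_j[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(min(r * r, 1.0))


def _window_r2(block: np.ndarray) -> np.ndarray:
    """Pairwise r^2 within a dosage block (n x w), missing pairwise-deleted."""
    masked = np.ma.masked_equal(block.astype(float), MISSING)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.ma.corrcoef(masked.T)
    r2 = np.asarray(corr.filled(np.nan)) ** 2
    np.fill_diagonal(r2, np.nan)
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    window_size_variants: int = 50,
    step: int = 25,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Sliding-window LD pruning in variant-count units, per chromosome.

    Within each window, the pair with the highest r^2 above ``r2_max``
    is broken by removing the member with the higher missing rate
    (ties: the later position).  Windows advance by ``step``; removal is
    permanent.

    Returns the sorted array of retained variant indices.
    """
    g = gm.genotypes
    miss_rate = (g == MISSING).mean(axis=0)
    removed = np.zeros(gm.n_variants, dtype=bool)
    chroms = gm.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx_all = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx_all), step):
            win = idx_all[start: start + window_size_variants]
            alive = win[~removed[win]]
            if alive.size < 2:
                if start + window_size_variants >= len(idx_all):
                    break
                continue
            r2 = _window_r2(g[:, alive])
            while True:
                with np.errstate(invalid="ignore"):
                    over = np.nan_to_num(r2, nan=0.0) > r2_max
                if not over.any():
                    break
                flat = np.nanargmax(np.where(over, r2, -1.0))
                a, b = np.unravel_index(flat, r2.shape)
                va, vb = alive[a], alive[b]
                if miss_rate[va] > miss_rate[vb]:
                    victim = a
                elif miss_rate[vb] > miss_rate[va]:
                    victim = b
                else:
                    victim = a if va > vb else b  # later position loses
                removed[alive[victim]] = True
                r2[victim, :] = np.nan
                r2[:, victim] = np.nan
            if start + window_size_variants >= len(idx_all):
                break
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# individual-level outliers
# ---------------------------------------------------------------------------

def het_missing_outliers(
    gm: GenotypeMatrix, sd_mult: float = 3.0, miss_max: float = 0.5
) -> list:
    """Individuals failing missingness or heterozygosity outlier checks.

    First removes individuals with per-individual missing fraction above
    ``miss_max``; then, among the remainder, individuals whose observed
    heterozygosity deviates more than ``sd_mult`` standard deviations
    from the mean.  Zero SD means no heterozygosity outliers.

    Returns the list of ``ind_id`` to remove.
    """
    if gm.n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    g = gm.genotypes
    called = g != MISSING
    miss_frac = 1.0 - called.mean(axis=1)
    ids = gm.individuals["ind_id"].to_numpy()
    out = list(ids[miss_frac > miss_max])

    survivors = np.flatnonzero(miss_frac <= miss_max)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = (g[survivors] == 1).sum(axis=1) / called[survivors].sum(axis=1)
    mean, sd = np.nanmean(het), np.nanstd(het)
    if sd > 0:
        z = np.abs(het - mean) / sd
        out.extend(ids[survivors[z > sd_mult]])
    return out
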