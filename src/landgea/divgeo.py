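"""Windowed diversity and differentiation statistics, distance matrices,
and Mantel / partial Mantel inference for isolation-by-distance and
isolation-by-environment.

Windows are half-open ``[1 + k*w, 1 + (k+1)*w)`` on 1-based positions.
Weir & Cockerham (1984) variance components are used for FST; windowed
and global estimates are the weighted ratio ``sum(a) / sum(a+b+c)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, DistanceMatrix, GenotypeMatrix


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def windowed_pi(gm: GenotypeMatrix, ind_idx=None, window: int = 10000) -> pd.DataFrame:
    """Nucleotide diversity in non-overlapping windows.

    Per site, ``pi = n_ref * n_alt / C(n, 2)`` over the called allele
    count ``n``; window value is the per-site sum divided by the window
    length, so monomorphic and missing positions contribute zero (the
    estimate is a lower bound where missingness is heavy).

    Returns a DataFrame ``chrom, start, end, pi, n_variants`` covering
    every window from position 1 to the last variant of each chromosome.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    sub = gm if ind_idx is None else gm.subset(ind_idx=ind_idx)
    g = sub.genotypes
    called = g != MISSING
    n = 2.0 * called.sum(axis=0)
    n_alt = np.where(called, g, 0).sum(axis=0)
    n_ref = n - n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = 2.0 * n_ref * n_alt / (n * (n - 1.0))
    pi_site = np.where(n >= 2, pi_site, 0.0)

    chroms = sub.variants["chrom"].to_numpy()
    pos = sub.variants["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        widx = (pos[sel] - 1) // window
        sums = pd.Series(pi_site[sel]).groupby(widx).sum()
        counts = pd.Series(pi_site[sel]).groupby(widx).size()
        for k in range(int(widx.max()) + 1):
            rows.append((chrom, 1 + k * window, 1 + (k + 1) * window,
                         float(sums.get(k, 0.0)) / window, int(counts.get(k, 0))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi", "n_variants"])


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(gm: GenotypeMatrix, pop_labels=None):
    """Per-site WC1984 variance components a, b, c.

    Sites where fewer than two populations have called genotypes get
    NaN components and are excluded from ratio estimates.
    """
    labels = (gm.individuals["pop_id"] if pop_labels is None
              else pd.Series(list(pop_labels))).to_numpy()
    pops = pd.unique(labels)
    r_all = len(pops)
    if r_all < 2:
        raise ValueError("need at least 2 populations")
    g = gm.genotypes
    called = g != MISSING
    m = gm.n_variants

    n_i = np.zeros((r_all, m))
    p_i = np.zeros((r_all, m))
    h_i = np.zeros((r_all, m))
    for k, pop in enumerate(pops):
        rows = labels == pop
        c = called[rows]
        n_i[k] = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(c, g[rows], 0).sum(axis=0) / (2.0 * n_i[k])
            h_i[k] = (g[rows] == 1).sum(axis=0) / n_i[k]

    has = n_i > 0
    r = has.sum(axis=0).astype(float)
    ok = r >= 2
    n_i = np.where(has, n_i, 0.0)
    p_i = np.where(has, p_i, 0.0)
    h_i = np.where(has, h_i, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n_i.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n_i ** 2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    bad = ~ok | (nbar <= 1.0) | ~np.isfinite(nc) | (nc == 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst(gm: GenotypeMatrix, pop_labels=None, mode: str = "global",
           window: int = 10000):
    """Weir & Cockerham FST.

    ``mode``: ``per-site`` -> array ``a / (a+b+c)``; ``global`` ->
    weighted scalar ``sum(a) / sum(a+b+c)``; ``windowed`` -> DataFrame
    of weighted window estimates.
    """
    a, b, c = _wc_components(gm, pop_labels)
    tot = a + b + c
    if mode == "per-site":
        with np.errstate(invalid="ignore", divide="ignore"):
            return a / tot
    if mode == "global":
        ok = np.isfinite(tot) & (tot != 0)
        denom = tot[ok].sum()
        return float(a[ok].sum() / denom) if denom != 0 else float("nan")
    if mode == "windowed":
        chroms = gm.variants["chrom"].to_numpy()
        pos = gm.variants["pos"].to_numpy()
        rows = []
        for chrom in pd.unique(chroms):
            sel = (chroms == chrom) & np.isfinite(tot)
            widx = (pos[sel] - 1) // window
            fr = pd.DataFrame({"w": widx, "a": a[sel], "tot": tot[sel]})
            grp = fr.groupby("w").sum()
            for k, row in grp.iterrows():
                est = row["a"] / row["tot"] if row["tot"] != 0 else np.nan
                rows.append((chrom, 1 + int(k) * window, 1 + (int(k) + 1) * window, est))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst"])
    raise ValueError(f"unknown mode {mode!r}")


def pairwise_fst_matrix(gm: GenotypeMatrix, var_idx=None) -> DistanceMatrix:
    """Global weighted WC FST for every population pair.

    Small negative estimates are retained (flagged by ``kind='fst'``).
    """
    sub = gm if var_idx is None else gm.subset(var_idx=var_idx)
    if sub.n_variants == 0:
        raise ValueError("empty variant subset")
    labels = sub.individuals["pop_id"].to_numpy()
    pops = list(pd.unique(labels))
    g = sub.genotypes
    called = g != MISSING
    m = sub.n_variants
    r_all = len(pops)

    n_i = np.zeros((r_all, m))
    p_i = np.zeros((r_all, m))
    h_i = np.zeros((r_all, m))
    for k, pop in enumerate(pops):
        rows = labels == pop
        c = called[rows]
        n_i[k] = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(c, g[rows], 0).sum(axis=0) / (2.0 * n_i[k])
            h_i[k] = (g[rows] == 1).sum(axis=0) / n_i[k]

    out = np.zeros((r_all, r_all))
    for i in range(r_all):
        for j in range(i + 1, r_all):
            ni, nj = n_i[i], n_i[j]
            ok = (ni > 0) & (nj > 0)
            ni, nj = ni[ok], nj[ok]
            pi_, pj = p_i[i][ok], p_i[j][ok]
            hi, hj = h_i[i][ok], h_i[j][ok]
            with np.errstate(invalid="ignore", divide="ignore"):
                n_tot = ni + nj
                nbar = n_tot / 2.0
                nc = n_tot - (ni ** 2 + nj ** 2) / n_tot  # r-1 = 1
                pbar = (ni * pi_ + nj * pj) / n_tot
                s2 = (ni * (pi_ - pbar) ** 2 + nj * (pj - pbar) ** 2) / nbar
                hbar = (ni * hi + nj * hj) / n_tot
                a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0)
                                   / (nbar - 1.0))
                b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0
                                             - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
                c = hbar / 2.0
                tot = a + b + c
            good = np.isfinite(tot) & (nbar > 1.0) & (nc > 0)
            denom = tot[good].sum()
            out[i, j] = out[j, i] = a[good].sum() / denom if denom != 0 else np.nan
    return DistanceMatrix(pops, out, kind="fst")


def geo_distance_matrix(populations: pd.DataFrame) -> DistanceMatrix:
    """Great-circle km matrix from a populations table."""
    from .simulate import distance_matrix_km

    d = distance_matrix_km(populations["lon"].to_numpy(),
                           populations["lat"].to_numpy())
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(populations["pop_id"]), d, kind="km")


def env_distance_matrix(env_values: pd.Series | pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between population environment values."""
    vals = pd.DataFrame(env_values)
    X = vals.to_numpy(dtype=float)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(list(vals.index), d, kind="env")


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _canonical(A: DistanceMatrix) -> DistanceMatrix:
    """Reorder to sorted labels so permutation p-values do not depend on
    the (arbitrary) input label order."""
    order = sorted(A.labels)
    return A if A.labels == order else A.reordered(order)


def _check_pair(A: DistanceMatrix, B: DistanceMatrix):
    if set(A.labels) != set(B.labels):
        raise ValueError("label sets differ")
    A, B = _canonical(A), _canonical(B)
    if A.n < 4:
        raise ValueError("need at least 4 labels")
    return A, B


def mantel(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, alternative: str = "greater"):
    """Mantel test: Pearson correlation of lower triangles with
    simultaneous row/column permutations of ``B``.

    ``p = (1 + #{permuted statistic at least as extreme}) / (n_perm + 1)``.
    """
    A, B = _check_pair(A, B)
    x = A.condensed()
    tri = np.tril_indices(A.n, k=-1)
    y = B.values[tri]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.n)
        yp = B.values[np.ix_(perm, perm)][tri]
        r_p = float(np.corrcoef(x, yp)[0, 1])
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        elif alternative == "two-sided":
            count += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (n_perm + 1)
    return r_obs, p


def partial_mantel(A: DistanceMatrix, B: DistanceMatrix, C: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0,
                   alternative: str = "greater"):
    """Partial Mantel test of A ~ B given C (Legendre residual method).

    The lower triangles of A and B are residualized on C; the residual
    matrix of A is permuted (rows/columns simultaneously).
    """
    A, B = _check_pair(A, B)
    _, C = _check_pair(A, C)
    tri = np.tril_indices(A.n, k=-1)
    c = C.values[tri]

    def residual_matrix(M: DistanceMatrix):
        v = M.values[tri]
        if c.std() == 0:
            res = v - v.mean()
        else:
            beta = np.polyfit(c, v, 1)
            res = v - np.polyval(beta, c)
        R = np.zeros_like(M.values)
        R[tri] = res
        return R + R.T

    RA = residual_matrix(A)
    RB = residual_matrix(B)
    ra, rb = RA[tri], RB[tri]
    if ra.std() < 1e-12 or rb.std() < 1e-12:
        raise ValueError("degenerate residuals: C collinear with A or B")
    r_obs = float(np.corrcoef(ra, rb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.n)
        rp = RA[np.ix_(perm, perm)][tri]
        r_p = float(np.corrcoef(rp, rb)[0, 1])
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1 + count) / (n_perm + 1)
    return r_obs, p
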