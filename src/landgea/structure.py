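"""Population structure and relatedness.

PCA on mean-imputed centered dosages, ancestry coefficients by
simplex-constrained alternating least squares (an admixture-style
nonnegative factorization), KING-robust pairwise kinship, and greedy
extraction of an unrelated individual set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SkPCA

from .datatypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, n_components: int = 10, impute: str = "mean"):
    """PCA of the dosage matrix with mean imputation of missing calls.

    Columns are mean-imputed then mean-centered; no variance scaling.

    Returns
    -------
    scores : (n_individuals, k) array
    loadings : (n_variants, k) array
    explained_variance_fraction : (k,) array, monotone nonincreasing
    """
    if impute != "mean":
        raise ValueError("only mean imputation is supported here")
    X = gm.genotypes.astype(float)
    miss = X == MISSING
    if miss.all(axis=0).any():
        raise ValueError("variant with no called genotypes")
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    k = min(n_components, min(X.shape) - 1) if min(X.shape) > 1 else 1
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.components_.T, model.explained_variance_ratio_


# ---------------------------------------------------------------------------
# ancestry coefficients
# ---------------------------------------------------------------------------

def _solve_simplex_rows(G: np.ndarray, C: np.ndarray) -> np.ndarray:
    """argmin_q  1/2 q'Gq - c'q  s.t. q >= 0, sum(q) = 1, batched over rows of C.

    Exact KKT solution by enumerating support sets (K is small).
    """
    K = G.shape[0]
    n = C.shape[0]
    Q = np.full((n, K), np.nan)
    best_obj = np.full(n, np.inf)
    for r in range(1, K + 1):
        for S in itertools.combinations(range(K), r):
            S = list(S)
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = G[np.ix_(S, S)]
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.zeros((r + 1, n))
            rhs[:r] = C[:, S].T
            rhs[r] = 1.0
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            qS = sol[:r].T           # (n, r)
            mu = sol[r]              # (n,)
            feas = (qS >= -1e-12).all(axis=1)
            # dual feasibility for excluded coordinates: grad_j + mu >= 0
            if r < K:
                notS = [j for j in range(K) if j not in S]
                grad = qS @ G[np.ix_(S, notS)] - C[:, notS]
                feas &= (grad + mu[:, None] >= -1e-9).all(axis=1)
            q_full = np.zeros((n, K))
            q_full[:, S] = np.clip(qS, 0.0, None)
            q_full /= q_full.sum(axis=1, keepdims=True)
            obj = 0.5 * np.einsum("ij,jk,ik->i", q_full, G, q_full) - (q_full * C).sum(axis=1)
            better = feas & (obj < best_obj - 1e-15)
            Q[better] = q_full[better]
            best_obj[better] = obj[better]
    return Q


def _solve_box_cols(M: np.ndarray, D: np.ndarray) -> np.ndarray:
    """argmin_f  1/2 f'Mf - d'f  s.t. 0 <= f <= 1, batched over columns of D.

    Exact KKT solution by enumerating clamp patterns (0 / 1 / free).
    """
    K = M.shape[0]
    m = D.shape[1]
    F = np.zeros((K, m))
    best_obj = np.full(m, np.inf)
    for pattern in itertools.product((0, 1, 2), repeat=K):  # 0=at0, 1=at1, 2=free
        free = [j for j in range(K) if pattern[j] == 2]
        ones = [j for j in range(K) if pattern[j] == 1]
        f = np.zeros((K, m))
        if ones:
            f[ones, :] = 1.0
        if free:
            rhs = D[free, :] - (M[np.ix_(free, ones)].sum(axis=1, keepdims=True)
                                if ones else 0.0)
            try:
                sol = np.linalg.solve(M[np.ix_(free, free)], rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(M[np.ix_(free, free)], rhs, rcond=None)
            f[free, :] = sol
        feas = np.ones(m, dtype=bool)
        if free:
            feas &= (f[free, :] >= -1e-12).all(axis=0) & (f[free, :] <= 1 + 1e-12).all(axis=0)
        grad = M @ f - D
        for j in range(K):
            if pattern[j] == 0:
                feas &= grad[j, :] >= -1e-9
            elif pattern[j] == 1:
                feas &= grad[j, :] <= 1e-9
        fc = np.clip(f, 0.0, 1.0)
        obj = 0.5 * np.einsum("kj,kl,lj->j", fc, M, fc) - (fc * D).sum(axis=0)
        better = feas & (obj < best_obj - 1e-15)
        F[:, better] = fc[:, better]
        best_obj[better] = obj[better]
    return F


class AncestryNMF(BaseEstimator):
    """Ancestry coefficients by alternating projected least squares.

    Factorizes the frequency-coded genotype matrix ``X`` (dosage / 2,
    values in [0, 1]) as ``X ~ Q F`` with ``Q`` rows on the K-simplex
    (individual ancestry proportions) and ``F`` in [0, 1] (cluster
    allele frequencies).  Both block updates are solved exactly, so the
    reconstruction loss is non-increasing per iteration.  The best of
    ``n_restarts`` random initializations is kept; deterministic for a
    fixed ``random_state``.

    Attributes
    ----------
    Q_ : (n, K) ancestry proportions, rows sum to 1
    F_ : (K, m) cluster allele frequencies
    loss_ : final squared reconstruction error
    loss_history_ : per-iteration losses of the winning restart
    """

    def __init__(self, K: int = 3, n_restarts: int = 5, max_iter: int = 100,
                 tol: float = 1e-7, random_state: int = 0):
        self.K = K
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if self.K < 1 or self.K > n:
            raise ValueError("K must be in [1, n_individuals]")
        if np.isnan(X).any():
            raise ValueError("X must be imputed (no NaN)")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            Q = rng.dirichlet(np.ones(self.K), size=n)
            F = rng.uniform(0.0, 1.0, size=(self.K, m))
            losses = []
            prev = np.inf
            for _it in range(self.max_iter):
                # F-step: box-constrained least squares per column
                M = Q.T @ Q + 1e-12 * np.eye(self.K)
                F = _solve_box_cols(M, Q.T @ X)
                # Q-step: simplex-constrained least squares per row
                G = F @ F.T + 1e-12 * np.eye(self.K)
                Q = _solve_simplex_rows(G, X @ F.T)
                loss = float(((X - Q @ F) ** 2).sum())
                losses.append(loss)
                if prev - loss < self.tol * max(prev, 1.0):
                    break
                prev = loss
            if best is None or losses[-1] < best[0]:
                best = (losses[-1], Q, F, losses)
        self.loss_, self.Q_, self.F_, self.loss_history_ = best
        self.n_iter_ = len(self.loss_history_)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).Q_


@dataclass
class AncestryMatrix:
    Q: pd.DataFrame  # individuals x K
    K: int
    loss: float


def nmf_ancestry(gm: GenotypeMatrix, K: int = 3, n_restarts: int = 5,
                 seed: int = 0) -> AncestryMatrix:
    """Ancestry coefficients for a genotype matrix (missing imputed by
    population-mode, then coded as dosage / 2)."""
    from .gea import impute_missing

    X = impute_missing(gm).astype(float) / 2.0
    model = AncestryNMF(K=K, n_restarts=n_restarts, random_state=seed).fit(X)
    Q = pd.DataFrame(model.Q_, index=gm.individuals["ind_id"],
                     columns=[f"Q{k + 1}" for k in range(K)])
    return AncestryMatrix(Q=Q, K=K, loss=model.loss_)


def assign_clusters(Q, threshold: float = 0.70) -> np.ndarray:
    """Argmax cluster per individual, or -1 when max membership < threshold."""
    Qv = np.asarray(Q, dtype=float)
    best = Qv.argmax(axis=1)
    return np.where(Qv.max(axis=1) >= threshold, best, -1)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def king_kinship(gm: GenotypeMatrix) -> pd.DataFrame:
    """KING-robust between-family kinship for all pairs (incl. self).

    phi_ij = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j)),
    counted over the loci called in both individuals.  Pairs with zero
    heterozygous loci get NaN.  Self-kinship is 0.5 by construction.
    """
    if gm.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    g = gm.genotypes
    called = (g != MISSING).astype(float)
    H = (g == 1).astype(float)
    A0 = (g == 0).astype(float)
    A2 = (g == 2).astype(float)
    n_hethet = H @ H.T
    n_opp = A0 @ A2.T + A2 @ A0.T
    n_het_shared = H @ called.T  # het loci of i among loci called in j
    denom = n_het_shared + n_het_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    ids = gm.individuals["ind_id"]
    return pd.DataFrame(phi, index=ids, columns=ids)


def unrelated_set(kinship: pd.DataFrame, degree: int = 2,
                  missing_rates=None) -> list:
    """Greedy maximal set of mutually unrelated individuals.

    The kinship cutoff is ``2 ** -(degree + 1.5)`` (degree 2 -> 0.0884).
    Repeatedly removes the individual with the most relationships above
    the cutoff (ties: more missing data, then later sort order) until no
    pair exceeds it.  Returns the kept ``ind_id`` list in input order.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    cutoff = 2.0 ** (-(degree + 1.5))
    phi = kinship.to_numpy().copy()
    np.fill_diagonal(phi, 0.0)
    phi = np.nan_to_num(phi, nan=0.0)
    n = phi.shape[0]
    miss = np.zeros(n) if missing_rates is None else np.asarray(missing_rates, dtype=float)
    alive = np.ones(n, dtype=bool)
    adj = phi > cutoff
    while True:
        counts = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        if counts.max() == 0:
            break
        top = counts.max()
        cand = np.flatnonzero((counts == top) & alive)
        cand = cand[miss[cand] == miss[cand].max()]
        victim = cand[-1]  # later sort order loses
        alive[victim] = False
    return list(kinship.index[alive])


# ---------------------------------------------------------------------------
# K selection helper
# ---------------------------------------------------------------------------

def select_k(X, ks=(1, 2, 3, 4, 5), mask_fraction: float = 0.1, seed: int = 0,
             **nmf_kwargs) -> pd.Series:
    """Masked-entry reconstruction RMSE across candidate K.

    A random ``mask_fraction`` of entries is hidden (replaced by column
    means) during fitting; the RMSE of reconstructing the hidden entries
    is returned per K (lower is better).
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    mask = rng.random(X.shape) < mask_fraction
    X_train = X.copy()
    col_mean = X.mean(axis=0)
    X_train[mask] = np.broadcast_to(col_mean, X.shape)[mask]
    out = {}
    for K in ks:
        model = AncestryNMF(K=K, random_state=seed, **nmf_kwargs).fit(X_train)
        recon = model.Q_ @ model.F_
        out[K] = float(np.sqrt(((recon[mask] - X[mask]) ** 2).mean()))
    return pd.Series(out, name="masked_rmse")
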