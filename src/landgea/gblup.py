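"""Genomic prediction: VanRaden relationship matrix and kinship BLUP.

The mixed model is ``y = mu + g + e`` with ``g ~ N(0, sigma_g^2 A)``;
the variance ratio ``delta = sigma_e^2 / sigma_g^2`` is estimated by
REML using a spectral decomposition of the training kinship submatrix
and a 1-D bounded search over log(delta).  Predictions for unobserved
individuals are the conditional expectations given the training records
(kernel-ridge form with a precomputed kinship kernel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import MISSING, GenotypeMatrix


def vanraden_A(gm_or_dosage, marker_idx=None) -> np.ndarray:
    """VanRaden additive genomic relationship matrix.

    ``Z = dosage - 2p`` per marker (missing mean-imputed), then
    ``A = Z Z' / (2 * sum_j p_j (1 - p_j))``.  Monomorphic markers are
    dropped; an all-monomorphic subset raises.
    """
    if isinstance(gm_or_dosage, GenotypeMatrix):
        G = gm_or_dosage.genotypes.astype(float)
    else:
        G = np.asarray(gm_or_dosage, dtype=float)
    if marker_idx is not None:
        G = G[:, np.asarray(marker_idx)]
    G[G == MISSING] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    G = np.where(np.isnan(G), 2.0 * p[None, :], G)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic")
    G, p = G[:, poly], p[poly]
    Z = G - 2.0 * p[None, :]
    scale = 2.0 * (p * (1.0 - p)).sum()
    return (Z @ Z.T) / scale


class GBLUP(BaseEstimator, RegressorMixin):
    """Kinship BLUP with REML variance estimation.

    Fit on a precomputed training kinship matrix and phenotypes;
    predict from the cross-kinship between new and training individuals
    (precomputed-kernel convention).

    Parameters
    ----------
    delta : float, optional
        Fix ``sigma_e^2 / sigma_g^2`` instead of estimating it by REML.
    log_delta_bounds : REML search interval on log(delta)
    tol : search tolerance on log(delta)

    Attributes
    ----------
    mu_, delta_, sigma_g2_, sigma_e2_, alpha_
    """

    def __init__(self, delta: float | None = None,
                 log_delta_bounds: tuple = (-10.0, 10.0), tol: float = 1e-6):
        self.delta = delta
        self.log_delta_bounds = log_delta_bounds
        self.tol = tol

    def fit(self, K, y):
        K = np.asarray(K, dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.size
        if n < 10:
            raise ValueError("need at least 10 training records")
        if K.shape != (n, n):
            raise ValueError("K must be the n x n training kinship")
        s, U = np.linalg.eigh(K)
        yt = U.T @ y
        ot = U.T @ np.ones(n)

        def neg_reml(log_delta: float) -> float:
            d = np.exp(log_delta)
            v = s + d
            denom = (ot ** 2 / v).sum()
            mu = (ot * yt / v).sum() / denom
            r = yt - mu * ot
            sg2 = (r ** 2 / v).sum() / (n - 1)
            return 0.5 * ((n - 1) * np.log(sg2) + np.log(v).sum() + np.log(denom))

        if self.delta is not None:
            log_d = float(np.log(self.delta))
        else:
            res = minimize_scalar(neg_reml, bounds=self.log_delta_bounds,
                                  method="bounded",
                                  options={"xatol": self.tol})
            log_d = float(res.x)
        d = float(np.exp(log_d))
        v = s + d
        denom = (ot ** 2 / v).sum()
        self.mu_ = float((ot * yt / v).sum() / denom)
        r = yt - self.mu_ * ot
        self.sigma_g2_ = float((r ** 2 / v).sum() / (n - 1))
        self.sigma_e2_ = self.sigma_g2_ * d
        self.delta_ = d
        # alpha = (K + delta I)^-1 (y - mu)
        self.alpha_ = U @ (r / v)
        self._train_gebv = K @ self.alpha_
        return self

    def predict(self, K_new):
        """Predicted phenotypic values ``mu + K_new @ alpha``.

        ``K_new`` is the (n_new x n_train) cross-kinship.
        """
        K_new = np.asarray(K_new, dtype=float)
        return self.mu_ + K_new @ self.alpha_


def gblup_fit(y: pd.Series, A: pd.DataFrame, train_ids, predict_ids,
              delta: float | None = None) -> pd.Series:
    """Predict genetic values for ``predict_ids`` from training records.

    ``A`` is the full relationship matrix (DataFrame indexed by ind_id);
    ``train_ids`` and ``predict_ids`` must be disjoint.
    """
    train_ids, predict_ids = list(train_ids), list(predict_ids)
    if set(train_ids) & set(predict_ids):
        raise ValueError("train and predict sets overlap")
    K_tt = A.loc[train_ids, train_ids].to_numpy()
    K_pt = A.loc[predict_ids, train_ids].to_numpy()
    model = GBLUP(delta=delta).fit(K_tt, pd.Series(y).loc[train_ids].to_numpy())
    return pd.Series(model.predict(K_pt), index=predict_ids)


@dataclass
class CVResult:
    """Cross-validated prediction accuracies per training size."""

    trait: str
    table: pd.DataFrame        # size, replicate, accuracy
    n_replicates: int
    n_markers: int
    seed: int

    def summary(self) -> pd.DataFrame:
        return (self.table.groupby("size")["accuracy"]
                .agg(["mean", "std", "count"]).reset_index())


def cv_accuracy(y: pd.Series, A: pd.DataFrame,
                sizes=(150, 250, 350, 450, 550), n_replicates: int = 200,
                seed: int = 0, trait: str = "trait",
                n_markers: int = 0) -> CVResult:
    """Random train/validation cross-validation of GBLUP accuracy.

    Per replicate a random training set of the given size is drawn, the
    remainder validates; accuracy is the Pearson correlation between
    predicted and observed values.  Deterministic per seed.
    """
    y = pd.Series(y)
    ids = list(A.index)
    n = len(ids)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size >= n:
            raise ValueError(f"training size {size} >= {n} individuals")
        if n - size < 5:
            raise ValueError(f"validation set below 5 for size {size}")
        for rep in range(n_replicates):
            perm = rng.permutation(n)
            train = [ids[i] for i in perm[:size]]
            valid = [ids[i] for i in perm[size:]]
            pred = gblup_fit(y, A, train, valid)
            acc = pearsonr(pred.to_numpy(), y.loc[valid].to_numpy())[0]
            rows.append((size, rep, acc))
    table = pd.DataFrame(rows, columns=["size", "replicate", "accuracy"])
    return CVResult(trait=trait, table=table, n_replicates=n_replicates,
                    n_markers=n_markers, seed=seed)
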