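"""Genotype-environment association.

Population-mode imputation, a deterministic least-squares latent factor
mixed model (LFMM) with genomic-inflation recalibration of p-values,
Bonferroni thresholds, and the Kendall-tau / weighted-Z (WZA) window
analysis on population allele frequencies.

The LFMM here is the least-squares member of the latent factor model
family: K latent factors are estimated as the leading left singular
vectors of the genotype matrix after ridge-regularized removal of the
environmental effect, then each variant is regressed on the environment
plus the factors by OLS.  It is deterministic and needs no sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import MISSING, GenotypeMatrix

#: Median of the chi-square(1 df) distribution, the reference for the
#: genomic inflation factor.
CHI2_1_MEDIAN = 0.456


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(gm: GenotypeMatrix, groups=None) -> np.ndarray:
    """Impute missing dosages by the modal dosage within the individual's
    population (fallback: global mode; ties: smaller dosage).

    Returns a complete ``int8`` dosage matrix; raises if a variant has
    no called genotype at all.
    """
    g = gm.genotypes
    labels = (gm.individuals["pop_id"] if groups is None
              else pd.Series(list(groups))).to_numpy()
    called = g != MISSING
    if (~called).all(axis=0).any():
        raise ValueError("variant with no called genotype cannot be imputed")
    out = g.copy()

    counts_global = np.stack([(g == d).sum(axis=0) for d in (0, 1, 2)])
    global_mode = counts_global.argmax(axis=0).astype(np.int8)  # argmax -> smaller dosage on tie

    for pop in pd.unique(labels):
        rows = np.flatnonzero(labels == pop)
        sub = g[rows]
        miss_rows, miss_cols = np.nonzero(sub == MISSING)
        if miss_rows.size == 0:
            continue
        counts = np.stack([(sub == d).sum(axis=0) for d in (0, 1, 2)])
        pop_mode = counts.argmax(axis=0).astype(np.int8)
        has_calls = counts.sum(axis=0) > 0
        fill = np.where(has_calls, pop_mode, global_mode)
        out[rows[miss_rows], miss_cols] = fill[miss_cols]
    return out


# ---------------------------------------------------------------------------
# LFMM
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Per-(variant, variable) association statistics."""

    table: pd.DataFrame          # variant, var, beta, z, p_raw, p_cal
    lambdas: dict                # env variable -> genomic inflation factor
    K: int
    method: str = "lfmm-lstsq"

    def for_var(self, var: str) -> pd.DataFrame:
        return self.table[self.table["var"] == var].reset_index(drop=True)


class LatentFactorMixedModel(BaseEstimator):
    """Deterministic least-squares LFMM.

    Parameters
    ----------
    K : number of latent factors absorbing population structure
    ridge : penalty for the preliminary removal of the env effect
        before the factor SVD
    calibrate : recalibrate p-values with the genomic inflation factor

    Attributes (after :meth:`fit`)
    ------------------------------
    U_ : dict of per-variable latent factor scores (n x K)
    result_ : :class:`AssociationResult`
    """

    def __init__(self, K: int = 3, ridge: float = 1e-5, calibrate: bool = True):
        self.K = K
        self.ridge = ridge
        self.calibrate = calibrate

    def fit(self, X, E):
        """Fit per environmental variable.

        Parameters
        ----------
        X : (n, m) complete dosage matrix
        E : DataFrame or array of per-individual environment values,
            one column per variable (standardized internally).
        """
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if self.K < 0 or self.K >= n - 2:
            raise ValueError("K must satisfy 0 <= K < n_individuals - 2")
        E = pd.DataFrame(E)
        Xc = X - X.mean(axis=0, keepdims=True)

        rows = []
        lambdas = {}
        self.U_ = {}
        for var in E.columns:
            e = E[var].to_numpy(dtype=float)
            if e.std() == 0:
                raise ValueError(f"constant environment variable {var!r}")
            e = (e - e.mean()) / e.std(ddof=0)

            if self.K > 0:
                # remove env effect with a ridge, then take leading factors
                bhat = (e @ Xc) / (e @ e + self.ridge)
                R = Xc - np.outer(e, bhat)
                U, _, _ = np.linalg.svd(R, full_matrices=False)
                U = U[:, : self.K]
            else:
                U = np.empty((n, 0))
            self.U_[var] = U

            D = np.column_stack([np.ones(n), e, U])
            q = D.shape[1]
            DtD_inv = np.linalg.inv(D.T @ D)
            coef = DtD_inv @ (D.T @ X)
            resid = X - D @ coef
            dof = n - q  # = n - K - 2
            sigma2 = (resid ** 2).sum(axis=0) / dof
            se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 1e-300))
            z = coef[1] / se
            # monomorphic columns carry no association information; their
            # coefficients are pure float noise over a degenerate se
            constant = X.std(axis=0) == 0
            z[constant] = 0.0
            p_raw = 2.0 * stats.t.sf(np.abs(z), dof)
            p_raw = np.clip(p_raw, np.nextafter(0, 1), 1.0)
            p_raw[constant] = 1.0
            if self.calibrate:
                # monomorphic columns are not tests; keep them out of the
                # inflation-factor median
                lam, _ = calibrate_pvalues(z[~constant])
                p_cal = stats.chi2.sf(z ** 2 / lam, df=1)
                p_cal = np.clip(p_cal, np.nextafter(0, 1), 1.0)
                p_cal[constant] = 1.0
            else:
                lam, p_cal = 1.0, p_raw
            lambdas[var] = lam
            rows.append(pd.DataFrame({
                "variant": np.arange(m), "var": var, "beta": coef[1],
                "z": z, "p_raw": p_raw, "p_cal": p_cal,
            }))
        self.result_ = AssociationResult(pd.concat(rows, ignore_index=True),
                                         lambdas, self.K)
        return self


def lfmm_fit(gm_or_X, env, K: int = 3, ridge: float = 1e-5,
             calibrate: bool = True) -> AssociationResult:
    """Fit the least-squares LFMM (thin wrapper over the estimator).

    ``gm_or_X`` may be a :class:`GenotypeMatrix` (imputed internally) or
    a complete dosage matrix.  ``env`` holds per-individual values, one
    column per variable.
    """
    if isinstance(gm_or_X, GenotypeMatrix):
        X = impute_missing(gm_or_X)
    else:
        X = np.asarray(gm_or_X)
    model = LatentFactorMixedModel(K=K, ridge=ridge, calibrate=calibrate)
    return model.fit(X, env).result_


def env_per_individual(gm: GenotypeMatrix, env: pd.DataFrame,
                       scenario: str = "current") -> pd.DataFrame:
    """Broadcast the population-level environment to individuals."""
    from .io import env_matrix

    wide = env_matrix(env, scenario)
    pops = gm.individuals["pop_id"]
    missing = set(pops) - set(wide.index)
    if missing:
        raise KeyError(f"no environment for populations {sorted(missing)}")
    return wide.loc[pops].reset_index(drop=True)


def calibrate_pvalues(z):
    """Genomic-control recalibration of association z-scores.

    ``lambda = median(z^2) / 0.456``; calibrated p is the upper tail of
    chi-square(1) at ``z^2 / lambda``.  Invariant to global rescaling
    of z.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 10:
        raise ValueError("need at least 10 z-scores to estimate lambda")
    lam = float(np.median(z ** 2) / CHI2_1_MEDIAN)
    p_cal = stats.chi2.sf(z ** 2 / lam, df=1)
    return lam, np.clip(p_cal, np.nextafter(0, 1), 1.0)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Kendall tau + WZA
# ---------------------------------------------------------------------------

@dataclass
class TauResult:
    """Kendall-tau correlations of population allele frequencies with
    environment, plus the mean-heterozygosity WZA weights."""

    table: pd.DataFrame   # variant, var, tau, p
    weights: np.ndarray   # per variant: mean over pops of p*(1-p)
    variants: pd.DataFrame


def kendall_tau_env(pop_freqs: pd.DataFrame, env: pd.DataFrame,
                    variants: pd.DataFrame | None = None) -> TauResult:
    """Kendall tau-b of per-population ALT frequencies vs environment.

    Parameters
    ----------
    pop_freqs : (variants x populations) frequency table (NaN allowed)
    env : (populations x variables) environment values

    Variants with constant frequency get NaN tau/p.  The per-variant WZA
    weight is the mean over populations of ``p * (1 - p)``.
    """
    freqs = pop_freqs.to_numpy(dtype=float)
    env = pd.DataFrame(env).loc[list(pop_freqs.columns)]
    if freqs.shape[1] < 4:
        raise ValueError("need at least 4 populations")
    weights = np.nanmean(freqs * (1.0 - freqs), axis=1)
    rows = []
    for var in env.columns:
        e = env[var].to_numpy(dtype=float)
        for i in range(freqs.shape[0]):
            f = freqs[i]
            ok = ~np.isnan(f)
            if ok.sum() < 4 or np.nanstd(f[ok]) == 0:
                tau, p = np.nan, np.nan
            else:
                tau, p = stats.kendalltau(f[ok], e[ok])
            rows.append((i, var, tau, p))
    table = pd.DataFrame(rows, columns=["variant", "var", "tau", "p"])
    return TauResult(table=table, weights=weights,
                     variants=variants if variants is not None else
                     pd.DataFrame(index=pop_freqs.index))


def wza(tau: TauResult, variants: pd.DataFrame, window: int = 10000,
        env_var: str | None = None) -> pd.DataFrame:
    """Weighted-Z analysis in non-overlapping windows.

    Per variant the tau p-value is converted to an empirical p by Hazen
    rank ``(r - 0.5) / n`` over all variants, then to
    ``z = probit(1 - p_emp)``; the window statistic is
    ``Z_W = sum(w_i z_i) / sqrt(sum(w_i^2))`` with the mean-pq weights.
    Windows without variants are omitted.
    """
    out = []
    for var, sub in tau.table.groupby("var", sort=False):
        if env_var is not None and var != env_var:
            continue
        sub = sub.set_index("variant")
        ok = sub["p"].notna()
        p = sub.loc[ok, "p"].to_numpy()
        idx = sub.index[ok].to_numpy()
        n = p.size
        ranks = stats.rankdata(p, method="average")
        emp = (ranks - 0.5) / n
        z = stats.norm.ppf(1.0 - emp)
        w = tau.weights[idx]
        chroms = variants["chrom"].to_numpy()[idx]
        pos = variants["pos"].to_numpy()[idx]
        widx = (pos - 1) // window
        df = pd.DataFrame({"chrom": chroms, "w": widx, "wz": w * z, "w2": w ** 2,
                           "n": 1})
        grp = df.groupby(["chrom", "w"], sort=False).sum()
        for (chrom, k), row in grp.iterrows():
            out.append((var, chrom, 1 + int(k) * window, 1 + (int(k) + 1) * window,
                        row["wz"] / np.sqrt(row["w2"]), int(row["n"])))
    return pd.DataFrame(out, columns=["var", "chrom", "start", "end",
                                      "z_w", "n_variants"])
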