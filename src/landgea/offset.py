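"""Risk of non-adaptedness (RONA) genomic offset.

Per selected SNP, a linear regression of population allele frequency on
an environmental variable predicts the frequency "required" under a
future environment; RONA for a population is the weighted mean absolute
gap between its current frequencies and those requirements, weighted by
each SNP's adjusted R-squared (floored at zero).  A space-for-time
variant scores populations against a common-garden environment instead
of a future climate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gea import AssociationResult, bonferroni_threshold


def select_gea_snps(assoc: AssociationResult, env_var: str,
                    alpha: float = 0.05, n_tests: int | None = None) -> np.ndarray:
    """Variants with Bonferroni-adjusted calibrated p below ``alpha``.

    ``n_tests`` defaults to the number of variants tested for the
    variable.  Returns variant indices (possibly empty; downstream
    consumers raise on empty selections).
    """
    sub = assoc.for_var(env_var)
    n = n_tests if n_tests is not None else len(sub)
    sel = sub.loc[sub["p_cal"] * n < alpha, "variant"].to_numpy()
    return sel


def _fit_freq_env(freqs: np.ndarray, env_now: np.ndarray):
    """Vectorized per-SNP OLS of frequency on environment.

    Returns intercepts a, slopes b and nonnegative adjusted-R2 weights.
    """
    n = env_now.size
    if n < 3:
        raise ValueError("need at least 3 populations")
    ex = env_now - env_now.mean()
    sxx = (ex ** 2).sum()
    fbar = freqs.mean(axis=1)
    b = (freqs @ ex) / sxx
    a = fbar - b * env_now.mean()
    pred = a[:, None] + b[:, None] * env_now[None, :]
    ss_res = ((freqs - pred) ** 2).sum(axis=1)
    ss_tot = ((freqs - fbar[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot > 0, r2, 0.0)
    adj = 1.0 - (1.0 - r2) * (n - 1.0) / (n - 2.0)
    w = np.maximum(adj, 0.0)
    return a, b, w


def rona(pop_freqs: pd.DataFrame, env_now: pd.Series, env_future: pd.Series,
         env_var: str = "env", scenario: str = "future",
         use_fitted: bool = False, fit_pops=None) -> pd.DataFrame:
    """RONA per population for one environmental variable.

    Parameters
    ----------
    pop_freqs : (selected SNPs x populations) ALT-frequency table
    env_now, env_future : per-population environment values (current and
        projected); indices must cover the populations of ``pop_freqs``
    use_fitted : anchor the distance at the fitted current frequency
        instead of the observed one (sensitivity variant; with it, RONA
        is exactly 0 when the future environment equals the current one)
    fit_pops : optional subset of populations used to fit the
        regressions; all populations are still scored

    Returns a DataFrame ``pop_id, var, scenario, rona, n_snps, sum_weights``.
    """
    if pop_freqs.shape[0] < 1:
        raise ValueError("no SNPs selected")
    pops = list(pop_freqs.columns)
    env_now = pd.Series(env_now).loc[pops]
    env_future = pd.Series(env_future).loc[pops]
    freqs = pop_freqs.to_numpy(dtype=float)

    fit_cols = ([pops.index(p) for p in fit_pops] if fit_pops is not None
                else list(range(len(pops))))
    a, b, w = _fit_freq_env(freqs[:, fit_cols],
                            env_now.to_numpy()[fit_cols])
    sw = w.sum()
    if sw == 0:
        raise ValueError("no informative SNPs (all adjusted R2 <= 0)")

    required = a[:, None] + b[:, None] * env_future.to_numpy()[None, :]
    if use_fitted:
        anchor = a[:, None] + b[:, None] * env_now.to_numpy()[None, :]
    else:
        anchor = freqs
    gap = np.abs(required - anchor)            # SNPs x pops
    rona_pop = (w @ gap) / sw
    return pd.DataFrame({"pop_id": pops, "var": env_var, "scenario": scenario,
                         "rona": rona_pop, "n_snps": freqs.shape[0],
                         "sum_weights": sw})


def rona_space_for_time(pop_freqs: pd.DataFrame, env_now: pd.Series,
                        garden_env: float, env_var: str = "env",
                        use_fitted: bool = False, fit_pops=None) -> pd.DataFrame:
    """RONA against a common-garden environment (space-for-time).

    Identical computation to :func:`rona` with the future environment of
    every population replaced by the scalar ``garden_env``.
    """
    garden = pd.Series(float(garden_env), index=pop_freqs.columns)
    return rona(pop_freqs, env_now, garden, env_var=env_var,
                scenario="garden", use_fitted=use_fitted, fit_pops=fit_pops)
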