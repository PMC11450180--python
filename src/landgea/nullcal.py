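"""Randomization-based significance calibration for GEA scans.

The population-to-environment assignment is permuted (equivalent to
randomizing the population coordinates while keeping the genotypes and
their structure intact), the association scan is re-run on the permuted
data, and the ratio of random to real hit counts across a -log10(p)
threshold grid yields data-driven significance thresholds: the value of
t at which random data produce only 5% (or 50%) as many associations as
the real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def randomize_environment(populations: pd.DataFrame, env: pd.DataFrame,
                          seed: int = 0) -> pd.DataFrame:
    """Permute the population -> environment assignment.

    The entire environment row block of each population (all variables,
    all scenarios) moves together, preserving inter-variable
    correlations; genotypes are untouched.  A plain uniform permutation
    (derangement not enforced), deterministic per seed.
    """
    pops = list(populations["pop_id"])
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pops))
    mapping = {pops[i]: pops[perm[i]] for i in range(len(pops))}
    out = env.copy()
    out["pop_id"] = out["pop_id"].map(lambda p: mapping.get(p, p))
    return out


@dataclass
class CalibrationResult:
    """Real-vs-random hit-ratio curve and derived thresholds."""

    grid: np.ndarray            # -log10 p thresholds
    real_hits: np.ndarray
    rand_hits_mean: np.ndarray
    ratio: np.ndarray           # rand/real, NaN where real_hits == 0
    t_5pct: float | None
    t_50pct: float | None
    n_randomizations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.grid, "real_hits": self.real_hits,
                             "rand_hits_mean": self.rand_hits_mean,
                             "ratio": self.ratio})


def ratio_curve(p_real, p_rand_list, grid_step: float = 0.1) -> CalibrationResult:
    """Hit-count ratio curve over a -log10(p) grid.

    At each grid point t, ``real_hits = #{p_real <= 10^-t}`` and
    ``rand_hits_mean`` is the mean of the same count over the
    randomized runs; ``ratio = rand_hits_mean / real_hits`` (NaN where
    the real count is zero).
    """
    p_real = np.asarray(p_real, dtype=float)
    p_rand_list = [np.asarray(p, dtype=float) for p in p_rand_list]
    if p_real.size == 0 or not p_rand_list:
        raise ValueError("empty inputs")
    for p in p_rand_list:
        if p.size != p_real.size:
            raise ValueError("randomized p vector length mismatch")
    t_max = max(1.0, float(-np.log10(p_real.min())))
    grid = np.arange(1.0, t_max + grid_step / 2.0, grid_step)
    thresholds = 10.0 ** (-grid)
    real = (p_real[None, :] <= thresholds[:, None]).sum(axis=1).astype(float)
    rand = np.mean(
        [(p[None, :] <= thresholds[:, None]).sum(axis=1) for p in p_rand_list],
        axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(real > 0, rand / real, np.nan)
    cr = CalibrationResult(grid=grid, real_hits=real, rand_hits_mean=rand,
                           ratio=ratio, t_5pct=None, t_50pct=None,
                           n_randomizations=len(p_rand_list))
    cr.t_5pct = threshold_at(cr, 0.05)
    cr.t_50pct = threshold_at(cr, 0.5)
    return cr


def threshold_at(cr: CalibrationResult, target: float) -> float | None:
    """Smallest grid t whose ratio stays at or below ``target`` from t on.

    Monotone-envelope rule: undefined entries (zero real hits) impose no
    constraint.  Returns None when no such t exists.
    """
    ratio = cr.ratio
    ok = np.isfinite(ratio)
    # suffix condition: all defined ratios at >= t are <= target
    good_from = np.ones(len(ratio) + 1, dtype=bool)
    for i in range(len(ratio) - 1, -1, -1):
        good_from[i] = good_from[i + 1] and (not ok[i] or ratio[i] <= target)
    idx = np.flatnonzero(good_from[:-1])
    if idx.size == 0:
        return None
    return float(cr.grid[idx[0]])
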