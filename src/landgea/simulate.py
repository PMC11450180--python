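"""Synthetic landscape generator.

Emulates the statistical structure of a range-wide forest-tree
resequencing study: populations scattered over a geographic extent,
spatially autocorrelated allele frequencies (isolation-by-distance via a
Gaussian-process logit-frequency field), environmental clines correlated
with geography, a minority of clinal adaptive loci, within-population
full-sib pairs, deleterious/synonymous annotation classes for load
analyses, and a polygenic phenotype with controlled heritability.

The generator's defaults define the study conditions used throughout the
test suite; they are not tuning knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import MISSING, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km (Earth radius 6371.0 km).

    Accepts scalars or broadcastable arrays of degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def distance_matrix_km(lon, lat) -> np.ndarray:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


@dataclass
class EnvDef:
    """A synthetic environmental variable: linear geographic cline + noise."""

    name: str
    a_lat: float
    a_lon: float
    noise_sd: float


def _default_env_defs():
    # Coefficients scale the geographic cline to roughly unit SD over the
    # default extent (lat SD 4.3 deg, lon SD 11.5 deg); noise_sd sets the
    # non-geographic share of variance.  Interpolated bioclim surfaces over
    # complex terrain keep a large local component (elevation lapse rates,
    # coastality, orographic precipitation), so a linear lat/lon trend
    # realistically explains only ~50-60% of the variance.
    return [
        EnvDef("bio6", a_lat=-0.23, a_lon=-0.02, noise_sd=0.8),
        EnvDef("bio3", a_lat=0.02, a_lon=0.087, noise_sd=1.0),
        EnvDef("bio12", a_lat=0.12, a_lon=-0.045, noise_sd=1.0),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic landscape.

    Defaults give ~60 populations x 8 diploids, 5,000 neutral + 25
    adaptive + 300 deleterious + 300 synonymous variants on 12
    chromosomes, strong isolation-by-distance and clinal adaptive loci.
    """

    n_pops: int = 60
    inds_per_pop: int = 8
    n_neutral: int = 5000
    n_adaptive: int = 25
    n_deleterious: int = 300
    n_synonymous: int = 300
    lon_range: tuple = (0.0, 40.0)
    lat_range: tuple = (40.0, 55.0)
    gp_range: float = 0.3       # correlation length, fraction of extent diagonal
    gp_sill: float = 1.0        # logit-scale GP variance
    adaptive_slope: float = 0.8  # logit-frequency change per SD of env
    adaptive_env: str = "bio6"   # variable driving the planted loci
    adaptive_cluster_size: int = 5  # planted loci per shared 10-kb window
    env_defs: list = field(default_factory=_default_env_defs)
    future_delta_sd: float = 1.0  # future scenario shift, SD units per variable
    sibling_pair_fraction: float = 0.1
    missing_rate: float = 0.02
    h2: float = 0.5
    n_causal: int = 50           # neutral loci underlying the phenotype
    ancestral_flip_rate: float = 0.1
    depth_mode: float = 40.0
    depth_sd: float = 8.0
    n_chroms: int = 12
    mean_spacing_bp: int = 2000  # average inter-variant spacing
    window_bp: int = 10000
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pops", "inds_per_pop", "n_neutral", "n_adaptive",
                     "n_deleterious", "n_synonymous"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gp_range <= 0:
            raise ValueError("gp_range must be > 0")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        total = self.n_neutral + self.n_adaptive + self.n_deleterious + self.n_synonymous
        if self.n_adaptive > total or total == 0:
            raise ValueError("infeasible variant counts")

    @property
    def n_variants(self) -> int:
        return self.n_neutral + self.n_adaptive + self.n_deleterious + self.n_synonymous


@dataclass
class SimulatedDataset:
    """Everything one simulation produces, including ground truth."""

    gm: GenotypeMatrix
    populations: pd.DataFrame     # pop_id, lon, lat
    env: pd.DataFrame             # long form: pop_id, scenario, var, value
    annotations: pd.DataFrame     # chrom, pos, effect, ancestral
    phenotypes: pd.DataFrame      # ind_id, trait, year, value
    truth: pd.DataFrame           # per variant: class, adaptive, beta, ancestral, dp, ...
    kin_pairs: pd.DataFrame       # ind_id_1, ind_id_2, relation
    dp: np.ndarray                # per-variant simulated depth
    pop_freqs: pd.DataFrame       # true per-population ALT frequencies (variants x pops)


def _place_variants(cfg: SimConfig, rng: np.random.Generator):
    """Lay out variant positions and classes along the genome.

    Adaptive loci are planted in clusters sharing a 10-kb window to
    emulate a locally adaptive haplotype block; all other classes are
    scattered uniformly.
    """
    m = cfg.n_variants
    per_chrom = np.full(cfg.n_chroms, m // cfg.n_chroms)
    per_chrom[: m % cfg.n_chroms] += 1
    chrom_len = int(max(per_chrom.max(), 1) * cfg.mean_spacing_bp + cfg.window_bp)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    # adaptive clusters first, so their windows are known
    n_clusters = math.ceil(cfg.n_adaptive / cfg.adaptive_cluster_size) if cfg.n_adaptive else 0
    cluster_pos = {}  # chrom -> set of positions
    remaining = cfg.n_adaptive
    adaptive_records = []
    for c in range(n_clusters):
        size = min(cfg.adaptive_cluster_size, remaining)
        remaining -= size
        chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
        w0 = int(rng.integers(0, chrom_len // cfg.window_bp)) * cfg.window_bp + 1
        offs = rng.choice(cfg.window_bp, size=size, replace=False)
        for p in np.sort(offs):
            pos = int(w0 + p)
            cluster_pos.setdefault(chrom, set()).add(pos)
            adaptive_records.append((chrom, pos))
    adaptive_set = {(c, p) for c, p in adaptive_records}

    records = []
    n_other = m - cfg.n_adaptive
    other_per_chrom = np.full(cfg.n_chroms, n_other // cfg.n_chroms)
    other_per_chrom[: n_other % cfg.n_chroms] += 1
    for ci, chrom in enumerate(chrom_names):
        taken = cluster_pos.get(chrom, set())
        k = int(other_per_chrom[ci])
        pos = set()
        while len(pos) < k:
            draw = rng.integers(1, chrom_len + 1, size=2 * (k - len(pos)))
            for p in draw:
                p = int(p)
                if p not in taken and p not in pos:
                    pos.add(p)
                    if len(pos) == k:
                        break
        for p in sorted(pos | taken):
            records.append((chrom, p))

    variants = pd.DataFrame(records, columns=["chrom", "pos"])
    classes = np.array(["neutral"] * len(variants), dtype=object)
    is_adaptive = np.array(
        [(c, p) in adaptive_set for c, p in zip(variants["chrom"], variants["pos"])]
    )
    classes[is_adaptive] = "adaptive"
    other_idx = np.flatnonzero(~is_adaptive)
    shuffled = rng.permutation(other_idx)
    classes[shuffled[: cfg.n_deleterious]] = "deleterious"
    classes[shuffled[cfg.n_deleterious: cfg.n_deleterious + cfg.n_synonymous]] = "synonymous"
    variants["cls"] = classes
    variants["ref"] = "A"
    variants["alt"] = "T"
    variants["id"] = [f"{c}:{p}" for c, p in zip(variants["chrom"], variants["pos"])]
    return variants


def simulate_landscape(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Generate a full synthetic dataset. Bit-identical for a fixed seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_pops, n_ind = cfg.n_pops, cfg.n_pops * cfg.inds_per_pop

    # (1) populations uniform over the extent
    lon = rng.uniform(*cfg.lon_range, size=n_pops)
    lat = rng.uniform(*cfg.lat_range, size=n_pops)
    pop_ids = [f"P{i + 1:03d}" for i in range(n_pops)]
    populations = pd.DataFrame({"pop_id": pop_ids, "lon": lon, "lat": lat})

    # (3) environmental clines, standardized over populations
    env_rows = []
    env_std = {}
    for ed in cfg.env_defs:
        raw = ed.a_lat * lat + ed.a_lon * lon + rng.normal(0.0, ed.noise_sd, size=n_pops)
        std = (raw - raw.mean()) / raw.std(ddof=0)
        env_std[ed.name] = std
        env_rows.append(pd.DataFrame(
            {"pop_id": pop_ids, "scenario": "current", "var": ed.name, "value": std}))
        env_rows.append(pd.DataFrame(
            {"pop_id": pop_ids, "scenario": "future", "var": ed.name,
             "value": std + cfg.future_delta_sd}))
    env = pd.concat(env_rows, ignore_index=True)

    # variant layout
    variants = _place_variants(cfg, rng)
    m = len(variants)
    cls = variants["cls"].to_numpy()
    field_mask = np.isin(cls, ("neutral", "adaptive"))  # GP-structured classes

    # (2) GP logit-frequency field with exponential covariance
    d = distance_matrix_km(lon, lat)
    diag_km = great_circle_km(cfg.lon_range[0], cfg.lat_range[0],
                              cfg.lon_range[1], cfg.lat_range[1])
    cov = cfg.gp_sill * np.exp(-d / (cfg.gp_range * diag_km))
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(n_pops))

    n_field = int(field_mask.sum())
    mu = logit(rng.uniform(0.05, 0.95, size=n_field))
    gp = L @ rng.standard_normal((n_pops, n_field))
    logit_freq = mu[None, :] + gp  # pops x field variants

    # (4) clinal shift on planted adaptive loci
    drive = env_std[cfg.adaptive_env]
    adaptive_in_field = cls[field_mask] == "adaptive"
    logit_freq[:, adaptive_in_field] += cfg.adaptive_slope * drive[:, None]
    p_field = expit(logit_freq)

    # (7) load classes: spatially unstructured derived frequencies;
    # ancestral = REF except for a fraction of flipped sites (ALT ancestral)
    ancestral = np.array(["unknown"] * m, dtype=object)
    p_pop = np.empty((n_pops, m))
    p_pop[:, field_mask] = p_field
    derived_q = np.full(m, np.nan)
    for name, a, b in (("deleterious", 0.5, 5.0), ("synonymous", 0.8, 0.8)):
        idx = np.flatnonzero(cls == name)
        q = rng.beta(a, b, size=idx.size)
        flip = rng.random(idx.size) < cfg.ancestral_flip_rate
        ancestral[idx] = np.where(flip, "alt", "ref")
        alt_freq = np.where(flip, 1.0 - q, q)
        derived_q[idx] = q
        p_pop[:, idx] = alt_freq[None, :]

    # (5) genotypes ~ Binomial(2, p_pop)
    pop_of_ind = np.repeat(np.arange(n_pops), cfg.inds_per_pop)
    G = rng.binomial(2, p_pop[pop_of_ind, :]).astype(np.int8)

    # (6) full-sib pairs in a fraction of populations
    n_sib_pops = int(round(cfg.sibling_pair_fraction * n_pops))
    sib_pops = rng.choice(n_pops, size=n_sib_pops, replace=False)
    kin_rows = []
    for sp in sib_pops:
        parents = rng.binomial(2, p_pop[sp, :], size=(2, m))
        for child_slot in range(2):
            t1 = rng.random(m) < parents[0] / 2.0
            t2 = rng.random(m) < parents[1] / 2.0
            G[sp * cfg.inds_per_pop + child_slot, :] = (t1.astype(np.int8) + t2.astype(np.int8))
        kin_rows.append((sp, 0, 1, "full_sib"))

    ind_ids = [f"{pop_ids[p]}_i{k + 1}" for p in range(n_pops) for k in range(cfg.inds_per_pop)]
    kin_pairs = pd.DataFrame(
        [(f"{pop_ids[p]}_i{a + 1}", f"{pop_ids[p]}_i{b + 1}", rel) for p, a, b, rel in kin_rows],
        columns=["ind_id_1", "ind_id_2", "relation"],
    )

    # (8) phenotype from 50 causal neutral loci, exact realized heritability
    neutral_idx = np.flatnonzero(cls == "neutral")
    causal = rng.choice(neutral_idx, size=min(cfg.n_causal, neutral_idx.size), replace=False)
    effects = rng.standard_normal(causal.size)
    g_score = G[:, causal].astype(float) @ effects
    e = rng.standard_normal(n_ind)
    e = (e - e.mean()) / e.std(ddof=0)
    var_g = g_score.var(ddof=0)
    if cfg.h2 in (0.0, 1.0):
        sd_e = 0.0 if cfg.h2 == 1.0 else 1.0
        g_score = g_score if cfg.h2 == 1.0 else np.zeros(n_ind)
    else:
        sd_e = math.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2)
    y = g_score + sd_e * e
    phenotypes = pd.DataFrame(
        {"ind_id": ind_ids, "trait": "growth", "year": 2022, "value": y})

    # (9) per-variant depth, truncated normal
    dp = np.maximum(1.0, rng.normal(cfg.depth_mode, cfg.depth_sd, size=m))

    # missingness applied after phenotype construction
    if cfg.missing_rate > 0:
        mask = rng.random(G.shape) < cfg.missing_rate
        G[mask] = MISSING

    individuals = pd.DataFrame(
        {"ind_id": ind_ids, "pop_id": np.repeat(pop_ids, cfg.inds_per_pop)})
    gm = GenotypeMatrix(G, variants[["chrom", "pos", "ref", "alt", "id"]], individuals)

    effect = np.where(np.isin(cls, ("deleterious", "synonymous")), cls, "other")
    annotations = pd.DataFrame(
        {"chrom": variants["chrom"], "pos": variants["pos"],
         "effect": effect, "ancestral": ancestral})

    beta = np.where(cls == "adaptive", cfg.adaptive_slope, 0.0)
    eff_size = np.zeros(m)
    eff_size[causal] = effects
    truth = pd.DataFrame(
        {"id": variants["id"], "chrom": variants["chrom"], "pos": variants["pos"],
         "cls": cls, "adaptive": cls == "adaptive", "beta": beta,
         "ancestral": ancestral, "causal": np.isin(np.arange(m), causal),
         "effect_size": eff_size, "dp": dp, "derived_q": derived_q})

    pop_freqs = pd.DataFrame(p_pop.T, index=variants["id"], columns=pop_ids)

    return SimulatedDataset(gm=gm, populations=populations, env=env,
                            annotations=annotations, phenotypes=phenotypes,
                            truth=truth, kin_pairs=kin_pairs, dp=dp,
                            pop_freqs=pop_freqs)
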