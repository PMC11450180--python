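"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`GenotypeMatrix`: an individuals x variants
matrix of ALT-allele dosages (0, 1, 2) with a reserved sentinel for
uncalled genotypes, plus variant and individual metadata frames.
Population, environment, annotation and phenotype tables are plain
pandas DataFrames with fixed column schemas validated by the helpers in
:mod:`landgea.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an uncalled genotype.  Every downstream operation must
#: branch on it explicitly; it is never a valid dosage.
MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]
INDIVIDUAL_COLUMNS = ["ind_id", "pop_id"]


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes coded as ALT-allele dosage per (individual, variant).

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_variants)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    variants
        DataFrame with columns ``chrom, pos, ref, alt, id``; ``pos`` is
        1-based and strictly increasing within each chromosome.
    individuals
        DataFrame with columns ``ind_id, pop_id``; ``ind_id`` unique.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        if not np.issubdtype(self.genotypes.dtype, np.integer):
            raise ValueError("genotypes must be integer-typed")
        self.genotypes = self.genotypes.astype(np.int8, copy=False)
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} genotype entries outside {{0,1,2,{MISSING}}}"
            )
        self.variants = pd.DataFrame(self.variants).reset_index(drop=True)
        self.individuals = pd.DataFrame(self.individuals).reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variants table lacks columns {missing_cols}")
        for c in INDIVIDUAL_COLUMNS:
            if c not in self.individuals.columns:
                raise ValueError(f"individuals table lacks column {c!r}")
        if len(self.variants) != self.genotypes.shape[1]:
            raise ValueError("variant table length does not match genotype columns")
        if len(self.individuals) != self.genotypes.shape[0]:
            raise ValueError("individual table length does not match genotype rows")
        if self.individuals["ind_id"].duplicated().any():
            dup = self.individuals["ind_id"][self.individuals["ind_id"].duplicated()]
            raise ValueError(f"duplicate ind_id: {sorted(set(dup))}")
        # positions strictly increasing within each chromosome, in record order
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("positions not strictly increasing within chromosome")

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def pop_ids(self) -> np.ndarray:
        """Unique population ids in order of first appearance."""
        return self.individuals["pop_id"].unique()

    def called_mask(self) -> np.ndarray:
        """Boolean mask of called genotypes, same shape as ``genotypes``."""
        return self.genotypes != MISSING

    # -- subsetting ----------------------------------------------------------

    def subset(self, ind_idx=None, var_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given positional indices."""
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        var_idx = np.arange(self.n_variants) if var_idx is None else np.asarray(var_idx)
        if ind_idx.dtype == bool:
            ind_idx = np.flatnonzero(ind_idx)
        if var_idx.dtype == bool:
            var_idx = np.flatnonzero(var_idx)
        return GenotypeMatrix(
            self.genotypes[np.ix_(ind_idx, var_idx)].copy(),
            self.variants.iloc[var_idx].reset_index(drop=True),
            self.individuals.iloc[ind_idx].reset_index(drop=True),
        )

    def with_populations(self, mapping) -> "GenotypeMatrix":
        """Attach population ids from a ``{ind_id: pop_id}`` mapping."""
        ind = self.individuals.copy()
        unknown = [i for i in ind["ind_id"] if i not in mapping]
        if unknown:
            raise KeyError(f"no population for individuals {unknown[:5]}")
        ind["pop_id"] = [mapping[i] for i in ind["ind_id"]]
        return GenotypeMatrix(self.genotypes.copy(), self.variants, ind)

    def __eq__(self, other) -> bool:  # dosage-level equality
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.variants[VARIANT_COLUMNS].astype(str).equals(
                other.variants[VARIANT_COLUMNS].astype(str)
            )
            and list(self.individuals["ind_id"]) == list(other.individuals["ind_id"])
        )


def allele_frequencies(gm: GenotypeMatrix, by: str = "all") -> pd.DataFrame:
    """ALT-allele frequency per variant, overall or per population.

    ``freq = (n_het + 2 * n_hom_alt) / (2 * n_called)`` per group; groups
    with no called genotype at a variant get ``NaN``.

    Parameters
    ----------
    gm : GenotypeMatrix
    by : {"all", "population"}

    Returns
    -------
    DataFrame indexed like ``gm.variants`` with one column per group
    (``"all"`` or one per ``pop_id``).
    """
    g = gm.genotypes
    called = g != MISSING
    dose = np.where(called, g, 0)

    def _freq(rows: np.ndarray) -> np.ndarray:
        n_called = called[rows].sum(axis=0)
        alt = dose[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = alt / (2.0 * n_called)
        return np.where(n_called > 0, f, np.nan)

    if by == "all":
        out = {"all": _freq(np.arange(gm.n_individuals))}
    elif by == "population":
        pops = gm.individuals["pop_id"].to_numpy()
        out = {}
        for pop in gm.pop_ids:
            out[pop] = _freq(np.flatnonzero(pops == pop))
    else:
        raise ValueError(f"unknown grouping {by!r}")
    return pd.DataFrame(out, index=gm.variants.index)


@dataclass
class DistanceMatrix:
    """Symmetric population-level distance matrix with labels.

    ``kind`` tags the metric (``fst``, ``km`` or ``env``).  FST matrices
    may carry slightly negative off-diagonal entries (estimator property);
    they are retained, not clipped.
    """

    labels: list
    values: np.ndarray
    kind: str = "km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reordered(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)
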