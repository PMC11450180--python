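"""Derived-allele polarization and genetic load statistics.

Variants are polarized to derived dosage using the ancestral-allele
annotation (ancestral = ALT flips the dosage); per-individual recessive
and additive load are counts of derived deleterious variants (homozygous
or total) normalized by the synonymous analogues, which adjusts for
heterozygosity and missingness differences between individuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix


def polarize(gm: GenotypeMatrix, annotations: pd.DataFrame):
    """Convert ALT dosage to derived-allele dosage.

    ``ancestral == 'ref'`` keeps the dosage, ``'alt'`` maps it to
    ``2 - dosage`` (missing stays missing); variants with unknown or
    absent ancestral state are masked out.

    Returns
    -------
    (derived, usable, effects)
        derived : int8 matrix of derived dosages (MISSING preserved)
        usable : boolean per-variant mask (known ancestral state)
        effects : per-variant effect class aligned to ``gm.variants``
            ("other" where unannotated)
    """
    key = pd.MultiIndex.from_frame(gm.variants[["chrom", "pos"]])
    ann = annotations.set_index(["chrom", "pos"])
    unmatched = ann.index.difference(key)
    if len(unmatched) > 0:
        warnings.warn(f"{len(unmatched)} annotation rows without matching variant; ignored")
    ann = ann.loc[ann.index.intersection(key)]
    ancestral = pd.Series("unknown", index=key)
    effects = pd.Series("other", index=key)
    ancestral.loc[ann.index] = ann["ancestral"]
    effects.loc[ann.index] = ann["effect"]

    anc = ancestral.to_numpy()
    usable = np.isin(anc, ("ref", "alt"))
    derived = gm.genotypes.copy()
    flip = anc == "alt"
    miss = derived == MISSING
    derived[:, flip] = 2 - derived[:, flip]
    derived[miss] = MISSING
    return derived, usable, effects.to_numpy()


def genetic_load(derived: np.ndarray, effects: np.ndarray, usable: np.ndarray,
                 individuals: pd.DataFrame,
                 recessive_denominator: str = "homozygous") -> dict:
    """Per-individual and per-population recessive/additive load.

    recessive_load = (# derived homozygotes at deleterious sites) /
    (# derived homozygotes at synonymous sites); additive_load = (sum of
    derived dosages at deleterious sites) / (same at synonymous sites).
    Counts use only each individual's called sites; zero denominators
    yield NaN with a warning.

    ``recessive_denominator='total'`` divides the recessive numerator by
    the total synonymous derived-allele count instead (the normalization
    is ambiguous in common usage; homozygous-synonymous is the default).
    """
    eff = np.asarray(effects, dtype=object)
    del_idx = np.flatnonzero(usable & (eff == "deleterious"))
    syn_idx = np.flatnonzero(usable & (eff == "synonymous"))
    if del_idx.size == 0 or syn_idx.size == 0:
        raise ValueError("need at least one usable deleterious and synonymous variant")

    def counts(cols):
        sub = derived[:, cols]
        called = sub != MISSING
        hom = ((sub == 2) & called).sum(axis=1)
        alleles = np.where(called, sub, 0).sum(axis=1)
        return hom, alleles

    hom_del, alleles_del = counts(del_idx)
    hom_syn, alleles_syn = counts(syn_idx)
    rec_den = hom_syn if recessive_denominator == "homozygous" else alleles_syn

    with np.errstate(invalid="ignore", divide="ignore"):
        recessive = np.where(rec_den > 0, hom_del / rec_den, np.nan)
        additive = np.where(alleles_syn > 0, alleles_del / alleles_syn, np.nan)
    if np.isnan(recessive).any() or np.isnan(additive).any():
        warnings.warn("individuals with zero synonymous denominator: load set to NaN")

    ind = pd.DataFrame({
        "ind_id": individuals["ind_id"], "pop_id": individuals["pop_id"],
        "n_hom_del": hom_del, "n_del_alleles": alleles_del,
        "n_hom_syn": hom_syn, "n_syn_alleles": alleles_syn,
        "recessive_load": recessive, "additive_load": additive,
    })
    pops = (ind.groupby("pop_id", sort=False)[["recessive_load", "additive_load"]]
            .mean().reset_index())
    return {"individuals": ind, "populations": pops}
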