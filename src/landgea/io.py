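"""Readers and writers for the pipeline's external formats.

VCF parsing goes through cyvcf2; only the GT subfield is consumed.  The
remaining formats are tab-delimited tables with a header row:

* populations: ``pop_id  lon  lat  [label]``
* environment (long form): ``pop_id  scenario  var  value``
* annotations: ``chrom  pos  effect  ancestral``
* phenotypes: ``ind_id  trait  year  value``
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

ENV_SCENARIOS = ("current", "future", "garden")
EFFECTS = ("synonymous", "deleterious", "other")
ANCESTRAL = ("ref", "alt", "unknown")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, biallelic_only: bool = True, pop_map=None) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT in FORMAT) into a :class:`GenotypeMatrix`.

    Dosage is the number of ALT alleles; ``./.`` and half-calls such as
    ``0/.`` map to the missing sentinel.  Phasing separators are ignored.
    Multi-allelic records are dropped when ``biallelic_only`` and raise
    otherwise.  Record order is preserved exactly.

    Parameters
    ----------
    path : str or Path
    biallelic_only : bool
        Drop records with more than one ALT allele instead of raising.
    pop_map : mapping, optional
        ``{ind_id: pop_id}``; individuals without a mapping get ``""``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows = []
    meta = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if biallelic_only:
                continue
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} with biallelic_only=False"
            )
        dosages = np.empty(len(samples), dtype=np.int8)
        for k, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid GT for sample {samples[k]} at {rec.CHROM}:{rec.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dosages[k] = MISSING
            else:
                dosages[k] = alleles[0] + alleles[1]
        rows.append(dosages)
        meta.append(
            (rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.ID or f"{rec.CHROM}:{rec.POS}")
        )
    vcf.close()

    genotypes = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt", "id"])
    pop_map = pop_map or {}
    individuals = pd.DataFrame(
        {"ind_id": samples, "pop_id": [pop_map.get(s, "") for s in samples]}
    )
    return GenotypeMatrix(genotypes, variants, individuals)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> str:
    """Write a minimal VCF v4.2 (CHROM..FORMAT + GT) for ``gm``.

    Round-trips through :func:`read_vcf` at dosage-level equality.
    """
    chroms = list(dict.fromkeys(gm.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            sub = gm.variants.loc[gm.variants["chrom"] == c, "pos"]
            fh.write(f"##contig=<ID={c},length={int(sub.max()) + 1 if len(sub) else 1}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(gm.individuals["ind_id"])
        fh.write("\t".join(header) + "\n")
        G = gm.genotypes
        for j, v in gm.variants.iterrows():
            fields = [
                str(v["chrom"]), str(int(v["pos"])), str(v["id"]),
                str(v["ref"]), str(v["alt"]), ".", "PASS", ".", "GT",
            ]
            fields += [_GT_STR[int(g)] for g in G[:, j]]
            fh.write("\t".join(fields) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_populations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pop_id": str})
    _require(df, ["pop_id", "lon", "lat"], "populations")
    if df["pop_id"].duplicated().any():
        raise ValueError("duplicate pop_id in populations table")
    if not df["lon"].between(-180, 180).all() or not df["lat"].between(-90, 90).all():
        raise ValueError("coordinates out of range")
    return df


def read_env(path) -> pd.DataFrame:
    """Long-form environment table: one row per (pop_id, scenario, var)."""
    df = pd.read_csv(path, sep="\t", dtype={"pop_id": str, "scenario": str, "var": str})
    _require(df, ["pop_id", "scenario", "var", "value"], "env")
    bad = set(df["scenario"]) - set(ENV_SCENARIOS)
    if bad:
        raise ValueError(f"unknown scenarios {sorted(bad)}")
    if df.duplicated(["pop_id", "scenario", "var"]).any():
        raise ValueError("duplicate (pop_id, scenario, var) rows in env table")
    return df


def env_matrix(env: pd.DataFrame, scenario: str = "current") -> pd.DataFrame:
    """Pivot the long env table into a pops x variables matrix for one scenario."""
    sub = env[env["scenario"] == scenario]
    if sub.empty:
        raise ValueError(f"no env rows for scenario {scenario!r}")
    wide = sub.pivot(index="pop_id", columns="var", values="value")
    if wide.isna().any().any():
        raise ValueError(f"variable set not identical across populations ({scenario})")
    return wide


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "effect": str, "ancestral": str})
    _require(df, ["chrom", "pos", "effect", "ancestral"], "annotations")
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("more than one annotation row per variant")
    if not set(df["effect"]) <= set(EFFECTS):
        raise ValueError("effect must be synonymous/deleterious/other")
    if not set(df["ancestral"]) <= set(ANCESTRAL):
        raise ValueError("ancestral must be ref/alt/unknown")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ind_id": str, "trait": str})
    _require(df, ["ind_id", "trait", "year", "value"], "phenotypes")
    if df.duplicated(["ind_id", "trait", "year"]).any():
        raise ValueError("duplicate (ind_id, trait, year)")
    return df


def write_table(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def _require(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table lacks columns {missing}")
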