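"""Text formats: PLINK-1 ped/map, dosage TSV, pedigree TSV, phenotype TSV,
association TSV, and the YAML pipeline configuration.

All tabular formats are tab-delimited with a mandatory header row (except
PLINK, whose layout is fixed) and use "NA" as the missing-data sentinel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ailrep.core import GenotypeMatrix
from ailrep.simdata import Pedigree

NA = "NA"


# ----------------------------------------------------------------------
# Dosage TSV  (rows = SNPs: snp_id, chrom, pos, [cm, dosage_r2,] samples...)
# ----------------------------------------------------------------------

_META_COLS = ["snp_id", "chrom", "pos", "cm", "a0", "a1", "dosage_r2", "trait_proxy"]


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    meta = [c for c in _META_COLS if c in genotypes.snp_map.columns]
    dose = pd.DataFrame(genotypes.dosages.T, columns=genotypes.sample_ids)
    df = pd.concat([genotypes.snp_map[meta].reset_index(drop=True), dose], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[NA], dtype={"chrom": str})
    meta = [c for c in _META_COLS if c in df.columns]
    samples = [c for c in df.columns if c not in meta]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, df[meta], samples)


# ----------------------------------------------------------------------
# PLINK-1 text (.ped/.map), alleles A/B
# ----------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Hard-call PLINK text pair; fractional dosages are rounded."""
    prefix = Path(prefix)
    gmap = genotypes.snp_map
    cm = gmap["cm"] if "cm" in gmap.columns else pd.Series(0.0, index=gmap.index)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for i in range(len(gmap)):
            fh.write(
                f"{gmap['chrom'].iloc[i]}\t{gmap['snp_id'].iloc[i]}\t"
                f"{float(cm.iloc[i])}\t{int(gmap['pos'].iloc[i])}\n"
            )
    a0 = gmap["a0"] if "a0" in gmap.columns else pd.Series("A", index=gmap.index)
    a1 = gmap["a1"] if "a1" in gmap.columns else pd.Series("B", index=gmap.index)
    calls = {0: lambda i: (a0.iloc[i], a0.iloc[i]),
             1: lambda i: (a0.iloc[i], a1.iloc[i]),
             2: lambda i: (a1.iloc[i], a1.iloc[i])}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for s, sid in enumerate(genotypes.sample_ids):
            fields = ["FAM", sid, "0", "0", "0", "-9"]
            for i in range(genotypes.n_snps):
                d = genotypes.dosages[s, i]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    g1, g2 = calls[int(round(d))](i)
                    fields += [g1, g2]
            fh.write("\t".join(fields) + "\n")


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    gmap = pd.read_csv(
        prefix.with_suffix(".map"), sep="\t", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    gmap["a0"], gmap["a1"] = "A", "B"
    dosages, samples = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            samples.append(fields[1])
            alleles = fields[6:]
            row = np.empty(len(gmap))
            for i in range(len(gmap)):
                g1, g2 = alleles[2 * i], alleles[2 * i + 1]
                row[i] = np.nan if g1 == "0" else (g1 == "B") + (g2 == "B")
            dosages.append(row)
    cols = ["snp_id", "chrom", "pos", "cm", "a0", "a1"]
    return GenotypeMatrix(np.array(dosages), gmap[cols], samples)


# ----------------------------------------------------------------------
# Pedigree / phenotype / association TSVs
# ----------------------------------------------------------------------

def write_pedigree_tsv(pedigree: Pedigree, path) -> None:
    df = pedigree.df.copy()
    for col in ("sire_id", "dam_id"):
        df[col] = df[col].map(lambda v: "0" if v is None else v)
    df.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["generation"] = df["generation"].astype(int)
    return Pedigree(df)


def write_phenotype_tsv(pheno: pd.DataFrame, path) -> None:
    if pheno.columns[0] != "individual_id":
        raise ValueError("first phenotype column must be individual_id")
    pheno.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], dtype={"individual_id": str})


ASSOC_TSV_COLUMNS = {
    "chrom": "chr", "snp_id": "rs", "pos": "ps", "n_obs": "n_obs",
    "af": "af", "beta": "beta", "se": "se", "p": "p_wald",
    "neg_log10_p": "neg_log10_p",
}


def write_assoc_tsv(assoc: pd.DataFrame, path) -> None:
    """Association table with GEMMA-like column names."""
    out = assoc[list(ASSOC_TSV_COLUMNS)].rename(columns=ASSOC_TSV_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_assoc_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], dtype={"chr": str})
    inverse = {v: k for k, v in ASSOC_TSV_COLUMNS.items()}
    return df.rename(columns=inverse)


def write_kinship_tsv(kinship: pd.DataFrame, path) -> None:
    kinship.to_csv(path, sep="\t", na_rep=NA)


def read_kinship_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ----------------------------------------------------------------------
# Config
# ----------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
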