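"""Shared containers: genotype matrices with SNP maps, chromosome naming."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every SNP map must carry.
MAP_COLUMNS = ("snp_id", "chrom", "pos")


def normalize_chrom(chrom) -> str:
    """Normalize a chromosome label to its unprefixed string form.

    Accepts "1".."19", "X" and "chr"-prefixed synonyms; comparison is
    always on the normalized string.
    """
    s = str(chrom)
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass
class GenotypeMatrix:
    """Biallelic dosages for a set of samples with an accompanying SNP map.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_snps)`` with values in ``[0, 2]``
        (alternate-allele dosage); ``NaN`` marks missing calls.
    snp_map
        Data frame with at least ``snp_id``, ``chrom``, ``pos`` columns;
        optional columns include ``cm`` (genetic position), ``a0``/``a1``
        (allele labels), ``dosage_r2`` (imputation quality) and
        ``trait_proxy`` (coat-color proxy flags).
    sample_ids
        One identifier per row of ``dosages``.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x SNPs) array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for "
                f"{self.dosages.shape[0]} dosage rows"
            )
        for col in MAP_COLUMNS:
            if col not in self.snp_map.columns:
                raise ValueError(f"snp_map missing required column {col!r}")
        if len(self.snp_map) != self.dosages.shape[1]:
            raise ValueError(
                f"{len(self.snp_map)} map rows for "
                f"{self.dosages.shape[1]} dosage columns"
            )
        self.snp_map = self.snp_map.reset_index(drop=True).copy()
        self.snp_map["chrom"] = self.snp_map["chrom"].map(normalize_chrom)
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def imputed(self) -> np.ndarray:
        """Dosages with missing values mean-imputed per SNP."""
        out = self.dosages.copy()
        if np.isnan(out).any():
            means = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(np.isnan(out))
            out[idx] = means[idx[1]]
        return out

    def dosage_of(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP id."""
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
        return self.dosages[:, hits[0]]

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            mask = mask_or_ids
        else:
            wanted = set(map(str, mask_or_ids))
            mask = np.array([s in wanted for s in self.snp_ids])
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.snp_map.loc[mask].reset_index(drop=True),
            list(self.sample_ids),
        )

    def subset_samples(self, ids) -> "GenotypeMatrix":
        wanted = [str(i) for i in ids]
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [i for i in wanted if i not in pos]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        rows = [pos[i] for i in wanted]
        return GenotypeMatrix(self.dosages[rows], self.snp_map.copy(), wanted)
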