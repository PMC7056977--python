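"""Sample- and SNP-level quality control.

Sample QC flags heterozygosity outliers, sex mismatches from sex-chromosome
read ratios, pedigree/GRM kinship discordance and coat-color/genotype
discordance. SNP QC applies minor-allele-frequency, Hardy-Weinberg and
imputation-quality filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ailrep.core import GenotypeMatrix

# Default sex-inference intervals for the X/Y read ratio (data-derived
# 95% CIs; override for other platforms).
FEMALE_RATIO_INTERVAL = (196.84, 214.3)
MALE_RATIO_INTERVAL = (2.13, 2.18)

HET_TOL = 1e-9  # a call counts as heterozygous when |dosage - 1| < 0.5


def heterozygosity(genotypes: GenotypeMatrix, chroms: list | None = None) -> pd.Series:
    """Per-sample proportion of heterozygous calls on the given chromosomes.

    ``chroms=None`` means all autosomes (every chromosome except X/Y/MT).
    """
    cmap = genotypes.snp_map["chrom"]
    if chroms is None:
        mask = ~cmap.isin(["X", "Y", "MT", "M"]).to_numpy()
    else:
        mask = cmap.isin([str(c) for c in chroms]).to_numpy()
    d = genotypes.dosages[:, mask]
    het = np.abs(d - 1.0) < 0.5
    ok = ~np.isnan(d)
    counts = ok.sum(axis=1)
    bad = np.flatnonzero(counts == 0)
    if bad.size:
        raise ValueError(
            f"all genotypes missing for sample(s): "
            f"{[genotypes.sample_ids[i] for i in bad]}"
        )
    prop = (het & ok).sum(axis=1) / counts
    return pd.Series(prop, index=genotypes.sample_ids, name="het_prop")


def heterozygosity_filter(genotypes: GenotypeMatrix, k_sd: float = 3.0) -> pd.DataFrame:
    """Flag samples whose autosomal heterozygosity is > ``k_sd`` SDs off the mean."""
    if genotypes.n_samples < 3:
        raise ValueError("heterozygosity filter needs at least 3 samples")
    het = heterozygosity(genotypes)
    mu, sd = het.mean(), het.std(ddof=0)
    flagged = (het - mu).abs() > k_sd * sd
    return pd.DataFrame(
        {"het_prop": het, "het_outlier": flagged.astype(bool)}
    ).rename_axis("individual_id")


def sex_check(
    read_ratios: pd.Series,
    recorded_sex: pd.Series,
    female_interval: tuple = FEMALE_RATIO_INTERVAL,
    male_interval: tuple = MALE_RATIO_INTERVAL,
) -> pd.DataFrame:
    """Infer sex from X/Y read ratios and flag disagreements.

    A ratio inside the female interval infers female, inside the male
    interval infers male, anything else is unassigned (and flagged).
    """
    for lo, hi in (female_interval, male_interval):
        if not lo < hi:
            raise ValueError("interval bounds must satisfy lo < hi")
    f_lo, f_hi = female_interval
    m_lo, m_hi = male_interval
    if max(f_lo, m_lo) < min(f_hi, m_hi):
        raise ValueError("female and male intervals overlap")
    ratios = read_ratios.astype(float)
    if (ratios < 0).any():
        raise ValueError("negative read ratio")
    inferred = pd.Series("unassigned", index=ratios.index, dtype=object)
    inferred[(ratios >= f_lo) & (ratios <= f_hi)] = "female"
    inferred[(ratios >= m_lo) & (ratios <= m_hi)] = "male"
    rec = recorded_sex.reindex(ratios.index).astype(str)
    mismatch = (inferred == "unassigned") | (inferred != rec)
    return pd.DataFrame(
        {
            "read_ratio": ratios,
            "inferred_sex": inferred,
            "recorded_sex": rec,
            "sex_mismatch": mismatch.astype(bool),
        }
    ).rename_axis("individual_id")


def kinship_concordance(
    pedigree_kinship: pd.DataFrame,
    grm: pd.DataFrame,
    delta_max: float = 0.10,
) -> pd.DataFrame:
    """Pairs whose pedigree and genotype relatedness disagree.

    Pedigree kinship is doubled onto the expected-allele-sharing scale of
    a centered GRM before comparison; diagonals are excluded.
    """
    if list(pedigree_kinship.index) != list(grm.index) or list(
        pedigree_kinship.columns
    ) != list(grm.columns):
        raise ValueError("pedigree kinship and GRM cover different samples")
    ids = list(pedigree_kinship.index)
    P = 2.0 * pedigree_kinship.to_numpy()
    G = grm.to_numpy()
    rows = []
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    diff = np.abs(P - G)[iu]
    for k in np.flatnonzero(diff > delta_max):
        i, j = iu[0][k], iu[1][k]
        rows.append(
            {
                "id_a": ids[i],
                "id_b": ids[j],
                "pedigree_relatedness": P[i, j],
                "grm_relatedness": G[i, j],
                "abs_diff": diff[k],
            }
        )
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "pedigree_relatedness", "grm_relatedness", "abs_diff"]
    )


def coat_color_concordance(
    coat: pd.Series,
    genotypes: GenotypeMatrix,
    flanking_snps: list,
) -> pd.DataFrame:
    """Check recorded albino status against albino-locus flanking markers.

    A sample is concordant when its recorded albino code (1 = albino)
    matches homozygosity for the alternate (albino-linked) allele at the
    flanking markers. Samples with all flanking genotypes missing are
    reported as untestable rather than flagged.
    """
    if not flanking_snps:
        raise ValueError("no flanking markers supplied")
    D = np.column_stack([genotypes.dosage_of(s) for s in flanking_snps])
    coat = coat.reindex(genotypes.sample_ids)
    rows = []
    for i, iid in enumerate(genotypes.sample_ids):
        d = D[i]
        ok = ~np.isnan(d)
        if not ok.any():
            rows.append({"individual_id": iid, "testable": False, "coat_discordant": False})
            continue
        homozygous_alt = bool(np.all(d[ok] >= 2.0 - 1e-9))
        recorded_albino = coat.loc[iid] == 1
        rows.append(
            {
                "individual_id": iid,
                "testable": True,
                "coat_discordant": bool(recorded_albino != homozygous_alt),
            }
        )
    return pd.DataFrame(rows).set_index("individual_id")


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square Hardy-Weinberg test p-value from genotype counts."""
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0  # monomorphic: no test possible
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chisq = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chisq, df=1))


def hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    """Vector of HWE p-values, treating dosages as hard calls."""
    out = np.empty(genotypes.n_snps)
    d = genotypes.dosages
    for k in range(genotypes.n_snps):
        col = d[:, k]
        col = col[~np.isnan(col)]
        n_aa = int(np.sum(col < 0.5))
        n_het = int(np.sum(np.abs(col - 1.0) < 0.5))
        n_AA = int(np.sum(col > 1.5))
        out[k] = hwe_test(n_AA, n_het, n_aa) if (n_aa + n_het + n_AA) else 1.0
    return out


def snp_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.1,
    hwe_min: float = 1.0e-6,
    r2_min: float = 0.9,
) -> pd.DataFrame:
    """Per-SNP QC report with a ``kept`` verdict.

    Keeps SNPs with MAF >= ``maf_min``, HWE p >= ``hwe_min``, and (when a
    ``dosage_r2`` column is present in the map) dosage r^2 > ``r2_min``.
    Kept SNPs with HWE p within 10x of the threshold are flagged
    ``hwe_near_threshold`` for manual review.
    """
    maf = genotypes.maf()
    hwe_p = hwe_pvalues(genotypes)
    kept = (maf >= maf_min) & (hwe_p >= hwe_min)
    report = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "maf": maf,
            "hwe_p": hwe_p,
        }
    )
    if "dosage_r2" in genotypes.snp_map.columns:
        r2 = genotypes.snp_map["dosage_r2"].to_numpy(dtype=float)
        report["dosage_r2"] = r2
        kept &= r2 > r2_min
    report["kept"] = kept
    report["hwe_near_threshold"] = kept & (hwe_p < 10.0 * hwe_min)
    return report


def sample_qc(
    genotypes: GenotypeMatrix,
    recorded_sex: pd.Series | None = None,
    read_ratios: pd.Series | None = None,
    pedigree_kinship: pd.DataFrame | None = None,
    grm: pd.DataFrame | None = None,
    coat: pd.Series | None = None,
    flanking_snps: list | None = None,
    k_sd: float = 3.0,
    delta_max: float = 0.10,
) -> pd.DataFrame:
    """Combined sample QC report; ``kept`` is true iff no flag is set.

    Checks whose inputs are absent contribute an all-false flag column.
    """
    report = heterozygosity_filter(genotypes, k_sd=k_sd)
    ids = report.index

    if read_ratios is not None and recorded_sex is not None:
        sexes = sex_check(read_ratios, recorded_sex)
        report = report.join(sexes[["inferred_sex", "sex_mismatch"]])
    else:
        report["sex_mismatch"] = False

    report["kinship_discordant"] = False
    if pedigree_kinship is not None and grm is not None:
        pairs = kinship_concordance(pedigree_kinship, grm, delta_max=delta_max)
        bad = set(pairs["id_a"]) | set(pairs["id_b"])
        report.loc[report.index.isin(bad), "kinship_discordant"] = True

    report["coat_discordant"] = False
    if coat is not None and flanking_snps is not None:
        cc = coat_color_concordance(coat, genotypes, flanking_snps)
        report.loc[cc.index, "coat_discordant"] = cc["coat_discordant"]

    flags = report[
        ["het_outlier", "sex_mismatch", "kinship_discordant", "coat_discordant"]
    ].astype(bool)
    report["kept"] = ~flags.any(axis=1)
    return report.loc[ids]
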