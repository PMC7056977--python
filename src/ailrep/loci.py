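"""Post-GWAS locus definition: LD, clumping, credible sets, conditional scans."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ailrep.core import GenotypeMatrix
from ailrep.lmm import _as_matrix, assoc_scan


def ld_r2(genotypes: GenotypeMatrix, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    xi = genotypes.dosage_of(snp_i)
    xj = genotypes.dosage_of(snp_j)
    ok = ~(np.isnan(xi) | np.isnan(xj))
    xi, xj = xi[ok], xj[ok]
    if np.var(xi) == 0 or np.var(xj) == 0:
        raise ValueError("LD undefined for a monomorphic SNP")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(min(r * r, 1.0))


def _r2_matrix(D: np.ndarray) -> np.ndarray:
    """Pairwise dosage r^2; monomorphic columns give NaN rows/cols."""
    Dc = D - np.nanmean(D, axis=0, keepdims=True)
    Dc = np.where(np.isnan(Dc), 0.0, Dc)
    sd = Dc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Dc / sd
        R = (Z.T @ Z) / D.shape[0]
    return np.clip(R**2, 0.0, 1.0)


def ld_decay(
    genotypes: GenotypeMatrix,
    max_dist: int = 100_000,
    maf_match: float = 0.05,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean pairwise r^2 by physical-distance bin.

    Only same-chromosome pairs within ``max_dist`` bp whose minor allele
    frequencies differ by less than ``maf_match`` contribute.
    """
    maf = genotypes.maf()
    chroms = genotypes.snp_map["chrom"].to_numpy()
    pos = genotypes.snp_map["pos"].to_numpy()
    dists, r2s = [], []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero((chroms == chrom) & (maf > 0))
        if sel.size < 2:
            continue
        R2 = _r2_matrix(genotypes.imputed()[:, sel])
        for a in range(sel.size):
            for b in range(a + 1, sel.size):
                d = abs(int(pos[sel[b]]) - int(pos[sel[a]]))
                if d > max_dist:
                    continue
                if abs(maf[sel[a]] - maf[sel[b]]) >= maf_match:
                    continue
                dists.append(d)
                r2s.append(R2[a, b])
    if not dists:
        warnings.warn("no qualifying SNP pairs for LD decay", stacklevel=2)
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
    dists = np.asarray(dists)
    r2s = np.asarray(r2s)
    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(dists, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            rows.append(
                {
                    "bin_start": edges[b],
                    "bin_end": edges[b + 1],
                    "mean_r2": float(r2s[sel].mean()),
                    "n_pairs": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Clumping
# ----------------------------------------------------------------------

@dataclass
class LeadLocus:
    """A lead SNP with the significant SNPs clumped to it."""

    lead_snp: str
    chrom: str
    pos: int
    p: float
    members: list = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self._span

    _span: int = 0


def clump(
    assoc: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_threshold: float,
    r2: float = 0.1,
    window_kb: float = 12_150.0,
) -> list:
    """Greedy LD clumping of significant SNPs.

    Repeatedly takes the most significant unassigned SNP with
    ``p <= p_threshold`` as a lead (ties broken by ascending position,
    then id) and assigns to it every unassigned significant SNP on the
    same chromosome within ``window_kb`` kb and with dosage ``r^2`` at or
    above the threshold.
    """
    sig = assoc[assoc["p"] <= p_threshold].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(
        ["p", "pos", "snp_id"], kind="stable"
    ).reset_index(drop=True)
    window_bp = window_kb * 1000.0
    assigned: set = set()
    loci: list = []
    pos_of = dict(zip(assoc["snp_id"], assoc["pos"]))
    for _, row in sig.iterrows():
        if row.snp_id in assigned:
            continue
        lead = LeadLocus(
            lead_snp=row.snp_id, chrom=str(row.chrom), pos=int(row.pos), p=float(row.p)
        )
        assigned.add(row.snp_id)
        members = [row.snp_id]
        lead_x = genotypes.dosage_of(row.snp_id)
        for _, other in sig.iterrows():
            if other.snp_id in assigned or str(other.chrom) != str(row.chrom):
                continue
            if abs(int(other.pos) - int(row.pos)) > window_bp:
                continue
            x = genotypes.dosage_of(other.snp_id)
            ok = ~(np.isnan(lead_x) | np.isnan(x))
            if np.var(lead_x[ok]) == 0 or np.var(x[ok]) == 0:
                continue
            if np.corrcoef(lead_x[ok], x[ok])[0, 1] ** 2 >= r2:
                assigned.add(other.snp_id)
                members.append(other.snp_id)
        lead.members = members
        spans = [int(pos_of[m]) for m in members]
        lead._span = max(spans) - min(spans)
        loci.append(lead)
    return loci


# ----------------------------------------------------------------------
# Credible sets
# ----------------------------------------------------------------------

@dataclass
class CredibleSet:
    """Region posterior summary for one lead locus."""

    table: pd.DataFrame  # snp_id, z, posterior, in_set
    lead_snp: str
    coverage: float
    span_bp: int


def credible_set(
    region: pd.DataFrame,
    genotypes: GenotypeMatrix,
    lead: str,
    r2_min: float = 0.8,
    coverage: float = 0.99,
    prior_variance: float | None = None,
) -> CredibleSet:
    """Smallest set of linked SNPs reaching the target posterior coverage.

    ``region`` must have ``snp_id`` and ``z`` columns. The region is
    first restricted to SNPs with ``r^2 >= r2_min`` with the lead; each
    SNP's posterior is proportional to ``exp(z^2 / 2)`` (equal-prior
    approximation; pass ``prior_variance`` for the asymptotic Bayes
    factor with a normal effect prior instead), normalized over the
    region. SNPs are added in descending posterior order until the
    cumulative posterior reaches ``coverage``.
    """
    if lead not in set(region["snp_id"]):
        raise ValueError(f"lead SNP {lead!r} not in region")
    keep = []
    for snp in region["snp_id"]:
        keep.append(snp == lead or ld_r2(genotypes, lead, snp) >= r2_min)
    reg = region.loc[keep, ["snp_id", "z"]].reset_index(drop=True)
    z = reg["z"].to_numpy(dtype=float)
    if prior_variance is None:
        logbf = z**2 / 2.0
    else:
        w, v = prior_variance, 1.0
        logbf = 0.5 * np.log(v / (v + w)) + z**2 / 2.0 * w / (v + w)
    post = np.exp(logbf - logsumexp(logbf))
    order = np.argsort(-post, kind="stable")
    csum = np.cumsum(post[order])
    n_in = int(np.searchsorted(csum, coverage) + 1)
    n_in = min(n_in, len(post))
    in_set = np.zeros(len(post), dtype=bool)
    in_set[order[:n_in]] = True
    # lead always included
    in_set[reg.index[reg["snp_id"] == lead][0]] = True
    table = reg.assign(posterior=post, in_set=in_set)
    pos_of = dict(
        zip(genotypes.snp_map["snp_id"], genotypes.snp_map["pos"])
    )
    spans = [int(pos_of[s]) for s in table.loc[table["in_set"], "snp_id"] if s in pos_of]
    span = (max(spans) - min(spans)) if spans else 0
    return CredibleSet(table=table, lead_snp=lead, coverage=coverage, span_bp=span)


# ----------------------------------------------------------------------
# Conditional rescan
# ----------------------------------------------------------------------

def conditional_scan(
    y,
    W,
    genotypes: GenotypeMatrix,
    condition_on: list,
    loco: bool = True,
    **scan_kwargs,
) -> pd.DataFrame:
    """Re-run the scan with the given SNPs' dosages added as covariates.

    Conditioning SNPs that are monomorphic or collinear with the existing
    covariates are dropped with a warning; the conditioned SNPs themselves
    are excluded from the rescan.
    """
    y = np.asarray(y, dtype=float)
    W = _as_matrix(W, y.size)
    cols = [W]
    used = []
    for snp in condition_on:
        x = genotypes.dosage_of(snp)
        x = np.where(np.isnan(x), np.nanmean(x), x)
        trial = np.column_stack(cols + [x])
        if np.var(x) == 0 or np.linalg.matrix_rank(trial) < trial.shape[1]:
            warnings.warn(
                f"conditioning SNP {snp} dropped (monomorphic or collinear)",
                stacklevel=2,
            )
            continue
        cols.append(x[:, None])
        used.append(snp)
    W_aug = np.column_stack(cols) if len(cols) > 1 else W
    rest = genotypes.subset_snps(
        ~np.isin(genotypes.snp_ids, np.asarray(condition_on, dtype=object))
    )
    return assoc_scan(y, W_aug, rest, loco=loco, **scan_kwargs)
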