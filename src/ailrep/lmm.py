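"""Linear-mixed-model association engine.

Implements the variance-component model ``y = W a + x b + u + e`` with
``u ~ MVN(0, sigma_g2 K)`` and ``e ~ MVN(0, sigma_e2 I)``. The null model
is fitted by REML through a single eigendecomposition of the relatedness
matrix and a one-dimensional search over the variance ratio; per-SNP tests
then hold the ratio fixed (re-estimating only the overall scale per SNP),
so a scan costs one weighted regression per SNP. Relatedness matrices are
built per chromosome with the tested chromosome left out (LOCO).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ailrep.core import GenotypeMatrix, normalize_chrom

ASSOC_COLUMNS = [
    "chrom", "snp_id", "pos", "n_obs", "af",
    "beta", "se", "p", "neg_log10_p", "monomorphic",
]


# ----------------------------------------------------------------------
# GRM
# ----------------------------------------------------------------------

def compute_grm(
    genotypes: GenotypeMatrix, exclude_chrom: str | None = None
) -> np.ndarray:
    """Centered genetic relatedness matrix.

    Columns are mean-centered and the cross-product is scaled by the sum
    of per-SNP dosage variances, so the average diagonal is 1 on data in
    Hardy-Weinberg proportions. ``exclude_chrom`` drops one chromosome
    (the LOCO convention).
    """
    mask = np.ones(genotypes.n_snps, dtype=bool)
    if exclude_chrom is not None:
        mask &= genotypes.snp_map["chrom"].to_numpy() != normalize_chrom(exclude_chrom)
    X = genotypes.imputed()[:, mask]
    if X.shape[1] < 1 or (exclude_chrom is not None and X.shape[1] < 2):
        raise ValueError("no usable SNPs left for the GRM")
    Xc = X - X.mean(axis=0, keepdims=True)
    denom = np.sum(Xc.var(axis=0))
    if denom <= 0:
        raise ValueError("all GRM SNPs are monomorphic")
    return (Xc @ Xc.T) / denom


# ----------------------------------------------------------------------
# Null model REML
# ----------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance-component estimates from the no-SNP (null) model."""

    sigma_g2: float
    sigma_e2: float
    lambda_ratio: float
    loglik: float
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _as_matrix(W, n):
    if W is None:
        return np.ones((n, 1))
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    return W


def _reml_loglik(lam, ytil, Wtil, s, logdet_WtW):
    """Restricted log-likelihood for a variance ratio ``lam``, profiled
    over the fixed effects and the residual variance."""
    n, c = Wtil.shape
    d = lam * s + 1.0
    w = 1.0 / d
    WtDW = Wtil.T @ (Wtil * w[:, None])
    WtDy = Wtil.T @ (ytil * w)
    try:
        alpha = np.linalg.solve(WtDW, WtDy)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    resid = ytil - Wtil @ alpha
    rss = float(resid @ (resid * w))
    if rss <= 0:
        return -np.inf, None, None
    sign, logdet_WtDW = np.linalg.slogdet(WtDW)
    if sign <= 0:
        return -np.inf, None, None
    nc = n - c
    ll = 0.5 * (
        nc * np.log(nc / (2.0 * np.pi))
        - nc
        - nc * np.log(rss)
        - np.sum(np.log(d))
        - logdet_WtDW
        + logdet_WtW
    )
    return ll, alpha, rss / nc


def fit_null(y, W, K) -> VarianceComponents:
    """REML fit of the null (no-SNP) mixed model.

    One eigendecomposition of ``K`` reduces the problem to a 1-D search
    over the genetic/residual variance ratio on a log10 grid spanning
    [-5, 5], refined by bounded Brent optimization. Boundary fits are
    returned rather than raised.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not np.all(np.isfinite(y)):
        bad = list(np.flatnonzero(~np.isfinite(y)))
        raise ValueError(f"non-finite trait values at sample indices {bad}")
    W = _as_matrix(W, n)
    if n < W.shape[1] + 2:
        raise ValueError("too few samples for the covariate matrix")
    K = np.asarray(K, dtype=float)
    K = 0.5 * (K + K.T)
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    ytil = U.T @ y
    Wtil = U.T @ W
    sign, logdet_WtW = np.linalg.slogdet(W.T @ W)
    if sign <= 0:
        raise ValueError("covariate matrix is rank deficient")

    grid = np.concatenate([[0.0], 10.0 ** np.linspace(-5, 5, 81)])
    lls = np.array(
        [_reml_loglik(l, ytil, Wtil, s, logdet_WtW)[0] for l in grid]
    )
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -_reml_loglik(l, ytil, Wtil, s, logdet_WtW)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(res.x) if -res.fun >= lls[best] else float(grid[best])
    else:
        lam = float(grid[best])
    ll, alpha, sigma_e2 = _reml_loglik(lam, ytil, Wtil, s, logdet_WtW)
    return VarianceComponents(
        sigma_g2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        lambda_ratio=lam,
        loglik=ll,
        alpha=np.asarray(alpha),
    )


# ----------------------------------------------------------------------
# Association scan
# ----------------------------------------------------------------------

class _Whitened:
    """Trait/covariates rotated and scaled to unit residual covariance
    under a fixed variance ratio."""

    def __init__(self, y, W, K, lambda_ratio):
        n = y.size
        if K is None:
            self.U = None
            sw = np.ones(n)
        else:
            s, U = np.linalg.eigh(0.5 * (K + K.T))
            s = np.clip(s, 0.0, None)
            self.U = U
            sw = 1.0 / np.sqrt(lambda_ratio * s + 1.0)
        self.sqrt_w = sw
        self.ystar = self._rotate(y)
        Wstar = self._rotate(W)
        self.Q, _ = np.linalg.qr(Wstar)
        self.c = W.shape[1]
        self.y_resid = self.ystar - self.Q @ (self.Q.T @ self.ystar)

    def _rotate(self, v):
        r = v if self.U is None else (self.U.T @ v if v.ndim == 1 else self.U.T @ v)
        return r * (self.sqrt_w if v.ndim == 1 else self.sqrt_w[:, None])

    def residualize(self, M):
        Mstar = self._rotate(M)
        return Mstar - self.Q @ (self.Q.T @ Mstar)


def _scan_block(wh: _Whitened, X: np.ndarray):
    """Per-SNP weighted regression of the whitened trait on each dosage
    column, covariates projected out; residual scale re-estimated per SNP."""
    n = wh.ystar.size
    df = n - wh.c - 1
    Xr = wh.residualize(X)
    xtx = np.einsum("ij,ij->j", Xr, Xr)
    mono = xtx <= 1e-12
    xtx_safe = np.where(mono, 1.0, xtx)
    xty = Xr.T @ wh.y_resid
    beta = xty / xtx_safe
    yty = float(wh.y_resid @ wh.y_resid)
    rss = np.maximum(yty - beta**2 * xtx_safe, 1e-300)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / xtx_safe)
    chisq = (beta / se) ** 2
    p = stats.chi2.sf(chisq, df=1)
    beta[mono] = 0.0
    se[mono] = np.inf
    p[mono] = 1.0
    return beta, se, p, mono


def assoc_scan(
    y,
    W,
    genotypes: GenotypeMatrix,
    loco: bool = True,
    kinship: np.ndarray | None = None,
    lambda_ratio: float | None = None,
) -> pd.DataFrame:
    """Genome scan under the mixed model.

    With ``loco=True`` a GRM and null fit are computed per chromosome with
    that chromosome excluded; otherwise a single relatedness matrix is
    used (``kinship`` if supplied, else the all-SNP GRM, or the identity
    when ``kinship`` is explicitly the string ``"identity"``). The
    variance ratio is held at the null fit for every SNP on a chromosome
    and only the residual scale is re-estimated per SNP, so with an
    identity relatedness matrix the scan reduces exactly to OLS.
    """
    y = np.asarray(y, dtype=float)
    W = _as_matrix(W, y.size)
    X = genotypes.imputed()
    chroms = genotypes.snp_map["chrom"].to_numpy()
    af = X.mean(axis=0) / 2.0
    n_obs = (~np.isnan(genotypes.dosages)).sum(axis=0)

    beta = np.empty(genotypes.n_snps)
    se = np.empty(genotypes.n_snps)
    p = np.empty(genotypes.n_snps)
    mono = np.empty(genotypes.n_snps, dtype=bool)

    if loco:
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            K = compute_grm(genotypes, exclude_chrom=chrom)
            fit = fit_null(y, W, K)
            wh = _Whitened(y, W, K, fit.lambda_ratio)
            beta[sel], se[sel], p[sel], mono[sel] = _scan_block(wh, X[:, sel])
    else:
        if isinstance(kinship, str) and kinship == "identity":
            K, lam = None, 0.0
        else:
            K = np.asarray(kinship) if kinship is not None else compute_grm(genotypes)
            lam = lambda_ratio if lambda_ratio is not None else fit_null(y, W, K).lambda_ratio
        wh = _Whitened(y, W, K, lam)
        beta[:], se[:], p[:], mono[:] = _scan_block(wh, X)

    with np.errstate(divide="ignore"):
        nlp = -np.log10(np.maximum(p, 1e-300))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "snp_id": genotypes.snp_ids,
            "pos": genotypes.snp_map["pos"].to_numpy(),
            "n_obs": n_obs,
            "af": af,
            "beta": beta,
            "se": se,
            "p": p,
            "neg_log10_p": nlp,
            "monomorphic": mono,
        }
    )


# ----------------------------------------------------------------------
# Rank-based inverse normal transform
# ----------------------------------------------------------------------

def quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse normal transform, ``Phi^-1((rank - 0.5) / n)``.

    Ties receive averaged ranks; missing values stay missing.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    x = v[ok]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("constant vector cannot be quantile normalized")
    ranks = stats.rankdata(x, method="average")
    out = np.full(v.shape, np.nan)
    out[ok] = stats.norm.ppf((ranks - 0.5) / x.size)
    return out


# ----------------------------------------------------------------------
# Permutation threshold
# ----------------------------------------------------------------------

def permutation_threshold(
    y,
    W,
    genotypes: GenotypeMatrix,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    kinship: np.ndarray | None = None,
) -> float:
    """Genome-wide significance threshold from trait permutations.

    Each permutation shuffles the trait rows against the fixed
    (covariates, genotypes), re-fits the covariates, and records the
    genome-wide maximum -log10 p; the threshold is the requested quantile
    of those maxima. When a relatedness matrix is given, the variance
    ratio is fixed at the unpermuted null fit.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(y, dtype=float)
    n = y.size
    W = _as_matrix(W, n)
    rng = np.random.default_rng(seed)

    if kinship is not None:
        lam = fit_null(y, W, kinship).lambda_ratio
        wh = _Whitened(y, W, kinship, lam)
    else:
        wh = _Whitened(y, W, None, 0.0)

    X = genotypes.imputed()
    Xr = wh.residualize(X)
    xtx = np.einsum("ij,ij->j", Xr, Xr)
    keep = xtx > 1e-12
    Xr, xtx = Xr[:, keep], xtx[keep]
    df = n - W.shape[1] - 1

    # Whitening is linear, so permute raw y then rotate all at once.
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perm].T  # n x n_perm
    Ystar = wh._rotate(Yp)
    Yr = Ystar - wh.Q @ (wh.Q.T @ Ystar)
    B = Xr.T @ Yr  # SNPs x perms
    yty = np.einsum("ij,ij->j", Yr, Yr)
    num = B**2 / xtx[:, None]
    rss = np.maximum(yty[None, :] - num, 1e-300)
    chisq_max = (num * df / rss).max(axis=0)
    min_p = stats.chi2.sf(chisq_max, df=1)
    return float(np.quantile(-np.log10(np.maximum(min_p, 1e-300)), quantile))


# ----------------------------------------------------------------------
# Mega-analysis
# ----------------------------------------------------------------------

def _is_binary(y) -> bool:
    vals = np.unique(np.asarray(y, dtype=float))
    vals = vals[~np.isnan(vals)]
    return vals.size <= 2


def mega_scan(cohorts: list, loco: bool = True) -> pd.DataFrame:
    """Pooled-sample scan over multiple cohorts.

    Continuous traits are inverse-normal transformed within each cohort
    (binary traits pass through untouched); samples are then concatenated
    with a cohort indicator appended to the covariates, and the scan runs
    on the SNP set shared by all cohorts.

    ``cohorts`` is a list of ``(y, W, genotypes)`` triples.
    """
    if len(cohorts) < 2:
        raise ValueError("mega_scan needs at least two cohorts")
    shared = None
    for _, _, g in cohorts:
        ids = set(g.snp_ids)
        shared = ids if shared is None else shared & ids
    if not shared:
        raise ValueError("cohorts share no SNPs")
    order = [s for s in cohorts[0][2].snp_ids if s in shared]

    ys, Ws, Ds, samples = [], [], [], []
    for y, W, g in cohorts:
        y = np.asarray(y, dtype=float)
        ys.append(y if _is_binary(y) else quantile_normalize(y))
        Ws.append(_as_matrix(W, y.size))
        sub = g.subset_snps(order)
        reorder = pd.Index(sub.snp_ids).get_indexer(order)
        Ds.append(sub.dosages[:, reorder])
        samples.extend(f"c{len(ys)}:{s}" for s in sub.sample_ids)
        if sub.n_samples != y.size:
            raise ValueError("trait and genotypes disagree on sample count")

    y_all = np.concatenate(ys)
    c_max = max(w.shape[1] for w in Ws)
    W_rows = []
    for k, w in enumerate(Ws):
        pad = np.zeros((w.shape[0], c_max - w.shape[1]))
        ind = np.zeros((w.shape[0], len(cohorts) - 1))
        if k > 0:
            ind[:, k - 1] = 1.0
        W_rows.append(np.hstack([w, pad, ind]))
    W_all = np.vstack(W_rows)
    # drop exactly collinear columns (e.g. duplicated intercepts)
    q, r = np.linalg.qr(W_all)
    keep = np.abs(np.diag(r)) > 1e-9
    W_all = W_all[:, keep]

    snp_map = cohorts[0][2].subset_snps(order).snp_map
    snp_map = snp_map.set_index("snp_id").loc[order].reset_index()
    merged = GenotypeMatrix(np.vstack(Ds), snp_map, samples)
    return assoc_scan(y_all, W_all, merged, loco=loco)
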