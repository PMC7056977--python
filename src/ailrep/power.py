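"""Replication power: mixed-model simulation over an effect-size grid,
plus a closed-form normal companion used for validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ailrep.lmm import VarianceComponents, _Whitened


@dataclass
class PowerConfig:
    """Effect-size grid and Monte-Carlo settings for power simulation."""

    effect_sizes: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 50)
    )
    n_reps: int = 2500
    genomewide_neg_log10_p: float = 4.85
    nominal_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.effect_sizes = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        if self.effect_sizes.size == 0:
            raise ValueError("effect-size grid is empty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        gw_p = 10.0 ** (-self.genomewide_neg_log10_p)
        if gw_p > self.nominal_alpha:
            raise ValueError(
                "genome-wide threshold must be at least as strict as nominal alpha"
            )


def replication_power(
    snp_dosage,
    kinship,
    null_fit: VarianceComponents,
    config: PowerConfig,
) -> pd.DataFrame:
    """Simulated power to detect one SNP across an effect-size grid.

    For each effect size, simulates ``n_reps`` traits
    ``y = intercept + x * beta + u + e`` with variance components fixed at
    the null fit, tests the SNP with the same fixed-ratio mixed-model
    regression the scan uses, and reports the fraction of replicates whose
    p beats each threshold, with binomial Monte-Carlo standard errors.
    """
    x = np.asarray(snp_dosage, dtype=float)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    n = x.size
    rng = np.random.default_rng(config.seed)
    K = None if kinship is None else np.asarray(kinship, dtype=float)

    intercept = np.ones((n, 1))
    wh = _Whitened(np.zeros(n), intercept, K, null_fit.lambda_ratio)
    xr = wh.residualize(x[:, None])[:, 0]
    xtx = float(xr @ xr)
    if xtx <= 1e-12:
        raise ValueError("test SNP is monomorphic")
    df = n - 2

    if K is not None:
        L = np.linalg.cholesky(
            0.5 * (K + K.T) + 1e-9 * np.eye(n)
        )

    gw_p = 10.0 ** (-config.genomewide_neg_log10_p)
    rows = []
    for beta in config.effect_sizes:
        # noise is common across the grid only through the rng stream
        G = (
            np.sqrt(null_fit.sigma_g2) * (L @ rng.standard_normal((n, config.n_reps)))
            if K is not None and null_fit.sigma_g2 > 0
            else 0.0
        )
        E = np.sqrt(null_fit.sigma_e2) * rng.standard_normal((n, config.n_reps))
        Y = beta * x[:, None] + G + E
        Ystar = wh._rotate(Y)
        Yr = Ystar - wh.Q @ (wh.Q.T @ Ystar)
        b = (xr @ Yr) / xtx
        yty = np.einsum("ij,ij->j", Yr, Yr)
        rss = np.maximum(yty - b**2 * xtx, 1e-300)
        chisq = b**2 * xtx * df / rss
        p = stats.chi2.sf(chisq, df=1)
        pow_gw = float(np.mean(p < gw_p))
        pow_nom = float(np.mean(p < config.nominal_alpha))
        rows.append(
            {
                "effect_size": float(beta),
                "power_genomewide": pow_gw,
                "power_nominal": pow_nom,
                "mc_se_genomewide": float(
                    np.sqrt(pow_gw * (1 - pow_gw) / config.n_reps)
                ),
                "mc_se_nominal": float(
                    np.sqrt(pow_nom * (1 - pow_nom) / config.n_reps)
                ),
            }
        )
    return pd.DataFrame(rows)


def analytic_power(
    beta: float,
    se: float,
    alpha: float | None = None,
    z_threshold: float | None = None,
) -> float:
    """Two-sided power of a Wald test with noncentrality ``beta / se``.

    Supply either a significance level ``alpha`` or a z threshold
    directly; returns ``P(|N(beta/se, 1)| > z)``.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if z_threshold is None:
        if alpha is None:
            raise ValueError("need alpha or z_threshold")
        z_threshold = stats.norm.isf(alpha / 2.0)
    ncp = beta / se
    return float(
        stats.norm.sf(z_threshold - ncp) + stats.norm.cdf(-z_threshold - ncp)
    )


def z_threshold_from_neg_log10_p(neg_log10_p: float) -> float:
    """Two-sided z threshold equivalent to a ``-log10 p`` cutoff."""
    return float(stats.norm.isf(10.0 ** (-neg_log10_p) / 2.0))


def simulate_wald_power(
    ncp: float, z_threshold: float, n_reps: int = 2500, seed: int = 0
) -> float:
    """Monte-Carlo power from ``n_reps`` draws of ``N(ncp, 1)``."""
    rng = np.random.default_rng(seed)
    z = rng.normal(ncp, 1.0, n_reps)
    return float(np.mean(np.abs(z) > z_threshold))
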