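"""Cross-cohort replication assessment.

Couples empirical replication rates (Bonferroni 0.05/M) and a sign test
with two random-effects models for paired discovery/replication z-scores:

* WC — a shared effect ``lam ~ N(0, sigma_g2)`` plus unit noise in each
  study; captures winner's curse alone.
* WC+C — adds independent study-specific effects ``d(i) ~ N(0, sigma_ci2)``,
  capturing heterogeneity/confounding on top of winner's curse.

Both are fitted by maximum likelihood with the discovery statistic's
marginal truncated to the ascertainment region ``|s1| > t_disc``, and the
replication statistic modeled through its conditional given ``s1``.
Predicted replication rates are means of conditional tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ailrep.simdata import SummaryPair


# ----------------------------------------------------------------------
# Locus-level comparison and sign test
# ----------------------------------------------------------------------

def classify_replication(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    genomewide_threshold: float = 5e-8,
    rep_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus replication verdicts for matched association rows.

    Both tables need ``snp_id``, ``p`` and ``beta`` columns (``af``/``se``
    are carried through when present). A locus is nominally replicated
    when the replication p-value is below ``rep_alpha`` and the betas
    share a strict sign; genome-wide replication additionally requires
    the replication p to beat ``genomewide_threshold``.
    """
    d = discovery.set_index("snp_id")
    r = replication.set_index("snp_id")
    unmatched = sorted(set(d.index) ^ set(r.index))
    if unmatched:
        raise ValueError(f"unmatched loci: {unmatched}")
    rows = []
    for snp in d.index:
        b1, b2 = float(d.loc[snp, "beta"]), float(r.loc[snp, "beta"])
        p2 = float(r.loc[snp, "p"])
        same = np.sign(b1) == np.sign(b2) and b1 != 0 and b2 != 0
        nominal = same and p2 < rep_alpha
        rows.append(
            {
                "snp_id": snp,
                "disc_p": float(d.loc[snp, "p"]),
                "disc_beta": b1,
                "rep_p": p2,
                "rep_beta": b2,
                "same_sign": bool(same),
                "nominal_replicated": bool(nominal),
                "genomewide_replicated": bool(nominal and p2 < genomewide_threshold),
            }
        )
    return pd.DataFrame(rows)


def sign_test(beta_pairs, exact_p: bool = True):
    """Count beta pairs with strictly matching signs.

    A zero beta counts as disagreement. Returns ``(n_agree, n_total, p)``
    with ``p`` the exact two-sided binomial p-value against 0.5 (or
    ``None`` when not requested).
    """
    pairs = list(beta_pairs)
    if not pairs:
        raise ValueError("sign test needs at least one pair")
    agree = sum(
        1 for a, b in pairs if a != 0 and b != 0 and np.sign(a) == np.sign(b)
    )
    n = len(pairs)
    p = stats.binomtest(agree, n, 0.5).pvalue if exact_p else None
    return agree, n, p


# ----------------------------------------------------------------------
# Random-effects models
# ----------------------------------------------------------------------

@dataclass
class ReplicationFit:
    """Fitted variance components of a WC or WC+C model."""

    model: str  # "WC" or "WC+C"
    sigma_g2: float
    sigma_c1_2: float
    sigma_c2_2: float
    loglik: float
    n_variants: int
    t_disc: float | None

    @property
    def v1(self) -> float:
        return self.sigma_g2 + self.sigma_c1_2 + 1.0

    @property
    def v2(self) -> float:
        return self.sigma_g2 + self.sigma_c2_2 + 1.0


def _loglik(params, s1, s2, t_disc, wc):
    if wc:
        sg2, sc1, sc2 = params[0], 0.0, 0.0
    else:
        sg2, sc1, sc2 = params
    v1 = sg2 + sc1 + 1.0
    v2 = sg2 + sc2 + 1.0
    cond_var = v2 - sg2**2 / v1
    if cond_var <= 0:
        return -np.inf
    ll = np.sum(stats.norm.logpdf(s1, scale=np.sqrt(v1)))
    if t_disc is not None:
        tail = 2.0 * stats.norm.sf(t_disc / np.sqrt(v1))
        if tail <= 0:
            return -np.inf
        ll -= s1.size * np.log(tail)
    mu = (sg2 / v1) * s1
    ll += np.sum(stats.norm.logpdf(s2, loc=mu, scale=np.sqrt(cond_var)))
    return float(ll)


def fit_replication_model(pair: SummaryPair, model: str = "WC+C") -> ReplicationFit:
    """Maximum-likelihood variance components for paired z-scores.

    The likelihood is the product over variants of the marginal of ``s1``
    truncated to ``|s1| > t_disc`` (no truncation when the pair carries no
    ascertainment threshold) times the conditional of ``s2`` given ``s1``.
    Optimized with L-BFGS-B from several starting points (including
    moment-based starts); WC constrains both study-specific variances to
    zero, so its optimum is always feasible for WC+C.
    """
    model = model.upper().replace("WCC", "WC+C")
    if model not in ("WC", "WC+C"):
        raise ValueError("model must be 'WC' or 'WC+C'")
    if pair.n_variants < 2:
        raise ValueError("model fitting requires at least two variants")
    s1, s2, t = pair.s1, pair.s2, pair.t_disc
    wc = model == "WC"

    # moment starts (unascertained formulas; crude but cheap)
    cov = max(float(np.mean(s1 * s2)), 1e-3)
    var1 = max(float(np.var(s1)) - 1.0, 1e-3)
    var2 = max(float(np.var(s2)) - 1.0, 1e-3)
    starts = []
    for sg in (0.1, 1.0, 10.0, 100.0, cov):
        if wc:
            starts.append([sg])
        else:
            starts.append([sg, max(var1 - sg, 0.0), max(var2 - sg, 0.0)])
            starts.append([sg, 1.0, 1.0])
    if not wc:
        # the WC optimum itself, to guarantee nesting
        wc_fit = fit_replication_model(pair, "WC")
        starts.append([wc_fit.sigma_g2, 0.0, 0.0])

    bounds = [(0.0, 1e6)] * (1 if wc else 3)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda p: -_loglik(p, s1, s2, t, wc),
            x0=np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("replication model optimization failed")
    params = list(best.x) + [0.0, 0.0] if wc else list(best.x)
    return ReplicationFit(
        model=model,
        sigma_g2=float(params[0]),
        sigma_c1_2=float(params[1]),
        sigma_c2_2=float(params[2]),
        loglik=float(-best.fun),
        n_variants=pair.n_variants,
        t_disc=t,
    )


def conditional_distribution(fit: ReplicationFit, s1) -> tuple:
    """Mean and variance of the replication statistic given ``s1``."""
    s1 = np.asarray(s1, dtype=float)
    mean = (fit.sigma_g2 / fit.v1) * s1
    var = fit.v2 - fit.sigma_g2**2 / fit.v1
    return mean, float(var)


def predicted_replication_rate(
    fit: ReplicationFit, pair: SummaryPair, rep_threshold: float
) -> float:
    """Mean conditional probability that ``|s2|`` exceeds the threshold."""
    if rep_threshold <= 0:
        raise ValueError("rep_threshold must be positive")
    mean, var = conditional_distribution(fit, pair.s1)
    sd = np.sqrt(var)
    prob = stats.norm.sf((rep_threshold - mean) / sd) + stats.norm.cdf(
        (-rep_threshold - mean) / sd
    )
    return float(np.mean(prob))


def empirical_replication_rate(
    pair: SummaryPair, M: int | None = None, rep_alpha: float = 0.05
) -> float:
    """Fraction of discovery-significant variants passing 0.05/M in replication."""
    if M is None:
        M = pair.n_variants
    if M == 0:
        raise ValueError("no discovery-significant variants")
    z_crit = stats.norm.isf(rep_alpha / M / 2.0)
    return float(np.mean(np.abs(pair.s2) > z_crit))


# ----------------------------------------------------------------------
# z-scores from association tables
# ----------------------------------------------------------------------

def z_from_assoc(assoc: pd.DataFrame) -> np.ndarray:
    """Signed z-scores: ``sign(beta) * |Phi^-1(p/2)|``, with a ``beta/se``
    fallback where p underflows the normal quantile."""
    p = assoc["p"].to_numpy(dtype=float)
    beta = assoc["beta"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        z = np.abs(stats.norm.isf(np.clip(p, 1e-320, 1.0) / 2.0))
    bad = ~np.isfinite(z)
    if bad.any():
        z[bad] = np.abs(beta[bad] / assoc["se"].to_numpy(dtype=float)[bad])
    return np.where(beta < 0, -z, z)


def pair_from_assoc(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    disc_neg_log10_threshold: float,
) -> SummaryPair:
    """Ascertained z-score pair from two association tables.

    Keeps variants whose discovery ``-log10 p`` beats the threshold and
    that appear in both tables; the ascertainment threshold is carried
    on the z scale.
    """
    shared = discovery[discovery["snp_id"].isin(set(replication["snp_id"]))]
    sig = shared[shared["p"] <= 10.0 ** (-disc_neg_log10_threshold)]
    if sig.empty:
        raise ValueError("no discovery-significant variants shared with replication")
    rep = replication.set_index("snp_id").loc[sig["snp_id"]].reset_index()
    z1 = z_from_assoc(sig)
    z2 = z_from_assoc(rep)
    t_z = float(stats.norm.isf(10.0 ** (-disc_neg_log10_threshold) / 2.0))
    # numeric guard: keep t consistent with the kept variants
    t_z = min(t_z, float(np.abs(z1).min()) - 1e-9)
    return SummaryPair(list(sig["snp_id"]), z1, z2, t_z)
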