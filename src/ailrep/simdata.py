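"""Synthetic two-founder intercross cohorts.

Everything downstream of this module consumes only its outputs: pedigrees
bred by random mating, genotypes gene-dropped through the pedigree with
Haldane recombination, pedigree kinship matrices, mixed-model phenotypes
(quantitative and coat-color), and paired discovery/replication z-scores
drawn from a shared-plus-study-specific random-effects generative model.

All operations are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ailrep.core import GenotypeMatrix, normalize_chrom


class BreedingError(RuntimeError):
    """Raised when a generation cannot supply enough mating pairs."""


# ----------------------------------------------------------------------
# Pedigree
# ----------------------------------------------------------------------

class Pedigree:
    """Parent links per individual, ordered oldest generation first.

    Wraps a data frame with columns ``individual_id``, ``sire_id``,
    ``dam_id``, ``sex`` ("male"/"female") and ``generation``. Founders
    (generation 0) have no parents; parents always precede offspring.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["individual_id", "sire_id", "dam_id", "sex", "generation"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"pedigree missing column {col!r}")
        df = df[required].reset_index(drop=True).copy()
        df["individual_id"] = df["individual_id"].astype(str)
        df["generation"] = df["generation"].astype(int)
        for col in ("sire_id", "dam_id"):
            df[col] = df[col].map(
                lambda v: None if v is None or (isinstance(v, float) and np.isnan(v))
                or str(v) in ("0", "", "NA") else str(v)
            )
        if df["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        gen = dict(zip(df["individual_id"], df["generation"]))
        for _, row in df.iterrows():
            has_parents = row.sire_id is not None and row.dam_id is not None
            if row.generation == 0:
                if row.sire_id is not None or row.dam_id is not None:
                    raise ValueError(
                        f"founder {row.individual_id} has parents listed"
                    )
            else:
                if not has_parents:
                    raise ValueError(
                        f"non-founder {row.individual_id} lacks a parent"
                    )
                for p in (row.sire_id, row.dam_id):
                    if p not in gen:
                        raise ValueError(f"unknown parent {p!r}")
                    if gen[p] >= row.generation:
                        raise ValueError(
                            f"parent {p} does not precede {row.individual_id}"
                        )
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def individual_ids(self) -> list:
        return list(self.df["individual_id"])

    def generation_ids(self, generation: int) -> list:
        sel = self.df[self.df["generation"] == generation]
        return list(sel["individual_id"])

    @property
    def n_generations(self) -> int:
        return int(self.df["generation"].max()) + 1


def build_ail_pedigree(
    n_families: int,
    n_generations: int,
    offspring_per_pair: int = 4,
    seed: int = 0,
) -> Pedigree:
    """Breed a two-founder advanced intercross pedigree.

    Generation 0 holds the two inbred founders (one sire, one dam);
    generation 1 is their F1 litter; each later generation is produced by
    ``n_families`` randomly paired couples, avoiding full-sibling matings
    whenever an alternative pairing exists. ``n_generations`` counts the
    generations bred after the founders, so the deepest generation index
    equals ``n_generations``.
    """
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    if offspring_per_pair < 1:
        raise ValueError("offspring_per_pair must be >= 1")
    rng = np.random.default_rng(seed)

    rows = [
        ("F0_sire", None, None, "male", 0),
        ("F0_dam", None, None, "female", 0),
    ]
    # F1: one large litter, sexes balanced so breeding can always proceed.
    n_f1 = max(2 * n_families, offspring_per_pair)
    sexes = ["male"] * (n_f1 // 2) + ["female"] * (n_f1 - n_f1 // 2)
    rng.shuffle(sexes)
    current = []
    for i, sex in enumerate(sexes):
        iid = f"F1_{i}"
        rows.append((iid, "F0_sire", "F0_dam", sex, 1))
        current.append((iid, sex, ("F0_sire", "F0_dam")))

    for g in range(2, n_generations + 1):
        males = [(i, p) for i, s, p in current if s == "male"]
        females = [(i, p) for i, s, p in current if s == "female"]
        n_pairs = min(n_families, len(males), len(females))
        if n_pairs < 2:
            raise BreedingError(
                f"generation {g}: only {n_pairs} mating pair(s) available"
            )
        rng.shuffle(males)
        rng.shuffle(females)
        pairs = _pair_avoiding_sibs(males, females, n_pairs, rng)
        nxt = []
        k = 0
        for sire, dam in pairs:
            litter_sexes = ["male"] * (offspring_per_pair // 2) + [
                "female"
            ] * (offspring_per_pair - offspring_per_pair // 2)
            rng.shuffle(litter_sexes)
            for sex in litter_sexes:
                iid = f"F{g}_{k}"
                rows.append((iid, sire, dam, sex, g))
                nxt.append((iid, sex, (sire, dam)))
                k += 1
        current = nxt

    return Pedigree(
        pd.DataFrame(
            rows,
            columns=["individual_id", "sire_id", "dam_id", "sex", "generation"],
        )
    )


def _pair_avoiding_sibs(males, females, n_pairs, rng):
    """Greedy pairing that skips full-sib couples when any non-sib remains."""
    females = list(females)
    pairs = []
    for sire, sire_parents in males:
        if len(pairs) == n_pairs or not females:
            break
        non_sib = [k for k, (_, fp) in enumerate(females) if fp != sire_parents]
        pool = non_sib if non_sib else list(range(len(females)))
        j = pool[int(rng.integers(len(pool)))]
        dam, _ = females.pop(j)
        pairs.append((sire, dam))
    return pairs


# ----------------------------------------------------------------------
# Genetic map + gene dropping
# ----------------------------------------------------------------------

def make_genetic_map(
    n_chrom: int = 2,
    snps_per_chrom: int = 50,
    chrom_length_cm: float = 80.0,
    bp_per_cm: float = 2_000_000.0,
    seed: int = 0,
    albino_proxy: bool = False,
    agouti_proxy: bool = False,
) -> pd.DataFrame:
    """Evenly spread SNPs with jittered positions on ``n_chrom`` chromosomes.

    When requested, flags one mid-chromosome SNP as the albino proxy
    (chromosome 1) and one as the agouti proxy (last chromosome) via the
    ``trait_proxy`` column.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chrom + 1):
        base = np.linspace(0.0, chrom_length_cm, snps_per_chrom)
        jitter = rng.uniform(0, chrom_length_cm / (4 * snps_per_chrom), snps_per_chrom)
        cm = np.sort(base + jitter)
        pos = np.maximum(1, np.round(cm * bp_per_cm / 100).astype(int) + 1)
        pos = np.maximum.accumulate(pos + np.arange(snps_per_chrom))
        for k in range(snps_per_chrom):
            rows.append(
                {
                    "snp_id": f"chr{c}.{pos[k]}",
                    "chrom": str(c),
                    "pos": int(pos[k]),
                    "cm": float(cm[k]),
                    "a0": "A",
                    "a1": "B",
                    "trait_proxy": "",
                }
            )
    df = pd.DataFrame(rows)
    if albino_proxy:
        mid = snps_per_chrom // 2
        df.loc[mid, "trait_proxy"] = "albino"
    if agouti_proxy:
        idx = (n_chrom - 1) * snps_per_chrom + snps_per_chrom // 2
        df.loc[idx, "trait_proxy"] = "agouti"
    return df


def gene_drop(pedigree: Pedigree, genetic_map: pd.DataFrame, seed: int = 0) -> GenotypeMatrix:
    """Drop founder haplotypes down the pedigree with Haldane recombination.

    The two founders carry opposite homozygous genotypes at every SNP
    (dosages 0 and 2); every transmitted gamete recombines the parent's
    two haplotypes with inter-marker crossover probability
    ``0.5 * (1 - exp(-2d))`` for map distance ``d`` in Morgans.
    """
    gmap = genetic_map.reset_index(drop=True).copy()
    if len(gmap) < 1:
        raise ValueError("genetic map has no SNPs")
    if "cm" not in gmap.columns or gmap["cm"].isna().any():
        raise ValueError("every SNP needs a genetic position (cm)")
    gmap["chrom"] = gmap["chrom"].map(normalize_chrom)

    n_snps = len(gmap)
    # Per-chromosome recombination fractions between adjacent SNPs; a
    # fraction of 0.5 at chromosome starts makes chromosomes independent.
    d_morgan = np.diff(gmap["cm"].to_numpy()) / 100.0
    same_chrom = gmap["chrom"].to_numpy()[1:] == gmap["chrom"].to_numpy()[:-1]
    rec = np.where(same_chrom, 0.5 * (1.0 - np.exp(-2.0 * np.abs(d_morgan))), 0.5)

    rng = np.random.default_rng(seed)
    ped = pedigree.df
    founders = ped[ped["generation"] == 0]["individual_id"].tolist()
    if len(founders) != 2:
        raise ValueError("gene_drop expects exactly two founders")

    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {
        founders[0]: (np.zeros(n_snps, dtype=np.int8), np.zeros(n_snps, dtype=np.int8)),
        founders[1]: (np.ones(n_snps, dtype=np.int8), np.ones(n_snps, dtype=np.int8)),
    }

    def gamete(parent_id: str) -> np.ndarray:
        h0, h1 = haplos[parent_id]
        # crossover state: 0 -> copy h0, 1 -> copy h1
        switch = np.empty(n_snps, dtype=bool)
        switch[0] = rng.random() < 0.5
        switch[1:] = rng.random(n_snps - 1) < rec
        state = np.cumsum(switch) % 2
        return np.where(state == 0, h0, h1).astype(np.int8)

    ordered = ped.sort_values("generation", kind="stable")
    for _, row in ordered[ordered["generation"] > 0].iterrows():
        haplos[row.individual_id] = (gamete(row.sire_id), gamete(row.dam_id))

    ids = pedigree.individual_ids
    dosages = np.array(
        [haplos[i][0] + haplos[i][1] for i in ids], dtype=float
    )
    return GenotypeMatrix(dosages, gmap, ids)


# ----------------------------------------------------------------------
# Pedigree kinship
# ----------------------------------------------------------------------

def kinship_from_pedigree(pedigree: Pedigree) -> pd.DataFrame:
    """Recursive (tabular-method) kinship coefficients.

    Founders are assumed unrelated and non-inbred. Returns a symmetric
    data frame indexed by individual id; the diagonal is ``0.5 * (1 + f)``
    with ``f`` the inbreeding coefficient.
    """
    df = pedigree.df.sort_values("generation", kind="stable").reset_index(drop=True)
    ids = list(df["individual_id"])
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n))
    sire = [idx[s] if s is not None else -1 for s in df["sire_id"]]
    dam = [idx[d] if d is not None else -1 for d in df["dam_id"]]
    for i in range(n):
        si, di = sire[i], dam[i]
        if si < 0:
            K[i, i] = 0.5
        else:
            K[i, i] = 0.5 * (1.0 + K[si, di])
            for j in range(i):
                K[i, j] = K[j, i] = 0.5 * (K[si, j] + K[di, j])
    out = pd.DataFrame(K, index=ids, columns=ids)
    return out.loc[pedigree.individual_ids, pedigree.individual_ids]


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------

@dataclass
class TraitSimSpec:
    """Parameters of one simulated trait.

    ``causal_effects`` maps SNP id to its additive effect (trait SD units
    per alternate allele). ``study_effect_var`` adds an independent
    N(0, study_effect_var) shift to each causal effect per call, emulating
    cohort-specific confounding. For coat traits the proxy SNP is looked
    up from the map's ``trait_proxy`` flags.
    """

    causal_effects: dict = dataclasses.field(default_factory=dict)
    sigma_g2: float = 0.0
    sigma_e2: float = 1.0
    covariate_effects: dict = dataclasses.field(default_factory=dict)
    study_effect_var: float = 0.0
    trait_type: str = "quantitative"
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_g2, self.sigma_e2, self.study_effect_var) < 0:
            raise ValueError("variances must be non-negative")
        if self.trait_type not in ("quantitative", "albino", "agouti"):
            raise ValueError(f"unknown trait type {self.trait_type!r}")


def _proxy_snp(genotypes: GenotypeMatrix, kind: str) -> str:
    flags = genotypes.snp_map.get("trait_proxy")
    if flags is None or not (flags == kind).any():
        raise ValueError(f"no SNP flagged as {kind!r} proxy in the map")
    return str(genotypes.snp_map.loc[flags == kind, "snp_id"].iloc[0])


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    kinship: pd.DataFrame | np.ndarray | None,
    spec: TraitSimSpec,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw one trait for every sample in ``genotypes``.

    Quantitative traits follow ``y = W a + sum_k x_k b_k + u + e`` with
    ``u ~ MVN(0, sigma_g2 K)`` and ``e ~ MVN(0, sigma_e2 I)``. The albino
    trait is 1 iff the sample is homozygous for the alternate allele at
    the albino-proxy SNP; agouti is dominant at its proxy SNP and coded
    missing for albino samples.
    """
    n = genotypes.n_samples
    rng = np.random.default_rng(spec.seed)
    ids = genotypes.sample_ids

    if spec.trait_type in ("albino", "agouti"):
        alb = genotypes.dosage_of(_proxy_snp(genotypes, "albino"))
        albino = (alb >= 2.0 - 1e-9).astype(float)
        if spec.trait_type == "albino":
            values = albino
        else:
            ag = genotypes.dosage_of(_proxy_snp(genotypes, "agouti"))
            values = (ag >= 1.0 - 1e-9).astype(float)
            values[albino == 1.0] = np.nan
        return pd.DataFrame({"individual_id": ids, spec.trait_type: values})

    y = np.zeros(n)
    if covariates is not None:
        for col, alpha in spec.covariate_effects.items():
            y += alpha * covariates[col].to_numpy(dtype=float)
    if spec.causal_effects:
        shift = rng.normal(0.0, np.sqrt(spec.study_effect_var), len(spec.causal_effects))
        for k, (snp, beta) in enumerate(sorted(spec.causal_effects.items())):
            y += (beta + shift[k]) * genotypes.dosage_of(snp)
    if spec.sigma_g2 > 0:
        if kinship is None:
            raise ValueError("sigma_g2 > 0 requires a kinship matrix")
        K = kinship.to_numpy() if isinstance(kinship, pd.DataFrame) else np.asarray(kinship)
        K = 0.5 * (K + K.T)
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise ValueError("kinship matrix is not positive semi-definite")
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        y += np.sqrt(spec.sigma_g2) * (L @ rng.standard_normal(n))
    y += np.sqrt(spec.sigma_e2) * rng.standard_normal(n)
    return pd.DataFrame({"individual_id": ids, "trait": y})


# ----------------------------------------------------------------------
# Paired summary statistics
# ----------------------------------------------------------------------

@dataclass
class SummaryPair:
    """Paired discovery/replication z-scores with ascertainment threshold."""

    variant_ids: list
    s1: np.ndarray
    s2: np.ndarray
    t_disc: float | None = None

    def __post_init__(self):
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if self.s1.shape != self.s2.shape:
            raise ValueError("s1 and s2 must align")
        if len(self.variant_ids) != self.s1.size:
            raise ValueError("variant ids must align with z-scores")
        if self.t_disc is not None and np.any(np.abs(self.s1) <= self.t_disc):
            raise ValueError("ascertained pair contains |s1| <= t_disc")

    @property
    def n_variants(self) -> int:
        return self.s1.size


def simulate_summary_pair(
    n_variants: int,
    sigma_g2: float,
    sigma_c1_2: float = 0.0,
    sigma_c2_2: float = 0.0,
    t_disc: float | None = None,
    seed: int = 0,
) -> SummaryPair:
    """Draw paired z-scores from the shared/study-specific effects model.

    Per variant: shared effect ``lam ~ N(0, sigma_g2)``, study effects
    ``d1 ~ N(0, sigma_c1_2)``, ``d2 ~ N(0, sigma_c2_2)``, unit noise;
    ``s1 = lam + d1 + e1`` and ``s2 = lam + d2 + e2``. With ``t_disc``
    set, rejection-samples until ``n_variants`` pass ``|s1| > t_disc``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if min(sigma_g2, sigma_c1_2, sigma_c2_2) < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    kept1, kept2 = [], []
    need = n_variants
    while need > 0:
        m = need if t_disc is None else max(4 * need, 256)
        lam = rng.normal(0.0, np.sqrt(sigma_g2), m)
        s1 = lam + rng.normal(0.0, np.sqrt(sigma_c1_2), m) + rng.standard_normal(m)
        s2 = lam + rng.normal(0.0, np.sqrt(sigma_c2_2), m) + rng.standard_normal(m)
        if t_disc is not None:
            keep = np.abs(s1) > t_disc
            s1, s2 = s1[keep], s2[keep]
        kept1.append(s1[:need])
        kept2.append(s2[:need])
        need -= len(kept1[-1])
    s1 = np.concatenate(kept1)
    s2 = np.concatenate(kept2)
    ids = [f"v{k}" for k in range(n_variants)]
    return SummaryPair(ids, s1, s2, t_disc)
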