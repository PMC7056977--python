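"""End-to-end orchestration: simulate two cohorts, QC, scan each, define
loci, assess replication, estimate power, and mega-analyze.

The configuration is a nested mapping (see ``default_config``); every
stage block is validated before any stage runs, a manifest records
parameters, seeds and output checksums, and a stage failure halts the run
leaving earlier outputs intact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ailrep import io, lmm, loci, power, qc, replication, simdata

SPEC_VERSION = 1


def default_config() -> dict:
    return {
        "spec_version": SPEC_VERSION,
        "seed": 0,
        "simulate": {
            "n_families": 20,
            "n_generations": 6,
            "offspring_per_pair": 4,
            "n_chrom": 3,
            "snps_per_chrom": 40,
            "chrom_length_cm": 80.0,
            "n_causal": 2,
            "effect_size": 0.4,
            "sigma_g2": 0.3,
            "sigma_e2": 0.7,
            "study_effect_var": 0.0,
        },
        "qc": {"maf_min": 0.1, "hwe_min": 1.0e-6, "r2_min": 0.9,
               "het_sd": 3.0, "kinship_delta": 0.10},
        "gwas": {"loco": True},
        "threshold": {"n_perm": 200, "quantile": 0.95},
        "clump": {"r2": 0.1, "window_kb": 12150.0},
        "credset": {"r2_min": 0.8, "coverage": 0.99},
        "replicate": {"rep_alpha": 0.05},
        "power": {"grid": 10, "reps": 200, "gw_neg_log10_p": 4.85},
    }


def validate_config(cfg: dict) -> None:
    base = default_config()
    if cfg.get("spec_version") != SPEC_VERSION:
        raise ValueError(f"config spec_version must be {SPEC_VERSION}")
    for section, defaults in base.items():
        if section in ("spec_version", "seed"):
            continue
        block = cfg.get(section, {})
        if not isinstance(block, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in block.items():
            if key not in defaults:
                raise ValueError(f"unknown key {section}.{key}")
            if not isinstance(value, (int, float, bool)):
                raise ValueError(f"{section}.{key} must be numeric, got {value!r}")
    sim = {**base["simulate"], **cfg.get("simulate", {})}
    if sim["n_families"] < 2 or sim["n_generations"] < 2:
        raise ValueError("simulate block violates breeding preconditions")
    qc_blk = {**base["qc"], **cfg.get("qc", {})}
    if not (0 <= qc_blk["maf_min"] <= 0.5 and 0 <= qc_blk["hwe_min"] <= 1):
        raise ValueError("qc thresholds out of range")
    thr = {**base["threshold"], **cfg.get("threshold", {})}
    if thr["n_perm"] < 100:
        raise ValueError("threshold.n_perm must be >= 100")


def _merge(cfg: dict) -> dict:
    base = default_config()
    out = {"spec_version": SPEC_VERSION, "seed": int(cfg.get("seed", base["seed"]))}
    for section, defaults in base.items():
        if section in ("spec_version", "seed"):
            continue
        out[section] = {**defaults, **cfg.get(section, {})}
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_cohort(cfg, seed, out, tag, manifest):
    sim = cfg["simulate"]
    ped = simdata.build_ail_pedigree(
        int(sim["n_families"]), int(sim["n_generations"]),
        int(sim["offspring_per_pair"]), seed=seed,
    )
    gmap = simdata.make_genetic_map(
        n_chrom=int(sim["n_chrom"]), snps_per_chrom=int(sim["snps_per_chrom"]),
        chrom_length_cm=float(sim["chrom_length_cm"]), seed=seed,
        albino_proxy=True, agouti_proxy=True,
    )
    geno_all = simdata.gene_drop(ped, gmap, seed=seed + 1)
    last_gen = ped.n_generations - 1
    cohort_ids = ped.generation_ids(last_gen) + ped.generation_ids(last_gen - 1)
    geno = geno_all.subset_samples(cohort_ids)
    kin = simdata.kinship_from_pedigree(ped).loc[cohort_ids, cohort_ids]

    rng = np.random.default_rng(seed + 2)
    causal = list(
        rng.choice(geno.snp_ids, size=int(sim["n_causal"]), replace=False)
    )
    spec = simdata.TraitSimSpec(
        causal_effects={s: float(sim["effect_size"]) for s in causal},
        sigma_g2=float(sim["sigma_g2"]), sigma_e2=float(sim["sigma_e2"]),
        study_effect_var=float(sim["study_effect_var"]), seed=seed + 3,
    )
    pheno = simdata.simulate_phenotypes(geno, kin, spec)
    pheno = pheno.rename(columns={"trait": "trait1"})
    alb = simdata.simulate_phenotypes(geno, kin, simdata.TraitSimSpec(trait_type="albino"))
    pheno["albino"] = alb["albino"].to_numpy()

    io.write_dosage_tsv(geno, out / f"{tag}.dosage.tsv")
    io.write_pedigree_tsv(ped, out / f"{tag}.pedigree.tsv")
    io.write_phenotype_tsv(pheno, out / f"{tag}.pheno.tsv")
    manifest["stages"]["simulate"]["outputs"] += [
        f"{tag}.dosage.tsv", f"{tag}.pedigree.tsv", f"{tag}.pheno.tsv"
    ]
    return geno, kin, pheno, causal


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run all stages in dependency order; returns the manifest."""
    validate_config(cfg)
    cfg = _merge(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = {
        "spec_version": SPEC_VERSION,
        "config": cfg,
        "stages": {s: {"outputs": []} for s in
                   ["simulate", "qc", "gwas", "clump", "credset",
                    "replicate", "power"]},
    }

    # --- simulate two cohorts sharing a map (different breeding seeds)
    genoA, kinA, phenoA, causalA = _simulate_cohort(cfg, seed, out, "cohortA", manifest)
    genoB, kinB, phenoB, _ = _simulate_cohort(cfg, seed + 1000, out, "cohortB", manifest)

    # --- qc
    q = cfg["qc"]
    reports = {}
    for tag, geno in (("cohortA", genoA), ("cohortB", genoB)):
        snp_rep = qc.snp_filter(
            geno, maf_min=q["maf_min"], hwe_min=q["hwe_min"], r2_min=q["r2_min"]
        )
        snp_rep.to_csv(out / f"{tag}.snp_qc.tsv", sep="\t", index=False)
        samp_rep = qc.sample_qc(geno, k_sd=q["het_sd"])
        samp_rep.to_csv(out / f"{tag}.sample_qc.tsv", sep="\t")
        manifest["stages"]["qc"]["outputs"] += [f"{tag}.snp_qc.tsv", f"{tag}.sample_qc.tsv"]
        reports[tag] = snp_rep
    genoA = genoA.subset_snps(reports["cohortA"]["kept"].to_numpy())
    genoB = genoB.subset_snps(reports["cohortB"]["kept"].to_numpy())

    # --- gwas per cohort
    scans = {}
    for tag, geno, pheno in (("cohortA", genoA, phenoA), ("cohortB", genoB, phenoB)):
        y = lmm.quantile_normalize(pheno["trait1"].to_numpy())
        scan = lmm.assoc_scan(y, None, geno, loco=bool(cfg["gwas"]["loco"]))
        io.write_assoc_tsv(scan, out / f"{tag}.assoc.tsv")
        manifest["stages"]["gwas"]["outputs"].append(f"{tag}.assoc.tsv")
        scans[tag] = scan

    # --- permutation threshold on cohort A
    thr = lmm.permutation_threshold(
        lmm.quantile_normalize(phenoA["trait1"].to_numpy()), None, genoA,
        n_perm=int(cfg["threshold"]["n_perm"]),
        quantile=float(cfg["threshold"]["quantile"]), seed=seed + 7,
    )
    manifest["threshold_neg_log10_p"] = thr

    # --- clump + credible set on cohort A
    p_cut = 10.0 ** (-thr)
    lead_loci = loci.clump(
        scans["cohortA"], genoA, p_threshold=p_cut,
        r2=float(cfg["clump"]["r2"]), window_kb=float(cfg["clump"]["window_kb"]),
    )
    clump_df = pd.DataFrame(
        [
            {"lead_snp": l.lead_snp, "chrom": l.chrom, "pos": l.pos, "p": l.p,
             "n_members": len(l.members), "span_bp": l.span_bp,
             "member_ids": ",".join(l.members)}
            for l in lead_loci
        ],
        columns=["lead_snp", "chrom", "pos", "p", "n_members", "span_bp", "member_ids"],
    )
    clump_df.to_csv(out / "cohortA.clumps.tsv", sep="\t", index=False)
    manifest["stages"]["clump"]["outputs"].append("cohortA.clumps.tsv")

    if lead_loci:
        lead = lead_loci[0]
        scan = scans["cohortA"]
        region = scan[scan["chrom"] == lead.chrom][["snp_id"]].copy()
        region["z"] = replication.z_from_assoc(scan[scan["chrom"] == lead.chrom])
        cs = loci.credible_set(
            region, genoA, lead.lead_snp,
            r2_min=float(cfg["credset"]["r2_min"]),
            coverage=float(cfg["credset"]["coverage"]),
        )
        cs.table.to_csv(out / "cohortA.credset.tsv", sep="\t", index=False)
        manifest["stages"]["credset"]["outputs"].append("cohortA.credset.tsv")

    # --- replication (A as discovery)
    rep_report = {}
    try:
        pair = replication.pair_from_assoc(scans["cohortA"], scans["cohortB"], thr)
        for model in ("WC", "WC+C"):
            fit = replication.fit_replication_model(pair, model)
            z_bonf = float(
                stats.norm.isf(cfg["replicate"]["rep_alpha"] / pair.n_variants / 2.0)
            )
            rep_report[model] = {
                "sigma_g2": fit.sigma_g2, "sigma_c1_2": fit.sigma_c1_2,
                "sigma_c2_2": fit.sigma_c2_2, "loglik": fit.loglik,
                "n_variants": fit.n_variants, "t_disc": fit.t_disc,
                "predicted_rate": replication.predicted_replication_rate(
                    fit, pair, z_bonf
                ),
            }
        rep_report["empirical_rate"] = replication.empirical_replication_rate(
            pair, rep_alpha=float(cfg["replicate"]["rep_alpha"])
        )
    except ValueError as exc:
        rep_report["skipped"] = str(exc)
    (out / "replication.json").write_text(json.dumps(rep_report, indent=2))
    manifest["stages"]["replicate"]["outputs"].append("replication.json")

    # --- power at the first causal SNP, cohort B as replication set
    yB = lmm.quantile_normalize(phenoB["trait1"].to_numpy())
    KB = lmm.compute_grm(genoB)
    nf = lmm.fit_null(yB, None, KB)
    pc = power.PowerConfig(
        effect_sizes=np.linspace(0, 0.8, int(cfg["power"]["grid"])),
        n_reps=int(cfg["power"]["reps"]),
        genomewide_neg_log10_p=float(cfg["power"]["gw_neg_log10_p"]),
        seed=seed + 9,
    )
    snp = causalA[0] if causalA[0] in set(genoB.snp_ids) else genoB.snp_ids[0]
    curve = power.replication_power(genoB.dosage_of(snp), KB, nf, pc)
    curve.to_csv(out / "power.tsv", sep="\t", index=False)
    manifest["stages"]["power"]["outputs"].append("power.tsv")

    # --- checksums + manifest
    checks = {}
    for stage in manifest["stages"].values():
        for rel in stage["outputs"]:
            checks[rel] = _checksum(out / rel)
    manifest["checksums"] = checks
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
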