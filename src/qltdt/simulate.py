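"""Synthetic nuclear-family data generator.

Emulates a lipid-lowering-drug family study: nuclear families with
genotyped parents and offspring, two correlated log-normal traits
(triglyceride-like primary trait and HDL-like covariate trait) measured at
four time points, a treatment administered between time points 2 and 3,
per-time-point missingness, and an optional confounded two-subpopulation
stratification scenario.  Every stage of the analysis pipeline can be
exercised against data with known truth.

Parents are drawn under Hardy-Weinberg at the configured minor-allele
frequency; offspring genotypes arise from fair Mendelian gamete draws, so
under a zero genetic effect the transmission test's null holds exactly.
A single master seed spawns named substreams (structure, genotypes,
phenotypes, missingness), so changing one scenario dimension does not
perturb the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .family_data import NuclearFamilyUnit, OffspringObs
from .phenotypes import (
    adjust_for_covariate,
    build_phenotypes,
    get_definition,
    log_transform,
    prepare_phenotypes,
)
from .transmission import Mode, test_variant

TRAIT_COLUMNS = ["TG1", "TG2", "TG3", "TG4"]
COV_COLUMNS = ["HDL1", "HDL2", "HDL3", "HDL4"]

#: log-scale per-allele effect giving mid-range (~50-70%) power at the
#: default design (200 families, MAF 0.3, bivariate phenotype)
CALIBRATED_EFFECT = 0.09


@dataclass(frozen=True)
class Stratification:
    """Two confounded subpopulations: different MAFs and a trait mean shift.

    Families are split evenly; subpopulation 2 has minor-allele frequency
    ``maf2`` and its members' log-trait means are shifted by ``delta``.
    Because allele frequency and phenotype level move together, naive
    association between the non-transmission (allele-frequency) channel
    and the trait is confounded.
    """

    maf1: float = 0.1
    maf2: float = 0.5
    delta: float = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the target study design.

    Effects are on the natural-log trait scale: ``genetic_effect`` per
    transmitted minor allele, ``drug_effect`` added at time points 3-4,
    ``covariate_coupling`` per unit of centered log-covariate.
    """

    seed: int
    n_families: int = 200
    offspring_min: int = 2
    offspring_max: int = 8
    n_variants: int = 1
    maf: float = 0.3
    genetic_effect: float = 0.0
    drug_effect: float = -0.25
    time_means: tuple[float, ...] = (4.70, 4.72, 4.70, 4.68)
    covariate_means: tuple[float, ...] = (3.90, 3.92, 3.95, 3.93)
    residual_sd: float = 0.5
    residual_correlation: float = 0.5
    family_effect_sd: float = 0.3
    covariate_coupling: float = -0.3
    covariate_residual_sd: float = 0.3
    covariate_correlation: float = 0.5
    covariate_family_sd: float = 0.15
    missing_rates_trait: tuple[float, ...] = (0.27, 0.0, 0.44, 0.26)
    missing_rates_covariate: tuple[float, ...] = (0.27, 0.0, 0.28, 0.22)
    stratification: Optional[Stratification] = None
    correlated_transmissions: float = 0.0  # robustness scenario, default off

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        for rho in (self.residual_correlation, self.covariate_correlation):
            if not (0.0 <= rho < 1.0):
                raise ValueError("exchangeable correlation must lie in [0, 1)")
        for r in (*self.missing_rates_trait, *self.missing_rates_covariate):
            if not (0.0 <= r < 1.0):
                raise ValueError("missing rates must lie in [0, 1)")
        if not (1 <= self.offspring_min <= self.offspring_max):
            raise ValueError("invalid offspring-per-family range")
        if len(self.time_means) != 4 or len(self.covariate_means) != 4:
            raise ValueError("exactly 4 time points are modelled")


def calibration_config(seed: int, **overrides) -> SimulationConfig:
    """Config used by the calibration/power harnesses.

    Identical to the defaults except missingness is off: statistic
    calibration is separated from imputation, which has its own checks.
    """
    overrides.setdefault("missing_rates_trait", (0.0,) * 4)
    overrides.setdefault("missing_rates_covariate", (0.0,) * 4)
    return SimulationConfig(seed=seed, **overrides)


def stratified_config(seed: int, **overrides) -> SimulationConfig:
    """The confounded two-subpopulation null scenario."""
    overrides.setdefault("stratification", Stratification())
    return calibration_config(seed, **overrides)


@dataclass
class SimulatedData:
    """In-memory result of one simulation (pre-serialization)."""

    config: SimulationConfig
    individual_ids: list[str]
    family_ids: np.ndarray  # family index per individual
    family_labels: list[str]
    role: np.ndarray  # 0 father, 1 mother, 2 offspring
    subpop: np.ndarray  # per family
    dosage: np.ndarray  # individuals x variants
    variant_ids: list[str]
    trait_log: np.ndarray  # latent complete log-scale values, n x 4
    covariate_log: np.ndarray
    trait_raw: pd.DataFrame  # exp scale with NaN for masked cells
    covariate_raw: pd.DataFrame

    @property
    def founder_ids(self) -> list[str]:
        return [i for i, r in zip(self.individual_ids, self.role) if r < 2]

    @property
    def offspring_mask(self) -> np.ndarray:
        return self.role == 2


def _exchangeable_noise(rng, n, t, sd, rho):
    shared = rng.standard_normal(n)[:, None]
    indep = rng.standard_normal((n, t))
    return sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep)


def simulate_arrays(config: SimulationConfig) -> SimulatedData:
    """Generate one dataset in memory; deterministic in ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_geno, rng_pheno, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    F = config.n_families
    n_off = rng_struct.integers(config.offspring_min, config.offspring_max + 1, size=F)
    subpop = np.zeros(F, dtype=int)
    if config.stratification is not None:
        subpop[F // 2:] = 1

    ids: list[str] = []
    fam_idx: list[int] = []
    role: list[int] = []
    fam_labels = [f"F{i + 1:04d}" for i in range(F)]
    for i in range(F):
        ids += [f"{fam_labels[i]}_P1", f"{fam_labels[i]}_P2"]
        fam_idx += [i, i]
        role += [0, 1]
        for j in range(n_off[i]):
            ids.append(f"{fam_labels[i]}_C{j + 1}")
            fam_idx.append(i)
            role.append(2)
    fam_idx = np.array(fam_idx)
    role = np.array(role)
    n = len(ids)
    is_child = role == 2

    # genotypes: parents HWE, offspring fair Mendelian gametes
    if config.stratification is None:
        p_fam = np.full(F, config.maf)
    else:
        p_fam = np.where(subpop == 0, config.stratification.maf1, config.stratification.maf2)
    V = config.n_variants
    dosage = np.empty((n, V), dtype=int)
    parent_rows = ~is_child
    dosage[parent_rows] = rng_geno.binomial(2, p_fam[fam_idx[parent_rows]][:, None], size=(parent_rows.sum(), V))
    father_row = np.flatnonzero(role == 0)  # one per family, ordered
    mother_row = np.flatnonzero(role == 1)
    child_rows = np.flatnonzero(is_child)
    fd = dosage[father_row][fam_idx[child_rows]]
    md = dosage[mother_row][fam_idx[child_rows]]
    u1 = rng_geno.random(size=(len(child_rows), V))
    u2 = rng_geno.random(size=(len(child_rows), V))
    if config.correlated_transmissions > 0.0:
        # robustness scenario: siblings copy the first sib's gametes w.p. c
        first_of_fam = np.concatenate(([True], np.diff(fam_idx[child_rows]) != 0))
        copy = (rng_geno.random(len(child_rows)) < config.correlated_transmissions) & ~first_of_fam
        fam_first_index = np.maximum.accumulate(np.where(first_of_fam, np.arange(len(child_rows)), 0))
        u1 = np.where(copy[:, None], u1[fam_first_index], u1)
        u2 = np.where(copy[:, None], u2[fam_first_index], u2)
    gf = (u1 < fd / 2.0).astype(int)
    gm = (u2 < md / 2.0).astype(int)
    dosage[child_rows] = gf + gm

    # phenotypes (log scale); variant 0 is the causal one when effect != 0
    causal = dosage[:, 0].astype(float)
    mu_c = np.array(config.covariate_means)
    cov_log = mu_c[None, :] + _exchangeable_noise(
        rng_pheno, n, 4, config.covariate_residual_sd, config.covariate_correlation
    )
    cov_log[is_child] += (config.covariate_family_sd * rng_pheno.standard_normal(F))[
        fam_idx[is_child], None
    ]
    mu_t = np.array(config.time_means)
    drug = np.array([0.0, 0.0, 1.0, 1.0]) * config.drug_effect
    trait_log = (
        mu_t[None, :]
        + drug[None, :]
        + config.genetic_effect * causal[:, None]
        + config.covariate_coupling * (cov_log - mu_c[None, :])
    )
    if config.stratification is not None:
        trait_log += (config.stratification.delta * subpop[fam_idx])[:, None]
    trait_log[is_child] += (config.family_effect_sd * rng_pheno.standard_normal(F))[
        fam_idx[is_child], None
    ]
    trait_log += _exchangeable_noise(rng_pheno, n, 4, config.residual_sd,
                                     config.residual_correlation)

    trait_raw = np.exp(trait_log)
    cov_raw = np.exp(cov_log)
    mask_t = rng_miss.random((n, 4)) < np.array(config.missing_rates_trait)[None, :]
    mask_c = rng_miss.random((n, 4)) < np.array(config.missing_rates_covariate)[None, :]
    trait_df = pd.DataFrame(np.where(mask_t, np.nan, trait_raw), index=ids, columns=TRAIT_COLUMNS)
    cov_df = pd.DataFrame(np.where(mask_c, np.nan, cov_raw), index=ids, columns=COV_COLUMNS)
    trait_df.index.name = cov_df.index.name = "individual_id"

    variant_ids = [f"snp{v + 1}" for v in range(V)]
    return SimulatedData(
        config=config, individual_ids=ids, family_ids=fam_idx,
        family_labels=fam_labels, role=role, subpop=subpop, dosage=dosage,
        variant_ids=variant_ids, trait_log=trait_log, covariate_log=cov_log,
        trait_raw=trait_df, covariate_raw=cov_df,
    )


# ---------------------------------------------------------------------------
# serialization to the pipeline's on-disk formats


def write_pedigree(data: SimulatedData, path: str) -> None:
    with open(path, "w") as fh:
        for i, ind in enumerate(data.individual_ids):
            fam = data.family_labels[data.family_ids[i]]
            if data.role[i] == 2:
                father, mother, sex = f"{fam}_P1", f"{fam}_P2", "0"
            else:
                father, mother = "0", "0"
                sex = "1" if data.role[i] == 0 else "2"
            fh.write(f"{fam} {ind} {father} {mother} {sex} -9\n")


def write_vcf(data: SimulatedData, path: str) -> None:
    n_chrom = 22
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in range(1, n_chrom + 1):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(data.individual_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for v, vid in enumerate(data.variant_ids):
            chrom = v % n_chrom + 1
            pos = 10_000 * (v // n_chrom + 1) + 137
            gts = "\t".join(gt_str[int(d)] for d in data.dosage[:, v])
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_phenotypes(data: SimulatedData, path: str) -> None:
    wide = pd.concat([data.trait_raw, data.covariate_raw], axis=1)
    wide.to_csv(path, sep="\t", na_rep="NA")


def write_truth(data: SimulatedData, path: str) -> None:
    truth = {
        "config": dataclasses.asdict(data.config),
        "causal_variant": data.variant_ids[0] if data.config.genetic_effect else None,
        "variant_ids": data.variant_ids,
        "individual_ids": data.individual_ids,
        "role": data.role.tolist(),
        "subpopulation_by_family": data.subpop.tolist(),
        "dosage": data.dosage.tolist(),
        "trait_log": data.trait_log.tolist(),
        "covariate_log": data.covariate_log.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(truth, fh)


def simulate_dataset(config: SimulationConfig, out_dir: str) -> dict:
    """Generate a dataset and write PED/VCF/TSV/truth files.

    Returns the mapping of artifact names to paths.  Identical configs
    (including seed) produce byte-identical files.
    """
    data = simulate_arrays(config)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "pedigree": os.path.join(out_dir, "families.ped"),
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_pedigree(data, paths["pedigree"])
    write_vcf(data, paths["vcf"])
    write_phenotypes(data, paths["phenotypes"])
    write_truth(data, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# in-memory analysis of a simulated dataset (calibration / power harnesses)


def _units_for_variant(data: SimulatedData, variant: int = 0) -> list[NuclearFamilyUnit]:
    units = []
    col = data.dosage[:, variant]
    father_row = np.flatnonzero(data.role == 0)
    mother_row = np.flatnonzero(data.role == 1)
    for i, fam in enumerate(data.family_labels):
        fd, md = int(col[father_row[i]]), int(col[mother_row[i]])
        if fd != 1 and md != 1:
            continue
        rows = np.flatnonzero((data.family_ids == i) & (data.role == 2))
        offspring = [OffspringObs(data.individual_ids[r], int(col[r])) for r in rows]
        if offspring:
            units.append(NuclearFamilyUnit(fam, fd, md, offspring))
    return units


def prepare_offspring_phenotypes(data: SimulatedData, definition: str) -> dict:
    """Offspring phenotype vectors for one definition of a simulated dataset.

    Complete data skips the (no-op) EM/imputation stage; with missingness
    the full founder-EM + plug-in imputation pipeline runs.
    """
    d = get_definition(definition)
    founders = data.founder_ids
    has_missing = data.trait_raw.isna().any().any() or (
        d.adjusted and data.covariate_raw.isna().any().any()
    )
    if has_missing:
        phen, _ = prepare_phenotypes(
            data.trait_raw, data.covariate_raw if d.adjusted else None,
            founders, [definition],
        )
        scores = phen[definition]
    else:
        trait_log = log_transform(data.trait_raw)
        if d.adjusted:
            trait_log = adjust_for_covariate(trait_log, log_transform(data.covariate_raw), founders)
        scores = build_phenotypes(d, trait_log)
    score_arr = scores.to_numpy()
    return {
        ind: score_arr[i]
        for i, ind in enumerate(data.individual_ids)
        if data.role[i] == 2
    }


def analyze_simulated(
    data: SimulatedData,
    definition: str = "MTBAT",
    mode: Mode = "both_parents",
    variant: int = 0,
    min_informative: int = 21,
    phenotype_map: Optional[dict] = None,
):
    """Run phenotype preparation + transmission test on one simulated variant."""
    d = get_definition(definition)
    pmap = phenotype_map if phenotype_map is not None else prepare_offspring_phenotypes(data, definition)
    units = _units_for_variant(data, variant)
    return test_variant(units, pmap, d.k, mode=mode,
                        variant_id=data.variant_ids[variant],
                        min_informative=min_informative)


def _replicate_seeds(seed: int, n: int) -> list[int]:
    # keep spawned seeds small enough to round-trip through configs
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1]


def simulate_null_statistics(
    config: SimulationConfig,
    n_replicates: int,
    mode: Mode = "both_parents",
    definition: str = "MTBAT",
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo null distribution of the Wald statistic.

    Requires ``genetic_effect == 0``.  Runs the in-memory pipeline once per
    replicate on a single variant and reports the statistics, p-values,
    empirical size at ``alpha`` with a binomial 99% interval, and the count
    of replicates excluded for degenerate fits.
    """
    if config.genetic_effect != 0.0:
        raise ValueError("null calibration requires genetic_effect == 0")
    stats_, pvals = [], []
    n_excluded = 0
    for s in _replicate_seeds(config.seed, n_replicates):
        data = simulate_arrays(replace(config, seed=s))
        res = analyze_simulated(data, definition=definition, mode=mode)
        if res.status != "ok":
            n_excluded += 1
            continue
        stats_.append(res.statistic)
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    stats_ = np.array(stats_)
    m = len(pvals)
    size = float(np.mean(pvals < alpha)) if m else float("nan")
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / m) if m else float("nan")
    return {
        "statistics": stats_, "p_values": pvals,
        "empirical_size": size, "size_ci99": (size - half, size + half),
        "n_used": m, "n_excluded": n_excluded,
        "df": get_definition(definition).k,
    }


def simulate_power_curve(
    config: SimulationConfig,
    effect_grid: Sequence[float],
    n_replicates: int,
    modes: Sequence[Mode] = ("both_parents", "het_only"),
    definition: str = "MTBAT",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection rate per (effect size, mode), paired across modes.

    The same simulated replicate is analyzed under every mode, so mode
    comparisons share Monte-Carlo noise.  Returns a table with power and
    its Monte-Carlo standard error.
    """
    rows = []
    for a in effect_grid:
        base = replace(config, genetic_effect=float(a))
        hits = {m: 0 for m in modes}
        used = {m: 0 for m in modes}
        for s in _replicate_seeds(config.seed, n_replicates):
            data = simulate_arrays(replace(base, seed=s))
            pmap = prepare_offspring_phenotypes(data, definition)
            for m in modes:
                res = analyze_simulated(data, definition, m, phenotype_map=pmap)
                if res.status == "ok":
                    used[m] += 1
                    hits[m] += int(res.p_value < alpha)
        for m in modes:
            pw = hits[m] / used[m] if used[m] else float("nan")
            mcse = float(np.sqrt(pw * (1 - pw) / used[m])) if used[m] else float("nan")
            rows.append({"effect": float(a), "mode": m, "power": pw,
                         "mcse": mcse, "n_used": used[m]})
    return pd.DataFrame(rows)
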