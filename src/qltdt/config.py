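"""Run configuration and the end-to-end pipeline driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from . import __version__
from .family_data import read_genotypes, read_pedigree
from .phenotypes import prepare_phenotypes, read_phenotypes
from .scan import ScanDataset, run_scan, write_results

logger = logging.getLogger(__name__)

ALL_DEFINITIONS = ["MTBAT", "MTBATAdj", "TBATPre", "TBATPreAdj", "TBATPost", "TBATPostAdj"]


@dataclass
class RunConfig:
    pedigree: str
    vcf: str
    phenotypes: str
    out_dir: str = "qltdt_out"
    definitions: list[str] = field(default_factory=lambda: list(ALL_DEFINITIONS))
    mode: str = "both_parents"
    fdr_level: float = 0.05
    maf_threshold: float = 0.05
    min_informative: int = 21
    sandwich: str = "family"
    trait_columns: list[str] = field(default_factory=lambda: ["TG1", "TG2", "TG3", "TG4"])
    covariate_columns: list[str] = field(default_factory=lambda: ["HDL1", "HDL2", "HDL3", "HDL4"])
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError("fdr_level must lie in (0, 1)")
        if not (0.0 <= self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")
        if self.mode not in ("both_parents", "het_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sandwich not in ("family", "offspring"):
            raise ValueError(f"unknown sandwich clustering {self.sandwich!r}")


def load_run_config(yaml_path: Optional[str], **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides.

    Any override whose value is None is ignored (the YAML/default wins).
    """
    base: dict = {}
    if yaml_path:
        with open(yaml_path) as fh:
            base = yaml.safe_load(fh) or {}
    for key, val in overrides.items():
        if val is not None:
            base[key] = val
    return RunConfig(**base)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """prepare -> scan on disk inputs; writes results, scan log and manifest.

    Returns the artifact path mapping.  Fatal errors propagate as
    exceptions (the CLI turns them into a one-line diagnostic and a
    nonzero exit); per-variant problems are recorded in the results table.
    """
    for p in (config.pedigree, config.vcf, config.phenotypes):
        if not os.path.exists(p):
            raise FileNotFoundError(f"input file not found: {p}")
    os.makedirs(config.out_dir, exist_ok=True)

    logger.info("reading pedigree %s", config.pedigree)
    pedigree = read_pedigree(config.pedigree)
    logger.info("reading genotypes %s", config.vcf)
    genotypes = read_genotypes(config.vcf, pedigree)
    logger.info("reading phenotypes %s", config.phenotypes)
    wide = read_phenotypes(config.phenotypes)
    trait = wide[config.trait_columns]
    need_cov = any(d.endswith("Adj") for d in config.definitions)
    covariate = wide[config.covariate_columns] if need_cov else None

    logger.info("preparing phenotypes for %s", ",".join(config.definitions))
    phen, report = prepare_phenotypes(trait, covariate, pedigree.founders, config.definitions)

    dataset = ScanDataset(pedigree, genotypes, phen)
    paths = {
        "results": os.path.join(config.out_dir, "results.tsv"),
        "scan_log": os.path.join(config.out_dir, "scan_log.jsonl"),
        "manifest": os.path.join(config.out_dir, "manifest.json"),
        "prep_report": os.path.join(config.out_dir, "phenotype_report.json"),
    }
    logger.info("scanning %d variants", genotypes.n_variants)
    results = run_scan(
        dataset, config.definitions, mode=config.mode, fdr_level=config.fdr_level,
        maf_threshold=config.maf_threshold, min_informative=config.min_informative,
        cluster=config.sandwich, log_path=paths["scan_log"],
    )
    write_results(results, paths["results"])
    with open(paths["prep_report"], "w") as fh:
        json.dump(report, fh, indent=2)
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {
            "pedigree": _sha256(config.pedigree),
            "vcf": _sha256(config.vcf),
            "phenotypes": _sha256(config.phenotypes),
        },
        "n_variants_tested": int((results["status"] == "ok").sum()),
        "n_significant": int(results["significant"].sum()),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote %s", paths["results"])
    return paths
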