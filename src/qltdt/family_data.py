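"""Pedigree, genotype and nuclear-family handling.

Reads PED/FAM pedigrees and VCF genotypes, orients every variant to its
minor allele (computed among founders), applies the monomorphic / low-MAF
variant filters, and assembles the per-SNP nuclear-family units the
transmission test consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"

#: a variant is kept only if its founder minor-allele frequency is >= this
DEFAULT_MAF_THRESHOLD = 0.05

#: a variant is testable only with strictly more than 20 informative families
DEFAULT_MIN_INFORMATIVE = 21


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class NuclearFamily:
    """A father-mother pair and their common offspring."""

    family_id: str
    father_id: str
    mother_id: str
    offspring_ids: tuple[str, ...]


@dataclass
class PedigreeTable:
    """Validated pedigree: individuals, parent links, founder flags.

    ``table`` has columns family_id, individual_id, father_id, mother_id,
    sex, founder.  ``nuclear_families`` is the decomposition into
    father-mother pairs with their common offspring.
    """

    table: pd.DataFrame
    nuclear_families: list[NuclearFamily] = field(default_factory=list)

    @property
    def individuals(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def founders(self) -> list[str]:
        return list(self.table.loc[self.table["founder"], "individual_id"])

    def __post_init__(self) -> None:
        if not self.nuclear_families:
            self.nuclear_families = _decompose_nuclear(self.table)


def _decompose_nuclear(table: pd.DataFrame) -> list[NuclearFamily]:
    fams: list[NuclearFamily] = []
    kids = table[(table["father_id"] != MISSING_PARENT) & (table["mother_id"] != MISSING_PARENT)]
    for (fam, fa, mo), grp in kids.groupby(["family_id", "father_id", "mother_id"], sort=True):
        fams.append(NuclearFamily(str(fam), str(fa), str(mo), tuple(grp["individual_id"])))
    return fams


def read_pedigree(path: str) -> PedigreeTable:
    """Read a whitespace-delimited PED/FAM file.

    Columns: family, individual, father, mother[, sex, phenotype]. "0"
    denotes a missing parent.  Founders are rows with both parents missing.

    Raises :class:`PedigreeError` on duplicate individual IDs, parent IDs
    that do not resolve within the family, or cyclic parentage.
    """
    raw = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if raw.shape[1] < 4:
        raise PedigreeError(f"pedigree file {path!r} needs >=4 columns, got {raw.shape[1]}")
    table = raw.iloc[:, :4].copy()
    table.columns = ["family_id", "individual_id", "father_id", "mother_id"]
    table["sex"] = raw.iloc[:, 4] if raw.shape[1] > 4 else "0"
    return build_pedigree(table)


def build_pedigree(table: pd.DataFrame) -> PedigreeTable:
    """Validate a pedigree data frame and derive founder flags."""
    table = table.copy()
    dup = table["individual_id"][table["individual_id"].duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate individual ID {dup.iloc[0]!r}")
    # a parent specified only "half way" cannot be decomposed into trios
    half = (table["father_id"] == MISSING_PARENT) ^ (table["mother_id"] == MISSING_PARENT)
    if half.any():
        bad = table.loc[half, "individual_id"].iloc[0]
        raise PedigreeError(f"individual {bad!r} has exactly one missing parent")
    table["founder"] = (table["father_id"] == MISSING_PARENT) & (
        table["mother_id"] == MISSING_PARENT
    )

    by_family = {fam: set(grp["individual_id"]) for fam, grp in table.groupby("family_id")}
    parent_of: dict[str, tuple[str, str]] = {}
    for row in table.itertuples(index=False):
        if row.founder:
            continue
        for pid in (row.father_id, row.mother_id):
            if pid not in by_family[row.family_id]:
                raise PedigreeError(
                    f"parent {pid!r} of {row.individual_id!r} not present in family {row.family_id!r}"
                )
        parent_of[row.individual_id] = (row.father_id, row.mother_id)

    _check_acyclic(parent_of)
    return PedigreeTable(table.reset_index(drop=True))


def _check_acyclic(parent_of: dict[str, tuple[str, str]]) -> None:
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            raise PedigreeError(f"cyclic parentage involving {node!r}")
        state[node] = 0
        for p in parent_of.get(node, ()):
            visit(p, stack + [node])
        state[node] = 1

    for ind in list(parent_of):
        visit(ind, [])


# ---------------------------------------------------------------------------
# genotypes


class GenotypeError(ValueError):
    """Raised for unusable genotype input."""


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix (individuals x variants).

    ``dosage`` is float with NaN for missing calls; non-missing entries are
    0/1/2 counts of the minor allele after per-variant orientation.
    ``variants`` has columns variant_id, chromosome, position, flipped.
    """

    individuals: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self._row = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def row_index(self, individual_id: str) -> int:
        return self._row[individual_id]

    def dosage_of(self, individual_id: str, variant_index: int) -> float:
        return float(self.dosage[self._row[individual_id], variant_index])


def read_genotypes(path: str, pedigree: PedigreeTable) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into minor-allele dosages.

    Multi-allelic records are skipped with a warning; samples absent from
    the pedigree are ignored; dosages are oriented so that the counted
    allele is the minor allele among pedigree founders.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    keep = [i for i, s in enumerate(samples) if s in set(pedigree.individuals)]
    if not keep:
        raise GenotypeError(f"no overlap between VCF samples and pedigree individuals in {path!r}")
    kept_ids = [samples[i] for i in keep]

    rows = []
    meta = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", rec.CHROM, rec.POS)
            continue
        gt = rec.gt_types.astype(float)  # 0/1/2 ALT dosage, 3 unknown (gts012)
        gt[gt == 3] = np.nan
        rows.append(gt[keep])
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS))
    if not rows:
        raise GenotypeError(f"no usable biallelic records in {path!r}")

    dosage = np.stack(rows, axis=1)  # individuals x variants
    variants = pd.DataFrame(meta, columns=["variant_id", "chromosome", "position"])
    gm = GenotypeMatrix(kept_ids, variants, dosage)
    return orient_to_minor_allele(gm, pedigree)


def orient_to_minor_allele(genotypes: GenotypeMatrix, pedigree: PedigreeTable) -> GenotypeMatrix:
    """Flip variants whose counted-allele frequency among founders exceeds 0.5.

    Ties (frequency exactly 0.5) keep the original orientation, so the
    operation is idempotent.
    """
    founder_rows = [genotypes.row_index(f) for f in pedigree.founders if f in genotypes._row]
    sub = genotypes.dosage[founder_rows]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(sub, axis=0) / 2.0
    flip = freq > 0.5
    dosage = genotypes.dosage.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    variants = genotypes.variants.copy()
    variants["flipped"] = flip
    return GenotypeMatrix(genotypes.individuals, variants, dosage)


def minor_allele_frequency(
    genotypes: GenotypeMatrix, pedigree: PedigreeTable
) -> np.ndarray:
    """Per-variant minor-allele frequency among founders.

    Returns NaN for variants with no genotyped founder (flagged unusable
    downstream).  After orientation the result is <= 0.5 by construction.
    """
    founder_rows = [genotypes.row_index(f) for f in pedigree.founders if f in genotypes._row]
    sub = genotypes.dosage[founder_rows]
    with np.errstate(invalid="ignore"):
        return np.nanmean(sub, axis=0) / 2.0


def filter_variants(
    genotypes: GenotypeMatrix,
    pedigree: PedigreeTable,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> tuple[list[int], pd.DataFrame]:
    """Apply the monomorphic / low-MAF exclusions.

    Returns (retained variant indices, exclusion log with columns
    variant_id, reason).  A variant is retained iff its founder MAF is
    defined, nonzero (not monomorphic) and >= ``maf_threshold``.
    """
    maf = minor_allele_frequency(genotypes, pedigree)
    retained: list[int] = []
    excluded: list[tuple[str, str]] = []
    for i, f in enumerate(maf):
        vid = genotypes.variants["variant_id"].iloc[i]
        if np.isnan(f):
            excluded.append((vid, "no_genotyped_founder"))
        elif f == 0.0:
            excluded.append((vid, "monomorphic"))
        elif f < maf_threshold:
            excluded.append((vid, f"maf_below_{maf_threshold}"))
        else:
            retained.append(i)
    log = pd.DataFrame(excluded, columns=["variant_id", "reason"])
    return retained, log


# ---------------------------------------------------------------------------
# per-SNP nuclear family units


@dataclass
class OffspringObs:
    individual_id: str
    dosage: int
    phenotype: Optional[np.ndarray] = None


@dataclass
class NuclearFamilyUnit:
    """One informative nuclear family at one SNP."""

    family_id: str
    father_dosage: int
    mother_dosage: int
    offspring: list[OffspringObs]


def _mendelian_consistent(f: int, m: int, c: int) -> bool:
    gametes = {0: (0,), 1: (0, 1), 2: (1,)}
    return c in {gf + gm for gf in gametes[f] for gm in gametes[m]}


def informative_families(
    variant_index: int,
    pedigree: PedigreeTable,
    genotypes: GenotypeMatrix,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> tuple[list[NuclearFamilyUnit], bool]:
    """Assemble informative nuclear-family units for one variant.

    A family enters iff both parents are genotyped and at least one parent
    is heterozygous.  Offspring with missing genotypes are dropped;
    Mendelian-inconsistent offspring are dropped with a warning.  The
    testable flag is true iff strictly more than ``min_informative - 1``
    informative families remain.
    """
    units: list[NuclearFamilyUnit] = []
    col = genotypes.dosage[:, variant_index]
    for fam in pedigree.nuclear_families:
        try:
            fd = col[genotypes.row_index(fam.father_id)]
            md = col[genotypes.row_index(fam.mother_id)]
        except KeyError:
            continue
        if np.isnan(fd) or np.isnan(md):
            continue
        fd, md = int(fd), int(md)
        if fd != 1 and md != 1:
            continue
        offspring = []
        for cid in fam.offspring_ids:
            try:
                cd = col[genotypes.row_index(cid)]
            except KeyError:
                continue
            if np.isnan(cd):
                continue
            cd = int(cd)
            if not _mendelian_consistent(fd, md, cd):
                logger.warning(
                    "Mendelian inconsistency at variant %s: family %s offspring %s (%d,%d)->%d",
                    genotypes.variants["variant_id"].iloc[variant_index],
                    fam.family_id, cid, fd, md, cd,
                )
                continue
            offspring.append(OffspringObs(cid, cd))
        if offspring:
            units.append(NuclearFamilyUnit(fam.family_id, fd, md, offspring))
    testable = len(units) >= min_informative
    return units, testable
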