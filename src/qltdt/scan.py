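"""Genome scan orchestration: per-variant tests, FDR control, result I/O."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .family_data import (
    DEFAULT_MAF_THRESHOLD,
    DEFAULT_MIN_INFORMATIVE,
    GenotypeMatrix,
    PedigreeTable,
    filter_variants,
    informative_families,
)
from .phenotypes import get_definition
from .transmission import Mode, test_variant

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "variant_id", "chromosome", "position", "phenotype_definition", "mode",
    "n_informative_families", "n_offspring_used", "statistic", "df",
    "p_value", "q_value", "significant", "status",
]


def benjamini_hochberg(p_values: Sequence[float], fdr_level: float = 0.05):
    """Step-up BH procedure.

    Returns (q_values, reject flags).  q_(i) = min_{j>=i} (m/j) p_(j),
    capped at 1; the rejection set is every p at or below the largest
    p_(i) <= (i/m) * level.  Ties are handled by a stable sort.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = np.minimum.accumulate((m / np.arange(m, 0, -1)) * ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    passing = np.flatnonzero(ranked <= (np.arange(1, m + 1) / m) * fdr_level)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return q, reject


@dataclass
class ScanDataset:
    """Inputs to a scan: pedigree, oriented genotypes, prepared phenotypes."""

    pedigree: PedigreeTable
    genotypes: GenotypeMatrix
    phenotypes: dict  # definition name -> DataFrame (individual x k)


def run_scan(
    dataset: ScanDataset,
    definitions: Sequence[str],
    mode: Mode = "both_parents",
    fdr_level: float = 0.05,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    cluster: str = "family",
    log_path: Optional[str] = None,
) -> pd.DataFrame:
    """Test every retained variant under every phenotype definition.

    Emits one row per (variant, definition); BH is applied within each
    definition across rows with status "ok".  Output rows are sorted by
    (chromosome, position, definition) so the scan is invariant to input
    variant order.  Per-variant failures are recorded in ``status`` and
    never abort the scan.
    """
    retained, _excl = filter_variants(dataset.genotypes, dataset.pedigree, maf_threshold)
    phen_maps = {}
    for name in definitions:
        d = get_definition(name)
        df = dataset.phenotypes[name]
        phen_maps[name] = (d, {ind: row.to_numpy() for ind, row in df.iterrows()})

    rows = []
    log_records = []
    for vi in retained:
        vmeta = dataset.genotypes.variants.iloc[vi]
        units, testable = informative_families(
            vi, dataset.pedigree, dataset.genotypes, min_informative
        )
        for name in definitions:
            d, pmap = phen_maps[name]
            res = test_variant(
                units, pmap, d.k, mode=mode, variant_id=str(vmeta["variant_id"]),
                min_informative=min_informative, cluster=cluster, testable=testable,
            )
            rows.append({
                "variant_id": res.variant_id,
                "chromosome": str(vmeta["chromosome"]),
                "position": int(vmeta["position"]),
                "phenotype_definition": name,
                "mode": mode,
                "n_informative_families": res.n_informative_families,
                "n_offspring_used": res.n_offspring_used,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "status": res.status,
            })
            log_records.append({
                "variant_id": res.variant_id, "definition": name,
                "status": res.status, "message": res.message,
                **{k: v for k, v in res.diagnostics.items() if np.isscalar(v)},
            })

    results = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c not in ("q_value", "significant")])
    results["q_value"] = np.nan
    results["significant"] = False
    for name in definitions:
        sel = (results["phenotype_definition"] == name) & (results["status"] == "ok")
        if sel.any():
            q, rej = benjamini_hochberg(results.loc[sel, "p_value"].to_numpy(), fdr_level)
            results.loc[sel, "q_value"] = q
            results.loc[sel, "significant"] = rej
    results = results.sort_values(
        ["chromosome", "position", "phenotype_definition"], kind="stable"
    ).reset_index(drop=True)[RESULT_COLUMNS]

    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec) + "\n")
    return results


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write the scan table as TSV (header + fixed column order, %.6g floats)."""
    out = results[RESULT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str) -> pd.DataFrame:
    """Round-trip reader for :func:`write_results` output."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return df[RESULT_COLUMNS]
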