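"""Longitudinal phenotype preparation.

Turns raw individual x time-point trait tables into the k-dimensional
offspring phenotype vectors the transmission test consumes: natural-log
transform, advisory Kolmogorov-Smirnov normality report, EM estimation of
the multivariate-normal mean/covariance on founders with plug-in
conditional-expectation imputation for everyone, optional covariate
(HDL-style) adjustment by founder-fitted least squares, and first
principal components of the pre-treatment and post-treatment time-point
pairs.

Phenotype definitions follow the treatment design (a drug administered
between time points 2 and 3): the pre-treatment summary is PC1 of time
points 1-2, the post-treatment summary PC1 of time points 3-4, and the
bivariate phenotype stacks both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class PhenotypeError(ValueError):
    pass


# A PhenotypeMatrix is a pandas DataFrame indexed by individual_id with one
# column per trait x time point; NaN marks missing cells.


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a wide phenotype TSV (individual_id + one column per measurement)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
    df = df.set_index(df.columns[0])
    df.index.name = "individual_id"
    return df.astype(float)


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform all observed cells; missing cells stay missing.

    Raises :class:`PhenotypeError` naming the first offending individual and
    column if any observed value is <= 0.
    """
    bad = (matrix <= 0).any()
    if bad.any():
        col = bad.idxmax()
        ind = (matrix[col] <= 0).idxmax()
        raise PhenotypeError(f"nonpositive value for individual {ind!r}, column {col!r}")
    return np.log(matrix)


def ks_normality(values: Sequence[float], level: float = 0.05) -> tuple[float, float, bool]:
    """One-sample KS test against N(mean, sd) with plug-in estimates.

    Returns (statistic, p_value, departs) with departs = (p < level).  The
    plug-in makes the classical p-value anti-conservative (Lilliefors
    situation); the check is advisory and never gates the pipeline.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 8:
        raise PhenotypeError(f"need >= 8 observed values, got {len(v)}")
    sd = v.std(ddof=0)
    if sd == 0:
        raise PhenotypeError("constant vector: normality test undefined")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p), bool(p < level)


# ---------------------------------------------------------------------------
# EM for multivariate normal with ignorable missingness


@dataclass
class MvnParams:
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise PhenotypeError("covariance not symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-10:
            raise PhenotypeError("covariance not positive semidefinite")


@dataclass
class EmResult:
    params: MvnParams
    loglik: list[float]
    converged: bool
    n_iter: int
    n_rows_used: int


def _nearest_psd(a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (a + a.T))
    return (v * np.maximum(w, eps)) @ v.T


def _available_case_init(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = np.nanmean(X, axis=0)
    p = X.shape[1]
    cov = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            xi, xj = X[both, i], X[both, j]
            if len(xi) >= 2:
                cov[i, j] = cov[j, i] = np.mean((xi - xi.mean()) * (xj - xj.mean()))
            else:
                cov[i, j] = cov[j, i] = 0.0
    return mu, _nearest_psd(cov)


def _observed_loglik(X, patterns, mu, cov) -> float:
    ll = 0.0
    for obs_cols, rows in patterns:
        sub = X[np.ix_(rows, obs_cols)]
        mvn = stats.multivariate_normal(mu[obs_cols], cov[np.ix_(obs_cols, obs_cols)],
                                        allow_singular=True)
        ll += float(np.sum(mvn.logpdf(sub)))
    return ll


def _missing_patterns(X: np.ndarray):
    """Group row indices by their observed-column pattern."""
    obs = ~np.isnan(X)
    patterns = []
    seen: dict[bytes, int] = {}
    for i, row in enumerate(obs):
        key = row.tobytes()
        if key in seen:
            patterns[seen[key]][1].append(i)
        else:
            seen[key] = len(patterns)
            patterns.append((np.flatnonzero(row), [i]))
    return [(cols, np.array(rows)) for cols, rows in patterns]


def em_mvn_fit(
    matrix: pd.DataFrame | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> EmResult:
    """Maximum-likelihood MVN fit under ignorable (MCAR/MAR) missingness.

    EM with exact conditional-moment E-steps per missingness pattern; the
    observed-data log-likelihood is recorded each iteration and is
    guaranteed nondecreasing.  Covariance uses the ML (1/n) denominator.
    All-missing rows are dropped with a warning; every column needs at
    least two observed values.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise PhenotypeError("expected a 2-D matrix")
    keep = ~np.all(np.isnan(X), axis=1)
    if not keep.all():
        logger.warning("dropping %d all-missing rows from EM input", (~keep).sum())
        X = X[keep]
    n, p = X.shape
    if np.any(np.sum(~np.isnan(X), axis=0) < 2):
        raise PhenotypeError("every column needs >= 2 observed values")

    mu, cov = _available_case_init(X)
    patterns = _missing_patterns(X)
    loglik = [_observed_loglik(X, patterns, mu, cov)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for obs_cols, rows in patterns:
            mis_cols = np.setdiff1d(np.arange(p), obs_cols)
            Yo = X[np.ix_(rows, obs_cols)]
            comp = np.empty((len(rows), p))
            comp[:, obs_cols] = Yo
            if len(mis_cols):
                Soo = cov[np.ix_(obs_cols, obs_cols)]
                Smo = cov[np.ix_(mis_cols, obs_cols)]
                C = np.linalg.solve(Soo, Smo.T).T  # Smo @ Soo^-1
                comp[:, mis_cols] = mu[mis_cols] + (Yo - mu[obs_cols]) @ C.T
                cond = cov[np.ix_(mis_cols, mis_cols)] - C @ Smo.T
            s1 += comp.sum(axis=0)
            s2 += comp.T @ comp
            if len(mis_cols):
                s2[np.ix_(mis_cols, mis_cols)] += len(rows) * cond
        mu = s1 / n
        cov = s2 / n - np.outer(mu, mu)
        cov = 0.5 * (cov + cov.T)
        loglik.append(_observed_loglik(X, patterns, mu, cov))
        if loglik[-1] - loglik[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return EmResult(MvnParams(mu, cov), loglik, converged, it, n)


def conditional_impute(row: Sequence[float], params: MvnParams) -> np.ndarray:
    """Complete one partial observation by its conditional MVN expectation.

    Missing block = mu_m + S_mo S_oo^-1 (y_o - mu_o); observed entries are
    returned untouched.  An all-missing row is filled with the mean vector.
    A singular observed-block covariance falls back to the pseudo-inverse
    with a warning.
    """
    y = np.asarray(row, dtype=float).copy()
    mis = np.isnan(y)
    if not mis.any():
        return y
    if mis.all():
        return params.mean.copy()
    o = np.flatnonzero(~mis)
    m = np.flatnonzero(mis)
    Soo = params.covariance[np.ix_(o, o)]
    Smo = params.covariance[np.ix_(m, o)]
    resid = y[o] - params.mean[o]
    try:
        y[m] = params.mean[m] + Smo @ np.linalg.solve(Soo, resid)
    except np.linalg.LinAlgError:
        logger.warning("singular observed-block covariance; using pseudo-inverse")
        y[m] = params.mean[m] + Smo @ (np.linalg.pinv(Soo) @ resid)
    return y


def impute_matrix(matrix: pd.DataFrame, params: MvnParams) -> pd.DataFrame:
    """Apply :func:`conditional_impute` row-wise under fixed parameters."""
    out = matrix.copy()
    vals = out.to_numpy(dtype=float)
    for i in range(vals.shape[0]):
        if np.isnan(vals[i]).any():
            vals[i] = conditional_impute(vals[i], params)
    out.iloc[:, :] = vals
    return out


# ---------------------------------------------------------------------------
# covariate adjustment and principal-component summaries


def adjust_for_covariate(
    trait: pd.DataFrame, covariate: pd.DataFrame, founders: Iterable[str]
) -> pd.DataFrame:
    """Residualize each trait time point on all covariate time points.

    One OLS regression (with intercept) per trait column, fitted on
    founders only; residuals are computed for every individual with the
    founder-fitted coefficients.  Inputs must be complete (post-imputation).
    """
    founders = [f for f in founders if f in trait.index]
    if not founders:
        raise PhenotypeError("no founders present in the trait matrix")
    if trait.isna().any().any() or covariate.isna().any().any():
        raise PhenotypeError("adjustment requires complete (imputed) matrices")
    covariate = covariate.loc[trait.index]
    Xf = np.column_stack([np.ones(len(founders)), covariate.loc[founders].to_numpy()])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise PhenotypeError("rank-deficient covariate design on founders")
    Xall = np.column_stack([np.ones(len(trait)), covariate.to_numpy()])
    resid = trait.copy()
    for col in trait.columns:
        beta, *_ = np.linalg.lstsq(Xf, trait.loc[founders, col].to_numpy(), rcond=None)
        resid[col] = trait[col].to_numpy() - Xall @ beta
    return resid


def first_principal_component(two_columns: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Scores on the leading eigenvector of the 2x2 sample covariance.

    The eigenvector sign is fixed so its component sum is positive (first
    component positive on a tie), making scores reproducible across runs.
    """
    X = np.asarray(two_columns, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise PhenotypeError("expected an n x 2 matrix")
    if X.shape[0] < 3:
        raise PhenotypeError("need at least 3 rows")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / X.shape[0]
    if np.allclose(cov, 0.0):
        raise PhenotypeError("zero covariance matrix: no principal axis")
    w, v = np.linalg.eigh(cov)
    vec = v[:, np.argmax(w)]
    s = vec.sum()
    if s < 0 or (s == 0 and vec[0] < 0):
        vec = -vec
    return Xc @ vec


# ---------------------------------------------------------------------------
# phenotype definitions


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named summary of the four longitudinal time points.

    k = 2 for the bivariate (pre, post) definitions, 1 otherwise; adjusted
    definitions operate on covariate-residualized matrices.
    """

    name: str
    k: int
    adjusted: bool
    blocks: tuple[tuple[int, int], ...]  # time-point index pairs entering PC1


DEFINITIONS: dict[str, PhenotypeDefinition] = {
    "MTBAT": PhenotypeDefinition("MTBAT", 2, False, ((0, 1), (2, 3))),
    "MTBATAdj": PhenotypeDefinition("MTBATAdj", 2, True, ((0, 1), (2, 3))),
    "TBATPre": PhenotypeDefinition("TBATPre", 1, False, ((0, 1),)),
    "TBATPreAdj": PhenotypeDefinition("TBATPreAdj", 1, True, ((0, 1),)),
    "TBATPost": PhenotypeDefinition("TBATPost", 1, False, ((2, 3),)),
    "TBATPostAdj": PhenotypeDefinition("TBATPostAdj", 1, True, ((2, 3),)),
}


def get_definition(name: str) -> PhenotypeDefinition:
    try:
        return DEFINITIONS[name]
    except KeyError:
        raise PhenotypeError(
            f"unknown phenotype definition {name!r}; expected one of {sorted(DEFINITIONS)}"
        ) from None


def build_phenotypes(
    definition: PhenotypeDefinition | str, trait: pd.DataFrame
) -> pd.DataFrame:
    """Build per-individual phenotype vectors for one definition.

    ``trait`` is the complete log-scale (and, for adjusted definitions,
    residualized) 4-column trait matrix.  Returns a DataFrame indexed like
    ``trait`` with k columns of PC1 scores.
    """
    if isinstance(definition, str):
        definition = get_definition(definition)
    if trait.shape[1] != 4:
        raise PhenotypeError(f"expected 4 time-point columns, got {trait.shape[1]}")
    if trait.isna().any().any():
        raise PhenotypeError("phenotype construction requires a complete matrix")
    cols = {}
    for a, b in definition.blocks:
        label = "pre" if (a, b) == (0, 1) else "post"
        cols[label] = first_principal_component(trait.iloc[:, [a, b]].to_numpy())
    return pd.DataFrame(cols, index=trait.index)


def prepare_phenotypes(
    trait_raw: pd.DataFrame,
    covariate_raw: Optional[pd.DataFrame],
    founders: Iterable[str],
    definitions: Sequence[str],
    em_tol: float = 1e-8,
    em_max_iter: int = 500,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Full preparation pipeline: log -> KS report -> founder EM -> impute
    -> (adjust) -> PC summaries, for each requested definition.

    Returns ({definition name: phenotype vectors}, report dict with the KS
    table and EM convergence info).  Deterministic given the inputs.
    """
    defs = [get_definition(d) if isinstance(d, str) else d for d in definitions]
    need_cov = any(d.adjusted for d in defs)
    if need_cov and covariate_raw is None:
        raise PhenotypeError("adjusted definitions require a covariate trait matrix")

    trait_log = log_transform(trait_raw)
    report: dict = {"ks": [], "em": {}}
    matrices = {"trait": trait_log}
    if covariate_raw is not None:
        matrices["covariate"] = log_transform(covariate_raw)

    for label, mat in matrices.items():
        for col in mat.columns:
            vals = mat[col].dropna().to_numpy()
            try:
                stat, p, departs = ks_normality(vals)
            except PhenotypeError:
                continue
            report["ks"].append({"matrix": label, "column": str(col), "statistic": stat,
                                 "p_value": p, "departs": departs})

    founders = [f for f in founders if f in trait_log.index]
    joint = (
        pd.concat([matrices["trait"], matrices["covariate"]], axis=1)
        if "covariate" in matrices else matrices["trait"]
    )
    em = em_mvn_fit(joint.loc[founders], tol=em_tol, max_iter=em_max_iter)
    report["em"] = {"converged": em.converged, "n_iter": em.n_iter,
                    "loglik_final": em.loglik[-1], "n_founders": em.n_rows_used}
    joint_complete = impute_matrix(joint, em.params)
    nt = matrices["trait"].shape[1]
    trait_c = joint_complete.iloc[:, :nt]
    cov_c = joint_complete.iloc[:, nt:] if "covariate" in matrices else None

    out: dict[str, pd.DataFrame] = {}
    resid_cache: Optional[pd.DataFrame] = None
    for d in defs:
        if d.adjusted:
            if resid_cache is None:
                resid_cache = adjust_for_covariate(trait_c, cov_c, founders)
            out[d.name] = build_phenotypes(d, resid_cache)
        else:
            out[d.name] = build_phenotypes(d, trait_c)
    return out, report
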