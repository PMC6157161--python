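"""Quasi-likelihood transmission test for multivariate quantitative traits.

The model conditions parental minor-allele transmission on offspring
phenotype.  Per offspring j in an informative nuclear family (at least one
heterozygous parent), Z_j indicates whether the designated heterozygous
parent transmitted the minor allele and W_j whether the other parent did.
Both indicators get logistic mean models sharing a phenotype coefficient
vector gamma:

    E[Z_j | Y_j] = expit(alpha1 + gamma' Y_j)
    E[W_j | Y_j] = expit(alpha2 + gamma' Y_j)

with Bernoulli working variances, solved as quasi-score (GEE-type)
equations by Fisher scoring.  Association is a Wald test of gamma = 0 on
the sandwich covariance, chi-square with k = dim(Y) degrees of freedom
under the null.

The W channel is what distinguishes the both-parents test from the
classical heterozygous-parent-only TDT: a homozygous "other" parent
transmits deterministically, and those deterministic transmissions carry
the allele-frequency information that boosts power — and that makes the
test sensitive to population stratification.  When both parents are
heterozygous and the child is heterozygous, the individual transmissions
are unidentifiable and the offspring contributes through the observable
total S = Z + W instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, f as fdist

from .family_data import NuclearFamilyUnit

logger = logging.getLogger(__name__)

Mode = Literal["both_parents", "het_only"]
Cluster = Literal["family", "offspring"]

_GAMETES = {0: (0,), 1: (0, 1), 2: (1,)}


class TransmissionError(ValueError):
    """Raised for trios that cannot be encoded."""


class DegenerateFitError(RuntimeError):
    """Raised when the estimating equations are degenerate (e.g. separation)."""


@dataclass(frozen=True)
class TransmissionObs:
    """Transmission indicators for one offspring.

    Z/W are None when individually unidentifiable (double-heterozygous
    parents with a heterozygous child); S = Z + W is always defined.
    """

    Z: Optional[int]
    W: Optional[int]
    S: int
    w_deterministic: bool = False
    double_het_ambiguous: bool = False


def encode_transmission(
    father_dosage: int, mother_dosage: int, child_dosage: int
) -> TransmissionObs:
    """Encode (Z, W) for one parent-parent-child dosage trio.

    The designated heterozygous parent (Z) is the father when both parents
    are heterozygous.  Raises :class:`TransmissionError` when neither
    parent is heterozygous or the trio is Mendelian-inconsistent.
    """
    f, m, c = father_dosage, mother_dosage, child_dosage
    for d in (f, m, c):
        if d not in (0, 1, 2):
            raise TransmissionError(f"dosage {d!r} outside {{0,1,2}}")
    if f != 1 and m != 1:
        raise TransmissionError(f"no heterozygous parent in trio ({f},{m},{c})")
    pairs = [(gf, gm) for gf in _GAMETES[f] for gm in _GAMETES[m] if gf + gm == c]
    if not pairs:
        raise TransmissionError(f"Mendelian-inconsistent trio ({f},{m},{c})")

    # Z belongs to the designated het parent: father if he is heterozygous
    if f == 1:
        z_pair = [(z, w) for z, w in pairs]
    else:
        z_pair = [(w, z) for z, w in pairs]  # mother is the Z parent
    zs = {p[0] for p in z_pair}
    ws = {p[1] for p in z_pair}
    other = m if f == 1 else f
    w_det = other != 1
    if len(zs) == 1 and len(ws) == 1:
        z, w = zs.pop(), ws.pop()
        return TransmissionObs(z, w, z + w, w_deterministic=w_det)
    # both parents heterozygous, child heterozygous: exactly one transmitted
    return TransmissionObs(None, None, 1, double_het_ambiguous=True)


# ---------------------------------------------------------------------------
# quasi-likelihood fit


@dataclass
class QLModelSpec:
    """Dimension/mode of the transmission model.

    theta = (alpha1, alpha2, gamma[k]) in both_parents mode and
    (alpha1, gamma[k]) in het_only mode.
    """

    k: int
    mode: Mode = "both_parents"

    @property
    def n_params(self) -> int:
        return (2 if self.mode == "both_parents" else 1) + self.k

    @property
    def gamma_slice(self) -> slice:
        start = 2 if self.mode == "both_parents" else 1
        return slice(start, start + self.k)


@dataclass
class QLFit:
    theta_hat: np.ndarray
    vcov: np.ndarray
    n_offspring_used: int
    n_families_used: int
    converged: bool
    n_iter: int
    n_clusters: int = 0
    diagnostics: dict = field(default_factory=dict)


def _stack_components(
    observations: Sequence[tuple[TransmissionObs, np.ndarray, object]],
    spec: QLModelSpec,
):
    """Flatten per-offspring observations into scalar estimating components.

    Component kinds: 0 = Z (alpha1 link), 1 = W (alpha2 link), 2 = S for
    double-het-ambiguous offspring (sum of the two link means).
    """
    kinds, xs, ys, fam_idx, off_idx = [], [], [], [], []
    fam_ids: dict = {}
    n_det = n_amb = 0
    for j, (obs, y, fam) in enumerate(observations):
        fi = fam_ids.setdefault(fam, len(fam_ids))
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.shape[0] != spec.k:
            raise ValueError(f"phenotype length {y.shape[0]} != k={spec.k}")
        if obs.double_het_ambiguous:
            n_amb += 1
            if spec.mode == "both_parents":
                kinds.append(2); xs.append(obs.S); ys.append(y)
                fam_idx.append(fi); off_idx.append(j)
            continue  # dropped in het_only mode
        kinds.append(0); xs.append(obs.Z); ys.append(y)
        fam_idx.append(fi); off_idx.append(j)
        if spec.mode == "both_parents":
            n_det += int(obs.w_deterministic)
            kinds.append(1); xs.append(obs.W); ys.append(y)
            fam_idx.append(fi); off_idx.append(j)
    return (
        np.array(kinds, dtype=int),
        np.array(xs, dtype=float),
        np.array(ys, dtype=float).reshape(len(xs), spec.k) if xs else np.empty((0, spec.k)),
        np.array(fam_idx, dtype=int),
        np.array(off_idx, dtype=int),
        {"n_w_deterministic": n_det, "n_double_het_ambiguous": n_amb,
         "n_families": len(fam_ids)},
    )


def _mean_and_weight(theta, kinds, Y, spec: QLModelSpec):
    """Working means lambda, variances V and Jacobian rows D for theta."""
    p = spec.n_params
    gam = theta[spec.gamma_slice]
    eta_y = Y @ gam
    lam = np.empty(len(kinds))
    V = np.empty(len(kinds))
    D = np.zeros((len(kinds), p))
    isz, isw, iss = kinds == 0, kinds == 1, kinds == 2
    lz = expit(theta[0] + eta_y)
    vz = lz * (1.0 - lz)
    if spec.mode == "both_parents":
        lw = expit(theta[1] + eta_y)
        vw = lw * (1.0 - lw)
    lam[isz] = lz[isz]
    V[isz] = vz[isz]
    D[isz, 0] = vz[isz]
    D[isz, spec.gamma_slice] = vz[isz, None] * Y[isz]
    if spec.mode == "both_parents":
        lam[isw] = lw[isw]
        V[isw] = vw[isw]
        D[isw, 1] = vw[isw]
        D[isw, spec.gamma_slice] = vw[isw, None] * Y[isw]
        lam[iss] = lz[iss] + lw[iss]
        V[iss] = vz[iss] + vw[iss]
        D[iss, 0] = vz[iss]
        D[iss, 1] = vw[iss]
        D[iss, spec.gamma_slice] = (vz[iss] + vw[iss])[:, None] * Y[iss]
    return lam, V, D


def ql_fit(
    observations: Sequence[tuple[TransmissionObs, np.ndarray, object]],
    spec: QLModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
    cluster: Cluster = "family",
    bias_correction: bool = True,
) -> QLFit:
    """Solve the quasi-score equations sum_j D_j' V_j^-1 (X_j - lambda_j) = 0.

    Fisher scoring with step-halving from theta = 0.  The sandwich
    covariance A^-1 B A^-1 accumulates B over independent units: nuclear
    families by default (transmissions from a homozygous parent are shared
    across siblings), or single offspring with ``cluster="offspring"``.
    With ``bias_correction`` the Mancl-DeRouen leverage adjustment
    (I - H_c)^-1 is applied to each cluster's residuals before forming B,
    removing the downward small-sample bias of the plug-in sandwich.

    ``observations`` is a sequence of (TransmissionObs, phenotype vector,
    family label) triples, one per offspring.

    Raises :class:`ValueError` on constant phenotype columns and
    :class:`DegenerateFitError` on separation-type degeneracy.
    """
    kinds, X, Y, fam_idx, off_idx, diag = _stack_components(observations, spec)
    p = spec.n_params
    if len(X) < p:
        raise DegenerateFitError(f"only {len(X)} scalar components for {p} parameters")
    if spec.k and np.any(np.ptp(Y, axis=0) == 0.0):
        bad = int(np.flatnonzero(np.ptp(Y, axis=0) == 0.0)[0])
        raise ValueError(f"phenotype column {bad} is constant; cannot identify gamma")
    for kind, label in ((0, "Z"), (1, "W")):
        vals = X[kinds == kind]
        if len(vals) and np.all(vals == vals[0]):
            raise DegenerateFitError(
                f"all {label} transmission components equal {int(vals[0])} (separation)"
            )

    theta = np.zeros(p)
    lam, V, D = _mean_and_weight(theta, kinds, Y, spec)
    resid = X - lam
    U = D.T @ (resid / V)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = D.T @ (D / V[:, None])
        try:
            step = np.linalg.solve(A, U)
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError(f"singular information matrix: {exc}") from exc
        # step-halving on the score norm
        norm0 = float(np.linalg.norm(U))
        for _ in range(30):
            cand = theta + step
            lam, V, D = _mean_and_weight(cand, kinds, Y, spec)
            resid = X - lam
            U = D.T @ (resid / V)
            if np.linalg.norm(U) <= norm0 or np.linalg.norm(step) < 1e-14:
                break
            step *= 0.5
        theta = cand
        if np.linalg.norm(U) < tol:
            converged = True
            break
    if np.max(np.abs(theta)) > 30.0:
        raise DegenerateFitError("parameter drift beyond +/-30 (separation)")
    if not converged:
        logger.warning("quasi-score iteration did not converge in %d steps", max_iter)

    A = D.T @ (D / V[:, None])
    Ainv = np.linalg.inv(A)
    unit = fam_idx if cluster == "family" else off_idx
    B = np.zeros((p, p))
    n_clusters = 0
    for c in np.unique(unit):
        idx = unit == c
        Dc, Vc, rc = D[idx], V[idx], resid[idx]
        if bias_correction:
            Hc = (Dc @ Ainv @ Dc.T) / Vc[None, :]
            try:
                rc = np.linalg.solve(np.eye(len(rc)) - Hc, rc)
            except np.linalg.LinAlgError:
                logger.warning("singular leverage adjustment in one cluster; skipped")
        g = Dc.T @ (rc / Vc)
        B += np.outer(g, g)
        n_clusters += 1
    vcov = Ainv @ B @ Ainv
    vcov = 0.5 * (vcov + vcov.T)

    diag.update(n_components=len(X), cluster=cluster)
    return QLFit(
        theta_hat=theta,
        vcov=vcov,
        n_offspring_used=len(np.unique(off_idx)),
        n_families_used=diag["n_families"],
        converged=converged,
        n_iter=it,
        n_clusters=n_clusters,
        diagnostics=diag,
    )


@dataclass
class WaldResult:
    statistic: float
    df: int
    p_value: float


def wald_test(fit: QLFit, spec: QLModelSpec, small_sample: bool = True) -> WaldResult:
    """Wald test of H0: gamma = 0 against the chi-square(k) reference.

    The quadratic form T = gamma' vcov_gg^-1 gamma is chi-square(k) only
    as the number of independent clusters grows; with a few hundred
    families its estimated covariance adds Hotelling-type noise.  With
    ``small_sample`` the p-value is taken from the matching
    F(k, nu - k + 1) reference with nu = n_clusters - 1 and the reported
    statistic is the chi-square(k) quantile of that p-value, so
    p == chi2(k).sf(statistic) always holds and the statistic is
    chi-square-calibrated at any cluster count.
    """
    sl = spec.gamma_slice
    gam = fit.theta_hat[sl]
    vg = fit.vcov[sl, sl]
    try:
        stat = float(gam @ np.linalg.solve(vg, gam))
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(f"singular gamma covariance block: {exc}") from exc
    stat = max(stat, 0.0)
    k = spec.k
    nu = fit.n_clusters - 1
    if small_sample and nu >= k + 1:
        p_f = float(fdist.sf(stat * (nu - k + 1) / (nu * k), k, nu - k + 1))
        stat = float(chi2.isf(p_f, k)) if p_f > 0 else stat
        return WaldResult(stat, k, float(chi2.sf(stat, k)))
    return WaldResult(stat, k, float(chi2.sf(stat, k)))


# ---------------------------------------------------------------------------
# per-variant driver


@dataclass
class VariantResult:
    variant_id: str
    status: str  # ok | untested | degenerate
    n_informative_families: int
    n_offspring_used: int = 0
    statistic: float = np.nan
    df: int = 0
    p_value: float = np.nan
    message: str = ""
    diagnostics: dict = field(default_factory=dict)


def test_variant(
    units: Sequence[NuclearFamilyUnit],
    phenotypes: dict,
    k: int,
    mode: Mode = "both_parents",
    variant_id: str = "",
    min_informative: int = 21,
    cluster: Cluster = "family",
    testable: Optional[bool] = None,
) -> VariantResult:
    """Run the transmission test on one variant's informative families.

    ``phenotypes`` maps offspring ID to its length-k phenotype vector;
    offspring without prepared phenotypes are skipped.  Fit failures are
    returned as flagged results, never raised.
    """
    n_fam = len(units)
    if testable is None:
        testable = n_fam >= min_informative
    if not testable:
        return VariantResult(variant_id, "untested", n_fam,
                             message=f"{n_fam} informative families (need >= {min_informative})")
    spec = QLModelSpec(k=k, mode=mode)
    obs: list[tuple[TransmissionObs, np.ndarray, object]] = []
    for unit in units:
        for child in unit.offspring:
            y = phenotypes.get(child.individual_id)
            if y is None:
                continue
            try:
                t = encode_transmission(unit.father_dosage, unit.mother_dosage, child.dosage)
            except TransmissionError:
                continue
            obs.append((t, np.asarray(y, float), unit.family_id))
    try:
        fit = ql_fit(obs, spec, cluster=cluster)
        wald = wald_test(fit, spec)
    except (DegenerateFitError, ValueError, np.linalg.LinAlgError) as exc:
        return VariantResult(variant_id, "degenerate", n_fam, message=str(exc))
    if not fit.converged:
        return VariantResult(variant_id, "degenerate", n_fam, message="no convergence")
    return VariantResult(
        variant_id, "ok", n_fam,
        n_offspring_used=fit.n_offspring_used,
        statistic=wald.statistic, df=wald.df, p_value=wald.p_value,
        diagnostics=fit.diagnostics,
    )
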