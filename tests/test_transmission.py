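import numpy as np
import pytest

from qltdt.family_data import NuclearFamilyUnit, OffspringObs
from qltdt.transmission import (
    DegenerateFitError,
    QLFit,
    QLModelSpec,
    TransmissionError,
    encode_transmission,
    ql_fit,
    wald_test,
)
from qltdt.transmission import test_variant as run_variant_test

GAMETES = {0: (0,), 1: (0, 1), 2: (1,)}


def enumeration_oracle(f, m, c):
    """Exhaustive parental-gamete enumeration for one trio.

    Returns ('error', reason) or (Z-set, W-set, S) where Z refers to the
    designated heterozygous parent (father if both are heterozygous).
    """
    pairs = [(gf, gm) for gf in GAMETES[f] for gm in GAMETES[m] if gf + gm == c]
    if f != 1 and m != 1:
        return ("error", "no_het")
    if not pairs:
        return ("error", "mendel")
    if f == 1:
        zw = pairs
    else:
        zw = [(gm, gf) for gf, gm in pairs]
    return ({z for z, _ in zw}, {w for _, w in zw}, c)


class TestEncodeTransmission:
    @pytest.mark.parametrize("trio, expected", [
        ((1, 0, 1), (1, 0, True)),   # minor allele must come from het father
        ((1, 1, 2), (1, 1, False)),  # both transmitted
        ((1, 2, 2), (1, 1, True)),   # homozygous mother forced W=1
        ((0, 1, 1), (1, 0, True)),   # het mother is the Z parent
    ])
    def test_forced_configurations(self, trio, expected):
        obs = encode_transmission(*trio)
        z, w, det = expected
        assert (obs.Z, obs.W, obs.w_deterministic) == (z, w, det)
        assert obs.S == z + w and not obs.double_het_ambiguous

    def test_double_het_heterozygous_child_ambiguous(self):
        obs = encode_transmission(1, 1, 1)
        assert obs.Z is None and obs.W is None
        assert obs.S == 1 and obs.double_het_ambiguous

    def test_all_27_combinations_match_enumeration(self):
        for f in (0, 1, 2):
            for m in (0, 1, 2):
                for c in (0, 1, 2):
                    oracle = enumeration_oracle(f, m, c)
                    if oracle[0] == "error":
                        with pytest.raises(TransmissionError):
                            encode_transmission(f, m, c)
                        continue
                    zs, ws, s = oracle
                    obs = encode_transmission(f, m, c)
                    assert obs.S == s
                    if len(zs) == 1 and len(ws) == 1:
                        assert obs.Z == zs.pop() and obs.W == ws.pop()
                        assert not obs.double_het_ambiguous
                    else:
                        assert obs.Z is None and obs.double_het_ambiguous

    def test_invalid_dosage_rejected(self):
        with pytest.raises(TransmissionError):
            encode_transmission(3, 1, 1)


def _bernoulli_z_observations(rng, n, k, gamma=None):
    """Unambiguous het-father trios with Z ~ logistic in the phenotype."""
    from scipy.special import expit
    from qltdt.transmission import TransmissionObs

    Y = rng.normal(size=(n, k))
    eta = 0.2 + (Y @ gamma if gamma is not None else 0.0)
    Z = (rng.random(n) < expit(eta)).astype(int)
    return [(TransmissionObs(int(z), 0, int(z), w_deterministic=True), y, i)
            for i, (z, y) in enumerate(zip(Z, Y))]


class TestQlFit:
    @pytest.mark.parametrize("k", [1, 2])
    def test_het_only_equals_logistic_ml(self, k):
        import statsmodels.api as sm

        rng = np.random.default_rng(17 + k)
        obs = _bernoulli_z_observations(rng, 400, k, gamma=np.full(k, 0.3))
        spec = QLModelSpec(k=k, mode="het_only")
        fit = ql_fit(obs, spec)
        Z = np.array([o.Z for o, _, _ in obs])
        Y = np.array([y for _, y, _ in obs])
        glm = sm.GLM(Z, sm.add_constant(Y), family=sm.families.Binomial()).fit(tol=1e-12)
        np.testing.assert_allclose(fit.theta_hat, glm.params, atol=1e-6)

    def test_null_intercepts_near_zero(self):
        # under Mendelian transmission the link intercepts are logit(1/2) = 0
        rng = np.random.default_rng(23)
        obs = []
        from qltdt.transmission import TransmissionObs
        for i in range(600):
            z, w = rng.integers(0, 2), rng.integers(0, 2)
            obs.append((TransmissionObs(int(z), int(w), int(z + w)), rng.normal(size=1), i // 4))
        fit = ql_fit(obs, QLModelSpec(k=1, mode="both_parents"))
        assert abs(fit.theta_hat[0]) < 0.2 and abs(fit.theta_hat[1]) < 0.2

    def test_constant_phenotype_column_rejected(self):
        rng = np.random.default_rng(29)
        obs = _bernoulli_z_observations(rng, 60, 1)
        obs = [(o, np.zeros(1), f) for o, _, f in obs]
        with pytest.raises(ValueError, match="constant"):
            ql_fit(obs, QLModelSpec(k=1, mode="het_only"))

    def test_separation_flagged(self):
        from qltdt.transmission import TransmissionObs

        rng = np.random.default_rng(31)
        obs = [(TransmissionObs(1, None, 1), rng.normal(size=1), i) for i in range(50)]
        obs = [(TransmissionObs(1, 0, 1, w_deterministic=True), y, f) for _, y, f in obs]
        with pytest.raises(DegenerateFitError):
            ql_fit([(o, y, f) for o, y, f in obs], QLModelSpec(k=1, mode="het_only"))

    def test_ambiguous_double_het_uses_total(self):
        """Double-het ambiguous offspring contribute S with summed mean."""
        from qltdt.transmission import TransmissionObs

        rng = np.random.default_rng(37)
        n = 500
        Y = rng.normal(size=(n, 1))
        obs = []
        for i in range(n):
            z, w = rng.integers(0, 2), rng.integers(0, 2)
            if i % 3 == 0:
                if z + w == 1:
                    obs.append((TransmissionObs(None, None, 1, double_het_ambiguous=True),
                                Y[i], i))
                else:
                    obs.append((TransmissionObs(int(z), int(w), int(z + w)), Y[i], i))
            else:
                obs.append((TransmissionObs(int(z), int(w), int(z + w)), Y[i], i))
        fit = ql_fit(obs, QLModelSpec(k=1, mode="both_parents"))
        assert fit.converged
        assert fit.diagnostics["n_double_het_ambiguous"] > 0


class TestWaldTest:
    def _fit(self, theta, vcov, n_clusters=10_000):
        theta = np.asarray(theta, float)
        return QLFit(theta, np.asarray(vcov, float), 100, 50, True, 3,
                     n_clusters=n_clusters)

    def test_zero_gamma_gives_unit_p(self):
        spec = QLModelSpec(k=1, mode="het_only")
        fit = self._fit([0.1, 0.0], np.eye(2) * 0.01)
        res = wald_test(fit, spec)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile_example(self):
        spec = QLModelSpec(k=1, mode="het_only")
        fit = self._fit([0.0, 0.5], [[0.01, 0.0], [0.0, 0.0651]])
        res = wald_test(fit, spec, small_sample=False)
        assert res.statistic == pytest.approx(0.25 / 0.0651, rel=1e-12)
        assert res.p_value == pytest.approx(0.05, abs=5e-4)
        assert res.df == 1

    def test_bivariate_matches_explicit_inversion(self):
        rng = np.random.default_rng(41)
        A = rng.normal(size=(2, 2))
        vg = A @ A.T + 0.5 * np.eye(2)
        gam = rng.normal(size=2)
        vcov = np.zeros((4, 4))
        vcov[:2, :2] = np.eye(2)
        vcov[2:, 2:] = vg
        spec = QLModelSpec(k=2, mode="both_parents")
        res = wald_test(self._fit([0, 0, *gam], vcov), spec)
        det = vg[0, 0] * vg[1, 1] - vg[0, 1] ** 2
        inv = np.array([[vg[1, 1], -vg[0, 1]], [-vg[0, 1], vg[0, 0]]]) / det
        expected = float(gam @ inv @ gam)
        res_raw = wald_test(self._fit([0, 0, *gam], vcov), spec, small_sample=False)
        assert res_raw.statistic == pytest.approx(expected, abs=1e-10)
        # large-cluster small-sample correction barely moves the statistic
        assert res.statistic == pytest.approx(expected, rel=1e-3)

    def test_small_sample_correction_shrinks_statistic(self):
        spec = QLModelSpec(k=2, mode="both_parents")
        vcov = np.eye(4) * 0.05
        raw = wald_test(self._fit([0, 0, 0.4, 0.3], vcov), spec, small_sample=False)
        corr = wald_test(self._fit([0, 0, 0.4, 0.3], vcov, n_clusters=100), spec)
        assert corr.statistic < raw.statistic


class TestTestVariant:
    def _units(self, rng, n_fam, n_off=3, effect=0.0, maf=0.3):
        units, pmap = [], {}
        for i in range(n_fam):
            fd, md = rng.binomial(2, maf, 2)
            if fd != 1 and md != 1:
                fd = 1
            offspring = []
            for j in range(n_off):
                cid = f"F{i}_C{j}"
                cd = int(rng.random() < fd / 2) + int(rng.random() < md / 2)
                offspring.append(OffspringObs(cid, cd))
                pmap[cid] = np.array([effect * cd + rng.normal()])
            units.append(NuclearFamilyUnit(f"F{i}", int(fd), int(md), offspring))
        return units, pmap

    def test_untested_below_family_threshold(self):
        rng = np.random.default_rng(43)
        units, pmap = self._units(rng, 20)
        res = run_variant_test(units, pmap, 1)
        assert res.status == "untested"
        res = run_variant_test(units, pmap, 1, min_informative=20)
        assert res.status == "ok"

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(47)
        units, pmap = self._units(rng, 120, effect=0.8)
        res = run_variant_test(units, pmap, 1)
        assert res.status == "ok" and res.p_value < 1e-4

    def test_parent_label_symmetry(self):
        """Swapping father/mother genotypes leaves the statistic unchanged."""
        rng = np.random.default_rng(53)
        units, pmap = self._units(rng, 80, effect=0.3)
        swapped = [NuclearFamilyUnit(u.family_id, u.mother_dosage, u.father_dosage,
                                     u.offspring) for u in units]
        r1 = run_variant_test(units, pmap, 1)
        r2 = run_variant_test(swapped, pmap, 1)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
        r1h = run_variant_test(units, pmap, 1, mode="het_only")
        r2h = run_variant_test(swapped, pmap, 1, mode="het_only")
        assert r1h.statistic == pytest.approx(r2h.statistic, rel=1e-9)

    def test_degenerate_fit_is_flagged_not_raised(self):
        units = [NuclearFamilyUnit(f"F{i}", 1, 0, [OffspringObs(f"F{i}_C0", 1)])
                 for i in range(30)]
        pmap = {f"F{i}_C0": np.array([float(i)]) for i in range(30)}
        res = run_variant_test(units, pmap, 1, min_informative=5)
        assert res.status == "degenerate"
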