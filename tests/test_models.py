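"""TPB likelihood and joint log-densities against independent oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from plantocc.data import env_design
from plantocc.models import (
    Model1,
    Model2,
    TPBData,
    build_model1,
    build_model2,
    tpb_loglik,
)
from conftest import make_record


class TestTPBLoglik:
    def test_unreported_is_log_one_minus_psi_independent_of_p(self):
        rec = make_record(N=20, y=None)
        for p in (0.1, 0.5, 0.9):
            assert tpb_loglik(rec, psi=0.5, p=p) == pytest.approx(np.log(0.5))

    def test_certain_outcome_tends_to_zero(self):
        rec = make_record(N=10, y=0)
        assert tpb_loglik(rec, psi=1 - 1e-12, p=1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_reported_matches_binomial_pmf_oracle(self):
        # ln 0.37 + ln(C(10,3) 0.2^3 0.8^7) ~ -2.5971
        rec = make_record(N=10, y=3)
        val = tpb_loglik(rec, psi=0.37, p=0.2)
        oracle = np.log(0.37) + stats.binom.logpmf(3, 10, 0.2)
        assert val == pytest.approx(oracle, abs=1e-12)
        assert val == pytest.approx(-2.5971, abs=1e-4)

    def test_invalid_psi_rejected(self):
        with pytest.raises(ValueError):
            tpb_loglik(make_record(y=1), psi=0.0, p=0.5)

    def test_boundary_p_with_mismatched_count_rejected(self):
        with pytest.raises(ValueError):
            tpb_loglik(make_record(N=10, y=3), psi=0.5, p=0.0)


def oracle_model1_logp(model: Model1, z: np.ndarray) -> float:
    """Term-by-term summation with scipy distributions (independent path)."""
    d = model.data
    j, n = d.n_species, d.n_records
    alpha = z[:j]
    log_theta = z[j : 2 * j]
    z_tau = z[2 * j : 2 * j + n]
    theta = np.exp(log_theta)
    total = 0.0
    total += stats.t.logpdf(alpha, df=3, scale=5).sum()
    total += sum(stats.expon.logpdf(t) + lt for t, lt in zip(theta, log_theta))
    total += stats.norm.logpdf(z_tau).sum()
    psi = None
    if model.include_psi:
        u = z[-1]
        psi = expit(u)
        total += np.log(psi) + np.log1p(-psi)  # Uniform prior + Jacobian
    for i in range(n):
        sp = d.species_idx[i]
        p_i = expit(alpha[sp] + theta[sp] * z_tau[i])
        if d.reported[i]:
            if model.include_psi:
                total += np.log(psi)
            total += stats.binom.logpmf(int(d.y[i]), int(d.N[i]), p_i)
        elif model.include_psi:
            total += np.log1p(-psi)
    return total


def oracle_model2_logp(model: Model2, z: np.ndarray) -> float:
    d = model.data
    j, n, s, t = d.n_species, d.n_records, model.s, model.t
    pos = 0
    intercept = z[pos]; pos += 1
    beta = z[pos : pos + s]; pos += s
    eps = z[pos : pos + t]; pos += t
    log_omega = z[pos]; pos += 1
    z_phi = z[pos : pos + j]; pos += j
    log_theta = z[pos : pos + j]; pos += j
    z_tau = z[pos : pos + n]; pos += n
    omega = np.exp(log_omega)
    theta = np.exp(log_theta)
    total = 0.0
    total += stats.t.logpdf(intercept, df=3, scale=5)
    total += stats.t.logpdf(beta, df=3, scale=5).sum()
    total += stats.t.logpdf(eps, df=3, scale=5).sum()
    total += stats.expon.logpdf(omega) + log_omega
    total += sum(stats.expon.logpdf(th) + lt for th, lt in zip(theta, log_theta))
    total += stats.norm.logpdf(z_phi).sum() + stats.norm.logpdf(z_tau).sum()
    alpha = intercept + d.X_sp @ eps + omega * z_phi
    psi = None
    if model.include_psi:
        u = z[pos]
        psi = expit(u)
        total += np.log(psi) + np.log1p(-psi)
    for i in range(n):
        sp = d.species_idx[i]
        p_i = expit(alpha[sp] + d.X_env[i] @ beta + theta[sp] * z_tau[i])
        if d.reported[i]:
            if model.include_psi:
                total += np.log(psi)
            total += stats.binom.logpmf(int(d.y[i]), int(d.N[i]), p_i)
        elif model.include_psi:
            total += np.log1p(-psi)
    return total


def tiny_records():
    specs = [
        ("spA", 12, 3, False), ("spA", 30, None, True), ("spA", 15, 0, False),
        ("spB", 50, 20, False), ("spB", 10, None, False),
        ("spC", 22, 7, False), ("spC", 18, None, True), ("spC", 40, 39, False),
    ]
    return [
        make_record(record_id=f"r{i}", species_id=s, N=n, y=y, mentioned=m)
        for i, (s, n, y, m) in enumerate(specs)
    ]


class TestJointDensityOracle:
    @pytest.mark.parametrize("include_psi", [True, False])
    def test_model1_matches_term_by_term_summation(self, include_psi, rng):
        model = build_model1(tiny_records(), include_psi=include_psi)
        for _ in range(5):
            z = rng.normal(scale=0.8, size=model.dim)
            lp, _ = model.logp_grad(z)
            assert lp == pytest.approx(oracle_model1_logp(model, z), abs=1e-10)

    @pytest.mark.parametrize("include_psi", [True, False])
    def test_model2_matches_term_by_term_summation(self, include_psi, rng):
        recs = tiny_records()
        x_env = rng.normal(size=(len(recs), 3))
        x_sp = rng.normal(size=(3, 2))
        model = build_model2(
            recs, x_env, x_sp, ["spA", "spB", "spC"], include_psi=include_psi
        )
        for _ in range(5):
            z = rng.normal(scale=0.8, size=model.dim)
            lp, _ = model.logp_grad(z)
            assert lp == pytest.approx(oracle_model2_logp(model, z), abs=1e-10)

    def test_numba_and_numpy_paths_agree(self, small_model_inputs, rng):
        m = build_model2(
            small_model_inputs["records"],
            small_model_inputs["X_env"],
            small_model_inputs["X_sp"],
            small_model_inputs["species_labels"],
        )
        z = rng.normal(scale=0.5, size=m.dim)
        lp_a, g_a = m.logp_grad(z)
        lp_b, g_b = m._logp_grad_numpy(z)
        assert lp_a == pytest.approx(lp_b, abs=1e-9)
        assert np.allclose(g_a, g_b, atol=1e-9)


class TestGradients:
    @pytest.mark.parametrize("which", ["model1", "model2"])
    def test_gradient_matches_finite_differences(self, which, rng):
        recs = tiny_records()
        if which == "model1":
            model = build_model1(recs)
        else:
            model = build_model2(
                recs, rng.normal(size=(len(recs), 3)), rng.normal(size=(3, 2)),
                ["spA", "spB", "spC"],
            )
        z = rng.normal(scale=0.5, size=model.dim)
        _, grad = model.logp_grad(z)
        h = 1e-6
        for i in range(model.dim):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fd = (model.logp_grad(zp)[0] - model.logp_grad(zm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(fd, abs=1e-4, rel=1e-4)


class TestStructuralProperties:
    def test_unreported_records_uninformative_about_p_parameters(self, rng):
        recs = [
            make_record(record_id=f"r{i}", species_id="spA", N=20, y=None)
            for i in range(6)
        ]
        model = build_model1(recs)
        j = model.data.n_species
        z = rng.normal(scale=0.5, size=model.dim)
        z2 = z.copy()
        z2[:j] += 1.7  # shift alpha
        lp1, _ = model.logp_grad(z)
        lp2, _ = model.logp_grad(z2)
        # the difference is entirely the alpha prior difference
        prior_diff = (
            stats.t.logpdf(z2[:j], df=3, scale=5).sum()
            - stats.t.logpdf(z[:j], df=3, scale=5).sum()
        )
        assert lp2 - lp1 == pytest.approx(prior_diff, abs=1e-10)

    def test_all_unreported_likelihood_is_m_log_one_minus_psi(self):
        recs = [
            make_record(record_id=f"r{i}", species_id="spA", N=20, y=None)
            for i in range(6)
        ]
        model = build_model1(recs)
        z = np.zeros(model.dim)
        u = 0.3
        z[-1] = u
        lp, _ = model.logp_grad(z)
        z_ref = z.copy()
        z_ref[-1] = 0.0
        lp_ref, _ = model.logp_grad(z_ref)
        psi, psi_ref = expit(u), 0.5
        expected_diff = (
            (len(recs) + 1) * (np.log1p(-psi) - np.log1p(-psi_ref))
            + np.log(psi) - np.log(psi_ref)
        )
        assert lp - lp_ref == pytest.approx(expected_diff, abs=1e-10)

    def test_covariate_rescaling_invariance(self, rng):
        recs = tiny_records()
        x_env = rng.normal(size=(len(recs), 2))
        x_sp = rng.normal(size=(3, 1))
        m_a = build_model2(recs, x_env, x_sp, ["spA", "spB", "spC"])
        x2 = x_env.copy()
        x2[:, 0] *= 2.0
        m_b = build_model2(recs, x2, x_sp, ["spA", "spB", "spC"])
        z = rng.normal(scale=0.5, size=m_a.dim)
        z_b = z.copy()
        z_b[1] = z[1] / 2.0  # halve the first env coefficient
        lik_a = m_a.logp_grad(z)[0] - stats.t.logpdf(z[1], df=3, scale=5)
        lik_b = m_b.logp_grad(z_b)[0] - stats.t.logpdf(z_b[1], df=3, scale=5)
        assert lik_a == pytest.approx(lik_b, abs=1e-10)

    def test_model2_collapses_to_intercept_model_when_designs_vanish(self, rng):
        recs = tiny_records()
        x_env = np.zeros((len(recs), 2))
        x_sp = np.zeros((3, 1))
        m2 = build_model2(recs, x_env, x_sp, ["spA", "spB", "spC"])
        z = rng.normal(scale=0.5, size=m2.dim)
        named = m2.constrain_batch(z[None, :])
        # alpha collapses to I + phi
        expected_alpha = named["I"][0, 0] + named["phi"][0]
        assert np.allclose(named["alpha"][0], expected_alpha)

    def test_reporting_mle_is_reported_fraction(self):
        from plantocc.models import PsiOnlyModel
        from scipy.optimize import minimize_scalar

        m = PsiOnlyModel(n_reported=30, n_unreported=70)
        # strip the Jacobian/prior to get the pure likelihood MLE
        res = minimize_scalar(
            lambda u: -(30 * np.log(expit(u)) + 70 * np.log1p(-expit(u))),
            bounds=(-5, 5),
            method="bounded",
        )
        assert expit(res.x) == pytest.approx(0.3, abs=1e-5)

    def test_zero_record_species_excluded_with_warning(self):
        recs = tiny_records()
        with pytest.warns(UserWarning, match="zero records"):
            model = build_model1(recs, species_labels=["spA", "spB", "spC", "spD"])
        assert model.data.species_labels == ["spA", "spB", "spC"]


class TestTPBDataValidation:
    def test_misaligned_env_design_rejected(self):
        with pytest.raises(ValueError, match="X_env"):
            TPBData.from_records(tiny_records(), X_env=np.zeros((3, 2)))

    def test_unknown_record_species_rejected(self):
        with pytest.raises(ValueError, match="not in the design"):
            TPBData.from_records(tiny_records(), species_labels=["spA", "spB"])
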