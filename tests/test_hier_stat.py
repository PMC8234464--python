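"""Hierarchical model densities, the conjugate-reduction oracle, and MAP."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from navpop.channel_core import FACTOR_NAMES
from navpop.clamp_protocols import CurveData, ProtocolSpec
from navpop.data_model import ExperimentRecord, StudyDataset
from navpop.hier_stat import (
    FactorSpace,
    HierModel,
    HierParams,
    Priors,
    experiment_loglik,
    map_estimate,
    param_row_loglik,
    reduced_factor_space,
)

LOG2PI = math.log(2 * math.pi)


def _toy_record(rid="t1", paper="p1", y=(-0.2, 0.1, 0.05), temp=17.0):
    x = np.array([0.0, 1.0, 2.0])
    proto = ProtocolSpec(kind="REC", inter_pulse_intervals=tuple(x + 1.0))
    return ExperimentRecord(
        id=rid, paper_id=paper, kind="REC", protocol=proto,
        data=CurveData(x, np.asarray(y, float)), temperature=temp)


def _identity_model(n_records=4, K=3, sigma_e=0.3, seed=0):
    """Biophysical model replaced by an identity map onto the free factors."""
    rng = np.random.default_rng(seed)
    space = reduced_factor_space(FACTOR_NAMES[:K])
    records = [
        _toy_record(rid=f"r{i}", paper="p1",
                    y=space.reference() + rng.normal(0, 0.5, K))
        for i in range(n_records)
    ]
    ds = StudyDataset(records=records)
    model = HierModel(
        ds, space=space,
        simulate_fn=lambda rec, fv: space.project(fv))
    return model, space, sigma_e


class TestExperimentLoglik:
    def test_zero_residual_value(self, small_dataset):
        truth, ds, latents = small_dataset
        rec = ds.records[0]
        sigma = 0.25
        row = latents["PV"][0]
        fv = truth.space.embed(row)
        pred = np.asarray(rec.data.y, float)
        ll = experiment_loglik(rec, fv, sigma, predicted=pred)
        n = rec.data.y.size
        assert ll == pytest.approx(n * math.log(1 / (sigma * math.sqrt(2 * math.pi))))

    def test_doubling_sigma_closed_form(self):
        rec = _toy_record()
        pred = np.zeros(3)
        space = FactorSpace()
        fv = space.embed(space.reference())
        r2 = float(np.sum(rec.data.y**2))
        l1 = experiment_loglik(rec, fv, 0.1, predicted=pred)
        l2 = experiment_loglik(rec, fv, 0.2, predicted=pred)
        expected_delta = -3 * math.log(2) + 0.5 * r2 * (1 / 0.1**2 - 1 / 0.2**2)
        assert l2 - l1 == pytest.approx(expected_delta, rel=1e-12)

    def test_hand_computed_three_point(self):
        rec = _toy_record(y=(1.0, 2.0, 3.0))
        pred = np.array([0.5, 2.5, 3.0])
        sigma = 0.4
        fv = FactorSpace().embed(FactorSpace().reference())
        manual = sum(-0.5 * LOG2PI - math.log(sigma) - 0.5 * (d / sigma) ** 2
                     for d in (0.5, -0.5, 0.0))
        got = experiment_loglik(rec, fv, sigma, predicted=pred)
        assert got == pytest.approx(manual, rel=1e-12)


class TestParamRowLoglik:
    def _h(self, K, beta0=None, Sigma=None):
        return HierParams(
            beta0=np.zeros(K) if beta0 is None else beta0,
            beta_temp=np.zeros(K),
            uvep=np.zeros((1, K)),
            sigma_uvep=np.ones(K),
            Sigma_param=np.eye(K) if Sigma is None else Sigma,
            sigma_exp={"IV": 1.0},
            PV=np.zeros((1, K)),
        )

    def test_standard_normal_at_mode(self):
        h = self._h(25)
        assert param_row_loglik(np.zeros(25), 0, 0.0, h) == pytest.approx(
            -12.5 * LOG2PI)

    def test_mean_reduces_to_beta0(self, rng):
        K = 6
        beta0 = rng.normal(size=K)
        h = self._h(K, beta0=beta0)
        h.beta_temp = rng.normal(size=K)  # irrelevant at T = 0
        lp_at_beta0 = param_row_loglik(beta0, 0, 0.0, h)
        assert lp_at_beta0 == pytest.approx(-K / 2 * LOG2PI)

    def test_matches_scipy_mvn(self, rng):
        K = 8
        A = rng.normal(size=(K, K))
        Sigma = A @ A.T + K * np.eye(K)
        beta0 = rng.normal(size=K)
        h = self._h(K, beta0=beta0, Sigma=Sigma)
        h.beta_temp = rng.normal(size=K)
        h.uvep = rng.normal(size=(1, K))
        T = 5.0
        for _ in range(5):
            x = rng.normal(size=K)
            mean = beta0 + h.beta_temp * T + h.uvep[0]
            ref = multivariate_normal.logpdf(x, mean=mean, cov=Sigma)
            assert param_row_loglik(x, 0, T, h) == pytest.approx(ref, rel=1e-10)


class TestLogPosterior:
    def test_additivity_over_experiments(self, small_dataset):
        truth, ds, _ = small_dataset
        # drop a record whose paper keeps other records
        drop = next(i for i, r in enumerate(ds.records)
                    if sum(q.paper_id == r.paper_id for q in ds.records) > 1)
        sub = StudyDataset(records=[r for i, r in enumerate(ds.records)
                                    if i != drop])
        m_full = HierModel(ds, space=truth.space)
        m_sub = HierModel(sub, space=truth.space)
        h = m_full.initial_params()
        h_sub = m_sub.initial_params()
        h_sub.PV = np.delete(h.PV, drop, axis=0)
        lp_full = m_full.log_posterior(h)
        lp_sub = m_sub.log_posterior(h_sub)
        extra = (m_full.experiment_loglik(drop, h.PV[drop], h)
                 + param_row_loglik(h.PV[drop], int(m_full.record_paper[drop]),
                                    float(m_full.T[drop]), h))
        assert lp_full == pytest.approx(lp_sub + extra, rel=1e-9)

    def test_sharper_uvep_prior_penalises_large_offsets_more(self, small_dataset):
        truth, ds, _ = small_dataset
        model = HierModel(ds, space=truth.space)
        h_small = model.initial_params()
        h_small.sigma_uvep = np.full(truth.space.k, 0.1)
        h_large = model.initial_params()
        h_large.sigma_uvep = np.full(truth.space.k, 2.0)
        wide = Priors.default(truth.space)
        sharp = Priors.default(truth.space)
        sharp.sigma_uvep_scale = 0.25
        model.priors = wide
        d_small = model.hyperprior_loglik(h_small)
        d_large = model.hyperprior_loglik(h_large)
        model.priors = sharp
        penalty_small = d_small - model.hyperprior_loglik(h_small)
        penalty_large = d_large - model.hyperprior_loglik(h_large)
        assert penalty_large > penalty_small

    def test_invariant_to_record_order(self, small_dataset):
        truth, ds, _ = small_dataset
        model = HierModel(ds, space=truth.space)
        h = model.initial_params()
        lp = model.log_posterior(h)
        # reverse records within each paper block (keeps paper order stable)
        perm = []
        for pid in ds.papers:
            idx = [i for i, r in enumerate(ds.records) if r.paper_id == pid]
            perm.extend(reversed(idx))
        ds2 = StudyDataset(records=[ds.records[i] for i in perm])
        model2 = HierModel(ds2, space=truth.space)
        h2 = model2.initial_params()
        h2.PV = h.PV[perm]
        assert model2.log_posterior(h2) == pytest.approx(lp, rel=1e-12)


class TestConjugateReduction:
    def test_map_matches_closed_form_ridge(self):
        """With the channel replaced by an identity map the posterior in
        (beta0, PV) is Gaussian; the numerical maximiser must agree with the
        closed-form normal-equations solution to 1e-6."""
        model, space, sigma_e = _identity_model(n_records=4, K=3)
        K = space.k
        n = len(model.ds)
        sigma_p = 0.5
        base = model.initial_params()
        base.Sigma_param = sigma_p**2 * np.eye(K)
        base.uvep[:] = 0.0
        base.beta_temp[:] = 0.0
        for kind in base.sigma_exp:
            base.sigma_exp[kind] = sigma_e
        Y = np.stack([r.data.y for r in model.ds.records])

        def neg_lp(z):
            h = base.copy()
            h.beta0 = z[:K]
            h.PV = z[K:].reshape(n, K)
            return -model.log_posterior(h)

        z0 = np.concatenate([base.beta0, np.tile(base.beta0, n)])
        res = minimize(neg_lp, z0, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})

        # independent closed form, per dimension: stationarity of the
        # quadratic in (beta0_j, P_1j..P_nj)
        m_prior = model.priors.beta0_mean
        s0 = model.priors.beta0_sd
        beta_hat = np.empty(K)
        pv_hat = np.empty((n, K))
        for j in range(K):
            A = np.zeros((n + 1, n + 1))
            b = np.zeros(n + 1)
            A[0, 0] = n / sigma_p**2 + 1 / s0**2
            b[0] = m_prior[j] / s0**2
            for i in range(n):
                A[0, 1 + i] = -1 / sigma_p**2
                A[1 + i, 0] = -1 / sigma_p**2
                A[1 + i, 1 + i] = 1 / sigma_e**2 + 1 / sigma_p**2
                b[1 + i] = Y[i, j] / sigma_e**2
            sol = np.linalg.solve(A, b)
            beta_hat[j] = sol[0]
            pv_hat[:, j] = sol[1:]

        assert np.allclose(res.x[:K], beta_hat, atol=1e-6)
        assert np.allclose(res.x[K:].reshape(n, K), pv_hat, atol=1e-6)


class TestMapEstimate:
    class _FakeChain:
        def __init__(self, states, lps):
            self.states = states
            self.log_post = np.asarray(lps, float)

    def test_single_state(self):
        chain = self._FakeChain(["only"], [1.0])
        assert map_estimate(chain) == "only"

    def test_ties_take_latest(self):
        chain = self._FakeChain(["a", "b", "c"], [2.0, 5.0, 5.0])
        assert map_estimate(chain) == "c"

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            map_estimate(self._FakeChain([], []))

    def test_returns_mode_of_toy_target(self):
        states = [{"x": v} for v in (-1.0, 0.0, 0.3)]
        lps = [-(s["x"] ** 2) for s in states]
        assert map_estimate(self._FakeChain(states, lps))["x"] == 0.0
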