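"""Custom MCMC sampler for the hierarchical channel model.

The posterior factorises into two qualitatively different blocks:

* hyperparameters (``beta0``, ``betaTemp``, the UVEP offsets and their
  scales, the factor covariance ``Sigma_param`` and the per-kind error
  std devs), whose conditionals given the per-experiment factor rows are
  tractable — these are updated by exact Gibbs draws where conjugate
  (Gaussian regression coefficients, UVEP offsets, inverse-Wishart
  covariance) and by 1-D slice sampling for the Half-Normal scale
  parameters;
* the per-experiment factor rows ``PV``, whose likelihood requires
  simulating voltage-clamp protocols and is therefore gradient-free —
  these are updated by adaptive random-walk Metropolis-Hastings with a
  multivariate normal jump tuned per experiment (scale driven toward a
  0.234 acceptance rate, jump covariance an exponentially-weighted
  moving average of the row's history), plus a crossover exchange move
  every 10 iterations that copies a random ~10% subset of factors from a
  donor experiment in the same paper- or kind-group.

Adaptation runs during warm-up only and is frozen afterwards, so the
post-warm-up chain is Markov.  All randomness flows from a single root
seed through per-experiment child streams; two runs with the same seed
produce bit-identical chains.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import invwishart

from .data_model import crossover_groups
from .hier_stat import HierModel, HierParams, param_row_loglik

__all__ = [
    "FitConfig",
    "AdaptiveProposal",
    "Chain",
    "mh_step_row",
    "crossover_mask",
    "slice_sample_positive",
    "run_chain",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class FitConfig:
    iterations: int = 1000
    warmup: int | None = None  # default: half of iterations
    thin: int = 10
    seed: int = 0
    crossover_every: int = 10
    crossover_prob: float = 0.10
    target_accept: float = 0.234
    adapt_gamma: float = 0.05  # log-scale step of the acceptance controller
    cov_weight: float = 0.02  # moving-average weight for the jump covariance
    init_scale: float = 0.1  # initial jump std per factor

    def resolved_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup


class AdaptiveProposal:
    """Per-experiment multivariate-normal jump with acceptance-rate tuning.

    The jump is ``MVN(0, scale^2 * C)``.  During warm-up, ``scale`` moves
    multiplicatively toward the target acceptance rate and ``C`` tracks
    an exponentially-weighted moving average of the row's empirical
    covariance (with a PSD jitter).  ``freeze()`` stops all adaptation.
    """

    def __init__(self, k: int, init_scale: float = 0.1,
                 target_accept: float = 0.234, gamma: float = 0.05,
                 cov_weight: float = 0.02):
        self.k = k
        self.scale = init_scale
        self.target = target_accept
        self.gamma = gamma
        self.w = cov_weight
        self.C = np.eye(k)
        self._chol = np.eye(k)
        self._mean = np.zeros(k)
        self._cov = np.eye(k)
        self._seen = 0
        self.n_proposed = 0
        self.n_accepted = 0
        self.frozen = False

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else math.nan

    def draw_jump(self, rng: np.random.Generator) -> np.ndarray:
        return self.scale * (self._chol @ rng.standard_normal(self.k))

    def update(self, row: np.ndarray, accepted: bool) -> None:
        """Record an MH outcome; adapt scale and covariance unless frozen."""
        self.n_proposed += 1
        self.n_accepted += int(accepted)
        if self.frozen:
            return
        self.scale *= math.exp(self.gamma * ((1.0 if accepted else 0.0) - self.target))
        self.scale = min(max(self.scale, 1e-6), 1e3)
        self._seen += 1
        if self._seen == 1:
            self._mean = row.copy()
        else:
            d = row - self._mean
            self._mean = self._mean + self.w * d
            self._cov = (1 - self.w) * self._cov + self.w * np.outer(d, d)
        if self._seen >= 2 * self.k and self._seen % 20 == 0:
            C = self._cov + 1e-8 * np.eye(self.k)
            try:
                chol = cholesky(C, lower=True)
            except np.linalg.LinAlgError:
                return
            self.C, self._chol = C, chol

    def freeze(self) -> None:
        self.frozen = True


def mh_step_row(rng: np.random.Generator, row: np.ndarray, logp: float,
                logp_fn, proposal: AdaptiveProposal):
    """One Metropolis-Hastings step with a symmetric MVN jump.

    ``logp_fn(candidate) -> (logp, aux)``; returns
    ``(row', logp', aux', accepted)`` where ``aux'`` is ``None`` for a
    rejected move (the caller keeps its cached quantities).
    """
    cand = row + proposal.draw_jump(rng)
    cand_lp, aux = logp_fn(cand)
    accept = math.log(rng.random()) < cand_lp - logp if np.isfinite(cand_lp) else False
    proposal.update(row, accept)
    if accept:
        return cand, cand_lp, aux, True
    return row, logp, None, False


def crossover_mask(rng: np.random.Generator, k: int, prob: float) -> np.ndarray:
    """Independent Bernoulli(prob) inclusion mask over the k factors."""
    return rng.random(k) < prob


def slice_sample_positive(rng: np.random.Generator, x0: float, logf,
                          w: float = 0.5, max_steps: int = 50) -> float:
    """Univariate slice sampler on (0, inf) with stepping-out and shrinkage."""
    log_y = logf(x0) + math.log(rng.random())
    u = rng.random()
    lo = max(x0 - u * w, 1e-12)
    hi = lo + w
    for _ in range(max_steps):
        if lo <= 1e-12 or logf(lo) < log_y:
            break
        lo = max(lo - w, 1e-12)
    for _ in range(max_steps):
        if logf(hi) < log_y:
            break
        hi += w
    for _ in range(max_steps):
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) >= log_y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


@dataclass
class Chain:
    """Thinned MCMC output with log-posteriors and sampler diagnostics."""

    states: list
    log_post: np.ndarray
    accept_rates: np.ndarray  # per-experiment MH acceptance
    crossover_accept: float
    config: FitConfig
    seed: int

    def __len__(self) -> int:
        return len(self.states)

    def stacked(self, attr: str) -> np.ndarray:
        return np.stack([np.asarray(getattr(s, attr)) for s in self.states])


# ---------------------------------------------------------------------------
# Gibbs updates for the hyperparameters
# ---------------------------------------------------------------------------

def _update_betas(rng, model: HierModel, h: HierParams) -> None:
    """Joint conjugate draw of (beta0, betaTemp) given rows, UVEP and Sigma."""
    pr = model.priors
    K = h.beta0.size
    n = h.PV.shape[0]
    X = np.column_stack([np.ones(n), model.T])  # (n, 2)
    R = h.PV - h.uvep[model.record_paper]  # (n, K)
    Sigma_inv = np.linalg.inv(h.Sigma_param)
    XtX = X.T @ X
    prior_prec = np.concatenate([
        np.column_stack([np.full(K, 1.0 / pr.beta0_sd**2),
                         np.full(K, 1.0 / pr.beta_temp_sd**2)]).ravel()
    ])
    prior_mean = np.column_stack([pr.beta0_mean, pr.beta_temp_mean]).ravel()
    # vec stacks per-factor (beta0_j, betaTemp_j) pairs
    Lam = np.kron(Sigma_inv, XtX) + np.diag(prior_prec)
    b = (X.T @ R @ Sigma_inv).T.ravel() + prior_prec * prior_mean
    cho = cho_factor(Lam, lower=True)
    mean = cho_solve(cho, b)
    L = cholesky(Lam, lower=True)
    z = rng.standard_normal(2 * K)
    draw = mean + np.linalg.solve(L.T, z)
    draw = draw.reshape(K, 2)
    h.beta0 = draw[:, 0].copy()
    h.beta_temp = draw[:, 1].copy()


def _update_uvep(rng, model: HierModel, h: HierParams) -> None:
    Sigma_inv = np.linalg.inv(h.Sigma_param)
    for p in range(len(model.paper_ids)):
        idx = np.flatnonzero(model.record_paper == p)
        resid = (h.PV[idx] - h.beta0[None, :]
                 - np.outer(model.T[idx], h.beta_temp)).sum(axis=0)
        Lam = len(idx) * Sigma_inv + np.diag(1.0 / h.sigma_uvep**2)
        b = Sigma_inv @ resid
        mean = np.linalg.solve(Lam, b)
        L = cholesky(Lam, lower=True)
        h.uvep[p] = mean + np.linalg.solve(L.T, rng.standard_normal(h.beta0.size))


def _update_sigma_uvep(rng, model: HierModel, h: HierParams) -> None:
    scale = model.priors.sigma_uvep_scale
    P = h.uvep.shape[0]
    for j in range(h.sigma_uvep.size):
        ssq = float(np.sum(h.uvep[:, j] ** 2))

        def logf(s, _ssq=ssq):
            return (-0.5 * (s / scale) ** 2) - P * math.log(s) - 0.5 * _ssq / s**2

        h.sigma_uvep[j] = slice_sample_positive(rng, float(h.sigma_uvep[j]), logf,
                                                w=0.25)


def _update_sigma_param(rng, model: HierModel, h: HierParams) -> None:
    pr = model.priors
    E = h.PV - h.beta0[None, :] - np.outer(model.T, h.beta_temp) \
        - h.uvep[model.record_paper]
    S = E.T @ E
    df = pr.iw_df + E.shape[0]
    scale = pr.iw_scale + S
    h.Sigma_param = invwishart.rvs(df=df, scale=scale, random_state=rng)
    h.Sigma_param = np.atleast_2d(h.Sigma_param)


def _update_sigma_exp(rng, model: HierModel, h: HierParams, rss, npts) -> None:
    scale = model.priors.sigma_exp_scale
    for kind in model.kinds:
        idx = [i for i, r in enumerate(model.ds.records) if r.kind == kind]
        total_rss = float(sum(rss[i] for i in idx))
        total_n = int(sum(npts[i] for i in idx))

        def logf(s, _rss=total_rss, _n=total_n):
            return (-0.5 * (s / scale) ** 2) - _n * math.log(s) - 0.5 * _rss / s**2

        h.sigma_exp[kind] = slice_sample_positive(
            rng, float(h.sigma_exp[kind]), logf, w=0.1)


# ---------------------------------------------------------------------------
# The full sampler
# ---------------------------------------------------------------------------

def run_chain(model: HierModel, config: FitConfig | None = None) -> Chain:
    """Run the Metropolis-within-Gibbs sampler with crossover moves.

    Alternates exact/slice Gibbs updates of the hyperparameters with
    adaptive MH updates of the per-experiment factor rows; every
    ``crossover_every`` iterations a crossover exchange move runs over
    all experiments.  Fully reproducible from ``config.seed``.
    """
    config = config or FitConfig()
    n_exp = len(model.ds)
    K = model.space.k
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(n_exp + 2)
    hyper_rng = np.random.default_rng(streams[0])
    cross_rng = np.random.default_rng(streams[1])
    row_rngs = [np.random.default_rng(s) for s in streams[2:]]

    groups = crossover_groups(model.ds)
    partitions = [groups["by_paper"], groups["by_kind"]]
    group_of = []
    for i in range(n_exp):
        group_of.append([next(g for g in part if i in g) for part in partitions])

    h = model.initial_params()

    # caches: per-record predicted curve, residual sum of squares, point count
    pred = [None] * n_exp
    rss = np.zeros(n_exp)
    npts = np.array([model.ds.records[i].data.y.size for i in range(n_exp)])
    for i in range(n_exp):
        try:
            pred[i] = model.predict(i, h.PV[i])
            rss[i] = float(np.sum((model.ds.records[i].data.y - pred[i]) ** 2))
        except Exception as e:  # noqa: BLE001 - init must be finite
            raise RuntimeError(
                f"non-finite log-posterior at initialization (record "
                f"{model.ds.records[i].id}); consider starting from the prior "
                f"mean") from e
    if not np.all(np.isfinite(rss)):
        raise RuntimeError("non-finite log-posterior at initialization; "
                           "consider starting from the prior mean")

    def exp_ll(i: int, rss_i: float) -> float:
        s = h.sigma_exp[model.ds.records[i].kind]
        return -0.5 * npts[i] * _LOG2PI - npts[i] * math.log(s) - 0.5 * rss_i / s**2

    def full_logpost(cho) -> float:
        lp = model.hyperprior_loglik(h) + model.uvep_loglik(h)
        for i in range(n_exp):
            lp += param_row_loglik(h.PV[i], int(model.record_paper[i]),
                                   float(model.T[i]), h, cho=cho)
            lp += exp_ll(i, rss[i])
        return float(lp)

    proposals = [AdaptiveProposal(K, config.init_scale, config.target_accept,
                                  config.adapt_gamma, config.cov_weight)
                 for _ in range(n_exp)]
    warmup = config.resolved_warmup()

    cho = cho_factor(h.Sigma_param, lower=True)
    states: list[HierParams] = [h.copy()]
    log_posts: list[float] = [full_logpost(cho)]
    cross_prop = 0
    cross_acc = 0

    def row_logp(i: int, row: np.ndarray):
        try:
            p = model.predict(i, row)
        except Exception:  # noqa: BLE001 - failed simulation => impossible move
            return -np.inf, None
        r = float(np.sum((model.ds.records[i].data.y - p) ** 2))
        if not np.isfinite(r):
            return -np.inf, None
        lp = exp_ll(i, r) + param_row_loglik(row, int(model.record_paper[i]),
                                             float(model.T[i]), h, cho=cho)
        return lp, (p, r)

    for it in range(1, config.iterations + 1):
        if it == warmup + 1:
            for prop in proposals:
                prop.freeze()

        # --- hyperparameter Gibbs sweep (no protocol simulations needed) ---
        _update_betas(hyper_rng, model, h)
        _update_uvep(hyper_rng, model, h)
        _update_sigma_uvep(hyper_rng, model, h)
        _update_sigma_param(hyper_rng, model, h)
        cho = cho_factor(h.Sigma_param, lower=True)
        _update_sigma_exp(hyper_rng, model, h, rss, npts)

        # --- per-experiment adaptive MH ---
        for i in range(n_exp):
            cur_lp = exp_ll(i, rss[i]) + param_row_loglik(
                h.PV[i], int(model.record_paper[i]), float(model.T[i]), h, cho=cho)
            new_row, _, aux, accepted = mh_step_row(
                row_rngs[i], h.PV[i].copy(), cur_lp,
                lambda cand, _i=i: row_logp(_i, cand), proposals[i])
            if accepted:
                h.PV[i] = new_row
                pred[i], rss[i] = aux

        # --- crossover exchange every `crossover_every` iterations ---
        if it % config.crossover_every == 0:
            for i in range(n_exp):
                mask = crossover_mask(cross_rng, K, config.crossover_prob)
                part = int(cross_rng.integers(2))
                group = group_of[i][part]
                donor = int(group[cross_rng.integers(len(group))])
                if not mask.any() or donor == i:
                    continue  # identity move, trivially accepted
                cand = h.PV[i].copy()
                cand[mask] = h.PV[donor][mask]
                cur_lp = exp_ll(i, rss[i]) + param_row_loglik(
                    h.PV[i], int(model.record_paper[i]), float(model.T[i]), h,
                    cho=cho)
                cand_lp, aux = row_logp(i, cand)
                cross_prop += 1
                if np.isfinite(cand_lp) and \
                        math.log(cross_rng.random()) < cand_lp - cur_lp:
                    h.PV[i] = cand
                    pred[i], rss[i] = aux
                    cross_acc += 1

        if it > warmup and (it - warmup) % config.thin == 0:
            states.append(h.copy())
            log_posts.append(full_logpost(cho))

    return Chain(
        states=states,
        log_post=np.asarray(log_posts),
        accept_rates=np.array([p.acceptance_rate for p in proposals]),
        crossover_accept=cross_acc / cross_prop if cross_prop else math.nan,
        config=config,
        seed=config.seed,
    )
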