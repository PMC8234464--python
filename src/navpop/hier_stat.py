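"""Hierarchical Bayesian statistical model wrapped around the channel model.

Structure (all on the unconstrained factor scale):

* Experiment level: the observed curve of experiment *i* equals the
  biophysical prediction under that experiment's own factor row ``P_i``
  plus i.i.d. Gaussian noise whose standard deviation is specific to the
  experiment *kind* (IV curves carry far more spread than normalised
  steady-state curves).
* Parameter level: ``P_i ~ MVN(beta0 + betaTemp * T_i + u_paper(i),
  Sigma_param)`` where ``T_i`` is the bath temperature minus 17 degC,
  ``betaTemp`` is the per-degree effect, and ``u_p`` is the per-paper
  random offset ("UVEP effect": undefined variability in experimental
  protocol across labs) with ``u_p ~ N(0, diag(sigma_uvep^2))``.
  The zero-mean UVEP prior keeps the paper effects summing softly to
  zero and prefers small offsets; ``Sigma_param`` is a full covariance
  so factors may be correlated across experiments.
* Hyperpriors: ``beta0_j ~ N(m_j, 5^2)`` centred on the package's
  reference Na_v1.5 factors; ``betaTemp_j ~ N(mu_lit_j, 0.5^2)`` with
  ``mu_lit`` encoding literature Q10-type temperature sensitivity of the
  kinetic factors; ``sigma_uvep_j`` and the per-kind error std devs are
  Half-Normal(1); ``Sigma_param ~ Inverse-Wishart`` (weakly informative,
  prior mean ``0.01 I``), chosen for its exact conditional update in the
  Gibbs sweep.

The model optionally restricts inference to a *free* subset of the 25
factors; pinned factors stay at the reference values.  The map from a
record + factor row to a predicted curve is injectable, so the
biophysical model can be replaced by an identity map to obtain a fully
conjugate linear-Gaussian reduction for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import invwishart

from .channel_core import (
    DEFAULT_FACTORS,
    FACTOR_NAMES,
    FactorVector,
    transform_factors,
)
from .clamp_protocols import (
    CurveData,
    IntegrationError,
    ProtocolSpec,
    normalize_iv,
    run_protocol,
)
from .data_model import ExperimentRecord, StudyDataset

__all__ = [
    "TEMPERATURE_REFERENCE",
    "FactorSpace",
    "Priors",
    "HierParams",
    "HierModel",
    "simulate_record",
    "experiment_loglik",
    "param_row_loglik",
    "map_estimate",
]

#: Temperature covariate reference: T enters as (bath temperature - 17 degC).
TEMPERATURE_REFERENCE = 17.0

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Factor subsetting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorSpace:
    """Mapping between a free factor subvector and the full 25-factor space."""

    free_names: tuple[str, ...] = FACTOR_NAMES
    pinned: dict = field(default_factory=lambda: dict(DEFAULT_FACTORS))

    def __post_init__(self) -> None:
        unknown = set(self.free_names) - set(FACTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown factor names: {sorted(unknown)}")

    @property
    def k(self) -> int:
        return len(self.free_names)

    def embed(self, sub: np.ndarray) -> FactorVector:
        """Free subvector -> full FactorVector (pinned values elsewhere)."""
        d = dict(self.pinned)
        for name, v in zip(self.free_names, np.asarray(sub, dtype=float)):
            d[name] = float(v)
        return FactorVector.from_dict(d)

    def project(self, fv: FactorVector) -> np.ndarray:
        d = fv.to_dict()
        return np.array([d[n] for n in self.free_names])

    def reference(self) -> np.ndarray:
        return np.array([self.pinned[n] for n in self.free_names])


def reduced_factor_space(names: tuple[str, ...] | list[str]) -> FactorSpace:
    return FactorSpace(free_names=tuple(names))


# ---------------------------------------------------------------------------
# Parameters and priors
# ---------------------------------------------------------------------------

@dataclass
class HierParams:
    """All statistical parameters of the hierarchical model (K free factors)."""

    beta0: np.ndarray  # (K,)
    beta_temp: np.ndarray  # (K,)
    uvep: np.ndarray  # (P, K) paper random effects
    sigma_uvep: np.ndarray  # (K,)
    Sigma_param: np.ndarray  # (K, K)
    sigma_exp: dict  # kind -> error std dev
    PV: np.ndarray  # (N, K) per-experiment factor rows

    def validate(self) -> None:
        K = self.beta0.size
        if self.beta_temp.shape != (K,) or self.sigma_uvep.shape != (K,):
            raise ValueError("inconsistent factor dimension")
        if self.Sigma_param.shape != (K, K):
            raise ValueError("Sigma_param has wrong shape")
        if not np.allclose(self.Sigma_param, self.Sigma_param.T):
            raise ValueError("Sigma_param must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma_param) <= 0):
            raise ValueError("Sigma_param must be positive definite")
        if np.any(self.sigma_uvep <= 0) or any(s <= 0 for s in self.sigma_exp.values()):
            raise ValueError("all std devs must be positive")
        if self.uvep.shape[1] != K or self.PV.shape[1] != K:
            raise ValueError("uvep/PV column count must equal factor count")

    def copy(self) -> "HierParams":
        return HierParams(self.beta0.copy(), self.beta_temp.copy(), self.uvep.copy(),
                          self.sigma_uvep.copy(), self.Sigma_param.copy(),
                          dict(self.sigma_exp), self.PV.copy())

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0.tolist(),
            "beta_temp": self.beta_temp.tolist(),
            "uvep": self.uvep.tolist(),
            "sigma_uvep": self.sigma_uvep.tolist(),
            "Sigma_param": self.Sigma_param.tolist(),
            "sigma_exp": {k: float(v) for k, v in self.sigma_exp.items()},
            "PV": self.PV.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierParams":
        return cls(np.asarray(d["beta0"], float), np.asarray(d["beta_temp"], float),
                   np.asarray(d["uvep"], float), np.asarray(d["sigma_uvep"], float),
                   np.asarray(d["Sigma_param"], float),
                   {k: float(v) for k, v in d["sigma_exp"].items()},
                   np.asarray(d["PV"], float))


#: Literature-informed prior means for the temperature effect (per degC, factor
#: scale): warming speeds kinetics (log time-constant maxima fall, roughly
#: Q10 ~ 2.7 => -0.1 per degC) and mildly raises conductance (Q10 ~ 1.5).
def _default_mu_lit() -> dict:
    mu = {name: 0.0 for name in FACTOR_NAMES}
    for name in FACTOR_NAMES:
        if name.endswith("max_factor") or name == "baseline_factor":
            mu[name] = -0.1
    mu["GNaFactor"] = 0.04
    return mu


@dataclass
class Priors:
    """Hyperprior settings on the unconstrained factor scale."""

    beta0_mean: np.ndarray  # (K,)
    beta0_sd: float = 5.0
    beta_temp_mean: np.ndarray = None  # (K,)
    beta_temp_sd: float = 0.5
    sigma_uvep_scale: float = 1.0  # Half-Normal
    sigma_exp_scale: float = 1.0  # Half-Normal
    iw_df: float = None  # Inverse-Wishart nu (default K + 4)
    iw_scale: np.ndarray = None  # Psi (default 0.01 * (nu - K - 1) * I)

    @classmethod
    def default(cls, space: FactorSpace) -> "Priors":
        K = space.k
        mu_lit = _default_mu_lit()
        nu = K + 4
        return cls(
            beta0_mean=space.reference(),
            beta_temp_mean=np.array([mu_lit[n] for n in space.free_names]),
            iw_df=nu,
            iw_scale=0.01 * (nu - K - 1) * np.eye(K),
        )


# ---------------------------------------------------------------------------
# Record simulation and likelihood
# ---------------------------------------------------------------------------

def _protocol_at_data_x(record: ExperimentRecord) -> ProtocolSpec:
    """The record's protocol re-targeted to the observed x grid."""
    d = record.protocol.to_dict()
    x = record.data.x.tolist()
    if record.kind in ("IV", "SSA", "SSI"):
        d["test_potentials"] = x
    elif record.kind == "REC":
        d["inter_pulse_intervals"] = x
    # TRACE keeps its sample_dt grid
    return ProtocolSpec.from_dict(d)


def simulate_record(record: ExperimentRecord, factors: FactorVector,
                    method: str = "analytic") -> np.ndarray:
    """Predicted values on the record's comparison scale at its x grid.

    IV simulations are normalised exactly as the data were (signed square
    root, preceded by scaling to minimum -1 for records that were not
    capacitance-normalised).
    """
    p = transform_factors(factors)
    spec = _protocol_at_data_x(record)
    curve = run_protocol(p, spec, method=method)
    if record.kind == "IV":
        curve = CurveData(curve.x, curve.y,
                          capacitance_normalized=record.capacitance_normalized,
                          units=curve.units)
        curve = normalize_iv(curve)
    if record.kind == "TRACE":
        return np.interp(record.data.x, curve.x, curve.y)
    return curve.y


def _gauss_loglik(resid: np.ndarray, sigma: float) -> float:
    n = resid.size
    return float(-0.5 * n * _LOG2PI - n * math.log(sigma)
                 - 0.5 * np.dot(resid, resid) / sigma**2)


def experiment_loglik(record: ExperimentRecord, factors: FactorVector,
                      sigma_exp: float, method: str = "analytic",
                      predicted: np.ndarray | None = None) -> float:
    """Gaussian log-likelihood of one experiment's curve given a factor row."""
    try:
        pred = predicted if predicted is not None else simulate_record(
            record, factors, method=method)
    except (IntegrationError, ValueError):
        return -np.inf
    resid = record.data.y - pred
    if not np.all(np.isfinite(resid)):
        return -np.inf
    return _gauss_loglik(resid, sigma_exp)


def mvn_logpdf(x: np.ndarray, mean: np.ndarray, cho) -> float:
    """MVN log-density given a precomputed ``cho_factor`` of the covariance."""
    d = x - mean
    k = x.size
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return float(-0.5 * (k * _LOG2PI + logdet + d @ cho_solve(cho, d)))


def param_row_loglik(P_i: np.ndarray, paper_index: int, T: float,
                     h: HierParams, cho=None) -> float:
    """Log-density of one experiment's factor row under the parameter level."""
    mean = h.beta0 + h.beta_temp * T + h.uvep[paper_index]
    if cho is None:
        cho = cho_factor(h.Sigma_param, lower=True)
    return mvn_logpdf(np.asarray(P_i, float), mean, cho)


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0) - math.log(scale) - 0.5 * _LOG2PI - 0.5 * (x / scale) ** 2


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class HierModel:
    """Log-posterior machinery binding a dataset to the hierarchical model.

    Parameters
    ----------
    dataset:
        The experiments to fit.
    space:
        Which of the 25 factors are free (default: all).
    priors:
        Hyperprior settings (default: :meth:`Priors.default`).
    simulate_fn:
        ``(record, FactorVector) -> predicted y``.  Defaults to the full
        protocol simulation; tests may inject e.g. an identity map.
    """

    def __init__(self, dataset: StudyDataset, space: FactorSpace | None = None,
                 priors: Priors | None = None, simulate_fn=None,
                 sim_method: str = "analytic"):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.ds = dataset
        self.space = space or FactorSpace()
        self.priors = priors or Priors.default(self.space)
        self.sim_method = sim_method
        self._simulate_fn = simulate_fn
        self.paper_ids = dataset.papers
        self.paper_index = {pid: i for i, pid in enumerate(self.paper_ids)}
        self.kinds = dataset.kinds
        self.T = np.array([r.temperature - TEMPERATURE_REFERENCE
                           for r in dataset.records])
        self.record_paper = np.array([self.paper_index[r.paper_id]
                                      for r in dataset.records])

    # -- simulation ---------------------------------------------------------
    def predict(self, i: int, row: np.ndarray) -> np.ndarray:
        fv = self.space.embed(row)
        if self._simulate_fn is not None:
            return np.asarray(self._simulate_fn(self.ds.records[i], fv), float)
        return simulate_record(self.ds.records[i], fv, method=self.sim_method)

    def experiment_loglik(self, i: int, row: np.ndarray, h: HierParams,
                          predicted: np.ndarray | None = None) -> float:
        r = self.ds.records[i]
        try:
            pred = predicted if predicted is not None else self.predict(i, row)
        except (IntegrationError, ValueError):
            return -np.inf
        resid = r.data.y - pred
        if not np.all(np.isfinite(resid)):
            return -np.inf
        return _gauss_loglik(resid, h.sigma_exp[r.kind])

    # -- priors -------------------------------------------------------------
    def hyperprior_loglik(self, h: HierParams) -> float:
        pr = self.priors
        lp = float(np.sum(-0.5 * _LOG2PI - math.log(pr.beta0_sd)
                          - 0.5 * ((h.beta0 - pr.beta0_mean) / pr.beta0_sd) ** 2))
        lp += float(np.sum(-0.5 * _LOG2PI - math.log(pr.beta_temp_sd)
                           - 0.5 * ((h.beta_temp - pr.beta_temp_mean) / pr.beta_temp_sd) ** 2))
        lp += sum(_halfnormal_logpdf(float(s), pr.sigma_uvep_scale) for s in h.sigma_uvep)
        lp += sum(_halfnormal_logpdf(float(s), pr.sigma_exp_scale)
                  for s in h.sigma_exp.values())
        try:
            lp += float(invwishart.logpdf(h.Sigma_param, df=pr.iw_df, scale=pr.iw_scale))
        except np.linalg.LinAlgError:
            return -np.inf
        return lp

    def uvep_loglik(self, h: HierParams) -> float:
        return float(np.sum(-0.5 * _LOG2PI - np.log(h.sigma_uvep)
                            - 0.5 * (h.uvep / h.sigma_uvep) ** 2))

    # -- posterior ----------------------------------------------------------
    def log_posterior(self, h: HierParams) -> float:
        """Sum of experiment likelihoods, parameter-level densities, UVEP
        densities and hyperpriors; ``-inf`` outside the support."""
        try:
            cho = cho_factor(h.Sigma_param, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        if np.any(h.sigma_uvep <= 0) or any(s <= 0 for s in h.sigma_exp.values()):
            return -np.inf
        lp = self.hyperprior_loglik(h)
        if not np.isfinite(lp):
            return lp
        lp += self.uvep_loglik(h)
        for i in range(len(self.ds)):
            lp += param_row_loglik(h.PV[i], int(self.record_paper[i]),
                                   float(self.T[i]), h, cho=cho)
            lp += self.experiment_loglik(i, h.PV[i], h)
        return float(lp)

    def initial_params(self) -> HierParams:
        """Prior-mean initial state (the sampler's default start)."""
        K = self.space.k
        pr = self.priors
        # Half-Normal(s) mean = s * sqrt(2/pi)
        hn_mean = math.sqrt(2.0 / math.pi)
        beta0 = pr.beta0_mean.copy()
        uvep = np.zeros((len(self.paper_ids), K))
        Sigma = pr.iw_scale / (pr.iw_df - K - 1)
        PV = np.tile(beta0, (len(self.ds), 1)) + np.outer(self.T, pr.beta_temp_mean)
        return HierParams(
            beta0=beta0,
            beta_temp=pr.beta_temp_mean.copy(),
            uvep=uvep,
            sigma_uvep=np.full(K, pr.sigma_uvep_scale * hn_mean),
            Sigma_param=Sigma,
            sigma_exp={k: pr.sigma_exp_scale * hn_mean for k in self.kinds},
            PV=PV,
        )


def map_estimate(chain) -> HierParams:
    """The sampled state with maximal log-posterior (ties -> latest draw)."""
    lp = np.asarray(chain.log_post, dtype=float)
    if lp.size == 0:
        raise ValueError("empty chain")
    best = int(np.flatnonzero(lp == lp.max())[-1])
    return chain.states[best]
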