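"""Hybrid Markov/Hodgkin-Huxley model of the cardiac Na+ channel Na_v1.5.

The channel is represented by three independent gating modules:

* an activation module with two states (open ``Om`` and closed ``Cm``),
  equivalent to a Hodgkin-Huxley *m* gate cubed in the open probability;
* a fast inactivation module, a linear three-state chain
  ``Af <-> Cf <-> If`` (active, closed, inactivated);
* a slow inactivation module ``As <-> Cs <-> Is`` with the same topology.

The ``A <-> C`` transition of each inactivation chain is governed by the
shared inactivation steady state ``hss`` with a module-specific time
constant (``tau_hf`` fast, ``tau_hs`` slow); the ``C <-> I`` transition
(recovery) uses ``jss``/``tau_j`` identically in both chains.  The open
probability is ``Om^3 * (Ahf*Af + (1-Ahf)*As)`` where ``Ahf`` is the
fraction of fast versus slow inactivation.

All 25 model parameters are driven by unconstrained real *factors*:
positivity-constrained parameters (conductance, slopes, time-constant
maxima, the shared baseline) through an exponential transform, the
fraction ``Ahf`` through a logistic transform, and voltage shifts through
the identity.  At a fixed membrane potential the whole system is linear
in the state, which the protocol layer exploits for exact
piecewise-constant-voltage integration.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import math

import numpy as np

__all__ = [
    "FACTOR_NAMES",
    "N_FACTORS",
    "N_STATES",
    "STATE_NAMES",
    "DEFAULT_FACTORS",
    "FactorVector",
    "ChannelParams",
    "ChannelState",
    "BathConditions",
    "transform_factors",
    "inverse_transform",
    "mss",
    "hss",
    "jss",
    "tau_m",
    "tau_hf",
    "tau_hs",
    "tau_j",
    "gate_rates",
    "ode_rhs",
    "open_probability",
    "nernst",
    "current",
    "stationary_state",
]

# ---------------------------------------------------------------------------
# Factor bookkeeping
# ---------------------------------------------------------------------------

#: Canonical ordering of the 25 unconstrained factors; shared by every module.
FACTOR_NAMES: tuple[str, ...] = (
    "GNaFactor",
    "mss_shift",
    "mss_slope_factor",
    "tau_m_shift",
    "tau_m_max_factor",
    "tau_m_slope1_factor",
    "tau_m_slope2_factor",
    "hss_shift",
    "hss_slope_factor",
    "tau_hf_shift",
    "tau_hf_max_factor",
    "tau_hf_slope1_factor",
    "tau_hf_slope2_factor",
    "tau_hs_shift",
    "tau_hs_max_factor",
    "tau_hs_slope1_factor",
    "tau_hs_slope2_factor",
    "jss_shift",
    "jss_slope_factor",
    "tau_j_shift",
    "tau_j_max_factor",
    "tau_j_slope1_factor",
    "tau_j_slope2_factor",
    "baseline_factor",
    "AhfFactor",
)

N_FACTORS = len(FACTOR_NAMES)  # 25
N_STATES = 8
STATE_NAMES: tuple[str, ...] = ("Om", "Cm", "Af", "Cf", "If", "As", "Cs", "Is")

_FACTOR_INDEX = {name: i for i, name in enumerate(FACTOR_NAMES)}

# Factors passed through exp() to yield strictly positive parameters.
_EXP_FACTORS = frozenset(
    name
    for name in FACTOR_NAMES
    if name.endswith(("slope_factor", "slope1_factor", "slope2_factor", "max_factor"))
    or name in ("GNaFactor", "baseline_factor")
)
# Shifts are identity-transformed; Ahf is logistic.
_SHIFT_FACTORS = frozenset(n for n in FACTOR_NAMES if n.endswith("shift"))

# Guard for exp() overflow; slopes additionally floored away from zero.
_EXP_CLIP = 500.0
_SLOPE_FLOOR = 1e-6

#: Reference human-atrial Na_v1.5 parameterisation on the factor scale:
#: activation midpoint near -40 mV (slope ~7 mV), inactivation/recovery
#: midpoints near -82 mV (slope ~6 mV), tau maxima ~0.4 ms (m), 8 ms (hf),
#: 60 ms (hs), 150 ms (j), 1 ms shared baseline, Ahf ~ 0.9.
DEFAULT_FACTORS: dict[str, float] = {
    "GNaFactor": 0.0,
    "mss_shift": 40.0,
    "mss_slope_factor": math.log(7.0),
    "tau_m_shift": -40.0,
    "tau_m_max_factor": math.log(0.4),
    "tau_m_slope1_factor": math.log(12.0),
    "tau_m_slope2_factor": math.log(12.0),
    "hss_shift": -82.0,
    "hss_slope_factor": math.log(6.0),
    "tau_hf_shift": -70.0,
    "tau_hf_max_factor": math.log(8.0),
    "tau_hf_slope1_factor": math.log(12.0),
    "tau_hf_slope2_factor": math.log(30.0),
    "tau_hs_shift": -75.0,
    "tau_hs_max_factor": math.log(60.0),
    "tau_hs_slope1_factor": math.log(15.0),
    "tau_hs_slope2_factor": math.log(30.0),
    "jss_shift": -82.0,
    "jss_slope_factor": math.log(6.0),
    "tau_j_shift": -85.0,
    "tau_j_max_factor": math.log(150.0),
    "tau_j_slope1_factor": math.log(15.0),
    "tau_j_slope2_factor": math.log(20.0),
    "baseline_factor": 0.0,
    "AhfFactor": 2.2,
}


@dataclass(frozen=True)
class FactorVector:
    """The 25 unconstrained parameters of one channel model.

    Values are stored in the canonical :data:`FACTOR_NAMES` order.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_FACTORS,):
            raise ValueError(f"FactorVector needs exactly {N_FACTORS} entries, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("FactorVector entries must be finite")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "FactorVector":
        missing = set(FACTOR_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing factors: {sorted(missing)}")
        return cls(np.array([d[name] for name in FACTOR_NAMES], dtype=float))

    @classmethod
    def default(cls) -> "FactorVector":
        return cls.from_dict(DEFAULT_FACTORS)

    def to_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(FACTOR_NAMES, self.values)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FactorVector":
        return cls.from_dict(json.loads(s))

    def replace(self, **kwargs: float) -> "FactorVector":
        d = self.to_dict()
        for k, v in kwargs.items():
            if k not in _FACTOR_INDEX:
                raise KeyError(k)
            d[k] = float(v)
        return FactorVector.from_dict(d)

    def __getitem__(self, name: str) -> float:
        return float(self.values[_FACTOR_INDEX[name]])


@dataclass(frozen=True)
class ChannelParams:
    """Biophysical parameters on their natural (constrained) scale."""

    GNa: float
    mss_shift: float
    mss_slope: float
    tau_m_shift: float
    tau_m_max: float
    tau_m_slope1: float
    tau_m_slope2: float
    hss_shift: float
    hss_slope: float
    tau_hf_shift: float
    tau_hf_max: float
    tau_hf_slope1: float
    tau_hf_slope2: float
    tau_hs_shift: float
    tau_hs_max: float
    tau_hs_slope1: float
    tau_hs_slope2: float
    jss_shift: float
    jss_slope: float
    tau_j_shift: float
    tau_j_max: float
    tau_j_slope1: float
    tau_j_slope2: float
    baseline: float
    Ahf: float

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ChannelParams":
        return cls(**{k: float(d[k]) for k in cls.__dataclass_fields__})


@dataclass
class ChannelState:
    """Occupancies of the 8 Markov states (three conserved modules)."""

    Om: float
    Cm: float
    Af: float
    Cf: float
    If: float
    As: float
    Cs: float
    Is: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Om, self.Cm, self.Af, self.Cf, self.If,
                         self.As, self.Cs, self.Is], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ChannelState":
        return cls(*(float(x) for x in np.asarray(arr, dtype=float)))

    def validate(self, tol: float = 1e-6) -> None:
        arr = self.as_array()
        if np.any(arr < -tol) or np.any(arr > 1 + tol):
            raise ValueError("occupancies must lie in [0, 1]")
        for lo, hi in ((0, 2), (2, 5), (5, 8)):
            if abs(arr[lo:hi].sum() - 1.0) > tol:
                raise ValueError("module occupancies must sum to 1")


@dataclass(frozen=True)
class BathConditions:
    """Recording-bath conditions entering the Nernst potential."""

    temperature: float = 22.0  # degC
    Na_out: float = 140.0  # mM
    Na_in: float = 9.1  # mM

    def __post_init__(self) -> None:
        if self.Na_out <= 0 or self.Na_in <= 0:
            raise ValueError("Na+ concentrations must be positive")

    def to_dict(self) -> dict[str, float]:
        return {"temperature": self.temperature, "Na_out": self.Na_out, "Na_in": self.Na_in}

    @classmethod
    def from_dict(cls, d: dict) -> "BathConditions":
        return cls(**{k: float(d[k]) for k in ("temperature", "Na_out", "Na_in")})


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform_factors(f: FactorVector) -> ChannelParams:
    """Map unconstrained factors to constrained biophysical parameters.

    Exponential transform for positivity (conductance base 1, slopes,
    tau maxima, baseline), logistic for the fast fraction ``Ahf``,
    identity for voltage shifts.
    """
    d = f.to_dict()
    out: dict[str, float] = {}
    for name, v in d.items():
        if name in _EXP_FACTORS:
            val = math.exp(min(max(v, -_EXP_CLIP), _EXP_CLIP))
            if "slope" in name:
                val = max(val, _SLOPE_FLOOR)
            key = _param_key(name)
        elif name == "AhfFactor":
            val = 1.0 / (1.0 + math.exp(-min(max(v, -_EXP_CLIP), _EXP_CLIP)))
            key = "Ahf"
        else:  # shift
            val = v
            key = name
        out[key] = val
    return ChannelParams(**out)


def _param_key(factor_name: str) -> str:
    if factor_name == "GNaFactor":
        return "GNa"
    if factor_name == "baseline_factor":
        return "baseline"
    return factor_name.removesuffix("_factor")


def inverse_transform(p: ChannelParams) -> FactorVector:
    """Inverse of :func:`transform_factors`; round-trips to 1e-12."""
    d = p.to_dict()
    vals = {}
    for name in FACTOR_NAMES:
        if name in _EXP_FACTORS:
            vals[name] = math.log(d[_param_key(name)])
        elif name == "AhfFactor":
            a = d["Ahf"]
            vals[name] = math.log(a / (1.0 - a))
        else:
            vals[name] = d[name]
    return FactorVector.from_dict(vals)


# ---------------------------------------------------------------------------
# Steady-state and time-constant curves
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP)))


def mss(v, p: ChannelParams):
    """Activation steady state, increasing in v; midpoint at ``-mss_shift``."""
    return _sigmoid(-(np.asarray(v, dtype=float) + p.mss_shift) / p.mss_slope)


def hss(v, p: ChannelParams):
    """Inactivation steady state, decreasing in v; midpoint at ``hss_shift``.

    Note the sign convention differs from :func:`mss`: the curves are
    written exactly as printed, ``hss`` and ``jss`` use ``v - shift``
    while ``mss`` uses ``v + shift``.
    """
    return _sigmoid((np.asarray(v, dtype=float) - p.hss_shift) / p.hss_slope)


def jss(v, p: ChannelParams):
    """Recovery steady state, decreasing in v; midpoint at ``jss_shift``."""
    return _sigmoid((np.asarray(v, dtype=float) - p.jss_shift) / p.jss_slope)


def _bi_exponential_tau(v, shift, tau_max, slope_right, slope_left, scaled_baseline):
    v = np.asarray(v, dtype=float)
    x = v - shift
    denom = np.exp(np.clip(x / slope_right, -_EXP_CLIP, _EXP_CLIP)) + np.exp(
        np.clip(-x / slope_left, -_EXP_CLIP, _EXP_CLIP)
    )
    return scaled_baseline + tau_max / denom


# Baseline scale constants for gates m, hf, hs, j.
_BASELINE_SCALE = {"m": 1.0 / 15.0, "hf": 1.0 / 10.0, "hs": 1.0, "j": 1.0}


def tau_m(v, p: ChannelParams):
    """Activation time constant (ms); asymptote ``baseline/15``."""
    return _bi_exponential_tau(v, p.tau_m_shift, p.tau_m_max,
                               p.tau_m_slope1, p.tau_m_slope2,
                               p.baseline * _BASELINE_SCALE["m"])


def tau_hf(v, p: ChannelParams):
    """Fast inactivation time constant (ms); asymptote ``baseline/10``."""
    return _bi_exponential_tau(v, p.tau_hf_shift, p.tau_hf_max,
                               p.tau_hf_slope2, p.tau_hf_slope1,
                               p.baseline * _BASELINE_SCALE["hf"])


def tau_hs(v, p: ChannelParams):
    """Slow inactivation time constant (ms); asymptote ``baseline``."""
    return _bi_exponential_tau(v, p.tau_hs_shift, p.tau_hs_max,
                               p.tau_hs_slope2, p.tau_hs_slope1,
                               p.baseline * _BASELINE_SCALE["hs"])


def tau_j(v, p: ChannelParams):
    """Recovery time constant (ms); asymptote ``baseline``."""
    return _bi_exponential_tau(v, p.tau_j_shift, p.tau_j_max,
                               p.tau_j_slope2, p.tau_j_slope1,
                               p.baseline * _BASELINE_SCALE["j"])


# ---------------------------------------------------------------------------
# Markov rates, ODE right-hand side, current
# ---------------------------------------------------------------------------

def gate_rates(ss, tau):
    """Convert an HH (steady state, time constant) pair to two-state rates.

    ``alpha = ss/tau`` (toward the permissive state), ``beta = (1-ss)/tau``,
    so that ``alpha/(alpha+beta) = ss`` and ``1/(alpha+beta) = tau``.
    """
    ss = np.asarray(ss, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(ss <= 0) or np.any(ss >= 1):
        raise ValueError("steady state must lie strictly in (0, 1)")
    if np.any(tau <= 0):
        raise ValueError("time constant must be positive")
    return ss / tau, (1.0 - ss) / tau


def _all_rates(v, p: ChannelParams):
    """All module transition rates at potential(s) v."""
    a_m, b_m = gate_rates(mss(v, p), tau_m(v, p))
    a_hf, b_hf = gate_rates(hss(v, p), tau_hf(v, p))
    a_hs, b_hs = gate_rates(hss(v, p), tau_hs(v, p))
    a_j, b_j = gate_rates(jss(v, p), tau_j(v, p))
    return a_m, b_m, a_hf, b_hf, a_hs, b_hs, a_j, b_j


def ode_rhs(s, v: float, p: ChannelParams) -> np.ndarray:
    """Time derivative of the 8 occupancies at fixed potential ``v``.

    Accepts a :class:`ChannelState` or a length-8 array (solver-friendly).
    Within each module the derivatives sum to zero exactly.
    """
    y = s.as_array() if isinstance(s, ChannelState) else np.asarray(s, dtype=float)
    Om, Cm, Af, Cf, If, As, Cs, Is = y
    a_m, b_m, a_hf, b_hf, a_hs, b_hs, a_j, b_j = _all_rates(v, p)

    dOm = a_m * Cm - b_m * Om
    # fast chain Af <-(hss,tau_hf)-> Cf <-(jss,tau_j)-> If
    dAf = a_hf * Cf - b_hf * Af
    dIf = b_j * Cf - a_j * If
    dCf = -(dAf + dIf)
    # slow chain, same recovery rates
    dAs = a_hs * Cs - b_hs * As
    dIs = b_j * Cs - a_j * Is
    dCs = -(dAs + dIs)
    return np.array([dOm, -dOm, dAf, dCf, dIf, dAs, dCs, dIs])


def open_probability(s, Ahf: float):
    """Open probability ``Om^3 * (Ahf*Af + (1-Ahf)*As)``."""
    if not 0.0 < Ahf < 1.0:
        raise ValueError("Ahf must lie in (0, 1)")
    if isinstance(s, ChannelState):
        Om, Af, As = s.Om, s.Af, s.As
    else:
        y = np.asarray(s, dtype=float)
        Om, Af, As = y[..., 0], y[..., 2], y[..., 5]
    return Om**3 * (Ahf * Af + (1.0 - Ahf) * As)


_R = 8.314462618  # J/(mol K)
_F = 96485.33212  # C/mol


def nernst(b: BathConditions) -> float:
    """Na+ reversal potential (mV) from the trans-membrane concentration ratio."""
    if b.Na_out <= 0 or b.Na_in <= 0:
        raise ValueError("concentrations must be positive")
    t_kelvin = b.temperature + 273.15
    return 1000.0 * _R * t_kelvin / _F * math.log(b.Na_out / b.Na_in)


def current(v, s, p: ChannelParams, E_Na: float):
    """Sodium current ``GNa * P_open * (v - E_Na)`` (ohmic driving force)."""
    return p.GNa * open_probability(s, p.Ahf) * (np.asarray(v, dtype=float) - E_Na)


def stationary_state(v: float, p: ChannelParams) -> ChannelState:
    """Stationary occupancies at fixed potential (detailed-balance chains)."""
    m_inf = float(mss(v, p))
    h_inf = float(hss(v, p))
    j_inf = float(jss(v, p))
    # chain weights A : C : I = hss*jss : (1-hss)*jss : (1-hss)*(1-jss)
    wA, wC, wI = h_inf * j_inf, (1 - h_inf) * j_inf, (1 - h_inf) * (1 - j_inf)
    z = wA + wC + wI
    A, C, I = wA / z, wC / z, wI / z
    return ChannelState(Om=m_inf, Cm=1 - m_inf, Af=A, Cf=C, If=I, As=A, Cs=C, Is=I)


# ---------------------------------------------------------------------------
# Exact propagation at fixed voltage (used by the protocol layer)
# ---------------------------------------------------------------------------

@dataclass
class SegmentSolution:
    """Closed-form gating trajectory over one constant-voltage segment.

    The activation pair relaxes mono-exponentially; each inactivation
    chain is a 3x3 linear system solved by eigendecomposition.  Calling
    the object with a time array returns state occupancies of shape
    ``(len(t), 8)``.
    """

    m_inf: float
    tau_m_v: float
    m0: float
    eig_f: tuple[np.ndarray, np.ndarray, np.ndarray]  # (lambdas, V, coeffs)
    eig_s: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, N_STATES))
        m = self.m_inf + (self.m0 - self.m_inf) * np.exp(-t / self.tau_m_v)
        out[:, 0] = m
        out[:, 1] = 1.0 - m
        for cols, (lam, V, c) in (((2, 3, 4), self.eig_f), ((5, 6, 7), self.eig_s)):
            # x(t) = V @ (c * exp(lam t)); lam real for these chains
            traj = (V[None, :, :] * (c * np.exp(np.outer(t, lam)))[:, None, :]).sum(-1)
            out[:, cols[0]] = traj[:, 0]
            out[:, cols[1]] = traj[:, 1]
            out[:, cols[2]] = traj[:, 2]
        return out


def _chain_eig(a_h, b_h, a_j, b_j, x0):
    """Eigendecomposition propagator for a 3-state chain A<->C<->I."""
    Q = np.array([
        [-b_h, a_h, 0.0],
        [b_h, -(a_h + b_j), a_j],
        [0.0, b_j, -a_j],
    ])
    lam, V = np.linalg.eig(Q)
    lam = lam.real
    V = V.real
    c = np.linalg.solve(V, x0)
    return lam, V, c


def segment_solution(v: float, p: ChannelParams, s0) -> SegmentSolution:
    """Exact solution of the gating ODEs at constant ``v`` from state ``s0``."""
    y0 = s0.as_array() if isinstance(s0, ChannelState) else np.asarray(s0, dtype=float)
    a_m, b_m, a_hf, b_hf, a_hs, b_hs, a_j, b_j = (float(r) for r in _all_rates(v, p))
    tau = 1.0 / (a_m + b_m)
    m_inf = a_m * tau
    eig_f = _chain_eig(a_hf, b_hf, a_j, b_j, y0[2:5])
    eig_s = _chain_eig(a_hs, b_hs, a_j, b_j, y0[5:8])
    return SegmentSolution(m_inf=m_inf, tau_m_v=tau, m0=float(y0[0]),
                           eig_f=eig_f, eig_s=eig_s)
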