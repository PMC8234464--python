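"""Single-cell pacing and 1-D fiber conduction with the fitted Na+ channel.

The channel is embedded in a minimal host membrane behind the
:class:`HostCellAdapter` contract: any callable that maps
``(V, host_state, t)`` to the non-sodium ionic current and the host-state
derivative can serve as the host.  The bundled
:class:`MinimalAtrialHost` combines an inward-rectifier-like background
K+ current, a slow delayed repolarising current and a small background
leak, parameterised to rest near -80 mV with an atrial-like action
potential duration.  Validation quantities computed here — maximum
upstroke velocity dV/dt_max and conduction velocity — are dominated by
the sodium current and the intercellular coupling.

Whole-cell use requires the same adjustments applied in the source
analysis: the inactivation/recovery steady-state midpoints move +16 mV,
the activation/inactivation steady-state slopes widen by 1.6 mV
(additive by default, multiplicative optionally) and the conductance is
tuned to a target mean upstroke velocity.

Numerics: fixed-step integration with exact exponential (Rush-Larsen
style) updates for the gating chains — the activation pair exactly, the
three-state chains by sequential pairwise splitting — and forward Euler
for the membrane potential; the 1-D fiber adds nearest-neighbour
resistive coupling with no-flux boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channel_core import (
    BathConditions,
    ChannelParams,
    FactorVector,
    nernst,
    stationary_state,
    transform_factors,
)

__all__ = [
    "WholeCellAdjustments",
    "HostCellAdapter",
    "MinimalAtrialHost",
    "FiberSpec",
    "APRecord",
    "FiberResult",
    "adjust_params",
    "pace_cell",
    "pace_population",
    "simulate_fiber",
    "tune_gna",
    "TuningError",
]


class TuningError(RuntimeError):
    """Conductance target unreachable within the allowed scalar bounds."""


@dataclass
class WholeCellAdjustments:
    """Parameter-scale adjustments applied after the factor transform."""

    ss_shift: float = 16.0  # mV, positive shift of hss/jss midpoints
    slope_delta: float = 1.6  # widening of mss/hss steady-state slopes
    slope_mode: str = "additive"  # or "multiplicative"
    gna_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.slope_mode not in ("additive", "multiplicative"):
            raise ValueError("slope_mode must be 'additive' or 'multiplicative'")


def adjust_params(p: ChannelParams, adj: WholeCellAdjustments) -> ChannelParams:
    """Apply whole-cell adjustments to constrained channel parameters."""
    if adj.slope_mode == "additive":
        mss_slope = p.mss_slope + adj.slope_delta
        hss_slope = p.hss_slope + adj.slope_delta
    else:
        mss_slope = p.mss_slope * adj.slope_delta
        hss_slope = p.hss_slope * adj.slope_delta
    return replace(
        p,
        hss_shift=p.hss_shift + adj.ss_shift,
        jss_shift=p.jss_shift + adj.ss_shift,
        mss_slope=mss_slope,
        hss_slope=hss_slope,
        GNa=p.GNa * adj.gna_scale,
    )


# ---------------------------------------------------------------------------
# Host membrane
# ---------------------------------------------------------------------------

@dataclass
class StimulusSchedule:
    amplitude: float = -80.0  # pA/pF (inward)
    duration: float = 2.0  # ms
    bcl: float = 1000.0  # ms
    beats: int = 2


@dataclass
class HostCellAdapter:
    """Contract for a host membrane model.

    ``currents(V, host_state, t)`` returns ``(I_host, d_host_state/dt)``
    for vectorised ``V`` (shape ``(n_cells,)``) and host state of shape
    ``(n_host_states, n_cells)``.  ``initial_state(n)`` returns the
    host-state array; ``resting_potential`` seeds the membrane voltage.
    """

    currents: object
    initial_state: object
    capacitance: float = 1.0  # uF/cm^2 (currents in pA/pF)
    resting_potential: float = -80.0
    stimulus: StimulusSchedule = field(default_factory=StimulusSchedule)


class MinimalAtrialHost:
    """Inward-rectifier K+ current + slow delayed repolariser + leak.

    Rests near -80 mV and repolarises within a few hundred ms; the one
    host state variable is the delayed-rectifier activation gate.
    """

    E_K = -87.0
    g_K1 = 0.6
    g_x = 0.15
    tau_x = 80.0  # ms
    g_b = 0.03
    E_b = -20.0

    def currents(self, V, host_state, t):
        x = host_state[0]
        i_k1 = self.g_K1 * (V - self.E_K) / (1.0 + np.exp((V + 70.0) / 7.0))
        i_x = self.g_x * x * (V - self.E_K)
        i_b = self.g_b * (V - self.E_b)
        x_inf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
        dx = (x_inf - x) / self.tau_x
        return i_k1 + i_x + i_b, np.asarray([dx])

    def initial_state(self, n):
        return np.zeros((1, n))


def default_host(stimulus: StimulusSchedule | None = None) -> HostCellAdapter:
    m = MinimalAtrialHost()
    return HostCellAdapter(currents=m.currents, initial_state=m.initial_state,
                           stimulus=stimulus or StimulusSchedule())


# ---------------------------------------------------------------------------
# Vectorised channel parameter arrays
# ---------------------------------------------------------------------------

class _ParamArrays:
    """Per-cell channel parameters as flat arrays for vectorised stepping."""

    def __init__(self, params: list[ChannelParams]):
        for name in ChannelParams.__dataclass_fields__:
            setattr(self, name, np.array([getattr(p, name) for p in params]))

    def curves(self, V):
        mss = 1.0 / (1.0 + np.exp(-(V + self.mss_shift) / self.mss_slope))
        hss = 1.0 / (1.0 + np.exp((V - self.hss_shift) / self.hss_slope))
        jss = 1.0 / (1.0 + np.exp((V - self.jss_shift) / self.jss_slope))
        tm = self.baseline / 15.0 + self.tau_m_max / (
            np.exp((V - self.tau_m_shift) / self.tau_m_slope1)
            + np.exp(-(V - self.tau_m_shift) / self.tau_m_slope2))
        thf = self.baseline / 10.0 + self.tau_hf_max / (
            np.exp((V - self.tau_hf_shift) / self.tau_hf_slope2)
            + np.exp(-(V - self.tau_hf_shift) / self.tau_hf_slope1))
        ths = self.baseline + self.tau_hs_max / (
            np.exp((V - self.tau_hs_shift) / self.tau_hs_slope2)
            + np.exp(-(V - self.tau_hs_shift) / self.tau_hs_slope1))
        tj = self.baseline + self.tau_j_max / (
            np.exp((V - self.tau_j_shift) / self.tau_j_slope2)
            + np.exp(-(V - self.tau_j_shift) / self.tau_j_slope1))
        return mss, hss, jss, tm, thf, ths, tj


@dataclass
class APRecord:
    """Per-beat action-potential measurements for one paced cell."""

    dvdt_max: np.ndarray  # per beat, mV/ms
    apd90: np.ndarray  # per beat, ms (nan if not repolarized)
    v_rest: float
    v_peak: np.ndarray
    repolarized: np.ndarray  # per-beat flag
    t: np.ndarray | None = None
    V: np.ndarray | None = None

    @property
    def steady_dvdt_max(self) -> float:
        return float(self.dvdt_max[-1])


@dataclass
class FiberResult:
    activation_times: np.ndarray  # per cell, ms from last stimulus
    dvdt_max_cells: np.ndarray  # per cell
    upstroke: float  # mean over measurement cells
    cv: float | None  # cm/s, None on conduction block
    block_reason: str | None = None


@dataclass
class FiberSpec:
    n_cells: int = 100
    coupling: float = 15.0  # 1/ms, nearest-neighbour conductance / Cm
    cell_length: float = 100.0  # um
    stim_cells: int = 5  # cells 0..stim_cells-1 receive the stimulus
    upstroke_cells: tuple = (20, 30, 40, 50, 60, 70, 80)
    cv_cells: tuple = (30, 80)

    def __post_init__(self) -> None:
        if self.n_cells < max(self.upstroke_cells + self.cv_cells) + 1:
            raise ValueError("fiber too short for the configured measurement cells")


# ---------------------------------------------------------------------------
# Core fixed-step integrator (batch of cells, optional coupling)
# ---------------------------------------------------------------------------

def _simulate(params: list[ChannelParams], host: HostCellAdapter,
              bath: BathConditions, dt: float, coupling: float | None,
              record_traces: bool, stim_cells: int = 3):
    """Paced integration of a batch of cells; returns per-beat measurements.

    With ``coupling`` set, cells form a 1-D cable (no-flux ends) and only
    the first :class:`FiberSpec` stimulus cells are paced directly.
    """
    n = len(params)
    pa = _ParamArrays(params)
    e_na = nernst(bath)
    stim = host.stimulus
    V = np.full(n, host.resting_potential, dtype=float)
    # start gates at their stationary values for the resting potential
    s0 = [stationary_state(host.resting_potential, p) for p in params]
    m = np.array([s.Om for s in s0])
    Af = np.array([s.Af for s in s0])
    Cf = np.array([s.Cf for s in s0])
    If = np.array([s.If for s in s0])
    As = np.array([s.As for s in s0])
    Cs = np.array([s.Cs for s in s0])
    Is = np.array([s.Is for s in s0])
    host_state = np.asarray(host.initial_state(n), dtype=float)

    stim_mask = np.zeros(n)
    if coupling is None:
        stim_mask[:] = 1.0
    else:
        stim_mask[: min(stim_cells, n)] = 1.0

    n_steps_beat = int(round(stim.bcl / dt))
    beats = stim.beats
    dvdt_max = np.zeros((beats, n))
    t_at_max = np.zeros((beats, n))
    v_peak = np.full((beats, n), -np.inf)
    v_min_late = np.full((beats, n), np.inf)
    apd90 = np.full((beats, n), np.nan)
    v_rest0 = V.copy()

    traces_t, traces_v = [], []
    record_every = max(int(round(0.5 / dt)), 1)

    for b in range(beats):
        crossed = np.zeros(n, dtype=bool)
        for k in range(n_steps_beat):
            t_in_beat = k * dt
            mss, hss, jss, tm, thf, ths, tj = pa.curves(V)
            p_open = m**3 * (pa.Ahf * Af + (1.0 - pa.Ahf) * As)
            i_na = pa.GNa * p_open * (V - e_na)
            i_host, dhost = host.currents(V, host_state, t_in_beat)
            i_stim = stim.amplitude * stim_mask if t_in_beat < stim.duration else 0.0
            dV = -(i_na + i_host + i_stim) / host.capacitance
            if coupling is not None and n > 1:
                lap = np.empty(n)
                lap[1:-1] = V[:-2] - 2 * V[1:-1] + V[2:]
                lap[0] = V[1] - V[0]
                lap[-1] = V[-2] - V[-1]
                dV = dV + coupling * lap

            better = dV > dvdt_max[b]
            dvdt_max[b][better] = dV[better]
            t_at_max[b][better] = t_in_beat
            np.maximum(v_peak[b], V, out=v_peak[b])

            # exact exponential gate updates
            m += (mss - m) * (-np.expm1(-dt / tm))
            aT = Af + Cf
            Af += (hss * aT - Af) * (-np.expm1(-dt / thf))
            Cf = aT - Af
            cT = Cf + If
            Cf += (jss * cT - Cf) * (-np.expm1(-dt / tj))
            If = cT - Cf
            aT = As + Cs
            As += (hss * aT - As) * (-np.expm1(-dt / ths))
            Cs = aT - As
            cT = Cs + Is
            Cs += (jss * cT - Cs) * (-np.expm1(-dt / tj))
            Is = cT - Cs

            V = V + dt * dV
            host_state = host_state + dt * dhost

            if record_traces and k % record_every == 0:
                traces_t.append(b * stim.bcl + t_in_beat)
                traces_v.append(V.copy())

            # APD90: downward crossing of rest + 10% of amplitude
            thresh = v_rest0 + 0.1 * (v_peak[b] - v_rest0)
            newly = (~crossed) & (t_in_beat > stim.duration + 2.0) & (V < thresh) \
                & (v_peak[b] > v_rest0 + 20.0)
            apd90[b][newly] = t_in_beat
            crossed |= newly
            np.minimum(v_min_late[b], V, out=v_min_late[b])

    return {
        "dvdt_max": dvdt_max,
        "t_at_max": t_at_max,
        "v_peak": v_peak,
        "apd90": apd90,
        "repolarized": ~np.isnan(apd90),
        "v_rest": v_rest0,
        "t": np.asarray(traces_t) if record_traces else None,
        "V": np.asarray(traces_v) if record_traces else None,
    }


# ---------------------------------------------------------------------------
# Public drivers
# ---------------------------------------------------------------------------

def _prepare_params(factors, adjustments):
    """Channel params per cell; ``adjustments`` may be one or one-per-cell."""
    fvs = [factors] if isinstance(factors, FactorVector) else list(factors)
    if adjustments is None or isinstance(adjustments, WholeCellAdjustments):
        adjs = [adjustments or WholeCellAdjustments()] * len(fvs)
    else:
        adjs = list(adjustments)
        if len(adjs) != len(fvs):
            raise ValueError("need one adjustment set, or one per cell")
    return [adjust_params(transform_factors(fv), adj)
            for fv, adj in zip(fvs, adjs)]


def pace_cell(factors: FactorVector, host: HostCellAdapter | None = None,
              adjustments: WholeCellAdjustments | None = None,
              bcl: float = 1000.0, beats: int = 2,
              bath: BathConditions | None = None, dt: float = 0.005,
              record_traces: bool = False) -> APRecord:
    """Pace a single cell and measure per-beat dV/dt_max and APD90.

    Failure to repolarise within a cycle flags the beat rather than
    raising; the steady-beat (last-beat) upstroke is the headline value.
    """
    host = host or default_host()
    host.stimulus.bcl = bcl
    host.stimulus.beats = beats
    bath = bath or BathConditions(temperature=37.0)
    params = _prepare_params(factors, adjustments)
    res = _simulate(params, host, bath, dt, coupling=None,
                    record_traces=record_traces)
    return APRecord(
        dvdt_max=res["dvdt_max"][:, 0],
        apd90=res["apd90"][:, 0],
        v_rest=float(res["v_rest"][0]),
        v_peak=res["v_peak"][:, 0],
        repolarized=res["repolarized"][:, 0],
        t=res["t"],
        V=res["V"][:, 0] if res["V"] is not None else None,
    )


def pace_population(draws: list[FactorVector], host: HostCellAdapter | None = None,
                    adjustments=None,
                    bcl: float = 1000.0, beats: int = 2,
                    bath: BathConditions | None = None,
                    dt: float = 0.01) -> np.ndarray:
    """Steady-beat dV/dt_max for every population member (vectorised batch).

    ``adjustments`` may be a single :class:`WholeCellAdjustments` or a
    list with one entry per draw (e.g. for a conductance sweep).
    """
    host = host or default_host()
    host.stimulus.bcl = bcl
    host.stimulus.beats = beats
    bath = bath or BathConditions(temperature=37.0)
    params = _prepare_params(draws, adjustments)
    res = _simulate(params, host, bath, dt, coupling=None, record_traces=False)
    return res["dvdt_max"][-1]


def simulate_fiber(pop_draws, host: HostCellAdapter | None = None,
                   fiber: FiberSpec | None = None, bcl: float = 1000.0,
                   beats: int = 1,
                   adjustments: WholeCellAdjustments | None = None,
                   bath: BathConditions | None = None,
                   dt: float = 0.01) -> FiberResult:
    """1-D cable simulation: per-cell activation times, upstroke and CV.

    ``pop_draws`` is either one factor vector (homogeneous fiber) or one
    per cell.  The fiber upstroke is the mean dV/dt_max over the
    measurement cells; CV uses the activation-time difference between
    the two configured cells (activation time = time of maximal dV/dt).
    """
    host = host or default_host()
    fiber = fiber or FiberSpec()
    host.stimulus.bcl = bcl
    host.stimulus.beats = beats
    bath = bath or BathConditions(temperature=37.0)
    if isinstance(pop_draws, FactorVector):
        fvs = [pop_draws] * fiber.n_cells
    else:
        fvs = list(pop_draws)
        if len(fvs) == 1:
            fvs = fvs * fiber.n_cells
        if len(fvs) != fiber.n_cells:
            raise ValueError("need one draw, or one per fiber cell")
    params = _prepare_params(fvs, adjustments)
    res = _simulate(params, host, bath, dt, coupling=fiber.coupling,
                    record_traces=False, stim_cells=fiber.stim_cells)
    dvdt = res["dvdt_max"][-1]
    t_act = res["t_at_max"][-1]
    upstroke = float(np.mean(dvdt[list(fiber.upstroke_cells)]))
    c_a, c_b = fiber.cv_cells
    activated = res["v_peak"][-1] > res["v_rest"] + 20.0
    if not (activated[c_a] and activated[c_b]) or t_act[c_b] <= t_act[c_a]:
        return FiberResult(t_act, dvdt, upstroke, cv=None,
                           block_reason="conduction block between CV cells")
    cv_um_ms = (c_b - c_a) * fiber.cell_length / (t_act[c_b] - t_act[c_a])
    return FiberResult(t_act, dvdt, upstroke, cv=float(cv_um_ms * 0.1))  # cm/s


def tune_gna(pop_mean_factors: FactorVector, host: HostCellAdapter | None = None,
             target_dvdt: float = 250.0,
             adjustments: WholeCellAdjustments | None = None,
             bcl: float = 1000.0, beats: int = 2, tol: float = 0.02,
             dt: float = 0.01,
             bounds: tuple[float, float] = (0.1, 10.0)) -> float:
    """Find the GNa scalar at which the mean-cell dV/dt_max hits the target.

    Successive interval bisection on a batched geometric grid of
    candidate scales (dV/dt_max is monotone in GNa, so each refinement
    brackets the target).  Deterministic; raises :class:`TuningError` if
    the target lies outside what the scalar bounds can reach.
    """
    if target_dvdt <= 0:
        raise ValueError("target upstroke velocity must be positive")
    base = adjustments or WholeCellAdjustments()

    def measure_grid(scales: np.ndarray) -> np.ndarray:
        adjs = [replace(base, gna_scale=base.gna_scale * float(s))
                for s in scales]
        return pace_population([pop_mean_factors] * len(adjs), host, adjs,
                               bcl=bcl, beats=beats, dt=dt)

    lo, hi = bounds
    for level in range(4):
        grid = np.geomspace(lo, hi, 9)
        f = measure_grid(grid)
        if level == 0 and not (f[0] <= target_dvdt <= f[-1]):
            raise TuningError(
                f"target {target_dvdt} mV/ms outside reachable range "
                f"[{f[0]:.1f}, {f[-1]:.1f}] for GNa scale in {bounds}")
        best = int(np.argmin(np.abs(f - target_dvdt)))
        if abs(f[best] - target_dvdt) / target_dvdt <= tol:
            return float(grid[best])
        k = int(np.searchsorted(f, target_dvdt))
        lo = float(grid[max(k - 1, 0)])
        hi = float(grid[min(k, grid.size - 1)])
    return float(0.5 * (lo + hi))
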