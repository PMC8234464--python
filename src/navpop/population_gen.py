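"""Physiological population of channel models from the fitted distribution.

Draws parameter sets from the fitted multivariate normal
``MVN(beta0 + betaTemp * (T - 17), Sigma_param)`` — the per-paper UVEP
offsets are deliberately excluded so draws represent the overall
population rather than any one lab.  Before drawing, the variability of
the two IV-shift factors (``mss_shift`` and ``tau_hf_shift``), which is
inflated by the large spread of IV-curve locations in the source data,
is capped at a standard deviation of 0.4 on the factor scale; the cap
rescales rows/columns of the covariance so every correlation
coefficient is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel_core import BathConditions, FactorVector, transform_factors
from .clamp_protocols import IntegrationError, ProtocolSpec, run_protocol
from .hier_stat import TEMPERATURE_REFERENCE, FactorSpace, HierParams

__all__ = [
    "DEFAULT_VARIABILITY_CAPS",
    "PopulationSpec",
    "cap_variability",
    "draw_population",
    "population_curves",
    "PopulationSummary",
]

#: Std-dev ceilings (factor scale) applied before population draws.
DEFAULT_VARIABILITY_CAPS: dict[str, float] = {"mss_shift": 0.4, "tau_hf_shift": 0.4}


@dataclass
class PopulationSpec:
    n: int = 100
    temperature: float = 37.0  # degC; body temperature default, configurable
    bath: BathConditions = field(default_factory=lambda: BathConditions(
        temperature=37.0, Na_out=140.0, Na_in=9.1))
    variability_caps: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIABILITY_CAPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("population size must be positive")
        if any(c <= 0 for c in self.variability_caps.values()):
            raise ValueError("variability caps must be positive")


def cap_variability(Sigma: np.ndarray, caps: dict[str, float],
                    space: FactorSpace | None = None) -> np.ndarray:
    """Cap per-factor std devs while preserving all correlations.

    For each named factor whose std exceeds its cap, the corresponding
    row and column of the covariance are rescaled by ``cap/std`` so the
    factor's variance becomes ``cap^2``; correlation coefficients are
    untouched and positive definiteness is preserved (congruence by a
    positive diagonal matrix).
    """
    space = space or FactorSpace()
    Sigma = np.array(Sigma, dtype=float, copy=True)
    scale = np.ones(Sigma.shape[0])
    for name, cap in caps.items():
        if name not in space.free_names:
            continue
        j = space.free_names.index(name)
        std = float(np.sqrt(Sigma[j, j]))
        if std > cap:
            scale[j] = cap / std
    D = np.diag(scale)
    return D @ Sigma @ D


def draw_population(h: HierParams, spec: PopulationSpec,
                    space: FactorSpace | None = None) -> list[FactorVector]:
    """Seeded draws from the capped fitted normal; UVEP effects excluded."""
    space = space or FactorSpace()
    rng = np.random.default_rng(spec.seed)
    mean = h.beta0 + h.beta_temp * (spec.temperature - TEMPERATURE_REFERENCE)
    Sigma = cap_variability(h.Sigma_param, spec.variability_caps, space)
    draws = rng.multivariate_normal(mean, Sigma, size=spec.n,
                                    method="cholesky")
    return [space.embed(row) for row in draws]


@dataclass
class PopulationSummary:
    """Per-protocol population summary: pointwise mean/std of the individual
    curves plus the theoretical-mean curve (protocol at the distribution mean)."""

    x: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    theoretical: np.ndarray
    n_ok: int
    n_failed: int


def population_curves(draws: list[FactorVector],
                      protocols: dict[str, ProtocolSpec],
                      mean_factors: FactorVector,
                      method: str = "analytic") -> dict[str, PopulationSummary]:
    """Run each protocol for every population member and summarise.

    Individual simulation failures are dropped and counted; the
    theoretical-mean curve is the protocol run at ``mean_factors``.
    """
    out: dict[str, PopulationSummary] = {}
    for name, spec in protocols.items():
        curves = []
        failed = 0
        for fv in draws:
            try:
                curves.append(run_protocol(transform_factors(fv), spec,
                                           method=method).y)
            except (IntegrationError, ValueError):
                failed += 1
        theo = run_protocol(transform_factors(mean_factors), spec, method=method)
        ys = np.stack(curves)
        out[name] = PopulationSummary(
            x=theo.x,
            mean=ys.mean(axis=0),
            std=ys.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(theo.y),
            theoretical=theo.y,
            n_ok=len(curves),
            n_failed=failed,
        )
    return out
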