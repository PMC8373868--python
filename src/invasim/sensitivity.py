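"""Morris one-at-a-time elementary-effects sensitivity analysis.

Parameters are varied one at a time along random trajectories in the unit
hypercube; each unit-cube point is mapped to parameter space through the
parameter's prior quantile function.  For each parameter the elementary
effects (output change per unit normalized step) are aggregated into
``mu_star`` (mean absolute effect — the headline sensitivity index) and
``sigma`` (their standard deviation, capturing interactions and
nonlinearity).

Priors: parameters with a literature anchor get a truncated normal with
mean equal to the anchored estimate ``m_e`` and variance ``2 * m_e``
(truncated to the parameter's valid range); phenotype parameters with no
anchor are uniform on [0, 1].  Unbounded truncated-normal priors are
normalized through their quantile function clipped to the 1st-99th
percentile band so that "the range of variation" is finite.

The simulator output fed to the analysis is the restricted mean
invasion-free survival time (area under the Kaplan-Meier curve up to the
censoring horizon); the mean over uncensored patients is available as an
alternative.  Cohorts at different design points share per-patient seed
streams (common random numbers) to reduce elementary-effect noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import simulate_cohort
from .immune import InflammationScheme
from .parameters import (
    ModelParameters,
    SENSITIVITY_PARAMETERS,
    UNIFORM_PRIOR_PARAMETERS,
    is_integer_parameter,
    parameter_bounds,
)
from .survival import SurvivalData, km_estimate, mean_uncensored, restricted_mean

__all__ = [
    "ParameterPrior",
    "MorrisDesign",
    "MorrisResult",
    "build_priors",
    "sample_trajectories",
    "compute_mu_star",
    "run_morris",
]

_EDGE = 1e-9  # nudge away from open bounds
_QLO, _QHI = 0.01, 0.99  # percentile clipping for unbounded priors


@dataclass(frozen=True)
class ParameterPrior:
    """Sampling prior of one tunable parameter.

    ``kind`` is ``"uniform"`` (bounds ``lo``/``hi``) or ``"truncnorm"``
    (mean ``m_e``, variance ``2 m_e``, truncated to [``lo``, ``hi``]).
    """

    name: str
    kind: Literal["uniform", "truncnorm"]
    lo: float
    hi: float
    m_e: float = 0.0

    def quantile(self, u: float | np.ndarray) -> float | np.ndarray:
        """Map unit-interval coordinates to parameter values."""
        u = np.clip(u, 0.0, 1.0)
        if self.kind == "uniform":
            value = self.lo + (self.hi - self.lo) * u
        else:
            if self.m_e <= 0:
                return np.full_like(np.asarray(u, dtype=float), self.m_e)
            sd = np.sqrt(2.0 * self.m_e)
            a = (self.lo - self.m_e) / sd
            b = (self.hi - self.m_e) / sd if np.isfinite(self.hi) else np.inf
            # finite working range even for half-open supports
            uq = _QLO + (_QHI - _QLO) * u
            value = stats.truncnorm.ppf(uq, a, b, loc=self.m_e, scale=sd)
        return np.clip(value, self.lo, np.inf if not np.isfinite(self.hi) else self.hi)


@dataclass(frozen=True)
class MorrisDesign:
    """r trajectories of k+1 points each in the unit hypercube.

    Consecutive points within a trajectory differ in exactly one coordinate
    by +-``delta``.
    """

    points: np.ndarray  # shape (r, k+1, k)
    names: tuple[str, ...]
    levels: int
    delta: float

    @property
    def r(self) -> int:
        return self.points.shape[0]

    @property
    def k(self) -> int:
        return self.points.shape[2]


@dataclass(frozen=True)
class MorrisResult:
    """Per-parameter mu* (mean |elementary effect|) and sigma."""

    names: tuple[str, ...]
    mu_star: np.ndarray
    sigma: np.ndarray
    r: int
    n_patients_per_eval: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "mu_star": self.mu_star,
                "sigma": self.sigma,
                "r": self.r,
                "n_patients_per_eval": self.n_patients_per_eval,
            }
        )

    def ranking(self) -> list[str]:
        """Parameter names sorted by decreasing mu*."""
        order = np.argsort(-self.mu_star, kind="stable")
        return [self.names[i] for i in order]


def build_priors(
    params: ModelParameters,
    registry: Sequence[str] = SENSITIVITY_PARAMETERS,
) -> list[ParameterPrior]:
    """Priors for every registry parameter, anchored at the current values.

    Phenotype parameters (the mutation and mesenchymal effect sizes,
    effector efficacies and the EMT threshold) have no literature anchor
    and get uniform [0, 1] priors; all remaining parameters get the
    truncated normal N(m_e, 2 m_e) centered on their current (anchored)
    value.
    """
    priors = []
    for name in registry:
        lo, hi = parameter_bounds(name)
        if lo is None:
            raise ValueError(f"parameter {name!r} has no lower bound")
        if name in UNIFORM_PRIOR_PARAMETERS:
            if hi is None:
                raise ValueError(
                    f"uniform prior requires a bounded range for {name!r}"
                )
            priors.append(
                ParameterPrior(
                    name, "uniform", lo + _EDGE, hi - _EDGE
                )
            )
        else:
            m_e = float(getattr(params, name))
            priors.append(
                ParameterPrior(
                    name,
                    "truncnorm",
                    max(lo, _EDGE) if name in ("k_0", "k_1", "k_2", "k_4", "k_tau", "t_mes", "cycle_hours") else float(lo),
                    np.inf if hi is None else float(hi),
                    m_e=m_e,
                )
            )
    return priors


def sample_trajectories(
    priors: Sequence[ParameterPrior],
    r: int = 30,
    levels: int = 4,
    rng: np.random.Generator | None = None,
) -> MorrisDesign:
    """Standard Morris trajectory design on the unit hypercube.

    Step size ``delta = levels / (2 (levels - 1))``.  Each trajectory picks
    a random grid base point, a random step direction per coordinate, and a
    random coordinate order; every consecutive pair of points differs in
    exactly one coordinate by +-delta.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if levels < 2 or levels % 2:
        raise ValueError("levels must be an even integer >= 2")
    if rng is None:
        rng = np.random.default_rng()
    k = len(priors)
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(levels // 2) / (levels - 1)  # values with v + delta <= 1

    points = np.empty((r, k + 1, k), dtype=float)
    for t in range(r):
        low = grid[rng.integers(grid.size, size=k)]
        sign = rng.integers(2, size=k) * 2 - 1  # +-1: step direction
        start = np.where(sign > 0, low, low + delta)
        order = rng.permutation(k)
        x = start.copy()
        points[t, 0] = x
        for j, coord in enumerate(order):
            x = x.copy()
            x[coord] += sign[coord] * delta
            points[t, j + 1] = x
    return MorrisDesign(
        points=points,
        names=tuple(p.name for p in priors),
        levels=levels,
        delta=delta,
    )


def compute_mu_star(design: MorrisDesign, outputs: np.ndarray) -> MorrisResult:
    """Aggregate elementary effects into mu* and sigma per parameter.

    ``outputs`` has shape (r, k+1): one model output per design point.
    The elementary effect of the step at which coordinate *i* moved by
    ``s * delta`` is ``(y_after - y_before) / (s * delta)`` in normalized
    units.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape != design.points.shape[:2]:
        raise ValueError(
            f"outputs shape {outputs.shape} does not match design "
            f"{design.points.shape[:2]}"
        )
    k = design.k
    effects: list[list[float]] = [[] for _ in range(k)]
    for t in range(design.r):
        dx = np.diff(design.points[t], axis=0)  # (k, k)
        dy = np.diff(outputs[t])
        for j in range(k):
            coord = int(np.argmax(np.abs(dx[j])))
            step = dx[j, coord]
            effects[coord].append(dy[j] / step)
    mu_star = np.array([np.mean(np.abs(e)) for e in effects])
    sigma = np.array(
        [np.std(e, ddof=1) if len(e) > 1 else 0.0 for e in effects]
    )
    return MorrisResult(
        names=design.names, mu_star=mu_star, sigma=sigma, r=design.r
    )


def _apply_point(
    params: ModelParameters,
    priors: Sequence[ParameterPrior],
    point: np.ndarray,
) -> ModelParameters:
    changes = {}
    for prior, u in zip(priors, point):
        value = float(prior.quantile(float(u)))
        if is_integer_parameter(prior.name):
            value = max(1, int(round(value)))
        changes[prior.name] = value
    return params.replace(**changes)


def run_morris(
    params: ModelParameters,
    scheme: InflammationScheme,
    priors: Sequence[ParameterPrior],
    r: int = 30,
    n_patients_per_eval: int = 1000,
    master_seed: int = 0,
    levels: int = 4,
    output: Literal["rmst", "mean_uncensored"] = "rmst",
) -> MorrisResult:
    """Morris analysis of the simulator over the given priors.

    Each design point is mapped through the prior quantiles, a cohort of
    ``n_patients_per_eval`` patients is simulated (same master seed at
    every point: common random numbers), and the restricted mean
    invasion-free survival (horizon ``max_cycles``, in cycles) is the
    analysed output.
    """
    design_rng = np.random.default_rng(
        np.random.SeedSequence([master_seed, 0x4D5253])
    )
    design = sample_trajectories(priors, r=r, levels=levels, rng=design_rng)
    outputs = np.empty(design.points.shape[:2])
    for t in range(design.r):
        for j in range(design.k + 1):
            pt_params = _apply_point(params, priors, design.points[t, j])
            pt_scheme = InflammationScheme(
                mode=scheme.mode,
                ihd=pt_params.ihd,
                ild=pt_params.ild,
                start_state=scheme.start_state,
            )
            cohort = simulate_cohort(
                pt_params, pt_scheme, n_patients_per_eval, master_seed
            )
            data = SurvivalData(cohort.times(), cohort.events())
            if output == "rmst":
                outputs[t, j] = restricted_mean(
                    km_estimate(data), pt_params.max_cycles
                )
            else:
                outputs[t, j] = mean_uncensored(data)
    result = compute_mu_star(design, outputs)
    return MorrisResult(
        names=result.names,
        mu_star=result.mu_star,
        sigma=result.sigma,
        r=result.r,
        n_patients_per_eval=n_patients_per_eval,
    )
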