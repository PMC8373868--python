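"""Continuous immune dynamics, TGF-beta, and inflammation scheduling.

NK cells follow constant recruitment with linear death; CTL and Treg
recruitment is forced by the number of mutant tumor cells cleared by the
immune system in the current cycle (antigen stimulation), with Treg
recruitment further modulated by a saturating function of TGF-beta.
TGF-beta itself is algebraic: produced by mutant tumor cells and Tregs.

Within one cell cycle the forcing terms are frozen at their cycle-start
values, so each population obeys a linear ODE ``N' = a - d N`` with the
exact one-cycle solution ``N(1) = a/d + (N0 - a/d) exp(-d)``; no numerical
integrator (and no hidden tolerance) is involved.

Inflammation is an exogenous deterministic schedule of LOW/HIGH states;
the CTL and Treg recruitment coefficients are the only state-paired
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .parameters import ModelParameters

__all__ = [
    "ImmuneState",
    "InflammationState",
    "InflammationMode",
    "InflammationScheme",
    "ClearanceTally",
    "inflammation_state",
    "resolve_params",
    "compute_tgfb",
    "linear_ode_step",
    "step_immune",
    "apply_deactivation",
]


class InflammationState(Enum):
    LOW = "low"
    HIGH = "high"


class InflammationMode(Enum):
    CONSTANT_LOW = "constant_low"
    CONSTANT_HIGH = "constant_high"
    CYCLING = "cycling"


@dataclass(frozen=True)
class InflammationScheme:
    """Deterministic LOW/HIGH inflammation schedule.

    In CYCLING mode the schedule alternates blocks of ``ild`` LOW cycles
    and ``ihd`` HIGH cycles, beginning with ``start_state``, with the
    half-open convention [block start, block start + duration).
    """

    mode: InflammationMode = InflammationMode.CYCLING
    ihd: int = 50
    ild: int = 100
    start_state: InflammationState = InflammationState.LOW

    def __post_init__(self) -> None:
        if self.mode is InflammationMode.CYCLING:
            if self.ihd < 1 or self.ild < 1:
                raise ValueError("cycling scheme requires ihd >= 1 and ild >= 1")

    @classmethod
    def constant(cls, state: InflammationState) -> "InflammationScheme":
        mode = (
            InflammationMode.CONSTANT_LOW
            if state is InflammationState.LOW
            else InflammationMode.CONSTANT_HIGH
        )
        return cls(mode=mode)

    @classmethod
    def from_params(cls, params: ModelParameters,
                    mode: InflammationMode = InflammationMode.CYCLING,
                    start_state: InflammationState = InflammationState.LOW,
                    ) -> "InflammationScheme":
        return cls(mode=mode, ihd=params.ihd, ild=params.ild,
                   start_state=start_state)


@dataclass(frozen=True)
class ImmuneState:
    """Continuous NK/CTL/Treg population sizes and TGF-beta concentration."""

    n_nk: float = 0.0
    n_ctl: float = 0.0
    n_treg: float = 0.0
    tgfb: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_nk, self.n_ctl, self.n_treg, self.tgfb) < 0:
            raise ValueError("immune populations and TGF-beta must be >= 0")


@dataclass(frozen=True)
class ClearanceTally:
    """Immune clearances of the current cycle (forcing for recruitment)."""

    cleared_by_nk: int = 0
    cleared_by_ctl: int = 0
    cleared_mutant: int = 0

    def __post_init__(self) -> None:
        if min(self.cleared_by_nk, self.cleared_by_ctl, self.cleared_mutant) < 0:
            raise ValueError("clearance counts must be >= 0")
        if self.cleared_mutant > self.cleared_by_nk + self.cleared_by_ctl:
            raise ValueError(
                "cleared_mutant cannot exceed total immune clearances"
            )


def inflammation_state(
    cycle_index: int, scheme: InflammationScheme
) -> InflammationState:
    """Inflammation state at a post-warmup cycle index (0-based)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if scheme.mode is InflammationMode.CONSTANT_LOW:
        return InflammationState.LOW
    if scheme.mode is InflammationMode.CONSTANT_HIGH:
        return InflammationState.HIGH
    period = scheme.ihd + scheme.ild
    phase = cycle_index % period
    if scheme.start_state is InflammationState.LOW:
        return (
            InflammationState.LOW
            if phase < scheme.ild
            else InflammationState.HIGH
        )
    return (
        InflammationState.HIGH if phase < scheme.ihd else InflammationState.LOW
    )


def resolve_params(
    state: InflammationState, params: ModelParameters
) -> tuple[float, float]:
    """Effective (sigma_ctl, sigma_treg) for the given inflammation state."""
    if state is InflammationState.LOW:
        return params.sigma_ctl_low, params.sigma_treg_low
    return params.sigma_ctl_high, params.sigma_treg_high


def compute_tgfb(
    n_mut: int, immune: ImmuneState, params: ModelParameters
) -> float:
    """TGF-beta produced by mutant tumor cells and Tregs (algebraic)."""
    if n_mut < 0:
        raise ValueError("mutant count must be >= 0")
    return params.tau_mut * n_mut + params.tau_treg * immune.n_treg


def linear_ode_step(n0: float, a: float, d: float) -> float:
    """Exact one-cycle solution of ``N' = a - d N`` from ``N(0) = n0``.

    ``N(1) = a/d + (n0 - a/d) exp(-d)``; requires ``d > 0``.
    """
    if d <= 0:
        raise ValueError("death rate must be > 0")
    eq = a / d
    return eq + (n0 - eq) * math.exp(-d)


def step_immune(
    immune: ImmuneState,
    tally: ClearanceTally,
    tau: float,
    state: InflammationState,
    params: ModelParameters,
    n_mut_star: int | None = None,
) -> ImmuneState:
    """Advance NK/CTL/Treg one cell cycle with frozen forcing.

    ``n_mut_star`` (immune-cleared mutant cells forcing recruitment)
    defaults to the tally's current-cycle count; the engine passes the
    cumulative count instead when configured.  TGF-beta is *not* updated
    here — it is recomputed algebraically after the populations move.
    """
    if tau < 0:
        raise ValueError("TGF-beta concentration must be >= 0")
    if n_mut_star is None:
        n_mut_star = tally.cleared_mutant
    sigma_ctl, sigma_treg = resolve_params(state, params)

    a_nk = params.sigma_nk
    a_ctl = sigma_ctl * n_mut_star
    a_treg = sigma_treg * n_mut_star * tau / (1.0 + tau / params.k_4)

    return ImmuneState(
        n_nk=max(0.0, linear_ode_step(immune.n_nk, a_nk, params.d_nk)),
        n_ctl=max(0.0, linear_ode_step(immune.n_ctl, a_ctl, params.d_ctl)),
        n_treg=max(0.0, linear_ode_step(immune.n_treg, a_treg, params.d_treg)),
        tgfb=immune.tgfb,
    )


def apply_deactivation(
    immune: ImmuneState, tally: ClearanceTally, params: ModelParameters
) -> ImmuneState:
    """Remove exhausted effectors: a fixed number per successful clearance.

    Applied before the population ODE step each cycle; floored at zero.
    """
    return replace(
        immune,
        n_nk=max(
            0.0,
            immune.n_nk
            - params.deactivation_per_kill_nk * tally.cleared_by_nk,
        ),
        n_ctl=max(
            0.0,
            immune.n_ctl
            - params.deactivation_per_kill_ctl * tally.cleared_by_ctl,
        ),
    )
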