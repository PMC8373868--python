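"""Model parameters and the sensitivity-tunable registry.

The simulator couples discrete tumor-cell agents to continuous immune
populations (NK, CTL, Treg) and a TGF-beta field.  All rate constants,
phenotype effect sizes, saturation constants and run-control settings live
in :class:`ModelParameters`; the 31 biologically tunable entries among them
form :data:`SENSITIVITY_PARAMETERS`, the registry swept by the Morris
sensitivity analysis.

Tumor size is scaled so that carrying capacity is of order 1e2 cells
(a 1e9-cell tumor rescaled); all population parameters are on that scale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterator


class ParameterError(ValueError):
    """A parameter value violates its documented range."""


# name -> (lower, upper, lower_open, integer)
# Closed bounds unless *lower_open*; None means unbounded on that side.
_BOUNDS: dict[str, tuple[float | None, float | None, bool, bool]] = {
    "p": (0.0, 1.0, False, False),
    "d_c": (0.0, 1.0, False, False),
    "delta_p": (0.0, 1.0, False, False),
    "delta_a": (0.0, 1.0, False, False),
    "delta_ie": (0.0, 1.0, False, False),
    "delta_mga": (0.0, 1.0, False, False),
    "delta_mie": (0.0, 1.0, False, False),
    "k_0": (0.0, None, True, False),
    "k_1": (0.0, None, True, False),
    "k_2": (0.0, None, True, False),
    "k_4": (0.0, None, True, False),
    "e_nk": (0.0, 1.0, False, False),
    "e_ctl": (0.0, 1.0, False, False),
    "sigma_nk": (0.0, None, False, False),
    "d_nk": (0.0, None, False, False),
    "sigma_ctl_low": (0.0, None, False, False),
    "sigma_ctl_high": (0.0, None, False, False),
    "d_ctl": (0.0, None, False, False),
    "sigma_treg_low": (0.0, None, False, False),
    "sigma_treg_high": (0.0, None, False, False),
    "d_treg": (0.0, None, False, False),
    "tau_mut": (0.0, None, False, False),
    "tau_treg": (0.0, None, False, False),
    "t_mes": (0.0, 1.0, True, False),
    "emt_gain": (0.0, None, False, False),
    "emt_decay": (0.0, None, False, False),
    "k_tau": (0.0, None, True, False),
    "delta_mut_baseline": (0.0, 1.0, False, False),
    "ihd": (1, None, False, True),
    "ild": (1, None, False, True),
    "n_0": (1, None, False, True),
    "warmup_cycles": (1, None, False, True),
    "max_cycles": (1, None, False, True),
    "mut_increment": (0.0, 1.0, False, False),
    "cycle_hours": (0.0, None, True, False),
    "progression_threshold": (0.0, 1.0, True, False),
    "deactivation_per_kill_nk": (0.0, None, False, False),
    "deactivation_per_kill_ctl": (0.0, None, False, False),
}


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the tumor-immune-EMT model.

    Defaults are the shipped calibrated set: carrying capacity
    ``k_0 * (p/d_c - 1)`` of order 1e2 cells, a non-degenerate distribution
    of times to invasion inside the 2000-cycle horizon, survival decreasing
    in mesenchymal immune evasion, and an interior survival optimum in
    mesenchymal growth arrest under cycling inflammation.

    Parameters
    ----------
    p, d_c
        Baseline per-cycle probabilities of proliferation and apoptosis of
        an unmutated epithelial cell (before crowding).
    delta_p, delta_a, delta_ie
        Effect sizes of the proliferation / apoptosis / immune-evasion
        pathway mutations, each in [0, 1].
    delta_mga, delta_mie
        Mesenchymal growth arrest and mesenchymal immune evasion:
        proportional reduction of a mesenchymal cell's proliferation and
        immune-clearance probabilities. 1 = complete arrest / evasion.
    k_0
        Tumor crowding constant (cells); divides proliferation as
        ``1/(1 + N_C/k_0)``.
    k_1
        Effector-target saturation constant of immune clearance (cells).
    k_2
        Treg suppression constant (cells); divides effector efficacy as
        ``1/(1 + N_Treg/k_2)``.
    k_4
        TGF-beta saturation constant of Treg recruitment (concentration
        units).
    e_nk, e_ctl
        Maximal per-cycle clearance efficacies of NK cells and CTLs
        (``e_ctl > e_nk``: CTLs clear with greater efficiency).
    sigma_nk, d_nk
        Constant NK recruitment (cells/cycle) and per-cycle NK death rate.
    sigma_ctl_low, sigma_ctl_high, d_ctl
        CTL recruitment per immune-cleared mutant cell in the low / high
        inflammation state, and the per-cycle CTL death rate.
    sigma_treg_low, sigma_treg_high, d_treg
        Treg recruitment coefficients (per cleared mutant, modulated by
        TGF-beta) in the low / high inflammation state, and Treg death rate.
    tau_mut, tau_treg
        TGF-beta production per mutant tumor cell and per Treg.
    t_mes
        EMT-score threshold above which a cell is mesenchymal.
    emt_gain, emt_decay, k_tau
        EMT-score dynamics: per-cycle gain toward 1 under TGF-beta
        (half-saturation ``k_tau``) and per-cycle decay toward 0.
    delta_mut_baseline
        Immunogenicity of unmutated cells (0 = invisible to effectors;
        cells with at least one mutation have immunogenicity 1).
    ihd, ild
        Inflammation high / low durations of the cycling scheme (cycles).
    n_0
        Initial number of in-situ tumor cells.
    warmup_cycles, max_cycles
        Length of the pre-mutation warmup and the post-warmup censoring
        horizon (cycles).
    mut_increment
        Per-proliferation increment of the cell-autonomous mutation
        probability.
    cycle_hours
        Wall-clock length of one cell cycle (hours).
    progression_threshold
        Mutant fraction at or above which the tumor is invasive.
    deactivation_per_kill_nk, deactivation_per_kill_ctl
        Effector cells removed per successful tumor-cell clearance
        (exhaustion).
    cumulative_clearance
        If True, CTL/Treg recruitment is forced by the cumulative number of
        immune-cleared mutant cells instead of the count in the current
        cycle.
    """

    p: float = 0.75
    d_c: float = 0.25
    delta_p: float = 0.9
    delta_a: float = 0.9
    delta_ie: float = 0.9
    delta_mga: float = 0.2
    delta_mie: float = 0.5
    k_0: float = 150.0
    k_1: float = 100.0
    k_2: float = 15.0
    k_4: float = 2.0
    e_nk: float = 0.12
    e_ctl: float = 0.6
    sigma_nk: float = 4.0
    d_nk: float = 0.1
    sigma_ctl_low: float = 0.3
    sigma_ctl_high: float = 2.5
    d_ctl: float = 0.08
    sigma_treg_low: float = 0.5
    sigma_treg_high: float = 1.5
    d_treg: float = 0.05
    tau_mut: float = 0.05
    tau_treg: float = 0.1
    t_mes: float = 0.5
    emt_gain: float = 0.35
    emt_decay: float = 0.05
    k_tau: float = 0.5
    delta_mut_baseline: float = 0.0
    ihd: int = 50
    ild: int = 100
    n_0: int = 10
    warmup_cycles: int = 1000
    max_cycles: int = 2000
    mut_increment: float = 1e-4
    cycle_hours: float = 18.0
    progression_threshold: float = 0.5
    deactivation_per_kill_nk: float = 1.0
    deactivation_per_kill_ctl: float = 1.0
    cumulative_clearance: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every bounded field against its documented range."""
        for name, (lo, hi, lo_open, integer) in _BOUNDS.items():
            value = getattr(self, name)
            if integer and (not isinstance(value, (int,)) or isinstance(value, bool)):
                if float(value) != int(value):
                    raise ParameterError(f"{name} must be an integer, got {value!r}")
                object.__setattr__(self, name, int(value))
                value = int(value)
            if not math.isfinite(float(value)):
                raise ParameterError(f"{name} must be finite, got {value!r}")
            if lo is not None and (value < lo or (lo_open and value <= lo)):
                op = ">" if lo_open else ">="
                raise ParameterError(f"{name} must be {op} {lo}, got {value!r}")
            if hi is not None and value > hi:
                raise ParameterError(f"{name} must be <= {hi}, got {value!r}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (and re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


#: The 31 biologically tunable parameters swept by the Morris analysis.
#: Run-control settings (n_0, warmup/max cycles, mut_increment, cycle_hours,
#: progression threshold) and the structural delta_mut_baseline are fixed.
SENSITIVITY_PARAMETERS: tuple[str, ...] = (
    "p",
    "d_c",
    "delta_p",
    "delta_a",
    "delta_ie",
    "delta_mga",
    "delta_mie",
    "k_0",
    "k_1",
    "k_2",
    "k_4",
    "e_nk",
    "e_ctl",
    "sigma_nk",
    "d_nk",
    "sigma_ctl_low",
    "sigma_ctl_high",
    "d_ctl",
    "sigma_treg_low",
    "sigma_treg_high",
    "d_treg",
    "tau_mut",
    "tau_treg",
    "t_mes",
    "emt_gain",
    "emt_decay",
    "k_tau",
    "ihd",
    "ild",
    "deactivation_per_kill_nk",
    "deactivation_per_kill_ctl",
)

#: Registry parameters with no literature anchor; their sensitivity prior is
#: uniform on the full valid range [0, 1].
UNIFORM_PRIOR_PARAMETERS: frozenset[str] = frozenset(
    {
        "delta_p",
        "delta_a",
        "delta_ie",
        "delta_mga",
        "delta_mie",
        "e_nk",
        "e_ctl",
        "t_mes",
    }
)


def parameter_bounds(name: str) -> tuple[float | None, float | None]:
    """Valid (lower, upper) range of a parameter; None = unbounded."""
    if name not in _BOUNDS:
        raise KeyError(name)
    lo, hi, _, _ = _BOUNDS[name]
    return lo, hi


def is_integer_parameter(name: str) -> bool:
    return _BOUNDS[name][3]


def iter_sensitivity_parameters() -> Iterator[str]:
    return iter(SENSITIVITY_PARAMETERS)
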