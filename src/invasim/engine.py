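"""End-to-end simulation of one tumor and of in-silico patient cohorts.

One *patient* is one stochastic realization of the model: a warmup phase
(no mutations, innate NK immunity only) brings the tumor from ``n_0`` cells
to carrying capacity; the main phase then runs the full hybrid dynamics —
per-cell fate draws, mutation acquisition, effector exhaustion, the immune
ODE step, TGF-beta and EMT updates — until the mutant fraction reaches the
progression threshold (time to invasion, in post-warmup cycles) or the
censoring horizon ``max_cycles`` is hit.

Within a cycle the update is synchronous: all fates are drawn against the
cycle-start populations, then applied.  Mutation acquisition is applied to
the proliferating parent before duplication, so a daughter inherits the
full (possibly just-extended) mutational profile of its parent; daughters
start with mutation probability 0, are born epithelial (EMT score 0 — the
EMT state dilutes through division, which is what maintains phenotype
heterogeneity between fast-dividing clones and the resting bulk), and are
not exposed to fate decisions until the next cycle.

Randomness: each patient owns one ``numpy`` Generator.  Per cycle it draws,
in order, (1) one uniform per cell for the fate, (2) one uniform per
proliferating cell for mutation acceptance, (3) one integer per acquiring
cell for the pathway choice.  The warmup phase, where all cells are
exchangeable, draws a single multinomial per cycle.  Per-patient seeds are
derived from the cohort master seed via
``SeedSequence([master_seed, patient_index])``, so cohorts are reproducible
and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cells import CellPopulation, Fate, emt_score_step, fate_probability_matrix
from .immune import (
    ClearanceTally,
    ImmuneState,
    InflammationScheme,
    compute_tgfb,
    apply_deactivation,
    inflammation_state,
    linear_ode_step,
    step_immune,
)
from .parameters import ModelParameters

__all__ = [
    "TumorState",
    "PatientRecord",
    "CohortResult",
    "run_warmup",
    "step_cycle",
    "check_progression",
    "simulate_patient",
    "simulate_from_state",
    "simulate_cohort",
    "cycles_to_days",
    "patient_seed",
]

TRAJECTORY_COLUMNS = (
    "cycle",
    "n_tumor",
    "n_mutant",
    "n_mesenchymal",
    "n_nk",
    "n_ctl",
    "n_treg",
    "tgfb",
    "inflammation",
)


@dataclass
class TumorState:
    """Full mutable simulation state of one tumor."""

    pop: CellPopulation
    immune: ImmuneState
    scheme: InflammationScheme
    rng: np.random.Generator
    cycle_index: int = 0
    cumulative_cleared_mutant: int = 0
    extinct: bool = False

    @property
    def n_tumor(self) -> int:
        return len(self.pop)


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient outcome: time to invasion (cycles) with censor flag."""

    time_to_invasion: int
    censored: bool
    extinct: bool = False
    seed: int = 0
    trajectory: Optional[pd.DataFrame] = None


@dataclass(frozen=True)
class CohortResult:
    """A cohort of independent patient simulations under one parameter set."""

    patients: tuple[PatientRecord, ...]
    parameters: ModelParameters
    scheme: InflammationScheme
    master_seed: int

    def __len__(self) -> int:
        return len(self.patients)

    def times(self) -> np.ndarray:
        return np.array([p.time_to_invasion for p in self.patients])

    def events(self) -> np.ndarray:
        return np.array([not p.censored for p in self.patients])

    def censoring_fraction(self) -> float:
        return float(np.mean([p.censored for p in self.patients]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": np.arange(len(self.patients)),
                "seed": [p.seed for p in self.patients],
                "time_to_invasion_cycles": self.times(),
                "time_to_invasion_days": [
                    round(cycles_to_days(p.time_to_invasion, self.parameters))
                    for p in self.patients
                ],
                "censored": [p.censored for p in self.patients],
                "extinct": [p.extinct for p in self.patients],
            }
        )


def cycles_to_days(cycles: float, params: ModelParameters) -> float:
    """Convert cell cycles to days at ``cycle_hours`` per cycle."""
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    return cycles * params.cycle_hours / 24.0


def check_progression(state: TumorState, params: ModelParameters) -> bool:
    """True iff the mutant fraction has reached the progression threshold.

    An extinct tumor has not progressed (the extinction flag is carried on
    the state).
    """
    n = state.n_tumor
    if n == 0:
        state.extinct = True
        return False
    return state.pop.n_mutant() / n >= params.progression_threshold


def run_warmup(
    params: ModelParameters,
    rng: np.random.Generator,
    scheme: InflammationScheme | None = None,
    return_sizes: bool = False,
) -> TumorState | tuple[TumorState, np.ndarray]:
    """Grow the tumor to carrying capacity with mutations off, NK only.

    All cells are identical during warmup (unmutated, epithelial, zero
    TGF-beta), so fates are drawn as one multinomial per cycle.  NK cells
    start at their recruitment/death equilibrium ``sigma_nk/d_nk``; CTLs
    and Tregs are absent.  Extinction is flagged, not raised.

    With ``return_sizes`` the per-cycle tumor sizes are returned alongside
    the final state (for steady-state diagnostics).
    """
    if scheme is None:
        scheme = InflammationScheme.from_params(params)
    n = int(params.n_0)
    sizes = np.empty(params.warmup_cycles, dtype=int) if return_sizes else None
    n_nk = params.sigma_nk / params.d_nk if params.d_nk > 0 else 0.0
    base_clear = params.delta_mut_baseline
    for cycle in range(params.warmup_cycles):
        if n == 0:
            if sizes is not None:
                sizes[cycle:] = 0
            break
        rho_p = params.p / (1.0 + n / params.k_0)
        rho_a = params.d_c
        if base_clear > 0.0 and n_nk > 0.0:
            rho_nk = base_clear * (
                n_nk / (n / params.k_1 + n_nk) * params.e_nk
            )
        else:
            rho_nk = 0.0
        active = rho_p + rho_a + rho_nk
        if active > 1.0:
            rho_p, rho_a, rho_nk = (
                rho_p / active,
                rho_a / active,
                rho_nk / active,
            )
            active = 1.0
        counts = rng.multinomial(n, [rho_p, rho_a, rho_nk, 1.0 - active])
        n = n + int(counts[0]) - int(counts[1]) - int(counts[2])
        if params.d_nk > 0:
            n_nk = max(
                0.0, n_nk - params.deactivation_per_kill_nk * int(counts[2])
            )
            n_nk = linear_ode_step(n_nk, params.sigma_nk, params.d_nk)
        if sizes is not None:
            sizes[cycle] = n
    state = TumorState(
        pop=CellPopulation.naive(n),
        immune=ImmuneState(n_nk=n_nk),
        scheme=scheme,
        rng=rng,
        cycle_index=0,
        extinct=n == 0,
    )
    if return_sizes:
        return state, sizes
    return state


def step_cycle(
    state: TumorState, params: ModelParameters
) -> tuple[TumorState, ClearanceTally]:
    """Advance the full model one post-warmup cell cycle in place.

    Order per cycle: (1) synchronous fate assignment and application,
    (2) mutation machinery for proliferating cells (parents first, then
    daughter duplication), (3) effector exhaustion followed by the exact
    linear-ODE immune step with cycle-start forcing, (4) algebraic TGF-beta
    recomputation, (5) EMT-score and phenotype update for every cell.
    """
    pop = state.pop
    n = len(pop)
    infl = inflammation_state(state.cycle_index, state.scheme)
    if n == 0:
        state.extinct = True
        state.cycle_index += 1
        return state, ClearanceTally()
    immune = state.immune

    # (1) fates against cycle-start populations
    probs = fate_probability_matrix(
        pop, n, immune.n_nk, immune.n_ctl, immune.n_treg, params
    )
    cum = np.cumsum(probs, axis=1)
    u = state.rng.random(n)
    fates = np.minimum((u[:, None] >= cum).sum(axis=1), 4)

    prolif_idx = np.flatnonzero(fates == Fate.PROLIFERATE)
    cleared_nk = fates == Fate.CLEARED_BY_NK
    cleared_ctl = fates == Fate.CLEARED_BY_CTL
    cleared = cleared_nk | cleared_ctl
    mutated = pop.mutated
    tally = ClearanceTally(
        cleared_by_nk=int(np.count_nonzero(cleared_nk)),
        cleared_by_ctl=int(np.count_nonzero(cleared_ctl)),
        cleared_mutant=int(np.count_nonzero(cleared & mutated)),
    )

    # (2) mutation machinery on proliferating parents
    k = prolif_idx.size
    if k:
        accept = state.rng.random(k) < pop.mut_prob[prolif_idx]
        pop.mut_prob[prolif_idx[~accept]] += params.mut_increment
        acquirers = prolif_idx[accept]
        pop.mut_prob[acquirers] = 0.0
        for i in acquirers:
            open_paths = [
                arr
                for arr in (pop.prolif_mut, pop.apop_mut, pop.ie_mut)
                if not arr[i]
            ]
            if open_paths:
                open_paths[int(state.rng.integers(len(open_paths)))][i] = True

    survivors = pop.select(~((fates == Fate.APOPTOSE) | cleared))
    # daughters inherit the full mutational profile but are born epithelial:
    # the EMT state dilutes through division (score 0), and the mutation
    # ladder restarts (mut_prob 0)
    daughters = pop.select(prolif_idx)
    daughters.mut_prob[:] = 0.0
    daughters.emt_score[:] = 0.0
    daughters.mesenchymal[:] = False
    new_pop = CellPopulation.concatenate([survivors, daughters])

    # (3) exhaustion, then the exact ODE step with cycle-start forcing
    state.cumulative_cleared_mutant += tally.cleared_mutant
    n_mut_star = (
        state.cumulative_cleared_mutant
        if params.cumulative_clearance
        else tally.cleared_mutant
    )
    immune = apply_deactivation(immune, tally, params)
    immune = step_immune(
        immune, tally, state.immune.tgfb, infl, params, n_mut_star=n_mut_star
    )

    # (4) TGF-beta from post-update mutant and Treg numbers
    tgfb = compute_tgfb(new_pop.n_mutant(), immune, params)
    immune = replace(immune, tgfb=tgfb)

    # (5) EMT score and phenotype for every cell
    new_pop.emt_score = np.asarray(
        emt_score_step(new_pop.emt_score, tgfb, params), dtype=float
    )
    new_pop.mesenchymal = new_pop.emt_score > params.t_mes

    state.pop = new_pop
    state.immune = immune
    state.cycle_index += 1
    if len(new_pop) == 0:
        state.extinct = True
    return state, tally


def simulate_from_state(
    state: TumorState,
    params: ModelParameters,
    seed: int = 0,
    record_trajectory: bool = False,
) -> PatientRecord:
    """Run the post-warmup main loop from an arbitrary starting state."""
    rows: list[tuple] = []

    def snapshot() -> None:
        rows.append(
            (
                state.cycle_index,
                state.n_tumor,
                state.pop.n_mutant(),
                state.pop.n_mesenchymal(),
                state.immune.n_nk,
                state.immune.n_ctl,
                state.immune.n_treg,
                state.immune.tgfb,
                inflammation_state(
                    max(state.cycle_index - 1, 0), state.scheme
                ).value,
            )
        )

    def finish(time: int, censored: bool) -> PatientRecord:
        traj = (
            pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
            if record_trajectory
            else None
        )
        return PatientRecord(
            time_to_invasion=time,
            censored=censored,
            extinct=state.extinct,
            seed=seed,
            trajectory=traj,
        )

    if state.extinct or state.n_tumor == 0:
        state.extinct = True
        return finish(params.max_cycles, True)
    if check_progression(state, params):
        return finish(state.cycle_index, False)
    for t in range(state.cycle_index + 1, params.max_cycles + 1):
        step_cycle(state, params)
        if record_trajectory:
            snapshot()
        if state.extinct:
            return finish(params.max_cycles, True)
        if check_progression(state, params):
            return finish(t, False)
    return finish(params.max_cycles, True)


def simulate_patient(
    params: ModelParameters,
    scheme: InflammationScheme,
    seed: int,
    record_trajectory: bool = False,
) -> PatientRecord:
    """Warmup plus main loop for one patient; fully determined by the seed."""
    rng = np.random.default_rng(seed)
    state = run_warmup(params, rng, scheme)
    return simulate_from_state(
        state, params, seed=seed, record_trajectory=record_trajectory
    )


def patient_seed(master_seed: int, index: int) -> int:
    """Deterministic per-patient seed split of the cohort master seed."""
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(
            1, np.uint32
        )[0]
    )


def simulate_cohort(
    params: ModelParameters,
    scheme: InflammationScheme,
    n_patients: int,
    master_seed: int,
    record_trajectories: bool = False,
) -> CohortResult:
    """Simulate ``n_patients`` independent patients.

    Per-patient seeds depend only on ``(master_seed, patient_index)``, so
    the result is independent of execution order and two cohorts with the
    same master seed share their random-number streams patient-by-patient
    (common random numbers across parameter settings).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    records = tuple(
        simulate_patient(
            params,
            scheme,
            patient_seed(master_seed, i),
            record_trajectory=record_trajectories,
        )
        for i in range(n_patients)
    )
    return CohortResult(
        patients=records,
        parameters=params,
        scheme=scheme,
        master_seed=master_seed,
    )
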