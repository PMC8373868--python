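"""Tumor-cell agents: fate probabilities, mutation machinery, EMT score.

Each agent carries three monotone pathway-mutation flags (proliferation,
apoptosis, immune evasion), a continuous EMT score in [0, 1] with a derived
mesenchymal flag, and a cell-autonomous mutation probability that grows
linearly with consecutive non-mutating proliferations.

Per cycle a cell takes exactly one of five fates — proliferate, apoptose,
be cleared by an NK cell, be cleared by a CTL, or rest in G0 — drawn from
probabilities that depend on the cell's mutations and phenotype, tumor
crowding, and the current immune state.  Scalar operations work on a single
:class:`TumorCell`; the engine uses the vectorized
:func:`fate_probability_matrix` over a :class:`CellPopulation`
(struct-of-arrays), and the two paths are required to agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "Fate",
    "TumorCell",
    "FateProbabilities",
    "CellPopulation",
    "compute_fate_probabilities",
    "fate_probability_matrix",
    "draw_fate",
    "update_mutation_machinery",
    "choose_mutation_pathway",
    "update_emt_score",
    "emt_score_step",
]

_SUM_TOL = 1e-9


class Fate(IntEnum):
    """Mutually exclusive per-cycle cell fates."""

    PROLIFERATE = 0
    APOPTOSE = 1
    CLEARED_BY_NK = 2
    CLEARED_BY_CTL = 3
    REST = 4


@dataclass(frozen=True)
class TumorCell:
    """One tumor-cell agent.

    ``mut_prob`` equals (consecutive non-mutating proliferations since the
    last mutation or birth) x the per-proliferation increment; mutation
    flags never revert.
    """

    prolif_mut: bool = False
    apop_mut: bool = False
    ie_mut: bool = False
    emt_score: float = 0.0
    mesenchymal: bool = False
    mut_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.emt_score <= 1.0:
            raise ValueError(f"emt_score must be in [0,1], got {self.emt_score}")
        if self.mut_prob < 0.0:
            raise ValueError(f"mut_prob must be >= 0, got {self.mut_prob}")

    @property
    def mutated(self) -> bool:
        """True if the cell carries at least one pathway mutation."""
        return self.prolif_mut or self.apop_mut or self.ie_mut


@dataclass(frozen=True)
class FateProbabilities:
    """The five per-cycle fate probabilities of one cell (sum to 1)."""

    rho_p: float
    rho_a: float
    rho_nk: float
    rho_ctl: float
    rho_r: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rho_p, self.rho_a, self.rho_nk, self.rho_ctl, self.rho_r]
        )

    def validate(self, tol: float = _SUM_TOL) -> None:
        arr = self.as_array()
        if np.any(arr < -tol) or np.any(arr > 1 + tol):
            raise ValueError(f"fate probabilities outside [0,1]: {arr}")
        if abs(arr.sum() - 1.0) > tol:
            raise ValueError(f"fate probabilities sum to {arr.sum()}, not 1")


class CellPopulation:
    """Struct-of-arrays container for the tumor-cell agents of one tumor."""

    __slots__ = ("prolif_mut", "apop_mut", "ie_mut", "emt_score", "mut_prob",
                 "mesenchymal")

    def __init__(
        self,
        prolif_mut: np.ndarray,
        apop_mut: np.ndarray,
        ie_mut: np.ndarray,
        emt_score: np.ndarray,
        mesenchymal: np.ndarray,
        mut_prob: np.ndarray,
    ) -> None:
        self.prolif_mut = np.asarray(prolif_mut, dtype=bool)
        self.apop_mut = np.asarray(apop_mut, dtype=bool)
        self.ie_mut = np.asarray(ie_mut, dtype=bool)
        self.emt_score = np.asarray(emt_score, dtype=float)
        self.mesenchymal = np.asarray(mesenchymal, dtype=bool)
        self.mut_prob = np.asarray(mut_prob, dtype=float)

    @classmethod
    def naive(cls, n: int) -> "CellPopulation":
        """*n* unmutated epithelial cells with zero EMT score and mut_prob."""
        return cls(
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=float),
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=float),
        )

    @classmethod
    def from_cells(cls, cells: list[TumorCell]) -> "CellPopulation":
        return cls(
            np.array([c.prolif_mut for c in cells], dtype=bool),
            np.array([c.apop_mut for c in cells], dtype=bool),
            np.array([c.ie_mut for c in cells], dtype=bool),
            np.array([c.emt_score for c in cells], dtype=float),
            np.array([c.mesenchymal for c in cells], dtype=bool),
            np.array([c.mut_prob for c in cells], dtype=float),
        )

    def __len__(self) -> int:
        return self.prolif_mut.shape[0]

    def cell(self, i: int) -> TumorCell:
        return TumorCell(
            bool(self.prolif_mut[i]),
            bool(self.apop_mut[i]),
            bool(self.ie_mut[i]),
            float(self.emt_score[i]),
            bool(self.mesenchymal[i]),
            float(self.mut_prob[i]),
        )

    @property
    def mutated(self) -> np.ndarray:
        return self.prolif_mut | self.apop_mut | self.ie_mut

    def n_mutant(self) -> int:
        return int(np.count_nonzero(self.mutated))

    def n_mesenchymal(self) -> int:
        return int(np.count_nonzero(self.mesenchymal))

    def select(self, mask_or_index: np.ndarray) -> "CellPopulation":
        return CellPopulation(
            self.prolif_mut[mask_or_index],
            self.apop_mut[mask_or_index],
            self.ie_mut[mask_or_index],
            self.emt_score[mask_or_index],
            self.mesenchymal[mask_or_index],
            self.mut_prob[mask_or_index],
        )

    @staticmethod
    def concatenate(pops: list["CellPopulation"]) -> "CellPopulation":
        return CellPopulation(
            np.concatenate([p.prolif_mut for p in pops]),
            np.concatenate([p.apop_mut for p in pops]),
            np.concatenate([p.ie_mut for p in pops]),
            np.concatenate([p.emt_score for p in pops]),
            np.concatenate([p.mesenchymal for p in pops]),
            np.concatenate([p.mut_prob for p in pops]),
        )

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            self.prolif_mut.copy(),
            self.apop_mut.copy(),
            self.ie_mut.copy(),
            self.emt_score.copy(),
            self.mesenchymal.copy(),
            self.mut_prob.copy(),
        )


def _clearance_term(
    effector: float,
    efficacy: float,
    n_tumor: float,
    n_treg: float,
    params: ModelParameters,
) -> float:
    """Shared saturating form of NK/CTL clearance (zero if no effectors)."""
    if effector <= 0.0:
        return 0.0
    return (
        effector
        / (n_tumor / params.k_1 + effector)
        * (efficacy / (1.0 + n_treg / params.k_2))
    )


def fate_probability_matrix(
    pop: CellPopulation,
    n_tumor: int,
    n_nk: float,
    n_ctl: float,
    n_treg: float,
    params: ModelParameters,
) -> np.ndarray:
    """Per-cycle fate probabilities for every cell, shape ``(n, 5)``.

    Columns follow :class:`Fate` order.  Proliferation is suppressed by
    crowding (``1/(1+N_C/k_0)``) and by mesenchymal growth arrest; apoptosis
    is reduced by the apoptosis-pathway mutation; NK/CTL clearance is a
    saturating function of effector and tumor numbers, suppressed by Tregs,
    by the immune-evasion mutation and by the mesenchymal phenotype, and
    applies only to immunogenic cells.  Rest takes the complementary mass
    (with proportional rescaling in the parameter-pathological case where
    the four active fates exceed probability 1).
    """
    if n_tumor < 1:
        raise ValueError("n_tumor must be >= 1 (the cell itself counts)")
    if min(n_nk, n_ctl, n_treg) < 0:
        raise ValueError("immune populations must be non-negative")

    zeta = pop.mesenchymal.astype(float)
    crowding = 1.0 / (1.0 + n_tumor / params.k_0)

    rho_p = (
        params.p
        * (1.0 + pop.prolif_mut * params.delta_p)
        * (1.0 - zeta * params.delta_mga)
        * crowding
    )
    rho_a = params.d_c * (1.0 - pop.apop_mut * params.delta_a)

    delta_mut = np.where(pop.mutated, 1.0, params.delta_mut_baseline)
    evasion = (1.0 - pop.ie_mut * params.delta_ie) * (
        1.0 - zeta * params.delta_mie
    )
    nk_term = _clearance_term(n_nk, params.e_nk, n_tumor, n_treg, params)
    ctl_term = _clearance_term(n_ctl, params.e_ctl, n_tumor, n_treg, params)
    rho_nk = delta_mut * evasion * nk_term
    rho_ctl = delta_mut * evasion * ctl_term

    probs = np.empty((len(pop), 5), dtype=float)
    probs[:, Fate.PROLIFERATE] = rho_p
    probs[:, Fate.APOPTOSE] = rho_a
    probs[:, Fate.CLEARED_BY_NK] = rho_nk
    probs[:, Fate.CLEARED_BY_CTL] = rho_ctl
    active = probs[:, :4].sum(axis=1)
    over = active > 1.0
    if np.any(over):
        probs[over, :4] /= active[over, None]
        active = np.minimum(active, 1.0)
    probs[:, Fate.REST] = 1.0 - active
    return probs


def compute_fate_probabilities(
    cell: TumorCell,
    n_tumor: int,
    n_nk: float,
    n_ctl: float,
    n_treg: float,
    params: ModelParameters,
) -> FateProbabilities:
    """Fate probabilities of a single cell (scalar view of the matrix form)."""
    row = fate_probability_matrix(
        CellPopulation.from_cells([cell]), n_tumor, n_nk, n_ctl, n_treg, params
    )[0]
    return FateProbabilities(*map(float, row))


def draw_fate(probs: FateProbabilities, rng: np.random.Generator) -> Fate:
    """Draw one categorical fate; reproducible given the generator state."""
    probs.validate()
    arr = probs.as_array()
    cum = np.cumsum(arr)
    u = rng.random()
    return Fate(int(np.searchsorted(cum, u, side="right").clip(0, 4)))


def update_mutation_machinery(
    cell: TumorCell, params: ModelParameters, rng: np.random.Generator
) -> tuple[TumorCell, bool]:
    """Mutation step for a cell whose fate this cycle is proliferation.

    With probability ``mut_prob`` the cell gains one mutation (uniformly
    among its not-yet-mutated pathways) and its mutation probability resets
    to 0; otherwise the probability increases by ``params.mut_increment``.
    """
    if rng.random() < cell.mut_prob:
        mutated = choose_mutation_pathway(cell, rng)
        return replace(mutated, mut_prob=0.0), True
    return replace(cell, mut_prob=cell.mut_prob + params.mut_increment), False


def choose_mutation_pathway(
    cell: TumorCell, rng: np.random.Generator
) -> TumorCell:
    """Flip one currently-unmutated pathway flag, uniformly at random.

    A fully mutated cell is returned unchanged (saturated acquisition is a
    no-op, not an error).
    """
    open_paths = [
        name
        for name, flagged in (
            ("prolif_mut", cell.prolif_mut),
            ("apop_mut", cell.apop_mut),
            ("ie_mut", cell.ie_mut),
        )
        if not flagged
    ]
    if not open_paths:
        return cell
    chosen = open_paths[int(rng.integers(len(open_paths)))]
    return replace(cell, **{chosen: True})


def emt_score_step(
    score: np.ndarray | float, tgfb: float, params: ModelParameters
) -> np.ndarray | float:
    """One cycle of the EMT-score recurrence, clamped to [0, 1].

    score' = score + emt_gain * tgfb/(tgfb + k_tau) * (1 - score)
                   - emt_decay * score

    A saturating (Hill-type) TGF-beta activation pulls the score toward 1;
    a linear decay pulls it toward 0.  At constant TGF-beta the score
    converges to ``g / (g + emt_decay)`` with
    ``g = emt_gain * tgfb/(tgfb + k_tau)``.
    """
    if tgfb < 0:
        raise ValueError("TGF-beta concentration must be non-negative")
    gain = params.emt_gain * tgfb / (tgfb + params.k_tau) if tgfb > 0 else 0.0
    return np.clip(score + gain * (1.0 - score) - params.emt_decay * score, 0.0, 1.0)


def update_emt_score(
    cell: TumorCell, tgfb: float, params: ModelParameters
) -> TumorCell:
    """Advance a cell's EMT score one cycle and refresh its phenotype.

    The cell is mesenchymal iff the updated score is strictly above the
    threshold ``t_mes``.
    """
    new_score = float(emt_score_step(cell.emt_score, tgfb, params))
    return replace(
        cell, emt_score=new_score, mesenchymal=new_score > params.t_mes
    )
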