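"""Mutations, adenoma detection, and cytotoxic therapy scheduling.

Mutant cells carry multiplicative and additive modifiers of their positional
divide/die targets (for example x1.3 divide with x1.1 die for the adenoma
experiments, or +0.16 divide with +0.1 die for the tumor cells of the
therapy experiments).  The modifiers act on the target *before* feedback, so
mutants show the same delayed plasticity as normal cells, and they are
inherited by all progeny, which also inherit the founder's clone label.

Cytotoxicity follows the classic proliferation-dependence of chemotherapy
and radiation: during an active dose, a cell's extra per-tick kill
probability is its divide probability *at dose onset* (or at birth for
cells born mid-dose) times the dose ``lethality``.  Doses are scheduled as
fractionated courses (``interval`` > ``duration`` leaves recovery gaps) or
metronomic exposure (``interval`` == ``duration``, continuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .lattice import CryptState

__all__ = [
    "MutantPhenotype",
    "TherapyProtocol",
    "AdenomaCriterion",
    "MutationEvent",
    "TherapyCourse",
    "DoseContext",
    "introduce_mutant",
    "chemo_death_probability",
    "dose_active",
    "begin_dose_snapshot",
    "detect_adenoma",
    "resize_adjustment",
]


@dataclass(frozen=True)
class MutantPhenotype:
    """Modifiers applied to a mutant cell's positional targets."""

    divide_factor: float = 1.0
    divide_offset: float = 0.0
    die_factor: float = 1.0
    die_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.divide_factor <= 0 or self.die_factor <= 0:
            raise ValueError("phenotype factors must be > 0")

    @property
    def is_neutral(self) -> bool:
        return (
            self.divide_factor == 1.0
            and self.divide_offset == 0.0
            and self.die_factor == 1.0
            and self.die_offset == 0.0
        )


# Table-style phenotypes used across experiments
ADENOMA_PHENOTYPE = MutantPhenotype(divide_factor=1.3, die_factor=1.1)
TUMOR_PHENOTYPE = MutantPhenotype(divide_offset=0.16, die_offset=0.1)


@dataclass(frozen=True)
class TherapyProtocol:
    """Dose schedule: lethality, duration (ticks), start-to-start interval."""

    lethality: float = 2.0
    duration: int = 3
    interval: int = 24
    trigger_mutant_fraction: float = 0.5
    mode: str = "fractionated"
    max_doses: int | None = None

    def __post_init__(self) -> None:
        if self.lethality < 0:
            raise ValueError("lethality must be >= 0")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.mode not in ("fractionated", "metronomic"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.mode == "metronomic":
            if self.interval != self.duration:
                raise ValueError("metronomic dosing requires interval == duration")
        elif self.interval < self.duration:
            raise ValueError("fractionated dosing requires interval >= duration")
        if not (0.0 <= self.trigger_mutant_fraction <= 1.0):
            raise ValueError("trigger_mutant_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AdenomaCriterion:
    """A crypt is adenomatous once it holds 40% more cells than its baseline."""

    excess_fraction: float = 0.40
    baseline_total: int = 0

    def __post_init__(self) -> None:
        if self.excess_fraction <= 0:
            raise ValueError("excess_fraction must be > 0")


@dataclass(frozen=True)
class MutationEvent:
    """Schedule one mutant introduction during a run."""

    at_tick: int
    rows_from_top: int
    phenotype: MutantPhenotype


@dataclass(frozen=True)
class TherapyCourse:
    """Schedule a therapy course; starts at ``at_tick`` or at the tick the
    mutant fraction first reaches ``protocol.trigger_mutant_fraction``."""

    protocol: TherapyProtocol
    at_tick: int | None = None


@dataclass
class DoseContext:
    """Bookkeeping for the currently active dose (if any)."""

    active: bool = False
    lethality: float = 0.0
    doses_given: int = 0

    def begin(self, lethality: float) -> None:
        self.active = True
        self.lethality = lethality
        self.doses_given += 1

    def end(self) -> None:
        self.active = False
        self.lethality = 0.0


def introduce_mutant(
    state: CryptState,
    rows_from_top: int,
    phenotype: MutantPhenotype,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Turn one cell at the given row into a mutant with the given phenotype.

    The column is drawn uniformly among columns occupied at that row.  The
    cell keeps its clone label; the mutant flag and phenotype are inherited
    by all progeny.  Returns the (column, row) chosen.
    """
    candidates = np.flatnonzero(state.heights > rows_from_top)
    if rows_from_top < 0 or candidates.size == 0:
        raise ValueError(
            f"no living cell {rows_from_top} rows from the top (depth {state.depth()})"
        )
    col = int(rng.choice(candidates))
    state.fdat[K.F_DFAC, col, rows_from_top] = phenotype.divide_factor
    state.fdat[K.F_DOFF, col, rows_from_top] = phenotype.divide_offset
    state.fdat[K.F_KFAC, col, rows_from_top] = phenotype.die_factor
    state.fdat[K.F_KOFF, col, rows_from_top] = phenotype.die_offset
    state.idat[K.I_MUT, col, rows_from_top] = 0 if phenotype.is_neutral else 1
    return col, rows_from_top


def chemo_death_probability(divide_prob_snapshot: float, lethality: float) -> float:
    """Per-tick kill probability during a dose: ``min(1, snapshot * lethality)``."""
    if not (0.0 <= divide_prob_snapshot <= 1.0):
        raise ValueError("snapshot must be in [0, 1]")
    if lethality < 0:
        raise ValueError("lethality must be >= 0")
    return min(1.0, divide_prob_snapshot * lethality)


def dose_active(tick: int, therapy_start: int, protocol: TherapyProtocol) -> bool:
    """Whether a dose is being applied at ``tick``.

    Doses start at ``therapy_start`` and recur every ``interval`` ticks for
    ``duration`` ticks each, up to ``max_doses`` if set.  Metronomic
    protocols (interval == duration) are continuously active.
    """
    if tick < 0:
        raise ValueError("tick must be >= 0")
    if tick < therapy_start:
        return False
    phase = (tick - therapy_start) % protocol.interval
    if phase >= protocol.duration:
        return False
    if protocol.max_doses is not None:
        dose_index = (tick - therapy_start) // protocol.interval
        if dose_index >= protocol.max_doses:
            return False
    return True


def begin_dose_snapshot(state: CryptState) -> None:
    """Record every living cell's current divide probability at dose onset.

    The snapshot is what the chemotherapy kill probability uses for the
    whole dose; cells born during the dose use their birth-time divide
    probability (the kernel stamps it at birth).
    """
    state.fdat[K.F_SNAP] = state.fdat[K.F_DIVP]


def detect_adenoma(n_total: int, criterion: AdenomaCriterion) -> bool:
    """True once the crypt exceeds its baseline by the criterion's fraction."""
    if criterion.baseline_total <= 0:
        raise ValueError("baseline_total must be > 0")
    return n_total >= (1.0 + criterion.excess_fraction) * criterion.baseline_total


def resize_adjustment(
    n_total: int, cell_target: int, gain: float = 0.1, m_max: float = 2.0
) -> float:
    """Proportional controller multiplier on all divide targets.

    ``clip(1 + gain * (cell_target - n_total) / cell_target, 0, m_max)``;
    equals 1 when the crypt is at its target size.  Used to retarget the
    crypt to a different steady size (e.g. crypts of other organisms).
    """
    if cell_target <= 0:
        raise ValueError("cell_target must be > 0")
    m = 1.0 + gain * (cell_target - n_total) / cell_target
    return min(m_max, max(0.0, m))
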