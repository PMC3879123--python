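"""Simulation engine: configuration, the per-tick update, and reporters.

One time unit (tick, nominally 4.5 h) consists of a single randomized pass
over the cells alive at the start of the tick — each cell draws death with
its current die probability (chemotherapy-augmented while a dose is active)
and, if it survives, division with its current divide probability — followed
by a synchronous feedback update of every cell's probabilities toward its
positional targets.  Newborn cells are not visited in the tick of their
birth.

Because both event probabilities are determined by *relative* position in
the gradients, the crypt is near the critical point of a birth-death
process: the total count fluctuates about a quasi-stationary mean rather
than being pinned deterministically, which is what the biopsy calibration
data demand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .gradients import (
    CellType,
    FeedbackParams,
    GradientSpec,
    Orientation,
    classify_cell,
)
from .lattice import CryptState, init_crypt

__all__ = [
    "SimConfig",
    "TickReport",
    "RunResult",
    "seed_stream",
    "step",
    "run",
    "count_types",
    "is_monoclonal",
    "detect_extinction",
    "detect_unbounded",
]


@dataclass(frozen=True)
class SimConfig:
    """All interface parameters of the crypt model.

    Defaults are the calibrated values: gradient powers 11.5 (divide) and
    14 (die) with maxima 0.2 (the fastest cells cycle about once per day at
    a 4.5 h time unit), gradient spans that follow the crypt's mean column
    height, a quiescent niche anchored three rows above the 68-row resting
    depth, differentiation threshold 0.008 on the current divide
    probability, and gradient feedback strengths (0.1, 0.3, 0.5) for
    quiescent / proliferating / differentiated cells.  A 36 x 68 lattice
    starts at 2448 cells, matching the measured mean of 2427.8 cells per
    crypt.
    """

    cells_per_row: int = 36
    rows_at_start: int = 68
    divide_spec: GradientSpec = field(
        default_factory=lambda: GradientSpec(0.0, 0.2, 11.5, Orientation.BOTTOM_HIGH)
    )
    die_spec: GradientSpec = field(
        default_factory=lambda: GradientSpec(0.0, 0.2, 14.0, Orientation.TOP_HIGH)
    )
    quiesce_depth: int = 3
    niche_anchor: str = "absolute"  # or "moving": niche tracks the gradient span
    niche_band_rows: int = 0  # 0: the niche extends to all deeper rows
    diff_threshold: float = 0.008
    gradient_length_mode: str = "mean"
    die_gradient_length_mode: str = "mean"
    feedback: FeedbackParams = field(
        default_factory=lambda: FeedbackParams(0.1, 0.3, 0.5)
    )
    die_feedback_strength: float | None = None
    polar_division: bool = True
    resize_adjust: bool = False
    cell_target: int = 2428
    resize_gain: float = 0.1
    resize_max: float = 2.0
    unbounded_factor: float = 4.0
    time_unit_hours: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_row < 1 or self.rows_at_start < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.quiesce_depth < 0:
            raise ValueError(f"quiesce_depth must be >= 0, got {self.quiesce_depth}")
        if not (0.0 <= self.diff_threshold <= 1.0):
            raise ValueError(
                f"diff_threshold must be in [0, 1], got {self.diff_threshold}"
            )
        if not self.unbounded_factor > 1.0:
            raise ValueError(
                f"unbounded_factor must be > 1, got {self.unbounded_factor}"
            )
        if self.die_feedback_strength is not None and not (
            0.0 <= self.die_feedback_strength <= 1.0
        ):
            raise ValueError("die_feedback_strength must be in [0, 1] or None")
        for attr in ("gradient_length_mode", "die_gradient_length_mode"):
            if getattr(self, attr) not in ("mean", "column", "fixed", "max_depth"):
                raise ValueError(
                    f"{attr} must be 'mean', 'column', 'fixed' or "
                    f"'max_depth', got {getattr(self, attr)!r}"
                )

    @property
    def niche_row(self) -> int:
        """First row (from the top) of the stem-cell niche.

        The niche is anchored at absolute anatomical depth: every cell
        ``quiesce_depth`` or more rows below the crypt's resting length
        (``rows_at_start``) responds to the quiescent target instead of the
        divide gradient.  Because deeper cells all quiesce, the niche acts
        as the crypt's size regulator, with a response time set by the
        quiescent feedback strength.
        """
        return self.rows_at_start - self.quiesce_depth

    def in_niche(self, row_from_top: int) -> bool:
        """Whether a row lies inside the quiescent niche band."""
        if row_from_top < self.niche_row:
            return False
        if self.niche_band_rows > 0:
            return row_from_top < self.niche_row + self.niche_band_rows
        return True

    def gradient_span(self, state=None, column: int | None = None) -> float:
        """Divide-gradient span in rows: the crypt's mean column height in
        the default ``mean`` mode (the gradient length follows the total
        number of cells), a column's own height in ``column`` mode, the
        deepest column in ``max_depth`` mode, ``rows_at_start`` in ``fixed``
        mode."""
        if self.gradient_length_mode == "fixed" or state is None:
            return float(self.rows_at_start)
        if self.gradient_length_mode == "column" and column is not None:
            return max(1.0, float(state.heights[column]))
        if self.gradient_length_mode == "mean":
            return max(1.0, state.n_total / state.cells_per_row)
        return max(1.0, float(state.depth()))

    # -- config-file mapping (keys named after the model's interface) --
    _INTERFACE_KEYS = {
        "SetCellsPerRow": "cells_per_row",
        "RowsAtStart": "rows_at_start",
        "QuiesceDepth": "quiesce_depth",
        "DiffCellProbabilityThreshold": "diff_threshold",
        "PolarDivision": "polar_division",
        "ResizeCryptAdjust": "resize_adjust",
        "CellTarget": "cell_target",
        "ResizeGain": "resize_gain",
        "ResizeMaxMultiplier": "resize_max",
        "UnboundedFactor": "unbounded_factor",
        "TimeUnitHours": "time_unit_hours",
        "Seed": "seed",
        "DieFeedbackStrength": "die_feedback_strength",
        "GradientLengthMode": "gradient_length_mode",
        "DieGradientLengthMode": "die_gradient_length_mode",
        "QuiesceBandRows": "niche_band_rows",
    }

    def to_interface_dict(self) -> dict:
        d = {k: getattr(self, attr) for k, attr in self._INTERFACE_KEYS.items()}
        d.update(
            CptDivPwr=self.divide_spec.power,
            CryptDivideMax=self.divide_spec.maximum,
            CryptDivideMin=self.divide_spec.minimum,
            CryptDiePwr=self.die_spec.power,
            CryptDieMax=self.die_spec.maximum,
            CryptDieMin=self.die_spec.minimum,
            QuiescentFeedbackStrength=self.feedback.quiescent_strength,
            ProliferatingFeedbackStrength=self.feedback.proliferating_strength,
            DifferentiatedFeedbackStrength=self.feedback.differentiated_strength,
        )
        return d

    @classmethod
    def from_interface_dict(cls, mapping: dict) -> "SimConfig":
        base = cls()
        kwargs = {}
        mapping = dict(mapping)
        ds = base.divide_spec
        ks = base.die_spec
        ds = GradientSpec(
            mapping.pop("CryptDivideMin", ds.minimum),
            mapping.pop("CryptDivideMax", ds.maximum),
            mapping.pop("CptDivPwr", ds.power),
            Orientation.BOTTOM_HIGH,
        )
        ks = GradientSpec(
            mapping.pop("CryptDieMin", ks.minimum),
            mapping.pop("CryptDieMax", ks.maximum),
            mapping.pop("CryptDiePwr", ks.power),
            Orientation.TOP_HIGH,
        )
        fb = FeedbackParams(
            mapping.pop("QuiescentFeedbackStrength", base.feedback.quiescent_strength),
            mapping.pop(
                "ProliferatingFeedbackStrength", base.feedback.proliferating_strength
            ),
            mapping.pop(
                "DifferentiatedFeedbackStrength", base.feedback.differentiated_strength
            ),
        )
        for key, value in mapping.items():
            if key not in cls._INTERFACE_KEYS:
                raise KeyError(f"unknown interface parameter: {key}")
            kwargs[cls._INTERFACE_KEYS[key]] = value
        return cls(divide_spec=ds, die_spec=ks, feedback=fb, **kwargs)

    def with_updates(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TickReport:
    """End-of-tick counts emitted by the engine."""

    tick: int
    n_total: int
    n_quiescent: int
    n_proliferating: int
    n_differentiated: int
    n_mutant: int
    n_clones: int
    deaths_normal: int
    deaths_chemo: int
    deaths_chemo_healthy: int
    births: int

    @classmethod
    def from_buffer(cls, tick: int, out: np.ndarray) -> "TickReport":
        return cls(
            tick=tick,
            n_total=int(out[K.R_TOTAL]),
            n_quiescent=int(out[K.R_Q]),
            n_proliferating=int(out[K.R_P]),
            n_differentiated=int(out[K.R_D]),
            n_mutant=int(out[K.R_MUT]),
            n_clones=int(out[K.R_CLONES]),
            deaths_normal=int(out[K.R_DEATH]),
            deaths_chemo=int(out[K.R_CHEMO]),
            deaths_chemo_healthy=int(out[K.R_CHEMO_HEALTHY]),
            births=int(out[K.R_BIRTHS]),
        )


def seed_stream(seed: int) -> None:
    """Seed the kernel random stream (one stream per process)."""
    K.seed_rng(int(seed) % 2**31)


def _divide_multiplier(config: SimConfig, n_total: int) -> float:
    if not config.resize_adjust:
        return 1.0
    from .interventions import resize_adjustment

    return resize_adjustment(
        n_total, config.cell_target, config.resize_gain, config.resize_max
    )


def step(state: CryptState, config: SimConfig, dose=None) -> TickReport:
    """Advance ``state`` one time unit in place and return the tick report.

    ``dose`` is an active :class:`~cryptsim.interventions.DoseContext` (or
    None); while active, every visited cell draws an extra chemotherapy kill
    with probability ``min(1, snapshot_divide_prob * lethality)`` before its
    normal death draw.  The kernel random stream must have been seeded via
    :func:`seed_stream` (``run`` does this automatically).
    """
    state.ensure_capacity(state.depth() + state.n_total + 2)
    if state.initial_clone_count < 1:
        state.initial_clone_count = max(1, state.n_total)
    clone_seen = np.zeros(state.cells_per_row * state.row_capacity, np.uint8)
    out = np.zeros(K.NREP, np.int64)
    chemo_active = 1 if (dose is not None and dose.active and dose.lethality > 0) else 0
    lethality = float(dose.lethality) if chemo_active else 0.0
    status = K.step_kernel(
        state.heights,
        state.fdat,
        state.idat,
        clone_seen,
        config.divide_spec.minimum,
        config.divide_spec.maximum,
        config.divide_spec.power,
        config.die_spec.minimum,
        config.die_spec.maximum,
        config.die_spec.power,
        {"mean": -2, "column": -1, "max_depth": 0}.get(
            config.gradient_length_mode, config.rows_at_start
        ),
        {"mean": -2, "column": -1, "max_depth": 0}.get(
            config.die_gradient_length_mode, config.rows_at_start
        ),
        config.niche_row if config.niche_anchor == "absolute" else -int(config.quiesce_depth),
        int(config.niche_band_rows),
        float(config.diff_threshold),
        config.feedback.quiescent_strength,
        config.feedback.proliferating_strength,
        config.feedback.differentiated_strength,
        -1.0 if config.die_feedback_strength is None else config.die_feedback_strength,
        1 if config.polar_division else 0,
        chemo_active,
        lethality,
        _divide_multiplier(config, state.n_total),
        out,
    )
    if status != K.STATUS_OK:
        raise RuntimeError("lattice row capacity exceeded inside a tick")
    state.tick += 1
    return TickReport.from_buffer(state.tick, out)


@dataclass
class RunResult:
    """Reports, final state and run metadata from :func:`run`."""

    reports: pd.DataFrame
    state: CryptState
    config: SimConfig
    seed: int | None
    metadata: dict
    events: list

    def save(self, out_dir) -> None:
        """Write the time-series CSV, event-log CSV and metadata JSON."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reports.to_csv(out / "timeseries.csv", index=False)
        pd.DataFrame(self.events, columns=["tick", "event", "payload"]).to_csv(
            out / "events.csv", index=False
        )
        meta = dict(self.metadata)
        meta["seed"] = self.seed
        meta["config"] = {
            k: (v if not isinstance(v, (np.integer, np.floating)) else v.item())
            for k, v in self.config.to_interface_dict().items()
        }
        (out / "run.json").write_text(json.dumps(meta, indent=2, default=str))


def run(
    config: SimConfig,
    ticks: int,
    interventions=(),
    seed: int | None = None,
    state: CryptState | None = None,
    stop_when=None,
    collect: bool = True,
    initial_rows: int | None = None,
) -> RunResult:
    """Run the crypt for ``ticks`` time units with optional interventions.

    Parameters
    ----------
    config
        Simulation parameters.
    ticks
        Number of time units to simulate (the run may stop earlier if
        ``stop_when`` fires).
    interventions
        Iterable of :class:`~cryptsim.interventions.MutationEvent` and
        :class:`~cryptsim.interventions.TherapyCourse` objects.
    seed
        Seeds the kernel stream and the intervention RNG; defaults to
        ``config.seed``.  Pass ``seed=None`` together with an explicit
        ``state`` to continue an existing stream.
    state
        Continue from an existing crypt instead of a fresh one.
    stop_when
        Optional ``f(report) -> bool`` evaluated after every tick.

    The same (config, seed) pair always reproduces the same report sequence.
    """
    from .interventions import (
        DoseContext,
        MutationEvent,
        TherapyCourse,
        begin_dose_snapshot,
        dose_active,
        introduce_mutant,
    )

    if ticks < 0:
        raise ValueError(f"ticks must be >= 0, got {ticks}")
    if seed is None and state is None:
        seed = config.seed
    if seed is not None:
        ss = np.random.SeedSequence(int(seed))
        kernel_seed = int(ss.generate_state(1)[0] % 2**31)
        seed_stream(kernel_seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
    else:
        rng = np.random.default_rng(0)  # only used if interventions need it

    if state is None:
        state = init_crypt(config, initial_rows=initial_rows)
    initial_total = state.n_total if state.n_total else 1

    mutations = sorted(
        (iv for iv in interventions if isinstance(iv, MutationEvent)),
        key=lambda m: m.at_tick,
    )
    therapies = [iv for iv in interventions if isinstance(iv, TherapyCourse)]
    if len(therapies) > 1:
        raise ValueError("at most one therapy course per run")
    therapy = therapies[0] if therapies else None
    therapy_start: int | None = therapy.at_tick if therapy else None

    reports: list[TickReport] = []
    events: list[tuple] = []
    meta = {
        "extinction_time": None,
        "unbounded_time": None,
        "monoclonal_time": None,
        "cure_time": None,
        "end_tick": state.tick,
        "initial_total": initial_total,
    }
    dose = DoseContext()
    last_mutant_fraction = 0.0
    mi = 0

    for _ in range(ticks):
        now = state.tick
        while mi < len(mutations) and mutations[mi].at_tick <= now:
            m = mutations[mi]
            col, row = introduce_mutant(state, m.rows_from_top, m.phenotype, rng)
            events.append((now, "mutation", f"col={col},row={row}"))
            mi += 1
        if therapy is not None and therapy_start is None:
            if last_mutant_fraction >= therapy.protocol.trigger_mutant_fraction > 0:
                therapy_start = now
        if therapy is not None and therapy_start is not None:
            active = dose_active(now, therapy_start, therapy.protocol)
            if active and not dose.active:
                begin_dose_snapshot(state)
                dose.begin(therapy.protocol.lethality)
                events.append((now, "dose_start", f"lethality={therapy.protocol.lethality}"))
            elif not active and dose.active:
                dose.end()
                events.append((now, "dose_end", ""))

        rep = step(state, config, dose if dose.active else None)
        if collect:
            reports.append(rep)

        if rep.n_total:
            last_mutant_fraction = rep.n_mutant / rep.n_total
        else:
            last_mutant_fraction = 0.0
        if meta["extinction_time"] is None and rep.n_total == 0:
            meta["extinction_time"] = rep.tick
            events.append((rep.tick, "extinct", ""))
        if (
            meta["unbounded_time"] is None
            and rep.n_total >= config.unbounded_factor * initial_total
        ):
            meta["unbounded_time"] = rep.tick
            events.append((rep.tick, "unbounded", f"n={rep.n_total}"))
        if meta["monoclonal_time"] is None and rep.n_clones == 1 and rep.n_total > 0:
            meta["monoclonal_time"] = rep.tick
        if (
            meta["cure_time"] is None
            and therapy_start is not None
            and rep.tick > therapy_start
            and rep.n_mutant == 0
        ):
            meta["cure_time"] = rep.tick
            events.append((rep.tick, "cure", ""))
        if stop_when is not None and stop_when(rep):
            break

    meta["end_tick"] = state.tick
    meta["therapy_start"] = therapy_start
    frame = pd.DataFrame([dataclasses.asdict(r) for r in reports]) if collect else pd.DataFrame()
    return RunResult(
        reports=frame, state=state, config=config, seed=seed, metadata=meta, events=events
    )


def count_types(state: CryptState, config: SimConfig) -> tuple[int, int, int]:
    """(n_quiescent, n_proliferating, n_differentiated) for the current state.

    Vectorized re-derivation of the classification (independent of the tick
    kernel's own counting, which tests cross-check against this).
    """
    depth = state.depth()
    if depth == 0:
        return (0, 0, 0)
    n_q = n_p = n_d = 0
    for c in range(state.cells_per_row):
        h = int(state.heights[c])
        if h == 0:
            continue
        p = state.fdat[K.F_DIVP, c, :h]
        rows = np.arange(h)
        in_niche = rows >= config.niche_row
        if config.niche_band_rows > 0:
            in_niche &= rows < config.niche_row + config.niche_band_rows
        prolif = p >= config.diff_threshold
        quiesc = in_niche & ~prolif
        n_p += int(prolif.sum())
        n_q += int(quiesc.sum())
        n_d += int(h - prolif.sum() - quiesc.sum())
    return (n_q, n_p, n_d)


def is_monoclonal(state: CryptState) -> bool:
    """True iff exactly one founder label remains among living cells.

    An extinct crypt is not monoclonal.  Since no fresh labels are created
    after initialization, monoclonality is absorbing.
    """
    if state.n_total == 0:
        return False
    return state.clone_ids().size == 1


def detect_extinction(report: TickReport) -> bool:
    return report.n_total == 0


def detect_unbounded(
    report: TickReport, config: SimConfig, initial_total: int
) -> bool:
    """True once the population reaches ``unbounded_factor`` x the initial total."""
    return report.n_total >= config.unbounded_factor * initial_total
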