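"""Canned in-silico experiments and the parameter-sweep harness.

Each experiment orchestrates independent replicate runs with
well-separated seeds, mirroring the studies the calibrated crypt was built
for:

* :func:`calibration_experiment` — 49 crypts, 1000 time units each, started
  at different sizes; end-of-run cell-type counts compared to the biopsy
  reference by a chi-squared goodness-of-fit on the three type means.
* :func:`monoclonal_experiment` — neutral drift to monoclonality; records
  per-replicate conversion times and the winning founder.
* :func:`adenoma_experiment` — one mutant placed at a chosen row after
  burn-in; efficiency is the percent of replicates whose total count
  reaches 140% of the pre-mutation baseline.
* :func:`therapy_experiment` — tumor growth to a 50% mutant fraction, then
  fractionated chemotherapy; sweeps the dose duration at interval = 8x
  duration and reports time-to-cure and collateral damage.
* :func:`parameter_sweep` — generic Cartesian grid x replicates harness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import SimConfig, run
from .gradients import FeedbackParams, GradientSpec
from .interventions import (
    ADENOMA_PHENOTYPE,
    TUMOR_PHENOTYPE,
    AdenomaCriterion,
    MutantPhenotype,
    MutationEvent,
    TherapyCourse,
    TherapyProtocol,
    detect_adenoma,
    introduce_mutant,
)
from .reference import ReferenceStats, load_reference

__all__ = [
    "SweepSpec",
    "summary_stats",
    "replicate_seed",
    "calibration_experiment",
    "CalibrationResult",
    "monoclonal_experiment",
    "MonoclonalResult",
    "adenoma_experiment",
    "AdenomaResult",
    "therapy_experiment",
    "TherapyResult",
    "parameter_sweep",
]


def replicate_seed(base_seed: int, *keys: int) -> int:
    """Well-mixed, reproducible seed for replicate ``keys`` under ``base_seed``.

    Uses numpy's SeedSequence mixing so nearby base seeds and replicate
    indices give decorrelated streams; result fits in 31 bits.
    """
    ss = np.random.SeedSequence([int(base_seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % 2**31)


def summary_stats(values) -> tuple[float, float, float]:
    """(mean, sample SD, CV%) of a list of counts; requires n >= 2, mean != 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return mean, sd, 100.0 * sd / mean


# ---------------------------------------------------------------- calibration


@dataclass
class CalibrationResult:
    stats: pd.DataFrame  # per cell type and total: mean, sd, cv_pct
    counts: pd.DataFrame  # raw end-of-run counts per crypt
    chi2: float
    p_value: float
    reference: ReferenceStats

    def mean(self, cell_type: str) -> float:
        return float(self.stats.set_index("cell_type").loc[cell_type, "mean"])

    def cv_pct(self, cell_type: str) -> float:
        return float(self.stats.set_index("cell_type").loc[cell_type, "cv_pct"])


def chi_squared_fit(observed_means, simulated_means) -> tuple[float, float]:
    """Goodness of fit of observed type means to simulated expectations.

    ``chi2 = sum((obs - sim)^2 / sim)`` over the three cell-type categories,
    df = 2.  Zero iff the means coincide.  Categories with a zero simulated
    mean (possible in tiny demonstration crypts) are excluded, with the
    degrees of freedom reduced accordingly.
    """
    obs = np.asarray(observed_means, dtype=float)
    sim = np.asarray(simulated_means, dtype=float)
    if np.any(sim < 0):
        raise ValueError("simulated means must be nonnegative")
    keep = sim > 0
    if not keep.any():
        raise ValueError("all simulated means are zero")
    chi2 = float(np.sum((obs[keep] - sim[keep]) ** 2 / sim[keep]))
    return chi2, float(sps.chi2.sf(chi2, df=max(1, int(keep.sum()) - 1)))


def calibration_experiment(
    config: SimConfig | None = None,
    n_crypts: int = 49,
    ticks: int = 1000,
    seed: int = 0,
    rows_range: tuple[int, int] = (61, 75),
    reference: ReferenceStats | None = None,
) -> CalibrationResult:
    """Simulate ``n_crypts`` crypts, each initiated with a different size.

    Initial heights are drawn uniformly from ``rows_range`` (inclusive) —
    the crypts differ in starting size but share the same anatomy (gradient
    shape and niche depth) — each crypt runs ``ticks`` time units, and the
    end-of-run snapshot counts (one time point per crypt, like the biopsy)
    are summarized per type.
    """
    if n_crypts < 2:
        raise ValueError("n_crypts must be >= 2")
    config = config or SimConfig()
    reference = reference or load_reference()
    size_rng = np.random.default_rng(replicate_seed(seed, 977))
    rows = size_rng.integers(rows_range[0], rows_range[1] + 1, size=n_crypts)
    records = []
    for r in range(n_crypts):
        res = run(config, ticks, seed=replicate_seed(seed, r), initial_rows=int(rows[r]))
        last = res.reports.iloc[-1]
        records.append(
            {
                "crypt": r,
                "rows_at_start": int(rows[r]),
                "quiescent_stem": int(last.n_quiescent),
                "proliferating": int(last.n_proliferating),
                "differentiated": int(last.n_differentiated),
                "total": int(last.n_total),
            }
        )
    counts = pd.DataFrame(records)
    stat_rows = []
    for ct in ("quiescent_stem", "proliferating", "differentiated", "total"):
        vals = counts[ct].to_numpy(dtype=float)
        if vals.mean() == 0.0:  # tiny demo crypts can have empty classes
            mean, sd, cv = 0.0, float(vals.std(ddof=1)), float("nan")
        else:
            mean, sd, cv = summary_stats(vals)
        stat_rows.append({"cell_type": ct, "mean": mean, "sd": sd, "cv_pct": cv})
    stats_df = pd.DataFrame(stat_rows)
    obs = [reference.mean(ct) for ct in ("quiescent_stem", "proliferating", "differentiated")]
    sim = [s["mean"] for s in stat_rows[:3]]
    chi2, p = chi_squared_fit(obs, sim)
    return CalibrationResult(
        stats=stats_df, counts=counts, chi2=chi2, p_value=p, reference=reference
    )


# ----------------------------------------------------------------- monoclonal


@dataclass
class MonoclonalResult:
    times: list[int]  # conversion times of uncensored replicates
    winner_clones: list[int]
    n_censored: int
    mean: float
    sd: float


def monoclonal_experiment(
    config: SimConfig | None = None,
    n_reps: int = 30,
    max_ticks: int = 15000,
    seed: int = 0,
) -> MonoclonalResult:
    """Neutral-drift conversion times for ``n_reps`` independent crypts.

    Every cell starts as its own founder; a replicate converts at the first
    tick a single founder label remains.  Replicates that neither convert
    nor go extinct within ``max_ticks`` are censored and excluded from the
    moments (their count is reported).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or SimConfig()
    times: list[int] = []
    winners: list[int] = []
    censored = 0
    for r in range(n_reps):
        res = run(
            config,
            max_ticks,
            seed=replicate_seed(seed, r),
            stop_when=lambda rep: rep.n_clones <= 1,
        )
        t = res.metadata["monoclonal_time"]
        if t is None:
            censored += 1
            continue
        times.append(int(t))
        winners.append(int(res.state.clone_ids()[0]))
    if len(times) >= 2:
        mean, sd, _ = summary_stats(times)
    elif times:
        mean, sd = float(times[0]), float("nan")
    else:
        mean = sd = float("nan")
    return MonoclonalResult(
        times=times, winner_clones=winners, n_censored=censored, mean=mean, sd=sd
    )


# -------------------------------------------------------------------- adenoma


@dataclass
class AdenomaResult:
    rows_from_top: int
    n_reps: int
    n_adenoma: int
    efficiency_pct: float
    baseline_totals: list[float]
    adenoma_times: list[int]  # ticks from mutation to detection (successes)


def adenoma_experiment(
    config: SimConfig | None = None,
    rows_from_top: int = 59,
    phenotype: MutantPhenotype = ADENOMA_PHENOTYPE,
    n_reps: int = 40,
    horizon: int = 5000,
    burn_in: int = 200,
    seed: int = 0,
    excess_fraction: float = 0.40,
) -> AdenomaResult:
    """Adenoma-formation efficiency of one mutant at a given crypt row.

    Each replicate burns in to quasi-stationarity, records its baseline mean
    total (last 100 burn-in ticks), introduces one mutant cell at
    ``rows_from_top`` (uniformly random column), and then runs until the
    total reaches 140% of baseline (adenoma), the mutant lineage dies out,
    or ``horizon`` ticks elapse.
    """
    config = config or SimConfig()
    n_adenoma = 0
    baselines: list[float] = []
    times: list[int] = []
    for r in range(n_reps):
        s = replicate_seed(seed, r)
        res = run(config, burn_in, seed=s)
        tail = res.reports.tail(min(100, burn_in))
        baseline = float(tail.n_total.mean())
        baselines.append(baseline)
        criterion = AdenomaCriterion(excess_fraction, int(round(baseline)))
        rng = np.random.default_rng(replicate_seed(seed, r, 1))
        row = min(rows_from_top, res.state.depth() - 1)
        introduce_mutant(res.state, row, phenotype, rng)
        mutation_tick = res.state.tick
        seen_mutant = not phenotype.is_neutral  # neutral mutants are unflagged

        def stop(rep, criterion=criterion, seen=seen_mutant):
            if detect_adenoma(rep.n_total, criterion):
                return True
            if seen and rep.n_mutant == 0:
                return True  # lineage extinct; adenoma no longer reachable
            return False

        res2 = run(
            config,
            horizon,
            state=res.state,
            seed=replicate_seed(seed, r, 2),
            stop_when=stop,
        )
        if len(res2.reports) and detect_adenoma(
            int(res2.reports.iloc[-1].n_total), criterion
        ):
            n_adenoma += 1
            times.append(int(res2.reports.iloc[-1].tick) - mutation_tick)
    return AdenomaResult(
        rows_from_top=rows_from_top,
        n_reps=n_reps,
        n_adenoma=n_adenoma,
        efficiency_pct=100.0 * n_adenoma / n_reps,
        baseline_totals=baselines,
        adenoma_times=times,
    )


# -------------------------------------------------------------------- therapy


@dataclass
class TherapyResult:
    table: pd.DataFrame  # per duration: means of time-to-cure and collateral
    replicates: pd.DataFrame  # per (duration, rep) raw outcomes
    knee_duration: int | None


def find_knee(durations, mean_ttc, rel_tol: float = 0.15) -> int | None:
    """Smallest duration whose mean time-to-cure is within ``rel_tol`` of the
    best achieved at any duration (the plateau onset)."""
    m = np.asarray(mean_ttc, dtype=float)
    ok = np.isfinite(m)
    if not ok.any():
        return None
    best = np.nanmin(m)
    for d, v in zip(durations, m):
        if np.isfinite(v) and v <= best * (1.0 + rel_tol):
            return int(d)
    return None


def therapy_experiment(
    config: SimConfig | None = None,
    durations=(1, 2, 3, 4, 6, 8),
    lethality: float = 2.0,
    interval_factor: int = 8,
    phenotype: MutantPhenotype = TUMOR_PHENOTYPE,
    rows_from_top: int = 63,
    trigger_mutant_fraction: float = 0.5,
    n_reps: int = 20,
    burn_in: int = 100,
    max_ticks: int = 6000,
    seed: int = 0,
) -> TherapyResult:
    """Sweep the chemotherapy dose duration at interval = 8x duration.

    Each replicate grows a tumor clone (+0.16 divide, +0.1 die) from one
    cell in the lower proliferative region until mutants are half the crypt,
    then applies fractionated chemotherapy at the given lethality until no
    mutant remains.  Reports per-duration mean time-to-cure, cumulative
    healthy-cell chemotherapy deaths, and the minimum healthy-cell count
    during therapy.  Replicates whose tumor never reaches the trigger, or
    that are not cured within ``max_ticks``, are flagged.
    """
    if not durations:
        raise ValueError("durations must be nonempty")
    config = config or SimConfig()
    rows = []
    for d in durations:
        protocol = TherapyProtocol(
            lethality=lethality,
            duration=int(d),
            interval=int(interval_factor * d),
            trigger_mutant_fraction=trigger_mutant_fraction,
        )
        for r in range(n_reps):
            s = replicate_seed(seed, int(d), r)
            interventions = [
                MutationEvent(burn_in, rows_from_top, phenotype),
                TherapyCourse(protocol),
            ]
            state_seen = {"mutant_seen": False}
            cap = 5 * config.cells_per_row * config.rows_at_start

            def stop(rep, info=state_seen, cap=cap):
                if rep.n_total >= cap:
                    return True  # runaway tumor; flagged as uncured
                if rep.n_mutant > 0:
                    info["mutant_seen"] = True
                    return False
                return info["mutant_seen"]  # cure or lineage extinction

            res = run(config, max_ticks, interventions=interventions, seed=s, stop_when=stop)
            start = res.metadata["therapy_start"]
            cure = res.metadata["cure_time"]
            reports = res.reports
            if start is not None:
                during = reports[reports.tick > start]
                collateral_deaths = int(during.deaths_chemo_healthy.sum())
                min_healthy = int((during.n_total - during.n_mutant).min()) if len(during) else None
            else:
                collateral_deaths = 0
                min_healthy = None
            rows.append(
                {
                    "duration": int(d),
                    "rep": r,
                    "seed": s,
                    "triggered": start is not None,
                    "cured": cure is not None,
                    "time_to_cure": (cure - start) if (cure is not None and start is not None) else np.nan,
                    "collateral_chemo_deaths": collateral_deaths,
                    "min_healthy_cells": min_healthy,
                }
            )
    reps = pd.DataFrame(rows)
    agg = (
        reps[reps.triggered]
        .groupby("duration")
        .agg(
            n=("rep", "size"),
            n_cured=("cured", "sum"),
            mean_time_to_cure=("time_to_cure", "mean"),
            sd_time_to_cure=("time_to_cure", "std"),
            mean_collateral_deaths=("collateral_chemo_deaths", "mean"),
            mean_min_healthy=("min_healthy_cells", "mean"),
        )
        .reset_index()
    )
    knee = find_knee(agg.duration.tolist(), agg.mean_time_to_cure.tolist())
    return TherapyResult(table=agg, replicates=reps, knee_duration=knee)


# ---------------------------------------------------------------------- sweep


# interface parameter name -> how to apply it to a SimConfig
def _apply_param(config: SimConfig, name: str, value) -> SimConfig:
    simple = SimConfig._INTERFACE_KEYS
    if name in simple:
        return config.with_updates(**{simple[name]: value})
    ds, ks, fb = config.divide_spec, config.die_spec, config.feedback
    if name == "CptDivPwr":
        return config.with_updates(divide_spec=GradientSpec(ds.minimum, ds.maximum, value, ds.orientation))
    if name == "CryptDivideMax":
        return config.with_updates(divide_spec=GradientSpec(ds.minimum, value, ds.power, ds.orientation))
    if name == "CryptDivideMin":
        return config.with_updates(divide_spec=GradientSpec(value, ds.maximum, ds.power, ds.orientation))
    if name == "CryptDiePwr":
        return config.with_updates(die_spec=GradientSpec(ks.minimum, ks.maximum, value, ks.orientation))
    if name == "CryptDieMax":
        return config.with_updates(die_spec=GradientSpec(ks.minimum, value, ks.power, ks.orientation))
    if name == "CryptDieMin":
        return config.with_updates(die_spec=GradientSpec(value, ks.maximum, ks.power, ks.orientation))
    if name == "QuiescentFeedbackStrength":
        return config.with_updates(feedback=FeedbackParams(value, fb.proliferating_strength, fb.differentiated_strength))
    if name == "ProliferatingFeedbackStrength":
        return config.with_updates(feedback=FeedbackParams(fb.quiescent_strength, value, fb.differentiated_strength))
    if name == "DifferentiatedFeedbackStrength":
        return config.with_updates(feedback=FeedbackParams(fb.quiescent_strength, fb.proliferating_strength, value))
    raise KeyError(f"unknown sweep parameter: {name}")


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian parameter grid with replicates (behavior-space style)."""

    parameters: dict  # interface name -> list of values
    replicates: int = 1
    ticks: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.parameters or any(len(v) == 0 for v in self.parameters.values()):
            raise ValueError("parameter grid must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def parameter_sweep(spec: SweepSpec, base_config: SimConfig | None = None) -> pd.DataFrame:
    """Run the grid x replicates and return one row per run with end-of-run
    reporters and the seed used."""
    import itertools

    base_config = base_config or SimConfig()
    names = list(spec.parameters)
    for n in names:
        _apply_param(base_config, n, list(spec.parameters[n])[0])  # validate names
    rows = []
    for combo_idx, combo in enumerate(itertools.product(*(spec.parameters[n] for n in names))):
        cfg = base_config
        for n, v in zip(names, combo):
            cfg = _apply_param(cfg, n, v)
        for r in range(spec.replicates):
            s = replicate_seed(spec.seed, combo_idx, r)
            res = run(cfg, spec.ticks, seed=s)
            last = res.reports.iloc[-1]
            row = dict(zip(names, combo))
            row.update(
                rep=r,
                seed=s,
                ticks=spec.ticks,
                n_total=int(last.n_total),
                n_quiescent=int(last.n_quiescent),
                n_proliferating=int(last.n_proliferating),
                n_differentiated=int(last.n_differentiated),
                n_clones=int(last.n_clones),
                extinction_time=res.metadata["extinction_time"],
                unbounded_time=res.metadata["unbounded_time"],
            )
            rows.append(row)
    return pd.DataFrame(rows)
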