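"""Engine semantics: the randomized tick, reporters, and the enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cryptsim import _kernels as K
from cryptsim.engine import (
    SimConfig,
    count_types,
    detect_extinction,
    detect_unbounded,
    is_monoclonal,
    run,
    seed_stream,
    step,
)
from cryptsim.gradients import FeedbackParams, GradientSpec, Orientation
from cryptsim.lattice import init_crypt


def frozen_config(cols, rows, **kw):
    """Config whose cells never adapt (strength 0 everywhere), so current
    probabilities set by hand stay fixed."""
    kw.setdefault("feedback", FeedbackParams(0.0, 0.0, 0.0))
    kw.setdefault("die_feedback_strength", 0.0)
    return SimConfig(cells_per_row=cols, rows_at_start=rows, **kw)


def set_probs(state, divide, die):
    h = state.heights
    for c in range(state.cells_per_row):
        state.fdat[K.F_DIVP, c, : h[c]] = divide
        state.fdat[K.F_DIEP, c, : h[c]] = die


class TestStepBasics:
    def test_absorbing_when_all_probabilities_zero(self):
        cfg = frozen_config(4, 3)
        state = init_crypt(cfg)
        set_probs(state, 0.0, 0.0)
        seed_stream(1)
        before = state.to_dataframe()
        rep = step(state, cfg)
        assert state.tick == 1
        assert rep.n_total == 12
        pd.testing.assert_frame_equal(
            state.to_dataframe().drop(columns="tick"), before.drop(columns="tick")
        )

    def test_forced_division_doubles_total(self):
        cfg = frozen_config(4, 3)
        state = init_crypt(cfg)
        set_probs(state, 1.0, 0.0)
        seed_stream(2)
        rep = step(state, cfg)
        assert rep.n_total == 24
        assert rep.births == 12

    def test_forced_death_extinguishes(self):
        cfg = frozen_config(4, 3)
        state = init_crypt(cfg)
        set_probs(state, 0.0, 1.0)
        seed_stream(3)
        rep = step(state, cfg)
        assert rep.n_total == 0
        assert detect_extinction(rep)

    def test_report_partition(self):
        cfg = SimConfig(cells_per_row=10, rows_at_start=20)
        res = run(cfg, 50, seed=4)
        r = res.reports
        assert (
            (r.n_quiescent + r.n_proliferating + r.n_differentiated) == r.n_total
        ).all()

    def test_kernel_counts_match_count_types(self):
        cfg = SimConfig(cells_per_row=10, rows_at_start=20)
        state = init_crypt(cfg)
        seed_stream(5)
        for _ in range(30):
            rep = step(state, cfg)
        assert count_types(state, cfg) == (
            rep.n_quiescent,
            rep.n_proliferating,
            rep.n_differentiated,
        )


class TestRun:
    def test_zero_ticks(self):
        cfg = SimConfig(cells_per_row=4, rows_at_start=4)
        res = run(cfg, 0, seed=1)
        assert res.reports.empty
        assert res.state.n_total == 16

    def test_determinism_same_seed(self):
        cfg = SimConfig(cells_per_row=8, rows_at_start=12)
        a = run(cfg, 80, seed=42)
        b = run(cfg, 80, seed=42)
        pd.testing.assert_frame_equal(a.reports, b.reports)

    def test_different_seeds_differ(self):
        cfg = SimConfig(cells_per_row=8, rows_at_start=12)
        a = run(cfg, 80, seed=42)
        b = run(cfg, 80, seed=43)
        assert not a.reports.equals(b.reports)

    def test_clone_count_non_increasing_and_monoclonal_absorbing(self):
        cfg = SimConfig(cells_per_row=5, rows_at_start=6)
        res = run(cfg, 400, seed=9)
        clones = res.reports.n_clones[res.reports.n_total > 0]
        assert (clones.diff().dropna() <= 0).all()
        mono_ticks = res.reports.tick[
            (res.reports.n_clones == 1) & (res.reports.n_total > 0)
        ]
        if len(mono_ticks):
            first = mono_ticks.iloc[0]
            after = res.reports[res.reports.tick >= first]
            alive = after[after.n_total > 0]
            assert (alive.n_clones == 1).all()
            assert is_monoclonal(res.state) or res.state.n_total == 0

    def test_subcritical_config_decays(self):
        # no divisions possible and a floor on the die gradient
        cfg = SimConfig(
            cells_per_row=6,
            rows_at_start=10,
            divide_spec=GradientSpec(0, 0, 1, Orientation.BOTTOM_HIGH),
            die_spec=GradientSpec(0.05, 0.2, 14, Orientation.TOP_HIGH),
        )
        res = run(cfg, 400, seed=11)
        assert res.metadata["extinction_time"] is not None

    def test_unbounded_detector(self):
        rep_like = run(SimConfig(cells_per_row=4, rows_at_start=4), 1, seed=1)
        r = rep_like.reports.iloc[-1]
        cfg = SimConfig(cells_per_row=4, rows_at_start=4, unbounded_factor=4.0)
        from cryptsim.engine import TickReport

        big = TickReport(1, 64, 0, 0, 64, 0, 1, 0, 0, 0, 0)
        assert detect_unbounded(big, cfg, 16)
        small = TickReport(1, 63, 0, 0, 63, 0, 1, 0, 0, 0, 0)
        assert not detect_unbounded(small, cfg, 16)

    def test_criticality_direction(self):
        """A much shallower divide gradient pushes the crypt supercritical
        (sustained expansion well above its resting size); a much steeper
        one starves it (collapse).  The quiescent niche absorbs part of the
        surplus, so expansion saturates rather than diverging."""
        shallow = SimConfig(
            cells_per_row=8,
            rows_at_start=16,
            divide_spec=GradientSpec(0, 0.2, 2.0, Orientation.BOTTOM_HIGH),
        )
        res = run(shallow, 800, seed=13)
        tail = res.reports.n_total.tail(200).mean()
        assert tail > 1.3 * 8 * 16
        steep = SimConfig(
            cells_per_row=8,
            rows_at_start=16,
            divide_spec=GradientSpec(0, 0.2, 30.0, Orientation.BOTTOM_HIGH),
        )
        res2 = run(steep, 800, seed=13)
        assert res2.reports.n_total.tail(200).mean() < 0.85 * 8 * 16


# ---------------------------------------------------------------- the oracle


def _oracle_insert(cols, c0, r0, ident):
    """Independent pure-python cascade: new cell at (c0+1, r0+1), occupants
    displaced diagonally until one lands at the first empty bottom slot."""
    C = len(cols)
    c, r = c0, r0
    moving = ident
    while True:
        c = (c + 1) % C
        r += 1
        if r >= len(cols[c]):
            cols[c].append(moving)
            return
        cols[c][r], moving = moving, cols[c][r]


def _oracle_remove(cols, ident):
    for col in cols:
        if ident in col:
            col.remove(ident)  # list.remove == pull-up for top-anchored stacks
            return
    raise AssertionError("cell not found")


def _oracle_distribution(cols0, p, d):
    """Exact one-tick distribution of the total cell count, enumerating all
    visit orders and per-cell (die / divide / nothing) outcomes."""
    dist = {}
    initial = [ident for col in cols0 for ident in col]

    def recurse(cols, remaining, prob):
        if prob == 0.0:
            return
        if not remaining:
            tot = sum(len(col) for col in cols)
            dist[tot] = dist.get(tot, 0.0) + prob
            return
        n = len(remaining)
        for i, ident in enumerate(remaining):
            rest = remaining[:i] + remaining[i + 1 :]
            psel = prob / n
            # death
            cols_d = [list(col) for col in cols]
            _oracle_remove(cols_d, ident)
            recurse(cols_d, rest, psel * d)
            # survive & divide
            cols_b = [list(col) for col in cols]
            for c, col in enumerate(cols_b):
                if ident in col:
                    _oracle_insert(cols_b, c, col.index(ident), ("new", ident))
                    break
            recurse(cols_b, rest, psel * (1 - d) * p)
            # survive quietly
            recurse([list(col) for col in cols], rest, psel * (1 - d) * (1 - p))

    recurse([list(col) for col in cols0], initial, 1.0)
    return dist


class TestOneTickOracle:
    def test_total_count_distribution_matches_enumeration(self):
        """One-tick totals on a 2x2 crypt match exhaustive enumeration over
        all visit orders and event outcomes, within 3 SE at 20,000 samples."""
        p, d = 0.35, 0.25
        expected = _oracle_distribution([[0, 1], [2, 3]], p, d)
        assert sum(expected.values()) == pytest.approx(1.0)

        cfg = frozen_config(2, 2)
        template = init_crypt(cfg)
        set_probs(template, p, d)
        fdat0 = template.fdat.copy()
        idat0 = template.idat.copy()
        heights0 = template.heights.copy()

        n_samples = 20000
        seed_stream(2024)
        observed = {}
        for _ in range(n_samples):
            template.fdat[:] = fdat0
            template.idat[:] = idat0
            template.heights[:] = heights0
            template.tick = 0
            rep = step(template, cfg)
            observed[rep.n_total] = observed.get(rep.n_total, 0) + 1

        for tot, prob in expected.items():
            if prob < 1e-6:
                continue
            obs = observed.get(tot, 0) / n_samples
            se = max(np.sqrt(prob * (1 - prob) / n_samples), 1e-9)
            assert abs(obs - prob) <= 3 * se + 1e-9, (
                f"total={tot}: observed {obs:.4f}, expected {prob:.4f}"
            )
        # no mass observed outside the enumerated support
        assert set(observed) <= set(expected)


class TestNeutralDrift:
    def test_winner_column_uniform_on_flat_crypt(self):
        """With flat gradients and no niche every cell has identical rates;
        the winning founder's column must be uniform (chi-squared)."""
        cfg = SimConfig(
            cells_per_row=5,
            rows_at_start=4,
            quiesce_depth=0,
            divide_spec=GradientSpec(0.18, 0.2, 0.5, Orientation.BOTTOM_HIGH),
            die_spec=GradientSpec(0.18, 0.2, 0.5, Orientation.TOP_HIGH),
            feedback=FeedbackParams(1, 1, 1),
        )
        rows = cfg.rows_at_start
        wins = np.zeros(cfg.cells_per_row)
        n_done = 0
        for r in range(250):
            res = run(
                cfg, 4000, seed=1000 + r, stop_when=lambda rep: rep.n_clones <= 1
            )
            if res.state.n_total == 0 or res.metadata["monoclonal_time"] is None:
                continue
            winner = int(res.state.clone_ids()[0])
            wins[winner // rows] += 1
            n_done += 1
        assert n_done >= 200
        chi2, pval = sps.chisquare(wins)
        assert pval > 0.01
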