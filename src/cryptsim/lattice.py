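"""The cylindrical roll-out lattice of crypt cells.

The crypt cylinder is cut open and flattened into a grid of
``cells_per_row`` columns with left/right wraparound.  Each column is a
top-anchored stack of cells: row 0 is the crypt top (lumen edge), a column
of height ``h`` occupies rows ``0..h-1`` contiguously, and columns may have
different heights so the crypt can deepen locally.

Two structural moves maintain the lattice:

* division (:func:`place_progeny`) keeps one progeny in the parent position
  and inserts the other one column over and one row down, displacing any
  occupant along the same diagonal until a displaced cell lands in the first
  empty slot at the bottom of its target column;
* death (:func:`remove_cell`) removes a cell and pulls the cells below it up
  one row, so movement up the crypt is driven by cell loss above, not by
  mitotic pressure from below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .gradients import classify_cell

__all__ = [
    "CellRecord",
    "CryptState",
    "init_crypt",
    "wrap_column",
    "place_progeny",
    "remove_cell",
    "crypt_depth",
]

_EMPTY_POS = np.empty(0, np.int64)


@dataclass
class CellRecord:
    """A read/write view of one cell's fields (see the field arrays in
    :mod:`cryptsim._kernels`)."""

    clone_id: int
    divide_prob_current: float
    die_prob_current: float
    divide_factor: float = 1.0
    divide_offset: float = 0.0
    die_factor: float = 1.0
    die_offset: float = 0.0
    is_mutant: bool = False


class CryptState:
    """Lattice state: column stacks of cells plus the tick counter.

    The per-cell data live in numpy arrays shared with the numba kernels;
    :meth:`get_cell` / :meth:`set_cell` provide a per-cell dataclass view for
    inspection and tests.
    """

    def __init__(self, cells_per_row: int, row_capacity: int) -> None:
        if cells_per_row < 1:
            raise ValueError(f"cells_per_row must be >= 1, got {cells_per_row}")
        self.cells_per_row = int(cells_per_row)
        self.heights = np.zeros(cells_per_row, np.int64)
        self.fdat = np.zeros((K.NF, cells_per_row, row_capacity), np.float64)
        self.idat = np.full((K.NI, cells_per_row, row_capacity), -1, np.int64)
        self.fdat[K.F_DFAC] = 1.0
        self.fdat[K.F_KFAC] = 1.0
        self.tick = 0
        self.initial_total = 0
        self.initial_clone_count = 0

    # -- capacity -----------------------------------------------------
    @property
    def row_capacity(self) -> int:
        return self.fdat.shape[2]

    def ensure_capacity(self, min_rows: int) -> None:
        """Grow the row dimension of the field arrays (cheap, rare)."""
        if min_rows <= self.row_capacity:
            return
        new_cap = max(min_rows, self.row_capacity + 64)
        fdat = np.zeros((K.NF, self.cells_per_row, new_cap), np.float64)
        idat = np.full((K.NI, self.cells_per_row, new_cap), -1, np.int64)
        fdat[:, :, : self.row_capacity] = self.fdat
        idat[:, :, : self.row_capacity] = self.idat
        fdat[K.F_DFAC, :, self.row_capacity :] = 1.0
        fdat[K.F_KFAC, :, self.row_capacity :] = 1.0
        self.fdat = fdat
        self.idat = idat

    # -- inspection ---------------------------------------------------
    @property
    def n_total(self) -> int:
        return int(self.heights.sum())

    def depth(self) -> int:
        return int(self.heights.max()) if self.cells_per_row else 0

    def is_occupied(self, col: int, row: int) -> bool:
        return 0 <= col < self.cells_per_row and 0 <= row < self.heights[col]

    def _check(self, col: int, row: int) -> None:
        if not self.is_occupied(col, row):
            raise IndexError(f"no cell at column {col}, row {row}")

    def get_cell(self, col: int, row: int) -> CellRecord:
        self._check(col, row)
        f = self.fdat[:, col, row]
        i = self.idat[:, col, row]
        return CellRecord(
            clone_id=int(i[K.I_CLONE]),
            divide_prob_current=float(f[K.F_DIVP]),
            die_prob_current=float(f[K.F_DIEP]),
            divide_factor=float(f[K.F_DFAC]),
            divide_offset=float(f[K.F_DOFF]),
            die_factor=float(f[K.F_KFAC]),
            die_offset=float(f[K.F_KOFF]),
            is_mutant=bool(i[K.I_MUT]),
        )

    def set_cell(self, col: int, row: int, cell: CellRecord) -> None:
        self._check(col, row)
        self.fdat[K.F_DIVP, col, row] = cell.divide_prob_current
        self.fdat[K.F_DIEP, col, row] = cell.die_prob_current
        self.fdat[K.F_DFAC, col, row] = cell.divide_factor
        self.fdat[K.F_DOFF, col, row] = cell.divide_offset
        self.fdat[K.F_KFAC, col, row] = cell.die_factor
        self.fdat[K.F_KOFF, col, row] = cell.die_offset
        self.idat[K.I_CLONE, col, row] = cell.clone_id
        self.idat[K.I_MUT, col, row] = 1 if cell.is_mutant else 0

    def clone_ids(self) -> np.ndarray:
        """Distinct clone labels among living cells."""
        ids = [
            self.idat[K.I_CLONE, c, : self.heights[c]]
            for c in range(self.cells_per_row)
        ]
        if not ids:
            return np.empty(0, np.int64)
        return np.unique(np.concatenate(ids)) if self.n_total else np.empty(0, np.int64)

    def column(self, col: int) -> list[CellRecord]:
        return [self.get_cell(col, r) for r in range(self.heights[col])]

    def to_dataframe(self, config=None) -> pd.DataFrame:
        """One row per living cell; adds the type label if a config is given."""
        rows = []
        if config is not None and hasattr(config, "gradient_span"):
            span = config.gradient_span(self)
        else:
            span = max(1, self.depth())
        for c in range(self.cells_per_row):
            for r in range(int(self.heights[c])):
                cell = self.get_cell(c, r)
                rec = {
                    "tick": self.tick,
                    "column": c,
                    "row_from_top": r,
                    "clone_id": cell.clone_id,
                    "is_mutant": cell.is_mutant,
                    "divide_prob": cell.divide_prob_current,
                    "die_prob": cell.die_prob_current,
                }
                if config is not None:
                    rec["type_label"] = classify_cell(cell, r, span, config).value
                rows.append(rec)
        return pd.DataFrame(rows)


def wrap_column(col: int, cells_per_row: int) -> int:
    """Cylindrical wraparound: a cell leaving the right edge of the roll-out
    reappears on the left (and symmetrically leftward)."""
    if cells_per_row < 1:
        raise ValueError(f"cells_per_row must be >= 1, got {cells_per_row}")
    return col % cells_per_row


def init_crypt(config, rng=None, initial_rows: int | None = None) -> CryptState:
    """Build the initial crypt: every column at ``initial_rows`` cells
    (default ``config.rows_at_start``).

    ``initial_rows`` lets replicate crypts start at different sizes while
    sharing the same anatomy (gradient powers and niche depth, which are
    anchored at ``config.rows_at_start``).  Each cell receives a unique
    clone label, and current divide/die probabilities warm-started at their
    positional targets (niche cells at the quiescent target 0).
    """
    cpr = int(config.cells_per_row)
    rows = int(config.rows_at_start if initial_rows is None else initial_rows)
    if cpr < 1 or rows < 1:
        raise ValueError(
            f"dimensions must be positive, got cells_per_row={cpr}, rows_at_start={rows}"
        )
    state = CryptState(cpr, rows + 64)
    state.heights[:] = rows

    r = np.arange(rows)
    y = (r + 0.5) / rows
    if getattr(config, "gradient_length_mode", "mean") == "fixed":
        y = np.minimum(1.0, (r + 0.5) / config.rows_at_start)
    if getattr(config, "die_gradient_length_mode", "mean") == "fixed":
        y_die = np.minimum(1.0, (r + 0.5) / config.rows_at_start)
    else:
        y_die = y
    ds = config.divide_spec
    ks = config.die_spec
    divp = ds.minimum + (ds.maximum - ds.minimum) * y**ds.power
    diep = ks.minimum + (ks.maximum - ks.minimum) * (1.0 - y_die) ** ks.power
    niche_mask = np.array([config.in_niche(int(rr)) for rr in r])
    divp[niche_mask] = 0.0  # niche: quiescent target

    state.fdat[K.F_DIVP, :, :rows] = divp
    state.fdat[K.F_DIEP, :, :rows] = diep
    state.fdat[K.F_SNAP, :, :rows] = divp
    clone = (np.arange(cpr)[:, None] * rows + r[None, :]).astype(np.int64)
    state.idat[K.I_CLONE, :, :rows] = clone
    state.idat[K.I_MUT, :, :rows] = 0
    state.initial_total = cpr * rows
    state.initial_clone_count = cpr * rows
    return state


def place_progeny(
    state: CryptState, parent_col: int, parent_row: int, direction: str = "right"
) -> CryptState:
    """Insert one progeny of the parent cell at the diagonal neighbor.

    The progeny is a copy of the parent's record (clone label, phenotype,
    and current divide probability; positional feedback pulls it toward its
    own target on the next tick).  Total cells increase by exactly one.
    """
    state._check(parent_col, parent_row)
    if direction not in ("right", "left"):
        raise ValueError(f"direction must be 'right' or 'left', got {direction!r}")
    state.ensure_capacity(state.depth() + 2)
    newf = state.fdat[:, parent_col, parent_row].copy()
    newf[K.F_SNAP] = newf[K.F_DIVP]
    newi = state.idat[:, parent_col, parent_row].copy()
    newi[K.I_VID] = -1
    status = K.insert_cascade(
        state.heights,
        state.fdat,
        state.idat,
        _EMPTY_POS,
        _EMPTY_POS,
        parent_col,
        parent_row,
        1 if direction == "right" else -1,
        newf,
        newi,
    )
    if status != K.STATUS_OK:
        raise RuntimeError("lattice row capacity exceeded during division cascade")
    return state


def remove_cell(state: CryptState, col: int, row: int) -> CryptState:
    """Remove the cell at (col, row); cells below move up one row."""
    state._check(col, row)
    K.remove_pullup(state.heights, state.fdat, state.idat, _EMPTY_POS, _EMPTY_POS, col, row)
    return state


def crypt_depth(state: CryptState) -> int:
    """Maximum occupied column height; 0 for an extinct crypt."""
    return state.depth()
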