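"""Packaged biopsy reference statistics used as the calibration target.

Per-cell-type mean, standard deviation and coefficient of variation of cell
counts measured across 49 normal human colon crypts (Ki-67 staining
distinguishes proliferating cells from quiescent stem cells at the crypt
bottom and differentiated cells above).  These numbers are a comparison
target only; the simulator never reads them during a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["ReferenceStats", "load_reference"]

N_CRYPTS = 49


@dataclass(frozen=True)
class ReferenceStats:
    """Mean/SD/CV% per cell type plus the total, over ``n_crypts`` crypts."""

    table: pd.DataFrame
    n_crypts: int = N_CRYPTS

    def row(self, cell_type: str) -> pd.Series:
        return self.table.set_index("cell_type").loc[cell_type]

    def mean(self, cell_type: str) -> float:
        return float(self.row(cell_type)["mean"])

    def sd(self, cell_type: str) -> float:
        return float(self.row(cell_type)["sd"])

    def cv_pct(self, cell_type: str) -> float:
        return float(self.row(cell_type)["cv_pct"])


def load_reference() -> ReferenceStats:
    """Load the packaged biopsy statistics table."""
    with resources.files("cryptsim.data").joinpath("biopsy_reference.csv").open() as fh:
        table = pd.read_csv(fh)
    return ReferenceStats(table=table)
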