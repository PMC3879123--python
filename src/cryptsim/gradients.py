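"""Positional divide/die probability gradients and cell-type classification.

The crypt axis is parameterized by a normalized depth ``y`` in ``[0, 1]``
(0 = top / lumen edge, 1 = crypt bottom).  Two power-law gradients govern the
per-tick event probabilities of every cell: the *divide* gradient rises
toward the crypt bottom, the *die* gradient rises toward the top.  A cell's
type (quiescent stem, proliferating, differentiated) is not intrinsic; it is
read off from the cell's position and its current divide probability, so
types are plastic and inter-convertible as cells move.

Cells do not respond to the gradients instantaneously.  Each tick a cell's
current divide probability moves a fraction ``strength`` of the way toward
the positional target (:func:`feedback_update`); ``strength = 1`` is an
immediate response, ``strength = 0`` no response.  The delay is what lets a
quiescent stem cell that is pushed out of the niche keep a low divide
probability for a while before becoming an active stem cell, and it is the
lever that reproduces the large crypt-to-crypt variation in cell counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Orientation",
    "CellType",
    "GradientSpec",
    "FeedbackParams",
    "gradient_value",
    "normalized_depth",
    "feedback_update",
    "target_divide_probability",
    "target_die_probability",
    "classify_cell",
]


class Orientation(enum.Enum):
    """Direction in which a gradient rises along the crypt axis."""

    BOTTOM_HIGH = "bottom_high"  # divide gradient: maximal at the crypt bottom
    TOP_HIGH = "top_high"  # die gradient: maximal at the lumen edge


class CellType(enum.Enum):
    """Position-determined, inter-convertible cell states."""

    QUIESCENT_STEM = "quiescent_stem"
    PROLIFERATING = "proliferating"
    DIFFERENTIATED = "differentiated"


@dataclass(frozen=True)
class GradientSpec:
    """Power-law probability gradient ``p(y) = min + (max - min) * y**power``.

    ``power = 0`` is a flat gradient, ``power = 1`` linear, ``power > 1``
    concave (the larger the power, the more the probability is concentrated
    at the high end).  For :attr:`Orientation.TOP_HIGH` the shape is mirrored,
    ``p(y) = min + (max - min) * (1 - y)**power``.
    """

    minimum: float = 0.0
    maximum: float = 1.0
    power: float = 1.0
    orientation: Orientation = Orientation.BOTTOM_HIGH

    def __post_init__(self) -> None:
        if not (0.0 <= self.minimum <= self.maximum <= 1.0):
            raise ValueError(
                f"require 0 <= minimum <= maximum <= 1, got "
                f"minimum={self.minimum}, maximum={self.maximum}"
            )
        if not self.power > 0.0:
            raise ValueError(f"power must be > 0, got {self.power}")
        if not isinstance(self.orientation, Orientation):
            raise ValueError(f"invalid orientation: {self.orientation!r}")


@dataclass(frozen=True)
class FeedbackParams:
    """Per-type gradient feedback strengths, each in ``[0, 1]``.

    The strength is the fraction of the gap between a cell's current divide
    probability and its positional target closed per tick.  Values below 1
    implement the delayed plasticity that calibration requires.
    """

    quiescent_strength: float = 0.1
    proliferating_strength: float = 0.5
    differentiated_strength: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "quiescent_strength",
            "proliferating_strength",
            "differentiated_strength",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def strength_for(self, cell_type: CellType) -> float:
        if cell_type is CellType.QUIESCENT_STEM:
            return self.quiescent_strength
        if cell_type is CellType.PROLIFERATING:
            return self.proliferating_strength
        return self.differentiated_strength


def gradient_value(y: float, spec: GradientSpec) -> float:
    """Evaluate a gradient at normalized depth ``y``.

    Parameters
    ----------
    y
        Normalized depth in ``[0, 1]``; 0 is the crypt top (lumen), 1 the
        bottom.
    spec
        Gradient shape.

    Returns
    -------
    float
        Probability in ``[spec.minimum, spec.maximum]``, monotone
        nondecreasing in ``y`` for ``BOTTOM_HIGH`` and nonincreasing for
        ``TOP_HIGH``.
    """
    if not (0.0 <= y <= 1.0):
        raise ValueError(f"normalized depth must be in [0, 1], got {y}")
    if spec.orientation is Orientation.BOTTOM_HIGH:
        base = y
    else:
        base = 1.0 - y
    if base == 0.0:  # exact endpoints, no FP residue
        return spec.minimum
    if base == 1.0:
        return spec.maximum
    return spec.minimum + (spec.maximum - spec.minimum) * base**spec.power


def normalized_depth(row_from_top: int, crypt_depth_rows: int) -> float:
    """Map a lattice row index to a normalized depth using row midpoints.

    ``y = (row_from_top + 0.5) / crypt_depth_rows`` so that the top row sits
    just below ``y = 0`` and the bottom row just above ``y = 1``; neither end
    of the crypt sees a deterministic probability of 0 or 1.  The depth used
    is the *global* crypt depth (tallest column), so the gradients rescale as
    the crypt as a whole deepens or shrinks.
    """
    if crypt_depth_rows < 1:
        raise ValueError(f"crypt_depth_rows must be >= 1, got {crypt_depth_rows}")
    if not (0 <= row_from_top < crypt_depth_rows):
        raise ValueError(
            f"row_from_top {row_from_top} outside current depth {crypt_depth_rows}"
        )
    return (row_from_top + 0.5) / crypt_depth_rows


def feedback_update(current: float, target: float, strength: float) -> float:
    """Move ``current`` a fraction ``strength`` of the way toward ``target``.

    Closed form after ``k`` iterated applications from ``p0``:
    ``target + (1 - strength)**k * (p0 - target)``.
    """
    for name, v in (("current", current), ("target", target), ("strength", strength)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return current + strength * (target - current)


def _apply_modifiers(target: float, factor: float, offset: float) -> float:
    return min(1.0, max(0.0, target * factor + offset))


def _clamped_depth(row_from_top: int, span_rows: int) -> float:
    # rows below a fixed gradient span sit at the gradient bottom (y = 1)
    return min(1.0, (row_from_top + 0.5) / span_rows)


def target_divide_probability(
    cell,
    row_from_top: int,
    crypt_depth_rows: int,
    config,
    divide_multiplier: float = 1.0,
) -> float:
    """Positional divide-probability target for one cell.

    Inside the stem-cell niche (within ``config.quiesce_depth`` rows of the
    crypt bottom) the cell responds to the quiescent target (0) instead of
    the divide gradient.  The cell's multiplicative mutant factor and
    additive offset act on the target before feedback, and the result is
    clipped to ``[0, 1]``.  ``divide_multiplier`` is the crypt-resizing
    controller's global multiplier (1 when the controller is off).

    ``crypt_depth_rows`` is the gradient span; cells deeper than the span
    (possible when the span is fixed) sit at the gradient bottom, inside
    the niche.  Mutant cells are insensitive to the niche's quiescence
    signal (constitutive pathway activation): they read the divide gradient
    even inside the niche.
    """
    if row_from_top < 0:
        raise ValueError(f"row_from_top must be >= 0, got {row_from_top}")
    if config.in_niche(row_from_top) and not cell.is_mutant:
        base = 0.0
    else:
        y = _clamped_depth(row_from_top, crypt_depth_rows)
        base = gradient_value(y, config.divide_spec)
    return _apply_modifiers(
        base * divide_multiplier, cell.divide_factor, cell.divide_offset
    )


def target_die_probability(
    cell, row_from_top: int, crypt_depth_rows: int, config
) -> float:
    """Positional die-probability target for one cell (mutant-modified, clipped)."""
    if row_from_top < 0:
        raise ValueError(f"row_from_top must be >= 0, got {row_from_top}")
    y = _clamped_depth(row_from_top, crypt_depth_rows)
    base = gradient_value(y, config.die_spec)
    return _apply_modifiers(base, cell.die_factor, cell.die_offset)


def classify_cell(cell, row_from_top: int, crypt_depth_rows: int, config) -> CellType:
    """Label a cell from its position and current divide probability.

    Mirrors the Ki-67 readout of the biopsy measurement: any cell whose
    current divide probability is at least ``config.diff_threshold`` is
    proliferating (in the niche such cells are active stem cells that have
    not yet quiesced); a non-dividing cell is a quiescent stem cell if it
    sits in the niche (at or below ``config.niche_row`` rows from the top)
    and differentiated otherwise.  The three labels partition the living
    cells.  ``crypt_depth_rows`` (the gradient span) is accepted for
    signature symmetry with the target functions.
    """
    if row_from_top < 0 or crypt_depth_rows < 1:
        raise ValueError(
            f"invalid position: row {row_from_top}, span {crypt_depth_rows}"
        )
    if cell.divide_prob_current >= config.diff_threshold:
        return CellType.PROLIFERATING
    if config.in_niche(row_from_top):
        return CellType.QUIESCENT_STEM
    return CellType.DIFFERENTIATED
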