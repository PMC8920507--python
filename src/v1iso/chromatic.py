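"""Cone weights, luminance tuning index, and cell classification.

A chromatically linear neuron's color weighting function (in phosphor
space) is re-expressed as signed L, M, S weights acting on cone contrast,
normalized so the absolute weights sum to one.  Cells are then labeled
simple, double-opponent (DO), or other spatially opponent (OSO) under two
alternative criteria sets: explicit cone-weight thresholds, or a luminance
tuning index with cutoffs at 0.33 and 0.67.  A significant excitatory
stimulus feature beyond the STA (the PC1 test) forces OSO regardless of
the weights, since cone weights are only interpretable for linear cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .display import (
    ConeFundamentals,
    ConeWeights,
    DisplayModel,
    cone_weights_from_phosphor_vector,
)
from .receptive_field import RFDecomposition

__all__ = [
    "CellClassification",
    "estimate_cone_weights",
    "luminance_tuning_index",
    "classify_cell",
]


@dataclass(frozen=True)
class CellClassification:
    label: str  # {"simple", "DO", "OSO"}
    basis: str  # {"pc1", "cone_weights", "luminance_index"}
    details: dict


def estimate_cone_weights(
    decomp: RFDecomposition,
    display: DisplayModel,
    fundamentals: ConeFundamentals,
) -> ConeWeights:
    """Convert the color weighting function to normalized cone weights."""
    return cone_weights_from_phosphor_vector(
        decomp.color_weighting, display, fundamentals
    )


def luminance_tuning_index(w: ConeWeights, lum: ConeWeights) -> float:
    """|cos angle| between a cell's cone weights and the luminance direction.

    Both vectors are L2-normalized before the projection so the index lies
    in [0, 1]: 1 for a pure luminance cell, 0 for one orthogonal to
    luminance.  Invariant to rescaling of either argument.
    """
    a = w.as_array()
    b = lum.as_array()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cone-weight vectors must be non-zero")
    return float(abs(a @ b) / (na * nb))


def _classify_by_cone_weights(w: ConeWeights) -> str:
    l, m, s = w.l, w.m, w.s
    al, am, as_ = abs(l), abs(m), abs(s)
    # simple: L and M same sign, jointly >= 80% of total weight, each >= 10%
    if l * m > 0 and al + am >= 0.8 and al >= 0.1 and am >= 0.1:
        return "simple"
    # DO route 1: S weight >= 20% alongside an opponent pair of weights
    signs = [np.sign(v) for v in (l, m, s) if v != 0]
    has_opponent_pair = len(set(signs)) > 1
    if as_ >= 0.2 and has_opponent_pair:
        return "DO"
    # DO route 2: L-M opponency, jointly >= 80%, each >= 20%
    if l * m < 0 and al + am >= 0.8 and al >= 0.2 and am >= 0.2:
        return "DO"
    return "OSO"


def classify_cell(
    w: ConeWeights | None,
    pc1_significant: bool,
    mode: str = "cone_weights",
    lti: float | None = None,
) -> CellClassification:
    """Label a cell simple / DO / OSO.

    A significant PC1 forces OSO.  Otherwise ``mode="cone_weights"`` applies
    the explicit thresholds on L, M, S weights and ``mode="luminance_index"``
    labels DO below 0.33, simple above 0.67, OSO between.
    """
    if pc1_significant:
        return CellClassification(
            label="OSO", basis="pc1", details={"pc1_significant": True}
        )
    if mode == "cone_weights":
        if w is None:
            raise ValueError("cone weights required for mode='cone_weights'")
        label = _classify_by_cone_weights(w)
        return CellClassification(
            label=label,
            basis="cone_weights",
            details={"l": w.l, "m": w.m, "s": w.s},
        )
    if mode == "luminance_index":
        if lti is None:
            raise ValueError("lti required for mode='luminance_index'")
        if lti < 0.33:
            label = "DO"
        elif lti > 0.67:
            label = "simple"
        else:
            label = "OSO"
        return CellClassification(
            label=label, basis="luminance_index", details={"lti": lti}
        )
    raise ValueError(f"unknown classification mode {mode!r}")
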