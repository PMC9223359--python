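"""Entropy weighting of indicators.

The information-entropy weight method assigns each indicator an objective
weight from how unevenly its scores are distributed across evaluation
units: an indicator whose scores barely vary carries little discriminating
information (entropy near 1, weight near 0), while a dispersed indicator
gets more weight.

For indicator j with scores s_1j..s_nj over n units and column total
s* = Σ_i s_ij:

    S_j = -(1 / ln n) Σ_i (s_ij / s*) ln(s_ij / s*)       (0·ln 0 := 0)
    w_j = (1 - S_j) / (m - Σ_k S_k)

so the m weights sum to one.  The natural/social subsystem weight sums
W_natural and W_social partition that total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .scoring import IndicatorRegistry, validate_score_matrix

__all__ = ["information_entropy", "entropy_weights", "WeightVector"]


def information_entropy(column: Sequence[float]) -> float:
    """Normalized Shannon entropy of one indicator's score column.

    Scores are converted to proportions of the column total; the entropy is
    normalized by ln(n) so that equal scores give exactly 1 and a point
    mass gives exactly 0.  Zero scores contribute nothing (0·ln 0 := 0).

    Raises
    ------
    ValueError
        For fewer than two units, negative scores, or an all-zero column
        (proportions undefined).
    """
    arr = np.asarray(list(column), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("entropy needs at least two evaluation units")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    if np.any(arr < 0.0):
        raise ValueError("scores must be non-negative")
    total = arr.sum()
    if total <= 0.0:
        raise ValueError("degenerate column: all scores are zero")
    p = arr / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(p), 0.0)
    s = float(-terms.sum() / math.log(n))
    # guard float fuzz at the extremes
    return min(1.0, max(0.0, s))


@dataclass(frozen=True)
class WeightVector:
    """Entropy weights per indicator plus subsystem sums.

    ``weights`` and ``entropies`` are indexed by indicator id; ``natural``
    and ``social`` list the indicator ids of each subsystem.
    """

    weights: pd.Series
    entropies: pd.Series
    natural: Tuple[str, ...]
    social: Tuple[str, ...]

    def __post_init__(self) -> None:
        total = float(self.weights.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if np.any(self.weights.to_numpy() < -1e-12):
            raise ValueError("weights must be non-negative")
        covered = set(self.natural) | set(self.social)
        if covered != set(self.weights.index):
            raise ValueError("subsystem assignment does not cover all indicators")

    @property
    def w_natural(self) -> float:
        """Integrated weight of the natural-function subsystem."""
        return float(self.weights[list(self.natural)].sum())

    @property
    def w_social(self) -> float:
        """Integrated weight of the social-function subsystem."""
        return float(self.weights[list(self.social)].sum())

    def subsystem_ids(self, subsystem: str) -> Tuple[str, ...]:
        if subsystem == "natural":
            return self.natural
        if subsystem == "social":
            return self.social
        raise ValueError(f"unknown subsystem {subsystem!r}")


def entropy_weights(
    matrix: pd.DataFrame, registry: IndicatorRegistry
) -> WeightVector:
    """Entropy weights for every indicator column of a score matrix.

    Evaluation units (rows, station-years) are pooled into a single weight
    set, matching a basin-level assessment.  Scores outside [0, 1] are
    rejected rather than clipped — rescaling belongs upstream.

    Raises
    ------
    ValueError
        If every column is uniform (all entropies 1: weights undefined), a
        column is all-zero, or the matrix is invalid.
    """
    validate_score_matrix(matrix)
    if matrix.shape[0] < 2:
        raise ValueError("entropy weighting needs at least two evaluation units")
    missing = [c for c in matrix.columns if c not in registry]
    if missing:
        raise KeyError(f"matrix columns not in registry: {missing}")
    entropies = pd.Series(
        {c: information_entropy(matrix[c].to_numpy()) for c in matrix.columns},
        name="entropy",
    )
    m = len(entropies)
    denom = m - float(entropies.sum())
    if denom <= 1e-12:
        raise ValueError(
            "all indicator columns are uniform: entropy weights undefined"
        )
    weights = (1.0 - entropies) / denom
    weights.name = "weight"
    natural = tuple(i for i in matrix.columns if registry[i].subsystem == "natural")
    social = tuple(i for i in matrix.columns if registry[i].subsystem == "social")
    return WeightVector(
        weights=weights, entropies=entropies, natural=natural, social=social
    )
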