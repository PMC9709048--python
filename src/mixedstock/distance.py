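"""Scaled inverse effective-distance matrices.

Dispersal from a rookery is assumed likelier toward nearby mixed stocks, so
the model weights expected contributions by the row-normalized reciprocal of
effective distance:

    P[i, j] = (1 / D[i, j]) / sum_j' (1 / D[i, j'])

Each row of P is a probability vector over rookeries for one mixed stock.
The uniform (matrix-of-ones) variant makes the weighted model collapse onto
the base many-to-many model and is used for ground-truthing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EffectiveDistanceMatrix
from .errors import ValidationError

__all__ = ["ScaledInverseDistanceMatrix", "scaled_inverse_distance", "uniform_matrix", "write_scaled_matrix"]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class ScaledInverseDistanceMatrix:
    """Row-stochastic matrix of scaled inverse distances (mixed stock x rookery)."""

    mixed_stock_labels: tuple
    rookery_labels: tuple
    P: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mixed_stock_labels", tuple(self.mixed_stock_labels))
        object.__setattr__(self, "rookery_labels", tuple(self.rookery_labels))
        P = np.asarray(self.P, dtype=float)
        if P.shape != (len(self.mixed_stock_labels), len(self.rookery_labels)):
            raise ValidationError("P shape does not match labels")
        if np.any(P <= 0):
            i, j = np.argwhere(P <= 0)[0]
            raise ValidationError(
                f"P must be strictly positive; offending cell "
                f"({self.mixed_stock_labels[i]!r}, {self.rookery_labels[j]!r})"
            )
        if np.any(np.abs(P.sum(axis=1) - 1.0) > _ROW_TOL * max(1, P.shape[1])):
            i = int(np.argmax(np.abs(P.sum(axis=1) - 1.0)))
            raise ValidationError(
                f"row for mixed stock {self.mixed_stock_labels[i]!r} does not sum to 1"
            )
        object.__setattr__(self, "P", P)


def scaled_inverse_distance(
    D: EffectiveDistanceMatrix, floor: float | None = None
) -> ScaledInverseDistanceMatrix:
    """Row-normalize inverse distances into the dispersal weight matrix P.

    ``floor`` optionally clips each entry from below (then renormalizes) so a
    single enormous distance cannot numerically extinguish a rookery; it is
    off by default, matching the plain definition.
    """
    inv = 1.0 / D.D
    P = inv / inv.sum(axis=1, keepdims=True)
    if floor is not None:
        if not 0 < floor < 1.0 / P.shape[1]:
            raise ValidationError("floor must lie in (0, 1/n_rookeries)")
        P = np.maximum(P, floor)
        P = P / P.sum(axis=1, keepdims=True)
    return ScaledInverseDistanceMatrix(D.mixed_stock_labels, D.rookery_labels, P)


def uniform_matrix(mixed_stock_labels, rookery_labels) -> ScaledInverseDistanceMatrix:
    """Row-normalized matrix of ones: every rookery equally weighted."""
    mixed_stock_labels = tuple(mixed_stock_labels)
    rookery_labels = tuple(rookery_labels)
    if not mixed_stock_labels or not rookery_labels:
        raise ValidationError("label lists must be non-empty")
    P = np.full((len(mixed_stock_labels), len(rookery_labels)), 1.0 / len(rookery_labels))
    return ScaledInverseDistanceMatrix(mixed_stock_labels, rookery_labels, P)


def write_scaled_matrix(P: ScaledInverseDistanceMatrix, path) -> None:
    """Write P as CSV with 12 significant digits."""
    import pandas as pd

    df = pd.DataFrame(P.P, index=list(P.mixed_stock_labels), columns=list(P.rookery_labels))
    df.to_csv(path, index_label="mixed_stock", float_format="%.12g")
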