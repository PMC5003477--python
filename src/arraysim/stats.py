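"""Derived per-gene visual statistics: MA and volcano coordinates.

MA coordinates compare two samples' log2 intensities as M = Ix2 - Ix1
(log2 ratio) against A = (Ix2 + Ix1) / 2 (mean log2 intensity); volcano
coordinates pair each gene's linear-scale fold change between group means
with its t-test p-value, highlighting genes past the conventional
p < 0.01 and two-fold-change thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SimulatedDataset

__all__ = ["MACoordinates", "VolcanoCoordinates", "ma_transform", "volcano_stats"]

P_HIGHLIGHT = 0.01
FC_HIGH = 2.0
FC_LOW = 0.5


@dataclass(frozen=True)
class MACoordinates:
    """Element-wise M = Ix2 - Ix1 and A = 0.5 * (Ix2 + Ix1) for one pair
    of samples; M = 1 (-1) means two-fold up- (down-) regulation."""

    m_values: np.ndarray
    a_values: np.ndarray
    sample_pair: tuple[str, str]


@dataclass(frozen=True)
class VolcanoCoordinates:
    """Per-gene linear fold change (2 ** group-mean difference), p-value,
    and the highlight mask (p < 0.01 and fold change > 2 or < 0.5, both
    strict)."""

    fold_change: np.ndarray
    p_value: np.ndarray
    highlighted: np.ndarray


def ma_transform(ix1, ix2, sample_pair=("x1", "x2")) -> MACoordinates:
    """MA coordinates of two log2-intensity vectors.

    Linear and invertible: ``ix2 = A + M/2``, ``ix1 = A - M/2``.
    """
    ix1 = np.asarray(ix1, dtype=float)
    ix2 = np.asarray(ix2, dtype=float)
    if ix1.shape != ix2.shape:
        raise ValueError(f"shape mismatch: {ix1.shape} vs {ix2.shape}")
    return MACoordinates(
        m_values=ix2 - ix1,
        a_values=0.5 * (ix2 + ix1),
        sample_pair=tuple(sample_pair),
    )


def volcano_stats(dataset: SimulatedDataset, p_values) -> VolcanoCoordinates:
    """Volcano coordinates for one simulated dataset.

    The fold change is ``2 ** (mean of test columns - mean of control
    columns)`` per gene; highlighting uses strict inequalities at p < 0.01
    and fold change > 2 or < 0.5, so a gene sitting exactly on a threshold
    is not flagged.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.shape[0] != dataset.x.shape[0]:
        raise ValueError(
            f"{p_values.shape[0]} p-values for {dataset.x.shape[0]} genes"
        )
    m1 = dataset.params.m1
    delta = dataset.x[:, m1:].mean(axis=1) - dataset.x[:, :m1].mean(axis=1)
    fc = np.exp2(delta)
    highlighted = (p_values < P_HIGHLIGHT) & ((fc > FC_HIGH) | (fc < FC_LOW))
    return VolcanoCoordinates(fold_change=fc, p_value=p_values, highlighted=highlighted)
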