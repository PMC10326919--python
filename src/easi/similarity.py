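"""Spectral comparison measures: MAR, Euclidean distance, cosine, NIST score.

All four measures compare a predicted abundance vector with a measured one
over the same peak panel.  MAR and the Euclidean distance are dissimilarity
measures on the residuals (lower = better match); the dot product (cosine)
and the weighted NIST-style score are similarity measures (higher = better).

The NIST-style match factor weights each channel's abundance as
``max(A, 0)**x * (m/z)**y`` before taking the cosine, with the classic
weights x = 0.6, y = 3 and a score ceiling of 999: the m/z term emphasises
heavy, structurally diagnostic fragments such as molecular ions, while the
fractional abundance exponent de-emphasises dominant base peaks.  Abundances
are floored at 0 only inside this weighting (fractional powers of negative
numbers are undefined); MAR, Euclidean and plain cosine use raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import PredictionRecord
from .peakmodel import PeakPanel

__all__ = ["WeightSpec", "mar", "euclidean", "dot_product", "nist_score"]


@dataclass(frozen=True)
class WeightSpec:
    """Weighting exponents and ceiling for the NIST-style match factor."""

    x: float = 0.6   # abundance exponent
    y: float = 3.0   # m/z exponent
    scale: float = 999.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def mar(record: PredictionRecord) -> float:
    """Mean absolute residual, in percent of base peak.

    ``(1/K) * sum_i |predicted_i - measured_i|``.  Unlike an RMS error the
    MAR does not scale with the number of channels, so values stay comparable
    across panel sizes.
    """
    if len(record.residuals) == 0:
        raise ValueError("cannot compute MAR of an empty record")
    return float(np.mean(np.abs(record.residuals)))


def euclidean(record: PredictionRecord) -> float:
    """Euclidean distance between predicted and measured abundance vectors."""
    if len(record.residuals) == 0:
        raise ValueError("cannot compute the Euclidean distance of an empty record")
    return float(np.sqrt(np.sum(record.residuals**2)))


def dot_product(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two abundance vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na = float(np.dot(a, a))
    nb = float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cannot take the cosine of a zero vector")
    if np.array_equal(a, b):
        return 1.0  # a perfect match is the ceiling by definition
    cos = float(np.dot(a, b) / np.sqrt(na * nb))
    return max(-1.0, min(1.0, cos))


def nist_score(
    a: np.ndarray,
    b: np.ndarray,
    panel: PeakPanel,
    weights: WeightSpec = WeightSpec(),
) -> float:
    """Weighted-cosine match factor between two panel abundance vectors.

    Each vector element is replaced by ``max(A, 0)**x * (m/z)**y`` and the
    cosine of the weighted vectors is scaled by ``weights.scale``, so an
    exact match scores the ceiling (999 at the defaults) exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(panel) or len(b) != len(panel):
        raise ValueError("vectors must match the panel length")
    mz = np.asarray(panel.channels, dtype=float)
    aw = np.clip(a, 0.0, None) ** weights.x * mz**weights.y
    bw = np.clip(b, 0.0, None) ** weights.x * mz**weights.y
    if not np.any(aw) or not np.any(bw):
        raise ValueError("weighted vector is all zero; score undefined")
    return weights.scale * dot_product(aw, bw)
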