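"""Mahalanobis distance of query spectra to the training cloud.

Replicate spectra of one compound form a tight, strongly covarying cloud in
panel-abundance space.  The Mahalanobis distance whitens that space by the
training covariance matrix, so the distance of a query spectrum to the
training mean reads as "how many multivariate standard deviations away",
directly on measured abundances — no per-ion linear modeling involved.

Channels that are constant across the training set (the base peak, pinned at
100 by normalisation) carry no variance and are dropped before inversion;
with a 20-peak panel this leaves 19 retained channels, which is also the
default degrees of freedom of the chi-square outlier test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .peakmodel import AbundanceMatrix

__all__ = [
    "CovarianceModel",
    "fit_covariance",
    "mahalanobis_distance",
    "distances_for_matrix",
    "chi2_outlier_test",
]


@dataclass(frozen=True)
class CovarianceModel:
    """Training mean and sample covariance over the retained panel channels."""

    panel_channels: tuple[int, ...]
    retained: tuple[int, ...]
    mean: np.ndarray        # % of base peak, over retained channels
    covariance: np.ndarray  # %^2, n-1 denominator, over retained channels
    n: int
    allow_pinv: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        k = len(self.retained)
        if self.covariance.shape != (k, k):
            raise ValueError("covariance shape must match the retained channels")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if not set(self.retained) <= set(self.panel_channels):
            raise ValueError("retained channels must be a subset of the panel")

    @property
    def k_retained(self) -> int:
        return len(self.retained)

    def reduce(self, query: np.ndarray) -> np.ndarray:
        """Project a full-panel vector onto the retained channels."""
        query = np.asarray(query, dtype=float)
        if len(query) == self.k_retained:
            return query
        if len(query) != len(self.panel_channels):
            raise ValueError(
                f"query has {len(query)} channels; expected "
                f"{len(self.panel_channels)} (panel) or {self.k_retained} (retained)"
            )
        idx = [self.panel_channels.index(c) for c in self.retained]
        return query[idx]


def fit_covariance(matrix: AbundanceMatrix, allow_pinv: bool = False) -> CovarianceModel:
    """Mean and sample covariance (n-1 denominator) of training rows.

    Zero-variance channels are recorded as dropped.  If there are fewer rows
    than retained channels + 1 the sample covariance is singular; a warning
    is issued and the pseudo-inverse contract is enabled for this model.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("covariance fitting needs at least 2 rows")
    vals = matrix.values.to_numpy(dtype=float)
    variances = vals.var(axis=0, ddof=1)
    keep = variances > 0
    retained = tuple(c for c, k in zip(matrix.panel.channels, keep) if k)
    sub = vals[:, keep]
    if n < len(retained) + 1:
        warnings.warn(
            f"{n} training rows for {len(retained)} retained channels: sample "
            "covariance is singular; falling back to the pseudo-inverse",
            stacklevel=2,
        )
        allow_pinv = True
    return CovarianceModel(
        panel_channels=matrix.panel.channels,
        retained=retained,
        mean=sub.mean(axis=0),
        covariance=np.cov(sub, rowvar=False, ddof=1).reshape(len(retained), len(retained)),
        n=n,
        allow_pinv=allow_pinv,
    )


def mahalanobis_distance(model: CovarianceModel, query: np.ndarray) -> float:
    """``sqrt((x - mean)^T C^-1 (x - mean))`` for one query vector.

    ``query`` may be given over the full panel (reduced internally) or
    already over the retained channels.  Solved via a Cholesky factorisation
    of C for numerical stability; a singular C raises unless the model allows
    the pseudo-inverse fallback.
    """
    diff = model.reduce(query) - model.mean
    try:
        cho = linalg.cho_factor(model.covariance)
        d2 = float(diff @ linalg.cho_solve(cho, diff))
    except linalg.LinAlgError:
        if not model.allow_pinv:
            raise ValueError(
                "singular covariance matrix; refit with allow_pinv=True to use "
                "the pseudo-inverse"
            ) from None
        d2 = float(diff @ np.linalg.pinv(model.covariance) @ diff)
    return float(np.sqrt(max(d2, 0.0)))


def distances_for_matrix(model: CovarianceModel, matrix: AbundanceMatrix) -> np.ndarray:
    """Mahalanobis distance of every row of ``matrix`` to the training cloud."""
    if matrix.panel.channels != model.panel_channels:
        raise ValueError("matrix panel does not match the covariance model")
    return np.array([mahalanobis_distance(model, matrix.row(sid)) for sid in matrix.ids])


def chi2_outlier_test(
    distance: float, df: int = 19, alpha: float = 0.05
) -> tuple[float, bool]:
    """Chi-square outlier test on a squared Mahalanobis distance.

    Under multivariate normality the squared distance of a member of the
    training population is approximately chi-square distributed with ``df``
    degrees of freedom (default 19, the retained channels of a 20-peak
    panel).  Returns ``(critical_value, is_outlier)`` where the critical
    value is the 1 - alpha chi-square quantile and a spectrum is flagged when
    ``distance**2`` exceeds it.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    return critical, bool(distance**2 > critical)
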