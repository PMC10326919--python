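"""Per-ion stepwise linear models and within-spectrum abundance prediction.

The central idea: in replicate EI spectra of one compound the normalised
fragment abundances are not independent — they co-vary almost linearly, a
consequence of the spectra responding to a shared effective internal-energy
state of the instrument.  Each panel ion's abundance can therefore be
predicted *from the other ions of the same query spectrum* by a linear model
fitted on training replicates.  Because the prediction adapts to the query,
it tracks systematic inter-laboratory shifts that a fixed consensus spectrum
cannot, while spectra of other compounds (which do not follow the learned
covariance pattern) produce large residuals.

Model selection is bidirectional stepwise least squares: candidates enter on
the smallest partial-F p-value below ``p_enter`` and leave when their
partial-F p-value exceeds ``p_remove`` (defaults 0.05 / 0.10).  Predictions
are deliberately *not* clipped to [0, 100]: wildly out-of-range predictions
are exactly how a non-matching spectrum reveals itself.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .peakmodel import AbundanceMatrix, ConsensusSpectrum, PeakPanel, consensus_from_matrix

__all__ = [
    "IonModel",
    "EASIModel",
    "PredictionRecord",
    "fit_stepwise",
    "fit_easi",
    "predict",
    "predict_matrix",
]

_RSS_TINY = 1e-12


@dataclass(frozen=True)
class IonModel:
    """One panel ion's linear model: target ~ intercept + sum(beta_c * x_c)."""

    target: int
    intercept: float
    coefficients: Mapping[int, float]
    r_squared: float
    residual_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", {int(k): float(v) for k, v in self.coefficients.items()}
        )
        if self.target in self.coefficients:
            raise ValueError("target channel cannot be its own covariate")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict_one(self, measured: Mapping[int, float]) -> float:
        return self.intercept + sum(
            beta * measured[c] for c, beta in self.coefficients.items()
        )


@dataclass(frozen=True)
class EASIModel:
    """One stepwise :class:`IonModel` per panel channel, plus the consensus.

    ``covariance`` optionally carries the fitted training covariance model so
    a single artifact can serve both the EASI and Mahalanobis classifiers.
    """

    panel: PeakPanel
    ion_models: Mapping[int, IonModel]
    consensus: ConsensusSpectrum
    settings: Mapping[str, float]
    training_hash: str = ""
    covariance: object | None = None

    def __post_init__(self) -> None:
        if set(self.ion_models) != set(self.panel.channels):
            raise ValueError("need exactly one IonModel per panel channel")

    def coefficient_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (intercepts, B) with predicted = intercepts + B @ measured."""
        k = len(self.panel)
        intercepts = np.zeros(k)
        B = np.zeros((k, k))
        pos = {c: i for i, c in enumerate(self.panel.channels)}
        for c, model in self.ion_models.items():
            i = pos[c]
            intercepts[i] = model.intercept
            for cov, beta in model.coefficients.items():
                B[i, pos[cov]] = beta
        return intercepts, B


@dataclass(frozen=True)
class PredictionRecord:
    """Measured, predicted and residual abundance vectors for one query.

    ``residuals = predicted - measured`` elementwise, in percent of base
    peak; all three vectors share the panel's channel order.  EASI
    predictions may fall below 0 or above 100 — that is informative, not an
    error.
    """

    spectrum_id: str
    approach: str  # "easi" | "consensus"
    channels: tuple[int, ...]
    measured: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    truth: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("measured", "predicted", "residuals"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.channels)
        if not (len(self.measured) == len(self.predicted) == len(self.residuals) == k):
            raise ValueError("measured/predicted/residual vectors must match the panel")
        if not np.allclose(self.residuals, self.predicted - self.measured, atol=1e-9):
            raise ValueError("residuals must equal predicted - measured")


# ---------------------------------------------------------------------------
# Stepwise fitting
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares with intercept column prepended; returns (coef, rss, rank)."""
    Xc = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    rss = float(np.sum((y - Xc @ coef) ** 2))
    return coef, rss, rank


def fit_stepwise(
    matrix: AbundanceMatrix,
    target: int,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    candidates: Sequence[int] | None = None,
) -> IonModel:
    """Bidirectional stepwise least-squares model for one panel ion.

    At each step the candidate with the smallest partial-F p-value enters if
    that p-value is below ``p_enter``; then any included covariate whose
    partial-F p-value exceeds ``p_remove`` is removed (worst first).  The
    procedure stops when no entry or removal changes the model, or when a
    previously visited covariate set recurs.

    Zero-variance covariates are excluded from candidacy (they would make the
    design singular); a zero-variance *target* yields a constant model with
    ``r_squared`` defined as 0.  A candidate whose entry would make the
    design rank-deficient is refused and the search continues.
    """
    target = int(target)
    if target not in matrix.panel.channels:
        raise ValueError(f"target {target} not in panel")
    n = len(matrix)
    if n < 3:
        raise ValueError("stepwise fitting needs at least 3 rows")
    if not (0 < p_enter < 1 and 0 < p_remove < 1):
        raise ValueError("p_enter and p_remove must lie in (0, 1)")

    y = matrix.values[target].to_numpy(dtype=float)
    if candidates is None:
        candidates = [c for c in matrix.panel.channels if c != target]
    else:
        candidates = [int(c) for c in candidates]
        if target in candidates:
            raise ValueError("target cannot be a candidate covariate")

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= _RSS_TINY:  # constant target: nothing to model
        return IonModel(target, float(y.mean()), {}, 0.0, 0.0)

    # drop zero-variance covariates from candidacy
    candidates = [
        c for c in candidates if matrix.values[c].to_numpy(dtype=float).std() > 0
    ]
    if n < len(candidates) + 10:
        warnings.warn(
            f"only {n} rows for {len(candidates)} candidate covariates; "
            "stepwise selection may be unstable",
            stacklevel=2,
        )

    cols = {c: matrix.values[c].to_numpy(dtype=float) for c in candidates}

    def design(sel: list[int]) -> np.ndarray:
        return (
            np.column_stack([cols[c] for c in sel]) if sel else np.empty((n, 0))
        )

    selected: list[int] = []
    _, rss_cur, _ = _ols(design(selected), y)
    seen: set[frozenset[int]] = {frozenset()}

    while True:
        changed = False
        # --- entry step ---
        if rss_cur > _RSS_TINY:
            best_p, best_c, best_rss = None, None, None
            p_new = len(selected) + 2  # intercept + selected + candidate
            df2 = n - p_new
            if df2 > 0:
                for c in candidates:
                    if c in selected:
                        continue
                    _, rss_new, rank = _ols(design(selected + [c]), y)
                    if rank < p_new:  # singular design: refuse this candidate
                        continue
                    if rss_new <= _RSS_TINY:
                        pval = 0.0
                    else:
                        F = max(rss_cur - rss_new, 0.0) / (rss_new / df2)
                        pval = float(stats.f.sf(F, 1, df2))
                    if best_p is None or pval < best_p:
                        best_p, best_c, best_rss = pval, c, rss_new
            if best_p is not None and best_p < p_enter:
                trial = frozenset(selected + [best_c])
                if trial not in seen:
                    selected.append(best_c)
                    rss_cur = best_rss
                    seen.add(trial)
                    changed = True
        # --- removal step ---
        while selected:
            p_cur = len(selected) + 1
            df2 = n - p_cur
            worst_p, worst_c, worst_rss = None, None, None
            for c in selected:
                others = [s for s in selected if s != c]
                _, rss_wo, _ = _ols(design(others), y)
                if rss_cur <= _RSS_TINY:
                    pval = 1.0 if rss_wo <= _RSS_TINY else 0.0
                elif df2 <= 0:
                    pval = 1.0
                else:
                    F = max(rss_wo - rss_cur, 0.0) / (rss_cur / df2)
                    pval = float(stats.f.sf(F, 1, df2))
                if worst_p is None or pval > worst_p:
                    worst_p, worst_c, worst_rss = pval, c, rss_wo
            if worst_p is not None and worst_p > p_remove:
                trial = frozenset(s for s in selected if s != worst_c)
                if trial in seen:
                    break
                selected.remove(worst_c)
                rss_cur = worst_rss
                seen.add(trial)
                changed = True
            else:
                break
        if not changed:
            break

    coef, rss, _ = _ols(design(selected), y)
    dof = n - (len(selected) + 1)
    r2 = max(0.0, min(1.0, 1.0 - rss / tss))
    resid_sd = float(np.sqrt(rss / dof)) if dof > 0 and rss > _RSS_TINY else 0.0
    return IonModel(
        target=target,
        intercept=float(coef[0]),
        coefficients={c: float(b) for c, b in zip(selected, coef[1:])},
        r_squared=r2,
        residual_sd=resid_sd,
    )


def _matrix_hash(matrix: AbundanceMatrix) -> str:
    h = hashlib.sha256()
    h.update("\n".join(matrix.ids).encode())
    h.update(np.ascontiguousarray(matrix.values.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()[:16]


def fit_easi(
    matrix: AbundanceMatrix,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> EASIModel:
    """Fit one stepwise model per panel channel on training replicates.

    ``matrix`` should contain only training replicates of the target
    compound; each channel is modeled on the other K-1 channels, and the
    consensus (mean/SD) is computed from the same rows.
    """
    if len(matrix.panel) < 2:
        raise ValueError("EASI needs a panel of at least 2 channels")
    ion_models = {
        c: fit_stepwise(matrix, c, p_enter=p_enter, p_remove=p_remove)
        for c in matrix.panel.channels
    }
    return EASIModel(
        panel=matrix.panel,
        ion_models=ion_models,
        consensus=consensus_from_matrix(matrix),
        settings={"p_enter": p_enter, "p_remove": p_remove},
        training_hash=_matrix_hash(matrix),
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _predict_vector(model: EASIModel, measured: np.ndarray, approach: str) -> np.ndarray:
    if approach == "consensus":
        return model.consensus.mean.copy()
    if approach == "easi":
        intercepts, B = model.coefficient_matrix()
        return intercepts + B @ measured
    raise ValueError(f"approach must be 'easi' or 'consensus', got {approach!r}")


def predict(
    model: EASIModel,
    measured: Sequence[float] | np.ndarray,
    approach: str,
    spectrum_id: str = "",
    truth: str = "unknown",
) -> PredictionRecord:
    """Predict panel abundances for one query under either approach.

    ``consensus`` returns the training means for every query; ``easi``
    evaluates each ion's linear model on the query's own measured covariates.
    Predictions are not clipped.  ``measured`` must be in panel order.
    """
    measured = np.asarray(measured, dtype=float)
    if len(measured) != len(model.panel):
        raise ValueError(
            f"query has {len(measured)} channels, panel expects {len(model.panel)}"
        )
    predicted = _predict_vector(model, measured, approach)
    return PredictionRecord(
        spectrum_id=spectrum_id,
        approach=approach,
        channels=model.panel.channels,
        measured=measured,
        predicted=predicted,
        residuals=predicted - measured,
        truth=truth,
    )


def predict_matrix(
    model: EASIModel, matrix: AbundanceMatrix, approach: str
) -> list[PredictionRecord]:
    """Predict every row of an abundance matrix (panel orders must match)."""
    if matrix.panel.channels != model.panel.channels:
        raise ValueError("matrix panel does not match the model panel")
    intercepts, B = model.coefficient_matrix()
    records = []
    for sid in matrix.ids:
        measured = matrix.row(sid)
        if approach == "consensus":
            predicted = model.consensus.mean.copy()
        elif approach == "easi":
            predicted = intercepts + B @ measured
        else:
            raise ValueError(f"approach must be 'easi' or 'consensus', got {approach!r}")
        records.append(
            PredictionRecord(
                spectrum_id=sid,
                approach=approach,
                channels=model.panel.channels,
                measured=measured,
                predicted=predicted,
                residuals=predicted - measured,
                truth=str(matrix.truth.loc[sid]),
            )
        )
    return records
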