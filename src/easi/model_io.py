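"""JSON persistence for trained models.

One file carries everything a scoring run needs: the peak panel, the per-ion
stepwise models (intercept, coefficient map, R-squared, residual SD), the
consensus statistics, the stepwise settings, a short hash of the training
matrix, and — optionally — the training covariance model for Mahalanobis
scoring.  Keys are sorted and floats written with full ``repr`` precision,
so the same model always serialises to identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .glm import EASIModel, IonModel
from .mahalanobis import CovarianceModel
from .peakmodel import ConsensusSpectrum, PeakPanel

__all__ = ["save_model", "load_model"]

_FORMAT = "easi-model/1"


def _model_to_dict(model: EASIModel) -> dict:
    doc = {
        "format": _FORMAT,
        "panel": list(model.panel.channels),
        "settings": dict(model.settings),
        "training_hash": model.training_hash,
        "consensus": {
            "mean": [float(v) for v in model.consensus.mean],
            "sd": [float(v) for v in model.consensus.sd],
            "n": model.consensus.n,
        },
        "ion_models": {
            str(c): {
                "intercept": m.intercept,
                "coefficients": {str(k): v for k, v in m.coefficients.items()},
                "r_squared": m.r_squared,
                "residual_sd": m.residual_sd,
            }
            for c, m in model.ion_models.items()
        },
    }
    if model.covariance is not None:
        cov: CovarianceModel = model.covariance
        doc["covariance"] = {
            "retained": list(cov.retained),
            "mean": [float(v) for v in cov.mean],
            "matrix": [[float(v) for v in row] for row in cov.covariance],
            "n": cov.n,
            "allow_pinv": cov.allow_pinv,
        }
    return doc


def save_model(model: EASIModel, path: str | Path) -> None:
    """Write a trained model (and any covariance model) as deterministic JSON."""
    Path(path).write_text(
        json.dumps(_model_to_dict(model), sort_keys=True, indent=1), encoding="utf-8"
    )


def load_model(path: str | Path) -> EASIModel:
    """Read a model file written by :func:`save_model`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not an EASI model file")
    panel = PeakPanel(tuple(doc["panel"]))
    consensus = ConsensusSpectrum(
        channels=panel.channels,
        mean=np.asarray(doc["consensus"]["mean"]),
        sd=np.asarray(doc["consensus"]["sd"]),
        n=int(doc["consensus"]["n"]),
    )
    ion_models = {
        int(c): IonModel(
            target=int(c),
            intercept=float(m["intercept"]),
            coefficients={int(k): float(v) for k, v in m["coefficients"].items()},
            r_squared=float(m["r_squared"]),
            residual_sd=float(m["residual_sd"]),
        )
        for c, m in doc["ion_models"].items()
    }
    covariance = None
    if "covariance" in doc:
        c = doc["covariance"]
        covariance = CovarianceModel(
            panel_channels=panel.channels,
            retained=tuple(int(v) for v in c["retained"]),
            mean=np.asarray(c["mean"]),
            covariance=np.asarray(c["matrix"]),
            n=int(c["n"]),
            allow_pinv=bool(c.get("allow_pinv", False)),
        )
    return EASIModel(
        panel=panel,
        ion_models=ion_models,
        consensus=consensus,
        settings=doc.get("settings", {}),
        training_hash=doc.get("training_hash", ""),
        covariance=covariance,
    )
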