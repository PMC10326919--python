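"""Consensus spectra, peak panels and labeled abundance matrices.

The traditional library-matching baseline treats the mean spectrum of a set
of replicate known positives as the exemplar against which every query is
compared.  This module builds that consensus, selects the panel of the K most
abundant fragment channels (K = 20 in the reference workflow), and lays
replicate spectra out as an N x K abundance matrix with truth labels, which
is the common input of the modeling and distance modules.

A panel channel missing from a spectrum is recorded as a true zero, not as
missing data: the absence of an expected fragment is itself evidence against
an identification (the "reverse search" logic of classical library matching).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import NominalSpectrum, TRUTH_LABELS

__all__ = [
    "PeakPanel",
    "ConsensusSpectrum",
    "AbundanceMatrix",
    "build_consensus",
    "consensus_from_matrix",
    "select_top_k",
    "assemble_matrix",
]


@dataclass(frozen=True)
class PeakPanel:
    """Ordered list of nominal m/z channels, descending consensus abundance."""

    channels: tuple[int, ...]

    def __post_init__(self) -> None:
        chans = tuple(int(c) for c in self.channels)
        object.__setattr__(self, "channels", chans)
        if len(chans) < 1:
            raise ValueError("panel must contain at least one channel")
        if len(set(chans)) != len(chans):
            raise ValueError("panel channels must be unique")

    def __len__(self) -> int:
        return len(self.channels)

    def index_of(self, channel: int) -> int:
        return self.channels.index(int(channel))


@dataclass(frozen=True)
class ConsensusSpectrum:
    """Per-channel mean and sample standard deviation of training replicates."""

    channels: tuple[int, ...]
    mean: np.ndarray  # % of base peak
    sd: np.ndarray    # % of base peak, n-1 denominator
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.n < 2:
            raise ValueError("a consensus needs at least 2 training spectra")
        if np.any(self.mean < 0) or np.any(self.mean > 100):
            raise ValueError("consensus means must lie in [0, 100]")
        if np.any(self.sd < 0):
            raise ValueError("consensus standard deviations must be non-negative")

    @property
    def zero_variance(self) -> np.ndarray:
        """Boolean mask of channels constant across the training replicates.

        The base peak (pinned at 100 by normalisation) is the typical case;
        downstream modules decide how to treat such channels.
        """
        return self.sd == 0.0


@dataclass
class AbundanceMatrix:
    """N spectra x K panel channels of percent-of-base-peak abundances.

    ``values`` is a DataFrame indexed by spectrum id with integer m/z
    columns in panel order; ``truth`` is an aligned Series of truth labels.
    """

    values: pd.DataFrame
    truth: pd.Series
    panel: PeakPanel

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != self.panel.channels:
            raise ValueError("matrix columns must equal the panel channels, in order")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate spectrum ids: {dupes}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if not self.truth.index.equals(self.values.index):
            raise ValueError("truth labels must align with the matrix rows")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def row(self, spectrum_id: str) -> np.ndarray:
        return self.values.loc[spectrum_id].to_numpy(dtype=float)

    def subset(self, truth: str) -> "AbundanceMatrix":
        """Rows restricted to one truth class."""
        if truth not in TRUTH_LABELS:
            raise ValueError(f"unknown truth label {truth!r}")
        mask = self.truth == truth
        return AbundanceMatrix(self.values[mask], self.truth[mask], self.panel)

    def to_csv(self, path: str | Path) -> None:
        """Serialise as wide CSV: spectrum_id, truth, then m/z columns."""
        df = self.values.copy()
        df.insert(0, "truth", self.truth)
        df.insert(0, "spectrum_id", df.index)
        df.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbundanceMatrix":
        df = pd.read_csv(path)
        if "spectrum_id" not in df.columns or "truth" not in df.columns:
            raise ValueError("abundance CSV needs 'spectrum_id' and 'truth' columns")
        df = df.set_index("spectrum_id")
        truth = df.pop("truth")
        df.columns = [int(float(c)) for c in df.columns]
        panel = PeakPanel(tuple(df.columns))
        return cls(df.astype(float), truth, panel)


def _abundance_rows(
    spectra: Sequence[NominalSpectrum], channels: Sequence[int]
) -> np.ndarray:
    """Stack spectra over ``channels``; absent channels contribute 0."""
    return np.array(
        [[s.abundance(c) for c in channels] for s in spectra], dtype=float
    )


def build_consensus(
    training: Sequence[NominalSpectrum], panel: PeakPanel
) -> ConsensusSpectrum:
    """Arithmetic mean and sample SD of the panel abundances of replicates."""
    if len(training) < 2:
        raise ValueError("need at least 2 training spectra for a consensus")
    rows = _abundance_rows(training, panel.channels)
    return ConsensusSpectrum(
        channels=panel.channels,
        mean=rows.mean(axis=0),
        sd=rows.std(axis=0, ddof=1),
        n=len(training),
    )


def consensus_from_matrix(matrix: AbundanceMatrix) -> ConsensusSpectrum:
    """Consensus computed from an already-assembled abundance matrix."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows for a consensus")
    vals = matrix.values.to_numpy(dtype=float)
    return ConsensusSpectrum(
        channels=matrix.panel.channels,
        mean=vals.mean(axis=0),
        sd=vals.std(axis=0, ddof=1),
        n=len(matrix),
    )


def select_top_k(training: Sequence[NominalSpectrum], k: int) -> PeakPanel:
    """The k channels with the largest mean abundance across ``training``.

    Ordered by descending mean abundance; ties broken by ascending m/z so the
    panel is deterministic.  Duplicating every training spectrum leaves the
    panel unchanged (means are unaffected).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    union = sorted({c for s in training for c in s.channels})
    if len(union) < k:
        raise ValueError(f"k={k} exceeds the {len(union)} available channels")
    rows = _abundance_rows(training, union)
    means = rows.mean(axis=0)
    order = sorted(range(len(union)), key=lambda i: (-means[i], union[i]))
    return PeakPanel(tuple(union[i] for i in order[:k]))


def assemble_matrix(
    spectra: Sequence[NominalSpectrum], panel: PeakPanel
) -> AbundanceMatrix:
    """Lay spectra out as rows over the panel channels.

    Panel channels absent from a spectrum are filled with 0; channels outside
    the panel are dropped.  Duplicate spectrum ids raise.
    """
    ids = [s.meta.spectrum_id for s in spectra]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate spectrum ids: {dupes}")
    values = pd.DataFrame(
        _abundance_rows(spectra, panel.channels),
        index=pd.Index(ids, name="spectrum_id"),
        columns=list(panel.channels),
    )
    truth = pd.Series([s.meta.truth for s in spectra], index=values.index, name="truth")
    return AbundanceMatrix(values, truth, panel)
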