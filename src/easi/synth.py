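"""Synthetic replicate EI spectra with the covariance structure EASI assumes.

Replicate spectra of one compound are generated from a one-dimensional
latent factor E — an effective internal-energy / instrument-state axis —
with each channel's raw intensity drawn as ``alpha_i + b_i * E + noise``,
floored at zero.  Because every channel responds linearly to the same latent
factor, normalised fragment abundances co-vary strongly (pairwise
correlations typically above 0.9), which is the empirical signature of real
replicate EI spectra that the per-ion linear models exploit.

Three spectrum populations are available:

* replicates of the target compound (``simulate_replicates``), optionally
  with the latent mean shifted to emulate a different laboratory or
  instrument epoch (``simulate_lab_shift``);
* spectrally distinct negatives: the same channels carrying a permuted
  intensity pattern driven by an independent latent factor;
* diastereomer-like negatives: generated by the positive law but with
  designated channel-pair abundance ratios multiplied by shift factors
  (defaults emulate the 94/96 and 152/155 ratio differences that separate
  cocaine from its diastereomers).

The default panel mimics cocaine's fragment channels so examples read
naturally; the intensity values themselves are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectra import RawSpectrum, SpectrumMeta

__all__ = [
    "GeneratorSpec",
    "DistinctNegativeSpec",
    "default_spec",
    "simulate_replicates",
    "simulate_lab_shift",
    "simulate_negatives",
]

NEGATIVE_KINDS = ("distinct", "diastereomer")


@dataclass(frozen=True)
class DistinctNegativeSpec:
    """A spectrally distinct negative compound: own intensities and slopes."""

    channels: tuple[int, ...]
    alphas: tuple[float, ...]
    slopes: tuple[float, ...]
    compound: str = "distinct_negative"

    def __post_init__(self) -> None:
        if not (len(self.channels) == len(self.alphas) == len(self.slopes)):
            raise ValueError("channels, alphas and slopes must have equal length")
        if any(a < 0 for a in self.alphas):
            raise ValueError("alphas must be non-negative")


@dataclass(frozen=True)
class GeneratorSpec:
    """Generative law for replicate spectra of the target compound.

    ``alphas`` are raw channel intensities at latent E = 0 and ``slopes``
    the per-channel response to E (raw units per latent unit).  The latent
    factor is Gaussian with ``latent_mean``/``latent_sd`` per batch;
    ``noise_sd`` is additive Gaussian measurement noise in raw units,
    floored at zero.  ``diastereomer_shifts`` maps ``(channel, partner)``
    pairs to the factor applied to the first channel's intensity, shifting
    that pair's abundance ratio.
    """

    channels: tuple[int, ...]
    alphas: tuple[float, ...]
    slopes: tuple[float, ...]
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    noise_sd: float = 2.0
    compound: str = "cocaine_like"
    diastereomer_shifts: Mapping[tuple[int, int], float] = field(default_factory=dict)
    diastereomer_compound: str = "diastereomer_like"
    distinct: DistinctNegativeSpec | None = None

    def __post_init__(self) -> None:
        if not (len(self.channels) == len(self.alphas) == len(self.slopes)):
            raise ValueError("channels, alphas and slopes must have equal length")
        if any(a < 0 for a in self.alphas):
            raise ValueError("alphas must be non-negative")
        if self.noise_sd < 0 or self.latent_sd < 0:
            raise ValueError("noise_sd and latent_sd must be non-negative")
        shifts = {}
        for pair, factor in dict(self.diastereomer_shifts).items():
            pair = (int(pair[0]), int(pair[1]))
            if factor <= 0:
                raise ValueError("ratio shift factors must be positive")
            if pair[0] not in self.channels or pair[1] not in self.channels:
                raise ValueError(f"shift pair {pair} not in the channel list")
            shifts[pair] = float(factor)
        object.__setattr__(self, "diastereomer_shifts", shifts)

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "channels": list(self.channels),
            "alphas": list(self.alphas),
            "slopes": list(self.slopes),
            "latent_mean": self.latent_mean,
            "latent_sd": self.latent_sd,
            "noise_sd": self.noise_sd,
            "compound": self.compound,
            "diastereomer_compound": self.diastereomer_compound,
            "diastereomer_shifts": [
                {"pair": list(pair), "factor": factor}
                for pair, factor in self.diastereomer_shifts.items()
            ],
        }
        if self.distinct is not None:
            doc["distinct"] = {
                "channels": list(self.distinct.channels),
                "alphas": list(self.distinct.alphas),
                "slopes": list(self.distinct.slopes),
                "compound": self.distinct.compound,
            }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        distinct = None
        if "distinct" in doc:
            d = doc["distinct"]
            distinct = DistinctNegativeSpec(
                channels=tuple(d["channels"]),
                alphas=tuple(d["alphas"]),
                slopes=tuple(d["slopes"]),
                compound=d.get("compound", "distinct_negative"),
            )
        shifts = {
            tuple(item["pair"]): item["factor"]
            for item in doc.get("diastereomer_shifts", [])
        }
        return cls(
            channels=tuple(doc["channels"]),
            alphas=tuple(doc["alphas"]),
            slopes=tuple(doc["slopes"]),
            latent_mean=doc.get("latent_mean", 0.0),
            latent_sd=doc.get("latent_sd", 1.0),
            noise_sd=doc.get("noise_sd", 2.0),
            compound=doc.get("compound", "cocaine_like"),
            diastereomer_shifts=shifts,
            diastereomer_compound=doc.get("diastereomer_compound", "diastereomer_like"),
            distinct=distinct,
        )


# Default cocaine-like panel: channel 82 is the (constant) base peak; most
# slopes share a sign so normalised abundances correlate positively, with two
# anticorrelated channels (77, 105) for realism.
_DEFAULT = {
    # channel: (alpha, slope)
    82: (1000.0, 0.0),
    182: (750.0, 45.0),
    83: (420.0, 18.0),
    94: (400.0, 25.0),
    105: (380.0, -20.0),
    77: (350.0, -22.0),
    96: (300.0, 15.0),
    303: (280.0, 20.0),
    97: (260.0, 12.0),
    272: (240.0, 16.0),
    198: (230.0, 14.0),
    152: (210.0, 12.0),
    42: (200.0, 10.0),
    51: (180.0, 11.0),
    55: (170.0, 9.0),
    67: (160.0, 8.0),
    119: (150.0, 8.0),
    122: (140.0, 7.0),
    155: (130.0, 7.0),
    181: (120.0, 6.0),
}


def default_spec() -> GeneratorSpec:
    """The stock cocaine-like generator used by examples and quick starts."""
    channels = tuple(_DEFAULT)
    alphas = tuple(_DEFAULT[c][0] for c in channels)
    slopes = tuple(_DEFAULT[c][1] for c in channels)
    # distinct negative: same channels, reversed intensity/slope assignment,
    # so the pattern is decorrelated from the positive compound but no panel
    # channel is ever entirely absent.
    distinct = DistinctNegativeSpec(
        channels=channels,
        alphas=tuple(reversed(alphas)),
        slopes=tuple(abs(s) for s in reversed(slopes)),
        compound="distinct_negative",
    )
    return GeneratorSpec(
        channels=channels,
        alphas=alphas,
        slopes=slopes,
        latent_mean=0.0,
        latent_sd=1.0,
        noise_sd=2.0,
        compound="cocaine_like",
        diastereomer_shifts={(94, 96): 0.6, (152, 155): 1.5},
        diastereomer_compound="diastereomer_like",
        distinct=distinct,
    )


def _simulate(
    channels: Sequence[int],
    alphas: np.ndarray,
    slopes: np.ndarray,
    latent_mean: float,
    latent_sd: float,
    noise_sd: float,
    n: int,
    rng: np.random.Generator,
    *,
    compound: str,
    truth: str,
    source: str,
    id_prefix: str,
    channel_factors: Mapping[int, float] | None = None,
) -> list[RawSpectrum]:
    factors = np.array(
        [channel_factors.get(c, 1.0) if channel_factors else 1.0 for c in channels]
    )
    spectra = []
    for i in range(n):
        latent = rng.normal(latent_mean, latent_sd)
        noise = rng.normal(0.0, noise_sd, size=len(channels)) if noise_sd > 0 else 0.0
        intensities = np.clip((alphas + slopes * latent) * factors + noise, 0.0, None)
        peaks = tuple(
            (float(c), float(v)) for c, v in zip(channels, intensities)
        )
        meta = SpectrumMeta(
            spectrum_id=f"{id_prefix}-{i:04d}",
            compound=compound,
            truth=truth,
            source=source,
        )
        spectra.append(RawSpectrum(peaks=peaks, meta=meta))
    return spectra


def simulate_replicates(
    spec: GeneratorSpec,
    n: int,
    seed: int,
    *,
    source: str = "lab1",
    id_prefix: str = "pos",
) -> list[RawSpectrum]:
    """Draw ``n`` replicate spectra of the target compound (known positives).

    Deterministic under a fixed seed: the same seed yields bit-identical
    output.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return _simulate(
        spec.channels,
        np.asarray(spec.alphas),
        np.asarray(spec.slopes),
        spec.latent_mean,
        spec.latent_sd,
        spec.noise_sd,
        n,
        rng,
        compound=spec.compound,
        truth="known_positive",
        source=source,
        id_prefix=id_prefix,
    )


def simulate_lab_shift(
    spec: GeneratorSpec,
    delta: float,
    n: int,
    seed: int,
    *,
    source: str = "lab_shifted",
    id_prefix: str = "shift",
) -> list[RawSpectrum]:
    """Replicates under the same law with the latent mean offset by ``delta``.

    Emulates spectra of the same compound collected on a different
    instrument or in a different laboratory: the systematic state of the
    instrument moves, the linear inter-ion relationships do not.
    """
    shifted = replace(spec, latent_mean=spec.latent_mean + delta)
    return simulate_replicates(shifted, n, seed, source=source, id_prefix=id_prefix)


def simulate_negatives(
    spec: GeneratorSpec,
    kind: str,
    n: int,
    seed: int,
    *,
    source: str = "lab1",
    id_prefix: str | None = None,
) -> list[RawSpectrum]:
    """Draw ``n`` known-negative spectra of the requested kind.

    ``distinct`` uses the independent negative-compound law from
    ``spec.distinct``; ``diastereomer`` applies the positive law with the
    configured channel-pair ratio shifts.
    """
    if kind not in NEGATIVE_KINDS:
        raise ValueError(f"kind must be one of {NEGATIVE_KINDS}")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if kind == "distinct":
        if spec.distinct is None:
            raise ValueError("generator spec has no distinct-negative specification")
        d = spec.distinct
        return _simulate(
            d.channels,
            np.asarray(d.alphas),
            np.asarray(d.slopes),
            spec.latent_mean,
            spec.latent_sd,
            spec.noise_sd,
            n,
            rng,
            compound=d.compound,
            truth="known_negative",
            source=source,
            id_prefix=id_prefix or "neg-distinct",
        )
    if not spec.diastereomer_shifts:
        raise ValueError("generator spec has no diastereomer ratio shifts")
    factors = {pair[0]: f for pair, f in spec.diastereomer_shifts.items()}
    return _simulate(
        spec.channels,
        np.asarray(spec.alphas),
        np.asarray(spec.slopes),
        spec.latent_mean,
        spec.latent_sd,
        spec.noise_sd,
        n,
        rng,
        compound=spec.diastereomer_compound,
        truth="known_negative",
        source=source,
        id_prefix=id_prefix or "neg-diastereomer",
        channel_factors=factors,
    )
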