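"""Reading, writing, binning and normalising unit-resolution EI mass spectra.

Spectra move through three representations:

* a :class:`RawSpectrum` holds centroided peaks as ``(m/z, intensity)`` pairs
  in arbitrary instrument units, exactly as parsed from an MSP or CSV file;
* :func:`bin_to_nominal` sums intensities into integer-Da channels
  (round-half-up, conserving ion current within a bin);
* a :class:`NominalSpectrum` is the normalised form used everywhere
  downstream: integer m/z channels holding relative abundances as percent of
  the base peak, whose abundance is exactly 100.

Metadata (spectrum id, compound, truth class, source laboratory) rides along
unchanged.  Truth labels classify spectra for benchmarking: ``known_positive``
replicates of the target compound, ``known_negative`` everything else, and
``unknown`` when no ground truth is recorded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TRUTH_LABELS",
    "SpectrumMeta",
    "RawSpectrum",
    "NominalSpectrum",
    "ParseError",
    "read_msp",
    "write_msp",
    "read_peak_csv",
    "bin_to_nominal",
    "normalize_to_base_peak",
    "nominalize",
]

TRUTH_LABELS = ("known_positive", "known_negative", "unknown")

#: fixed precision used by all text writers
_FMT = "{:.6g}"


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted; names the line."""


@dataclass(frozen=True)
class SpectrumMeta:
    """Identifying metadata carried by every spectrum."""

    spectrum_id: str
    compound: str = ""
    truth: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.spectrum_id:
            raise ValueError("spectrum_id must be non-empty")
        if self.truth not in TRUTH_LABELS:
            raise ValueError(
                f"truth must be one of {TRUTH_LABELS}, got {self.truth!r}"
            )


@dataclass(frozen=True)
class RawSpectrum:
    """A centroided spectrum in raw intensity units.

    ``peaks`` is a tuple of ``(mz, intensity)`` with ``mz > 0`` and
    ``intensity >= 0``; zero-intensity peaks are legal and preserved by the
    writers.
    """

    peaks: tuple[tuple[float, float], ...]
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple((float(m), float(i)) for m, i in self.peaks))
        for mz, inten in self.peaks:
            if not mz > 0:
                raise ValueError(f"m/z must be positive, got {mz}")
            if inten < 0:
                raise ValueError(f"intensity must be non-negative, got {inten}")


@dataclass(frozen=True)
class NominalSpectrum:
    """Integer-Da channels holding abundances in percent of the base peak."""

    channels: Mapping[int, float]
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        chans = {int(k): float(v) for k, v in self.channels.items()}
        object.__setattr__(self, "channels", chans)
        if chans:
            if any(v < 0 for v in chans.values()):
                raise ValueError("abundances must be non-negative")
            if max(chans.values()) != 100.0:
                raise ValueError("base peak of a NominalSpectrum must be exactly 100")

    def abundance(self, channel: int) -> float:
        """Relative abundance at ``channel``; absent channels read as 0."""
        return self.channels.get(int(channel), 0.0)


# ---------------------------------------------------------------------------
# MSP (NIST text) format
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^([A-Za-z][A-Za-z0-9 _]*):\s*(.*)$")
_KV_RE = re.compile(r"(\w+)=(\S+)")


def _meta_from_headers(headers: dict[str, str], line_no: int) -> SpectrumMeta:
    if "name" not in headers:
        raise ParseError(f"line {line_no}: record is missing a 'Name:' header")
    fields = {"compound": "", "truth": "unknown", "source": ""}
    for key, value in _KV_RE.findall(headers.get("comment", "")):
        if key in fields:
            fields[key] = value
    if fields["truth"] not in TRUTH_LABELS:
        raise ParseError(
            f"line {line_no}: invalid truth label {fields['truth']!r} in Comment"
        )
    return SpectrumMeta(spectrum_id=headers["name"], **fields)


def read_msp(path: str | Path) -> list[RawSpectrum]:
    """Read an MSP file into a list of :class:`RawSpectrum`, order preserved.

    The dialect accepted: ``Name:`` (required) plus optional ``Comment:`` and
    ``Num Peaks:`` headers, peak lines of whitespace- or semicolon-separated
    ``mz intensity`` pairs, records separated by blank lines.  Compound, truth
    and source metadata are carried as ``key=value`` tokens in the comment.
    An empty file yields an empty list; a malformed peak line raises
    :class:`ParseError` naming the line number.
    """
    spectra: list[RawSpectrum] = []
    headers: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    start_line = 0

    def flush(end_line: int) -> None:
        nonlocal headers, peaks
        if not headers and not peaks:
            return
        meta = _meta_from_headers(headers, start_line or end_line)
        if "num peaks" in headers:
            try:
                declared = int(headers["num peaks"])
            except ValueError as exc:
                raise ParseError(
                    f"line {start_line}: bad 'Num Peaks' value {headers['num peaks']!r}"
                ) from exc
            if declared != len(peaks):
                raise ParseError(
                    f"line {start_line}: 'Num Peaks: {declared}' but {len(peaks)} peaks found"
                )
        spectra.append(RawSpectrum(peaks=tuple(peaks), meta=meta))
        headers, peaks = {}, []

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line_no, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            flush(line_no)
            start_line = 0
            continue
        if not headers and not peaks:
            start_line = line_no
        m = _HEADER_RE.match(stripped)
        if m and not peaks:
            headers[m.group(1).strip().lower()] = m.group(2).strip()
            continue
        tokens = stripped.replace(";", " ").split()
        if len(tokens) % 2 != 0:
            raise ParseError(f"line {line_no}: malformed peak line {stripped!r}")
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise ParseError(
                f"line {line_no}: malformed peak line {stripped!r}"
            ) from exc
        peaks.extend(zip(values[0::2], values[1::2]))
    flush(len(lines))
    return spectra


def write_msp(spectra: Sequence[RawSpectrum], path: str | Path) -> None:
    """Write spectra as MSP text (UTF-8, 6 significant digits).

    ``read_msp(write_msp(S))`` reproduces peak lists and metadata at the
    printed precision.
    """
    out: list[str] = []
    for spec in spectra:
        meta = spec.meta
        out.append(f"Name: {meta.spectrum_id}")
        out.append(
            "Comment: "
            f"compound={meta.compound or 'unspecified'} "
            f"truth={meta.truth} source={meta.source or 'unspecified'}"
        )
        out.append(f"Num Peaks: {len(spec.peaks)}")
        for mz, inten in spec.peaks:
            out.append(f"{_FMT.format(mz)} {_FMT.format(inten)}")
        out.append("")
    Path(path).write_text("\n".join(out), encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV peak tables
# ---------------------------------------------------------------------------

def read_peak_csv(path: str | Path) -> list[RawSpectrum]:
    """Read a CSV peak table (header required) into raw spectra.

    Two dialects are auto-detected from the header:

    * long — columns ``spectrum_id, mz, intensity`` plus optional
      ``compound, truth, source``;
    * wide — one row per spectrum: ``spectrum_id`` (plus the optional
      metadata columns) followed by integer m/z column headers.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "spectrum_id" not in cols:
        raise ParseError(f"{path}: CSV must have a 'spectrum_id' column")

    def meta_for(row: pd.Series, sid: str) -> SpectrumMeta:
        return SpectrumMeta(
            spectrum_id=str(sid),
            compound=str(row[cols["compound"]]) if "compound" in cols else "",
            truth=str(row[cols["truth"]]) if "truth" in cols else "unknown",
            source=str(row[cols["source"]]) if "source" in cols else "",
        )

    if "mz" in cols and "intensity" in cols:  # long format
        spectra = []
        for sid, group in df.groupby(cols["spectrum_id"], sort=False):
            peaks = tuple(
                zip(group[cols["mz"]].astype(float), group[cols["intensity"]].astype(float))
            )
            spectra.append(RawSpectrum(peaks=peaks, meta=meta_for(group.iloc[0], sid)))
        return spectra

    # wide format: remaining columns must parse as m/z values
    meta_cols = {cols[k] for k in ("spectrum_id", "compound", "truth", "source") if k in cols}
    mz_cols = [c for c in df.columns if c not in meta_cols]
    try:
        mz_values = [float(c) for c in mz_cols]
    except ValueError as exc:
        raise ParseError(
            f"{path}: wide-format columns must be numeric m/z headers"
        ) from exc
    spectra = []
    for _, row in df.iterrows():
        peaks = tuple(
            (mz, float(row[c])) for mz, c in zip(mz_values, mz_cols) if float(row[c]) != 0.0
        )
        spectra.append(RawSpectrum(peaks=peaks, meta=meta_for(row, row[cols["spectrum_id"]])))
    return spectra


# ---------------------------------------------------------------------------
# Binning and normalisation
# ---------------------------------------------------------------------------

def normalize_to_base_peak(channels: Mapping[int, float]) -> dict[int, float]:
    """Scale channel intensities so the largest equals exactly 100.

    Idempotent and scale-invariant; raises ``ValueError`` on an all-zero or
    empty spectrum (no base peak to normalise to).
    """
    if not channels:
        raise ValueError("cannot normalise an empty spectrum")
    top = max(channels.values())
    if top <= 0:
        raise ValueError("cannot normalise an all-zero spectrum (no base peak)")
    return {int(k): (v / top) * 100.0 for k, v in channels.items()}


def bin_to_nominal(spectrum: RawSpectrum) -> NominalSpectrum:
    """Bin a raw spectrum to integer Da and normalise to the base peak.

    m/z values are rounded half-up to the nearest integer and intensities
    within a bin are summed, conserving ion current, before normalisation.
    """
    if not spectrum.peaks:
        raise ValueError("cannot bin a spectrum with no peaks")
    binned: dict[int, float] = {}
    for mz, inten in spectrum.peaks:
        chan = math.floor(mz + 0.5)  # round half-up
        binned[chan] = binned.get(chan, 0.0) + inten
    return NominalSpectrum(channels=normalize_to_base_peak(binned), meta=spectrum.meta)


def nominalize(spectra: Iterable[RawSpectrum]) -> list[NominalSpectrum]:
    """Convenience: bin and normalise a collection of raw spectra."""
    return [bin_to_nominal(s) for s in spectra]
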