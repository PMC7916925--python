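"""Impedance-spectrum data model, CSV I/O and 6 kHz feature extraction.

A spectrum is the LCR-meter reading of one egg at one contact position:
complex impedance Z(f) = R(f) + jX(f) sampled on a strictly increasing
frequency grid.  Four contact positions around the equator are averaged
pointwise before any analysis.  The classifier consumes the impedance
magnitude, resistance and reactance at 6 kHz together with the transient
decay rate derived from them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .transient import decay_rate, inductance_from_reactance

SPECTRUM_COLUMNS = ("frequency_hz", "resistance_ohm", "reactance_ohm")
MANIFEST_COLUMNS = ("sample_id", "position", "file", "label")
LABELS = ("gelled", "non_gelled", "unknown")

GELLED = "gelled"
NON_GELLED = "non_gelled"

#: feature frequency used throughout the analysis (Hz)
DEFAULT_FEATURE_FREQ = 6000.0


class SpectrumError(ValueError):
    """Raised for malformed spectra or spectrum files."""


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance samples for one egg at one contact position.

    Parameters
    ----------
    frequencies : array of float
        Strictly increasing grid, Hz, all positive.
    resistance : array of float
        Real part of Z at each grid point, ohm.
    reactance : array of float
        Imaginary part of Z at each grid point, ohm (negative for
        capacitive samples).
    sample_id : str
        Egg identifier.
    position : str
        Contact-position index "1".."4" or "averaged".
    label : str
        Gel state: "gelled", "non_gelled" or "unknown".
    """

    frequencies: np.ndarray
    resistance: np.ndarray
    reactance: np.ndarray
    sample_id: str = ""
    position: str = "1"
    label: str = "unknown"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        r = np.asarray(self.resistance, dtype=float)
        x = np.asarray(self.reactance, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise SpectrumError("frequency grid must be a non-empty 1-d array")
        if r.shape != f.shape or x.shape != f.shape:
            raise SpectrumError(
                "resistance and reactance must match the frequency grid length"
            )
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise SpectrumError("frequencies must be finite and positive")
        if np.any(np.diff(f) <= 0):
            raise SpectrumError("frequencies must be strictly increasing")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(x))):
            raise SpectrumError("resistance/reactance must be finite")
        if self.label not in LABELS:
            raise SpectrumError(f"unknown label {self.label!r}")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "resistance", r)
        object.__setattr__(self, "reactance", x)

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @property
    def impedance(self) -> np.ndarray:
        """Complex impedance Z = R + jX at each grid point."""
        return self.resistance + 1j * self.reactance

    @property
    def magnitude(self) -> np.ndarray:
        """|Z| = sqrt(R^2 + X^2) at each grid point."""
        return np.hypot(self.resistance, self.reactance)


@dataclass(frozen=True)
class FeatureVector:
    """Per-egg classification features evaluated at one frequency.

    ``decay_rate`` is the RLC transient attenuation constant alpha = R/(2|L|)
    with L taken from the net reactance at the feature frequency.
    """

    impedance_6k: float
    resistance_6k: float
    reactance_6k: float
    decay_rate: float
    sample_id: str = ""
    label: str = "unknown"

    def as_dict(self) -> dict[str, float]:
        return {
            "impedance_6k": self.impedance_6k,
            "resistance_6k": self.resistance_6k,
            "reactance_6k": self.reactance_6k,
            "decay_rate": self.decay_rate,
        }


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    position: str
    file: str
    label: str


@dataclass
class CohortManifest:
    """List of (sample id, position, spectrum file, label) rows.

    The (sample_id, position) pair is unique within a manifest.
    """

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.sample_id, e.position)
            if key in seen:
                raise SpectrumError(f"duplicate manifest entry for {key}")
            if e.label not in LABELS:
                raise SpectrumError(f"unknown label {e.label!r} in manifest")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)


def read_spectrum(path: str | Path, sample_id: str = "", position: str = "1",
                  label: str = "unknown") -> ImpedanceSpectrum:
    """Read a spectrum CSV with header ``frequency_hz,resistance_ohm,reactance_ohm``.

    Rows may appear in any order; the returned spectrum is sorted by
    frequency.  Duplicate frequencies, missing columns and non-numeric
    cells raise :class:`SpectrumError` naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectrumError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumError(f"{path}: missing column(s) {missing}")
    numeric = df[list(SPECTRUM_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SpectrumError(f"{path}: non-numeric cell at data row {row}")
    f = numeric["frequency_hz"].to_numpy()
    dup = pd.Series(f).duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SpectrumError(f"{path}: duplicate frequency at data row {row}")
    order = np.argsort(f, kind="stable")
    return ImpedanceSpectrum(
        frequencies=f[order],
        resistance=numeric["resistance_ohm"].to_numpy()[order],
        reactance=numeric["reactance_ohm"].to_numpy()[order],
        sample_id=sample_id or path.stem,
        position=position,
        label=label,
    )


def write_spectrum(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    """Write a spectrum as CSV in the canonical column order."""
    df = pd.DataFrame(
        {
            "frequency_hz": spectrum.frequencies,
            "resistance_ohm": spectrum.resistance,
            "reactance_ohm": spectrum.reactance,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV (``sample_id,position,file,label``)."""
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumError(f"{path}: missing manifest column(s) {missing}")
    entries = [
        ManifestEntry(r.sample_id, r.position, r.file, r.label)
        for r in df.itertuples()
    ]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.sample_id, e.position, e.file, e.label) for e in manifest.entries],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, index=False)


def average_positions(spectra: Sequence[ImpedanceSpectrum]) -> ImpedanceSpectrum:
    """Pointwise mean of R and X over contact positions of one egg.

    All spectra must share an identical frequency grid and sample id; no
    resampling is performed.  The result carries position ``"averaged"``.
    """
    if not spectra:
        raise SpectrumError("cannot average an empty list of spectra")
    ref = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.frequencies, ref.frequencies):
            raise SpectrumError("position spectra have mismatched frequency grids")
        if s.sample_id != ref.sample_id:
            raise SpectrumError("position spectra belong to different samples")
    r = np.mean([s.resistance for s in spectra], axis=0)
    x = np.mean([s.reactance for s in spectra], axis=0)
    return ImpedanceSpectrum(
        frequencies=ref.frequencies.copy(),
        resistance=r,
        reactance=x,
        sample_id=ref.sample_id,
        position="averaged",
        label=ref.label,
    )


def polar_decompose(R: float, X: float) -> tuple[float, float]:
    """Decompose Z = R + jX into (|Z|, theta) with theta = atan2(X, R).

    Round-trips exactly: R = |Z| cos(theta), X = |Z| sin(theta).
    """
    if R == 0 and X == 0:
        raise SpectrumError("phase undefined for Z = 0")
    return math.hypot(R, X), math.atan2(X, R)


def loss_factor(R: float, X: float) -> float:
    """Dielectric loss factor D = tan(delta) = R/|X|.

    delta = pi/2 - |theta| is the loss angle.  The magnitude of X is used
    so that capacitive samples (X < 0) report the conventional
    non-negative tan(delta).
    """
    if X == 0:
        raise SpectrumError("loss factor undefined for purely resistive sample (X = 0)")
    return R / abs(X)


def _loglinear_interp(freqs: np.ndarray, values: np.ndarray, f: float) -> float:
    """Linear interpolation of `values` in log10(frequency)."""
    return float(np.interp(math.log10(f), np.log10(freqs), values))


def extract_features(spectrum: ImpedanceSpectrum,
                     feature_freq: float = DEFAULT_FEATURE_FREQ) -> FeatureVector:
    """Evaluate (|Z|, R, X, alpha) at ``feature_freq``.

    R and X are interpolated separately, linearly in log10(f), when the
    feature frequency is not a grid point; |Z| is then recomputed from the
    interpolated Cartesian pair.  alpha = R/(2|L|) uses the inductance
    L = X/(2 pi f) implied by the net reactance.  Extrapolation outside
    the measured band is refused.
    """
    f = spectrum.frequencies
    if not (f[0] <= feature_freq <= f[-1]):
        raise SpectrumError(
            f"feature frequency {feature_freq} Hz outside measured band "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    idx = np.flatnonzero(f == feature_freq)
    if idx.size:
        i = int(idx[0])
        r = float(spectrum.resistance[i])
        x = float(spectrum.reactance[i])
    else:
        r = _loglinear_interp(f, spectrum.resistance, feature_freq)
        x = _loglinear_interp(f, spectrum.reactance, feature_freq)
    L = inductance_from_reactance(x, feature_freq)
    alpha = decay_rate(r, L) if L != 0 else math.nan
    return FeatureVector(
        impedance_6k=math.hypot(r, x),
        resistance_6k=r,
        reactance_6k=x,
        decay_rate=alpha,
        sample_id=spectrum.sample_id,
        label=spectrum.label,
    )


def features_from_positions(spectra: Iterable[ImpedanceSpectrum],
                            feature_freq: float = DEFAULT_FEATURE_FREQ) -> FeatureVector:
    """Average the position spectra of one egg, then extract features."""
    return extract_features(average_positions(list(spectra)), feature_freq)
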