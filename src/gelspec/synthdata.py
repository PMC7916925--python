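"""Seeded synthetic egg cohorts: spectra, labels and manifests.

Each synthetic egg is drawn from its class's fitted equivalent circuit
(series L-Warburg-C for a completely gelled egg, L-R1 + R2 parallel CPE
for an incompletely gelled one).  Egg-to-egg biological variation is
modelled as independent log-normal jitter of every magnitude parameter
around the class centre (default sd 0.15 decades).  The CPE exponent n
is a shape parameter, not a magnitude: it is perturbed additively with
a small sd (``EXPONENT_JITTER_SD`` times the log-magnitude jitter scale)
and clipped to (0, 1], which keeps every egg capacitive across the band.  Each of the four contact positions is
simulated separately with independent proportional complex measurement
noise (default sd 0.02 |Z| per quadrature component), then averaged, as
in the measurement protocol.

The default cohort is 30 + 30 training eggs and a 116-egg test cohort
(55 gelled / 61 non-gelled), 50 log-spaced frequencies over 2-300 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import circuit as ckt
from .spectra import (GELLED, NON_GELLED, CohortManifest, ImpedanceSpectrum,
                      ManifestEntry, average_positions, write_manifest,
                      write_spectrum)


class SynthError(ValueError):
    """Raised for invalid cohort specifications or output collisions."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of one synthetic cohort."""

    n_gelled_train: int = 30
    n_non_gelled_train: int = 30
    n_gelled_test: int = 55
    n_non_gelled_test: int = 61
    n_frequencies: int = 50
    f_min: float = 2e3
    f_max: float = 300e3
    jitter_dex: float = 0.15     # log10 sd of per-egg parameter jitter
    noise_sd: float = 0.02       # proportional complex noise, fraction of |Z|
    positions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_gelled_train, self.n_non_gelled_train,
                  self.n_gelled_test, self.n_non_gelled_test)
        if any(c < 0 for c in counts):
            raise SynthError("cohort counts must be non-negative")
        if self.jitter_dex < 0 or self.noise_sd < 0:
            raise SynthError("jitter and noise sds must be non-negative")
        if not (0 < self.f_min < self.f_max) or self.n_frequencies < 2:
            raise SynthError("invalid frequency grid")
        if self.positions < 1:
            raise SynthError("need at least one contact position")

    @property
    def n_test(self) -> int:
        return self.n_gelled_test + self.n_non_gelled_test

    def frequency_grid(self) -> np.ndarray:
        return ckt.default_frequency_grid(self.n_frequencies, self.f_min,
                                          self.f_max)


@dataclass(frozen=True)
class SyntheticEgg:
    """One simulated egg: its true circuit and measured spectra."""

    sample_id: str
    label: str
    network: ckt.CircuitNode
    position_spectra: tuple[ImpedanceSpectrum, ...]
    averaged: ImpedanceSpectrum


_CLASS_CENTERS = {
    GELLED: ckt.GELLED_PARAMS,
    NON_GELLED: ckt.NON_GELLED_PARAMS,
}


#: additive sd of CPE-exponent jitter per unit of magnitude jitter (dex);
#: with the default 0.15 dex this gives n ~ centre +- 0.02
EXPONENT_JITTER_SD = 0.02 / 0.15


def _jittered_network(state: str, spec: CohortSpec,
                      rng: np.random.Generator) -> ckt.CircuitNode:
    base = ckt.gelled_preset() if state == GELLED else ckt.non_gelled_preset()
    centers = _CLASS_CENTERS[state]
    drawn = {}
    for name, center in centers.items():
        if name == "CPE.n":
            # shape exponent: small additive perturbation, clipped physical
            value = center + rng.normal(0.0, EXPONENT_JITTER_SD * spec.jitter_dex)
            value = float(np.clip(value, 1e-3, 1.0))
        else:
            value = center * 10.0 ** rng.normal(0.0, spec.jitter_dex)
        drawn[name] = value
    return ckt.set_parameters(base, drawn)


def sample_egg(state: str, spec: CohortSpec, rng: np.random.Generator,
               sample_id: str = "egg") -> SyntheticEgg:
    """Draw one egg: jittered circuit plus noisy per-position spectra."""
    if state not in _CLASS_CENTERS:
        raise SynthError(f"unknown gel state {state!r}")
    net = _jittered_network(state, spec, rng)
    freqs = spec.frequency_grid()
    clean = ckt.simulate_spectrum(net, freqs, sample_id=sample_id,
                                  label=state)
    mag = clean.magnitude
    positions = []
    for k in range(spec.positions):
        noise_r = rng.normal(0.0, 1.0, size=len(freqs))
        noise_x = rng.normal(0.0, 1.0, size=len(freqs))
        positions.append(ImpedanceSpectrum(
            frequencies=freqs,
            resistance=clean.resistance + spec.noise_sd * mag * noise_r,
            reactance=clean.reactance + spec.noise_sd * mag * noise_x,
            sample_id=sample_id,
            position=str(k + 1),
            label=state,
        ))
    return SyntheticEgg(
        sample_id=sample_id,
        label=state,
        network=net,
        position_spectra=tuple(positions),
        averaged=average_positions(positions),
    )


def sample_cohort(spec: CohortSpec) -> tuple[list[SyntheticEgg], list[SyntheticEgg]]:
    """Draw the training and test cohorts in memory (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    train, test = [], []
    plan = [
        (train, GELLED, spec.n_gelled_train, "train_g"),
        (train, NON_GELLED, spec.n_non_gelled_train, "train_n"),
        (test, GELLED, spec.n_gelled_test, "test_g"),
        (test, NON_GELLED, spec.n_non_gelled_test, "test_n"),
    ]
    for bucket, state, count, prefix in plan:
        for i in range(count):
            bucket.append(sample_egg(state, spec, rng,
                                     sample_id=f"{prefix}{i+1:03d}"))
    return train, test


def generate_cohort(spec: CohortSpec, out_dir: str | Path,
                    ) -> tuple[CohortManifest, CohortManifest]:
    """Write a full cohort to disk; returns (train, test) manifests.

    Layout under ``out_dir``: per-position and position-averaged spectrum
    CSVs in ``spectra/``, ``train_manifest.csv`` (labels visible),
    ``test_manifest.csv`` (labels withheld) and ``test_truth.csv``.
    """
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    train, test = sample_cohort(spec)

    def write_egg(egg: SyntheticEgg, visible_label: str) -> list[ManifestEntry]:
        entries = []
        for s in (*egg.position_spectra, egg.averaged):
            rel = f"spectra/{egg.sample_id}_pos{s.position}.csv"
            path = out_dir / rel
            if path.exists():
                raise SynthError(f"output collision: {path}")
            write_spectrum(s, path)
            entries.append(ManifestEntry(egg.sample_id, s.position, rel,
                                         visible_label))
        return entries

    train_entries, test_entries, truth = [], [], []
    for egg in train:
        train_entries.extend(write_egg(egg, egg.label))
    for egg in test:
        test_entries.extend(write_egg(egg, "unknown"))
        truth.append((egg.sample_id, egg.label))

    train_manifest = CohortManifest(train_entries)
    test_manifest = CohortManifest(test_entries)
    write_manifest(train_manifest, out_dir / "train_manifest.csv")
    write_manifest(test_manifest, out_dir / "test_manifest.csv")
    (out_dir / "test_truth.csv").write_text(
        "sample_id,label\n" + "".join(f"{sid},{lab}\n" for sid, lab in truth)
    )
    return train_manifest, test_manifest
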