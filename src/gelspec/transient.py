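"""Dielectric and RLC resonance-circuit transient formulas.

An egg between the capacitor plates behaves like a series RLC circuit.
Its free response obeys L i'' + R i' + i/C = 0; in the under-damped
regime the current is an exponentially decaying cosine
i(t) = A exp(-alpha t) cos(omega_d t + theta), and the decay rate
alpha = R/(2|L|) discriminates gel states: a set gel dissipates the
transient slowly (small R relative to |X|), liquid albumen quickly.

Sign convention: an LCR meter reports the net reactance X = X_L - X_C,
which is negative for these capacitive samples, so the implied
inductance L = X/(2 pi f) is negative too.  All oscillator quantities
(alpha, omega_0) use |L| so they stay real and non-negative; the signed
literal formula is available via ``signed=True`` for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: vacuum permittivity, F/m
VACUUM_PERMITTIVITY = 8.85e-12


class TransientError(ValueError):
    """Raised for invalid transient-analysis inputs."""


@dataclass(frozen=True)
class ParallelPlateGeometry:
    """Parallel-plate capacitor geometry: C = eps' eps0 S / d."""

    relative_permittivity: float
    plate_area: float
    separation: float

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 0:
            raise TransientError("relative permittivity must be positive")
        if self.plate_area <= 0:
            raise TransientError("plate area must be positive")
        if self.separation <= 0:
            raise TransientError("plate separation must be positive")


@dataclass(frozen=True)
class RLCParameters:
    """Series RLC circuit values (R in ohm, L in henry, C in farad)."""

    R: float
    L: float
    C: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise TransientError("R must be non-negative")
        if self.L == 0:
            raise TransientError("L must be non-zero")
        if self.C <= 0:
            raise TransientError("C must be positive")


@dataclass(frozen=True)
class TransientSolution:
    """Damping summary of a series RLC circuit.

    alpha : decay rate (1/s); omega0 : natural frequency (rad/s);
    zeta = alpha/omega0 : damping factor; omega_d : damped frequency
    (rad/s), defined only in the under-damped regime zeta < 1.
    """

    alpha: float
    omega0: float
    zeta: float
    omega_d: float | None

    @property
    def under_damped(self) -> bool:
        return self.zeta < 1


def parallel_plate_capacitance(geom: ParallelPlateGeometry) -> float:
    """C = eps' * eps0 * S / d for a parallel-plate capacitor."""
    return (geom.relative_permittivity * VACUUM_PERMITTIVITY
            * geom.plate_area / geom.separation)


def inductance_from_reactance(X: float, f: float) -> float:
    """Inductance implied by net reactance: L = X / (2 pi f).

    Negative for net-capacitive samples (X < 0), matching what an LCR
    meter reports in inductance mode.
    """
    if f <= 0:
        raise TransientError("frequency must be positive")
    return X / (2 * math.pi * f)


def decay_rate(R: float, L: float, *, signed: bool = False) -> float:
    """Transient attenuation constant alpha = R / (2|L|), in 1/s.

    With ``signed=True`` the literal R/(2L) is returned instead, which is
    negative when L < 0 (net-capacitive sample).
    """
    if L == 0:
        raise TransientError("decay rate undefined for L = 0")
    if signed:
        return R / (2 * L)
    return R / (2 * abs(L))


def damping_parameters(p: RLCParameters) -> TransientSolution:
    """Natural frequency, damping factor and damped frequency of an RLC circuit.

    omega0 = 1/sqrt(|L| C), zeta = alpha/omega0; omega_d = omega0
    sqrt(1 - zeta^2) exists only when zeta < 1 (under-damped).
    """
    alpha = decay_rate(p.R, p.L)
    omega0 = 1.0 / math.sqrt(abs(p.L) * p.C)
    zeta = alpha / omega0
    omega_d = omega0 * math.sqrt(1 - zeta**2) if zeta < 1 else None
    return TransientSolution(alpha=alpha, omega0=omega0, zeta=zeta, omega_d=omega_d)


def transient_current(sol: TransientSolution, amplitude: float, phase: float,
                      t_grid: np.ndarray) -> np.ndarray:
    """Under-damped current trace i(t) = A exp(-alpha t) cos(omega_d t + theta).

    Only the under-damped branch (zeta < 1) is supported; over- and
    critically-damped circuits do not oscillate and are rejected.
    """
    if not sol.under_damped or sol.omega_d is None:
        raise TransientError(
            f"transient trace requires an under-damped circuit (zeta={sol.zeta:.4g} >= 1)"
        )
    t = np.asarray(t_grid, dtype=float)
    return amplitude * np.exp(-sol.alpha * t) * np.cos(sol.omega_d * t + phase)
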