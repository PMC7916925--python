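"""Complex nonlinear least-squares fitting of equivalent circuits.

The objective is the weighted sum of squared complex residuals

    F(p) = sum_f w_f |Z_model(f; p) - Z_obs(f)|^2

minimised over the free circuit parameters on a log10 scale (values span
picofarads to megaohms, so the search is performed in decades).  Modulus
weighting w_f = 1/|Z_obs(f)|^2 is the default: |Z| of an egg spans
several orders of magnitude across 2-300 kHz and unweighted residuals
would be dominated by the low-frequency arc.

Multi-start: ``n_starts`` Latin-hypercube draws inside the (log10) box
bounds, each refined with a trust-region reflective local solve; the
best local optimum wins.  Non-convergence is reported as data
(``converged=False``), not raised, so cohort-scale fitting can proceed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .circuit import (CircuitNode, from_dict, get_parameters, set_parameters,
                      simulate_spectrum, to_dict)
from .spectra import ImpedanceSpectrum

WEIGHTINGS = ("unit", "modulus", "proportional")


class FittingError(ValueError):
    """Raised for invalid fit specifications."""


@dataclass(frozen=True)
class FitSpec:
    """Template circuit plus search configuration for one fit.

    ``bounds`` maps each free parameter name (``"R1.R"`` style) to a
    positive, finite (lower, upper) box; parameters absent from
    ``bounds`` stay fixed at their template values.
    """

    template: CircuitNode
    bounds: dict[str, tuple[float, float]]
    weighting: str = "modulus"
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bounds:
            raise FittingError("at least one free parameter is required")
        known = set(get_parameters(self.template))
        for name, (lo, hi) in self.bounds.items():
            if name not in known:
                raise FittingError(f"unknown free parameter {name!r}")
            if not (0 < lo < hi and math.isfinite(hi)):
                raise FittingError(
                    f"bounds for {name!r} must be finite, positive and ordered"
                )
        if self.weighting not in WEIGHTINGS:
            raise FittingError(f"weighting must be one of {WEIGHTINGS}")
        if self.n_starts < 1:
            raise FittingError("n_starts must be >= 1")

    @property
    def free_names(self) -> list[str]:
        return sorted(self.bounds)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one circuit fit."""

    estimates: dict[str, float]
    residual: float
    per_frequency_residuals: np.ndarray
    converged: bool
    n_evaluations: int
    n_free: int

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "residual": self.residual,
            "per_frequency_residuals": [float(v) for v in
                                        self.per_frequency_residuals],
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "n_free": self.n_free,
        }


def _weights(spectrum: ImpedanceSpectrum, weighting: str) -> np.ndarray:
    mag2 = spectrum.resistance**2 + spectrum.reactance**2
    if weighting == "unit":
        return np.ones_like(mag2)
    if np.any(mag2 == 0):
        raise FittingError("zero |Z| sample incompatible with modulus weighting")
    # "proportional" and "modulus" coincide for complex residuals: both
    # scale each residual by 1/|Z_obs|.
    return 1.0 / mag2


def objective(spectrum: ImpedanceSpectrum, spec: FitSpec,
              values: dict[str, float]) -> tuple[float, np.ndarray]:
    """Weighted objective and per-frequency squared residuals at ``values``."""
    net = set_parameters(spec.template, values)
    model = simulate_spectrum(net, spectrum.frequencies)
    diff2 = ((model.resistance - spectrum.resistance) ** 2
             + (model.reactance - spectrum.reactance) ** 2)
    w = _weights(spectrum, spec.weighting)
    per_freq = w * diff2
    return float(per_freq.sum()), per_freq


def fit_circuit(spectrum: ImpedanceSpectrum, spec: FitSpec) -> FitResult:
    """Estimate the free circuit parameters of ``spec`` from a spectrum.

    Raises :class:`FittingError` when the spectrum has fewer points than
    free parameters.  Returns ``converged=False`` (never raises) when
    every start fails.
    """
    names = spec.free_names
    if len(spectrum) < len(names):
        raise FittingError(
            f"{len(names)} free parameters but only {len(spectrum)} frequencies"
        )
    lo = np.array([math.log10(spec.bounds[n][0]) for n in names])
    hi = np.array([math.log10(spec.bounds[n][1]) for n in names])
    w = _weights(spectrum, spec.weighting)
    sqrt_w = np.sqrt(w)
    z_obs = spectrum.impedance
    freqs = spectrum.frequencies

    def residual_vector(logp: np.ndarray) -> np.ndarray:
        values = {n: 10.0**v for n, v in zip(names, logp)}
        net = set_parameters(spec.template, values)
        model = simulate_spectrum(net, freqs)
        diff = model.impedance - z_obs
        return np.concatenate([sqrt_w * diff.real, sqrt_w * diff.imag])

    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    starts = lo + sampler.random(spec.n_starts) * (hi - lo)

    best = None
    n_evals = 0
    for x0 in starts:
        try:
            sol = least_squares(residual_vector, x0, bounds=(lo, hi),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-12)
        except Exception:
            continue
        n_evals += int(sol.nfev)
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return FitResult(
            estimates={n: math.nan for n in names},
            residual=math.inf,
            per_frequency_residuals=np.full(len(spectrum), math.inf),
            converged=False,
            n_evaluations=n_evals,
            n_free=len(names),
        )

    estimates = {n: 10.0**v for n, v in zip(names, best.x)}
    total, per_freq = objective(spectrum, spec, estimates)
    return FitResult(
        estimates=estimates,
        residual=total,
        per_frequency_residuals=per_freq,
        converged=True,
        n_evaluations=n_evals,
        n_free=len(names),
    )


def select_topology(spectrum: ImpedanceSpectrum,
                    candidates: Sequence[FitSpec]) -> tuple[int, list[FitResult]]:
    """Fit every candidate topology; return the best index and all results.

    Winner: smallest weighted residual among converged fits; ties broken
    by fewer free parameters, then lower candidate index.
    """
    if not candidates:
        raise FittingError("need at least one candidate topology")
    results = [fit_circuit(spectrum, c) for c in candidates]
    converged = [i for i, r in enumerate(results) if r.converged]
    if not converged:
        raise FittingError("no candidate topology converged")
    best = min(converged, key=lambda i: (results[i].residual,
                                         results[i].n_free, i))
    return best, results


def save_fit(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def spec_to_dict(spec: FitSpec) -> dict:
    return {
        "template": to_dict(spec.template),
        "bounds": {k: list(v) for k, v in spec.bounds.items()},
        "weighting": spec.weighting,
        "n_starts": spec.n_starts,
        "seed": spec.seed,
    }


def spec_from_dict(data: dict) -> FitSpec:
    return FitSpec(
        template=from_dict(data["template"]),
        bounds={k: (v[0], v[1]) for k, v in data["bounds"].items()},
        weighting=data.get("weighting", "modulus"),
        n_starts=int(data.get("n_starts", 8)),
        seed=int(data.get("seed", 0)),
    )


def decade_bounds(values: dict[str, float], half_width_decades: float = 0.5,
                  cap: dict[str, float] | None = None) -> dict[str, tuple[float, float]]:
    """Symmetric log-space bounds around known values.

    ``cap`` optionally clips upper bounds (e.g. CPE n <= 1).
    """
    out = {}
    for name, v in values.items():
        if v <= 0:
            raise FittingError(f"decade bounds need positive value for {name!r}")
        lo = v / 10**half_width_decades
        hi = v * 10**half_width_decades
        if cap and name in cap:
            hi = min(hi, cap[name])
        out[name] = (lo, hi)
    return out
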