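"""Equivalent-circuit element algebra and impedance-spectrum simulation.

Circuit networks are recursive series/parallel compositions of five
element kinds:

========== =============================== ==========================
kind       impedance Z(omega)              parameters
========== =============================== ==========================
resistor   R                               R (ohm)
inductor   j omega L                       L (henry)
capacitor  1 / (j omega C)                 C (farad)
warburg    tanh(B sqrt(j omega))           Y0 (1/(ohm sqrt(s))),
           / (Y0 sqrt(j omega))            B (sqrt(s))
cpe        1 / (Q0 (j omega)^n)            Q0 (s^n/ohm), n in [-1, 1]
========== =============================== ==========================

The Warburg element defaults to the finite-length ("short") diffusion
form above; set ``semi_infinite=True`` for Z = 1/(Y0 sqrt(j omega)).
The constant-phase element interpolates between an ideal capacitor
(n = 1), a pure resistor of 1/Q0 (n = 0) and an inductor (n = -1).

Two presets encode the fitted per-class circuits for preserved eggs: a
completely gelled egg is a series L-Warburg-C chain (diffusion-limited,
oblique Nyquist line), an incompletely gelled egg is L-R1 in series with
R2 parallel to a CPE (charge transfer, semicircular Nyquist arc).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np

from .spectra import ImpedanceSpectrum

ELEMENT_KINDS = ("resistor", "inductor", "capacitor", "warburg", "cpe")

# parameter names per element kind, in canonical order
ELEMENT_PARAMS = {
    "resistor": ("R",),
    "inductor": ("L",),
    "capacitor": ("C",),
    "warburg": ("Y0", "B"),
    "cpe": ("Q0", "n"),
}


class CircuitError(ValueError):
    """Raised for invalid circuit definitions or evaluation points."""


@dataclass(frozen=True)
class CircuitElement:
    """A single two-terminal circuit element.

    ``name`` optionally labels the element so a fitter can address its
    parameters (e.g. ``"R1.R"``).
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)
    name: str = ""
    semi_infinite: bool = False  # warburg only: drop the tanh factor

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise CircuitError(f"unknown element kind {self.kind!r}")
        expected = ELEMENT_PARAMS[self.kind]
        if set(self.params) != set(expected):
            raise CircuitError(
                f"{self.kind} expects parameters {expected}, got {tuple(self.params)}"
            )
        for key, value in self.params.items():
            if not math.isfinite(value):
                raise CircuitError(f"{self.kind}.{key} must be finite")
        if self.kind == "cpe":
            if not -1 <= self.params["n"] <= 1:
                raise CircuitError("CPE exponent n must lie in [-1, 1]")
            if self.params["Q0"] <= 0:
                raise CircuitError("CPE Q0 must be positive")
        elif self.kind == "warburg":
            if self.params["Y0"] <= 0 or self.params["B"] <= 0:
                raise CircuitError("Warburg Y0 and B must be positive")
        else:
            key = ELEMENT_PARAMS[self.kind][0]
            if self.params[key] <= 0:
                raise CircuitError(f"{self.kind} {key} must be positive")


@dataclass(frozen=True)
class Series:
    children: tuple["CircuitNode", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise CircuitError("series node needs at least one child")


@dataclass(frozen=True)
class Parallel:
    children: tuple["CircuitNode", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise CircuitError("parallel node needs at least one child")


CircuitNode = Union[CircuitElement, Series, Parallel]


def series(*children: CircuitNode) -> Series:
    return Series(tuple(children))


def parallel(*children: CircuitNode) -> Parallel:
    return Parallel(tuple(children))


def resistor(R: float, name: str = "") -> CircuitElement:
    return CircuitElement("resistor", {"R": R}, name=name)


def inductor(L: float, name: str = "") -> CircuitElement:
    return CircuitElement("inductor", {"L": L}, name=name)


def capacitor(C: float, name: str = "") -> CircuitElement:
    return CircuitElement("capacitor", {"C": C}, name=name)


def warburg(Y0: float, B: float = 1.0, name: str = "",
            semi_infinite: bool = False) -> CircuitElement:
    return CircuitElement("warburg", {"Y0": Y0, "B": B}, name=name,
                          semi_infinite=semi_infinite)


def cpe(Q0: float, n: float, name: str = "") -> CircuitElement:
    return CircuitElement("cpe", {"Q0": Q0, "n": n}, name=name)


def element_impedance(element: CircuitElement, f: float) -> complex:
    """Complex impedance of one element at frequency f (Hz).

    Complex powers and square roots use the principal branch; omega is in
    rad/s internally.
    """
    if not (f > 0 and math.isfinite(f)):
        raise CircuitError(f"frequency must be positive and finite, got {f}")
    omega = 2 * math.pi * f
    p = element.params
    if element.kind == "resistor":
        return complex(p["R"])
    if element.kind == "inductor":
        return 1j * omega * p["L"]
    if element.kind == "capacitor":
        return 1.0 / (1j * omega * p["C"])
    if element.kind == "cpe":
        return 1.0 / (p["Q0"] * (1j * omega) ** p["n"])
    # warburg
    s = np.sqrt(1j * omega)  # principal branch
    if element.semi_infinite:
        return complex(1.0 / (p["Y0"] * s))
    return complex(np.tanh(p["B"] * s) / (p["Y0"] * s))


def network_impedance(network: CircuitNode, f: float) -> complex:
    """Impedance of a series/parallel composition at frequency f (Hz)."""
    if isinstance(network, CircuitElement):
        return element_impedance(network, f)
    if isinstance(network, Series):
        return sum(network_impedance(c, f) for c in network.children)
    if isinstance(network, Parallel):
        admittance = 0j
        for c in network.children:
            z = network_impedance(c, f)
            if z == 0:
                return 0j  # short circuit dominates
            admittance += 1.0 / z
        if admittance == 0:
            raise CircuitError("parallel node with all branches open")
        return 1.0 / admittance
    raise CircuitError(f"not a circuit node: {network!r}")


def simulate_spectrum(network: CircuitNode, frequencies: Sequence[float],
                      sample_id: str = "", position: str = "1",
                      label: str = "unknown") -> ImpedanceSpectrum:
    """Forward-simulate R(f) and X(f) of a network over a frequency grid."""
    freqs = np.asarray(frequencies, dtype=float)
    z = np.array([network_impedance(network, float(f)) for f in freqs])
    return ImpedanceSpectrum(
        frequencies=freqs,
        resistance=z.real,
        reactance=z.imag,
        sample_id=sample_id,
        position=position,
        label=label,
    )


def default_frequency_grid(n_points: int = 50, f_min: float = 2e3,
                           f_max: float = 300e3) -> np.ndarray:
    """Log-spaced measurement grid over the 2-300 kHz band."""
    return np.logspace(math.log10(f_min), math.log10(f_max), n_points)


# -- fitted per-class circuits ------------------------------------------------
#
# The Warburg magnitude coefficient 4.786e6 ohm sqrt(s) is stored as the
# admittance Y0 = 1/4.786e6; the diffusion time constant B is not part of
# the fitted value set and defaults to 1 sqrt(s).

GELLED_PARAMS = {"L1.L": 218e-12, "W.Y0": 1.0 / 4.786e6, "W.B": 1.0,
                 "C1.C": 81.67e-12}
NON_GELLED_PARAMS = {"L1.L": 583.7e-6, "R1.R": 46.25, "R2.R": 298.3e3,
                     "CPE.Q0": 503.5e-12, "CPE.n": 0.8361}


def gelled_preset(B: float = 1.0) -> Series:
    """Series L - Warburg - C circuit of a completely gelled egg.

    L1 = 218 pH, Warburg magnitude 1/Y0 = 4.786 Mohm sqrt(s) (diffusion
    time constant B unreported by the fit, default 1 sqrt(s)),
    C1 = 81.67 pF.
    """
    return series(
        inductor(GELLED_PARAMS["L1.L"], name="L1"),
        warburg(GELLED_PARAMS["W.Y0"], B=B, name="W"),
        capacitor(GELLED_PARAMS["C1.C"], name="C1"),
    )


def non_gelled_preset() -> Series:
    """L - R1 series with R2 parallel CPE: an incompletely gelled egg.

    L1 = 583.7 uH, R1 = 46.25 ohm, R2 = 298.3 kohm,
    CPE Q0 = 503.5 ps^n/ohm with n = 0.8361 (capacitor-like, n > 0.8).
    """
    return series(
        inductor(NON_GELLED_PARAMS["L1.L"], name="L1"),
        resistor(NON_GELLED_PARAMS["R1.R"], name="R1"),
        parallel(
            resistor(NON_GELLED_PARAMS["R2.R"], name="R2"),
            cpe(NON_GELLED_PARAMS["CPE.Q0"], NON_GELLED_PARAMS["CPE.n"],
                name="CPE"),
        ),
    )


# -- parameter addressing and JSON round trip ---------------------------------

def iter_elements(network: CircuitNode) -> Iterator[CircuitElement]:
    """Depth-first iteration over the elements of a network."""
    if isinstance(network, CircuitElement):
        yield network
    else:
        for child in network.children:
            yield from iter_elements(child)


def parameter_names(network: CircuitNode) -> list[str]:
    """Addressable parameter names, ``<element name>.<param>``, in DFS order."""
    names = []
    for i, el in enumerate(iter_elements(network)):
        base = el.name or f"e{i}"
        names.extend(f"{base}.{p}" for p in ELEMENT_PARAMS[el.kind])
    return names


def get_parameters(network: CircuitNode) -> dict[str, float]:
    out = {}
    for i, el in enumerate(iter_elements(network)):
        base = el.name or f"e{i}"
        for p in ELEMENT_PARAMS[el.kind]:
            out[f"{base}.{p}"] = el.params[p]
    return out


def set_parameters(network: CircuitNode, values: dict[str, float]) -> CircuitNode:
    """Return a copy of the network with the named parameters replaced."""
    remaining = dict(values)
    counter = [0]

    def rebuild(node: CircuitNode) -> CircuitNode:
        if isinstance(node, CircuitElement):
            base = node.name or f"e{counter[0]}"
            counter[0] += 1
            params = dict(node.params)
            for p in ELEMENT_PARAMS[node.kind]:
                key = f"{base}.{p}"
                if key in remaining:
                    params[p] = remaining.pop(key)
            return CircuitElement(node.kind, params, name=node.name,
                                  semi_infinite=node.semi_infinite)
        children = tuple(rebuild(c) for c in node.children)
        return type(node)(children)

    result = rebuild(network)
    if remaining:
        raise CircuitError(f"unknown parameter name(s): {sorted(remaining)}")
    return result


def to_dict(network: CircuitNode) -> dict:
    """Serialize a network to the nested JSON schema."""
    if isinstance(network, CircuitElement):
        d = {"element": {"kind": network.kind, "params": dict(network.params)}}
        if network.name:
            d["element"]["name"] = network.name
        if network.semi_infinite:
            d["element"]["semi_infinite"] = True
        return d
    key = "series" if isinstance(network, Series) else "parallel"
    return {key: [to_dict(c) for c in network.children]}


def from_dict(data: dict) -> CircuitNode:
    """Deserialize a network from the nested JSON schema."""
    if "element" in data:
        e = data["element"]
        return CircuitElement(e["kind"], dict(e["params"]),
                              name=e.get("name", ""),
                              semi_infinite=e.get("semi_infinite", False))
    if "series" in data:
        return Series(tuple(from_dict(c) for c in data["series"]))
    if "parallel" in data:
        return Parallel(tuple(from_dict(c) for c in data["parallel"]))
    raise CircuitError(f"not a circuit description: {data!r}")


def save_network(network: CircuitNode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_dict(network), indent=2))


def load_network(path: str | Path) -> CircuitNode:
    return from_dict(json.loads(Path(path).read_text()))
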