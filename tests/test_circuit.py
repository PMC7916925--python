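"""Element impedances, network composition, presets and their physics."""

import cmath
import math

import numpy as np
import pytest

import gelspec as gs
from gelspec import circuit as ckt
from gelspec.circuit import CircuitError, default_frequency_grid


def oracle_impedance(node, f):
    """Independent recursive oracle using explicit complex arithmetic."""
    w = 2 * math.pi * f
    if isinstance(node, ckt.CircuitElement):
        p = node.params
        if node.kind == "resistor":
            return complex(p["R"])
        if node.kind == "inductor":
            return complex(0, w * p["L"])
        if node.kind == "capacitor":
            return 1 / complex(0, w * p["C"])
        if node.kind == "cpe":
            return 1 / (p["Q0"] * cmath.exp(p["n"] * cmath.log(complex(0, w))))
        root = cmath.sqrt(complex(0, w))
        if node.semi_infinite:
            return 1 / (p["Y0"] * root)
        return cmath.tanh(p["B"] * root) / (p["Y0"] * root)
    if isinstance(node, ckt.Series):
        return sum(oracle_impedance(c, f) for c in node.children)
    total = 0j
    for c in node.children:
        total += 1 / oracle_impedance(c, f)
    return 1 / total


def random_network(rng, depth=0):
    """Random small network for oracle-equivalence checks."""
    if depth >= 3 or rng.random() < 0.4:
        kind = rng.choice(ckt.ELEMENT_KINDS)
        if kind == "resistor":
            return ckt.resistor(10 ** rng.uniform(0, 5))
        if kind == "inductor":
            return ckt.inductor(10 ** rng.uniform(-9, -3))
        if kind == "capacitor":
            return ckt.capacitor(10 ** rng.uniform(-12, -6))
        if kind == "warburg":
            return ckt.warburg(10 ** rng.uniform(-8, -4),
                               B=10 ** rng.uniform(-3, 1))
        return ckt.cpe(10 ** rng.uniform(-12, -6), rng.uniform(-1, 1))
    combiner = ckt.series if rng.random() < 0.5 else ckt.parallel
    return combiner(*(random_network(rng, depth + 1)
                      for _ in range(rng.integers(2, 4))))


class TestElementImpedance:
    def test_resistor_is_frequency_independent(self):
        r = ckt.resistor(46.25)
        for f in (2e3, 6e3, 3e5):
            assert gs.element_impedance(r, f) == 46.25 + 0j

    def test_cpe_n1_equals_capacitor(self):
        c_val = 81.67e-12
        cap, c_cpe = ckt.capacitor(c_val), ckt.cpe(c_val, 1.0)
        for f in default_frequency_grid(20):
            z_c = gs.element_impedance(cap, f)
            z_q = gs.element_impedance(c_cpe, f)
            assert abs(z_q - z_c) <= 1e-12 * abs(z_c)

    def test_cpe_n0_equals_resistor(self):
        q0 = 2.0e-3
        el = ckt.cpe(q0, 0.0)
        for f in default_frequency_grid(20):
            z = gs.element_impedance(el, f)
            assert abs(z - 1 / q0) <= 1e-12 / q0

    def test_cpe_nminus1_equals_inductor(self):
        q0 = 1.0 / 583.7e-6  # Q0 = 1/L for n = -1
        el, ind = ckt.cpe(q0, -1.0), ckt.inductor(583.7e-6)
        for f in default_frequency_grid(20):
            z_l = gs.element_impedance(ind, f)
            z_q = gs.element_impedance(el, f)
            assert abs(z_q - z_l) <= 1e-12 * abs(z_l)

    def test_cpe_direct_evaluation_at_6khz(self):
        # frozen from the one-line oracle 1/(Q0*(j*2*pi*6000)**0.8361)
        el = ckt.cpe(503.5e-12, 0.8361)
        z = gs.element_impedance(el, 6000.0)
        expected = 1 / (503.5e-12 * (2j * math.pi * 6000.0) ** 0.8361)
        assert z == pytest.approx(expected, rel=1e-12)
        assert z.real == pytest.approx(75443.28, rel=1e-6)
        assert z.imag == pytest.approx(-286533.36, rel=1e-6)

    def test_warburg_high_frequency_limit_is_45_degrees(self):
        el = ckt.warburg(1e-6, B=1.0)
        z1 = gs.element_impedance(el, 1e5)
        z2 = gs.element_impedance(el, 4e5)
        assert cmath.phase(z1) == pytest.approx(-math.pi / 4, abs=1e-6)
        # |Z| ~ omega^{-1/2}: quadrupling f halves the magnitude
        assert abs(z2) == pytest.approx(abs(z1) / 2, rel=1e-6)

    def test_invalid_frequency_and_parameters_rejected(self):
        with pytest.raises(CircuitError):
            gs.element_impedance(ckt.resistor(10.0), 0.0)
        with pytest.raises(CircuitError):
            gs.element_impedance(ckt.resistor(10.0), -5.0)
        with pytest.raises(CircuitError):
            ckt.resistor(-1.0)
        with pytest.raises(CircuitError):
            ckt.cpe(1e-9, 1.5)


class TestNetworkComposition:
    def test_series_resistors_add(self):
        net = ckt.series(ckt.resistor(10.0), ckt.resistor(20.0))
        assert gs.network_impedance(net, 1e3) == 30 + 0j

    def test_parallel_of_equals_divides(self):
        z = gs.network_impedance(
            ckt.parallel(ckt.resistor(100.0), ckt.resistor(100.0)), 1e3)
        assert z == pytest.approx(50 + 0j)
        for k in (2, 3, 5):
            net = ckt.parallel(*(ckt.capacitor(1e-9) for _ in range(k)))
            ref = gs.element_impedance(ckt.capacitor(1e-9), 1e4)
            assert gs.network_impedance(net, 1e4) == pytest.approx(ref / k)

    def test_series_associativity(self):
        a, b, c = ckt.resistor(1.0), ckt.inductor(1e-6), ckt.capacitor(1e-9)
        left = ckt.series(ckt.series(a, b), c)
        right = ckt.series(a, ckt.series(b, c))
        for f in (2e3, 6e3, 3e5):
            assert gs.network_impedance(left, f) == pytest.approx(
                gs.network_impedance(right, f), rel=1e-14)

    def test_matches_recursive_oracle_on_random_networks(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            net = random_network(rng)
            for f in 10 ** rng.uniform(2, 6, size=3):
                z = gs.network_impedance(net, float(f))
                z_ref = oracle_impedance(net, float(f))
                assert abs(z - z_ref) <= 1e-12 * max(abs(z_ref), 1e-30)

    def test_non_gelled_topology_matches_hand_composition(self):
        f = 6000.0
        w = 2 * math.pi * f
        z_cpe = 1 / (503.5e-12 * (1j * w) ** 0.8361)
        z_par = 1 / (1 / 298.3e3 + 1 / z_cpe)
        expected = 1j * w * 583.7e-6 + 46.25 + z_par
        got = gs.network_impedance(gs.non_gelled_preset(), f)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_composite_rejected(self):
        with pytest.raises(CircuitError):
            ckt.Series(())
        with pytest.raises(CircuitError):
            ckt.Parallel(())


class TestSimulateSpectrum:
    def test_resistor_network_has_zero_reactance(self, band_grid):
        s = gs.simulate_spectrum(ckt.resistor(50.0), band_grid)
        assert np.all(s.reactance == 0)
        assert np.all(s.resistance == 50.0)

    def test_capacitor_magnitude_strictly_decreasing(self, band_grid):
        s = gs.simulate_spectrum(ckt.capacitor(1e-9), band_grid)
        assert np.all(np.diff(s.magnitude) < 0)


class TestPresets:
    def test_gelled_preset_parameters(self):
        params = ckt.get_parameters(gs.gelled_preset())
        assert params["L1.L"] == 218e-12
        assert params["C1.C"] == 81.67e-12
        assert params["W.Y0"] == pytest.approx(1 / 4.786e6)

    def test_non_gelled_preset_parameters(self):
        params = ckt.get_parameters(gs.non_gelled_preset())
        assert params["R1.R"] == 46.25
        assert params["R2.R"] == 298.3e3
        assert params["CPE.Q0"] == 503.5e-12
        assert params["CPE.n"] == 0.8361 > 0.8  # capacitor-like regime

    def test_gelled_capacitive_reactance_dominates_at_6khz(self):
        z = gs.network_impedance(gs.gelled_preset(), 6000.0)
        xc = 1 / (2 * math.pi * 6000.0 * 81.67e-12)  # ~3.25e5 ohm
        assert xc == pytest.approx(3.248e5, rel=1e-3)
        assert -z.imag == pytest.approx(xc, rel=0.1)
        assert abs(z.imag) > 10 * z.real

    def test_non_gelled_dc_limit_is_r1_plus_r2(self):
        z = gs.network_impedance(gs.non_gelled_preset(), 1e-3)
        assert abs(z) == pytest.approx(46.25 + 298.3e3, rel=0.01)

    def test_non_gelled_high_frequency_real_part_approaches_r1(self):
        reals = [gs.network_impedance(gs.non_gelled_preset(), f).real
                 for f in (1e8, 1e10, 1e12)]
        assert abs(reals[-1] - 46.25) < abs(reals[0] - 46.25)
        assert reals[-1] == pytest.approx(46.25, rel=0.01)

    def test_band_shape_claims(self, band_grid):
        """Capacitive reactance everywhere, falling |Z|, gelled above
        non-gelled at 6 kHz."""
        gelled = gs.simulate_spectrum(gs.gelled_preset(), band_grid)
        non = gs.simulate_spectrum(gs.non_gelled_preset(), band_grid)
        for s in (gelled, non):
            assert np.all(s.reactance < 0)
            assert np.all(np.diff(s.magnitude) <= 0)
        zg = abs(gs.network_impedance(gs.gelled_preset(), 6000.0))
        zn = abs(gs.network_impedance(gs.non_gelled_preset(), 6000.0))
        assert zg > zn


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        for net in (gs.gelled_preset(), gs.non_gelled_preset()):
            path = tmp_path / "net.json"
            ckt.save_network(net, path)
            back = ckt.load_network(path)
            assert ckt.get_parameters(back) == ckt.get_parameters(net)
            for f in (2e3, 6e3, 3e5):
                assert gs.network_impedance(back, f) == pytest.approx(
                    gs.network_impedance(net, f), rel=1e-15)

    def test_set_parameters_round_trip(self):
        net = gs.non_gelled_preset()
        updated = ckt.set_parameters(net, {"R1.R": 100.0})
        assert ckt.get_parameters(updated)["R1.R"] == 100.0
        assert ckt.get_parameters(net)["R1.R"] == 46.25  # original untouched
        with pytest.raises(CircuitError):
            ckt.set_parameters(net, {"nope.R": 1.0})
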