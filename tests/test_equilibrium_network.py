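"""Coupled-equilibrium solver and the catalyst-intermediate bias analysis."""

import math

import numpy as np
import pytest

from nativedg.equilibrium_network import (
    CONC_1X_MOLAR,
    SpeciesNetwork,
    _cz_ignoring_apparent_keq,
    apparent_delta_g,
    bias_scan,
    solve_equilibrium,
    two_strand_binding_closed_form,
)
from nativedg.thermo_core import delta_g_from_keq


def brute_force_equilibrium(net, n_coarse=240, n_refine=2):
    """Independent oracle: scan the 2-D reaction-extent space ([XZ], [YZ])
    for the minimum of the ideal-dilute Gibbs energy, refining the grid
    around the minimum to ~1e-5 of the initial range (finer grids probe
    energy differences below double precision)."""
    rt = 1.0  # work in units of RT; dG scaled below
    x_tot, y_tot, z_tot = net.totals["X"], net.totals["Y"], net.totals["Z"]
    g_xz = net.complex_dg["XZ"] / net.condition.rt
    g_yz = net.complex_dg["YZ"] / net.condition.rt

    def gibbs(a, b):
        # a = [XZ], b = [YZ]; invalid points -> inf
        x = x_tot - a
        y = y_tot - b
        z = z_tot - a - b
        bad = (x <= 0) | (y <= 0) | (z <= 0) | (a <= 0) | (b <= 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = (
                x * (np.log(x) - 1)
                + y * (np.log(y) - 1)
                + z * (np.log(z) - 1)
                + a * (g_xz + np.log(a) - 1)
                + b * (g_yz + np.log(b) - 1)
            )
        return np.where(bad, np.inf, g)

    lo_a, hi_a = 0.0, min(x_tot, z_tot)
    lo_b, hi_b = 0.0, min(y_tot, z_tot)
    for _ in range(n_refine + 1):
        a = np.linspace(lo_a, hi_a, n_coarse)
        b = np.linspace(lo_b, hi_b, n_coarse)
        aa, bb = np.meshgrid(a, b, indexing="ij")
        g = gibbs(aa, bb)
        i, j = np.unravel_index(np.argmin(g), g.shape)
        da = (hi_a - lo_a) / (n_coarse - 1)
        db = (hi_b - lo_b) / (n_coarse - 1)
        lo_a, hi_a = max(0.0, a[i] - da), min(min(x_tot, z_tot), a[i] + da)
        lo_b, hi_b = max(0.0, b[j] - db), min(min(y_tot, z_tot), b[j] + db)
    return a[i], b[j], da


class TestSolver:
    def test_symmetric_reaction_gives_equal_split(self, cond25):
        c = CONC_1X_MOLAR
        net = SpeciesNetwork(
            {"X": c, "Y": c, "Z": c, "C": 0.0}, {"XZ": -15.0, "YZ": -15.0}, cond25
        )
        st = solve_equilibrium(net)
        assert st["X"] == pytest.approx(st["Y"], rel=1e-9)
        assert st["XZ"] == pytest.approx(st["YZ"], rel=1e-9)
        assert st.reaction_quotient() == pytest.approx(1.0, rel=1e-9)

    def test_mass_balance_and_detailed_balance(self, cond25):
        c = CONC_1X_MOLAR
        net = SpeciesNetwork(
            {"X": c, "Y": 0.7 * c, "Z": 1.2 * c, "C": 0.1 * c},
            {"XZ": -12.3, "YZ": -11.8, "CZ": -10.0},
            cond25,
        )
        st = solve_equilibrium(net)
        assert st["X"] + st["XZ"] == pytest.approx(c, rel=1e-9)
        assert st["Y"] + st["YZ"] == pytest.approx(0.7 * c, rel=1e-9)
        assert st["Z"] + st["XZ"] + st["YZ"] + st["CZ"] == pytest.approx(
            1.2 * c, rel=1e-9
        )
        for name in ("XZ", "YZ", "CZ"):
            keq = math.exp(-net.complex_dg[name] / cond25.rt)
            q = st[name] / (st[name[0]] * st["Z"])
            assert q == pytest.approx(keq, rel=1e-6)

    def test_weak_catalyst_complex_is_a_no_op(self, cond25):
        c = CONC_1X_MOLAR
        base = SpeciesNetwork(
            {"X": c, "Y": c, "Z": c, "C": 0.0}, {"XZ": -14.8, "YZ": -15.0}, cond25
        )
        # CZ ten kcal/mol less stable than the duplexes: the catalyst is inert
        spiked = SpeciesNetwork(
            {"X": c, "Y": c, "Z": c, "C": 0.1 * c},
            {"XZ": -14.8, "YZ": -15.0, "CZ": -5.0},
            cond25,
        )
        st0, st1 = solve_equilibrium(base), solve_equilibrium(spiked)
        for sp in ("X", "Y", "XZ", "YZ"):
            assert st1[sp] == pytest.approx(st0[sp], rel=1e-6)

    def test_against_brute_force_gibbs_scan(self, cond25, rng):
        c = CONC_1X_MOLAR
        for _ in range(3):
            net = SpeciesNetwork(
                {
                    "X": float(rng.uniform(0.5, 1.5)) * c,
                    "Y": float(rng.uniform(0.5, 1.5)) * c,
                    "Z": float(rng.uniform(0.5, 1.5)) * c,
                    "C": 0.0,
                },
                # moderate stabilities so every species is populated
                {"XZ": float(rng.uniform(-10, -8)), "YZ": float(rng.uniform(-10, -8))},
                cond25,
            )
            a, b, resolution = brute_force_equilibrium(net)
            st = solve_equilibrium(net)
            assert st["XZ"] == pytest.approx(a, abs=2 * resolution)
            assert st["YZ"] == pytest.approx(b, abs=2 * resolution)

    def test_two_strand_limit_matches_quadratic(self, cond25):
        net = SpeciesNetwork(
            {"X": 3e-7, "Y": 0.0, "Z": 2e-7, "C": 0.0},
            {"XZ": -9.0, "YZ": -9.0},
            cond25,
        )
        st = solve_equilibrium(net)
        cf = two_strand_binding_closed_form(3e-7, 2e-7, -9.0, cond25)
        assert st["XZ"] == pytest.approx(cf, rel=1e-9)

    def test_keq_invariant_under_catalyst_load(self, cond25):
        c = CONC_1X_MOLAR
        quotients = []
        for frac in (0.0, 0.05, 0.1, 0.5):
            net = SpeciesNetwork(
                {"X": c, "Y": c, "Z": c, "C": frac * c},
                {"XZ": -15.3, "YZ": -15.0, "CZ": -14.0},
                cond25,
            )
            quotients.append(solve_equilibrium(net).reaction_quotient())
        assert np.allclose(quotients, quotients[0], rtol=1e-6)

    def test_scaling_preserves_yields_for_balanced_exchange(self, cond25):
        c = CONC_1X_MOLAR
        states = []
        for s in (1.0, 10.0):
            net = SpeciesNetwork(
                {"X": s * c, "Y": s * c, "Z": s * c, "C": 0.0},
                {"XZ": -30.5, "YZ": -30.0},
                cond25,
            )
            st = solve_equilibrium(net)
            states.append(st["XZ"] / (s * c))
        assert states[1] == pytest.approx(states[0], rel=1e-6)

    def test_negative_total_rejected(self, cond25):
        with pytest.raises(ValueError, match="must be finite and >= 0"):
            SpeciesNetwork({"X": -1e-9, "Y": 0, "Z": 0}, {"XZ": -10, "YZ": -10}, cond25)

    def test_complex_without_z_rejected(self, cond25):
        with pytest.raises(ValueError, match="common strand Z"):
            SpeciesNetwork(
                {"X": 1e-9, "Y": 1e-9, "Z": 1e-9, "C": 0.0},
                {"XZ": -10, "YZ": -10, "XC": -5},
                cond25,
            )


class TestApparentDeltaG:
    def test_clamped_sequestration_toy(self, cond25):
        # with [CZ] pinned at 0.1x and a symmetric reaction, the remaining
        # 0.9x of Z splits evenly: [XZ] = [YZ] = 0.45, and the catalyst-
        # blind algebra returns Keq = 0.45^2 / 0.55^2
        keq_app = _cz_ignoring_apparent_keq(0.45, {"XZ": 1.0, "Y": 1.0})
        assert keq_app == pytest.approx(0.45**2 / 0.55**2, rel=1e-12)
        bias = delta_g_from_keq(keq_app, cond25) - 0.0
        assert bias == pytest.approx(0.238, abs=2e-3)

    def test_no_catalyst_means_no_bias(self, cond25):
        c = CONC_1X_MOLAR
        net = SpeciesNetwork(
            {"X": c, "Y": c, "Z": c, "C": 0.0}, {"XZ": -30.4, "YZ": -30.0}, cond25
        )
        app = apparent_delta_g(net, {"XZ": c, "Y": c})
        assert app - net.reaction_delta_g() == pytest.approx(0.0, abs=1e-6)

    def test_bias_is_nonnegative(self, cond25, rng):
        c = CONC_1X_MOLAR
        for _ in range(5):
            motif = float(rng.uniform(-2, 2))
            net = SpeciesNetwork(
                {"X": c, "Y": c, "Z": c, "C": 0.1 * c},
                {
                    "XZ": -30.0 + motif,
                    "YZ": -30.0,
                    "CZ": -30.0 + float(rng.uniform(1.0, 4.0)),
                },
                cond25,
            )
            app = apparent_delta_g(net, {"XZ": c, "Y": c, "C": 0.1 * c})
            assert app - motif >= -1e-9

    def test_inconsistent_lane_initials_rejected(self, cond25):
        c = CONC_1X_MOLAR
        net = SpeciesNetwork(
            {"X": c, "Y": c, "Z": c, "C": 0.0}, {"XZ": -30.0, "YZ": -30.0}, cond25
        )
        with pytest.raises(ValueError, match="network declares"):
            apparent_delta_g(net, {"XZ": c, "Y": 2 * c})


class TestBiasScan:
    def test_zero_catalyst_gives_zero_bias(self):
        df = bias_scan([-1.0, 0.0, 1.0], [1.0], catalyst_fraction=0.0)
        assert df["bias"].abs().max() < 1e-9

    def test_bias_monotone_in_cz_stability(self):
        df = bias_scan([0.0], [1.0, 1.5, 2.0, 3.0], catalyst_fraction=0.1)
        biases = df.sort_values("cz_offset")["bias"].to_numpy()
        assert np.all(np.diff(biases) < 0)  # less stable CZ -> less bias

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            bias_scan([], [1.0])
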