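import numpy as np
import pytest

from conftest import interp_fwhm, moment_fwhm
from psispec.constants import DEBYE_PER_E_ANGSTROM
from psispec.exciton import (
    CoverageError,
    DisorderModel,
    ExcitonHamiltonian,
    LineShape,
    build_hamiltonian,
    diagonalize,
    simulate_absorption,
    simulated_difference,
)
from psispec.tresp import CouplingMatrix

# Site energies (diagonal) and couplings of the reference three-pigment
# antenna cluster: B18/B19/B40 with the wild-type geometry couplings.
WT_LABELS = ["B18", "B19", "B40"]
WT_ENERGIES = [14600.0, 14950.0, 14950.0]
WT_COUPLINGS = np.array(
    [[0.0, -71.0, -20.0], [-71.0, 0.0, -106.0], [-20.0, -106.0, 0.0]]
)


def wt_hamiltonian():
    cm = CouplingMatrix(WT_LABELS, WT_COUPLINGS)
    return build_hamiltonian(WT_ENERGIES, cm)


class TestBuildHamiltonian:
    def test_wt_triad_matrix(self):
        H = wt_hamiltonian()
        expected = WT_COUPLINGS + np.diag(WT_ENERGIES)
        np.testing.assert_array_equal(H.H, expected)
        assert H.H.trace() == sum(WT_ENERGIES)

    def test_single_site(self):
        H = build_hamiltonian([15000.0], CouplingMatrix(["x"], np.zeros((1, 1))))
        assert H.H.shape == (1, 1)
        assert H.H[0, 0] == 15000.0

    def test_permutation_consistency(self):
        H = wt_hamiltonian()
        perm = [2, 0, 1]
        cm_p = CouplingMatrix(
            [WT_LABELS[i] for i in perm], WT_COUPLINGS[np.ix_(perm, perm)]
        )
        H_p = build_hamiltonian([WT_ENERGIES[i] for i in perm], cm_p)
        inv = np.argsort(perm)
        np.testing.assert_array_equal(H_p.H[np.ix_(inv, inv)], H.H)

    def test_label_order_mismatch_rejected(self):
        from psispec.tresp import PigmentSite, TransitionChargeSet

        cs = TransitionChargeSet("toy", {"NB": 0.1, "ND": -0.1}, "t")
        sites = [
            PigmentSite("B19", {"NB": (0, 0, 0), "ND": (0, 1, 0)}, cs, 14950.0),
            PigmentSite("B18", {"NB": (9, 0, 0), "ND": (9, 1, 0)}, cs, 14600.0),
        ]
        cm = CouplingMatrix(["B18", "B19"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="order"):
            build_hamiltonian(sites, cm)

    def test_missing_site_energy_rejected(self):
        cm = CouplingMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            build_hamiltonian([15000.0], cm)
        with pytest.raises(ValueError, match="finite"):
            build_hamiltonian([15000.0, np.nan], cm)


class TestDiagonalize:
    def test_homodimer_closed_form(self):
        cm = CouplingMatrix(["a", "b"], np.array([[0.0, -100.0], [-100.0, 0.0]]))
        H = build_hamiltonian([15000.0, 15000.0], cm)
        mu = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        states = diagonalize(H, mu)
        np.testing.assert_allclose(states.energies, [14900.0, 15100.0])
        d_unit = DEBYE_PER_E_ANGSTROM**2
        np.testing.assert_allclose(
            states.dipole_strengths, [2.0 * d_unit, 0.0], atol=1e-9
        )

    @pytest.mark.parametrize("v", [10.0, 55.0, 240.0])
    def test_homodimer_splitting_is_2V(self, v):
        cm = CouplingMatrix(["a", "b"], np.array([[0.0, -v], [-v, 0.0]]))
        H = build_hamiltonian([15000.0, 15000.0], cm)
        states = diagonalize(H, np.zeros((2, 3)) + [0, 1, 0])
        assert states.energies[1] - states.energies[0] == pytest.approx(2 * v)

    def test_single_site_trivial(self):
        H = build_hamiltonian([15000.0], CouplingMatrix(["x"], np.zeros((1, 1))))
        states = diagonalize(H, [[0.0, 0.9, 0.0]])
        assert states.energies[0] == 15000.0
        assert states.dipole_strengths[0] == pytest.approx(
            0.81 * DEBYE_PER_E_ANGSTROM**2
        )

    def test_wt_lowest_state_matches_characteristic_polynomial(self):
        """Independent oracle: roots of det(H - EI) via the cubic's coefficients."""
        H = wt_hamiltonian()
        coeffs = np.poly(H.H)  # characteristic polynomial coefficients
        roots = np.sort(np.roots(coeffs).real)
        states = diagonalize(H, np.eye(3))
        np.testing.assert_allclose(states.energies, roots, rtol=1e-10)
        assert states.energies[0] == pytest.approx(14581.49, abs=0.01)
        assert 1e7 / states.energies[0] == pytest.approx(685.8, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_sum_rules_on_random_hamiltonians(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        V = rng.normal(0, 80, (n, n))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        energies = rng.uniform(14000, 15500, n)
        H = build_hamiltonian(energies, CouplingMatrix([f"p{i}" for i in range(n)], V))
        mu = rng.normal(0, 0.6, (n, 3))
        states = diagonalize(H, mu)
        C = states.coefficients
        np.testing.assert_allclose(C.T @ C, np.eye(n), atol=1e-8)
        assert states.energies.sum() == pytest.approx(H.H.trace(), rel=1e-6)
        assert states.dipole_strengths.sum() == pytest.approx(
            (mu**2).sum() * DEBYE_PER_E_ANGSTROM**2, rel=1e-8
        )
        assert np.all(np.diff(states.energies) >= 0)


class TestSimulateAbsorption:
    def single_site(self, energy=14600.0):
        return build_hamiltonian(
            [energy], CouplingMatrix(["x"], np.zeros((1, 1)))
        )

    def test_disorder_free_single_gaussian(self):
        spec = simulate_absorption(
            self.single_site(),
            [[0.0, 1.0, 0.0]],
            DisorderModel(site_fwhm=0.0, n_samples=1, seed=0),
            LineShape(),
        )
        assert interp_fwhm(spec.x, spec.y) == pytest.approx(10.0, abs=0.05)
        assert spec.x[np.argmax(spec.y)] == pytest.approx(14600.0, abs=1.0)
        # unit-area convolution kernel conserves the deposited dipole strength
        area = np.trapezoid(spec.y, spec.x)
        assert area == pytest.approx(DEBYE_PER_E_ANGSTROM**2, rel=1e-6)

    def test_disordered_linewidth_adds_in_quadrature(self):
        spec = simulate_absorption(
            self.single_site(),
            [[0.0, 1.0, 0.0]],
            DisorderModel(site_fwhm=300.0, n_samples=100_000, seed=1),
            LineShape(),
        )
        expected = np.hypot(300.0, 10.0)  # 300.17
        assert moment_fwhm(spec.x, spec.y) == pytest.approx(expected, abs=2.0)

    def test_bit_reproducible_for_fixed_seed(self):
        args = (
            self.single_site(),
            [[0.0, 1.0, 0.0]],
            DisorderModel(300.0, 5000, seed=42),
            LineShape(),
        )
        a = simulate_absorption(*args)
        b = simulate_absorption(*args)
        np.testing.assert_array_equal(a.y, b.y)

    def test_integrated_intensity_independent_of_couplings(self):
        mu = np.array([[0.0, 0.9, 0.0], [0.6, 0.3, 0.0], [0.0, 0.5, 0.7]])
        dis = DisorderModel(300.0, 20_000, seed=3)
        H0 = build_hamiltonian(
            WT_ENERGIES, CouplingMatrix(WT_LABELS, np.zeros((3, 3)))
        )
        H1 = wt_hamiltonian()
        area0 = np.trapezoid(*(lambda s: (s.y, s.x))(simulate_absorption(H0, mu, dis, LineShape())))
        area1 = np.trapezoid(*(lambda s: (s.y, s.x))(simulate_absorption(H1, mu, dis, LineShape())))
        assert area1 == pytest.approx(area0, rel=1e-3)

    def test_zero_coupling_limit_is_sum_of_singles(self):
        """With V=0 the disorder-averaged spectrum is the sum of independent
        single-pigment Gaussians centered at each site energy."""
        energies = [14400.0, 14800.0]
        mu = np.array([[0.0, 0.8, 0.0], [0.0, 0.6, 0.0]])
        H = build_hamiltonian(energies, CouplingMatrix(["a", "b"], np.zeros((2, 2))))
        dis = DisorderModel(300.0, 100_000, seed=5)
        shape = LineShape()
        spec = simulate_absorption(H, mu, dis, shape)
        sigma = np.sqrt(dis.sigma**2 + (10.0 / 2.3548200450309493) ** 2)
        analytic = np.zeros_like(spec.x)
        for e, m in zip(energies, mu):
            d = (m**2).sum() * DEBYE_PER_E_ANGSTROM**2
            analytic += d * np.exp(-0.5 * ((spec.x - e) / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi)
            )
        assert np.max(np.abs(spec.y - analytic)) < 0.05 * analytic.max()

    def test_grid_must_cover_band(self):
        H = self.single_site(11000.0)
        with pytest.raises(CoverageError):
            simulate_absorption(
                H, [[0, 1, 0]], DisorderModel(300.0, 10, 0), LineShape()
            )


class TestSimulatedDifference:
    def test_identical_inputs_give_zero(self):
        H = build_hamiltonian(
            WT_ENERGIES, CouplingMatrix(WT_LABELS, WT_COUPLINGS)
        )
        mu = np.eye(3) * 0.9
        spec = simulate_absorption(H, mu, DisorderModel(300.0, 2000, 0), LineShape())
        diff = simulated_difference(spec, spec)
        np.testing.assert_array_equal(diff.y, np.zeros_like(diff.y))

    def test_antisymmetric(self):
        mu = np.eye(3) * 0.9
        dis = DisorderModel(300.0, 2000, 0)
        H0 = build_hamiltonian(WT_ENERGIES, CouplingMatrix(WT_LABELS, np.zeros((3, 3))))
        H1 = wt_hamiltonian()
        a = simulate_absorption(H0, mu, dis, LineShape())
        b = simulate_absorption(H1, mu, dis, LineShape())
        ab = simulated_difference(a, b)
        ba = simulated_difference(b, a)
        np.testing.assert_allclose(ab.y, -ba.y, atol=1e-15)

    def test_offset_gaussians_cross_zero_at_midpoint(self):
        shape = LineShape()
        dis = DisorderModel(0.0, 1, 0)
        e1, e2 = 14590.0, 14610.0  # overlapping bands at 10 cm⁻¹ width
        a = simulate_absorption(
            build_hamiltonian([e1], CouplingMatrix(["x"], np.zeros((1, 1)))),
            [[0, 1, 0]], dis, shape,
        )
        b = simulate_absorption(
            build_hamiltonian([e2], CouplingMatrix(["x"], np.zeros((1, 1)))),
            [[0, 1, 0]], dis, shape,
        )
        diff = simulated_difference(a, b)
        mid = (e1 + e2) / 2
        crossings = np.where(np.diff(np.sign(diff.y[np.abs(diff.x - mid) < 40])))[0]
        window = diff.x[np.abs(diff.x - mid) < 40]
        assert any(abs(window[c] - mid) <= 1.0 for c in crossings)

    def test_grid_mismatch_rejected(self):
        H = build_hamiltonian([14600.0], CouplingMatrix(["x"], np.zeros((1, 1))))
        a = simulate_absorption(H, [[0, 1, 0]], DisorderModel(0, 1, 0), LineShape())
        other = LineShape(grid=np.arange(12000.0, 16000.0 + 2.0, 2.0))
        b = simulate_absorption(H, [[0, 1, 0]], DisorderModel(0, 1, 0), other)
        with pytest.raises(ValueError, match="grid"):
            simulated_difference(a, b)
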