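"""Frenkel-exciton Hamiltonian assembly, diagonalization and disorder averaging.

The model: N coupled pigments with site energies E_m on the diagonal and
excitonic couplings V_mn off the diagonal.  Eigenstates k carry transition
dipoles μ_k = Σ_m c_mk μ_m and absorb with intensity |μ_k|² (no frequency
prefactor — the Qy band is narrow).  Static (inhomogeneous) disorder is
modelled by Monte-Carlo sampling: each iteration perturbs every site energy
independently with Gaussian noise of a given FWHM, rediagonalizes, and
deposits each state's dipole strength at its transition energy on a
wavenumber grid; the average stick histogram is finally convolved with a
narrow Gaussian for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import DEBYE_PER_E_ANGSTROM, FWHM_TO_SIGMA
from .spectrum import Spectrum


class CoverageError(Exception):
    """Simulation grid does not cover the disorder-broadened band."""


@dataclass
class ExcitonHamiltonian:
    """Symmetric N×N matrix in cm⁻¹: diagonal E_m, off-diagonal V_mn."""

    labels: list
    H: np.ndarray

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        n = len(self.labels)
        if self.H.shape != (n, n):
            raise ValueError("Hamiltonian shape does not match labels")
        if not np.array_equal(self.H, self.H.T):
            raise ValueError("Hamiltonian must be exactly symmetric")
        if np.any(np.diagonal(self.H) <= 0):
            raise ValueError("site energies (diagonal) must be positive")

    @property
    def site_energies(self) -> np.ndarray:
        return np.diagonal(self.H).copy()


def build_hamiltonian(site_energies, couplings, labels=None) -> ExcitonHamiltonian:
    """Assemble H from site energies and a coupling matrix.

    ``site_energies`` is either a sequence of E_m (cm⁻¹) ordered like
    ``couplings.labels``, or a list of :class:`~psispec.tresp.PigmentSite`
    whose labels must match the coupling labels in order.
    """
    if hasattr(couplings, "labels"):
        c_labels, V = list(couplings.labels), np.asarray(couplings.V, dtype=float)
    else:
        V = np.asarray(couplings, dtype=float)
        c_labels = labels if labels is not None else [str(i) for i in range(V.shape[0])]
    if len(site_energies) and hasattr(site_energies[0], "site_energy"):
        s_labels = [s.label for s in site_energies]
        if s_labels != c_labels:
            raise ValueError(
                f"site order {s_labels} does not match coupling labels {c_labels}"
            )
        energies = np.array([s.site_energy for s in site_energies], dtype=float)
    else:
        energies = np.asarray(site_energies, dtype=float)
    if energies.shape != (len(c_labels),):
        raise ValueError("one site energy per coupling label is required")
    if np.any(~np.isfinite(energies)):
        raise ValueError("missing or non-finite site energy")
    H = V.copy()
    np.fill_diagonal(H, energies)
    return ExcitonHamiltonian(labels=c_labels, H=H)


@dataclass
class ExcitonStates:
    """Eigen-decomposition of an exciton Hamiltonian.

    ``energies`` ascending in cm⁻¹; ``coefficients`` orthonormal with
    columns = states; ``state_dipoles`` in e·Å; ``dipole_strengths`` in D².
    """

    energies: np.ndarray
    coefficients: np.ndarray
    state_dipoles: np.ndarray
    dipole_strengths: np.ndarray
    labels: list = field(default_factory=list)


def _site_dipole_matrix(site_dipoles) -> np.ndarray:
    """Accept PigmentSites or raw (N,3) e·Å vectors."""
    if len(site_dipoles) and hasattr(site_dipoles[0], "dipole"):
        return np.array([s.dipole for s in site_dipoles], dtype=float)
    return np.asarray(site_dipoles, dtype=float)


def diagonalize(H: ExcitonHamiltonian, site_dipoles) -> ExcitonStates:
    """Eigenstates of H with per-state transition dipoles and strengths.

    Satisfies the sum rules Σ_k E_k = tr(H) and Σ_k |μ_k|² = Σ_m |μ_m|²
    (couplings redistribute, never create, dipole strength).
    """
    M = _site_dipole_matrix(site_dipoles)
    if M.shape != (H.H.shape[0], 3):
        raise ValueError("one 3-vector dipole per site is required")
    w, C = np.linalg.eigh(H.H)
    mu_states = C.T @ M                      # (N,3) e·Å
    strengths = (mu_states**2).sum(axis=1) * DEBYE_PER_E_ANGSTROM**2
    return ExcitonStates(
        energies=w,
        coefficients=C,
        state_dipoles=mu_states,
        dipole_strengths=strengths,
        labels=list(H.labels),
    )


@dataclass
class DisorderModel:
    """Static site-energy disorder: independent Gaussian per pigment.

    ``site_fwhm`` is the full width at half maximum of the site-energy
    distribution (cm⁻¹); the sampling σ is FWHM/(2√(2 ln 2)).
    """

    site_fwhm: float = 300.0
    n_samples: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.site_fwhm < 0:
            raise ValueError("site_fwhm must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")

    @property
    def sigma(self) -> float:
        return self.site_fwhm * FWHM_TO_SIGMA


@dataclass
class LineShape:
    """Visualization convolution and simulation grid (wavenumbers)."""

    conv_fwhm: float = 10.0
    grid: np.ndarray = field(default_factory=lambda: np.arange(12000.0, 16000.0 + 1.0, 1.0))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.conv_fwhm < 0:
            raise ValueError("conv_fwhm must be nonnegative")
        if self.grid.ndim != 1 or self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be 1-D and strictly increasing")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


def simulate_absorption(
    H: ExcitonHamiltonian,
    site_dipoles,
    disorder: DisorderModel | None = None,
    shape: LineShape | None = None,
    batch_size: int = 20_000,
) -> Spectrum:
    """Disorder-averaged Qy absorption spectrum on a wavenumber grid.

    Per iteration the diagonal is perturbed by i.i.d. Gaussian noise
    (σ from ``disorder.site_fwhm``), the Hamiltonian rediagonalized, and each
    state's dipole strength deposited into the grid bin nearest its energy.
    The iteration-averaged histogram is convolved with a unit-area Gaussian
    of FWHM ``shape.conv_fwhm``.  Bit-reproducible for a fixed seed.
    """
    disorder = disorder if disorder is not None else DisorderModel()
    shape = shape if shape is not None else LineShape()
    M = _site_dipole_matrix(site_dipoles)
    n_pig = H.H.shape[0]
    if M.shape != (n_pig, 3):
        raise ValueError("one 3-vector dipole per site is required")

    margin = 5.0 * disorder.sigma + 2.0 * shape.conv_fwhm
    e_min, e_max = H.site_energies.min(), H.site_energies.max()
    if e_min - margin < shape.grid[0] or e_max + margin > shape.grid[-1]:
        raise CoverageError(
            f"grid [{shape.grid[0]:.0f}, {shape.grid[-1]:.0f}] cm⁻¹ does not cover "
            f"site energies [{e_min:.0f}, {e_max:.0f}] ± {margin:.0f} cm⁻¹"
        )

    rng = np.random.default_rng(disorder.seed)
    grid = shape.grid
    step = shape.step
    acc = np.zeros(grid.size)
    remaining = disorder.n_samples
    while remaining > 0:
        nb = min(batch_size, remaining)
        remaining -= nb
        Hs = np.broadcast_to(H.H, (nb, n_pig, n_pig)).copy()
        if disorder.sigma > 0:
            noise = rng.normal(0.0, disorder.sigma, size=(nb, n_pig))
        else:
            noise = np.zeros((nb, n_pig))
        idx = np.arange(n_pig)
        Hs[:, idx, idx] += noise
        w, C = np.linalg.eigh(Hs)                       # (nb,N), (nb,N,N)
        mu = np.einsum("bmk,mx->bkx", C, M)
        d = (mu**2).sum(axis=2) * DEBYE_PER_E_ANGSTROM**2
        bins = np.rint((w - grid[0]) / step).astype(int).ravel()
        dep = d.ravel()
        ok = (bins >= 0) & (bins < grid.size)  # draws beyond the 5σ margin are rare
        np.add.at(acc, bins[ok], dep[ok])
    acc /= disorder.n_samples * step                    # per-cm⁻¹ density

    if shape.conv_fwhm > 0:
        sigma_bins = shape.conv_fwhm * FWHM_TO_SIGMA / step
        acc = gaussian_filter1d(acc, sigma_bins, mode="constant", truncate=8.0)

    return Spectrum(
        grid.copy(),
        acc,
        unit="cm-1",
        metadata={
            "seed": disorder.seed,
            "n_samples": disorder.n_samples,
            "site_fwhm_cm-1": disorder.site_fwhm,
            "conv_fwhm_cm-1": shape.conv_fwhm,
            "labels": ",".join(H.labels),
        },
    )


def simulated_difference(spec_a: Spectrum, spec_b: Spectrum) -> Spectrum:
    """Pointwise a − b after normalizing each to unit area over its grid."""
    if spec_a.unit != spec_b.unit or not np.array_equal(spec_a.x, spec_b.x):
        raise ValueError("simulated spectra must share an identical grid")
    area_a = np.trapezoid(spec_a.y, spec_a.x)
    area_b = np.trapezoid(spec_b.y, spec_b.x)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("cannot area-normalize a spectrum with nonpositive area")
    return Spectrum(
        spec_a.x.copy(),
        spec_a.y / area_a - spec_b.y / area_b,
        unit=spec_a.unit,
        metadata={
            "operation": "simulated_difference",
            "a": spec_a.metadata.get("labels", ""),
            "b": spec_b.metadata.get("labels", ""),
        },
    )
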