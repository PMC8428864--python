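"""A sampled intensity-versus-axis curve, experimental or simulated.

The same container carries purified-complex absorption spectra read from
two-column CSV files, simulated disorder-averaged exciton spectra on a
wavenumber grid, and synthetic test spectra.  The axis is strictly monotonic
(ascending after construction through :func:`psispec.spectra_analysis.read_spectrum`)
and the unit tag distinguishes ``"nm"`` from ``"cm-1"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import WAVENUMBER_NM


@dataclass
class Spectrum:
    """Intensity sampled on a strictly monotonic axis.

    Parameters
    ----------
    x : array
        Axis values (wavelength in nm or wavenumber in cm⁻¹), strictly
        monotonic.
    y : array
        Intensities, same length as ``x``.
    unit : str
        Axis unit tag, ``"nm"`` or ``"cm-1"``.
    metadata : dict
        Free-form provenance (sample id, normalization state, generator
        parameters, seeds ...). Copied shallowly between operations.
    """

    x: np.ndarray
    y: np.ndarray
    unit: str = "nm"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("axis and intensity must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("spectrum contains non-finite values")
        d = np.diff(self.x)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("spectrum axis must be strictly monotonic")
        if self.unit not in ("nm", "cm-1"):
            raise ValueError(f"unknown axis unit {self.unit!r}")

    @property
    def ascending(self) -> bool:
        return bool(self.x[1] > self.x[0])

    def sorted(self) -> "Spectrum":
        """Return a copy with ascending axis."""
        if self.ascending:
            return Spectrum(self.x.copy(), self.y.copy(), self.unit, dict(self.metadata))
        return Spectrum(self.x[::-1].copy(), self.y[::-1].copy(), self.unit, dict(self.metadata))

    def to_wavelength(self) -> "Spectrum":
        """Convert a wavenumber-axis spectrum to wavelength (nm).

        Plain coordinate substitution λ = 10⁷/ν̃; intensities are carried
        over without a Jacobian reweighting (the Qy band is narrow enough
        that the Jacobian is a near-constant scale).
        """
        if self.unit == "nm":
            return self.sorted()
        return Spectrum(WAVENUMBER_NM / self.x, self.y, "nm", dict(self.metadata)).sorted()

    def to_wavenumber(self) -> "Spectrum":
        """Convert a wavelength-axis spectrum to wavenumbers (cm⁻¹)."""
        if self.unit == "cm-1":
            return self.sorted()
        return Spectrum(WAVENUMBER_NM / self.x, self.y, "cm-1", dict(self.metadata)).sorted()

    def interp(self, x_new) -> np.ndarray:
        """Linear interpolation of intensity at ``x_new`` (same unit)."""
        s = self.sorted()
        x_new = np.asarray(x_new, dtype=float)
        if (x_new < s.x[0]).any() or (x_new > s.x[-1]).any():
            raise ValueError("interpolation point outside spectral axis range")
        return np.interp(x_new, s.x, s.y)

    def write_csv(self, path) -> None:
        """Write as two-column CSV with ``#``-prefixed metadata header lines."""
        with open(path, "w") as fh:
            fh.write(f"# axis_unit: {self.unit}\n")
            for key, val in self.metadata.items():
                fh.write(f"# {key}: {val}\n")
            fh.write("axis,intensity\n")
            for xv, yv in zip(self.x, self.y):
                fh.write(f"{xv:.10g},{yv:.10g}\n")
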