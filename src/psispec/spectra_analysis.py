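"""Experimental absorption/emission spectra workup.

The workflow mirrors how purified pigment–protein complexes are compared:
spectra of equal pigment content are normalized to the integrated area of
the chlorophyll Q bands (550–775 nm by default), subtracted pairwise to
expose gained/lost bands, and the resulting difference features are
deconvolved into Gaussian components and summarized by peak positions and
intensity ratios (e.g. the F722:F685 fluorescence ratio used as a PSI:PSII
excitation-distribution proxy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .spectrum import Spectrum

logger = logging.getLogger(__name__)

GAUSS_LN2_4 = 4.0 * np.log(2.0)


class SpectrumIOError(Exception):
    """Unreadable or malformed spectrum file."""


class NormalizationError(Exception):
    """Spectrum cannot be area-normalized over the requested window."""


@dataclass(frozen=True)
class NormalizationWindow:
    """Integration window for area normalization (nm). Default: Q bands."""

    lo: float = 550.0
    hi: float = 775.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("window requires lo < hi")


@dataclass
class GaussianComponent:
    """One band of a deconvolution: center and FWHM in nm, signed amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("component FWHM must be positive")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-GAUSS_LN2_4 * ((x - self.center) / self.fwhm) ** 2)


@dataclass
class FitResult:
    """Outcome of a multi-Gaussian deconvolution."""

    components: list
    residual: np.ndarray
    converged: bool
    rms_residual: float
    region: tuple
    n_starts: int = 1
    message: str = ""

    def model(self, x):
        return sum((c(x) for c in self.components), np.zeros_like(np.asarray(x, dtype=float)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.center, c.fwhm, c.amplitude) for c in self.components],
            columns=["center_nm", "fwhm_nm", "amplitude"],
        )


def read_spectrum(path, dialect: str = "csv") -> Spectrum:
    """Read a two-column (axis, intensity) CSV/TSV file.

    ``#``-prefixed lines and an optional single header row are tolerated.
    A descending axis is sorted ascending and flagged in the metadata;
    duplicate axis values are an error.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, comment="#", header=None, skip_blank_lines=True)
    except (OSError, pd.errors.ParserError) as exc:
        raise SpectrumIOError(f"cannot read {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumIOError(f"{path}: expected two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    # optional one-line text header
    first = df.iloc[0]
    if not np.all([_is_number(v) for v in first]):
        df = df.iloc[1:]
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if not (_is_number(row[0]) and _is_number(row[1])):
            raise SpectrumIOError(f"{path}: non-numeric data at row {i}: {tuple(row)!r}")
    x = df.iloc[:, 0].astype(float).to_numpy()
    y = df.iloc[:, 1].astype(float).to_numpy()
    if np.unique(x).size != x.size:
        raise SpectrumIOError(f"{path}: duplicate axis values")
    meta = {"source": str(path)}
    order = np.argsort(x)
    if not np.array_equal(order, np.arange(x.size)):
        meta["sorted"] = True
        logger.info("%s: axis was not ascending; sorted", path)
    return Spectrum(x[order], y[order], unit="nm", metadata=meta)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _window_area(spec: Spectrum, window: NormalizationWindow) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated window edges."""
    s = spec.sorted()
    if window.lo < s.x[0] or window.hi > s.x[-1]:
        raise NormalizationError(
            f"window [{window.lo}, {window.hi}] outside axis range "
            f"[{s.x[0]}, {s.x[-1]}]"
        )
    inside = (s.x > window.lo) & (s.x < window.hi)
    xs = np.concatenate(([window.lo], s.x[inside], [window.hi]))
    ys = np.concatenate(([s.interp(window.lo)], s.y[inside], [s.interp(window.hi)]))
    return float(np.trapezoid(ys, xs))


def normalize_area(spec: Spectrum, window: NormalizationWindow | None = None) -> Spectrum:
    """Scale a spectrum so its integral over the window equals 1.

    Idempotent; the applied scale factor and window are recorded in the
    metadata.
    """
    window = window or NormalizationWindow()
    area = _window_area(spec, window)
    if area <= 0:
        raise NormalizationError(f"nonpositive integral {area:.3g} over the window")
    s = spec.sorted()
    meta = dict(s.metadata)
    meta["normalized_window_nm"] = (window.lo, window.hi)
    meta["normalization_scale"] = 1.0 / area * meta.get("normalization_scale", 1.0)
    return Spectrum(s.x, s.y / area, unit=s.unit, metadata=meta)


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """a − b on a's axis restricted to the overlap, b linearly interpolated.

    Both inputs should be area-normalized with the same window first (so
    that pure amplitude scalings cancel); antisymmetric on the common grid.
    """
    if a.unit != b.unit:
        raise ValueError("difference requires spectra with the same axis unit")
    sa, sb = a.sorted(), b.sorted()
    lo, hi = max(sa.x[0], sb.x[0]), min(sa.x[-1], sb.x[-1])
    if lo >= hi:
        raise ValueError("spectra axes do not overlap")
    mask = (sa.x >= lo) & (sa.x <= hi)
    x = sa.x[mask]
    y = sa.y[mask] - np.interp(x, sb.x, sb.y)
    return Spectrum(
        x,
        y,
        unit=a.unit,
        metadata={
            "operation": "difference",
            "a": sa.metadata.get("source", "a"),
            "b": sb.metadata.get("source", "b"),
        },
    )


def _multi_gauss(x, params, n):
    y = np.zeros_like(x)
    for i in range(n):
        a = params[f"a{i}"]
        c = params[f"c{i}"]
        w = params[f"w{i}"]
        y = y + a * np.exp(-GAUSS_LN2_4 * ((x - c) / w) ** 2)
    return y


def fit_gaussians(
    spec: Spectrum,
    region: tuple = (680.0, 730.0),
    n_components: int = 3,
    n_starts: int = 16,
    fwhm_bounds: tuple = (1.0, 40.0),
    init_fwhm: float = 6.0,
    seed: int = 0,
) -> FitResult:
    """Nonlinear least-squares fit of a sum of Gaussians over a region (nm).

    Deconvolutions are initialization-sensitive, so a multistart strategy is
    used: component centers are seeded at equally spaced quantiles of the
    region plus a seed at the observed extremum, jittered across ``n_starts``
    restarts, with amplitudes taken from local intensities and widths at
    ``init_fwhm`` nm.  The best-RMS converged solution wins.  Components are
    returned sorted by center; the convergence flag is honest.
    """
    s = spec.sorted()
    lo, hi = region
    mask = (s.x >= lo) & (s.x <= hi)
    x, y = s.x[mask], s.y[mask]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < 3 * n_components:
        raise ValueError(
            f"region holds {x.size} points; need >= {3 * n_components} "
            f"for {n_components} components"
        )
    rng = np.random.default_rng(seed)
    extremum = x[np.argmax(np.abs(y))]
    span = hi - lo

    def residual(p):
        vals = {k: p[k].value for k in p}
        return _multi_gauss(x, vals, n_components) - y

    def peel_centers():
        """Greedy init: repeatedly place a component at the residual extremum."""
        r = y.copy()
        centers = []
        for _ in range(n_components):
            i = int(np.argmax(np.abs(r)))
            centers.append(x[i])
            r = r - r[i] * np.exp(-GAUSS_LN2_4 * ((x - x[i]) / init_fwhm) ** 2)
        return np.array(centers)

    quant = np.quantile(x, np.linspace(0.15, 0.85, n_components))
    with_extremum = quant.copy()
    with_extremum[int(np.argmin(np.abs(quant - extremum)))] = extremum

    best = None
    for start in range(n_starts):
        if start == 0:
            centers = peel_centers()
        elif start == 1:
            centers = quant.copy()
        elif start == 2:
            centers = with_extremum.copy()
        else:
            base = (peel_centers(), quant, with_extremum)[start % 3]
            centers = base + rng.normal(0.0, span / 12.0, n_components)
        centers = np.clip(np.sort(centers), lo, hi)
        params = lmfit.Parameters()
        for i, c in enumerate(centers):
            a0 = float(np.interp(c, x, y))
            if a0 == 0.0:
                a0 = float(y[np.argmax(np.abs(y))]) / n_components
            params.add(f"a{i}", value=a0)
            params.add(f"c{i}", value=float(c), min=lo, max=hi)
            params.add(
                f"w{i}",
                value=init_fwhm * float(rng.uniform(0.8, 1.2)) if start > 2 else init_fwhm,
                min=fwhm_bounds[0],
                max=fwhm_bounds[1],
            )
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception:  # singular steps on bad starts are expected
            continue
        if not out.success:
            continue
        rms = float(np.sqrt(np.mean(out.residual**2)))
        if best is None or rms < best[0]:
            best = (rms, out)

    if best is None:
        return FitResult(
            components=[],
            residual=np.full_like(y, np.nan),
            converged=False,
            rms_residual=float("nan"),
            region=(lo, hi),
            n_starts=n_starts,
            message="no start converged",
        )
    rms, out = best
    comps = sorted(
        (
            GaussianComponent(
                center=out.params[f"c{i}"].value,
                fwhm=out.params[f"w{i}"].value,
                amplitude=out.params[f"a{i}"].value,
            )
            for i in range(n_components)
        ),
        key=lambda c: c.center,
    )
    at_bound = any(
        np.isclose(c.fwhm, fwhm_bounds[0]) or np.isclose(c.fwhm, fwhm_bounds[1])
        for c in comps
    )
    return FitResult(
        components=comps,
        residual=out.residual.copy(),
        converged=True,
        rms_residual=rms,
        region=(lo, hi),
        n_starts=n_starts,
        message="width at bound" if at_bound else "",
    )


def _parabolic_refine(x, y, i) -> tuple:
    """3-point parabola through (x[i-1..i+1], y); returns (x*, y*)."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom == 0:
        return float(x1), float(y1)
    # uniform-spacing parabola is exact; general form via fit for safety
    coef = np.polyfit(np.array([x0, x1, x2]), np.array([y0, y1, y2]), 2)
    if coef[0] == 0:
        return float(x1), float(y1)
    xs = -coef[1] / (2 * coef[0])
    if not (min(x0, x2) <= xs <= max(x0, x2)):
        return float(x1), float(y1)
    return float(xs), float(np.polyval(coef, xs))


def spectral_features(
    spec: Spectrum,
    region: tuple | None = None,
    probes=(),
    ratio_pairs=(),
) -> dict:
    """Extrema, probe intensities and intensity ratios of a spectrum.

    Returns a dict with the argmax/argmin wavelengths inside ``region``
    (parabolically refined around the extreme samples), linearly interpolated
    intensities at each probe wavelength, and the intensity ratio for each
    ``(num, den)`` pair.
    """
    s = spec.sorted()
    if region is None:
        region = (s.x[0], s.x[-1])
    lo, hi = region
    mask = (s.x >= lo) & (s.x <= hi)
    if mask.sum() < 3:
        raise ValueError("region holds fewer than 3 samples")
    x, y = s.x[mask], s.y[mask]
    imax, imin = int(np.argmax(y)), int(np.argmin(y))
    x_max, y_max = _parabolic_refine(x, y, imax)
    x_min, y_min = _parabolic_refine(x, y, imin)
    out = {
        "argmax": x_max,
        "max": y_max,
        "argmin": x_min,
        "min": y_min,
        "probes": {},
        "ratios": {},
    }
    for p in probes:
        out["probes"][float(p)] = float(s.interp(p))
    for num, den in ratio_pairs:
        denom = float(s.interp(den))
        if denom == 0:
            raise ZeroDivisionError(f"zero intensity at denominator probe {den} nm")
        out["ratios"][(float(num), float(den))] = float(s.interp(num)) / denom
    return out
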