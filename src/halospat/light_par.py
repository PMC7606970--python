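"""Intra-nodule light transmission and PAR estimation.

Spectra measured inside halite nodules (fiber-optic probe under a
broad-spectrum lamp) are divided by the unobstructed source spectrum to get
an effective transmission fraction per wavelength; the analysis window is
restricted to 500–900 nm where the measurements are reliable.  Transmission
profiles are standardized to the mean of the top-position measurements to
absorb inter-nodule variability.  Photosynthetically active radiation (PAR)
inside the nodule is estimated by band-integrating the transmitted solar
spectrum over 400–700 nm, dividing by the integrated solar spectrum, and
scaling by the maximum midday solar PAR (2100 µmol photons/m²/s at the
study site).  Because light scatters within the salt matrix, an optional
isotropy correction 1 + (upwelling/downwelling intensity ratio) may be
applied; it is off by default.

Where the PAR band extends below the data window, integration is carried out
over the intersection actually covered by both spectra and the effective
band is reported; extrapolation outside the data range is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "TransmissionProfile",
    "BandIntegralRatio",
    "ParEstimate",
    "DEFAULT_WINDOW_NM",
    "PAR_BAND_NM",
    "DEFAULT_PAR_MAX",
    "effective_transmission",
    "standardize_to_reference",
    "par_reduction_ratio",
    "estimate_par",
    "isotropy_correction",
    "band_ratio",
]

DEFAULT_WINDOW_NM = (500.0, 900.0)
PAR_BAND_NM = (400.0, 700.0)
DEFAULT_PAR_MAX = 2100.0  # µmol photons / m² / s, midday maximum at the site


@dataclass
class Spectrum:
    """Intensity (arbitrary detector units) on a strictly increasing
    wavelength grid in nm."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity shapes differ")
        if len(self.wavelength_nm) < 2:
            raise ValueError("spectrum needs at least two points")
        if not (np.diff(self.wavelength_nm) > 0).all():
            raise ValueError("wavelengths must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def interp(self, grid) -> np.ndarray:
        """Linear interpolation onto ``grid`` (must lie within range)."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.range_nm
        if grid.size and (grid.min() < lo or grid.max() > hi):
            raise ValueError("grid extends outside the measured range")
        return np.interp(grid, self.wavelength_nm, self.intensity)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(float), df["intensity"].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "intensity": self.intensity}
        ).to_csv(path, index=False)


@dataclass
class TransmissionProfile:
    """Effective transmission fraction per wavelength at one intra-nodule
    position.  Values may slightly exceed 1 from detector noise."""

    wavelength_nm: np.ndarray
    transmission: np.ndarray
    position: str = ""
    nodule: str = ""

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.transmission = np.asarray(self.transmission, dtype=float)
        if self.wavelength_nm.shape != self.transmission.shape:
            raise ValueError("wavelength and transmission shapes differ")
        if not np.isfinite(self.transmission).all():
            raise ValueError("transmission values must be finite")

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def interp(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.range_nm
        if grid.size and (grid.min() < lo or grid.max() > hi):
            raise ValueError("grid extends outside the profile range")
        return np.interp(grid, self.wavelength_nm, self.transmission)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "transmission": self.transmission}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BandIntegralRatio:
    """Band-integrated transmitted/incident ratio with the band actually
    integrated (intersection of the requested band and the data coverage)."""

    ratio: float
    band_nm: tuple[float, float]


@dataclass(frozen=True)
class ParEstimate:
    """PAR available at a position, µmol photons/m²/s."""

    par: float
    reduction_ratio: float
    par_max: float
    correction: float


def effective_transmission(
    measured: Spectrum,
    source: Spectrum,
    window: tuple[float, float] = DEFAULT_WINDOW_NM,
) -> TransmissionProfile:
    """Pointwise measured/source intensity ratio within the analysis window.

    The ratio is evaluated on the measured grid points that fall inside both
    spectra's ranges and the window; the source is linearly interpolated onto
    those points.
    """
    lo = max(measured.range_nm[0], source.range_nm[0], window[0])
    hi = min(measured.range_nm[1], source.range_nm[1], window[1])
    grid = measured.wavelength_nm
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        raise ValueError(
            "no usable wavelength overlap between measured and source "
            f"spectra within window {window}"
        )
    src = source.interp(grid)
    bad = grid[src <= 0]
    if bad.size:
        raise ValueError(
            f"source intensity is zero within the window at wavelengths {bad}"
        )
    return TransmissionProfile(
        wavelength_nm=grid, transmission=measured.interp(grid) / src
    )


def standardize_to_reference(
    profiles: list[TransmissionProfile], reference_position: str = "top"
) -> list[TransmissionProfile]:
    """Divide every profile by the mean profile of the reference position.

    Absorbs inter-nodule variability; the mean of the standardized reference
    profiles is identically 1.
    """
    refs = [p for p in profiles if p.position == reference_position]
    if not refs:
        raise ValueError(f"no profile at reference position {reference_position!r}")
    grid = refs[0].wavelength_nm
    ref_mean = np.mean([r.interp(grid) for r in refs], axis=0)
    if (ref_mean <= 0).any():
        raise ValueError("mean reference transmission is zero at some wavelengths")
    out = []
    for p in profiles:
        out.append(
            replace(p, wavelength_nm=grid, transmission=p.interp(grid) / ref_mean)
        )
    return out


def par_reduction_ratio(
    trans: TransmissionProfile,
    solar: Spectrum,
    band: tuple[float, float] = PAR_BAND_NM,
) -> BandIntegralRatio:
    """Area under the transmitted solar spectrum over the PAR band, divided
    by the area under the incident solar spectrum.

    Trapezoidal integration on the union of both grids restricted to the
    band; the band is clipped to the wavelengths both inputs actually cover.
    """
    lo = max(band[0], trans.range_nm[0], solar.range_nm[0])
    hi = min(band[1], trans.range_nm[1], solar.range_nm[1])
    if lo >= hi:
        raise ValueError(f"band {band} lies outside the data range")
    grid = np.union1d(trans.wavelength_nm, solar.wavelength_nm)
    grid = np.union1d(grid[(grid > lo) & (grid < hi)], [lo, hi])
    t = trans.interp(grid)
    s = solar.interp(grid)
    denom = np.trapezoid(s, grid)
    if denom <= 0:
        raise ValueError("solar spectrum integrates to zero over the band")
    return BandIntegralRatio(
        ratio=float(np.trapezoid(t * s, grid) / denom), band_nm=(lo, hi)
    )


def estimate_par(
    ratio: float,
    par_max: float = DEFAULT_PAR_MAX,
    correction: float = 1.0,
) -> ParEstimate:
    """PAR = reduction ratio × maximum solar PAR × isotropy correction.

    The correction defaults to 1 (no correction); pass the factor from
    :func:`isotropy_correction` to account for scattered upwelling light.
    """
    if ratio < 0:
        raise ValueError("reduction ratio must be non-negative")
    if par_max <= 0:
        raise ValueError("par_max must be positive")
    if correction < 1:
        raise ValueError("correction factor must be >= 1")
    return ParEstimate(
        par=float(ratio * par_max * correction),
        reduction_ratio=float(ratio),
        par_max=float(par_max),
        correction=float(correction),
    )


def _band_integral(spec, band) -> float:
    if np.isscalar(spec):
        return float(spec)
    lo = max(band[0], spec.range_nm[0]) if band else spec.range_nm[0]
    hi = min(band[1], spec.range_nm[1]) if band else spec.range_nm[1]
    if lo >= hi:
        raise ValueError("band lies outside the spectrum range")
    grid = spec.wavelength_nm
    grid = np.union1d(grid[(grid > lo) & (grid < hi)], [lo, hi])
    return float(np.trapezoid(spec.interp(grid), grid))


def isotropy_correction(downward, upward, band=None) -> float:
    """Correction for scattered light inside the salt matrix.

    ``downward`` is the intensity measured with the probe aimed away from
    the incident light (upwelling, back-scattered light), ``upward`` with the
    probe aimed toward it.  The factor is
    1 + (band-integrated downward / band-integrated upward); a downward/upward
    ratio of 30 % gives 1.3.  Accepts scalars or :class:`Spectrum` inputs.
    """
    num = _band_integral(downward, band)
    den = _band_integral(upward, band)
    if den <= 0:
        raise ValueError("upward intensity must be positive")
    if num < 0:
        raise ValueError("downward intensity must be non-negative")
    return 1.0 + num / den


def band_ratio(
    trans_a: TransmissionProfile,
    trans_b: TransmissionProfile,
    wavelength: float = 680.0,
    halfwidth: float = 10.0,
) -> float:
    """Mean transmission of ``trans_a`` over [λ±halfwidth] divided by that of
    ``trans_b``; used e.g. for the chlorophyll-a excitation band at 680 nm.

    With ``halfwidth=0`` the ratio is taken pointwise at λ by linear
    interpolation.
    """
    lo, hi = wavelength - halfwidth, wavelength + halfwidth
    for p in (trans_a, trans_b):
        if lo < p.range_nm[0] or hi > p.range_nm[1]:
            raise ValueError(
                f"window [{lo}, {hi}] nm not covered by profile {p.position!r}"
            )
    if halfwidth == 0:
        a = float(trans_a.interp([wavelength])[0])
        b = float(trans_b.interp([wavelength])[0])
    else:
        grid = np.union1d(
            np.union1d(trans_a.wavelength_nm, trans_b.wavelength_nm), [lo, hi]
        )
        grid = grid[(grid >= lo) & (grid <= hi)]
        width = hi - lo
        a = float(np.trapezoid(trans_a.interp(grid), grid) / width)
        b = float(np.trapezoid(trans_b.interp(grid), grid) / width)
    if b == 0:
        raise ValueError("reference profile transmission is zero in the window")
    return a / b
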