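"""Spectral-angle core: per-pixel angle maps and distribution summaries.

The spectral angle between a reference spectrum ``S_a`` and a test spectrum
``S_b`` treats both as B-dimensional vectors::

    theta = arccos( (S_a . S_b) / (|S_a| |S_b|) )     [degrees]

It is invariant to positive scaling of either argument, which makes it an
illumination-independent dissimilarity between reflectance spectra.  For
non-negative spectra the angle lies in [0, 90] degrees.

The coverage analysis computes theta for every pixel of a working ROI
against the mean spectrum of a reference ROI, then summarises the resulting
distribution (mean ``mu_theta``, population standard deviation
``sigma_theta``, fixed-width histogram).  Pixels whose spectrum has zero
norm or non-finite values cannot produce an angle; they are masked, counted
in QC, and excluded from all summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .datacube import Datacube, WavelengthGrid
from .roi import ROI

__all__ = [
    "Spectrum",
    "AngleMap",
    "AngleSummary",
    "spectral_angle",
    "mean_spectrum",
    "angle_map",
    "summarize",
]

DEFAULT_BIN_WIDTH_DEG = 0.1


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum on a wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("spectrum values must be 1-D")
        if vals.size != len(self.grid):
            raise ValueError(
                f"spectrum length {vals.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass
class AngleMap:
    """Per-pixel spectral angles (degrees) over an ROI.

    ``theta_deg`` has the ROI's shape; masked pixels (zero-norm or
    non-finite spectra) hold NaN and are flagged in ``mask``.
    """

    theta_deg: np.ndarray
    roi: ROI
    reference: Spectrum
    reference_mode: str = "same_timepoint"  # or "fixed_T0"

    def __post_init__(self) -> None:
        if self.theta_deg.shape != (self.roi.height_px, self.roi.width_px):
            raise ValueError("angle map shape must equal the ROI extent")
        if self.reference_mode not in ("same_timepoint", "fixed_T0"):
            raise ValueError(f"unknown reference mode {self.reference_mode!r}")

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel is masked (no valid angle)."""
        return ~np.isfinite(self.theta_deg)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def valid(self) -> np.ndarray:
        """Flat array of valid angles."""
        return self.theta_deg[~self.mask]

    def mean(self) -> float:
        valid = self.valid
        if valid.size == 0:
            raise ValueError("all pixels in the angle map are masked")
        return float(valid.mean())


@dataclass
class AngleSummary:
    """Distribution summary of an angle map: mu, sigma and a histogram."""

    mu_theta_deg: float
    sigma_theta_deg: float
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    n_pixels: int
    n_masked: int = 0

    def to_dict(self) -> dict:
        return {
            "mu_theta_deg": self.mu_theta_deg,
            "sigma_theta_deg": self.sigma_theta_deg,
            "bin_edges_deg": self.bin_edges_deg.tolist(),
            "counts": self.counts.tolist(),
            "n_pixels": self.n_pixels,
            "n_masked": self.n_masked,
        }


def spectral_angle(sa: Spectrum, sb: Spectrum) -> float:
    """Angle in degrees between two spectra on the same grid.

    Evaluated through the chord of the unit vectors,
    ``theta = 2 * arcsin(|u_a - u_b| / 2)``, which is algebraically equal to
    the clamped ``arccos`` of the normalised dot product but numerically
    stable near theta = 0, where the arccosine loses half its precision.
    """
    if sa.grid != sb.grid:
        raise ValueError("spectra are on different wavelength grids")
    na, nb = sa.norm, sb.norm
    if na == 0.0 or nb == 0.0:
        raise ValueError("spectral angle is undefined for a zero-norm spectrum")
    chord = float(np.linalg.norm(sa.values / na - sb.values / nb))
    half = min(1.0, max(-1.0, chord / 2.0))
    return float(np.degrees(2.0 * np.arcsin(half)))


def mean_spectrum(cube: Datacube, roi: ROI) -> Spectrum:
    """Per-band arithmetic mean spectrum over an ROI."""
    roi.check_inside(cube.shape)
    rs, cs = roi.slices
    block = cube.data[rs, cs, :]
    if block.size == 0:
        raise ValueError("ROI contains no pixels")
    return Spectrum(values=block.reshape(-1, cube.n_bands).mean(axis=0), grid=cube.grid)


def angle_map(
    cube: Datacube,
    work_roi: ROI,
    reference: Spectrum,
    reference_mode: str = "same_timepoint",
) -> AngleMap:
    """Spectral angle of every pixel in ``work_roi`` against ``reference``.

    Zero-norm pixels are masked (NaN) rather than raising; they are counted
    via :attr:`AngleMap.n_masked` and excluded from summaries.
    """
    if reference.grid != cube.grid:
        raise ValueError("reference spectrum is not on the cube's wavelength grid")
    if reference.norm == 0.0:
        raise ValueError("reference spectrum has zero norm")
    work_roi.check_inside(cube.shape)
    rs, cs = work_roi.slices
    block = cube.data[rs, cs, :]
    flat = block.reshape(-1, cube.n_bands)
    norms = np.linalg.norm(flat, axis=1)
    uref = reference.values / reference.norm
    with np.errstate(invalid="ignore", divide="ignore"):
        units = flat / norms[:, None]
        chord = np.linalg.norm(units - uref[None, :], axis=1)
    theta = np.degrees(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
    theta[norms == 0.0] = np.nan
    return AngleMap(
        theta_deg=theta.reshape(work_roi.height_px, work_roi.width_px),
        roi=work_roi,
        reference=reference,
        reference_mode=reference_mode,
    )


def summarize(
    amap: AngleMap, bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG
) -> AngleSummary:
    """Mean, population SD and fixed-width histogram of an angle map.

    Bins run from 0 to the smallest multiple of ``bin_width_deg`` at or
    above the maximum angle (at least one bin), so every valid pixel is
    counted exactly once.
    """
    if bin_width_deg <= 0:
        raise ValueError("bin_width_deg must be > 0")
    valid = amap.valid
    if valid.size == 0:
        raise ValueError("cannot summarise an angle map with all pixels masked")
    mu = float(valid.mean())
    sigma = float(valid.std(ddof=0))
    top = max(float(valid.max()), bin_width_deg)
    n_bins = int(np.ceil(top / bin_width_deg - 1e-12))
    n_bins = max(n_bins, 1)
    edges = np.arange(n_bins + 1) * bin_width_deg
    if edges[-1] < top:  # guard against rounding at the top edge
        edges = np.append(edges, edges[-1] + bin_width_deg)
    counts, edges = np.histogram(valid, bins=edges)
    return AngleSummary(
        mu_theta_deg=mu,
        sigma_theta_deg=sigma,
        bin_edges_deg=edges,
        counts=counts,
        n_pixels=int(valid.size),
        n_masked=amap.n_masked,
    )
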