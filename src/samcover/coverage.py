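"""Coverage statistics from paired before/after spectral-angle distributions.

Two reference modes drive the analysis of a (T0, Timm) measurement pair:

* *Spectral homogeneity* — each pixel of the working ROI is compared against
  the mean spectrum of the reference ROI at the **same** time point, giving
  ``mu_theta_ROI(t)``.  The homogeneity factor is the percentage shift::

      alpha_HF = 100 * (1 - mu_theta_ROI(Timm) / mu_theta_ROI(T0))

  ranging from -inf (drastic homogeneity loss) to 100 (perfect homogeneity:
  every spectrum in the ROI equals the ROI average, so the mean angle at
  Timm is zero).

* *Spectral change* — pixels at both time points are compared against the
  reference-ROI mean spectrum **fixed at T0**, giving
  ``mu_theta_ROI@T0(t)``.  The spectral shift factor is the signed
  difference::

      beta_SF = mu_theta_ROI@T0(Timm) - mu_theta_ROI@T0(T0)

  an illumination-independent analogue of the colour difference Delta-E.

``delta_mu = mu_theta(Timm) - mu_theta(T0)`` (same-time-point reference) is
the raw signed shift: negative means the homogeneity increased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .angles import (
    DEFAULT_BIN_WIDTH_DEG,
    AngleSummary,
    angle_map,
    mean_spectrum,
    spectral_angle,
    summarize,
)
from .datacube import Datacube
from .roi import ROI

__all__ = [
    "CoverageResult",
    "ContrastResult",
    "homogeneity_factor",
    "spectral_shift_factor",
    "delta_mu",
    "contrast_reduction",
    "evaluate_pair",
    "peak_positions",
]


#: Below this mean angle (degrees) a T0 scene is treated as numerically
#: uniform: the alpha_HF ratio would amplify pure floating-point residue,
#: so it is reported as NaN with a QC flag instead.  Real scenes sit orders
#: of magnitude above this (sensor noise alone gives ~1 degree).
DEGENERATE_MU_FLOOR_DEG = 1e-9


@dataclass
class CoverageResult:
    """Coverage statistics for one (model, product) measurement pair."""

    alpha_hf: float  # percent
    beta_sf: float  # degrees
    delta_mu_theta: float  # degrees
    mu_roi_T0: float  # same-timepoint reference, at T0
    mu_roi_Timm: float  # same-timepoint reference, at Timm
    mu_roiT0_T0: float  # fixed-T0 reference, at T0
    mu_roiT0_Timm: float  # fixed-T0 reference, at Timm
    sigma_roi_T0: float = float("nan")
    sigma_roi_Timm: float = float("nan")
    model: str = ""
    product: str = ""
    qc_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "product": self.product,
            "alpha_hf": self.alpha_hf,
            "beta_sf": self.beta_sf,
            "delta_mu_theta": self.delta_mu_theta,
            "mu_roi_T0": self.mu_roi_T0,
            "mu_roi_Timm": self.mu_roi_Timm,
            "mu_roiT0_T0": self.mu_roiT0_T0,
            "mu_roiT0_Timm": self.mu_roiT0_Timm,
            "sigma_roi_T0": self.sigma_roi_T0,
            "sigma_roi_Timm": self.sigma_roi_Timm,
            "qc_flags": ";".join(self.qc_flags),
        }


@dataclass
class ContrastResult:
    """Skin-spot contrast before/after application and its reduction."""

    delta_skin_spot_pre: float  # degrees
    delta_skin_spot_post: float  # degrees
    reduction_percent: float


def homogeneity_factor(mu_T0: float, mu_Timm: float) -> float:
    """alpha_HF = 100 * (1 - mu_Timm / mu_T0), in percent.

    Positive values mean the homogeneity increased; 100 is the
    perfect-homogeneity limit (all spectra equal to the average at Timm).
    """
    if not (mu_T0 > 0):
        raise ValueError(
            f"mu_theta(T0) must be > 0 (got {mu_T0}); the ratio is undefined"
        )
    if mu_Timm < 0:
        raise ValueError("mu_theta(Timm) must be >= 0")
    return 100.0 * (1.0 - mu_Timm / mu_T0)


def spectral_shift_factor(mu_fixedT0_at_Timm: float, mu_fixedT0_at_T0: float) -> float:
    """beta_SF = mu_theta@T0(Timm) - mu_theta@T0(T0), in degrees (signed)."""
    if not (np.isfinite(mu_fixedT0_at_Timm) and np.isfinite(mu_fixedT0_at_T0)):
        raise ValueError("inputs must be finite")
    if mu_fixedT0_at_Timm < 0 or mu_fixedT0_at_T0 < 0:
        raise ValueError("mean spectral angles must be >= 0")
    return mu_fixedT0_at_Timm - mu_fixedT0_at_T0


def delta_mu(mu_Timm: float, mu_T0: float) -> float:
    """Signed shift of the mean angle; negative = homogeneity increased."""
    if not (np.isfinite(mu_Timm) and np.isfinite(mu_T0)):
        raise ValueError("inputs must be finite")
    return mu_Timm - mu_T0


def contrast_reduction(pre: float, post: float) -> ContrastResult:
    """Reduction of skin-spot contrast: 100 * (1 - post/pre) percent."""
    if not (pre > 0):
        raise ValueError("pre-application contrast must be > 0")
    if post < 0:
        raise ValueError("post-application contrast must be >= 0")
    return ContrastResult(
        delta_skin_spot_pre=pre,
        delta_skin_spot_post=post,
        reduction_percent=100.0 * (1.0 - post / pre),
    )


def evaluate_pair(
    cube_T0: Datacube,
    cube_Timm: Datacube,
    ref_roi: ROI,
    work_roi: ROI,
    model: str = "",
    product: str = "",
) -> CoverageResult:
    """Full coverage evaluation of one measurement pair.

    Computes the four mean spectral angles (two reference modes at two time
    points) over ``work_roi``, with references taken as the mean spectrum of
    ``ref_roi``, then derives alpha_HF, beta_SF and delta-mu-theta.

    The same-time-point reference at Timm is recomputed from the Timm cube
    (no pixel registration between time points is assumed).  If the T0 scene
    is perfectly uniform (``mu_theta(T0) == 0``) alpha_HF is reported as NaN
    with a QC flag instead of raising, since beta_SF remains well defined.
    """
    if cube_T0.grid != cube_Timm.grid:
        raise ValueError("T0 and Timm cubes are on different wavelength grids")
    qc: list[str] = []

    ref_T0 = mean_spectrum(cube_T0, ref_roi)
    ref_Timm = mean_spectrum(cube_Timm, ref_roi)
    if ref_T0.norm == 0.0 or ref_Timm.norm == 0.0:
        raise ValueError("degenerate (zero-norm) reference spectrum")

    map_roi_T0 = angle_map(cube_T0, work_roi, ref_T0, "same_timepoint")
    map_roi_Timm = angle_map(cube_Timm, work_roi, ref_Timm, "same_timepoint")
    map_fix_Timm = angle_map(cube_Timm, work_roi, ref_T0, "fixed_T0")

    s_roi_T0 = summarize(map_roi_T0)
    s_roi_Timm = summarize(map_roi_Timm)
    s_fix_Timm = summarize(map_fix_Timm)
    # Fixed-T0 reference at T0 coincides with the same-timepoint map at T0.
    mu_fix_T0 = s_roi_T0.mu_theta_deg

    n_masked = map_roi_T0.n_masked + map_roi_Timm.n_masked + map_fix_Timm.n_masked
    if n_masked:
        qc.append(f"masked_pixels={n_masked}")

    if s_roi_T0.mu_theta_deg > DEGENERATE_MU_FLOOR_DEG:
        alpha = homogeneity_factor(s_roi_T0.mu_theta_deg, s_roi_Timm.mu_theta_deg)
    else:
        alpha = float("nan")
        qc.append("degenerate_t0_uniform_scene")
    beta = spectral_shift_factor(s_fix_Timm.mu_theta_deg, mu_fix_T0)
    if beta < 0:
        qc.append("negative_beta_sf")

    return CoverageResult(
        alpha_hf=alpha,
        beta_sf=beta,
        delta_mu_theta=delta_mu(s_roi_Timm.mu_theta_deg, s_roi_T0.mu_theta_deg),
        mu_roi_T0=s_roi_T0.mu_theta_deg,
        mu_roi_Timm=s_roi_Timm.mu_theta_deg,
        mu_roiT0_T0=mu_fix_T0,
        mu_roiT0_Timm=s_fix_Timm.mu_theta_deg,
        sigma_roi_T0=s_roi_T0.sigma_theta_deg,
        sigma_roi_Timm=s_roi_Timm.sigma_theta_deg,
        model=model,
        product=product,
        qc_flags=qc,
    )


def peak_positions(
    summary: AngleSummary,
    min_separation_deg: float = 0.5,
    smooth_bins: int = 5,
) -> list[tuple[float, float]]:
    """Peaks of the angle histogram, as (position_deg, mass_fraction).

    The histogram counts are smoothed with a ``smooth_bins``-wide moving
    average, local maxima separated by at least ``min_separation_deg`` are
    located, and every bin's mass is assigned to the nearest peak.  Peaks
    are returned ordered by position; the first corresponds to the base
    skin, later ones to features such as pigmented spots.  Peaks closer
    than the separation merge into one.
    """
    counts = np.asarray(summary.counts, dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("histogram is empty")
    edges = np.asarray(summary.bin_edges_deg, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]

    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts
    distance = max(1, int(np.ceil(min_separation_deg / bin_width)))
    idx, _ = find_peaks(smoothed, distance=distance)
    if idx.size == 0:
        idx = np.array([int(np.argmax(smoothed))])

    positions = centers[idx]
    # Assign each bin's mass to the nearest peak.
    nearest = np.argmin(np.abs(centers[:, None] - positions[None, :]), axis=1)
    total = counts.sum()
    fractions = np.array(
        [counts[nearest == k].sum() / total for k in range(positions.size)]
    )
    order = np.argsort(positions)
    return [(float(positions[k]), float(fractions[k])) for k in order]
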