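"""Randomised multi-scale ROI analysis: homogeneity and evenness vs. scale.

A single ROI gives one sample of the coverage statistics; where that ROI
sits, and how big it is, changes the answer (a region that straddles a
strong spot is not the region next to it).  To characterise the whole
working region at all scales, many square ROIs of random size and random
position are drawn inside it.  The across-ROI *variance* of a metric at a
given ROI size measures the texture or evenness of the skin at that scale:
for freckle-sized ROIs the metric jumps from ROI to ROI, while ROIs much
larger than the freckles average over many of them and the variance drops.

ROIs may overlap (dense coverage of the region is the point), sizes are
drawn uniformly in millimetres, and everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import angle_map, mean_spectrum, summarize
from .coverage import homogeneity_factor
from .colorimetry import delta_e_values, reflectance_to_lab
from .datacube import Datacube
from .roi import ROI, mm_to_px

__all__ = ["MultiROIConfig", "ScaleProfile", "sample_rois", "scale_profile"]

METRICS = ("mu_theta", "alpha_hf", "mean_lab")


@dataclass(frozen=True)
class MultiROIConfig:
    """Configuration of a randomised multi-scale ROI draw."""

    working_region: ROI
    n_rois: int = 500
    size_range_mm: tuple[float, float] = (1.0, 10.0)
    seed: int = 0
    metric: str = "mu_theta"
    n_size_bins: int = 5

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        lo, hi = self.size_range_mm
        if not (0 < lo <= hi):
            raise ValueError("size range must satisfy 0 < min <= max")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.n_size_bins < 1:
            raise ValueError("n_size_bins must be >= 1")


@dataclass
class ScaleProfile:
    """Across-ROI metric statistics per ROI-size bin."""

    metric: str
    bin_edges_mm: np.ndarray
    mean: np.ndarray  # NaN where the bin is empty
    variance: np.ndarray  # population variance; NaN where count < 1
    count: np.ndarray
    per_roi: pd.DataFrame  # columns: size_mm, row0, col0, value

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size_bin_lo_mm": self.bin_edges_mm[:-1],
                "size_bin_hi_mm": self.bin_edges_mm[1:],
                "metric_mean": self.mean,
                "metric_var": self.variance,
                "n": self.count,
            }
        )


def sample_rois(config: MultiROIConfig, cube: Datacube) -> list[ROI]:
    """Draw ``n_rois`` square ROIs inside the working region.

    Side length is uniform in ``size_range_mm`` (converted through the
    cube's pixel pitch), position uniform over all placements fully inside
    the working region.  Deterministic for a fixed seed.
    """
    region = config.working_region
    region.check_inside(cube.shape)
    lo_mm, hi_mm = config.size_range_mm
    max_side = mm_to_px(hi_mm, cube.pixel_pitch_um)
    if max_side > min(region.height_px, region.width_px):
        raise ValueError(
            f"maximum ROI side {max_side} px exceeds the working region "
            f"({region.height_px}x{region.width_px} px)"
        )
    if mm_to_px(lo_mm, cube.pixel_pitch_um) < 2:
        raise ValueError("minimum ROI size converts to fewer than 2 px")
    rng = np.random.default_rng(config.seed)
    rois = []
    for i in range(config.n_rois):
        size_mm = float(rng.uniform(lo_mm, hi_mm))
        side = mm_to_px(size_mm, cube.pixel_pitch_um)
        row0 = int(rng.integers(region.row0, region.row1 - side + 1))
        col0 = int(rng.integers(region.col0, region.col1 - side + 1))
        roi = ROI(name=f"mroi_{i}", row0=row0, col0=col0, height_px=side, width_px=side)
        # Stash the drawn physical size for binning.
        object.__setattr__(roi, "_size_mm", size_mm)
        rois.append(roi)
    return rois


def _roi_metric(
    metric: str,
    roi: ROI,
    cube_T0: Datacube,
    cube_Timm: Datacube | None,
    region_mean_lab: np.ndarray | None,
) -> float:
    if metric == "mu_theta":
        ref = mean_spectrum(cube_T0, roi)
        return summarize(angle_map(cube_T0, roi, ref)).mu_theta_deg
    if metric == "alpha_hf":
        # Local reference at each time point, per the ROI-relative
        # definition of the homogeneity factor.
        if cube_Timm is None:
            raise ValueError("alpha_hf metric needs a Timm cube")
        mu0 = summarize(angle_map(cube_T0, roi, mean_spectrum(cube_T0, roi))).mu_theta_deg
        mu1 = summarize(
            angle_map(cube_Timm, roi, mean_spectrum(cube_Timm, roi))
        ).mu_theta_deg
        if mu0 <= 0:
            return float("nan")
        return homogeneity_factor(mu0, mu1)
    if metric == "mean_lab":
        # Colour deviation of the ROI from the working region: Delta-E76
        # between the ROI mean colour and the region mean colour at T0.
        lab = reflectance_to_lab(cube_T0, roi)
        return float(delta_e_values(lab.mean(), region_mean_lab))
    raise ValueError(f"unknown metric {metric!r}")


def scale_profile(
    cube_T0: Datacube,
    cube_Timm: Datacube | None,
    config: MultiROIConfig,
) -> ScaleProfile:
    """Across-ROI mean and variance of the chosen metric, per size bin.

    Sizes are binned into ``n_size_bins`` log-spaced bins over the size
    range (a single bin when min == max).  Empty bins are reported with
    count 0 and NaN statistics.  Bit-reproducible for a fixed seed.
    """
    rois = sample_rois(config, cube_T0)
    region_mean_lab = None
    if config.metric == "mean_lab":
        region_mean_lab = reflectance_to_lab(cube_T0, config.working_region).mean()

    sizes = np.array([getattr(r, "_size_mm") for r in rois])
    values = np.array(
        [
            _roi_metric(config.metric, r, cube_T0, cube_Timm, region_mean_lab)
            for r in rois
        ]
    )

    lo, hi = config.size_range_mm
    if lo == hi:
        edges = np.array([lo, hi])
    else:
        edges = np.geomspace(lo, hi, config.n_size_bins + 1)
    which = np.clip(np.searchsorted(edges, sizes, side="right") - 1, 0, len(edges) - 2)

    n_bins = len(edges) - 1
    mean = np.full(n_bins, np.nan)
    var = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = values[which == b]
        sel = sel[np.isfinite(sel)]
        count[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            var[b] = sel.var(ddof=0)
    per_roi = pd.DataFrame(
        {
            "size_mm": sizes,
            "row0": [r.row0 for r in rois],
            "col0": [r.col0 for r in rois],
            "side_px": [r.height_px for r in rois],
            "value": values,
        }
    )
    return ScaleProfile(
        metric=config.metric,
        bin_edges_mm=edges,
        mean=mean,
        variance=var,
        count=count,
        per_roi=per_roi,
    )
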