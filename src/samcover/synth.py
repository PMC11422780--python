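"""Synthetic hyperspectral facial-patch scenes with ground truth.

The generator emulates the study conditions of a foundation-coverage test:
flat skin patches whose per-pixel reflectance spectra follow a smooth
logistic rise with wavelength (optionally carved by haemoglobin absorption
dips near 540 and 575 nm), darker melanin-like pigmented spots of varying
size and strength, foundation application as a linear spectral blend toward
a product shade with opacity ``o``, and multiplicative sensor noise at a
detector signal-to-noise ratio of 47.

Spatial structure comes from a smooth random melanin "mottle" field (the
base-skin angle-distribution width) plus disk-shaped spots (the secondary
peaks at higher spectral angle).  Because a pixel's spectral *angle* is
invariant to scalar gain, inhomogeneity is injected through the
wavelength-dependent melanin attenuation ``exp(-m * (lambda/550)^-3)``
rather than through brightness variation.

The foundation blend ``(1-o) * S + o * shade`` is a deliberate
simplification of film optics (no Kubelka-Munk scattering model); it
produces the qualitative behaviours the analysis relies on — spots and skin
both shift toward the shade, homogeneity rises with opacity, and the
full-opacity noiseless limit is analytically exact (all spectra equal the
shade, so alpha_HF = 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .angles import Spectrum
from .datacube import (
    DEFAULT_PIXEL_PITCH_UM,
    Datacube,
    WavelengthGrid,
    default_grid,
)

__all__ = [
    "SkinParams",
    "SpotParams",
    "ProductParams",
    "SimConfig",
    "SimScene",
    "skin_spectrum",
    "spot_spectrum",
    "apply_foundation",
    "add_noise",
    "generate_scene",
    "MODEL_PRESETS",
    "PRODUCT_PRESETS",
    "study_scenes",
    "study_table",
]

#: Detector signal-to-noise ratio of the emulated instrument.
DEFAULT_SNR = 47.0


@dataclass(frozen=True)
class SkinParams:
    """Parameters of the smooth bare-skin reflectance curve.

    The curve is a logistic rise ``r_min + (r_max - r_min) / (1 + exp(-(l -
    lambda0)/width))`` minus Gaussian haemoglobin dips at 540 and 575 nm.
    Defaults give a light skin tone rising from ~0.2 at 420 nm to ~0.55 at
    730 nm, the qualitative shape of measured cheek spectra.
    """

    r_min: float = 0.18
    r_max: float = 0.60
    lambda0_nm: float = 590.0
    width_nm: float = 45.0
    hb_dip_540: float = 0.035
    hb_dip_575: float = 0.025
    hb_width_nm: float = 12.0
    #: SD of the smooth per-pixel melanin mottle field (homogeneity floor).
    mottle_sd: float = 0.04
    #: Correlation length of the mottle field, mm.
    mottle_scale_mm: float = 1.5


@dataclass(frozen=True)
class SpotParams:
    """Pigmented-spot population: disk count, radii (mm), melanin strengths."""

    n_spots: int = 12
    radius_mm: tuple[float, float] = (0.4, 1.2)
    melanin: tuple[float, float] = (0.10, 0.30)


@dataclass(frozen=True)
class ProductParams:
    """A foundation product: shade spectrum parameters and opacity."""

    name: str = "product"
    opacity: float = 0.5
    shade: SkinParams = SkinParams(
        r_min=0.30, r_max=0.62, lambda0_nm=570.0, width_nm=55.0,
        hb_dip_540=0.0, hb_dip_575=0.0,
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError("opacity must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic (T0, Timm) scene."""

    size_px: tuple[int, int] = (96, 96)
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    grid: WavelengthGrid = field(default_factory=default_grid)
    skin: SkinParams = SkinParams()
    spots: SpotParams = SpotParams()
    product: ProductParams = ProductParams()
    snr: float | None = DEFAULT_SNR  # None = noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0 (or None for noiseless)")


@dataclass
class SimScene:
    """A generated scene: measurement pair plus the ground truth behind it."""

    cube_T0: Datacube
    cube_Timm: Datacube
    spot_mask: np.ndarray  # boolean (H, W)
    truth: dict


def skin_spectrum(params: SkinParams, grid: WavelengthGrid | None = None) -> Spectrum:
    """Smooth bare-skin reflectance on a grid; values must stay in (0, 1)."""
    grid = grid or default_grid()
    wl = grid.wavelengths_nm
    rise = params.r_min + (params.r_max - params.r_min) / (
        1.0 + np.exp(-(wl - params.lambda0_nm) / params.width_nm)
    )
    dips = params.hb_dip_540 * np.exp(
        -0.5 * ((wl - 540.0) / params.hb_width_nm) ** 2
    ) + params.hb_dip_575 * np.exp(-0.5 * ((wl - 575.0) / params.hb_width_nm) ** 2)
    values = rise - dips
    if np.any(values <= 0.0) or np.any(values >= 1.0):
        raise ValueError("skin parameters produce reflectance outside (0, 1)")
    return Spectrum(values=values, grid=grid)


def _melanin_od(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Relative melanin optical density, normalised to 1 at 550 nm."""
    return (np.asarray(wavelengths_nm, dtype=float) / 550.0) ** -3.0


def spot_spectrum(base: Spectrum, melanin_strength: float) -> Spectrum:
    """Darken a base spectrum with melanin-like attenuation.

    ``base * exp(-m * (lambda/550)^-3)``: stronger absorption at short
    wavelengths, identity at ``m = 0``.
    """
    if melanin_strength < 0:
        raise ValueError("melanin strength must be >= 0")
    k = _melanin_od(base.grid.wavelengths_nm)
    return Spectrum(values=base.values * np.exp(-melanin_strength * k), grid=base.grid)


def apply_foundation(cube: Datacube, shade: Spectrum, opacity: float) -> Datacube:
    """Linear spectral blend toward the product shade: (1-o)*S + o*shade."""
    if not (0.0 <= opacity <= 1.0):
        raise ValueError("opacity must lie in [0, 1]")
    if shade.grid != cube.grid:
        raise ValueError("shade spectrum is not on the cube's wavelength grid")
    data = (1.0 - opacity) * cube.data + opacity * shade.values
    meta = dict(cube.meta)
    meta["foundation_opacity"] = opacity
    return Datacube(data=data, grid=cube.grid, pixel_pitch_um=cube.pixel_pitch_um, meta=meta)


def add_noise(cube: Datacube, snr: float = DEFAULT_SNR, seed: int = 0) -> Datacube:
    """Multiplicative Gaussian sensor noise: per-voxel sigma = value / snr.

    Negative excursions are clipped at zero (reflectance cannot be
    negative).  Fully reproducible for a fixed seed.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = np.random.default_rng(seed)
    noisy = cube.data * (1.0 + rng.standard_normal(cube.data.shape) / snr)
    np.clip(noisy, 0.0, None, out=noisy)
    return Datacube(
        data=noisy, grid=cube.grid, pixel_pitch_um=cube.pixel_pitch_um, meta=dict(cube.meta)
    )


def _mottle_field(
    shape: tuple[int, int], sd: float, scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth non-negative random field with approximate SD ``sd``."""
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=max(scale_px, 1e-6), mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s * sd
    return np.clip(smooth + 2.0 * sd, 0.0, None)  # shift to keep m >= 0


def generate_scene(config: SimConfig) -> SimScene:
    """Generate a (T0, Timm) pair with ground truth, fully seeded.

    T0 is the bare-skin scene (mottle field + spots) with sensor noise;
    Timm is the clean scene blended toward the product shade at the
    configured opacity, with an independent noise realisation.
    """
    h, w = config.size_px
    grid = config.grid
    rng = np.random.default_rng(config.seed)

    base = skin_spectrum(config.skin, grid)
    k_mel = _melanin_od(grid.wavelengths_nm)

    scale_px = config.skin.mottle_scale_mm * 1000.0 / config.pixel_pitch_um
    m_field = _mottle_field((h, w), config.skin.mottle_sd, scale_px, rng)

    spot_mask = np.zeros((h, w), dtype=bool)
    spot_truth = []
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for _ in range(config.spots.n_spots):
        radius_mm = rng.uniform(*config.spots.radius_mm)
        radius_px = max(1, int(round(radius_mm * 1000.0 / config.pixel_pitch_um)))
        if 2 * radius_px >= min(h, w):
            raise ValueError(
                f"spot radius {radius_px} px does not fit in a {h}x{w} image"
            )
        cr = int(rng.integers(radius_px, h - radius_px))
        cc = int(rng.integers(radius_px, w - radius_px))
        strength = float(rng.uniform(*config.spots.melanin))
        disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius_px**2
        m_field = np.where(disk, m_field + strength, m_field)
        spot_mask |= disk
        spot_truth.append(
            {"row": cr, "col": cc, "radius_px": radius_px, "melanin": strength}
        )

    clean_T0 = base.values[None, None, :] * np.exp(
        -m_field[:, :, None] * k_mel[None, None, :]
    )
    cube_clean_T0 = Datacube(
        data=clean_T0,
        grid=grid,
        pixel_pitch_um=config.pixel_pitch_um,
        meta={"timepoint": "T0", "synthetic": "true"},
    )

    shade = skin_spectrum(config.product.shade, grid)
    cube_clean_Timm = apply_foundation(cube_clean_T0, shade, config.product.opacity)
    cube_clean_Timm.meta["timepoint"] = "Timm"

    if config.snr is not None:
        # Independent noise realisations per time point, derived from the
        # scene seed.
        cube_T0 = add_noise(cube_clean_T0, config.snr, seed=config.seed * 2 + 1)
        cube_Timm = add_noise(cube_clean_Timm, config.snr, seed=config.seed * 2 + 2)
    else:
        cube_T0 = cube_clean_T0
        cube_Timm = cube_clean_Timm

    truth = {
        "spots": spot_truth,
        "opacity": config.product.opacity,
        "product": config.product.name,
        "shade_values": shade.values.tolist(),
        "snr": config.snr,
        "seed": config.seed,
    }
    return SimScene(cube_T0=cube_T0, cube_Timm=cube_Timm, spot_mask=spot_mask, truth=truth)


# ---------------------------------------------------------------------------
# Study presets
# ---------------------------------------------------------------------------

#: Nine synthetic "models" spanning a spread of skin tones (rise level and
#: inflection), mottle amplitude and spot populations.  Documented package
#: constants, not fits to any measured panel.
MODEL_PRESETS: dict[str, SimConfig] = {}


def _build_model_presets() -> None:
    specs = [
        # (r_min, r_max, lambda0, mottle_sd, n_spots, melanin_hi)
        ("A", 0.20, 0.62, 585.0, 0.035, 10, 0.25),
        ("B", 0.16, 0.55, 595.0, 0.045, 14, 0.30),
        ("C", 0.24, 0.66, 580.0, 0.030, 8, 0.22),
        ("D", 0.14, 0.50, 600.0, 0.050, 16, 0.32),
        ("E", 0.18, 0.58, 590.0, 0.040, 12, 0.28),
        ("F", 0.22, 0.64, 582.0, 0.032, 9, 0.24),
        ("G", 0.12, 0.46, 605.0, 0.055, 18, 0.35),
        ("H", 0.17, 0.56, 592.0, 0.042, 13, 0.27),
        ("I", 0.21, 0.60, 588.0, 0.038, 11, 0.26),
    ]
    for name, r_min, r_max, lam0, mottle, n_spots, mel_hi in specs:
        MODEL_PRESETS[name] = SimConfig(
            skin=SkinParams(
                r_min=r_min, r_max=r_max, lambda0_nm=lam0, mottle_sd=mottle
            ),
            spots=SpotParams(n_spots=n_spots, melanin=(0.10, mel_hi)),
        )


_build_model_presets()

#: Three products of increasing coverage, modelled as increasing opacity.
PRODUCT_PRESETS: dict[str, ProductParams] = {
    "Low": ProductParams(name="Low", opacity=0.2),
    "Medium": ProductParams(name="Medium", opacity=0.5),
    "High": ProductParams(name="High", opacity=0.8),
}


def study_scenes(seed: int = 0, snr: float | None = DEFAULT_SNR):
    """Yield (model, product, SimScene) over the 9 x 3 synthetic study.

    Per-scene seeds are derived deterministically from ``seed`` so the whole
    study is reproducible; the bare-skin scene of a model differs between
    product tests (as in a real study, where T0 is re-measured each time).
    """
    for mi, (model, cfg) in enumerate(sorted(MODEL_PRESETS.items())):
        for pi, (pname, product) in enumerate(sorted(PRODUCT_PRESETS.items())):
            scene_seed = (seed * 1000 + mi * 10 + pi) % (2**31 - 1)
            scene_cfg = replace(cfg, product=product, snr=snr, seed=scene_seed)
            yield model, pname, generate_scene(scene_cfg)


def study_table(seed: int = 0, snr: float | None = DEFAULT_SNR):
    """Run the full synthetic study and return a tidy metric table.

    Evaluates every (model, product) pair with the standard nested-ROI
    layout (central reference patch inside a central working region) and
    returns a :class:`~samcover.stats.SampleTable` holding alpha_hf,
    beta_sf and delta_mu_theta rows, plus the per-pair results.
    """
    from .coverage import evaluate_pair
    from .roi import ROI
    from .stats import SampleTable
    import pandas as pd

    rows = []
    results = []
    for model, pname, scene in study_scenes(seed=seed, snr=snr):
        h, w = scene.cube_T0.shape[:2]
        work = ROI("work", row0=h // 2 - 32, col0=w // 2 - 32, height_px=64, width_px=64)
        ref = ROI("ref", row0=h // 2 - 12, col0=w // 2 - 12, height_px=24, width_px=24)
        res = evaluate_pair(
            scene.cube_T0, scene.cube_Timm, ref, work, model=model, product=pname
        )
        results.append(res)
        for metric, value in (
            ("alpha_hf", res.alpha_hf),
            ("beta_sf", res.beta_sf),
            ("delta_mu_theta", res.delta_mu_theta),
        ):
            rows.append(
                {"model": model, "product": pname, "metric": metric, "value": value}
            )
    return SampleTable(pd.DataFrame(rows)), results
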