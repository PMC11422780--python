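"""Legacy colorimetric baselines: CIELAB, Delta-E variants, Coxello index.

Reflectance spectra are integrated against the CIE 1964 10-degree observer
colour-matching functions under D65 illumination::

    X = k * sum_l R(l) S(l) xbar(l),   k = 100 / sum_l S(l) ybar(l)

(and likewise Y, Z), where the sum runs over the cube's wavelength grid.
The white point used by the Lab transform is computed from the same tables
and grid (the XYZ of a perfect reflector), which makes the conversion
self-consistent: R(l) = 1 maps exactly to L* = 100, a* = b* = 0.

The *Coxello index* is the volume of the L*a*b* distribution in an ROI,
``sigma_L * sigma_a * sigma_b`` (population SDs); its change between Timm
and T0 is the legacy homogeneity baseline against which the spectral-angle
statistics are compared.  Delta-E is available as CIE76 (the plain
Euclidean metric, the default), CIE94 and CIEDE2000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cie import cmf_on_grid, d65_on_grid
from .datacube import Datacube
from .roi import ROI

__all__ = [
    "LabImage",
    "CoxelloResult",
    "ColorDiffResult",
    "reflectance_to_lab",
    "xyz_to_lab",
    "delta_e",
    "coxello",
    "render_srgb",
    "white_point",
]

MIN_BANDS = 5
DELTA_E_FORMULAS = ("CIE76", "CIE94", "CIEDE2000")


@dataclass
class LabImage:
    """Per-pixel (L*, a*, b*) over an ROI, D65 / CIE 1964 10-degree."""

    lab: np.ndarray  # (..., 3)
    illuminant: str = "D65"
    observer: str = "CIE1964_10"

    @property
    def L(self) -> np.ndarray:
        return self.lab[..., 0]

    @property
    def a(self) -> np.ndarray:
        return self.lab[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.lab[..., 2]

    def mean(self) -> np.ndarray:
        return self.lab.reshape(-1, 3).mean(axis=0)

    def std(self) -> np.ndarray:
        """Population SDs (sigma_L, sigma_a, sigma_b)."""
        return self.lab.reshape(-1, 3).std(axis=0, ddof=0)


@dataclass
class CoxelloResult:
    index_T0: float
    index_Timm: float
    delta_index: float  # I(Timm) - I(T0)


@dataclass
class ColorDiffResult:
    delta_e: float
    formula: str


def _spectra_to_xyz(spectra: np.ndarray, wavelengths_nm: np.ndarray) -> np.ndarray:
    """XYZ of reflectance spectra ``(..., B)`` on a grid, D65 / 1964 10-deg."""
    cmf = cmf_on_grid(wavelengths_nm)  # (B, 3)
    spd = d65_on_grid(wavelengths_nm)  # (B,)
    k = 100.0 / float(spd @ cmf[:, 1])
    weighted = cmf * spd[:, None]  # (B, 3)
    return k * (spectra @ weighted)


def white_point(wavelengths_nm: np.ndarray) -> np.ndarray:
    """XYZ of the perfect reflector on this grid (the working white point)."""
    return _spectra_to_xyz(np.ones(len(wavelengths_nm)), wavelengths_nm)


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    """Standard CIE XYZ -> L*a*b* transform against an explicit white."""
    xyz = np.asarray(xyz, dtype=float)
    t = xyz / np.asarray(white, dtype=float)
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3.0 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def reflectance_to_lab(cube: Datacube, roi: ROI | None = None) -> LabImage:
    """Per-pixel CIELAB of an ROI (or the whole cube) under D65 / 1964 10-deg.

    Requires at least 5 bands; the cube grid must lie inside the tabulated
    CIE range (380-780 nm).
    """
    if cube.n_bands < MIN_BANDS:
        raise ValueError(
            f"grid too sparse for colorimetry: {cube.n_bands} bands < {MIN_BANDS}"
        )
    wl = cube.grid.wavelengths_nm
    if roi is not None:
        roi.check_inside(cube.shape)
        rs, cs = roi.slices
        block = cube.data[rs, cs, :]
    else:
        block = cube.data
    xyz = _spectra_to_xyz(block, wl)
    lab = xyz_to_lab(xyz, white_point(wl))
    return LabImage(lab=lab)


# ---------------------------------------------------------------------------
# Delta-E
# ---------------------------------------------------------------------------

def _de76(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    return np.sqrt(((lab1 - lab2) ** 2).sum(axis=-1))


def _de94(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    # Graphic-arts weights: kL = 1, K1 = 0.045, K2 = 0.015.
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]
    dL = L1 - L2
    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    dC = C1 - C2
    dH2 = np.maximum((a1 - a2) ** 2 + (b1 - b2) ** 2 - dC**2, 0.0)
    SC = 1.0 + 0.045 * C1
    SH = 1.0 + 0.015 * C1
    return np.sqrt(dL**2 + (dC / SC) ** 2 + dH2 / SH**2)


def _de2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    # CIEDE2000 per the standard formulation (Sharma et al. notation).
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]
    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)
    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0

    dLp = L2 - L1
    dCp = C2p - C1p
    dhp = h2p - h1p
    dhp = np.where(dhp > 180.0, dhp - 360.0, dhp)
    dhp = np.where(dhp < -180.0, dhp + 360.0, dhp)
    dhp = np.where(C1p * C2p == 0.0, 0.0, dhp)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp / 2.0))

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    hbp = np.where(
        C1p * C2p == 0.0,
        hsum,
        np.where(
            np.abs(h1p - h2p) <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )
    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    d_theta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * d_theta)) * RC
    return np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )


def delta_e(lab1, lab2, formula: str = "CIE76") -> ColorDiffResult:
    """Colour difference between two Lab coordinates (or arrays of them).

    ``formula`` is one of CIE76 (plain Euclidean, default), CIE94 or
    CIEDE2000.  For array inputs the mean Delta-E is reported.
    """
    name = formula.upper().replace("*", "").replace("DE", "DE")
    aliases = {
        "CIE76": "CIE76",
        "DE76": "CIE76",
        "CIE94": "CIE94",
        "DE94": "CIE94",
        "CIEDE2000": "CIEDE2000",
        "CIE2000": "CIEDE2000",
        "DE00": "CIEDE2000",
    }
    if name not in aliases:
        raise ValueError(
            f"unknown Delta-E formula {formula!r}; expected one of {DELTA_E_FORMULAS}"
        )
    name = aliases[name]
    l1 = lab1.lab if isinstance(lab1, LabImage) else np.asarray(lab1, dtype=float)
    l2 = lab2.lab if isinstance(lab2, LabImage) else np.asarray(lab2, dtype=float)
    func = {"CIE76": _de76, "CIE94": _de94, "CIEDE2000": _de2000}[name]
    value = func(l1, l2)
    return ColorDiffResult(delta_e=float(np.mean(value)), formula=name)


def delta_e_values(lab1, lab2, formula: str = "CIE76") -> np.ndarray:
    """Element-wise Delta-E for array inputs (no averaging)."""
    l1 = lab1.lab if isinstance(lab1, LabImage) else np.asarray(lab1, dtype=float)
    l2 = lab2.lab if isinstance(lab2, LabImage) else np.asarray(lab2, dtype=float)
    func = {"CIE76": _de76, "CIE94": _de94, "CIEDE2000": _de2000}[formula.upper()]
    return func(l1, l2)


# ---------------------------------------------------------------------------
# Coxello index
# ---------------------------------------------------------------------------

def coxello(lab_T0: LabImage, lab_Timm: LabImage) -> CoxelloResult:
    """sigma_L * sigma_a * sigma_b per time point and its Timm - T0 change.

    Positive ``delta_index`` means the colour distribution widened; for
    display next to the homogeneity factor the reporting layer may negate
    it so that positive indicates a homogeneity increase.
    """
    for lab in (lab_T0, lab_Timm):
        if lab.lab.reshape(-1, 3).shape[0] < 2:
            raise ValueError(
                "Coxello index needs at least 2 pixels (sigma of one pixel is degenerate)"
            )
    i0 = float(np.prod(lab_T0.std()))
    i1 = float(np.prod(lab_Timm.std()))
    return CoxelloResult(index_T0=i0, index_Timm=i1, delta_index=i1 - i0)


# ---------------------------------------------------------------------------
# sRGB rendering (visualisation only)
# ---------------------------------------------------------------------------

#: XYZ (D65) -> linear sRGB matrix (IEC 61966-2-1).
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def render_srgb(cube: Datacube) -> np.ndarray:
    """Render a cube to an 8-bit sRGB image under D65 (visualisation only).

    XYZ is normalised so the perfect reflector maps to display white, then
    converted to linear sRGB, gamma-encoded and clipped to gamut per
    channel.  Never used in any metric.
    """
    xyz = _spectra_to_xyz(cube.data, cube.grid.wavelengths_nm) / 100.0
    rgb_lin = xyz @ _XYZ_TO_SRGB.T
    rgb_lin = np.clip(rgb_lin, 0.0, None)
    srgb = np.where(
        rgb_lin <= 0.0031308,
        12.92 * rgb_lin,
        1.055 * np.power(rgb_lin, 1.0 / 2.4) - 0.055,
    )
    srgb = np.clip(srgb, 0.0, 1.0)
    return np.round(srgb * 255.0).astype(np.uint8)
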