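"""Standard CIE colorimetric data tables.

CIE 1964 10-degree standard observer colour-matching functions and the CIE
standard illuminant D65 relative spectral power distribution, tabulated at
10 nm from 380 to 780 nm.  These are the standard published values carried
to four decimal places (CMFs) and two (D65).

Only the D65 / 1964 10-degree combination is a supported contract of the
colorimetry module; the tables are interpolated linearly onto the cube's
wavelength grid, and the summation uses the grid spacing as the quadrature
weight, so the white point is always computed self-consistently from these
same tables.
"""

from __future__ import annotations

import numpy as np

#: Tabulation wavelengths (nm).
CIE_WAVELENGTHS_NM = np.arange(380.0, 790.0, 10.0)

#: CIE 1964 10-degree observer colour-matching functions (x10, y10, z10).
CMF_1964_10 = np.array(
    [
        # lambda   x10      y10      z10
        [380.0, 0.0002, 0.0000, 0.0007],
        [390.0, 0.0024, 0.0003, 0.0105],
        [400.0, 0.0191, 0.0020, 0.0860],
        [410.0, 0.0847, 0.0088, 0.3894],
        [420.0, 0.2045, 0.0214, 0.9725],
        [430.0, 0.3147, 0.0387, 1.5535],
        [440.0, 0.3837, 0.0621, 1.9673],
        [450.0, 0.3707, 0.0895, 1.9948],
        [460.0, 0.3023, 0.1282, 1.7454],
        [470.0, 0.1956, 0.1852, 1.3176],
        [480.0, 0.0805, 0.2536, 0.7721],
        [490.0, 0.0162, 0.3391, 0.4153],
        [500.0, 0.0038, 0.4608, 0.2185],
        [510.0, 0.0375, 0.6067, 0.1120],
        [520.0, 0.1177, 0.7618, 0.0607],
        [530.0, 0.2365, 0.8752, 0.0305],
        [540.0, 0.3768, 0.9620, 0.0137],
        [550.0, 0.5298, 0.9918, 0.0040],
        [560.0, 0.7052, 0.9973, 0.0000],
        [570.0, 0.8787, 0.9556, 0.0000],
        [580.0, 1.0142, 0.8689, 0.0000],
        [590.0, 1.1185, 0.7774, 0.0000],
        [600.0, 1.1240, 0.6583, 0.0000],
        [610.0, 1.0305, 0.5280, 0.0000],
        [620.0, 0.8563, 0.3981, 0.0000],
        [630.0, 0.6475, 0.2835, 0.0000],
        [640.0, 0.4316, 0.1798, 0.0000],
        [650.0, 0.2683, 0.1076, 0.0000],
        [660.0, 0.1526, 0.0603, 0.0000],
        [670.0, 0.0813, 0.0318, 0.0000],
        [680.0, 0.0409, 0.0159, 0.0000],
        [690.0, 0.0199, 0.0077, 0.0000],
        [700.0, 0.0096, 0.0037, 0.0000],
        [710.0, 0.0046, 0.0018, 0.0000],
        [720.0, 0.0022, 0.0008, 0.0000],
        [730.0, 0.0010, 0.0004, 0.0000],
        [740.0, 0.0005, 0.0002, 0.0000],
        [750.0, 0.0003, 0.0001, 0.0000],
        [760.0, 0.0001, 0.0000, 0.0000],
        [770.0, 0.0001, 0.0000, 0.0000],
        [780.0, 0.0000, 0.0000, 0.0000],
    ]
)

#: CIE standard illuminant D65, relative SPD (normalised to 100 at 560 nm).
D65_SPD = np.array(
    [
        [380.0, 49.98],
        [390.0, 54.65],
        [400.0, 82.75],
        [410.0, 91.49],
        [420.0, 93.43],
        [430.0, 86.68],
        [440.0, 104.86],
        [450.0, 117.01],
        [460.0, 117.81],
        [470.0, 114.86],
        [480.0, 115.92],
        [490.0, 108.81],
        [500.0, 109.35],
        [510.0, 107.80],
        [520.0, 104.79],
        [530.0, 107.69],
        [540.0, 104.41],
        [550.0, 104.05],
        [560.0, 100.00],
        [570.0, 96.33],
        [580.0, 95.79],
        [590.0, 88.69],
        [600.0, 90.01],
        [610.0, 89.60],
        [620.0, 87.70],
        [630.0, 83.29],
        [640.0, 83.70],
        [650.0, 80.03],
        [660.0, 80.21],
        [670.0, 82.28],
        [680.0, 78.28],
        [690.0, 69.72],
        [700.0, 71.61],
        [710.0, 74.35],
        [720.0, 61.60],
        [730.0, 69.89],
        [740.0, 75.09],
        [750.0, 63.59],
        [760.0, 46.42],
        [770.0, 66.81],
        [780.0, 63.38],
    ]
)


def cmf_on_grid(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Interpolate the 1964 10-degree CMFs onto a wavelength grid: (B, 3)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl[0] < CIE_WAVELENGTHS_NM[0] or wl[-1] > CIE_WAVELENGTHS_NM[-1]:
        raise ValueError(
            f"grid [{wl[0]}, {wl[-1]}] nm outside the tabulated CIE range "
            f"[{CIE_WAVELENGTHS_NM[0]}, {CIE_WAVELENGTHS_NM[-1]}] nm"
        )
    return np.column_stack(
        [np.interp(wl, CMF_1964_10[:, 0], CMF_1964_10[:, k]) for k in (1, 2, 3)]
    )


def d65_on_grid(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Interpolate the D65 SPD onto a wavelength grid: (B,)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return np.interp(wl, D65_SPD[:, 0], D65_SPD[:, 1])
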