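"""Data model and I/O for calibrated hyperspectral reflectance datacubes.

A datacube is an ``H x W x B`` array of per-pixel reflectance spectra: two
spatial dimensions and one spectral dimension.  Cubes are assumed to be
calibrated to reflectance (white-reference division happens upstream, in the
acquisition chain), so values are dimensionless and expected to lie in
``[0, ~1.2]`` — values slightly above 1 occur on specular glints and are
flagged in the QC summary rather than clipped, since clipping would bias the
downstream spectral-angle statistics.

Two on-disk formats are supported:

* ENVI ``.hdr``/``.img`` pairs (BSQ, BIL or BIP interleave, with the band
  wavelengths carried in the header) — the hyperspectral exchange standard.
* An HDF5 container (datasets ``/reflectance`` and ``/wavelengths_nm``,
  attributes ``pixel_pitch_um`` and a ``meta`` group) which preserves all
  metadata exactly.

Coordinate convention, fixed once for the whole package: row-major arrays,
``(row, col)`` indexing, 0-based, half-open ranges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
import h5py
import numpy as np

__all__ = [
    "WavelengthGrid",
    "Datacube",
    "Measurement",
    "default_grid",
    "read_cube",
    "write_cube",
    "resample_to_grid",
]

#: Default spectral grid: 420-730 nm inclusive at a 10 nm step, 32 bands.
DEFAULT_WAVELENGTHS_NM = np.arange(420.0, 740.0, 10.0)

#: Default spatial sampling in micrometres per pixel.
DEFAULT_PIXEL_PITCH_UM = 160.0

TIMEPOINTS = ("T0", "Timm")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-centre wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise ValueError("wavelengths must be finite and > 0")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)

    def __hash__(self) -> int:
        return hash(self.wavelengths_nm.tobytes())


def default_grid() -> WavelengthGrid:
    """The instrument's native grid: 420-730 nm at 10 nm, 32 bands."""
    return WavelengthGrid(DEFAULT_WAVELENGTHS_NM.copy())


@dataclass
class Datacube:
    """Calibrated reflectance image: ``data[row, col, band]``.

    Parameters
    ----------
    data
        ``H x W x B`` float array of reflectance values (finite, >= 0).
    grid
        Band-centre wavelengths; ``len(grid)`` must equal ``B``.
    pixel_pitch_um
        Spatial sampling in micrometres per pixel (> 0).
    meta
        Free-form key/value metadata (model, product, timepoint, operator...).
    """

    data: np.ndarray
    grid: WavelengthGrid
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"datacube must be 3-D (H, W, B); got shape {arr.shape}")
        if arr.shape[2] != len(self.grid):
            raise ValueError(
                f"band count {arr.shape[2]} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("reflectance values must all be finite")
        if np.any(arr < 0):
            raise ValueError("reflectance values must be >= 0")
        if not (self.pixel_pitch_um > 0):
            raise ValueError("pixel_pitch_um must be > 0")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def qc_summary(self) -> dict:
        """Counts of suspicious voxels (never modified, only reported)."""
        over_unity = int(np.count_nonzero(self.data > 1.0))
        zero_norm = int(
            np.count_nonzero(np.linalg.norm(self.data, axis=2) == 0.0)
        )
        return {
            "n_voxels_over_unity": over_unity,
            "n_pixels_zero_norm": zero_norm,
            "max_reflectance": float(self.data.max()) if self.data.size else 0.0,
        }


@dataclass
class Measurement:
    """One acquisition: a cube plus its place in the study design."""

    cube: Datacube
    timepoint: str
    model: str = ""
    product: str = ""
    repetition: str = ""
    operator: str = ""

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}; got {self.timepoint!r}"
            )


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float64): 5, np.dtype(np.float32): 4}


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{path}: not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # Join brace-delimited multi-line values first.
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_brace_list(value: str) -> list[str]:
    value = value.strip()
    if not (value.startswith("{") and value.endswith("}")):
        raise ValueError(f"expected a brace-delimited list, got {value!r}")
    return [item.strip() for item in value[1:-1].split(",") if item.strip()]


def _read_envi(path: Path) -> Datacube:
    path = Path(path)
    hdr_path = path.with_suffix(".hdr") if path.suffix != ".hdr" else path
    img_path = hdr_path.with_suffix(".img")
    if not hdr_path.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr_path}")
    if not img_path.exists():
        raise FileNotFoundError(f"ENVI data file not found: {img_path}")
    hdr = _parse_envi_header(hdr_path)

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in hdr:
            raise ValueError(f"{hdr_path}: ENVI header missing required key '{key}'")
    if "wavelength" not in hdr:
        raise ValueError(
            f"{hdr_path}: ENVI header missing 'wavelength' list; cannot build grid"
        )

    samples = int(hdr["samples"])  # columns
    lines = int(hdr["lines"])  # rows
    bands = int(hdr["bands"])
    dtype_code = int(hdr["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(hdr.get("byte order", "0")) != 0:
        dtype = dtype.newbyteorder(">")
    interleave = hdr["interleave"].lower()

    wavelengths = [float(v) for v in _parse_brace_list(hdr["wavelength"])]
    if len(wavelengths) != bands:
        raise ValueError(
            f"{hdr_path}: header declares {bands} bands but lists "
            f"{len(wavelengths)} wavelengths"
        )

    raw = np.fromfile(img_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"{img_path}: header declares {bands} bands for {lines}x{samples} "
            f"pixels ({expected} values) but file holds {raw.size}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported ENVI interleave {interleave!r}")

    pitch = float(hdr.get("pixel pitch um", DEFAULT_PIXEL_PITCH_UM))
    meta = {
        k[len("meta "):]: v for k, v in hdr.items() if k.startswith("meta ")
    }
    return Datacube(
        data=np.ascontiguousarray(data, dtype=float),
        grid=WavelengthGrid(np.asarray(wavelengths)),
        pixel_pitch_um=pitch,
        meta=meta,
    )


def _write_envi(cube: Datacube, path: Path, interleave: str = "bsq") -> Path:
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    img_path = path.with_suffix(".img")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data, dtype=np.float64)
    lines, samples, bands = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    np.ascontiguousarray(out).tofile(img_path)

    # Full round-trip precision for the grid (17 significant digits).
    wl = ", ".join(f"{w:.17g}" for w in cube.grid.wavelengths_nm)
    meta_lines = "".join(
        f"meta {key} = {value}\n" for key, value in sorted(cube.meta.items())
    )
    hdr_path.write_text(
        "ENVI\n"
        "description = {samcover reflectance datacube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float64)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"pixel pitch um = {cube.pixel_pitch_um:.6f}\n"
        f"wavelength = {{{wl}}}\n"
        f"{meta_lines}"
    )
    return img_path


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

def _read_container(path: Path) -> Datacube:
    with h5py.File(path, "r") as f:
        if "reflectance" not in f:
            raise ValueError(f"{path}: container missing dataset '/reflectance'")
        if "wavelengths_nm" not in f:
            raise ValueError(f"{path}: container missing dataset '/wavelengths_nm'")
        data = f["reflectance"][()]
        wl = f["wavelengths_nm"][()]
        if data.shape[2] != wl.shape[0]:
            raise ValueError(
                f"{path}: band count {data.shape[2]} does not match "
                f"{wl.shape[0]} stored wavelengths"
            )
        pitch = float(f.attrs.get("pixel_pitch_um", DEFAULT_PIXEL_PITCH_UM))
        meta = {}
        if "meta" in f:
            meta = {k: _h5attr(v) for k, v in f["meta"].attrs.items()}
    return Datacube(data=data, grid=WavelengthGrid(wl), pixel_pitch_um=pitch, meta=meta)


def _h5attr(value):
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.generic):
        return value.item()
    return value


def _write_container(cube: Datacube, path: Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.data)
        f.create_dataset("wavelengths_nm", data=cube.grid.wavelengths_nm)
        f.attrs["pixel_pitch_um"] = cube.pixel_pitch_um
        grp = f.create_group("meta")
        for key, value in cube.meta.items():
            grp.attrs[str(key)] = value
    return path


# ---------------------------------------------------------------------------
# Public I/O facade
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "container"
    return "envi"


def read_cube(path, format: str | None = None) -> Datacube:
    """Read a datacube from ``path`` (``envi`` or ``container`` format).

    The format is inferred from the file suffix when not given.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "container":
        return _read_container(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'envi' or 'container'")


def write_cube(cube: Datacube, path, format: str | None = None, **kwargs) -> Path:
    """Write a datacube; returns the path of the primary data file."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        return _write_envi(cube, path, **kwargs)
    if fmt == "container":
        return _write_container(cube, path)
    raise ValueError(f"unknown format {fmt!r}; expected 'envi' or 'container'")


def resample_to_grid(cube: Datacube, target: WavelengthGrid) -> Datacube:
    """Linearly interpolate every pixel spectrum onto ``target``.

    Extrapolation is refused: the target range must lie within the source
    range.
    """
    src = cube.grid.wavelengths_nm
    tgt = target.wavelengths_nm
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise ValueError(
            f"target grid [{tgt[0]}, {tgt[-1]}] nm extends outside source "
            f"range [{src[0]}, {src[-1]}] nm; extrapolation is not supported"
        )
    if cube.grid == target:
        return Datacube(
            data=cube.data.copy(),
            grid=target,
            pixel_pitch_um=cube.pixel_pitch_um,
            meta=dict(cube.meta),
        )
    # np.interp over the last axis, vectorised by hand with searchsorted.
    idx = np.searchsorted(src, tgt, side="left")
    idx = np.clip(idx, 1, src.size - 1)
    x0 = src[idx - 1]
    x1 = src[idx]
    w = (tgt - x0) / (x1 - x0)
    data = cube.data[..., idx - 1] * (1.0 - w) + cube.data[..., idx] * w
    # Exact band matches (w in {0,1}) are handled by the blend itself.
    return Datacube(
        data=data,
        grid=target,
        pixel_pitch_um=cube.pixel_pitch_um,
        meta=dict(cube.meta),
    )
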