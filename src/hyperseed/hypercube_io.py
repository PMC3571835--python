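"""ENVI hypercube I/O, reflectance calibration, spectral cropping and ROI extraction.

A hypercube is a 3-D array with two spatial axes and one spectral axis,
stored in memory as (rows, cols, bands) with a strictly increasing
wavelength vector in nanometres. On disk the ENVI convention is used: a
plain-text header file next to a raw binary file, with the interleave key
(``bil``/``bip``/``bsq``) deciding the on-disk axis order.

Reflectance calibration converts raw intensity I0 to relative reflectance
using a white reference W (maximum-reflectance frame) and a black reference
B (dark current): I = (I0 - B) / (W - B), computed per pixel and per band.
Pixels where the denominator is degenerate (W - B <= eps) are set to 0 and
recorded in a quality-control mask.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CapacityError,
    DimensionError,
    EnviFormatError,
    EnviIntegrityError,
    ParameterError,
    SpectralRangeError,
)

__all__ = [
    "Hypercube",
    "ReferencePair",
    "ROI",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "crop_spectral",
    "extract_rois",
]

# ENVI numeric data-type codes -> numpy dtypes. Only the two types the
# toolkit emits are accepted; anything else is rejected loudly.
_ENVI_DTYPES = {4: np.dtype("float32"), 12: np.dtype("uint16")}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """A (rows x cols x bands) data cube with its wavelength grid.

    ``kind`` distinguishes raw camera intensity from calibrated
    reflectance. ``meta`` carries optional QC artefacts such as the
    degenerate-denominator mask produced during calibration.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise DimensionError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ParameterError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")
        if self.kind == "raw" and self.data.size and np.min(self.data) < 0:
            raise ParameterError("raw cubes must be nonnegative")
        if self.kind == "reflectance" and self.data.size and not np.all(np.isfinite(self.data)):
            raise ParameterError("reflectance cubes must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferencePair:
    """White and black reference frames used for reflectance calibration."""

    white: Hypercube
    black: Hypercube

    def __post_init__(self):
        if self.white.shape != self.black.shape:
            raise DimensionError("white and black references must share shape")
        if not np.allclose(self.white.wavelengths, self.black.wavelengths):
            raise DimensionError("white and black references must share wavelengths")


@dataclass
class ROI:
    """A square region of interest cut from a parent image; treated as one sample.

    ``origin`` is the (row, col) of the upper-left pixel in the parent,
    0-based, row-major, origin at the image top-left.
    """

    cube: Hypercube
    origin: tuple[int, int]
    side: int

    def __post_init__(self):
        r, c, _ = self.cube.shape
        if r != self.side or c != self.side:
            raise DimensionError(
                f"ROI cube spatial dims {(r, c)} must equal side x side = {self.side}"
            )


# ---------------------------------------------------------------------------
# ENVI header / binary

_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type", "byte order")


def _parse_header(text: str, path) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError(f"{path}: missing ENVI magic on first line")
    # Fold brace-delimited multi-line blocks onto one line, then split key = value.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise EnviFormatError(f"{path}: header missing required key '{key}'")
    return fields


def _binary_path(header_path: Path) -> Path:
    candidates = [header_path.with_suffix(".img")]
    if header_path.suffix == ".hdr":
        candidates.append(header_path.with_suffix(""))
    for cand in candidates:
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(f"no binary file found next to header {header_path}")


def read_envi(header_path) -> Hypercube:
    """Read an ENVI header/binary pair into a (rows, cols, bands) cube.

    The interleave declared in the header only affects the on-disk layout;
    the returned axis order is always (rows, cols, bands).
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text(), header_path)

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        byte_order = int(fields["byte order"])
    except ValueError as exc:
        raise EnviFormatError(f"{header_path}: non-integer header value ({exc})") from exc
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"{header_path}: unsupported interleave '{interleave}'")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(
            f"{header_path}: unsupported data type code {dtype_code} "
            f"(supported: {sorted(_ENVI_DTYPES)})"
        )
    dtype = _ENVI_DTYPES[dtype_code]
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    wavelengths = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = np.array(
            [float(tok) for tok in inner.replace(",", " ").split()], dtype=float
        )
        if len(wavelengths) != bands:
            raise EnviFormatError(
                f"{header_path}: wavelength list length {len(wavelengths)} "
                f"!= bands {bands}"
            )
    else:
        wavelengths = np.arange(bands, dtype=float)

    binary = _binary_path(header_path)
    raw = np.fromfile(binary, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviIntegrityError(
            f"{binary}: holds {raw.size} values but header declares {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)
    kind = fields.get("hyperseed kind", "raw")
    return Hypercube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_envi(cube: Hypercube, header_path, interleave: str = "bil") -> Path:
    """Write a cube as an ENVI header/binary pair; returns the header path.

    The binary is written next to the header with an ``.img`` suffix.
    Round-trips are bit-exact for the declared data type (uint16 cubes are
    stored as uint16, everything else as little-endian float32).
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ParameterError(f"interleave must be bil/bip/bsq, got {interleave!r}")
    header_path = Path(header_path)
    binary = header_path.with_suffix(".img")

    dtype = np.dtype("uint16") if cube.data.dtype == np.uint16 else np.dtype("float32")
    data = cube.data.astype(dtype.newbyteorder("<"), copy=False)
    lines, samples, bands = cube.shape
    if interleave == "bsq":
        ondisk = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ondisk = data.transpose(0, 2, 1)
    else:
        ondisk = data

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"hyperseed kind = {cube.kind}\n"
        "wavelength = {\n"
        f" {wl}\n"
        "}\n"
    )
    try:
        header_path.write_text(header)
        np.ascontiguousarray(ondisk).tofile(binary)
    except OSError as exc:
        raise OSError(f"cannot write ENVI pair at {header_path}: {exc}") from exc
    return header_path


# ---------------------------------------------------------------------------
# Calibration, cropping, ROI extraction


def calibrate_reflectance(
    raw: Hypercube, refs: ReferencePair, eps: float = 1e-8
) -> Hypercube:
    """Convert raw intensity to relative reflectance: I = (I0 - B) / (W - B).

    Where the denominator W - B is <= ``eps`` the output reflectance is set
    to 0 and the voxel is flagged in ``meta['degenerate_mask']``. Values
    outside [0, 1.5] are kept untouched but counted in ``meta['qc']``.
    """
    if eps < 0:
        raise ParameterError(f"eps must be nonnegative, got {eps}")
    for name, ref in (("white", refs.white), ("black", refs.black)):
        if ref.shape != raw.shape:
            raise DimensionError(
                f"{name} reference shape {ref.shape} != raw shape {raw.shape}"
            )
        if not np.allclose(ref.wavelengths, raw.wavelengths):
            raise DimensionError(f"{name} reference wavelengths differ from raw cube")

    w = refs.white.data.astype(np.float64, copy=False)
    b = refs.black.data.astype(np.float64, copy=False)
    denom = w - b
    mask = denom <= eps
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(np.float64, copy=False) - b) / denom
    refl = np.where(mask, 0.0, refl)

    qc = {
        "n_degenerate": int(mask.sum()),
        "n_below_0": int(np.count_nonzero(refl < 0)),
        "n_above_1_5": int(np.count_nonzero(refl > 1.5)),
        "min": float(refl.min()) if refl.size else 0.0,
        "max": float(refl.max()) if refl.size else 0.0,
    }
    return Hypercube(
        refl,
        raw.wavelengths.copy(),
        kind="reflectance",
        meta={"degenerate_mask": mask, "qc": qc},
    )


def crop_spectral(cube: Hypercube, lo: float, hi: float) -> Hypercube:
    """Keep exactly the bands with lo <= wavelength <= hi (closed interval)."""
    if lo >= hi:
        raise ParameterError(f"lo ({lo}) must be < hi ({hi})")
    keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not keep.any():
        raise SpectralRangeError(
            f"no bands in [{lo}, {hi}] nm; cube covers "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    meta = {k: v for k, v in cube.meta.items() if k != "degenerate_mask"}
    if "degenerate_mask" in cube.meta:
        meta["degenerate_mask"] = cube.meta["degenerate_mask"][:, :, keep]
    return Hypercube(cube.data[:, :, keep], cube.wavelengths[keep], kind=cube.kind, meta=meta)


def _overlaps(a: tuple[int, int], b: tuple[int, int], side: int) -> bool:
    return abs(a[0] - b[0]) < side and abs(a[1] - b[1]) < side


def extract_rois(cube: Hypercube, side: int, n: int, seed: int) -> list[ROI]:
    """Draw ``n`` pairwise non-overlapping side x side ROIs at seeded random positions.

    Rejection sampling with a cap of 10*n proposals; if the cap is hit the
    positions fall back to a seeded shuffle of the non-overlapping grid
    tiling, so any feasible request succeeds deterministically.
    """
    rows, cols, _ = cube.shape
    if side < 1 or side > min(rows, cols):
        raise ParameterError(f"side {side} incompatible with image {rows}x{cols}")
    capacity = (rows // side) * (cols // side)
    if n < 1 or n > capacity:
        raise CapacityError(
            f"cannot place {n} non-overlapping {side}x{side} ROIs in a "
            f"{rows}x{cols} image; max achievable is {capacity}"
        )

    rng = np.random.default_rng(seed)
    origins: list[tuple[int, int]] = []
    for _ in range(10 * n):
        cand = (int(rng.integers(0, rows - side + 1)), int(rng.integers(0, cols - side + 1)))
        if all(not _overlaps(cand, o, side) for o in origins):
            origins.append(cand)
            if len(origins) == n:
                break
    if len(origins) < n:
        tiles = [(i * side, j * side) for i in range(rows // side) for j in range(cols // side)]
        rng.shuffle(tiles)
        origins = tiles[:n]

    rois = []
    for r0, c0 in origins:
        sub = Hypercube(
            cube.data[r0 : r0 + side, c0 : c0 + side].copy(),
            cube.wavelengths.copy(),
            kind=cube.kind,
        )
        rois.append(ROI(sub, (r0, c0), side))
    return rois
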