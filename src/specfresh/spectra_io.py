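"""Spectral containers, reflectance calibration, ROI extraction and table I/O.

The two central types are :class:`SpectralCube` (a rows x cols x bands stack
of raw sensor counts with dark/white reference frames) and
:class:`SpectrumSet` (a samples x bands reflectance matrix with wavelength
axis, optional grade labels, optional indicator columns and free-form
per-sample metadata).  Everything downstream of calibration operates on
``SpectrumSet``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCube",
    "SpectrumSet",
    "CalibrationError",
    "RoiPackingError",
    "calibrate",
    "extract_rois",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_envi_cube",
    "write_envi_cube",
]

#: Fine-grade vocabulary shared across the package (ordered by severity).
GRADE_VOCABULARY = ("Fresh", "SubFresh", "PreSpoiled", "Spoiled")

#: Reserved column names in spectrum tables (everything else must be a
#: ``wavelength_###.#nm`` column).
INDICATOR_COLUMNS = ("tvbn", "tac", "mpn")
LABEL_COLUMN = "label"

_WL_RE = re.compile(r"^wavelength_([0-9]+(?:\.[0-9]+)?)nm$")


class CalibrationError(ValueError):
    """Raised when too many pixels have a degenerate white-dark difference."""


class RoiPackingError(ValueError):
    """Raised when the requested number of non-overlapping ROIs cannot fit."""


def _as_band_reference(ref: np.ndarray, shape: tuple[int, int, int], name: str) -> np.ndarray:
    """Broadcast a 1-D per-band or 3-D per-pixel reference to cube shape."""
    ref = np.asarray(ref, dtype=float)
    if ref.ndim == 1:
        if ref.shape[0] != shape[2]:
            raise ValueError(f"{name} has {ref.shape[0]} bands, cube has {shape[2]}")
        return np.broadcast_to(ref, shape)
    if ref.ndim == 3:
        if ref.shape != shape:
            raise ValueError(f"{name} shape {ref.shape} != cube shape {shape}")
        return ref
    raise ValueError(f"{name} must be 1-D (per band) or 3-D (per pixel), got ndim={ref.ndim}")


@dataclass
class SpectralCube:
    """Raw (or calibrated) image stack with dark/white reference frames.

    Parameters
    ----------
    data:
        rows x cols x bands array of DN counts (or reflectance after
        :func:`calibrate`).
    dark, white:
        Dark / white reference frames; either per-band vectors (bands,) or
        full per-pixel stacks of the same shape as ``data``.
    wavelengths:
        Strictly increasing band centres in nm.
    """

    data: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    wavelengths: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.wavelengths.shape[0] != self.data.shape[2]:
            raise ValueError("wavelength count does not match band axis")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        for name, ref in (("dark", self.dark), ("white", self.white)):
            _as_band_reference(ref, self.data.shape, name)  # shape check only
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data contains non-finite values")
        if not self.calibrated and np.any(self.data < 0):
            raise ValueError("DN values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class SpectrumSet:
    """samples x bands reflectance matrix, the universal pipeline currency."""

    values: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray | None = None
    indicators: pd.DataFrame | None = None
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be samples x bands")
        if self.values.shape[1] != self.wavelengths.shape[0]:
            raise ValueError("column count must equal wavelength count")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values contain NaN/Inf")
        n = self.values.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != n:
                raise ValueError("label count does not match sample count")
            unknown = set(self.labels) - set(GRADE_VOCABULARY)
            if unknown:
                raise ValueError(f"unknown label token(s): {sorted(unknown)}")
        if self.indicators is not None:
            self.indicators = pd.DataFrame(self.indicators).reset_index(drop=True)
            if len(self.indicators) != n:
                raise ValueError("indicator row count does not match sample count")
            bad = set(self.indicators.columns) - set(INDICATOR_COLUMNS)
            if bad:
                raise ValueError(f"unknown indicator column(s): {sorted(bad)}")
        if len(self.meta) not in (0, n):
            raise ValueError("meta row count does not match sample count")
        self.meta = pd.DataFrame(self.meta).reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, wavelengths: np.ndarray | None = None) -> "SpectrumSet":
        """Copy carrying over labels/indicators/meta with new values."""
        return SpectrumSet(
            values=np.asarray(values, dtype=float),
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            labels=None if self.labels is None else self.labels.copy(),
            indicators=None if self.indicators is None else self.indicators.copy(),
            meta=self.meta.copy(),
        )

    def subset(self, rows: np.ndarray) -> "SpectrumSet":
        rows = np.asarray(rows)
        return SpectrumSet(
            values=self.values[rows],
            wavelengths=self.wavelengths,
            labels=None if self.labels is None else self.labels[rows],
            indicators=None if self.indicators is None else self.indicators.iloc[rows],
            meta=self.meta.iloc[rows] if len(self.meta) else self.meta,
        )

    def target(self, name: str) -> np.ndarray:
        """Return an indicator column or the label vector by name."""
        if name == LABEL_COLUMN:
            if self.labels is None:
                raise KeyError("set has no labels")
            return self.labels
        if self.indicators is None or name not in self.indicators.columns:
            raise KeyError(f"set has no indicator column {name!r}")
        return self.indicators[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(
    cube: SpectralCube,
    clip_max: float = 1.5,
    eps: float = 1e-9,
    max_invalid_fraction: float = 0.01,
) -> SpectralCube:
    """Black/white reflectance correction G = (I - B) / (W - B).

    Pixels/bands where ``W - B <= eps`` are flagged invalid and set to 0;
    if their fraction exceeds ``max_invalid_fraction`` a
    :class:`CalibrationError` is raised.  Output is clipped to
    ``[0, clip_max]``.
    """
    dark = _as_band_reference(cube.dark, cube.data.shape, "dark")
    white = _as_band_reference(cube.white, cube.data.shape, "white")
    denom = white - dark
    invalid = denom <= eps
    frac = float(invalid.mean())
    if frac > max_invalid_fraction:
        raise CalibrationError(
            f"{frac:.2%} of pixel/band cells have white-dark <= {eps} "
            f"(limit {max_invalid_fraction:.2%})"
        )
    g = np.zeros_like(cube.data)
    np.divide(cube.data - dark, denom, out=g, where=~invalid)
    g = np.clip(g, 0.0, clip_max)
    return replace(cube, data=g, calibrated=True)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def _max_packable(free: np.ndarray, size: int) -> int:
    """Greedy raster-scan estimate of how many size x size squares fit."""
    free = free.copy()
    count = 0
    rows, cols = free.shape
    r = 0
    while r + size <= rows:
        c = 0
        while c + size <= cols:
            if free[r : r + size, c : c + size].all():
                free[r : r + size, c : c + size] = False
                count += 1
                c += size
            else:
                c += 1
        r += 1
    return count


def extract_rois(
    cube: SpectralCube,
    n_rois: int = 20,
    roi_size: int = 10,
    seed: int = 0,
    mask: np.ndarray | None = None,
    max_tries: int = 10_000,
) -> SpectrumSet:
    """Sample non-overlapping square ROIs and average each into one spectrum.

    Squares use 0-based half-open ``[r, r+size) x [c, c+size)`` indexing and
    are drawn uniformly at random among positions fully inside ``mask``
    (default: whole image).  Each ROI contributes one row: the per-band mean
    over its pixels.  Deterministic for a fixed seed.
    """
    rows, cols, _ = cube.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (rows, cols):
        raise ValueError("mask shape must match cube spatial dimensions")
    if roi_size <= 0 or roi_size > min(rows, cols):
        raise ValueError("roi_size out of range")

    # positions whose full square lies inside the mask
    ok = np.zeros((rows - roi_size + 1, cols - roi_size + 1), dtype=bool)
    csum = np.cumsum(np.cumsum(mask.astype(int), 0), 1)
    padded = np.zeros((rows + 1, cols + 1), dtype=int)
    padded[1:, 1:] = csum
    for r in range(ok.shape[0]):
        for c in range(ok.shape[1]):
            s = (
                padded[r + roi_size, c + roi_size]
                - padded[r, c + roi_size]
                - padded[r + roi_size, c]
                + padded[r, c]
            )
            ok[r, c] = s == roi_size * roi_size

    rng = np.random.default_rng(seed)
    candidates = np.argwhere(ok)
    if candidates.shape[0] == 0:
        raise RoiPackingError("no valid ROI position inside mask (achievable maximum: 0)")

    occupied = np.zeros((rows, cols), dtype=bool)
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n_rois and tries < max_tries:
        r, c = candidates[rng.integers(candidates.shape[0])]
        tries += 1
        if occupied[r : r + roi_size, c : c + roi_size].any():
            continue
        occupied[r : r + roi_size, c : c + roi_size] = True
        placed.append((int(r), int(c)))
    if len(placed) < n_rois:
        # tight packings defeat rejection sampling; retry with a greedy pass
        # over the shuffled candidate list, then a deterministic raster scan
        for order in (rng.permutation(candidates.shape[0]), np.arange(candidates.shape[0])):
            occupied[:] = False
            placed = []
            for pos in order:
                r, c = candidates[pos]
                if occupied[r : r + roi_size, c : c + roi_size].any():
                    continue
                occupied[r : r + roi_size, c : c + roi_size] = True
                placed.append((int(r), int(c)))
                if len(placed) == n_rois:
                    break
            if len(placed) == n_rois:
                break
    if len(placed) < n_rois:
        achievable = _max_packable(mask, roi_size)
        raise RoiPackingError(
            f"could not place {n_rois} non-overlapping {roi_size}x{roi_size} ROIs "
            f"(achievable maximum is about {achievable})"
        )

    spectra = np.empty((n_rois, cube.n_bands))
    for i, (r, c) in enumerate(placed):
        spectra[i] = cube.data[r : r + roi_size, c : c + roi_size, :].mean(axis=(0, 1))
    meta = pd.DataFrame(
        {"roi": np.arange(n_rois), "row": [p[0] for p in placed], "col": [p[1] for p in placed]}
    )
    return SpectrumSet(values=spectra, wavelengths=cube.wavelengths, meta=meta)


# ---------------------------------------------------------------------------
# spectrum tables (CSV/TSV)
# ---------------------------------------------------------------------------

def write_spectrum_table(sset: SpectrumSet, path: str | Path, sep: str = ",", precision: int = 12) -> None:
    """Write a SpectrumSet to CSV/TSV with ``wavelength_###.#nm`` columns."""
    cols = {f"wavelength_{w:.4f}nm": sset.values[:, j] for j, w in enumerate(sset.wavelengths)}
    df = pd.DataFrame(cols)
    if sset.labels is not None:
        df[LABEL_COLUMN] = sset.labels
    if sset.indicators is not None:
        for c in sset.indicators.columns:
            df[c] = sset.indicators[c].to_numpy()
    for c in sset.meta.columns:
        df[c] = sset.meta[c].to_numpy()
    df.to_csv(path, sep=sep, index=False, float_format=f"%.{precision}g")


def read_spectrum_table(path: str | Path, sep: str | None = None) -> SpectrumSet:
    """Read a spectrum table written by :func:`write_spectrum_table`.

    ``sep=None`` sniffs comma vs tab from the header line.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    wl, wl_cols = [], []
    for c in df.columns:
        m = _WL_RE.match(c)
        if m:
            wl.append(float(m.group(1)))
            wl_cols.append(c)
    if not wl_cols:
        raise ValueError("no wavelength_###nm columns found")
    wl_arr = np.asarray(wl)
    if not np.all(np.diff(wl_arr) > 0):
        raise ValueError("wavelength header is not strictly increasing")
    values = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("ragged or non-numeric spectrum rows")
    labels = df[LABEL_COLUMN].to_numpy(dtype=object) if LABEL_COLUMN in df.columns else None
    ind_cols = [c for c in INDICATOR_COLUMNS if c in df.columns]
    indicators = df[ind_cols].astype(float) if ind_cols else None
    meta_cols = [c for c in df.columns if c not in wl_cols and c != LABEL_COLUMN and c not in ind_cols]
    meta = df[meta_cols] if meta_cols else pd.DataFrame()
    return SpectrumSet(values=values, wavelengths=wl_arr, labels=labels, indicators=indicators, meta=meta)


# ---------------------------------------------------------------------------
# ENVI-style cube I/O (header text file + raw BSQ/BIL binary)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {"4": np.float32, "5": np.float64, "12": np.uint16, "2": np.int16}
_ENVI_CODES = {np.dtype(np.float32): "4", np.dtype(np.float64): "5", np.dtype(np.uint16): "12"}


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # join { ... } blocks that may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(
    header_path: str | Path,
    dark: np.ndarray | None = None,
    white: np.ndarray | None = None,
) -> SpectralCube:
    """Read an ENVI header (+ companion raw binary) into a SpectralCube.

    Supports BSQ and BIL interleaves.  Dark/white frames are supplied
    separately (the format does not carry them); default to 0 / 1 which
    leaves DN values unchanged under calibration.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[fields.get("data type", "4")]
    interleave = fields.get("interleave", "bsq").lower()
    wl_text = fields.get("wavelength", "")
    wl = np.array([float(t) for t in wl_text.strip("{} ").split(",") if t.strip()], dtype=float)
    if wl.size != bands:
        raise ValueError("header wavelength list does not match band count")
    data_path = header_path.with_suffix(".raw")
    if not data_path.exists():
        data_path = header_path.with_suffix(".img")
    raw = np.fromfile(data_path, dtype=dtype)
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if dark is None:
        dark = np.zeros(bands)
    if white is None:
        white = np.ones(bands)
    return SpectralCube(data=cube.astype(float), dark=dark, white=white, wavelengths=wl)


def write_envi_cube(cube: SpectralCube, header_path: str | Path, interleave: str = "bsq") -> None:
    """Write cube data as ENVI header + .raw binary (float32)."""
    header_path = Path(header_path)
    rows, cols, bands = cube.shape
    data = cube.data.astype(np.float32)
    if interleave == "bsq":
        raw = data.transpose(2, 0, 1)
    elif interleave == "bil":
        raw = data.transpose(0, 2, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    raw.tofile(header_path.with_suffix(".raw"))
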