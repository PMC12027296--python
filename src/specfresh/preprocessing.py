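"""Spectral preprocessing operators: SNV, MSC, SG smoothing, FD, MA.

All operators are pure functions SpectrumSet -> SpectrumSet that preserve
shape, labels, indicators and metadata.  :func:`apply` dispatches on a
:class:`PreprocessSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectrumSet

__all__ = [
    "PreprocessSpec",
    "snv",
    "msc",
    "sg_smooth",
    "first_derivative",
    "moving_average",
    "apply",
]

METHODS = ("RAW", "SG", "MSC", "SNV", "FD", "MA")


@dataclass
class PreprocessSpec:
    """Configuration for a single preprocessing operator.

    ``method`` is one of RAW/SG/MSC/SNV/FD/MA; ``window``/``polyorder``
    apply to SG and MA, ``reference`` to MSC (None = set mean) and
    ``derivative_mode`` to FD.
    """

    method: str = "RAW"
    window: int = 11
    polyorder: int = 2
    reference: np.ndarray | None = None
    derivative_mode: str = "central_difference"  # or "sg_derivative"
    ma_window: int = 9

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not (0 <= self.polyorder <= self.window - 1):
            raise ValueError("polyorder must be in [0, window-1]")
        if self.derivative_mode not in ("central_difference", "sg_derivative"):
            raise ValueError(f"unknown derivative_mode {self.derivative_mode!r}")


def _tag(out: SpectrumSet, method: str) -> SpectrumSet:
    out.meta = out.meta.copy()
    out.meta["preprocess"] = method
    return out


def snv(sset: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-row (x - mean) / population sd."""
    x = sset.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        raise ValueError(f"constant spectrum (zero variance) at row(s) {bad.tolist()}")
    return _tag(sset.with_values((x - mu) / sd), "SNV")


def msc(sset: SpectrumSet, reference: np.ndarray | None = None) -> SpectrumSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as x ~ a + b * ref (ordinary least squares) and
    replaced by (x - a) / b.  ``reference`` defaults to the column-mean
    spectrum of the set; pass the training-set mean explicitly to avoid
    leakage when transforming validation/test data.
    """
    x = sset.values
    if x.shape[1] < 2:
        raise ValueError("MSC needs at least 2 bands")
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape[0] != x.shape[1]:
        raise ValueError("reference length does not match band count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("degenerate (constant) MSC reference")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        bad = np.nonzero(np.abs(b) < 1e-12)[0]
        raise ValueError(f"degenerate MSC slope at row(s) {bad.tolist()}")
    a = x.mean(axis=1) - b * ref.mean()
    out = (x - a[:, None]) / b[:, None]
    res = _tag(sset.with_values(out), "MSC")
    res.meta["msc_slope"] = b
    res.meta["msc_intercept"] = a
    return res


def sg_smooth(sset: SpectrumSet, window: int = 11, polyorder: int = 2, mode: str = "interp") -> SpectrumSet:
    """Savitzky-Golay smoothing along the band axis.

    ``mode='interp'`` fits the edge polynomial on the truncated window
    (scipy default); ``mode='mirror'`` reflects instead.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > sset.n_bands:
        raise ValueError(f"window {window} exceeds band count {sset.n_bands}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    out = savgol_filter(sset.values, window, polyorder, axis=1, mode=mode)
    return _tag(sset.with_values(out), "SG")


def first_derivative(sset: SpectrumSet, mode: str = "central_difference",
                     window: int = 11, polyorder: int = 2) -> SpectrumSet:
    """First derivative w.r.t. wavelength (reflectance / nm).

    Default is a central difference on the (possibly non-uniform)
    wavelength grid with one-sided differences at the edges; the
    ``sg_derivative`` mode uses Savitzky-Golay with deriv=1.
    """
    if sset.n_bands < 3:
        raise ValueError("need at least 3 bands for a derivative")
    if mode == "central_difference":
        out = np.gradient(sset.values, sset.wavelengths, axis=1)
    elif mode == "sg_derivative":
        delta = float(np.mean(np.diff(sset.wavelengths)))
        out = savgol_filter(sset.values, window, polyorder, deriv=1, delta=delta, axis=1, mode="interp")
    else:
        raise ValueError(f"unknown derivative mode {mode!r}")
    return _tag(sset.with_values(out), "FD")


def moving_average(sset: SpectrumSet, window: int = 9) -> SpectrumSet:
    """Boxcar mean along bands; windows truncate at the edges."""
    if window % 2 == 0:
        raise ValueError("moving-average window must be odd")
    if window > sset.n_bands:
        raise ValueError(f"window {window} exceeds band count {sset.n_bands}")
    n = sset.n_bands
    kernel = np.ones(window)
    sums = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, sset.values)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return _tag(sset.with_values(sums / counts), "MA")


def apply(spec: PreprocessSpec, sset: SpectrumSet) -> SpectrumSet:
    """Dispatch a PreprocessSpec over the five operators (plus RAW identity)."""
    m = spec.method
    if m == "RAW":
        return _tag(sset.with_values(sset.values.copy()), "RAW")
    if m == "SNV":
        return snv(sset)
    if m == "MSC":
        return msc(sset, spec.reference)
    if m == "SG":
        return sg_smooth(sset, spec.window, spec.polyorder)
    if m == "FD":
        return first_derivative(sset, spec.derivative_mode, spec.window, spec.polyorder)
    if m == "MA":
        return moving_average(sset, spec.ma_window)
    raise ValueError(f"unknown method token {m!r}")
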