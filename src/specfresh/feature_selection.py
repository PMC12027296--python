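"""Information-theoretic band selection, exact Shapley attribution and the
regression evaluation harness.

Mutual information is estimated with a plug-in entropy estimator on
discretized variables (equal-frequency binning by default, log base 2 so
every score is in bits).  Two selectors are provided:

* :func:`mim_rank` — rank bands by marginal MI against the target;
* :func:`ifs_select` — interaction-aware forward selection driven by joint
  MI.  Because a purely greedy chain started from the best single band can
  never detect a pair of bands that is informative only jointly, the
  selection is seeded with the best *pair* by joint MI when two or more
  bands are requested, then extended greedily.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .spectra_io import SpectrumSet

__all__ = [
    "MIEstimatorSpec",
    "BandSelection",
    "ShapleyResult",
    "RegressionReport",
    "mutual_information",
    "mim_rank",
    "ifs_select",
    "shapley_exact",
    "shap_band_contributions",
    "regression_report",
]


@dataclass
class MIEstimatorSpec:
    """Discretization settings for the plug-in MI estimator (bits)."""

    discretizer: str = "equal_frequency"  # or "equal_width"
    n_bins: int = 16
    target_mode: str = "auto"  # "auto" | "continuous" | "discrete"
    joint_cap: int = 3
    min_cell_count: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.discretizer not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown discretizer {self.discretizer!r}")


@dataclass
class BandSelection:
    """Ordered selected band indices with per-band scores (bits)."""

    method: str
    indices: list[int]
    scores: list[float]
    target: str = ""
    wavelengths: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be unique")
        self.scores = [max(0.0, float(s)) if s > -1e-12 else _raise_neg(s) for s in self.scores]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "target": self.target,
            "indices": [int(i) for i in self.indices],
            "scores": [float(s) for s in self.scores],
            "wavelengths": self.wavelengths,
        }


def _raise_neg(s: float) -> float:
    raise ValueError(f"score {s} is more negative than numerical tolerance")


@dataclass
class ShapleyResult:
    phi: np.ndarray
    value_fn_cache: dict

    @property
    def efficiency_gap(self) -> float:
        n = len(self.phi)
        full = self.value_fn_cache[(1 << n) - 1]
        empty = self.value_fn_cache[0]
        return float(abs(self.phi.sum() - (full - empty)))


@dataclass
class RegressionReport:
    r2: float
    rmse: float
    mae: float
    rpd: float

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae, "rpd": self.rpd}


# ---------------------------------------------------------------------------
# discretization and entropy
# ---------------------------------------------------------------------------

def discretize(x: np.ndarray, spec: MIEstimatorSpec, n_bins: int | None = None,
               force_continuous: bool = False) -> np.ndarray:
    """Map a variable to integer bin codes 0..k-1.

    Discrete variables (few unique values, or non-numeric) are passed
    through via their unique codes.  Degenerate quantile edges collapse to
    fewer bins; a constant variable yields a single bin.
    """
    x = np.asarray(x)
    if x.dtype.kind in "OUS":
        _, codes = np.unique(x, return_inverse=True)
        return codes
    x = x.astype(float)
    nb = spec.n_bins if n_bins is None else n_bins
    uniq = np.unique(x)
    if not force_continuous and uniq.size <= nb:
        return np.searchsorted(uniq, x)
    if spec.discretizer == "equal_frequency":
        qs = np.quantile(x, np.linspace(0, 1, nb + 1)[1:-1])
        edges = np.unique(qs)
    else:
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.shape[0], dtype=int)
        edges = np.linspace(lo, hi, nb + 1)[1:-1]
    return np.searchsorted(edges, x, side="right")


def _entropy_from_codes(codes: np.ndarray) -> float:
    """Plug-in entropy in bits from integer codes."""
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    p = counts / codes.shape[0]
    return float(-(p * np.log2(p)).sum())


def _joint_codes(code_list: Sequence[np.ndarray]) -> np.ndarray:
    out = code_list[0].astype(np.int64)
    for c in code_list[1:]:
        out = out * (int(c.max()) + 1) + c
    # re-index densely so bincount stays small
    _, out = np.unique(out, return_inverse=True)
    return out


def mutual_information(x: np.ndarray, y: np.ndarray, spec: MIEstimatorSpec | None = None) -> float:
    """Plug-in MI estimate I(X;Y) = H(X) + H(Y) - H(X,Y) in bits, clipped at 0."""
    spec = spec or MIEstimatorSpec()
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if x.shape[0] < 2 * spec.n_bins:
        warnings.warn("sample size below 2 * n_bins; MI estimate may be badly biased")
    cx = discretize(x, spec)
    cy = discretize(y, spec)
    hx = _entropy_from_codes(cx)
    hy = _entropy_from_codes(cy)
    hxy = _entropy_from_codes(_joint_codes([cx, cy]))
    return max(0.0, hx + hy - hxy)


def joint_mutual_information(codes: Sequence[np.ndarray], cy: np.ndarray) -> float:
    """I(X_1,...,X_m ; Y) from pre-discretized codes, in bits."""
    cj = _joint_codes(list(codes))
    h_x = _entropy_from_codes(cj)
    h_y = _entropy_from_codes(cy)
    h_xy = _entropy_from_codes(_joint_codes([cj, cy]))
    return max(0.0, h_x + h_y - h_xy)


def _band_codes(sset_values: np.ndarray, spec: MIEstimatorSpec, n_bins: int | None = None) -> list[np.ndarray]:
    return [discretize(sset_values[:, j], spec, n_bins=n_bins) for j in range(sset_values.shape[1])]


def _coarsened_bins(n_samples: int, dims: int, spec: MIEstimatorSpec) -> int:
    """Shrink per-dimension bins until the expected cell occupancy is sane."""
    nb = spec.n_bins
    while nb > 2 and n_samples / (nb ** dims * 2) < spec.min_cell_count:
        nb = max(2, nb // 2)
    return nb


# ---------------------------------------------------------------------------
# band selection
# ---------------------------------------------------------------------------

def mim_rank(sset: SpectrumSet, target: str, k: int, spec: MIEstimatorSpec | None = None) -> BandSelection:
    """Rank bands by marginal MI against the target; top-k, ties to lower index."""
    spec = spec or MIEstimatorSpec()
    if k <= 0:
        raise ValueError("k must be positive")
    k = min(k, sset.n_bands)
    y = sset.target(target)
    mis = np.array([mutual_information(sset.values[:, j], y, spec) for j in range(sset.n_bands)])
    # stable argsort on negated scores -> descending with ties toward lower index
    order = np.argsort(-mis, kind="stable")[:k]
    return BandSelection(
        method="MIM",
        indices=[int(i) for i in order],
        scores=[float(mis[i]) for i in order],
        target=target,
        wavelengths=[float(sset.wavelengths[i]) for i in order],
    )


def ifs_select(sset: SpectrumSet, target: str, k: int, spec: MIEstimatorSpec | None = None,
               pair_search: bool = True) -> BandSelection:
    """Interaction-aware forward selection by joint mutual information.

    For ``k >= 2`` (and ``pair_search`` enabled) the seed is the pair of
    bands maximizing the 2-band joint MI with the target, which lets the
    selector find purely synergistic pairs (e.g. XOR structure) that have
    zero marginal MI.  Subsequent bands are added greedily, each maximizing
    the joint MI of the candidate with the most recently selected bands
    (joint tables capped at ``spec.joint_cap`` dimensions, bins coarsened
    for high-dimensional tables).  Scores record the joint-MI objective at
    each step.
    """
    spec = spec or MIEstimatorSpec()
    if k <= 0:
        raise ValueError("k must be positive")
    n, b = sset.values.shape
    k = min(k, b)
    y = sset.target(target)
    cy = discretize(y, spec)

    single = mim_rank(sset, target, b, spec)
    mi_by_band = dict(zip(single.indices, single.scores))

    if k == 1 or not pair_search or b < 2:
        top = single.indices[:k]
        return BandSelection("IFS", top, [mi_by_band[i] for i in top], target,
                             [float(sset.wavelengths[i]) for i in top])

    nb2 = _coarsened_bins(n, 2, spec)
    codes2 = _band_codes(sset.values, spec, n_bins=nb2)
    best_pair, best_val = None, -1.0
    for i, j in itertools.combinations(range(b), 2):
        v = joint_mutual_information([codes2[i], codes2[j]], cy)
        if v > best_val + 1e-15:
            best_val, best_pair = v, (i, j)
    i, j = best_pair
    # order the seeded pair by marginal MI (stable: single informative band first)
    if mi_by_band[j] > mi_by_band[i]:
        i, j = j, i
    selected = [i, j]
    gains = [mi_by_band[i], best_val]

    nbj = _coarsened_bins(n, spec.joint_cap, spec)
    codesj = codes2 if nbj == nb2 else _band_codes(sset.values, spec, n_bins=nbj)
    while len(selected) < k:
        recent = selected[-(spec.joint_cap - 1):]
        base = [codesj[s] for s in recent]
        best_cand, best_gain = None, -1.0
        for cand in range(b):
            if cand in selected:
                continue
            v = joint_mutual_information(base + [codesj[cand]], cy)
            if v > best_gain + 1e-15:
                best_gain, best_cand = v, cand
        selected.append(best_cand)
        gains.append(best_gain)

    return BandSelection("IFS", selected, gains, target,
                         [float(sset.wavelengths[s]) for s in selected])


# ---------------------------------------------------------------------------
# exact Shapley values
# ---------------------------------------------------------------------------

def shapley_exact(value_fn: Callable[[tuple[int, ...]], float], n_features: int) -> ShapleyResult:
    """Exact Shapley values by full subset enumeration (n <= 12).

    ``value_fn`` receives a sorted tuple of 0-based feature indices and
    returns the coalition value f(S).
    """
    if n_features > 12:
        raise ValueError("exact enumeration limited to n <= 12; use a sampling approximation")
    cache: dict[int, float] = {}
    for mask in range(1 << n_features):
        subset = tuple(i for i in range(n_features) if mask >> i & 1)
        cache[mask] = float(value_fn(subset))

    fact = [math.factorial(i) for i in range(n_features + 1)]
    phi = np.zeros(n_features)
    denom = fact[n_features]
    for i in range(n_features):
        for mask in range(1 << n_features):
            if mask >> i & 1:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[n_features - s - 1] / denom
            phi[i] += w * (cache[mask | (1 << i)] - cache[mask])
    result = ShapleyResult(phi=phi, value_fn_cache=cache)
    if result.efficiency_gap > 1e-8:
        raise AssertionError(f"Shapley efficiency violated by {result.efficiency_gap}")
    return result


def shap_band_contributions(
    sset: SpectrumSet,
    target: str,
    selection: BandSelection,
    surrogate=None,
    n_background: int = 64,
    n_explain: int = 50,
    seed: int = 0,
) -> dict:
    """Mean |Shapley value| per selected band for a surrogate regressor.

    The coalition value for a sample x is the expected surrogate prediction
    with features outside S imputed by marginal sampling from a background
    set (fixed seed).  Exact enumeration requires |selection| <= 12.
    """
    idx = list(selection.indices)
    if len(idx) > 12:
        raise ValueError("exact SHAP mode limited to <= 12 selected bands")
    x = sset.values[:, idx]
    y = sset.target(target).astype(float)
    if surrogate is None:
        from sklearn.ensemble import RandomForestRegressor

        surrogate = RandomForestRegressor(n_estimators=60, random_state=seed)
        surrogate.fit(x, y)
    else:
        if not hasattr(surrogate, "predict"):
            raise ValueError("surrogate must expose predict()")
        if hasattr(surrogate, "fit"):  # sklearn estimator: enforce fitted state
            from sklearn.exceptions import NotFittedError
            from sklearn.utils.validation import check_is_fitted

            try:
                check_is_fitted(surrogate)
            except NotFittedError as e:
                raise ValueError("surrogate model must be fitted") from e

    rng = np.random.default_rng(seed)
    bg = x[rng.choice(x.shape[0], size=min(n_background, x.shape[0]), replace=False)]
    explain_rows = rng.choice(x.shape[0], size=min(n_explain, x.shape[0]), replace=False)

    k = len(idx)
    abs_phi = np.zeros(k)
    for row in explain_rows:
        xi = x[row]

        def value_fn(subset: tuple[int, ...], xi=xi) -> float:
            sim = bg.copy()
            for f in subset:
                sim[:, f] = xi[f]
            return float(surrogate.predict(sim).mean())

        res = shapley_exact(value_fn, k)
        abs_phi += np.abs(res.phi)
    abs_phi /= len(explain_rows)
    return {
        "band_indices": idx,
        "wavelengths": selection.wavelengths,
        "mean_abs_phi": abs_phi,
    }


# ---------------------------------------------------------------------------
# regression harness
# ---------------------------------------------------------------------------

def regression_report(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionReport:
    """R^2, RMSE, MAE and RPD (population sd of y_true over RMSE)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length with n >= 2")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant y_true: R^2 and RPD undefined")
    rmse = math.sqrt(ss_res / y_true.size)
    mae = float(np.abs(y_true - y_pred).mean())
    r2 = 1.0 - ss_res / ss_tot
    sd = float(y_true.std())  # population sd
    rpd = math.inf if rmse == 0 else sd / rmse
    return RegressionReport(r2=r2, rmse=rmse, mae=mae, rpd=rpd)
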