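"""Spectral pretreatment operators with a fit-on-calibration contract.

Seven operators cover the usual chemometric corrections for NIR absorbance
and Raman counts: row-wise standard normal variate (SNV), range
normalization (NOR), multiplicative scatter correction (MSC), baseline
correction (BA), Savitzky-Golay smoothing/derivatives (SG), first
derivative (FD = SG with derivative order 1), and mean centering (MC).
SNV, NOR, BA, SG and FD are row-local and stateless; MC and MSC estimate
statistics (column means, reference spectrum) on calibration rows only and
freeze them for cross-validation folds and prediction data.

Operators act on plain intensity matrices; :class:`PreprocessPipeline`
composes them left-to-right with the fit/apply split handled for you.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateRowError, ShapeError, SpecfuseError

_EPS = 1e-12


def _as2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per row, subtract mean and divide by the
    sample standard deviation (divisor n-1)."""
    X = _as2d(X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.where(sd[:, 0] < _EPS)[0]
    if bad.size:
        raise DegenerateRowError(f"constant row(s) {bad.tolist()[:5]} in SNV")
    return (X - mu) / sd


def fit_column_means(X_cal: np.ndarray) -> np.ndarray:
    return _as2d(X_cal).mean(axis=0)


def mean_center(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Subtract fitted calibration column means (MC)."""
    X = _as2d(X)
    means = np.asarray(means, dtype=float)
    if means.shape != (X.shape[1],):
        raise ShapeError(
            f"means have {means.size} columns, matrix has {X.shape[1]}"
        )
    return X - means[None, :]


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference (x ~ a*ref + b by least
    squares) and replaced by (x - b) / a, removing per-sample
    multiplicative and additive scatter.
    """
    X = _as2d(X)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ShapeError("reference length does not match column count")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom < _EPS:
        raise DegenerateRowError("zero-variance MSC reference spectrum")
    a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(a) < _EPS):
        raise DegenerateRowError("zero MSC slope; row uncorrelated with reference")
    b = X.mean(axis=1) - a * ref.mean()
    return (X - b[:, None]) / a[:, None]


def range_normalize(X: np.ndarray) -> np.ndarray:
    """Range normalization (NOR): per row, (x - min) / (max - min)."""
    X = _as2d(X)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    bad = np.where((hi - lo)[:, 0] < _EPS)[0]
    if bad.size:
        raise DegenerateRowError(f"constant row(s) {bad.tolist()[:5]} in NOR")
    return (X - lo) / (hi - lo)


def savitzky_golay(
    X: np.ndarray,
    window: int = 15,
    polyorder: int = 2,
    deriv: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay local-polynomial filter per row.

    ``deriv=0`` smooths; ``deriv=1`` with ``delta`` = grid step is the
    first-derivative (FD) operator in intensity per cm^-1.
    """
    X = _as2d(X)
    if window % 2 == 0 or window <= polyorder:
        raise SpecfuseError("SG window must be odd and greater than polyorder")
    if deriv > polyorder:
        raise SpecfuseError("SG derivative order must not exceed polyorder")
    if X.shape[1] < window:
        raise ShapeError(f"rows of length {X.shape[1]} shorter than window {window}")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=delta, axis=1, mode="interp",
    )


def baseline_correct(X: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Baseline correction (BA).

    ``linear`` subtracts the straight line through each row's first and
    last points and then shifts the row minimum to zero; ``offset``
    subtracts the row minimum only.  Constant rows map to zeros.
    """
    X = _as2d(X)
    if mode not in ("linear", "offset"):
        raise SpecfuseError(f"unknown baseline mode {mode!r}")
    if mode == "linear":
        p = X.shape[1]
        t = np.linspace(0.0, 1.0, p)
        line = X[:, [0]] + (X[:, [-1]] - X[:, [0]]) * t[None, :]
        X = X - line
    return X - X.min(axis=1, keepdims=True)


@dataclass
class PreprocessStep:
    """One named pretreatment with parameters and optional fitted state.

    Methods: ``snv``, ``nor``, ``mc``, ``msc``, ``ba``, ``sg``, ``fd``.
    ``sg`` accepts ``window``/``polyorder``/``deriv``; ``fd`` is ``sg`` with
    ``deriv=1``; ``ba`` accepts ``mode`` in {linear, offset}.
    """

    method: str
    params: dict[str, Any] = field(default_factory=dict)
    fitted_state: Any = None

    _STATELESS = {"snv", "nor", "ba", "sg", "fd"}

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        known = self._STATELESS | {"mc", "msc"}
        if self.method not in known:
            raise SpecfuseError(f"unknown preprocessing method {self.method!r}")

    def fit(self, X_cal: np.ndarray, wavenumbers: np.ndarray | None = None
            ) -> "PreprocessStep":
        if self.method == "mc":
            self.fitted_state = fit_column_means(X_cal)
        elif self.method == "msc":
            ref = self.params.get("reference")
            self.fitted_state = (
                np.asarray(ref, float) if ref is not None
                else _as2d(X_cal).mean(axis=0)
            )
        if wavenumbers is not None and self.method in ("sg", "fd"):
            self.params.setdefault(
                "delta", float(np.mean(np.diff(wavenumbers)))
            )
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        m = self.method
        if m == "snv":
            return snv(X)
        if m == "nor":
            return range_normalize(X)
        if m == "ba":
            return baseline_correct(X, mode=self.params.get("mode", "linear"))
        if m in ("sg", "fd"):
            return savitzky_golay(
                X,
                window=int(self.params.get("window", 15)),
                polyorder=int(self.params.get("polyorder", 2)),
                deriv=1 if m == "fd" else int(self.params.get("deriv", 0)),
                delta=float(self.params.get("delta", 1.0)),
            )
        if self.fitted_state is None:
            raise SpecfuseError(f"step {m!r} applied before fit")
        if m == "mc":
            return mean_center(X, self.fitted_state)
        return msc(X, self.fitted_state)


@dataclass
class PreprocessPipeline:
    """Ordered pretreatment steps applied left-to-right.

    ``fit`` estimates all stateful statistics from calibration rows (each
    step sees the output of the previous ones); ``transform`` applies the
    frozen pipeline to any matrix over the same grid.
    """

    steps: list[PreprocessStep] = field(default_factory=list)

    @classmethod
    def from_config(cls, config: Sequence[dict[str, Any] | str]) -> "PreprocessPipeline":
        steps = []
        for item in config:
            if isinstance(item, str):
                steps.append(PreprocessStep(item))
            else:
                spec = dict(item)
                steps.append(PreprocessStep(spec.pop("method"), spec))
        return cls(steps)

    def fit(self, X_cal: np.ndarray, wavenumbers: np.ndarray | None = None
            ) -> "PreprocessPipeline":
        Z = _as2d(X_cal)
        for step in self.steps:
            step.fit(Z, wavenumbers)
            Z = step.apply(Z)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = _as2d(X)
        for step in self.steps:
            Z = step.apply(Z)
        return Z

    def fit_transform(self, X_cal: np.ndarray,
                      wavenumbers: np.ndarray | None = None) -> np.ndarray:
        self.fit(X_cal, wavenumbers)
        return self.transform(X_cal)

    def clone_unfitted(self) -> "PreprocessPipeline":
        """Fresh copy with parameters kept and fitted state dropped."""
        steps = []
        for s in self.steps:
            params = {k: v for k, v in s.params.items() if k != "reference"}
            steps.append(PreprocessStep(s.method, copy.deepcopy(params)))
        return PreprocessPipeline(steps)
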