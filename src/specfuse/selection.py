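"""Wavenumber selection: CARS, SPA and IRIV over a calibration matrix.

All three selectors work against a cross-validated PLS backend on the
binary node coding; RMSECV is the root mean squared out-of-fold node
error.  Ties anywhere break to the lowest column index.

* CARS — competitive adaptive reweighted sampling: Monte-Carlo PLS runs
  rank variables by mean absolute regression coefficient across nodes; an
  exponentially decreasing retention ratio (all variables at run 1, two at
  the final run) combined with coefficient-weighted sampling shrinks the
  subset; the run with minimal RMSECV wins.
* SPA — successive projections algorithm: greedy chains that repeatedly
  add the column with the largest projection onto the orthogonal
  complement of the chosen span (minimal collinearity); chains are scored
  by cross-validated misclassification.
* IRIV — iteratively retaining informative variables: random binary
  inclusion designs score each variable by the error difference between
  subsets that include vs exclude it (Mann-Whitney assessed); variables
  whose inclusion does not lower the error are dropped, iterating to a
  fixed point, followed by backward elimination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .exceptions import SelectionError, SpecfuseError
from .io import ClassAlphabet
from .plsda import NodeCoding, _stratified_folds, decode_coding, simpls_fit


@dataclass
class SelectionResult:
    """Chosen column indices plus per-iteration diagnostics."""

    selected_indices: np.ndarray
    method: str
    rmsecv_trace: np.ndarray
    subset_size_trace: np.ndarray
    seed: int = 0
    n_runs: int = 0
    selected_wavenumbers: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.selected_indices.size == 0:
            raise SelectionError("empty selection")
        if np.unique(self.selected_indices).size != self.selected_indices.size:
            raise SelectionError("duplicate selected indices")

    def to_csv(self, path, n_columns: int | None = None,
               wavenumbers: np.ndarray | None = None) -> None:
        wns = wavenumbers if wavenumbers is not None else self.selected_wavenumbers
        p = n_columns or (len(wns) if wns is not None else
                          int(self.selected_indices.max()) + 1)
        sel = np.zeros(p, dtype=int)
        sel[self.selected_indices] = 1
        df = pd.DataFrame({"column": np.arange(p), "selected": sel})
        if wns is not None and len(wns) == p:
            df.insert(0, "wavenumber", np.asarray(wns))
        df.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "seed": int(self.seed),
            "n_runs": int(self.n_runs),
            "selected_indices": self.selected_indices.tolist(),
            "rmsecv_trace": np.asarray(self.rmsecv_trace).tolist(),
            "subset_size_trace": np.asarray(self.subset_size_trace).tolist(),
            "diagnostics": self.diagnostics,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class CarsConfig:
    """CARS settings; the retention-ratio constants are derived so run 1
    keeps all ``p`` variables and the final run keeps exactly 2."""

    n_runs: int = 100
    mc_sample_fraction: float = 0.8
    cv_folds: int = 5
    n_lv: int = 10

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise SpecfuseError("CARS needs n_runs >= 2")
        if not 0.0 < self.mc_sample_fraction < 1.0:
            raise SpecfuseError("mc_sample_fraction must be in (0, 1)")

    def edf_constants(self, p: int) -> tuple[float, float]:
        """(a, k) of the exponentially decreasing function r_i = a e^{-k i}."""
        N = self.n_runs
        a = (p / 2.0) ** (1.0 / (N - 1))
        k = np.log(p / 2.0) / (N - 1)
        return a, k

    def retention_counts(self, p: int) -> np.ndarray:
        a, k = self.edf_constants(p)
        runs = np.arange(1, self.n_runs + 1)
        counts = np.rint(p * a * np.exp(-k * runs)).astype(int)
        counts[0] = p  # boundary: run 1 keeps everything
        counts[-1] = 2  # boundary: final run keeps two
        return np.clip(counts, 2, p)


def _rmsecv(X: np.ndarray, Y: np.ndarray, folds: Sequence, n_lv: int) -> float:
    """Root mean squared out-of-fold node error over precomputed folds."""
    sq, count = 0.0, 0
    for tr, va in folds:
        nc = min(n_lv, X.shape[1], tr.size - 1)
        fit = simpls_fit(X[tr], Y[tr], nc)
        resid = fit.predict(X[va]) - Y[va]
        sq += float(np.sum(resid * resid))
        count += resid.size
    return float(np.sqrt(sq / count))


def cars_select(
    X: np.ndarray,
    Y: NodeCoding | np.ndarray,
    cfg: CarsConfig | None = None,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each run Monte-Carlo subsamples calibration rows, fits PLS on the
    surviving variables, and keeps ``K_i`` variables (the enforced
    exponentially decreasing count) by coefficient-weighted sampling
    without replacement.  RMSECV of each run's subset is measured on the
    full calibration rows; the subset with minimal RMSECV is returned.
    """
    cfg = cfg or CarsConfig()
    Ymat = Y.matrix if isinstance(Y, NodeCoding) else np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise SelectionError("CARS needs at least 2 variables")
    labels = np.argmax(Ymat, axis=1).astype(str)
    folds = _stratified_folds(labels, cfg.cv_folds, seed)
    counts = cfg.retention_counts(p)
    rng = np.random.default_rng(seed)
    n_mc = max(2, int(round(cfg.mc_sample_fraction * n)))

    current = np.arange(p)
    subsets: list[np.ndarray] = []
    rmse = np.empty(cfg.n_runs)
    sizes = np.empty(cfg.n_runs, dtype=int)
    for i in range(cfg.n_runs):
        rows = rng.choice(n, size=n_mc, replace=False)
        nc = min(cfg.n_lv, current.size, n_mc - 1)
        fit = simpls_fit(X[np.ix_(rows, current)], Ymat[rows], nc)
        w = np.abs(fit.coef()).mean(axis=1)
        if not np.all(np.isfinite(w)):
            raise SpecfuseError(f"non-finite PLS coefficients at CARS run {i + 1}")
        k_i = min(int(counts[i]), current.size)
        if k_i < current.size:
            prob = w + 1e-12
            prob /= prob.sum()
            pick = rng.choice(current.size, size=k_i, replace=False, p=prob)
            current = np.sort(current[pick])
        rmse[i] = _rmsecv(X[:, current], Ymat, folds, cfg.n_lv)
        sizes[i] = current.size
        subsets.append(current.copy())

    best = int(np.argmin(rmse))
    sel = subsets[best]
    return SelectionResult(
        selected_indices=sel,
        method="CARS",
        rmsecv_trace=rmse,
        subset_size_trace=sizes,
        seed=seed,
        n_runs=cfg.n_runs,
        selected_wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers)[sel],
        diagnostics={"best_run": best + 1, "edf_constants": cfg.edf_constants(p)},
    )


def chain_cv_error(
    X: np.ndarray,
    cols: Sequence[int],
    labels: np.ndarray,
    alphabet: ClassAlphabet,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Cross-validated misclassification count of a PLS-DA fit on ``cols``.

    The SPA objective.  Returns an integer count (deterministic folds) so
    chain comparisons are exact.
    """
    from .plsda import encode_labels  # local import to avoid cycle at module load

    cols = np.asarray(cols, dtype=int)
    coding = encode_labels(labels, alphabet)
    wrong = 0
    for tr, va in _stratified_folds(labels, folds, seed):
        nc = min(cols.size, tr.size - 1)
        fit = simpls_fit(X[np.ix_(tr, cols)], coding.matrix[tr], nc)
        pred = np.argmax(fit.predict(X[np.ix_(va, cols)]), axis=1)
        truth = np.argmax(coding.matrix[va], axis=1)
        wrong += int(np.sum(pred != truth))
    return wrong


def spa_chain(X: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Successive-projections chain from ``start``.

    Repeatedly adds the column with maximal norm of its projection onto
    the orthogonal complement of the selected span; exact ties break to
    the lowest column index.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    chain = [int(start)]
    basis = np.zeros((n, 0))
    x = X[:, start]
    basis = np.hstack([basis, (x / np.linalg.norm(x))[:, None]])
    resid = X - basis @ (basis.T @ X)
    while len(chain) < max_vars:
        norms = np.linalg.norm(resid, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < 1e-10:
            break
        chain.append(j)
        b = resid[:, j] / norms[j]
        basis = np.hstack([basis, b[:, None]])
        resid = resid - b[:, None] * (b @ resid)
    return chain


def spa_select(
    X: np.ndarray,
    labels: np.ndarray,
    alphabet: ClassAlphabet,
    max_vars: int,
    folds: int = 5,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
) -> SelectionResult:
    """Successive projections algorithm (deterministic).

    Builds one projection chain per starting column, scores every chain
    prefix of length 1..max_vars by :func:`chain_cv_error`, and returns
    the best chain.  Ties break to the shorter chain, then the lower
    starting column index.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if max_vars > min(n - 1, p):
        raise SpecfuseError("max_vars exceeds min(n_rows - 1, n_cols)")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms < 1e-12):
        bad = int(np.argmin(norms))
        raise SelectionError(f"zero-norm column {bad}")
    labels = np.asarray(labels, dtype=object)

    best: tuple[int, int, int] | None = None  # (error, length, start)
    best_chain: list[int] = []
    trace_err: list[float] = []
    trace_len: list[int] = []
    for start in range(p):
        chain = spa_chain(X, start, max_vars)
        for length in range(1, len(chain) + 1):
            err = chain_cv_error(X, chain[:length], labels, alphabet, folds, seed)
            key = (err, length, start)
            trace_err.append(err)
            trace_len.append(length)
            if best is None or key < best:
                best = key
                best_chain = chain[:length]
    sel = np.sort(np.asarray(best_chain, dtype=int))
    return SelectionResult(
        selected_indices=sel,
        method="SPA",
        rmsecv_trace=np.asarray(trace_err, dtype=float),
        subset_size_trace=np.asarray(trace_len, dtype=int),
        seed=seed,
        n_runs=len(trace_err),
        selected_wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers)[sel],
        diagnostics={"chain": [int(c) for c in best_chain],
                     "cv_misclassifications": int(best[0])},
    )


def iriv_round(
    X: np.ndarray,
    Ymat: np.ndarray,
    cols: np.ndarray,
    rng: np.random.Generator,
    folds: Sequence,
    n_sampling_rows: int = 500,
    n_lv: int = 10,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One IRIV classification round over ``cols``.

    Draws a binary inclusion design (inclusion probability 0.5), measures
    RMSECV of every row-subset, and scores each variable by
    ``dmean = mean(RMSECV without it) - mean(RMSECV with it)`` with a
    Mann-Whitney p-value.  Returns (keep_mask, dmean, pvalues): variables
    with ``dmean > 0`` (strong informative when p < alpha, else weak) are
    kept; the rest (uninformative / interfering) are dropped.
    """
    q = cols.size
    A = rng.random((n_sampling_rows, q)) < 0.5
    # every design row needs at least two variables to fit anything
    deficient = A.sum(axis=1) < 2
    for r in np.where(deficient)[0]:
        A[r, rng.choice(q, size=2, replace=False)] = True
    errors = np.empty(n_sampling_rows)
    for r in range(n_sampling_rows):
        sub = cols[A[r]]
        errors[r] = _rmsecv(X[:, sub], Ymat, folds, n_lv)
    dmean = np.empty(q)
    pvals = np.empty(q)
    for j in range(q):
        incl = errors[A[:, j]]
        excl = errors[~A[:, j]]
        if incl.size == 0 or excl.size == 0:  # vanishing chance at 500 rows
            dmean[j], pvals[j] = 1.0, 1.0
            continue
        dmean[j] = float(excl.mean() - incl.mean())
        pvals[j] = float(mannwhitneyu(incl, excl, alternative="two-sided").pvalue)
    return dmean > 0, dmean, pvals


def iriv_select(
    X: np.ndarray,
    Y: NodeCoding | np.ndarray,
    seed: int = 0,
    n_sampling_rows: int = 500,
    alpha: float = 0.05,
    cv_folds: int = 5,
    n_lv: int = 10,
    max_rounds: int = 30,
    wavenumbers: np.ndarray | None = None,
) -> SelectionResult:
    """Iteratively retaining informative variables.

    Classification rounds drop uninformative and interfering variables
    until a round drops nothing (all survivors informative), then a greedy
    backward elimination removes survivors whose removal does not raise
    RMSECV.
    """
    Ymat = Y.matrix if isinstance(Y, NodeCoding) else np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    labels = np.argmax(Ymat, axis=1).astype(str)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, cv_folds, seed)

    current = np.arange(X.shape[1])
    rmse_trace: list[float] = []
    size_trace: list[int] = [current.size]
    for _ in range(max_rounds):
        keep, dmean, pvals = iriv_round(
            X, Ymat, current, rng, folds, n_sampling_rows, n_lv, alpha
        )
        if keep.all():
            break
        current = current[keep]
        if current.size < 2:
            raise SelectionError(
                "IRIV eliminated (nearly) all variables; consider a looser "
                f"significance level than alpha={alpha}"
            )
        rmse_trace.append(_rmsecv(X[:, current], Ymat, folds, n_lv))
        size_trace.append(current.size)

    # backward elimination of the survivors
    base = _rmsecv(X[:, current], Ymat, folds, n_lv)
    while current.size > 1:
        errs = np.array([
            _rmsecv(X[:, np.delete(current, j)], Ymat, folds, n_lv)
            for j in range(current.size)
        ])
        j = int(np.argmin(errs))
        if errs[j] <= base:
            base = float(errs[j])
            current = np.delete(current, j)
            rmse_trace.append(base)
            size_trace.append(current.size)
        else:
            break

    return SelectionResult(
        selected_indices=current,
        method="IRIV",
        rmsecv_trace=np.asarray(rmse_trace, dtype=float),
        subset_size_trace=np.asarray(size_trace, dtype=int),
        seed=seed,
        n_runs=len(size_trace),
        selected_wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers)[current],
        diagnostics={"final_rmsecv": base, "alpha": alpha,
                     "n_sampling_rows": n_sampling_rows},
    )
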