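"""Multi-response PLS-DA with binary node coding.

Class membership over ``k`` classes is encoded as ``k`` binary nodes (1 =
belongs to this class, 0 = otherwise).  A multi-response PLS regression of
the node matrix on the spectra yields continuous node values — regression
outputs that may fall outside [0, 1] — and a sample is assigned to the
class of its maximal node value.

The PLS core is SIMPLS (de Jong 1993): deterministic, and it yields the
whole coefficient path in one fit, so cross-validated selection of the
latent-variable count costs one fit per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    LabelError,
    ShapeError,
    SpecfuseError,
    StratificationError,
)
from .io import ClassAlphabet
from .preprocessing import PreprocessPipeline

_TOL = 1e-12


@dataclass
class NodeCoding:
    """One-hot ("node") coding of class labels, columns ordered by alphabet."""

    alphabet: ClassAlphabet
    matrix: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return decode_coding(self)


def encode_labels(labels, alphabet: ClassAlphabet) -> NodeCoding:
    """Binary node coding: row i has a single 1 in its class's column."""
    labels = np.asarray(labels, dtype=object)
    alphabet.validate(labels)
    Y = np.zeros((labels.size, len(alphabet)))
    for i, lab in enumerate(labels):
        Y[i, alphabet.index(str(lab))] = 1.0
    return NodeCoding(alphabet, Y)


def decode_coding(coding: NodeCoding) -> np.ndarray:
    idx = np.argmax(coding.matrix, axis=1)
    return np.asarray([coding.alphabet.names[i] for i in idx], dtype=object)


@dataclass
class SimplsFit:
    """Fitted SIMPLS state: weights ``R``, loadings-basis ``V``, response
    loadings ``Q`` (one column per component), plus centering means."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    R: np.ndarray  # p x A
    Q: np.ndarray  # m x A
    n_components: int

    def coef(self, ncomp: int | None = None) -> np.ndarray:
        a = self.n_components if ncomp is None else min(ncomp, self.n_components)
        return self.R[:, :a] @ self.Q[:, :a].T

    def predict(self, X: np.ndarray, ncomp: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean.size:
            raise ShapeError(
                f"matrix has {X.shape[1]} variables, model expects {self.x_mean.size}"
            )
        return (X - self.x_mean) @ self.coef(ncomp) + self.y_mean

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Predictions for every component count 1..A, shape (A, n, m)."""
        X = np.asarray(X, dtype=float)
        Xc = X - self.x_mean
        T = Xc @ self.R  # n x A
        out = np.empty((self.n_components, X.shape[0], self.y_mean.size))
        acc = np.broadcast_to(self.y_mean, (X.shape[0], self.y_mean.size)).copy()
        for a in range(self.n_components):
            acc = acc + np.outer(T[:, a], self.Q[:, a])
            out[a] = acc
        return out


def simpls_fit(X: np.ndarray, Y: np.ndarray, n_components: int) -> SimplsFit:
    """SIMPLS fit of a multi-response linear model, centering X and Y.

    Stops early (with fewer components) if the deflated cross-product
    matrix degenerates; at ``n_components = rank(Xc)`` the coefficients
    coincide with the least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    if n_components < 1:
        raise SpecfuseError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise SpecfuseError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    S = Xc.T @ Yc
    R = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    V = np.zeros((p, n_components))
    a_done = 0
    for a in range(n_components):
        if m == 1:
            r = S[:, 0].copy()
        else:
            u, sv, _ = np.linalg.svd(S, full_matrices=False)
            r = u[:, 0] * sv[0]
        t = Xc @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-10:
            break
        t /= normt
        r = r / normt
        p_a = Xc.T @ t
        q_a = Yc.T @ t
        v = p_a - V[:, :a] @ (V[:, :a].T @ p_a)
        nv = np.linalg.norm(v)
        if nv < 1e-10:
            break
        v /= nv
        S = S - np.outer(v, v @ S)
        R[:, a], Q[:, a], V[:, a] = r, q_a, v
        a_done = a + 1
    if a_done == 0:
        raise SpecfuseError("no PLS component could be extracted (degenerate X or Y)")
    return SimplsFit(x_mean, y_mean, R[:, :a_done], Q[:, :a_done], a_done)


@dataclass
class PlsdaModel:
    """Fitted PLS-DA model: SIMPLS state plus the class alphabet."""

    alphabet: ClassAlphabet
    n_lv: int
    fit_: SimplsFit

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients, shape (n_variables, n_classes)."""
        return self.fit_.coef(self.n_lv)

    def predict_nodes(self, X: np.ndarray) -> np.ndarray:
        return predict_nodes(self, X)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return assign_classes(self.predict_nodes(X), self.alphabet)


def fit_plsda(X: np.ndarray, coding: NodeCoding, n_lv: int) -> PlsdaModel:
    """Fit multi-response PLS of the node coding on (preprocessed) spectra."""
    X = np.asarray(X, dtype=float)
    col_sd = X.std(axis=0)
    if np.any(col_sd < _TOL):
        warnings.warn(
            f"{int(np.sum(col_sd < _TOL))} constant column(s) in X; "
            "variable selection should have removed them",
            stacklevel=2,
        )
    return PlsdaModel(coding.alphabet, n_lv, simpls_fit(X, coding.matrix, n_lv))


def predict_nodes(model: PlsdaModel, X: np.ndarray) -> np.ndarray:
    """Continuous node values for each sample (n_samples x n_classes)."""
    return model.fit_.predict(X, model.n_lv)


def assign_classes(nodes: np.ndarray, alphabet: ClassAlphabet) -> np.ndarray:
    """Class of the maximal node value; ties break to the lowest index."""
    nodes = np.asarray(nodes, dtype=float)
    if not np.all(np.isfinite(nodes)):
        raise SpecfuseError("non-finite node values")
    idx = np.argmax(nodes, axis=1)
    return np.asarray([alphabet.names[i] for i in idx], dtype=object)


def _stratified_folds(labels: np.ndarray, folds: int, seed: int):
    labels = np.asarray(labels, dtype=object)
    _, counts = np.unique(labels.astype(str), return_counts=True)
    if folds < 2:
        raise SpecfuseError("folds must be >= 2")
    if folds > counts.min():
        raise StratificationError(
            f"{folds} folds but smallest class has {counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels.astype(str)))


def choose_n_lv(
    X: np.ndarray,
    coding: NodeCoding,
    max_lv: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Latent-variable count minimizing cross-validated misclassification.

    Ties go to the smallest count.  One SIMPLS fit per fold supplies the
    error of every candidate count.
    """
    X = np.asarray(X, dtype=float)
    labels = decode_coding(coding)
    max_lv = min(max_lv, X.shape[1], X.shape[0] - 1 - X.shape[0] // folds)
    max_lv = max(max_lv, 1)
    errors = np.zeros(max_lv)
    for tr, va in _stratified_folds(labels, folds, seed):
        f = simpls_fit(X[tr], coding.matrix[tr], max_lv)
        path = f.predict_path(X[va])  # (A, n_va, m)
        truth = np.argmax(coding.matrix[va], axis=1)
        for a in range(max_lv):
            pred = np.argmax(path[min(a, f.n_components - 1)], axis=1)
            errors[a] += np.sum(pred != truth)
    return int(np.argmin(errors)) + 1


@dataclass
class CVResult:
    """Out-of-fold node values: each sample predicted exactly once."""

    nodes: np.ndarray
    assigned: np.ndarray
    fold_of_sample: np.ndarray
    alphabet: ClassAlphabet


def cross_validate(
    X: np.ndarray,
    coding: NodeCoding,
    n_lv: int,
    folds: int = 10,
    seed: int = 0,
    preprocess: PreprocessPipeline | None = None,
    wavenumbers: np.ndarray | None = None,
    selected_indices: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold CV producing out-of-fold node values.

    When a ``preprocess`` pipeline is given, its statistics are refit on
    each training fold (no leakage of fold-external rows); variable
    selection indices, if any, are applied after preprocessing.
    """
    X = np.asarray(X, dtype=float)
    labels = decode_coding(coding)
    oof = np.full((X.shape[0], len(coding.alphabet)), np.nan)
    fold_of = np.full(X.shape[0], -1, dtype=int)
    for k, (tr, va) in enumerate(_stratified_folds(labels, folds, seed)):
        Xtr, Xva = X[tr], X[va]
        if preprocess is not None:
            pipe = preprocess.clone_unfitted()
            Xtr = pipe.fit_transform(Xtr, wavenumbers)
            Xva = pipe.transform(Xva)
        if selected_indices is not None:
            Xtr = Xtr[:, selected_indices]
            Xva = Xva[:, selected_indices]
        n_lv_k = min(n_lv, Xtr.shape[0] - 1, Xtr.shape[1])
        model = fit_plsda(Xtr, NodeCoding(coding.alphabet, coding.matrix[tr]), n_lv_k)
        oof[va] = model.predict_nodes(Xva)
        fold_of[va] = k
    assert not np.isnan(oof).any()
    return CVResult(oof, assign_classes(oof, coding.alphabet), fold_of, coding.alphabet)
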