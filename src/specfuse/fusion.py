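"""Bayesian decision-level fusion of two PLS-DA modalities.

Continuous node values from each modality's PLS-DA model are first turned
into class probabilities: negative node values are clipped to zero and the
rest renormalized to sum to one.  With ``pB`` (first modality, e.g. NIR)
and ``pC`` (second modality, e.g. Raman) the fused posterior over classes
``A_1..A_k`` under an equal prior is

    P(A_i | B and C) = pB_i * pC_i / sum_k pB_k * pC_k

A sample is assigned to the argmax class only when the top posterior
exceeds the runner-up by strictly more than a margin threshold (default
0.01); otherwise it stays unassigned.  Data-layer and feature-layer
concatenation fusion are provided as comparators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, SpecfuseError
from .io import ClassAlphabet

#: Sentinel label for samples failing the margin decision rule.
UNASSIGNED = "UNASSIGNED"

DEFAULT_THRESHOLD = 0.01


def node_to_probability(node_row: np.ndarray) -> np.ndarray:
    """Clip negative node values to 0 and renormalize to sum 1.

    An all-nonpositive row carries no usable class mass and maps to the
    uniform distribution with a warning.
    """
    row = np.asarray(node_row, dtype=float)
    if not np.all(np.isfinite(row)):
        raise SpecfuseError("non-finite node values")
    clipped = np.clip(row, 0.0, None)
    total = clipped.sum()
    if total <= 0.0:
        warnings.warn(
            "all node values nonpositive; falling back to uniform probability",
            stacklevel=2,
        )
        return np.full(row.size, 1.0 / row.size)
    return clipped / total


def node_matrix_to_probabilities(nodes: np.ndarray) -> np.ndarray:
    """Row-wise :func:`node_to_probability` (vectorized, same semantics)."""
    nodes = np.asarray(nodes, dtype=float)
    if not np.all(np.isfinite(nodes)):
        raise SpecfuseError("non-finite node values")
    clipped = np.clip(nodes, 0.0, None)
    totals = clipped.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] <= 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sample(s) with all-nonpositive node "
            "values; using uniform probability",
            stacklevel=2,
        )
        clipped[degenerate] = 1.0
        totals = clipped.sum(axis=1, keepdims=True)
    return clipped / totals


def bayes_fuse(
    pB: np.ndarray, pC: np.ndarray, prior: np.ndarray | None = None
) -> np.ndarray:
    """Posterior over classes from two modality probability vectors.

    With the default equal prior this is exactly the product rule above;
    a non-uniform ``prior`` weights the products before normalization.
    When the supports are disjoint (zero total product mass) the posterior
    is undefined; the fallback is the normalized average of the inputs.
    """
    pB = np.asarray(pB, dtype=float)
    pC = np.asarray(pC, dtype=float)
    if pB.shape != pC.shape:
        raise AlignmentError("probability vectors differ in length")
    w = np.full(pB.size, 1.0 / pB.size) if prior is None else np.asarray(prior, float)
    joint = w * pB * pC
    total = joint.sum()
    if total <= 0.0:
        avg = pB + pC
        return avg / avg.sum()
    return joint / total


def fusion_conflict(pB: np.ndarray, pC: np.ndarray) -> bool:
    """True when the two modalities have disjoint support (Eq.-undefined)."""
    return float(np.sum(np.asarray(pB) * np.asarray(pC))) <= 0.0


@dataclass
class PosteriorResult:
    """Fused posterior, margin and the margin-rule assignment for one sample."""

    posterior: np.ndarray
    assigned: str
    margin: float
    threshold: float
    sample_id: str | None = None
    conflict: bool = False
    degenerate: bool = False


def decide(
    posterior: np.ndarray,
    alphabet: ClassAlphabet,
    threshold: float = DEFAULT_THRESHOLD,
) -> PosteriorResult:
    """Two-criterion decision rule.

    Assign the argmax class iff (1) it holds the maximum posterior and
    (2) top1 - top2 is strictly greater than ``threshold``; otherwise
    UNASSIGNED.  Exact argmax ties have margin 0 and stay unassigned.
    """
    post = np.asarray(posterior, dtype=float)
    if not np.all(np.isfinite(post)):
        raise SpecfuseError("non-finite posterior")
    order = np.argsort(post, kind="stable")
    top1 = int(np.argmax(post))  # lowest index on ties
    top2_val = post[order[-2]] if post.size > 1 else 0.0
    margin = float(post[top1] - top2_val)
    # strict inequality up to float rounding: a margin equal to the
    # threshold (e.g. 0.505 - 0.495 vs 0.01) must stay unassigned
    assigned = alphabet.names[top1] if margin > threshold + 1e-12 else UNASSIGNED
    return PosteriorResult(post, assigned, margin, threshold)


@dataclass
class FusionReport:
    """Per-sample fusion outcomes over a dataset."""

    results: list[PosteriorResult]
    alphabet: ClassAlphabet
    threshold: float

    @property
    def assigned(self) -> np.ndarray:
        return np.asarray([r.assigned for r in self.results], dtype=object)

    @property
    def posteriors(self) -> np.ndarray:
        return np.vstack([r.posterior for r in self.results])

    def to_frame(self, true_labels: np.ndarray | None = None):
        import pandas as pd

        rows = []
        for i, r in enumerate(self.results):
            row = {"sample_id": r.sample_id or str(i)}
            if true_labels is not None:
                row["true"] = str(true_labels[i])
            row.update({f"p_{c}": r.posterior[j]
                        for j, c in enumerate(self.alphabet.names)})
            row.update({
                "assigned": r.assigned,
                "margin": r.margin,
                "conflict": r.conflict,
                "degenerate": r.degenerate,
            })
            rows.append(row)
        return pd.DataFrame(rows)


def fuse_dataset(
    nodesB: np.ndarray,
    nodesC: np.ndarray,
    alphabet: ClassAlphabet,
    threshold: float = DEFAULT_THRESHOLD,
    prior: np.ndarray | None = None,
    sample_ids_b: list[str] | None = None,
    sample_ids_c: list[str] | None = None,
) -> FusionReport:
    """Row-wise node->probability, Bayes fusion and margin decision.

    Rows of the two node matrices must describe the same samples in the
    same order; when sample ids are supplied, misalignment raises.
    """
    nodesB = np.asarray(nodesB, dtype=float)
    nodesC = np.asarray(nodesC, dtype=float)
    if nodesB.shape != nodesC.shape:
        raise AlignmentError(
            f"node matrices differ in shape: {nodesB.shape} vs {nodesC.shape}"
        )
    if sample_ids_b is not None and sample_ids_c is not None:
        if list(sample_ids_b) != list(sample_ids_c):
            raise AlignmentError("sample ids of the two modalities differ")
    ids = sample_ids_b or sample_ids_c
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probB = node_matrix_to_probabilities(nodesB)
        probC = node_matrix_to_probabilities(nodesC)
    degenerate_b = np.all(nodesB <= 0, axis=1)
    degenerate_c = np.all(nodesC <= 0, axis=1)
    for i in range(nodesB.shape[0]):
        conflict = fusion_conflict(probB[i], probC[i])
        post = bayes_fuse(probB[i], probC[i], prior)
        res = decide(post, alphabet, threshold)
        res.sample_id = ids[i] if ids is not None else None
        res.conflict = bool(conflict)
        res.degenerate = bool(degenerate_b[i] or degenerate_c[i])
        results.append(res)
    return FusionReport(results, alphabet, threshold)


@dataclass
class BlockScaler:
    """Per-column autoscaling of concatenation blocks, fit on calibration.

    NIR absorbance and Raman counts live on incommensurate scales; each
    block is autoscaled column-wise (calibration mean/SD, constant columns
    get unit SD) before concatenation so neither dominates the PLS fit.
    """

    means: list[np.ndarray] = field(default_factory=list)
    sds: list[np.ndarray] = field(default_factory=list)

    def fit(self, blocks: list[np.ndarray]) -> "BlockScaler":
        self.means, self.sds = [], []
        for B in blocks:
            B = np.asarray(B, dtype=float)
            sd = B.std(axis=0, ddof=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            self.means.append(B.mean(axis=0))
            self.sds.append(sd)
        return self

    def transform(self, blocks: list[np.ndarray]) -> np.ndarray:
        if len(blocks) != len(self.means):
            raise AlignmentError("block count differs from fitted state")
        out = []
        n = np.asarray(blocks[0]).shape[0]
        for B, mu, sd in zip(blocks, self.means, self.sds):
            B = np.asarray(B, dtype=float)
            if B.shape[0] != n:
                raise AlignmentError("blocks differ in row count")
            out.append((B - mu) / sd)
        return np.hstack(out)


def concat_fuse(
    block_a: np.ndarray,
    block_b: np.ndarray,
    scaler: BlockScaler | None = None,
) -> tuple[np.ndarray, BlockScaler]:
    """Concatenate two row-aligned blocks after per-block autoscaling.

    Used for both data-layer fusion (full preprocessed grids) and
    feature-layer fusion (per-modality selected variables); the fused
    matrix feeds a single PLS-DA.  Pass a fitted ``scaler`` to transform
    prediction rows with frozen calibration statistics.
    """
    blocks = [np.asarray(block_a, float), np.asarray(block_b, float)]
    if blocks[0].shape[0] != blocks[1].shape[0]:
        raise AlignmentError(
            f"row misalignment: {blocks[0].shape[0]} vs {blocks[1].shape[0]}"
        )
    if scaler is None:
        scaler = BlockScaler().fit(blocks)
    return scaler.transform(blocks), scaler
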