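"""Spectra containers and CSV I/O.

A :class:`SpectraMatrix` is the package's in-memory spectral table: an
``n_samples x n_wavenumbers`` intensity matrix with a strictly increasing
wavenumber grid (cm^-1), per-row sample ids and class labels.  The on-disk
format is a plain CSV whose first two columns are ``sample_id`` and
``label`` and whose remaining column headers are the wavenumbers.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    FormatError,
    LabelError,
    ParseError,
    RangeError,
    SplitError,
)

#: The eight codfish identities of the study design: Atlantic cod from
#: Denmark / Iceland / Norway / Russia, haddock from Iceland, Pacific cod
#: from Russia, and pollock from Russia / America.
DEFAULT_CLASSES: tuple[str, ...] = (
    "ACD", "ACI", "ACN", "ACR", "HDI", "PCR", "PR", "PA",
)


@dataclass(frozen=True)
class ClassAlphabet:
    """Ordered, unique class codes; position in ``names`` is the node index."""

    names: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise LabelError(f"class names are not unique: {self.names}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise LabelError(f"label {name!r} not in alphabet {self.names}") from None

    def validate(self, labels: Iterable[str]) -> None:
        bad = sorted({l for l in labels if l not in self.names})
        if bad:
            raise LabelError(f"labels {bad} not in alphabet {self.names}")


@dataclass
class SpectraMatrix:
    """Samples x wavenumbers intensity table with labels and grid metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray
    modality: str = "NIR"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.wavenumbers.ndim != 1:
            raise FormatError("wavenumbers must be a vector")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise FormatError("wavenumbers must be strictly increasing")
        n, p = self.intensities.shape
        if p != self.wavenumbers.size:
            raise FormatError(
                f"{p} intensity columns but {self.wavenumbers.size} wavenumbers"
            )
        if len(self.sample_ids) != n or self.labels.size != n:
            raise FormatError("sample_ids/labels length must match row count")
        if not np.all(np.isfinite(self.intensities)):
            raise ParseError("intensities contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.intensities.shape[1]

    def with_intensities(self, X: np.ndarray) -> "SpectraMatrix":
        """Copy with a new intensity matrix over the same grid and samples."""
        return replace(self, intensities=np.asarray(X, dtype=float))

    def select_columns(self, idx: Sequence[int]) -> "SpectraMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            wavenumbers=self.wavenumbers[idx],
            intensities=self.intensities[:, idx],
        )

    def subset(self, ids: Sequence[str]) -> "SpectraMatrix":
        """Rows for the given sample ids, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise FormatError(f"unknown sample ids: {missing[:5]}")
        rows = [pos[s] for s in ids]
        return replace(
            self,
            intensities=self.intensities[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            labels=self.labels[rows],
        )


def _format_wavenumber(w: float) -> str:
    # up to 4 decimal places, no trailing zeros
    s = f"{w:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


def read_spectra_csv(
    path,
    label_column: str = "label",
    alphabet: ClassAlphabet | None = None,
    modality: str = "NIR",
) -> SpectraMatrix:
    """Read a spectra CSV (``sample_id``, label column, wavenumber columns).

    The wavenumber grid is sorted ascending on read, permuting intensity
    columns consistently.  Raises :class:`ParseError` naming the offending
    row and column on non-numeric cells, :class:`FormatError` on duplicate
    wavenumber headers, and :class:`LabelError` when an ``alphabet`` is
    supplied and a label falls outside it.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_header = fh.readline().rstrip("\r\n").split(",")
    if len(raw_header) != len(set(raw_header)):
        seen, dup = set(), None
        for c in raw_header:
            if c in seen:
                dup = c
                break
            seen.add(c)
        raise FormatError(f"duplicate wavenumber header {dup!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise FormatError("spectra CSV needs sample_id, label and >=1 wavenumber")
    id_col = df.columns[0]
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found")
    wn_cols = [c for c in df.columns if c not in (id_col, label_column)]
    try:
        wns = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from None
    if np.unique(wns).size != wns.size:
        dup = wns[np.where(np.diff(np.sort(wns)) == 0)[0][0]] if wns.size else None
        raise FormatError(f"duplicate wavenumber header near {dup}")

    X = np.empty((len(df), len(wn_cols)), dtype=float)
    for j, c in enumerate(wn_cols):
        try:
            # numpy's str->float conversion is correctly rounded, so the
            # writer's repr payload round-trips bit-identically
            X[:, j] = df[c].to_numpy(dtype=object).astype(np.float64)
        except (ValueError, TypeError):
            bad = 0
            for i, v in enumerate(df[c]):
                try:
                    float(v)
                except ValueError:
                    bad = i
                    break
            raise ParseError(
                f"non-numeric cell at row {bad} (sample "
                f"{df[id_col].iloc[bad]!r}), column {c!r}"
            ) from None

    order = np.argsort(wns, kind="stable")
    labels = df[label_column].to_numpy(dtype=object)
    if alphabet is not None:
        alphabet.validate(labels)
    return SpectraMatrix(
        wavenumbers=wns[order],
        intensities=X[:, order],
        sample_ids=df[id_col].tolist(),
        labels=labels,
        modality=modality,
    )


def write_spectra_csv(m: SpectraMatrix, path, label_column: str = "label") -> None:
    """Write a spectra CSV that round-trips bit-identically through the reader.

    Intensities are written with ``repr`` (shortest float round-trip), so
    ``write(read(f))`` reproduces the numeric payload exactly.
    """
    buf = _stdio.StringIO()
    header = ["sample_id", label_column] + [
        _format_wavenumber(w) for w in m.wavenumbers
    ]
    buf.write(",".join(header) + "\n")
    for i in range(m.n_samples):
        row = [m.sample_ids[i], str(m.labels[i])]
        row.extend(repr(float(v)) for v in m.intensities[i])
        buf.write(",".join(row) + "\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def crop_range(m: SpectraMatrix, lo: float, hi: float) -> SpectraMatrix:
    """Keep exactly the columns with ``lo <= w <= hi`` (closed interval)."""
    if not lo < hi:
        raise RangeError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (m.wavenumbers >= lo) & (m.wavenumbers <= hi)
    if not mask.any():
        raise RangeError(f"no wavenumbers in [{lo}, {hi}]")
    return m.select_columns(np.where(mask)[0])


def average_replicates(
    m: SpectraMatrix, replicate_key: Mapping[str, str]
) -> SpectraMatrix:
    """Arithmetic per-column mean of replicate scans, one row per group.

    ``replicate_key`` maps each sample id to its group id.  Groups appear in
    order of first appearance; replicates of a group must share one label.
    """
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(m.sample_ids):
        g = replicate_key.get(sid, sid)
        groups.setdefault(g, []).append(i)
    ids, labels, rows = [], [], []
    for g, idx in groups.items():
        glabels = {m.labels[i] for i in idx}
        if len(glabels) > 1:
            raise ConsistencyError(
                f"replicate group {g!r} mixes labels {sorted(map(str, glabels))}"
            )
        ids.append(g)
        labels.append(next(iter(glabels)))
        rows.append(m.intensities[idx].mean(axis=0))
    return replace(
        m,
        intensities=np.vstack(rows),
        sample_ids=ids,
        labels=np.asarray(labels, dtype=object),
    )


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint calibration/prediction sample-id sets covering all samples."""

    calibration_ids: tuple[str, ...]
    prediction_ids: tuple[str, ...]
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, "cal") for s in self.calibration_ids]
        rows += [(s, "pred") for s in self.prediction_ids]
        return pd.DataFrame(rows, columns=["sample_id", "set"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "SplitAssignment":
        df = pd.read_csv(path, dtype=str)
        cal = tuple(df.loc[df["set"] == "cal", "sample_id"])
        pred = tuple(df.loc[df["set"] == "pred", "sample_id"])
        return cls(cal, pred, seed)


def stratified_split(
    m: SpectraMatrix, fraction: float = 0.75, seed: int = 0
) -> SplitAssignment:
    """Random per-class split into calibration/prediction sets.

    Per class, ``round(fraction * class_size)`` samples (ties resolved
    downward) go to calibration, clamped so both sets keep every class.
    Deterministic for a fixed seed: 0.75 on 40-sample classes gives the
    study's 30/10 per class, 240/80 overall.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for sid, lab in zip(m.sample_ids, m.labels):
        by_class.setdefault(str(lab), []).append(sid)
    cal: list[str] = []
    pred: list[str] = []
    for lab in sorted(by_class):
        ids = by_class[lab]
        if len(ids) < 2:
            raise SplitError(f"class {lab!r} has a single sample; cannot split")
        n_cal = int(np.ceil(fraction * len(ids) - 0.5))  # round half down
        n_cal = min(max(n_cal, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        cal.extend(ids[i] for i in perm[:n_cal])
        pred.extend(ids[i] for i in perm[n_cal:])
    id_order = {s: i for i, s in enumerate(m.sample_ids)}
    cal.sort(key=id_order.__getitem__)
    pred.sort(key=id_order.__getitem__)
    return SplitAssignment(tuple(cal), tuple(pred), seed)
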