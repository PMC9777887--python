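"""Dual-modality synthetic spectra with controllable complementarity.

The generator emulates the statistical structure the pipeline assumes:
two co-registered modalities on fixed grids (NIR-like 4000-9000 cm^-1,
2593 points; Raman-like 1000-2000 cm^-1, 669 points), eight classes of 40
samples measured in three replicate scans.  Each spectrum is a sum of
Gaussian peaks (a shared backbone at recognizable NIR/Raman band
positions plus class-specific peaks), corrupted by within-class peak
amplitude jitter, a low-order polynomial baseline, per-sample affine
scatter (a*x + b with a near 1) and i.i.d. noise; replicates share all
sample-level effects and differ by noise only.

Complementarity plants the property decision-level fusion exploits:
classes are paired, and a configured fraction of pairs share identical
peak libraries in one modality (indistinguishable there) while remaining
distinct in the other, alternating which modality is blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SpecfuseError
from .io import DEFAULT_CLASSES, ClassAlphabet, SpectraMatrix, average_replicates
from .preprocessing import snv

_BASE_PEAKS_NIR = (
    (5145.0, 150.0, 0.90),  # O-H first overtone (water)
    (6920.0, 180.0, 1.00),  # O-H second overtone (water)
    (8387.0, 120.0, 0.35),  # C-H second overtone (fat)
    (4500.0, 100.0, 0.50),  # N-H combination (protein)
    (5994.0, 90.0, 0.30),
    (7309.0, 110.0, 0.25),
)
_BASE_PEAKS_RAMAN = (
    (1004.0, 8.0, 1.00),   # phenylalanine ring
    (1262.0, 12.0, 0.50),  # amide III
    (1306.0, 14.0, 0.45),
    (1443.0, 16.0, 0.80),  # CH2 scissoring
    (1662.0, 18.0, 0.70),  # amide I
    (1750.0, 12.0, 0.25),  # C=O stretch
)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the study design (8 classes x
    40 samples x 3 replicate scans on the full grids)."""

    n_classes: int = 8
    samples_per_class: int = 40
    replicates_per_sample: int = 3
    nir_grid: tuple[float, float, int] = (4000.0, 9000.0, 2593)
    raman_grid: tuple[float, float, int] = (1000.0, 2000.0, 669)
    n_class_peaks: int = 3
    class_peak_amplitude: tuple[float, float] = (0.15, 0.45)
    nir_peak_width: tuple[float, float] = (30.0, 120.0)
    raman_peak_width: tuple[float, float] = (6.0, 25.0)
    amplitude_jitter_sd: float = 0.10
    scatter_slope_sd: float = 0.10
    scatter_offset_sd: float = 0.02
    baseline_degree: int = 2
    baseline_coeff_sd: float = 0.05
    noise_sd: float = 0.02
    complementarity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.complementarity <= 1.0:
            raise SpecfuseError("complementarity must be in [0, 1]")
        if self.complementarity > 0 and self.n_classes < 4:
            raise SpecfuseError(
                "complementarity needs >= 4 classes (two pairs, one blind "
                "per modality)"
            )
        if self.n_classes < 2:
            raise SpecfuseError("need at least 2 classes")

    @property
    def alphabet(self) -> ClassAlphabet:
        if self.n_classes == len(DEFAULT_CLASSES):
            return ClassAlphabet()
        return ClassAlphabet(tuple(f"C{i + 1}" for i in range(self.n_classes)))

    def grid(self, modality: str) -> np.ndarray:
        lo, hi, n = self.nir_grid if modality == "NIR" else self.raman_grid
        return np.linspace(lo, hi, int(n))


@dataclass
class PeakLibrary:
    """Per-class peak parameters for one modality."""

    centers: list[np.ndarray]
    widths: list[np.ndarray]
    amplitudes: list[np.ndarray]

    def template(self, cls: int, grid: np.ndarray) -> np.ndarray:
        G = _gauss_basis(self.centers[cls], self.widths[cls], grid)
        return self.amplitudes[cls] @ G


def _gauss_basis(centers: np.ndarray, widths: np.ndarray, grid: np.ndarray
                 ) -> np.ndarray:
    z = (grid[None, :] - centers[:, None]) / widths[:, None]
    return np.exp(-0.5 * z * z)


def _draw_libraries(cfg: SyntheticConfig, rng: np.random.Generator
                    ) -> tuple[PeakLibrary, PeakLibrary]:
    """Class peak libraries with the complementary blind-pair structure."""
    libs = {}
    for modality, base, wrange in (
        ("NIR", _BASE_PEAKS_NIR, cfg.nir_peak_width),
        ("RAMAN", _BASE_PEAKS_RAMAN, cfg.raman_peak_width),
    ):
        lo, hi, _ = cfg.nir_grid if modality == "NIR" else cfg.raman_grid
        span = hi - lo
        b_c = np.array([p[0] for p in base])
        b_w = np.array([p[1] for p in base])
        b_a = np.array([p[2] for p in base])
        centers, widths, amps = [], [], []
        for _cls in range(cfg.n_classes):
            c = rng.uniform(lo + 0.05 * span, hi - 0.05 * span, cfg.n_class_peaks)
            w = rng.uniform(*wrange, cfg.n_class_peaks)
            a = rng.uniform(*cfg.class_peak_amplitude, cfg.n_class_peaks)
            centers.append(np.concatenate([b_c, c]))
            widths.append(np.concatenate([b_w, w]))
            amps.append(np.concatenate([b_a, a]))
        libs[modality] = PeakLibrary(centers, widths, amps)

    # blind pairs: (0,1), (2,3), ... — even-indexed pairs are NIR-blind
    # (identical NIR library within the pair), odd-indexed Raman-blind.
    n_pairs = cfg.n_classes // 2
    n_blind = int(round(cfg.complementarity * n_pairs))
    for t in range(n_blind):
        i, j = 2 * t, 2 * t + 1
        blind = "NIR" if t % 2 == 0 else "RAMAN"
        lib = libs[blind]
        lib.centers[j] = lib.centers[i].copy()
        lib.widths[j] = lib.widths[i].copy()
        lib.amplitudes[j] = lib.amplitudes[i].copy()
    return libs["NIR"], libs["RAMAN"]


def blind_pairs(cfg: SyntheticConfig) -> list[tuple[int, int, str]]:
    """(class_i, class_j, blind_modality) triples implied by the config."""
    n_pairs = cfg.n_classes // 2
    n_blind = int(round(cfg.complementarity * n_pairs))
    return [
        (2 * t, 2 * t + 1, "NIR" if t % 2 == 0 else "RAMAN")
        for t in range(n_blind)
    ]


def class_templates(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless class templates, shape (n_classes, n_points) per modality."""
    rng = np.random.default_rng(cfg.seed)
    nir_lib, raman_lib = _draw_libraries(cfg, rng)
    nir = np.vstack([nir_lib.template(c, cfg.grid("NIR"))
                     for c in range(cfg.n_classes)])
    raman = np.vstack([raman_lib.template(c, cfg.grid("RAMAN"))
                       for c in range(cfg.n_classes)])
    return nir, raman


@dataclass
class SyntheticDataset:
    """Replicate-level spectra plus the replicate->sample map."""

    nir: SpectraMatrix
    raman: SpectraMatrix
    replicate_map: dict[str, str]
    config: SyntheticConfig

    def averaged(self) -> tuple[SpectraMatrix, SpectraMatrix]:
        return (
            average_replicates(self.nir, self.replicate_map),
            average_replicates(self.raman, self.replicate_map),
        )


def _simulate_modality(
    cfg: SyntheticConfig,
    lib: PeakLibrary,
    grid: np.ndarray,
    labels_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicate-level intensity matrix for one modality."""
    n = labels_idx.size
    reps = cfg.replicates_per_sample
    p = grid.size
    t = np.linspace(0.0, 1.0, p)
    vander = np.vander(t, cfg.baseline_degree + 1, increasing=True)  # p x (d+1)
    out = np.empty((n * reps, p))
    for cls in range(cfg.n_classes):
        rows = np.where(labels_idx == cls)[0]
        if rows.size == 0:
            continue
        G = _gauss_basis(lib.centers[cls], lib.widths[cls], grid)
        amp = lib.amplitudes[cls]
        jitter = 1.0 + cfg.amplitude_jitter_sd * rng.standard_normal(
            (rows.size, amp.size)
        )
        clean = np.clip(jitter * amp, 0.0, None) @ G
        coeffs = cfg.baseline_coeff_sd * rng.standard_normal(
            (rows.size, cfg.baseline_degree + 1)
        )
        baseline = coeffs @ vander.T
        slope = 1.0 + cfg.scatter_slope_sd * rng.standard_normal((rows.size, 1))
        offset = cfg.scatter_offset_sd * rng.standard_normal((rows.size, 1))
        signal = slope * clean + baseline + offset
        noise = cfg.noise_sd * rng.standard_normal((rows.size, reps, p))
        block = signal[:, None, :] + noise
        for r_local, r_global in enumerate(rows):
            out[r_global * reps:(r_global + 1) * reps] = block[r_local]
    return out


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Replicate-level dual-modality dataset under one seeded stream.

    With the default config, averaging replicates yields matrices of
    320 x 2593 (NIR) and 320 x 669 (Raman).  Same seed, same bytes.
    """
    rng = np.random.default_rng(cfg.seed)
    nir_lib, raman_lib = _draw_libraries(cfg, rng)
    alphabet = cfg.alphabet
    n = cfg.n_classes * cfg.samples_per_class
    labels_idx = np.repeat(np.arange(cfg.n_classes), cfg.samples_per_class)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    labels = np.asarray([alphabet.names[i] for i in labels_idx], dtype=object)

    X_nir = _simulate_modality(cfg, nir_lib, cfg.grid("NIR"), labels_idx, rng)
    X_raman = _simulate_modality(cfg, raman_lib, cfg.grid("RAMAN"), labels_idx, rng)

    reps = cfg.replicates_per_sample
    rep_ids = [f"{sid}_r{r + 1}" for sid in sample_ids for r in range(reps)]
    rep_labels = np.repeat(labels, reps)
    rep_map = {f"{sid}_r{r + 1}": sid for sid in sample_ids for r in range(reps)}
    nir = SpectraMatrix(cfg.grid("NIR"), X_nir, rep_ids, rep_labels, "NIR")
    raman = SpectraMatrix(cfg.grid("RAMAN"), X_raman, rep_ids, rep_labels, "RAMAN")
    return SyntheticDataset(nir, raman, rep_map, cfg)


def generate_averaged(cfg: SyntheticConfig
                      ) -> tuple[SpectraMatrix, SpectraMatrix]:
    """Replicate-averaged dataset (one row per physical sample)."""
    return generate(cfg).averaged()


def oracle_bayes_error(
    cfg: SyntheticConfig, n_draws: int = 2000, seed: int | None = None
) -> dict[str, float]:
    """Monte-Carlo nearest-template accuracies under the generative model.

    Fresh samples are drawn from the model, SNV-corrected (neutralizing
    the affine scatter) and classified by the nearest SNV-corrected class
    template; the fused channel concatenates both modalities with each
    block weighted by 1/sqrt(n_points).  These are upper-bound style
    references used to calibrate pipeline expectations; they bound what a
    classifier can see, not what PLS-DA achieves.
    """
    import dataclasses

    per_class = max(2, int(np.ceil(n_draws / cfg.n_classes)))
    draw_cfg = dataclasses.replace(
        cfg, samples_per_class=per_class, replicates_per_sample=1)
    # class structure (peak libraries) always follows cfg.seed; only the
    # Monte-Carlo sampling stream varies with the oracle seed
    lib_rng = np.random.default_rng(cfg.seed)
    nir_lib, raman_lib = _draw_libraries(cfg, lib_rng)
    sample_rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels_idx = np.repeat(np.arange(cfg.n_classes), per_class)
    X_nir = _simulate_modality(draw_cfg, nir_lib, cfg.grid("NIR"),
                               labels_idx, sample_rng)
    X_raman = _simulate_modality(draw_cfg, raman_lib, cfg.grid("RAMAN"),
                                 labels_idx, sample_rng)
    t_nir, t_raman = class_templates(cfg)

    def _sqdist(Z: np.ndarray, T: np.ndarray) -> np.ndarray:
        return (
            (Z * Z).sum(axis=1)[:, None]
            + (T * T).sum(axis=1)[None, :]
            - 2.0 * Z @ T.T
        )

    def _acc(X: np.ndarray, T: np.ndarray, truth: np.ndarray) -> float:
        d2 = _sqdist(snv(X), snv(T))
        return float(np.mean(np.argmin(d2, axis=1) == truth))

    truth = labels_idx
    acc_nir = _acc(X_nir, t_nir, truth)
    acc_raman = _acc(X_raman, t_raman, truth)

    zn = snv(X_nir) / np.sqrt(t_nir.shape[1])
    zr = snv(X_raman) / np.sqrt(t_raman.shape[1])
    tn = snv(t_nir) / np.sqrt(t_nir.shape[1])
    tr = snv(t_raman) / np.sqrt(t_raman.shape[1])
    Z = np.hstack([zn, zr])
    T = np.hstack([tn, tr])
    acc_fused = float(np.mean(np.argmin(_sqdist(Z, T), axis=1) == truth))
    return {"nir": acc_nir, "raman": acc_raman, "fused": acc_fused}
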