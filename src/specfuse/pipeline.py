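"""End-to-end workflow: split, preprocess, select, fit, CV, predict, fuse.

The top-level surface follows the model/results idiom: build a
:class:`DualSpectraFusion` from two replicate-averaged
:class:`~specfuse.io.SpectraMatrix` objects (or a synthetic config), call
``fit()``, and read the five comparator models' performance off the
returned :class:`FusionResults`:

* ``NIRS`` — single-modality PLS-DA on the (optionally selected) NIR grid
* ``RS`` — single-modality PLS-DA on the Raman grid
* ``NIRS-RS-D`` — data-layer fusion (full preprocessed grids concatenated)
* ``NIRS-RS-F`` — feature-layer fusion (selected variables concatenated)
* ``NIRS-RS-B`` — Bayesian decision fusion of the two single models

Every stochastic stage draws a named sub-seed from the master seed, so a
rerun with the same config and seed reproduces all numeric outputs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import evaluation, fusion, plsda, preprocessing, selection
from .exceptions import AlignmentError, SpecfuseError
from .io import (
    ClassAlphabet,
    SpectraMatrix,
    SplitAssignment,
    read_spectra_csv,
    stratified_split,
)
from .synthetic import SyntheticConfig, generate_averaged

DEFAULT_NIR_PREPROCESS = ({"method": "snv"}, {"method": "mc"})
DEFAULT_RAMAN_PREPROCESS = ({"method": "ba"}, {"method": "nor"})


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the reference workflow (SNV then
    MC for NIR, BA then NOR for Raman, IRIV-selected NIR features fused
    with the full-grid Raman model)."""

    simulate: SyntheticConfig | None = None
    nir_csv: str | None = None
    raman_csv: str | None = None
    nir_preprocess: tuple = DEFAULT_NIR_PREPROCESS
    raman_preprocess: tuple = DEFAULT_RAMAN_PREPROCESS
    nir_selection: str = "iriv"
    raman_selection: str = "none"
    selection_params: dict[str, dict[str, Any]] = field(default_factory=dict)
    n_lv: int | str = "cv"
    max_lv: int = 15
    cv_folds: int = 10
    threshold: float = 0.01
    fraction: float = 0.75
    modes: tuple[str, ...] = ("bayes", "feature", "data")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulate")
        if isinstance(sim, dict):
            for key in ("nir_grid", "raman_grid", "class_peak_amplitude",
                        "nir_peak_width", "raman_peak_width"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["simulate"] = SyntheticConfig(**sim)
        for key in ("nir_preprocess", "raman_preprocess", "modes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subseeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    names = ("split", "folds", "lv", "select_nir", "select_raman")
    return {n: int(s) for n, s in zip(names, rng.integers(0, 2**31 - 1, len(names)))}


@dataclass
class ModalityState:
    """Frozen per-modality artifacts of a fitted pipeline."""

    name: str
    pipeline: preprocessing.PreprocessPipeline
    selection: selection.SelectionResult | None
    selected: np.ndarray
    cal_features: np.ndarray
    pred_features: np.ndarray
    cal_full: np.ndarray
    pred_full: np.ndarray
    wavenumbers: np.ndarray


class DualSpectraFusion:
    """Dual-modality PLS-DA classifier with Bayesian decision fusion.

    Parameters
    ----------
    nir, raman : SpectraMatrix
        Replicate-averaged spectra of the same samples (aligned ids).
    config : RunConfig, optional
        Workflow settings; the master seed lives here.
    """

    def __init__(self, nir: SpectraMatrix, raman: SpectraMatrix,
                 config: RunConfig | None = None,
                 alphabet: ClassAlphabet | None = None):
        if nir.sample_ids != raman.sample_ids:
            raise AlignmentError("NIR and Raman sample ids are not aligned")
        if list(nir.labels) != list(raman.labels):
            raise AlignmentError("NIR and Raman labels disagree")
        self.nir = nir
        self.raman = raman
        self.config = config or RunConfig()
        names = tuple(sorted(set(map(str, nir.labels)),
                             key=list(map(str, nir.labels)).index))
        default = ClassAlphabet() if set(names) == set(ClassAlphabet().names) \
            else ClassAlphabet(tuple(sorted(names)))
        self.alphabet = alphabet or default

    @classmethod
    def from_simulation(cls, config: RunConfig) -> "DualSpectraFusion":
        sim = config.simulate or SyntheticConfig(seed=config.seed)
        if config.simulate is None:
            config = dataclasses.replace(config, simulate=sim)
        nir, raman = generate_averaged(sim)
        return cls(nir, raman, config, sim.alphabet)

    @classmethod
    def from_csv(cls, nir_path, raman_path, config: RunConfig | None = None,
                 alphabet: ClassAlphabet | None = None) -> "DualSpectraFusion":
        nir = read_spectra_csv(nir_path, alphabet=alphabet, modality="NIR")
        raman = read_spectra_csv(raman_path, alphabet=alphabet, modality="RAMAN")
        return cls(nir, raman, config, alphabet)

    # ------------------------------------------------------------------

    def _select(self, method: str, X: np.ndarray, coding: plsda.NodeCoding,
                labels: np.ndarray, wavenumbers: np.ndarray, seed: int
                ) -> selection.SelectionResult | None:
        method = (method or "none").lower()
        params = dict(self.config.selection_params.get(method, {}))
        if method == "none":
            return None
        if method == "cars":
            cfg = selection.CarsConfig(**params) if params else selection.CarsConfig()
            return selection.cars_select(X, coding, cfg, seed, wavenumbers)
        if method == "iriv":
            return selection.iriv_select(X, coding, seed,
                                         wavenumbers=wavenumbers, **params)
        if method == "spa":
            params.setdefault("max_vars", min(9, X.shape[0] - 1, X.shape[1]))
            return selection.spa_select(X, labels, self.alphabet,
                                        seed=seed, wavenumbers=wavenumbers, **params)
        raise SpecfuseError(f"unknown selection method {method!r}")

    def _choose_n_lv(self, X: np.ndarray, coding: plsda.NodeCoding,
                     seed: int) -> int:
        if isinstance(self.config.n_lv, int):
            return min(self.config.n_lv, X.shape[1], X.shape[0] - 1)
        return plsda.choose_n_lv(X, coding, self.config.max_lv,
                                 self.config.cv_folds, seed)

    def _cv_nodes(self, cal_raw: SpectraMatrix, pipe, selected, coding,
                  n_lv, seed) -> np.ndarray:
        cv = plsda.cross_validate(
            cal_raw.intensities, coding, n_lv, self.config.cv_folds, seed,
            preprocess=pipe.clone_unfitted(), wavenumbers=cal_raw.wavenumbers,
            selected_indices=selected,
        )
        return cv.nodes

    def _cv_nodes_fused(self, cal_nir: SpectraMatrix, cal_raman: SpectraMatrix,
                        sel_nir, sel_raman, coding, n_lv, seed) -> np.ndarray:
        """Out-of-fold nodes for a concatenation model, refitting both
        preprocessing pipelines and the block scaler inside each fold."""
        labels = plsda.decode_coding(coding)
        oof = np.full((cal_nir.n_samples, len(self.alphabet)), np.nan)
        for tr, va in plsda._stratified_folds(labels, self.config.cv_folds, seed):
            pn = preprocessing.PreprocessPipeline.from_config(
                self.config.nir_preprocess)
            pr = preprocessing.PreprocessPipeline.from_config(
                self.config.raman_preprocess)
            zn_tr = pn.fit_transform(cal_nir.intensities[tr], cal_nir.wavenumbers)
            zr_tr = pr.fit_transform(cal_raman.intensities[tr], cal_raman.wavenumbers)
            zn_va = pn.transform(cal_nir.intensities[va])
            zr_va = pr.transform(cal_raman.intensities[va])
            if sel_nir is not None:
                zn_tr, zn_va = zn_tr[:, sel_nir], zn_va[:, sel_nir]
            if sel_raman is not None:
                zr_tr, zr_va = zr_tr[:, sel_raman], zr_va[:, sel_raman]
            Xtr, scaler = fusion.concat_fuse(zn_tr, zr_tr)
            Xva, _ = fusion.concat_fuse(zn_va, zr_va, scaler)
            nc = min(n_lv, Xtr.shape[0] - 1, Xtr.shape[1])
            model = plsda.fit_plsda(
                Xtr, plsda.NodeCoding(self.alphabet, coding.matrix[tr]), nc)
            oof[va] = model.predict_nodes(Xva)
        return oof

    # ------------------------------------------------------------------

    def fit(self) -> "FusionResults":
        cfg = self.config
        seeds = _subseeds(cfg.seed)
        t0 = time.perf_counter()
        log: list[str] = []

        split = stratified_split(self.nir, cfg.fraction, seeds["split"])
        cal_ids, pred_ids = list(split.calibration_ids), list(split.prediction_ids)
        log.append(f"split: {len(cal_ids)} calibration / {len(pred_ids)} prediction")

        states: dict[str, ModalityState] = {}
        for name, m, pp_cfg, sel_method, sel_seed in (
            ("NIR", self.nir, cfg.nir_preprocess, cfg.nir_selection,
             seeds["select_nir"]),
            ("RAMAN", self.raman, cfg.raman_preprocess, cfg.raman_selection,
             seeds["select_raman"]),
        ):
            cal, pred = m.subset(cal_ids), m.subset(pred_ids)
            pipe = preprocessing.PreprocessPipeline.from_config(pp_cfg)
            z_cal = pipe.fit_transform(cal.intensities, cal.wavenumbers)
            z_pred = pipe.transform(pred.intensities)
            coding = plsda.encode_labels(cal.labels, self.alphabet)
            sel = self._select(sel_method, z_cal, coding, cal.labels,
                               cal.wavenumbers, sel_seed)
            idx = (np.arange(z_cal.shape[1]) if sel is None
                   else sel.selected_indices)
            states[name] = ModalityState(
                name, pipe, sel, idx, z_cal[:, idx], z_pred[:, idx],
                z_cal, z_pred, cal.wavenumbers,
            )
            log.append(
                f"{name}: {z_cal.shape[1]} variables -> {idx.size} selected "
                f"({sel_method or 'none'})"
            )

        cal_nir, pred_nir = self.nir.subset(cal_ids), self.nir.subset(pred_ids)
        cal_raman = self.raman.subset(cal_ids)
        cal_labels = cal_nir.labels
        pred_labels = pred_nir.labels
        coding = plsda.encode_labels(cal_labels, self.alphabet)

        node_sets: dict[str, dict[str, np.ndarray]] = {}
        models: dict[str, plsda.PlsdaModel] = {}
        n_lvs: dict[str, int] = {}

        # --- two single-modality models ---------------------------------
        for label, state, raw_cal in (
            ("NIRS", states["NIR"], cal_nir),
            ("RS", states["RAMAN"], cal_raman),
        ):
            n_lv = self._choose_n_lv(state.cal_features, coding, seeds["lv"])
            model = plsda.fit_plsda(state.cal_features, coding, n_lv)
            node_sets[label] = {
                "calibration": model.predict_nodes(state.cal_features),
                "cv": self._cv_nodes(raw_cal, state.pipeline, state.selected,
                                     coding, n_lv, seeds["folds"]),
                "prediction": model.predict_nodes(state.pred_features),
            }
            models[label] = model
            n_lvs[label] = n_lv
            log.append(f"{label}: n_lv={n_lv}")

        # --- concatenation comparators -----------------------------------
        concat_specs = {}
        if "data" in cfg.modes:
            concat_specs["NIRS-RS-D"] = (None, None, "full")
        if "feature" in cfg.modes:
            concat_specs["NIRS-RS-F"] = (
                states["NIR"].selected, states["RAMAN"].selected, "selected")
        for label, (sn, sr, kind) in concat_specs.items():
            if kind == "full":
                blocks_cal = (states["NIR"].cal_full, states["RAMAN"].cal_full)
                blocks_pred = (states["NIR"].pred_full, states["RAMAN"].pred_full)
            else:
                blocks_cal = (states["NIR"].cal_features,
                              states["RAMAN"].cal_features)
                blocks_pred = (states["NIR"].pred_features,
                               states["RAMAN"].pred_features)
            X_cal, scaler = fusion.concat_fuse(*blocks_cal)
            X_pred, _ = fusion.concat_fuse(*blocks_pred, scaler=scaler)
            n_lv = self._choose_n_lv(X_cal, coding, seeds["lv"])
            model = plsda.fit_plsda(X_cal, coding, n_lv)
            node_sets[label] = {
                "calibration": model.predict_nodes(X_cal),
                "cv": self._cv_nodes_fused(cal_nir, cal_raman, sn, sr,
                                           coding, n_lv, seeds["folds"]),
                "prediction": model.predict_nodes(X_pred),
            }
            models[label] = model
            n_lvs[label] = n_lv
            log.append(f"{label}: {X_cal.shape[1]} fused variables, n_lv={n_lv}")

        # --- Bayesian decision fusion ------------------------------------
        fusion_reports: dict[str, fusion.FusionReport] = {}
        if "bayes" in cfg.modes:
            for part in ("calibration", "cv", "prediction"):
                fusion_reports[part] = fusion.fuse_dataset(
                    node_sets["NIRS"][part], node_sets["RS"][part],
                    self.alphabet, cfg.threshold,
                )

        # --- evaluation ---------------------------------------------------
        reports: list[evaluation.PerformanceReport] = []
        truth = {"calibration": cal_labels, "cv": cal_labels,
                 "prediction": pred_labels}
        for label in [l for l in ("NIRS", "RS", "NIRS-RS-D", "NIRS-RS-F")
                      if l in node_sets]:
            rep = evaluation.PerformanceReport(label)
            for part, nodes in node_sets[label].items():
                assigned = plsda.assign_classes(nodes, self.alphabet)
                rep.add(part, evaluation.confusion(truth[part], assigned,
                                                   self.alphabet))
            reports.append(rep)
        if fusion_reports:
            rep = evaluation.PerformanceReport("NIRS-RS-B")
            for part, frep in fusion_reports.items():
                rep.add(part, evaluation.confusion(truth[part], frep.assigned,
                                                   self.alphabet))
            reports.append(rep)

        log.append(f"total {time.perf_counter() - t0:.1f}s")
        return FusionResults(
            model=self, config=cfg, split=split, states=states,
            plsda_models=models, n_lvs=n_lvs, node_sets=node_sets,
            fusion_reports=fusion_reports, reports=reports,
            cal_labels=cal_labels, pred_labels=pred_labels, log=log,
        )


@dataclass
class FusionResults:
    """Everything a fitted run produced: models, selections, out-of-fold
    node values, fusion outcomes and the five-model performance table."""

    model: DualSpectraFusion
    config: RunConfig
    split: SplitAssignment
    states: dict[str, ModalityState]
    plsda_models: dict[str, plsda.PlsdaModel]
    n_lvs: dict[str, int]
    node_sets: dict[str, dict[str, np.ndarray]]
    fusion_reports: dict[str, fusion.FusionReport]
    reports: list[evaluation.PerformanceReport]
    cal_labels: np.ndarray
    pred_labels: np.ndarray
    log: list[str]

    @property
    def table(self) -> pd.DataFrame:
        return evaluation.report_table(self.reports)

    def report(self, name: str) -> evaluation.PerformanceReport:
        for r in self.reports:
            if r.model_name == name:
                return r
        raise KeyError(name)

    def summary(self) -> str:
        lines = [
            "Dual-modality PLS-DA with Bayesian decision fusion",
            f"  samples: {self.model.nir.n_samples} "
            f"({len(self.split.calibration_ids)} cal / "
            f"{len(self.split.prediction_ids)} pred), "
            f"classes: {len(self.model.alphabet)}",
            f"  latent variables: " + ", ".join(
                f"{k}={v}" for k, v in self.n_lvs.items()),
            "",
            self.table.to_string(index=False),
        ]
        if self.fusion_reports:
            n_un = int(np.sum(
                self.fusion_reports["prediction"].assigned == fusion.UNASSIGNED))
            lines.append("")
            lines.append(
                f"  margin rule (threshold {self.config.threshold}): "
                f"{n_un} prediction sample(s) unassigned"
            )
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "metrics.csv", index=False,
                          float_format="%.2f")
        self.split.to_csv(out / "split.csv")
        for rep in self.reports:
            safe = rep.model_name.replace("/", "_")
            rep.to_json(out / f"report_{safe}.json")
            for part, cm in rep.confusions.items():
                cm.to_csv(out / f"confusion_{safe}_{part}.csv")
        for name, state in self.states.items():
            if state.selection is not None:
                state.selection.to_csv(
                    out / f"selection_{name}.csv",
                    n_columns=state.cal_full.shape[1],
                    wavenumbers=state.wavenumbers)
                state.selection.to_json(out / f"selection_{name}.json")
        for label, parts in self.node_sets.items():
            for part, nodes in parts.items():
                ids = (self.split.calibration_ids if part != "prediction"
                       else self.split.prediction_ids)
                df = pd.DataFrame(nodes, columns=list(self.model.alphabet.names))
                df.insert(0, "sample_id", list(ids))
                df.to_csv(out / f"nodes_{label}_{part}.csv", index=False)
        for part, frep in self.fusion_reports.items():
            ids = (self.split.calibration_ids if part != "prediction"
                   else self.split.prediction_ids)
            truth = self.cal_labels if part != "prediction" else self.pred_labels
            df = frep.to_frame(truth)
            df["sample_id"] = list(ids)
            df.to_csv(out / f"fusion_{part}.csv", index=False)
        manifest = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "models": [r.model_name for r in self.reports],
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        self.config.to_yaml(out / "config.yaml")
        (out / "log.txt").write_text("\n".join(self.log) + "\n", encoding="utf-8")
        return out


def run(config: RunConfig, outdir=None) -> FusionResults:
    """Execute the full workflow from a config (simulate or read CSVs)."""
    if config.nir_csv and config.raman_csv:
        model = DualSpectraFusion.from_csv(config.nir_csv, config.raman_csv,
                                           config)
    else:
        model = DualSpectraFusion.from_simulation(config)
    results = model.fit()
    if outdir is not None:
        results.save(outdir)
    return results
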