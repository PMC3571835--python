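"""End-to-end experiment: four feature combinations x two classifiers.

The experimental design mirrors a standard chemometric comparison:

1. calibrate every raw cube to reflectance and crop to the usable
   spectral window (500-900 nm by default);
2. treat each cube as one square ROI sample and take its mean spectrum;
3. stratified split into calibration and prediction sets;
4. fit PCA and RBF-KPCA on the calibration spectra (3 components each);
5. select effective wavelengths from the loading extrema of a pixel-level
   PCA fitted on a montage of calibration ROIs only;
6. compute the 4-per-band GLCM texture features at the selected bands;
7. for each feature mode (PC, PC+GLCM, KPC, KPC+GLCM): grid-search and
   train an LS-SVM, and train a BPNN, on the calibration set only;
8. report calibration and prediction accuracies, confusion matrices and
   misclassified sample ids.

Everything data-driven (split, PCA/KPCA fits, band selection, grid search,
feature scaling) sees calibration samples only; the run log records which
sample ids each such stage touched so leakage is assertable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_selection, classifiers, spectral_features, synthetic, texture
from .errors import CapacityError, DimensionError, ParameterError, StageError
from .hypercube_io import ROI, calibrate_reflectance, crop_spectral

__all__ = [
    "SplitPlan",
    "FeatureMatrix",
    "EvaluationReport",
    "ExperimentConfig",
    "ExperimentResult",
    "stratified_split",
    "assemble_features",
    "evaluate",
    "run_experiment",
    "FEATURE_MODES",
]

FEATURE_MODES = ("PC", "PC+GLCM", "KPC", "KPC+GLCM")


@dataclass
class SplitPlan:
    calibration_ids: np.ndarray
    prediction_ids: np.ndarray
    per_class_calibration: dict
    seed: int


def stratified_split(labels, n_cal_per_class: int, seed: int) -> SplitPlan:
    """Seeded per-class sampling without replacement; remainder predicts."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    cal, pred = [], []
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        if len(idx) <= n_cal_per_class:
            raise CapacityError(
                f"class {cls!r} has {len(idx)} samples; needs more than "
                f"n_cal_per_class={n_cal_per_class}"
            )
        perm = rng.permutation(idx)
        cal.extend(perm[:n_cal_per_class])
        pred.extend(perm[n_cal_per_class:])
    return SplitPlan(
        np.sort(np.array(cal)),
        np.sort(np.array(pred)),
        {cls: n_cal_per_class for cls in sorted(np.unique(labels).tolist())},
        seed,
    )


@dataclass
class FeatureMatrix:
    frame: pd.DataFrame  # named feature columns
    labels: np.ndarray
    mode: str

    @property
    def X(self) -> np.ndarray:
        return self.frame.to_numpy(float)


def assemble_features(
    pc_scores: np.ndarray | None,
    kpc_scores: np.ndarray | None,
    texture_vectors: np.ndarray | None,
    mode: str,
    band_set: band_selection.BandSet | None = None,
    labels=None,
) -> FeatureMatrix:
    """Column-stack the requested feature blocks (spectral first, texture second)."""
    if mode not in FEATURE_MODES:
        raise ParameterError(f"mode must be one of {FEATURE_MODES}, got {mode!r}")
    blocks, names = [], []
    spectral = pc_scores if mode.startswith("PC") else kpc_scores
    prefix = "pc" if mode.startswith("PC") else "kpc"
    if spectral is None:
        raise ParameterError(f"mode {mode} requires {prefix.upper()} scores")
    spectral = np.asarray(spectral, dtype=float)
    blocks.append(spectral)
    names.extend(f"{prefix}_{i + 1}" for i in range(spectral.shape[1]))
    if mode.endswith("+GLCM"):
        if texture_vectors is None:
            raise ParameterError(f"mode {mode} requires texture vectors")
        tv = np.asarray(texture_vectors, dtype=float)
        if tv.shape[0] != spectral.shape[0]:
            raise DimensionError(
                f"texture rows {tv.shape[0]} != spectral rows {spectral.shape[0]}"
            )
        blocks.append(tv)
        if band_set is not None and 4 * len(band_set) == tv.shape[1]:
            for wl in band_set.wavelengths:
                names.extend(f"glcm_{wl:.0f}_{f}" for f in texture.FEATURE_NAMES)
        else:
            names.extend(f"glcm_{i}" for i in range(tv.shape[1]))
    frame = pd.DataFrame(np.hstack(blocks), columns=names)
    lab = np.asarray(labels) if labels is not None else None
    return FeatureMatrix(frame, lab, mode)


@dataclass
class EvaluationReport:
    accuracy: float  # percent, full precision
    confusion: np.ndarray  # C x C over recognized predictions, rows = truth
    classes: list
    unrecognized_per_class: np.ndarray
    misclassified_ids: list

    @property
    def accuracy_display(self) -> float:
        """Accuracy rounded to 2 decimals for reporting."""
        return round(self.accuracy, 2)


def evaluate(true_labels, predicted_labels, classes=None, sample_ids=None) -> EvaluationReport:
    """Accuracy (percent), confusion matrix and misclassified ids.

    ``None`` predictions (the BPNN unrecognized flag) count as errors and
    are tallied per true class outside the C x C confusion matrix, so
    confusion row sums plus unrecognized counts equal the truth counts.
    """
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted_labels, dtype=object)
    if len(true_labels) != len(predicted):
        raise DimensionError(
            f"length mismatch: {len(true_labels)} truths, {len(predicted)} predictions"
        )
    if classes is None:
        classes = sorted(np.unique(true_labels).tolist())
    index = {c: i for i, c in enumerate(classes)}
    C = len(classes)
    confusion = np.zeros((C, C), dtype=int)
    unrecognized = np.zeros(C, dtype=int)
    ids = sample_ids if sample_ids is not None else np.arange(len(true_labels))
    wrong = []
    n_correct = 0
    for sid, t, p in zip(ids, true_labels, predicted):
        ti = index[t]
        if p is None:
            unrecognized[ti] += 1
            wrong.append(int(sid))
        else:
            confusion[ti, index[p]] += 1
            if p == t:
                n_correct += 1
            else:
                wrong.append(int(sid))
    accuracy = 100.0 * n_correct / len(true_labels)
    return EvaluationReport(accuracy, confusion, list(classes), unrecognized, wrong)


# ---------------------------------------------------------------------------
# Experiment orchestration


@dataclass
class ExperimentConfig:
    """All knobs of the end-to-end experiment; YAML round-trippable.

    ``n_cal_per_class=None`` scales the classic 40-of-55 split to the
    actual per-class count. ``data_dir=None`` generates the synthetic
    dataset in memory from ``seed``.
    """

    seed: int = 42
    data_dir: str | None = None
    # synthetic generation
    n_per_variety: int = 20
    side: int = 64
    bands: int = 128
    lo_nm: float = 380.0
    hi_nm: float = 1030.0
    noise_sd: float = 0.01
    gain_sd: float = 0.02
    signature_jitter_sd: float = 0.008
    # spectral window and features
    crop_lo_nm: float = 500.0
    crop_hi_nm: float = 900.0
    k_components: int = 3
    kpca_sigma2: float | str = "auto"
    # band selection
    n_bands: int = 3
    merge_window_nm: float = 10.0
    extrema_window: int = 11
    pixels_per_roi: int = 512
    # texture
    Ng: int = 8
    glcm_offset: tuple = (0, 1)
    glcm_symmetric: bool = True
    # split and classifiers
    n_cal_per_class: int | None = None
    folds: int = 10
    gamma_grid: list | None = None
    sigma2_grid: list | None = None
    bpnn_hidden: int = 9
    bpnn_learn_rate: float = 0.5
    bpnn_momentum: float = 0.6
    bpnn_goal_mse: float = 1e-5
    bpnn_max_epochs: int = 1000
    eps: float = 1e-8

    def resolved_n_cal(self, n_per_class: int) -> int:
        if self.n_cal_per_class is not None:
            return self.n_cal_per_class
        return max(1, min(n_per_class - 1, round(n_per_class * 40 / 55)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.glcm_offset, list):
            cfg.glcm_offset = tuple(cfg.glcm_offset)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["glcm_offset"] = list(self.glcm_offset)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class ExperimentResult:
    summary: pd.DataFrame  # rows = feature modes, accuracy cells in percent
    reports: dict  # (mode, classifier, split) -> EvaluationReport
    band_set: band_selection.BandSet
    grid_results: dict  # mode -> GridSearchResult
    split: SplitPlan
    log: list  # stage records incl. sample ids touched by fitted stages
    config: ExperimentConfig

    def summary_csv(self) -> str:
        return self.summary.to_csv(float_format="%.2f")


def _seeds_from(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full 4-feature-mode x 2-classifier comparison; deterministic."""
    (
        seed_data,
        seed_split,
        seed_montage,
        seed_grid,
        seed_bpnn,
    ) = _seeds_from(config.seed, 5)
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name})
        return name

    # --- data -------------------------------------------------------------
    try:
        if config.data_dir is not None:
            ds = synthetic.load_dataset(config.data_dir)
        else:
            ds = synthetic.generate_dataset(
                config.n_per_variety,
                side=config.side,
                bands=config.bands,
                lo_nm=config.lo_nm,
                hi_nm=config.hi_nm,
                noise_sd=config.noise_sd,
                gain_sd=config.gain_sd,
                signature_jitter_sd=config.signature_jitter_sd,
                seed=seed_data,
            )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("data", exc) from exc
    labels = ds.labels
    n = len(labels)
    stage("data")

    # --- calibrate + crop + mean spectra ----------------------------------
    try:
        rois, X = [], []
        for cube in ds.samples:
            refl = calibrate_reflectance(cube, ds.refs, config.eps)
            refl = crop_spectral(refl, config.crop_lo_nm, config.crop_hi_nm)
            refl.meta.pop("degenerate_mask", None)
            refl.data = refl.data.astype(np.float32)
            roi = ROI(refl, (0, 0), refl.shape[0])
            rois.append(roi)
            X.append(spectral_features.mean_spectrum(roi).astype(float))
        X = np.array(X, dtype=float)
    except Exception as exc:
        raise StageError("calibration", exc) from exc
    stage("calibration")

    # --- split ------------------------------------------------------------
    per_class = int(np.min(np.bincount(pd.factorize(labels)[0])))
    n_cal = config.resolved_n_cal(per_class)
    split = stratified_split(labels, n_cal, seed_split)
    cal, pred = split.calibration_ids, split.prediction_ids
    stage("split")

    # --- spectral features (fit on calibration only) -----------------------
    try:
        pca = spectral_features.fit_pca(X[cal], config.k_components)
        pc_scores = spectral_features.project_pca(pca, X)
        kpca = spectral_features.fit_kpca(
            X[cal], config.kpca_sigma2, config.k_components
        )
        kpc_scores = spectral_features.project_kpca(kpca, X)
    except Exception as exc:
        raise StageError("spectral_features", exc) from exc
    log.append({"stage": "spectral_fit", "sample_ids": cal.tolist()})

    # --- band selection on calibration ROIs only ---------------------------
    try:
        profile = band_selection.fit_montage_pca(
            [rois[i] for i in cal],
            config.k_components,
            pixels_per_roi=config.pixels_per_roi,
            seed=seed_montage,
        )
        band_set = band_selection.select_bands(
            profile,
            config.n_bands,
            merge_window_nm=config.merge_window_nm,
            window=config.extrema_window,
        )
    except Exception as exc:
        raise StageError("band_selection", exc) from exc
    log.append({"stage": "band_selection", "sample_ids": cal.tolist()})

    # --- texture ------------------------------------------------------------
    try:
        T = np.array(
            [
                texture.texture_vector(
                    roi,
                    band_set,
                    Ng=config.Ng,
                    offset=config.glcm_offset,
                    symmetric=config.glcm_symmetric,
                )
                for roi in rois
            ]
        )
    except Exception as exc:
        raise StageError("texture", exc) from exc
    stage("texture")

    # --- train + evaluate ---------------------------------------------------
    classes = sorted(np.unique(labels).tolist())
    reports: dict = {}
    grid_results: dict = {}
    cells = {}
    for mode in FEATURE_MODES:
        fm = assemble_features(pc_scores, kpc_scores, T, mode, band_set, labels)
        Xf = fm.X
        # autoscale on calibration statistics
        mu = Xf[cal].mean(axis=0)
        sd = Xf[cal].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xf - mu) / sd

        try:
            grid = classifiers.grid_search_lssvm(
                Z[cal],
                labels[cal],
                gamma_grid=config.gamma_grid,
                sigma2_grid=config.sigma2_grid,
                folds=config.folds,
                seed=seed_grid,
            )
            grid_results[mode] = grid
            log.append(
                {"stage": f"grid_search[{mode}]", "sample_ids": cal.tolist()}
            )
            lssvm = classifiers.fit_lssvm(
                Z[cal], labels[cal], grid.best_gamma, grid.best_sigma2, classes
            )
            bpnn = classifiers.fit_bpnn(
                Z[cal],
                labels[cal],
                hidden=config.bpnn_hidden,
                learn_rate=config.bpnn_learn_rate,
                momentum=config.bpnn_momentum,
                goal_mse=config.bpnn_goal_mse,
                max_epochs=config.bpnn_max_epochs,
                seed=seed_bpnn,
                classes=classes,
            )
        except Exception as exc:
            raise StageError(f"train[{mode}]", exc) from exc

        for split_name, ids in (("calibration", cal), ("prediction", pred)):
            pred_ls = classifiers.predict_lssvm(lssvm, Z[ids])
            rep_ls = evaluate(labels[ids], pred_ls, classes, ids)
            pred_nn, _ = classifiers.predict_bpnn(bpnn, Z[ids])
            rep_nn = evaluate(labels[ids], pred_nn, classes, ids)
            reports[(mode, "lssvm", split_name)] = rep_ls
            reports[(mode, "bpnn", split_name)] = rep_nn
            cells[(mode, "lssvm", split_name)] = rep_ls.accuracy_display
            cells[(mode, "bpnn", split_name)] = rep_nn.accuracy_display

    summary = pd.DataFrame(
        {
            "lssvm_calibration": [cells[(m, "lssvm", "calibration")] for m in FEATURE_MODES],
            "lssvm_prediction": [cells[(m, "lssvm", "prediction")] for m in FEATURE_MODES],
            "bpnn_calibration": [cells[(m, "bpnn", "calibration")] for m in FEATURE_MODES],
            "bpnn_prediction": [cells[(m, "bpnn", "prediction")] for m in FEATURE_MODES],
        },
        index=pd.Index(FEATURE_MODES, name="features"),
    )

    # leakage guard: fitted stages must have touched calibration ids only
    cal_set = set(cal.tolist())
    for rec in log:
        if "sample_ids" in rec:
            assert set(rec["sample_ids"]) <= cal_set, (
                f"leakage: stage {rec['stage']} touched non-calibration samples"
            )

    return ExperimentResult(summary, reports, band_set, grid_results, split, log, config)


def write_result(result: ExperimentResult, outdir) -> Path:
    """Persist summary CSV, band set, reports and log under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.csv").write_text(result.summary_csv())
    result.band_set.to_json(outdir / "bands.json")
    payload = {}
    for (mode, clf, split_name), rep in result.reports.items():
        payload[f"{mode}|{clf}|{split_name}"] = {
            "accuracy": rep.accuracy_display,
            "confusion": rep.confusion.tolist(),
            "classes": [str(c) for c in rep.classes],
            "unrecognized_per_class": rep.unrecognized_per_class.tolist(),
            "misclassified_ids": rep.misclassified_ids,
        }
    (outdir / "reports.json").write_text(json.dumps(payload, indent=2) + "\n")
    (outdir / "log.json").write_text(json.dumps(result.log, indent=2) + "\n")
    return outdir
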