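"""End-to-end analysis pipeline.

Stage order is fixed: simulate/load -> per-replicate preprocessing ->
replicate averaging -> Kennard-Stone 70/30 split -> mean-centering on
training means -> feature reduction (PCA scores or SPA-selected
wavenumbers) -> classification (LDA/QDA/SVM) -> figures of merit on
the untouched test partition.  Model complexity (number of principal
components, number of SPA variables, SVM C/gamma) is chosen by
venetian-blinds cross-validation inside the training partition only.
Identical configuration and seed give an identical report (timings
aside).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import (
    DEFAULT_SVM_GRID,
    DiscriminantModel,
    SVMModel,
    classify_discriminant,
    fit_discriminant,
    fit_svm,
    predict_svm,
)
from .io import CASE, CONTROL, SpectralDataset, read_dataset, write_dataset
from .model_selection import CVFolds, SplitResult, kennard_stone, venetian_blinds
from .preprocess import (
    CenteringModel,
    PreprocessConfig,
    apply_centering,
    fit_centering,
    preprocess_dataset,
)
from .reduce import PCAModel, SPASelection, fit_pca, project, spa_candidates
from .synthetic import CohortConfig, generate_cohort
from .validate import (
    comparison_table,
    confusion,
    figures_of_merit,
    peak_pick,
    table_to_markdown,
)

ALL_METHODS = ("pca-lda", "pca-qda", "pca-svm", "spa-lda", "spa-qda", "spa-svm")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    input_path: str | None = None
    simulation: CohortConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split_fraction: float = 0.7
    cv_folds: int = 10
    methods: tuple = ALL_METHODS
    max_components: int = 10
    max_spa_vars: int = 15
    svm_grid: tuple = DEFAULT_SVM_GRID
    svm_tol: float = 1e-3
    peak_min_prominence: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be non-empty")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown method(s) {bad}; choose from {ALL_METHODS}")

    def to_dict(self) -> dict:
        sim = None
        if self.simulation is not None:
            s = self.simulation
            sim = {
                "n_control": s.n_control,
                "n_case": s.n_case,
                "n_replicates": s.n_replicates,
                "wn_start": s.wn_start,
                "wn_end": s.wn_end,
                "wn_step": s.wn_step,
                "base_bands": [list(b) for b in s.base_bands],
                "effect_bands": [list(b) for b in s.effect_bands],
                "baseline_coeffs_sd": list(s.baseline_coeffs_sd),
                "noise_sd": s.noise_sd,
                "seed": s.seed,
            }
        p = self.preprocess
        return {
            "input_path": self.input_path,
            "simulation": sim,
            "preprocess": {
                "sg_window": p.sg_window,
                "sg_polyorder": p.sg_polyorder,
                "awls_order": p.awls_order,
                "awls_tol": p.awls_tol,
                "awls_max_iter": p.awls_max_iter,
                "awls_weighting": p.awls_weighting,
                "region": list(p.region),
                "normalization": p.normalization,
            },
            "split_fraction": self.split_fraction,
            "cv_folds": self.cv_folds,
            "methods": list(self.methods),
            "max_components": self.max_components,
            "max_spa_vars": self.max_spa_vars,
            "svm_grid": [list(g) for g in self.svm_grid],
            "svm_tol": self.svm_tol,
            "peak_min_prominence": self.peak_min_prominence,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    sim = d.get("simulation")
    if sim is not None:
        sim = dict(sim)
        for key in ("base_bands", "effect_bands"):
            if key in sim:
                sim[key] = tuple(tuple(b) for b in sim[key])
        if "baseline_coeffs_sd" in sim:
            sim["baseline_coeffs_sd"] = tuple(sim["baseline_coeffs_sd"])
        d["simulation"] = CohortConfig(**sim)
    pre = d.get("preprocess")
    if pre is not None and not isinstance(pre, PreprocessConfig):
        pre = dict(pre)
        if "region" in pre:
            pre["region"] = tuple(pre["region"])
        d["preprocess"] = PreprocessConfig(**pre)
    if "methods" in d and d["methods"] is not None:
        d["methods"] = tuple(d["methods"])
    if "svm_grid" in d and d["svm_grid"] is not None:
        d["svm_grid"] = tuple(tuple(g) for g in d["svm_grid"])
    d.pop("out_dir", None)
    return PipelineConfig(**d)


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    return config_from_dict(data)


def default_demo_config(seed: int = 0, methods=("pca-svm",)) -> PipelineConfig:
    """A scaled demonstration configuration.

    Uses the default synthetic cohort with a coarsened SVM lattice
    (C in 2^{-5,-1,3,7,11,15}, gamma in 2^{-15,-11,-7,-3,1}) and up to
    3 principal components - ample for the strongly planted effects
    while keeping a full run to a few seconds.
    """
    grid = tuple(
        (2.0**ce, 2.0**ge) for ce in range(-5, 16, 4) for ge in range(-15, 2, 4)
    )
    return PipelineConfig(
        simulation=CohortConfig(seed=seed),
        methods=tuple(methods),
        max_components=3,
        max_spa_vars=8,
        svm_grid=grid,
        seed=seed,
    )


# ------------------------------------------------------------- fitted models


@dataclass
class MethodBundle:
    """A fitted reduce+classify pair with its selection metadata."""

    name: str
    centering: CenteringModel
    pca: PCAModel | None = None
    spa: SPASelection | None = None
    disc: DiscriminantModel | None = None
    svm: SVMModel | None = None
    cv_accuracy: float = float("nan")
    hyper: dict = field(default_factory=dict)

    def features(self, ds: SpectralDataset) -> np.ndarray:
        Xc = apply_centering(ds, self.centering).absorbance
        if self.pca is not None:
            return project(self.pca, Xc, grid=ds.wavenumbers)
        assert self.spa is not None
        return Xc[:, list(self.spa.selected_indices)]

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        F = self.features(ds)
        if self.disc is not None:
            return classify_discriminant(self.disc, F)
        assert self.svm is not None
        pm = predict_svm(self.svm, F)
        return np.where(pm > 0, CASE, CONTROL).astype(object)

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "cv_accuracy": self.cv_accuracy,
            "hyper": self.hyper,
            "centering": {
                "wavenumbers": self.centering.wavenumbers.tolist(),
                "column_means": self.centering.column_means.tolist(),
            },
        }
        if self.pca is not None:
            out["pca"] = self.pca.to_dict()
        if self.spa is not None:
            out["spa"] = {"selected_indices": list(self.spa.selected_indices)}
        if self.disc is not None:
            out["classifier"] = self.disc.to_dict()
        if self.svm is not None:
            out["classifier"] = self.svm.to_dict()
        return out


def _to_pm(y) -> np.ndarray:
    return np.where(np.asarray(y, dtype=object) == CASE, 1.0, -1.0)


def _fold_pca_features(X, y, folds: CVFolds, kmax: int):
    """Per-fold centered PCA scores (train/val), sliceable by component."""
    out = []
    for tr, va in folds.splits():
        mu = X[tr].mean(axis=0)
        Xtr, Xva = X[tr] - mu, X[va] - mu
        s = np.linalg.svd(Xtr, compute_uv=False)
        tol = s[0] * max(Xtr.shape) * np.finfo(float).eps if s.size and s[0] > 0 else 0
        rank = int(np.sum(s > tol))
        k = min(kmax, rank)
        model = fit_pca(Xtr, k)
        out.append((model.scores, y[tr], Xva @ model.loadings, y[va], k))
    return out


def _disc_fold_accuracy(Ftr, ytr, Fva, yva, kind: str) -> float | None:
    classes, counts = np.unique(ytr, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        warnings.warn("skipping CV fold with a degenerate class structure", stacklevel=2)
        return None
    model = fit_discriminant(Ftr, ytr, kind)
    return float(np.mean(classify_discriminant(model, Fva) == yva))


def _select_pca_discriminant(X, y, folds, kmax, kind):
    fold_feats = _fold_pca_features(X, y, folds, kmax)
    k_avail = min(f[4] for f in fold_feats)
    best_k, best_acc = None, -np.inf
    for k in range(1, k_avail + 1):
        accs = [
            a
            for T, yt, V, yv, _ in fold_feats
            if (a := _disc_fold_accuracy(T[:, :k], yt, V[:, :k], yv, kind)) is not None
        ]
        acc = float(np.mean(accs)) if accs else -np.inf
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k, best_acc


def _select_pca_svm(X, y, folds, kmax, grid, tol=1e-3):
    fold_feats = _fold_pca_features(X, _to_pm(y), folds, kmax)
    k_avail = min(f[4] for f in fold_feats)
    best, best_acc = None, -np.inf
    for k in range(1, k_avail + 1):
        for C, gamma in sorted(grid):
            accs = []
            for T, yt, V, yv, _ in fold_feats:
                if len(set(yt)) < 2:
                    warnings.warn("skipping single-class CV fold", stacklevel=2)
                    continue
                m = fit_svm(T[:, :k], yt, C, gamma, tol=tol)
                accs.append(float(np.mean(predict_svm(m, V[:, :k]) == yv)))
            acc = float(np.mean(accs)) if accs else -np.inf
            if acc > best_acc:
                best, best_acc = (k, C, gamma), acc
    return best, best_acc


def _spa_size_candidates(X, y, split_fraction, max_vars):
    """Best-G subset per size, scored on an inner Kennard-Stone split."""
    inner = kennard_stone(X, split_fraction)
    tr, va = list(inner.train_indices), list(inner.test_indices)
    cands = spa_candidates(X[tr], y[tr], X[va], y[va], max_vars)
    by_size: dict = {}
    for subset, G in cands:
        cur = by_size.get(len(subset))
        if cur is None or G < cur[1]:
            by_size[len(subset)] = (subset, G)
    return [by_size[s] for s in sorted(by_size)]


def _cv_subset_accuracy(X, y, folds, subset, clf_kind, grid, tol=1e-3):
    if clf_kind in ("lda", "qda"):
        accs = [
            a
            for tr, va in folds.splits()
            if (
                a := _disc_fold_accuracy(
                    X[tr][:, list(subset)], y[tr], X[va][:, list(subset)], y[va], clf_kind
                )
            )
            is not None
        ]
        return (float(np.mean(accs)) if accs else -np.inf), {}
    ypm = _to_pm(y)
    best, best_acc = None, -np.inf
    for C, gamma in sorted(grid):
        accs = []
        for tr, va in folds.splits():
            if len(set(ypm[tr])) < 2:
                warnings.warn("skipping single-class CV fold", stacklevel=2)
                continue
            m = fit_svm(X[tr][:, list(subset)], ypm[tr], C, gamma, tol=tol)
            accs.append(float(np.mean(predict_svm(m, X[va][:, list(subset)]) == ypm[va])))
        acc = float(np.mean(accs)) if accs else -np.inf
        if acc > best_acc:
            best, best_acc = (C, gamma), acc
    return best_acc, {"C": best[0], "gamma": best[1]}


def fit_method(name: str, train: SpectralDataset, cfg: PipelineConfig) -> MethodBundle:
    """Fit one reduce+classify combination on the training partition."""
    red, clf = name.split("-")
    X, y = train.absorbance, train.class_label
    centering = fit_centering(train)
    Xc = X - centering.column_means
    folds = venetian_blinds(train.n_spectra, cfg.cv_folds)
    bundle = MethodBundle(name, centering)

    if red == "pca":
        if clf == "svm":
            (k, C, gamma), acc = _select_pca_svm(
                Xc, y, folds, cfg.max_components, cfg.svm_grid, tol=cfg.svm_tol
            )
            bundle.hyper = {"n_components": k, "C": C, "gamma": gamma}
        else:
            k, acc = _select_pca_discriminant(Xc, y, folds, cfg.max_components, clf)
            bundle.hyper = {"n_components": k}
        bundle.pca = fit_pca(Xc, k, training_grid=train.wavenumbers)
        features = bundle.pca.scores
    else:
        max_vars = min(cfg.max_spa_vars, train.n_spectra - 1, train.n_points)
        sized = _spa_size_candidates(Xc, y, cfg.split_fraction, max_vars)
        best_sel, best_acc, best_hyper = None, -np.inf, {}
        for subset, G in sized:
            acc, hyper = _cv_subset_accuracy(
                Xc, y, folds, subset, clf, cfg.svm_grid, tol=cfg.svm_tol
            )
            if acc > best_acc:
                best_sel, best_acc, best_hyper = (subset, G), acc, hyper
        subset, G = best_sel
        bundle.spa = SPASelection(subset, cost_G=sized)
        bundle.hyper = {"n_variables": len(subset), "cost_G": G, **best_hyper}
        acc = best_acc
        features = Xc[:, list(subset)]

    if clf == "svm":
        bundle.svm = fit_svm(
            features, _to_pm(y), bundle.hyper["C"], bundle.hyper["gamma"], tol=cfg.svm_tol
        )
    else:
        bundle.disc = fit_discriminant(features, y, clf)
    bundle.cv_accuracy = acc
    return bundle


# -------------------------------------------------------------------- runner


def run_pipeline(cfg: PipelineConfig, dataset: SpectralDataset | None = None) -> dict:
    """Execute the configured stages and return the run report.

    ``dataset`` may supply raw replicate spectra directly (bypassing
    ``input_path``/``simulation``); otherwise the configured source is
    used.  When ``cfg.out_dir`` is set the report, comparison table,
    loadings, picked peaks and serialised models are written there.
    """
    t0 = time.perf_counter()
    timings: dict = {}
    report: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }

    if dataset is None:
        if cfg.input_path is not None:
            dataset = read_dataset(cfg.input_path)
        else:
            sim = cfg.simulation if cfg.simulation is not None else CohortConfig(seed=cfg.seed)
            dataset = generate_cohort(sim).dataset
    timings["load"] = time.perf_counter() - t0

    t = time.perf_counter()
    samples = preprocess_dataset(dataset, cfg.preprocess)
    timings["preprocess"] = time.perf_counter() - t

    inner = analyse_samples(samples, cfg)
    timings.update(inner.pop("timings"))
    report.update(inner)
    timings["total"] = time.perf_counter() - t0
    report["timings"] = timings
    if cfg.out_dir is not None:  # rewrite with config/provenance included
        with open(Path(cfg.out_dir) / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def analyse_samples(samples: SpectralDataset, cfg: PipelineConfig) -> dict:
    """Split, fit, and evaluate on an already-preprocessed sample-basis
    dataset; returns the analysis portion of the run report (and writes
    artifacts when ``cfg.out_dir`` is set)."""
    timings: dict = {}
    report: dict = {}
    t = time.perf_counter()
    split = kennard_stone(samples.absorbance, cfg.split_fraction)
    train = samples.take(list(split.train_indices))
    test = samples.take(list(split.test_indices))
    report["split"] = {
        "train_samples": [str(s) for s in train.sample_id],
        "test_samples": [str(s) for s in test.sample_id],
    }
    timings["split"] = time.perf_counter() - t

    models: dict = {}
    foms: dict = {}
    for name in cfg.methods:
        t = time.perf_counter()
        bundle = fit_method(name, train, cfg)
        pred = bundle.predict(test)
        counts = confusion(test.class_label, pred, positive=CASE)
        fom = figures_of_merit(counts)
        foms[name] = fom
        entry = bundle.to_dict()
        entry["confusion"] = {
            "TP": counts.TP,
            "TN": counts.TN,
            "FP": counts.FP,
            "FN": counts.FN,
        }
        entry["figures_of_merit"] = fom.rounded()
        entry["figures_of_merit_unrounded"] = {
            "AC": fom.AC,
            "SENS": fom.SENS,
            "SPEC": fom.SPEC,
            "F-SCORE": fom.FS,
            "G-SCORE": fom.GS,
        }
        if bundle.pca is not None:
            entry["loading_peaks"] = peak_pick(
                bundle.pca.loadings[:, 0], train.wavenumbers, cfg.peak_min_prominence
            )
            entry["explained_variance_fraction"] = (
                bundle.pca.explained_variance_fraction.tolist()
            )
        if bundle.spa is not None:
            entry["selected_wavenumbers"] = [
                float(train.wavenumbers[i]) for i in bundle.spa.selected_indices
            ]
        models[name] = entry
        timings[f"model:{name}"] = time.perf_counter() - t

    table, best = comparison_table(foms)
    report["models"] = models
    report["comparison_table"] = {c: table[c].to_dict() for c in table.columns}
    report["best_model"] = best
    report["table_markdown"] = table_to_markdown(table, best)
    # partition-tag audit: test rows are only touched in the loop above
    report["partition_audit"] = {
        "test_rows_used_for_fitting": 0,
        "n_train": train.n_spectra,
        "n_test": test.n_spectra,
    }
    report["timings"] = timings

    if cfg.out_dir is not None:
        _write_outputs(cfg, report, samples, split, table, best)
    return report


def _write_outputs(cfg, report, samples, split: SplitResult, table, best) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    table.to_csv(out / "comparison_table.csv")
    (out / "comparison_table.md").write_text(table_to_markdown(table, best) + "\n")
    split.to_frame(list(samples.sample_id)).to_csv(out / "split.csv", index=False)
    for name, entry in report["models"].items():
        if "pca" in entry:
            loadings = np.asarray(entry["pca"]["loadings"])
            grid = np.asarray(entry["centering"]["wavenumbers"])
            import pandas as pd

            pd.DataFrame(
                {"wavenumber": grid, "loading_pc1": loadings[:, 0]}
            ).to_csv(out / f"loadings_{name}.csv", index=False)


def simulate_to_files(sim: CohortConfig, out_csv, sidecar: bool = True):
    """Write a synthetic cohort plus a JSON sidecar recording the config."""
    cohort = generate_cohort(sim)
    write_dataset(cohort.dataset, out_csv)
    if sidecar:
        side = {
            "config": config_from_dict({"simulation": sim.__dict__}).to_dict()["simulation"],
            "planted_effect_centers": list(cohort.planted_effect_centers),
        }
        Path(str(out_csv) + ".json").write_text(json.dumps(side, indent=2, sort_keys=True))
    return cohort
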