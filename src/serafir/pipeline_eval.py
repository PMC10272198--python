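"""Re-evaluation of serialised models on new labelled spectra."""

from __future__ import annotations

import numpy as np

from .classify import DiscriminantModel, SVMModel
from .io import SpectralDataset
from .pipeline import MethodBundle
from .preprocess import CenteringModel, PreprocessConfig, preprocess_dataset
from .reduce import PCAModel, SPASelection
from .validate import confusion, figures_of_merit


def bundle_from_dict(entry: dict) -> MethodBundle:
    centering = CenteringModel(
        np.asarray(entry["centering"]["wavenumbers"]),
        np.asarray(entry["centering"]["column_means"]),
    )
    bundle = MethodBundle(entry["name"], centering, hyper=dict(entry.get("hyper", {})))
    if "pca" in entry:
        loadings = np.asarray(entry["pca"]["loadings"])
        grid = entry["pca"].get("training_grid")
        bundle.pca = PCAModel(
            loadings,
            np.zeros((0, loadings.shape[1])),
            np.asarray(entry["pca"]["explained_variance_fraction"]),
            int(entry["pca"]["n_components"]),
            None if grid is None else np.asarray(grid),
        )
    if "spa" in entry:
        bundle.spa = SPASelection(tuple(entry["spa"]["selected_indices"]))
    clf = entry["classifier"]
    if clf["kind"] in ("lda", "qda"):
        bundle.disc = DiscriminantModel(
            clf["kind"],
            np.asarray(clf["classes"], dtype=object),
            np.asarray(clf["class_means"]),
            pooled_cov=None if clf["pooled_cov"] is None else np.asarray(clf["pooled_cov"]),
            class_covs=None
            if clf["class_covs"] is None
            else [np.asarray(C) for C in clf["class_covs"]],
        )
    else:
        bundle.svm = SVMModel(
            np.asarray(clf["support_vectors"]),
            np.asarray(clf["alphas"]),
            np.asarray(clf["labels"]),
            float(clf["bias"]),
            float(clf["gamma"]),
            float(clf["C"]),
        )
    return bundle


def evaluate_report(
    report: dict, dataset: SpectralDataset, precfg: PreprocessConfig | None = None
) -> dict:
    """Apply every model of a run report to raw replicate spectra."""
    samples = preprocess_dataset(dataset, precfg or PreprocessConfig())
    out: dict = {}
    for name, entry in report["models"].items():
        bundle = bundle_from_dict(entry)
        pred = bundle.predict(samples)
        counts = confusion(samples.class_label, pred)
        fom = figures_of_merit(counts)
        out[name] = {
            "confusion": {"TP": counts.TP, "TN": counts.TN, "FP": counts.FP, "FN": counts.FN},
            "figures_of_merit": fom.rounded(),
        }
    return out
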