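"""Spectral preprocessing chain.

The fixed pipeline order is: Savitzky-Golay smoothing of each replicate
spectrum, automatic-weighted-least-squares (AWLS) baseline correction,
truncation to the biofingerprint region, replicate averaging, and -
after the train/test split - mean-centering with the training column
means.  Every stage is deterministic.

AWLS here is an iterative polynomial fit in which points above the
current fitted baseline (absorption bands) lose their upward pull and
the fit is repeated until the coefficient vector stabilises.  The
default ``"clip"`` variant refits to ``min(y, baseline)`` — points
above the baseline contribute only at the baseline level, which is
stable under noise.  A strict 0/1 reweighting (``"binary"``: points
above the fit dropped entirely) and a soft logistic weighting
(``"soft"``) are selectable; the binary screen is well-behaved on
noise-free band-over-polynomial spectra but degenerates on noisy ones,
where the kept set shrinks until the polynomial is underdetermined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectralDataset

NORMALIZATIONS = ("none", "vector", "snv", "minmax")


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings of the preprocessing chain.

    ``sg_window``/``sg_polyorder`` control Savitzky-Golay smoothing
    (default 5-point window, 2nd-order polynomial); ``awls_*`` the
    baseline fit (default 2nd-order polynomial, convergence when the
    coefficient vector moves by < ``awls_tol`` in relative l2 norm);
    ``region`` the retained biofingerprint window in cm^-1, inclusive
    on both ends.  ``normalization`` variants other than ``"none"`` are
    provided for completeness but are not part of the default chain.
    """

    sg_window: int = 5
    sg_polyorder: int = 2
    awls_order: int = 2
    awls_tol: float = 1e-6
    awls_max_iter: int = 100
    awls_weighting: str = "clip"  # or "binary"/"soft"
    region: tuple = (1800.0, 900.0)
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.awls_max_iter < 1:
            raise ValueError("awls_max_iter must be >= 1")
        if self.awls_order < 0:
            raise ValueError("awls_order must be non-negative")
        if self.awls_weighting not in ("clip", "binary", "soft"):
            raise ValueError("awls_weighting must be 'clip', 'binary' or 'soft'")
        if not self.region[0] > self.region[1]:
            raise ValueError("region must be (high, low) with high > low")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")


class BaselineResult(NamedTuple):
    corrected: np.ndarray
    baseline: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class CenteringModel:
    """Training column means on the truncated grid."""

    wavenumbers: np.ndarray
    column_means: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.column_means = np.asarray(self.column_means, dtype=float)
        if self.wavenumbers.shape != self.column_means.shape:
            raise ValueError("column_means must match the grid length")


def savgol_smooth(spectrum, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial filter).

    Interior points take the value of the polynomial of order
    ``sg_polyorder`` least-squares fitted to their window; edge points
    are evaluated from the polynomial fitted to the nearest full
    window, so output length equals input length and polynomials of
    degree <= ``sg_polyorder`` are reproduced exactly.
    """
    cfg = cfg or PreprocessConfig()
    y = np.asarray(spectrum, dtype=float)
    if y.shape[-1] < cfg.sg_window:
        raise ValueError(
            f"spectrum of length {y.shape[-1]} shorter than window {cfg.sg_window}"
        )
    return savgol_filter(y, cfg.sg_window, cfg.sg_polyorder, mode="interp", axis=-1)


def awls_baseline(spectrum, grid, cfg: PreprocessConfig | None = None) -> BaselineResult:
    """Automatic-weighted-least-squares polynomial baseline correction.

    Returns ``(corrected, baseline, converged, n_iter)``; at
    ``awls_max_iter`` without convergence the last iterate is returned
    with ``converged=False`` rather than raising.
    """
    cfg = cfg or PreprocessConfig()
    y = np.asarray(spectrum, dtype=float)
    x = np.asarray(grid, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"spectrum length {y.size} != grid length {x.size}")
    # Vandermonde in a normalised coordinate for conditioning
    span = x.max() - x.min()
    t = (2 * (x - x.min()) / span - 1.0) if span > 0 else np.zeros_like(x)
    V = np.vander(t, cfg.awls_order + 1, increasing=True)

    w = np.ones_like(y)
    z = y.copy()  # working vector for the "clip" variant
    coeffs = None
    scale = max(np.max(np.abs(y)), 1e-300)
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.awls_max_iter + 1):
        if cfg.awls_weighting == "clip":
            new_coeffs, *_ = np.linalg.lstsq(V, z, rcond=None)
        else:
            sw = np.sqrt(w)
            new_coeffs, *_ = np.linalg.lstsq(V * sw[:, None], y * sw, rcond=None)
        baseline = V @ new_coeffs
        if coeffs is not None:
            denom = np.linalg.norm(coeffs)
            change = np.linalg.norm(new_coeffs - coeffs)
            if change <= cfg.awls_tol * max(denom, 1e-300):
                coeffs = new_coeffs
                converged = True
                break
        coeffs = new_coeffs
        resid = y - baseline
        if cfg.awls_weighting == "clip":
            z = np.minimum(z, baseline)
        elif cfg.awls_weighting == "binary":
            w = np.where(resid > 0, 0.0, 1.0)
            if not np.any(w > 0):  # degenerate: everything above the fit
                w = np.ones_like(y)
        else:
            from scipy.special import expit

            s = np.std(resid[resid <= 0]) if np.any(resid <= 0) else scale
            w = expit(-resid / max(s, 1e-300))
    baseline = V @ coeffs
    return BaselineResult(y - baseline, baseline, converged, n_iter)


def truncate_region(ds: SpectralDataset, region=None) -> SpectralDataset:
    """Keep grid columns with ``low <= wn <= high`` (inclusive)."""
    high, low = region if region is not None else PreprocessConfig().region
    if not high >= low:
        raise ValueError("region must be (high, low) with high >= low")
    keep = (ds.wavenumbers >= low) & (ds.wavenumbers <= high)
    if not keep.any():
        raise ValueError(f"region ({high}, {low}) does not overlap the grid")
    return SpectralDataset(
        ds.wavenumbers[keep],
        ds.absorbance[:, keep],
        ds.sample_id.copy(),
        ds.replicate_id.copy(),
        ds.class_label.copy(),
    )


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Arithmetic mean over replicates: one row per sample.

    Class labels must agree within a sample; the output keeps samples
    in first-occurrence order with ``replicate_id`` set to ``"mean"``.
    """
    order = ds.sample_order()
    means, classes = [], []
    for sid in order:
        rows = np.flatnonzero(ds.sample_id == sid)
        labs = set(ds.class_label[rows])
        if len(labs) > 1:
            raise ValueError(
                f"sample {sid!r} carries conflicting class labels {sorted(labs)}"
            )
        means.append(ds.absorbance[rows].mean(axis=0))
        classes.append(labs.pop())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-row-per-sample is balanced by design
        return SpectralDataset(
            ds.wavenumbers.copy(),
            np.asarray(means),
            np.asarray(order, dtype=object),
            np.asarray(["mean"] * len(order), dtype=object),
            np.asarray(classes, dtype=object),
        )


def fit_centering(train: SpectralDataset) -> CenteringModel:
    if train.n_spectra == 0:
        raise ValueError("cannot fit centering on an empty dataset")
    return CenteringModel(train.wavenumbers.copy(), train.absorbance.mean(axis=0))


def apply_centering(ds: SpectralDataset, model: CenteringModel) -> SpectralDataset:
    if not np.array_equal(ds.wavenumbers, model.wavenumbers):
        raise ValueError("dataset grid does not match the centering model grid")
    out = ds.copy()
    out.absorbance = out.absorbance - model.column_means
    return out


def apply_normalization(ds: SpectralDataset, kind: str) -> SpectralDataset:
    """Row-wise normalisation variants (not part of the default chain)."""
    if kind not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    out = ds.copy()
    A = out.absorbance
    if kind == "vector":
        norms = np.linalg.norm(A, axis=1, keepdims=True)
        out.absorbance = A / np.where(norms == 0, 1.0, norms)
    elif kind == "snv":
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, ddof=1, keepdims=True)
        out.absorbance = (A - mu) / np.where(sd == 0, 1.0, sd)
    elif kind == "minmax":
        lo = A.min(axis=1, keepdims=True)
        rng = A.max(axis=1, keepdims=True) - lo
        out.absorbance = (A - lo) / np.where(rng == 0, 1.0, rng)
    return out


def preprocess_dataset(
    ds: SpectralDataset, cfg: PreprocessConfig | None = None
) -> SpectralDataset:
    """Run the per-replicate chain and collapse to sample basis.

    Smoothing and baseline correction act on the full acquired grid;
    truncation to ``cfg.region`` follows (baseline estimation benefits
    from the wider support), then replicates are averaged.  Centering
    is deliberately *not* applied here - it must be fitted on the
    training partition only (see :func:`fit_centering`).
    """
    cfg = cfg or PreprocessConfig()
    out = ds.copy()
    out.absorbance = savgol_smooth(out.absorbance, cfg)
    corrected = np.empty_like(out.absorbance)
    for i in range(out.n_spectra):
        corrected[i] = awls_baseline(out.absorbance[i], out.wavenumbers, cfg).corrected
    out.absorbance = corrected
    out = truncate_region(out, cfg.region)
    if cfg.normalization != "none":
        out = apply_normalization(out, cfg.normalization)
    return average_replicates(out)


def config_with(cfg: PreprocessConfig, **kwargs) -> PreprocessConfig:
    return replace(cfg, **kwargs)
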