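"""Spectral dataset container and wide-CSV reading/writing.

The canonical on-disk dialect (``wide_csv``) is a UTF-8 comma-separated
table with header ``sample_id,replicate_id,class_label,<wn1>,<wn2>,...``
where ``<wn>`` are wavenumbers in cm^-1 and each subsequent row is one
replicate spectrum.  Wavenumbers are stored in descending order (the
FTIR convention, e.g. 4000 -> 600); ascending files are accepted and
canonicalised on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"
UNKNOWN = "unknown"
CLASS_LABELS = (CONTROL, CASE, UNKNOWN)

_META_COLUMNS = ("sample_id", "replicate_id", "class_label")


class SpectraIOError(ValueError):
    """Raised when a spectral table cannot be parsed or validated."""


@dataclass
class Spectrum:
    """A single absorbance spectrum on a strictly monotonic grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbance.size} absorbance values"
            )
        _check_monotonic(self.wavenumbers)


@dataclass
class SpectralDataset:
    """A stack of spectra sharing one wavenumber grid, with row metadata.

    Rows are replicate spectra; ``sample_id``/``replicate_id`` pairs are
    unique and ``class_label`` is one of ``"control"``, ``"case"`` or
    ``"unknown"``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: np.ndarray
    replicate_id: np.ndarray
    class_label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.replicate_id = np.asarray(self.replicate_id, dtype=object)
        if self.class_label is None:
            self.class_label = np.full(self.n_spectra, UNKNOWN, dtype=object)
        self.class_label = np.asarray(self.class_label, dtype=object)

        n, p = self.absorbance.shape
        if self.wavenumbers.size != p:
            raise ValueError(
                f"grid length {self.wavenumbers.size} != {p} absorbance columns"
            )
        if self.wavenumbers.size:
            _check_monotonic(self.wavenumbers)
            if self.wavenumbers.size > 1 and self.wavenumbers[0] < self.wavenumbers[-1]:
                # canonicalise to descending
                self.wavenumbers = self.wavenumbers[::-1].copy()
                self.absorbance = self.absorbance[:, ::-1].copy()
        for name in ("sample_id", "replicate_id", "class_label"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} has {getattr(self, name).size} entries, expected {n}")
        bad = [str(c) for c in np.unique(self.class_label) if c not in CLASS_LABELS]
        if bad:
            raise ValueError(f"unknown class labels {bad}; expected one of {CLASS_LABELS}")
        pairs = list(zip(self.sample_id, self.replicate_id))
        if len(set(pairs)) != len(pairs):
            seen: set = set()
            for row, pr in enumerate(pairs):
                if pr in seen:
                    raise SpectraIOError(
                        f"duplicate (sample_id, replicate_id) pair {pr!r} at row {row}"
                    )
                seen.add(pr)
        self._warn_unbalanced_replicates()

    def _warn_unbalanced_replicates(self) -> None:
        counts: dict = {}
        for s in self.sample_id:
            counts[s] = counts.get(s, 0) + 1
        if counts and len(set(counts.values())) > 1:
            warnings.warn(
                "samples carry unequal replicate counts: "
                + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
                stacklevel=3,
            )

    # -- convenience -------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.absorbance[i])

    def take(self, rows) -> "SpectralDataset":
        """Row-subset dataset (copies)."""
        rows = np.asarray(rows)
        return SpectralDataset(
            self.wavenumbers.copy(),
            self.absorbance[rows].copy(),
            self.sample_id[rows].copy(),
            self.replicate_id[rows].copy(),
            self.class_label[rows].copy(),
        )

    def copy(self) -> "SpectralDataset":
        return self.take(np.arange(self.n_spectra))

    def sample_order(self) -> list:
        """Unique sample ids in first-occurrence order."""
        seen: dict = {}
        for s in self.sample_id:
            seen.setdefault(s, None)
        return list(seen)


def _check_monotonic(wn: np.ndarray) -> None:
    if wn.size > 1:
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotonic")


def read_dataset(path, dialect: str = "wide_csv") -> SpectralDataset:
    """Read a :class:`SpectralDataset` from the wide-CSV dialect.

    The header must start with ``sample_id,replicate_id,class_label``
    followed by numeric wavenumbers; ascending grids are reordered to
    the descending canonical form.  Malformed files raise
    :class:`SpectraIOError` naming the offending row or column.
    """
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        header = pd.read_csv(path, nrows=0, index_col=False)
        cols = list(header.columns)
        if tuple(cols[:3]) != _META_COLUMNS:
            raise SpectraIOError(
                f"{path}: first three columns must be {','.join(_META_COLUMNS)}, "
                f"got {','.join(map(str, cols[:3]))}"
            )
        with warnings.catch_warnings():
            # ragged rows only warn under index_col=False; make them fatal
            warnings.simplefilter("error", pd.errors.ParserWarning)
            df = pd.read_csv(
                path,
                dtype={c: str for c in _META_COLUMNS},
                index_col=False,
                float_precision="round_trip",
            )
    except (pd.errors.ParserError, pd.errors.ParserWarning) as exc:
        raise SpectraIOError(f"cannot parse {path}: {exc}") from exc
    wn = []
    for c in cols[3:]:
        try:
            wn.append(float(c))
        except ValueError as exc:
            raise SpectraIOError(f"{path}: non-numeric wavenumber column {c!r}") from exc
    for name in _META_COLUMNS:
        missing = df[name].isna()
        if missing.any():
            row = int(np.flatnonzero(missing)[0])
            raise SpectraIOError(f"{path}: missing {name} at data row {row}")
    try:
        absorb = df[cols[3:]].to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraIOError(f"{path}: non-numeric absorbance value: {exc}") from exc
    try:
        return SpectralDataset(
            np.asarray(wn),
            absorb.reshape(len(df), len(wn)),
            df["sample_id"].to_numpy(dtype=object),
            df["replicate_id"].to_numpy(dtype=object),
            df["class_label"].to_numpy(dtype=object),
        )
    except ValueError as exc:
        raise SpectraIOError(f"{path}: {exc}") from exc


def write_dataset(ds: SpectralDataset, path) -> None:
    """Write ``ds`` in the wide-CSV dialect at full float precision.

    Floats are serialised with the shortest representation that
    round-trips, so ``read_dataset(write_dataset(ds))`` reproduces the
    dataset bit-identically for finite values.
    """
    df = pd.DataFrame(
        {
            "sample_id": ds.sample_id,
            "replicate_id": ds.replicate_id,
            "class_label": ds.class_label,
        }
    )
    # repr() gives the shortest decimal text that round-trips each float
    body = pd.DataFrame(
        [[repr(float(v)) for v in row] for row in ds.absorbance],
        columns=[repr(float(w)) for w in ds.wavenumbers],
        dtype=object,
    )
    pd.concat([df, body], axis=1).to_csv(path, index=False)
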