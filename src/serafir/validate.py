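"""Figures of merit and loading-peak identification.

The five figures of merit on a two-class confusion table are

    AC   = 100 * (TP + TN) / (TP + FP + TN + FN)
    SENS = 100 * TP / (TP + FN)
    SPEC = 100 * TN / (TN + FP)
    FS   = 2 * SENS * SPEC / (SENS + SPEC)      (harmonic mean)
    GS   = sqrt(SENS * SPEC)                    (geometric mean)

computed on unrounded SENS/SPEC; displayed tables round half away from
zero to integer percent.  The positive class is the case
(osteosarcopenia) group, so SENS is the case-detection rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import CASE, CONTROL

FOM_NAMES = ("AC", "SENS", "SPEC", "F-SCORE", "G-SCORE")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class FiguresOfMerit:
    """Unrounded percentages; use :meth:`rounded` for display."""

    AC: float
    SENS: float
    SPEC: float
    FS: float
    GS: float

    def rounded(self) -> dict:
        return {
            "AC": _round_half_away(self.AC),
            "SENS": _round_half_away(self.SENS),
            "SPEC": _round_half_away(self.SPEC),
            "F-SCORE": _round_half_away(self.FS),
            "G-SCORE": _round_half_away(self.GS),
        }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def confusion(y_true, y_pred, positive: str = CASE) -> ConfusionCounts:
    """Two-by-two tally with the declared positive class."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("label vectors must be non-empty and of equal length")
    allowed = {CONTROL, CASE}
    bad = (set(y_true.tolist()) | set(y_pred.tolist())) - allowed
    if bad:
        raise ValueError(f"labels {sorted(map(str, bad))} outside {sorted(allowed)}")
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def fscore_gscore(sens: float, spec: float) -> tuple[float, float]:
    """Harmonic and geometric means of SENS/SPEC percentages."""
    if not (0 <= sens <= 100 and 0 <= spec <= 100):
        raise ValueError("sens and spec must lie in [0, 100]")
    if sens + spec == 0:
        return 0.0, 0.0
    return 2.0 * sens * spec / (sens + spec), math.sqrt(sens * spec)


def figures_of_merit(c: ConfusionCounts) -> FiguresOfMerit:
    if c.TP + c.FN == 0:
        raise ValueError("no positive (case) samples among the evaluated labels")
    if c.TN + c.FP == 0:
        raise ValueError("no negative (control) samples among the evaluated labels")
    sens = 100.0 * c.TP / (c.TP + c.FN)
    spec = 100.0 * c.TN / (c.TN + c.FP)
    ac = 100.0 * (c.TP + c.TN) / c.total
    fs, gs = fscore_gscore(sens, spec)
    return FiguresOfMerit(ac, sens, spec, fs, gs)


def comparison_table(results: dict) -> tuple[pd.DataFrame, str]:
    """Model-by-merit table of integer percents, plus the best model.

    ``results`` maps model name -> :class:`FiguresOfMerit`.  The best
    model maximises AC, ties broken by maximal GS (on unrounded
    values), then by table order.
    """
    if not results:
        raise ValueError("need at least one model")
    table = pd.DataFrame(
        {name: fom.rounded() for name, fom in results.items()}
    ).reindex(list(FOM_NAMES))
    best = max(results, key=lambda k: (results[k].AC, results[k].GS))
    return table, best


def table_to_markdown(table: pd.DataFrame, best: str | None = None) -> str:
    cols = list(table.columns)
    header = (
        "| FOM | " + " | ".join(f"**{c}**" if c == best else c for c in cols) + " |"
    )
    sep = "|" + "---|" * (len(cols) + 1)
    lines = [header, sep]
    for fom in table.index:
        lines.append(
            "| " + str(fom) + " | " + " | ".join(str(int(table.loc[fom, c])) for c in cols) + " |"
        )
    return "\n".join(lines)


def peak_pick(loading, grid, min_prominence: float = 0.1) -> list[float]:
    """Wavenumbers of the |loading| peaks, in descending cm^-1 order.

    A peak is a local maximum of ``|loading|`` with prominence at least
    ``min_prominence`` times ``max |loading|``; a constant loading has
    no peaks.
    """
    loading = np.asarray(loading, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if loading.shape != grid.shape:
        raise ValueError("loading and grid must have equal length")
    if not 0 < min_prominence <= 1:
        raise ValueError("min_prominence must lie in (0, 1]")
    a = np.abs(loading)
    top = a.max() if a.size else 0.0
    if top == 0.0:
        return []
    idx, _ = find_peaks(a, prominence=min_prominence * top)
    return sorted((float(w) for w in grid[idx]), reverse=True)
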