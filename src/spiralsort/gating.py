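"""Cytometry gating: debris exclusion, DNA split, size split.

The end-product classes separate on two measured channels.  Events with
projected area at or below the debris gate (default 15 µm², inclusive)
are debris.  Of the rest, DNA-negative events (signal strictly below the
DNA threshold) are enucleated cells — they are inherently DNA-negative —
while DNA-positive events split on size: at or above the
nucleated/nucleus area cut they are nucleated cells, below it free
nuclei.  The DNA threshold is placed from an unstained control sample
(upper quantile of its background signal); the area cut is not dictated
by the data model and defaults to the midpoint of the preset's nucleated
and nucleus mean areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .populations import DEBRIS, DonorPreset
from .sorter import CELL_CLASSES

#: rectangle on (area, dna) as (area_min, area_max, dna_min, dna_max)
Rect = tuple[float, float, float, float]


def _rects_overlap(a: Rect, b: Rect) -> bool:
    return a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]


@dataclass(frozen=True)
class GateConfig:
    """Thresholds of the gating strategy.

    Boundary conventions (covered by tests): debris is inclusive at
    ``debris_area_max``; DNA-positive means ``dna_signal >= dna_threshold``;
    nucleated means ``area >= nucleated_min_area``.  Optional rectangular
    (area x dna) gates per class take precedence where an event falls
    inside one; they must be pairwise disjoint.
    """

    dna_threshold: float
    nucleated_min_area: float
    debris_area_max: float = 15.0
    rect_gates: Mapping[str, Rect] | None = None

    def __post_init__(self) -> None:
        if self.debris_area_max <= 0:
            raise ConfigError("debris_area_max must be positive")
        if self.dna_threshold < 0 or self.nucleated_min_area < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.rect_gates:
            items = list(self.rect_gates.items())
            for cls, r in items:
                if cls not in CELL_CLASSES:
                    raise ConfigError(f"rectangular gate for unknown class {cls!r}")
                if not (r[0] < r[1] and r[2] < r[3]):
                    raise ConfigError(f"degenerate rectangle for {cls!r}")
            for i, (ca, ra) in enumerate(items):
                for cb, rb in items[i + 1:]:
                    if _rects_overlap(ra, rb):
                        raise ConfigError(
                            f"rectangular gates for {ca!r} and {cb!r} overlap"
                        )


def default_gates_for_preset(
    preset: DonorPreset,
    dna_threshold: float | None = None,
    dna_quantile: float = 0.995,
) -> GateConfig:
    """Gates consistent with a preset.

    The nucleated/nucleus area cut is the midpoint of the two class mean
    areas; absent an explicit threshold the DNA gate is the background
    quantile taken analytically from the preset's unstained distribution.
    """
    if dna_threshold is None:
        dna_threshold = preset.dna_signal["enucleated"].quantile(dna_quantile)
    cut = 0.5 * (preset.area["nucleated"].loc + preset.area["nucleus"].loc)
    return GateConfig(dna_threshold=float(dna_threshold), nucleated_min_area=float(cut))


def fit_dna_threshold(unstained: pd.DataFrame, quantile: float = 0.995) -> float:
    """DNA-positivity threshold from an unstained control table.

    The threshold is the given upper quantile of the background DNA
    signal, so at most ``1 - quantile`` of unstained events read as
    DNA-positive.
    """
    if not 0 < quantile < 1:
        raise InputError("quantile must lie strictly between 0 and 1")
    if len(unstained) == 0:
        raise InputError("unstained table is empty")
    sig = unstained["dna_au"].to_numpy(dtype=float)
    if np.any(sig < 0):
        raise InputError("negative dna signal in unstained table")
    return float(np.quantile(sig, quantile))


def _classify_arrays(
    area: np.ndarray, dna: np.ndarray, gates: GateConfig
) -> np.ndarray:
    if np.any(area < 0) or np.any(dna < 0):
        raise InputError("negative area or fluorescence signal")
    labels = np.where(
        area <= gates.debris_area_max,
        DEBRIS,
        np.where(
            dna < gates.dna_threshold,
            "enucleated",
            np.where(area >= gates.nucleated_min_area, "nucleated", "nucleus"),
        ),
    ).astype(object)
    if gates.rect_gates:
        non_debris = area > gates.debris_area_max
        for cls, (a0, a1, d0, d1) in gates.rect_gates.items():
            inside = non_debris & (area >= a0) & (area < a1) & (dna >= d0) & (dna < d1)
            labels[inside] = cls
    return labels


def classify_event(area_um2: float, dna_au: float, gates: GateConfig) -> str:
    """Label a single event; exactly one of the four labels."""
    return str(_classify_arrays(np.array([area_um2]), np.array([dna_au]), gates)[0])


@dataclass(frozen=True)
class GatingResult:
    """Labelled table plus composition summary.

    ``composition`` holds fractions per biological class over non-debris
    events (empty dict when everything is debris); ``confusion`` and
    ``accuracy`` are present when the table carries ground truth.
    """

    table: pd.DataFrame
    composition: dict[str, float]
    debris_fraction: float
    confusion: pd.DataFrame | None = None
    accuracy: float | None = None

    @property
    def all_debris(self) -> bool:
        return not self.composition


def gate_table(table: pd.DataFrame, gates: GateConfig) -> GatingResult:
    """Apply the gating strategy to every event.

    Adds a ``gated_class`` column; the composition is computed after
    debris exclusion.  When a ``true_class`` column is present a
    confusion matrix (rows = truth, columns = gated) and overall accuracy
    are attached rather than any error raised — overlap between classes
    is a property of the sample, not a failure.
    """
    area = table["area_um2"].to_numpy(dtype=float) if len(table) else np.empty(0)
    dna = table["dna_au"].to_numpy(dtype=float) if len(table) else np.empty(0)
    labels = _classify_arrays(area, dna, gates)
    out = table.copy()
    out["gated_class"] = labels
    non_debris = labels != DEBRIS
    n_cells = int(non_debris.sum())
    composition = (
        {
            cls: float(np.sum(labels[non_debris] == cls)) / n_cells
            for cls in CELL_CLASSES
        }
        if n_cells
        else {}
    )
    debris_fraction = float((~non_debris).sum()) / len(out) if len(out) else 0.0
    confusion = accuracy = None
    if "true_class" in out.columns and len(out):
        order = list(CELL_CLASSES) + [DEBRIS]
        confusion = pd.crosstab(out["true_class"], out["gated_class"]).reindex(
            index=order, columns=order, fill_value=0
        )
        accuracy = float((out["true_class"] == out["gated_class"]).mean())
    return GatingResult(
        table=out,
        composition=composition,
        debris_fraction=debris_fraction,
        confusion=confusion,
        accuracy=accuracy,
    )
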