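"""Phenomenological focusing model, ROC construction, and outlet binning.

Cells travelling a spiral microchannel settle at class- and flow-rate-
dependent lateral equilibrium positions (distance from the outer wall).
The physics (shear-gradient, wall and deformability-induced lift plus
Dean drag) is not computed here; instead the measured position
distributions are carried as a table of (mean, SD) pairs per
(cell class, flow rate) — the :class:`FocusingModel`.

Separation potential between the target class (enucleated cells, which
at high flow rate shift toward the outer wall) and a contaminant class
is scored with a receiver operating characteristic over position
cut-offs: at cut-off x, TPR is the fraction of target cells found at or
below x and FPR the corresponding contaminant fraction.  Smaller
distance from the outer wall is the "positive" direction throughout.
The trapezoid area under that curve (AUC) drives flow-rate selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError, InputError, MissingModelEntryError

#: the three biological classes of the differentiation end-product
CELL_CLASSES = ("enucleated", "nucleated", "nucleus")


def _norm_rate(flow_rate: float) -> float:
    return round(float(flow_rate), 6)


@dataclass(frozen=True)
class FocusingModel:
    """Lateral-position distribution parameters per (class, flow rate).

    ``entries`` maps ``(cell_class, flow_rate_ml_min)`` to
    ``(mean_um, sd_um)``, positions measured from the outer wall.
    Combinations that were never measured are absent and accessing them
    raises :class:`MissingModelEntryError` — no interpolation.
    """

    entries: Mapping[tuple[str, float], tuple[float, float]]
    channel_width_um: float = 170.0

    def __post_init__(self) -> None:
        for (cls, q), (mean, sd) in self.entries.items():
            if not 0 <= mean <= self.channel_width_um:
                raise ConfigError(
                    f"mean position {mean} for ({cls}, {q}) outside channel"
                )
            if sd < 0:
                raise ConfigError(f"negative SD for ({cls}, {q})")

    def get(self, cell_class: str, flow_rate: float) -> tuple[float, float]:
        key = (cell_class, _norm_rate(flow_rate))
        try:
            return self.entries[key]
        except KeyError:
            raise MissingModelEntryError(cell_class, flow_rate) from None

    def has(self, cell_class: str, flow_rate: float) -> bool:
        return (cell_class, _norm_rate(flow_rate)) in self.entries

    def classes(self) -> list[str]:
        return sorted({cls for cls, _ in self.entries})

    def flow_rates(self) -> list[float]:
        return sorted({q for _, q in self.entries})

    def sample(
        self,
        cell_class: str,
        flow_rate: float,
        n: int,
        rng: np.random.Generator,
        truncate: bool = False,
    ) -> np.ndarray:
        """Draw ``n`` lateral positions (µm from the outer wall).

        Positions are normal(mean, sd); with ``truncate`` they are drawn
        from the normal truncated to [0, channel width] — the physical
        support used by the sorting simulation.
        """
        if n < 0:
            raise InputError("n must be non-negative")
        mean, sd = self.get(cell_class, flow_rate)
        if sd == 0:
            return np.full(n, mean)
        if truncate:
            a = (0.0 - mean) / sd
            b = (self.channel_width_um - mean) / sd
            return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        return rng.normal(mean, sd, size=n)

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path) -> None:
        doc: dict = {"channel_width_um": self.channel_width_um, "classes": {}}
        for (cls, q), (mean, sd) in sorted(self.entries.items()):
            doc["classes"].setdefault(cls, {})[q] = {"mean": mean, "sd": sd}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FocusingModel":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        try:
            entries = {
                (str(c), _norm_rate(q)): (float(p["mean"]), float(p["sd"]))
                for c, per_rate in doc["classes"].items()
                for q, p in per_rate.items()
            }
            return cls(entries=entries, channel_width_um=float(doc["channel_width_um"]))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed focusing-model file {path}: {exc}") from exc


def default_focusing_model() -> FocusingModel:
    """The measured position table shipped with the package.

    Means ± SDs per class at 0.2–1.0 ml/min; combinations that were not
    measured (nucleated at 0.8, nuclei at 0.2 ml/min) are absent.
    """
    with resources.as_file(
        resources.files("spiralsort.data") / "focusing_model.yaml"
    ) as p:
        return FocusingModel.from_yaml(p)


# ---------------------------------------------------------------------- ROC


@dataclass(frozen=True)
class ROCResult:
    """ROC over lateral-position cut-offs, target vs contaminant."""

    cutoffs_um: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff_um": self.cutoffs_um, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(
    target_positions: np.ndarray, contaminant_positions: np.ndarray
) -> ROCResult:
    """ROC of position cut-offs: positive = position at or below cut-off.

    TPR(x) = fraction of target cells with position <= x, FPR(x) the same
    fraction of contaminants.  Cut-offs sweep every observed position so
    the trapezoid AUC equals the Mann-Whitney probability
    P(target < contaminant) (+ half the tie mass).
    """
    t = np.asarray(target_positions, dtype=float)
    c = np.asarray(contaminant_positions, dtype=float)
    if t.size == 0 or c.size == 0:
        raise InputError("both position samples must be non-empty")
    cutoffs = np.unique(np.concatenate([t, c]))
    tpr = np.searchsorted(np.sort(t), cutoffs, side="right") / t.size
    fpr = np.searchsorted(np.sort(c), cutoffs, side="right") / c.size
    # anchor the curve at (0, 0); the last cut-off already gives (1, 1)
    cutoffs = np.concatenate([[cutoffs[0] - 1.0], cutoffs])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(cutoffs_um=cutoffs, tpr=tpr, fpr=fpr, auc=auc)


def gaussian_auc(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Closed-form AUC for two normal position distributions.

    Class 1 is the target and lower positions are positive, so
    AUC = Phi((mean2 - mean1) / sqrt(sd1^2 + sd2^2)).  Serves as the
    independent oracle for :func:`roc_curve`.
    """
    if sd1 < 0 or sd2 < 0:
        raise InputError("standard deviations must be non-negative")
    denom = math.hypot(sd1, sd2)
    if denom == 0:
        return 0.5 if mean1 == mean2 else (1.0 if mean1 < mean2 else 0.0)
    return float(stats.norm.cdf((mean2 - mean1) / denom))


def fit_position_model(
    positions: np.ndarray,
    lower: float | None = None,
    upper: float | None = None,
) -> tuple[float, float]:
    """Estimate the (mean, sd) of a position distribution from samples.

    Without bounds this is the plain sample mean and SD (ddof=1).  With
    ``lower``/``upper`` the estimate is the maximum-likelihood fit of a
    normal truncated to those bounds — the right estimator for in-channel
    measurements, where cells are only ever observed inside the channel
    and the naive sample mean is biased toward the centre.
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise InputError("need at least two positions to fit")
    m0, s0 = float(x.mean()), float(x.std(ddof=1))
    if lower is None and upper is None:
        return m0, s0
    lo = -np.inf if lower is None else float(lower)
    hi = np.inf if upper is None else float(upper)
    if np.any(x < lo) or np.any(x > hi):
        raise InputError("positions outside the stated truncation bounds")

    def nll(params):
        mu, log_sd = params
        sd = math.exp(log_sd)
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return -np.sum(stats.truncnorm.logpdf(x, a, b, loc=mu, scale=sd))

    from scipy import optimize

    res = optimize.minimize(
        nll, x0=[m0, math.log(max(s0, 1e-6))], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9},
    )
    return float(res.x[0]), float(math.exp(res.x[1]))


# ------------------------------------------------------------------ binning


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(chr(ord("A") + i) for i in range(n))


@dataclass(frozen=True)
class OutletBins:
    """Channel sections mapped to outlets, µm from the outer wall.

    Default: the 170 µm width quartered into outlets A (outer wall side)
    through D (inner wall).  Binning is half-open [edge_i, edge_{i+1})
    with the last bin closed at the channel width.
    """

    edges_um: tuple[float, ...] = (0.0, 42.5, 85.0, 127.5, 170.0)
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_um, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigError("bin edges must be strictly increasing")
        labels = self.labels or _default_labels(edges.size - 1)
        if len(labels) != edges.size - 1:
            raise ConfigError("need one label per bin")
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def width_um(self) -> float:
        return float(self.edges_um[-1])


def positions_to_outlets(
    positions_um: np.ndarray, bins: OutletBins | None = None
) -> pd.Series:
    """Count positions per outlet; conserves the number of events."""
    bins = bins or OutletBins()
    pos = np.asarray(positions_um, dtype=float)
    edges = np.asarray(bins.edges_um)
    if pos.size and (pos.min() < edges[0] or pos.max() > edges[-1]):
        raise InputError(
            f"positions outside [{edges[0]}, {edges[-1]}] µm; truncate upstream"
        )
    idx = np.searchsorted(edges, pos, side="right") - 1
    idx = np.clip(idx, 0, len(bins.labels) - 1)  # closes the last bin
    counts = np.bincount(idx, minlength=len(bins.labels))
    return pd.Series(counts, index=list(bins.labels), name="count")


def outlet_of(position_um: float, bins: OutletBins | None = None) -> str:
    """Outlet label for a single position (half-open bin convention)."""
    bins = bins or OutletBins()
    counts = positions_to_outlets(np.array([position_um]), bins)
    return str(counts.idxmax())


# ------------------------------------------------------- flow-rate choice


@dataclass(frozen=True)
class FlowRateSelection:
    """Chosen operating point plus the per-candidate AUC table."""

    flow_rate_ml_min: float
    auc_table: pd.DataFrame  # columns: flow_rate_ml_min, auc_vs_<class>..., min_auc


def select_flow_rate(
    model: FocusingModel,
    candidates: Iterable[float],
    n_per_class: int = 100_000,
    seed: int = 0,
    target: str = "enucleated",
    contaminants: tuple[str, ...] = ("nucleated", "nucleus"),
) -> FlowRateSelection:
    """Pick the flow rate whose worst available AUC is best.

    For each candidate, positions are simulated for the target and every
    contaminant with model entries at that rate, and the empirical ROC
    AUC computed.  The candidate maximizing the minimum available AUC
    wins; ties go to the higher flow rate (throughput preference).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    candidates = sorted(_norm_rate(q) for q in candidates)
    if not candidates:
        raise InputError("no candidate flow rates")
    for q, child in zip(candidates, ss.spawn(len(candidates))):
        if not model.has(target, q):
            continue
        rng = np.random.default_rng(child)
        t = model.sample(target, q, n_per_class, rng)
        row: dict = {"flow_rate_ml_min": q}
        aucs = []
        for cont in contaminants:
            if model.has(cont, q):
                c = model.sample(cont, q, n_per_class, rng)
                auc = roc_curve(t, c).auc
                row[f"auc_vs_{cont}"] = auc
                aucs.append(auc)
            else:
                row[f"auc_vs_{cont}"] = np.nan
        if not aucs:
            continue
        row["min_auc"] = min(aucs)
        rows.append(row)
    if not rows:
        raise InputError(
            "no candidate flow rate has focusing data for the target and a contaminant"
        )
    table = pd.DataFrame(rows)
    # stable argmax with tie-break toward higher flow rate: scan ascending,
    # accept >= so later (faster) candidates displace equal-scoring ones
    best_q, best_score = None, -np.inf
    for _, row in table.iterrows():
        if row["min_auc"] >= best_score:
            best_q, best_score = row["flow_rate_ml_min"], row["min_auc"]
    return FlowRateSelection(flow_rate_ml_min=float(best_q), auc_table=table)


# ----------------------------------------------------------- sorting stage


def simulate_sort(
    table: pd.DataFrame,
    model: FocusingModel,
    flow_rate: float,
    bins: OutletBins | None = None,
    seed: int = 0,
    class_column: str = "true_class",
) -> dict[str, pd.DataFrame]:
    """Route each event to an outlet via its class's position distribution.

    Every event draws a truncated-normal lateral position for its class at
    the given flow rate and is assigned the outlet whose channel section
    contains it.  Returns one sub-table per outlet (with a
    ``position_um`` column); events are conserved exactly.
    """
    bins = bins or OutletBins()
    present = [c for c in table[class_column].unique()] if len(table) else []
    missing = [c for c in present if not model.has(c, flow_rate)]
    if missing:
        raise MissingModelEntryError(missing[0], flow_rate)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    positions = np.empty(len(table), dtype=float)
    for cls in present:
        mask = (table[class_column] == cls).to_numpy()
        positions[mask] = model.sample(cls, flow_rate, int(mask.sum()), rng, truncate=True)
    out = table.copy()
    out["position_um"] = positions
    edges = np.asarray(bins.edges_um)
    idx = np.clip(np.searchsorted(edges, positions, side="right") - 1, 0, len(bins.labels) - 1)
    out["outlet"] = np.asarray(bins.labels)[idx] if len(out) else pd.Series(dtype=str)
    return {
        label: out[out["outlet"] == label].drop(columns="outlet").reset_index(drop=True)
        for label in bins.labels
    }
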