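"""Synthetic event tables with the structure of an erythroid end-product.

In vitro erythropoiesis from CD34+ cells yields a mixture of three
object classes — enucleated cells (the product), nucleated cells still
at earlier stages, and free-floating expelled nuclei — plus small
debris.  Each event carries a projected area (µm²), a deformability
index, a DNA-stain signal and a CD235a (glycophorin A) signal, the
measurables of a fluorescence + deformability cytometer.

Donor presets encode the qualitative orderings seen across donors:
nuclei are the stiffest class and enucleated cells the most deformable
everywhere, while relative *sizes* vary by donor:

* donor I   — enucleated cells overlap nuclei in area, shifted slightly
  larger (area AUC ≈ 0.68);
* donor II  — enucleated cells are the smallest and least deformable of
  the three donors' products;
* donor III — enucleated cells are clearly larger than nuclei
  (AUC ≈ 0.95) but overlap nucleated cells (AUC ≈ 0.56).

Absolute sizes are a modelling choice: the area means/SDs below were
solved from the closed-form Gaussian AUC to reproduce those printed
overlaps, not measured.  Families are normal (truncated at zero) for
area and deformability and log-normal for fluorescence; both are
configurable per preset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError, InputError
from .sorter import CELL_CLASSES, FocusingModel

DEBRIS = "debris"
#: column order of the canonical event CSV
EVENT_COLUMNS = (
    "event_id",
    "true_class",
    "diameter_um",
    "area_um2",
    "deformability",
    "dna_au",
    "cd235a_au",
)


@dataclass(frozen=True)
class Dist:
    """A location-scale distribution for one event attribute.

    ``normal`` is truncated at zero (areas, deformabilities and positions
    are non-negative); ``lognormal`` interprets ``loc`` as the median and
    ``scale`` as the SD of the log (fluorescence signals).
    """

    loc: float
    scale: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ConfigError("scale must be non-negative")
        if self.family not in ("normal", "lognormal"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.family == "lognormal" and self.loc <= 0:
            raise ConfigError("lognormal median must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0:
            return np.full(n, self.loc)
        if self.family == "normal":
            a = (0.0 - self.loc) / self.scale
            return stats.truncnorm.rvs(
                a, np.inf, loc=self.loc, scale=self.scale, size=n, random_state=rng
            )
        return rng.lognormal(math.log(self.loc), self.scale, size=n)

    def quantile(self, q: float) -> float:
        if self.family == "normal":
            if self.scale == 0:
                return self.loc
            a = (0.0 - self.loc) / self.scale
            return float(stats.truncnorm.ppf(q, a, np.inf, loc=self.loc, scale=self.scale))
        return float(self.loc * math.exp(self.scale * stats.norm.ppf(q)))


_ATTRS = ("area", "deformability", "dna_signal", "cd235a_signal")


@dataclass(frozen=True)
class DonorPreset:
    """Per-donor composition and attribute distributions.

    ``class_fractions`` is a simplex over the three biological classes;
    ``debris_fraction`` is the additional share of the *total* event
    stream that is sub-cellular debris (area below the debris gate).
    """

    donor_id: str
    class_fractions: Mapping[str, float]
    area: Mapping[str, Dist]
    deformability: Mapping[str, Dist]
    dna_signal: Mapping[str, Dist]
    cd235a_signal: Mapping[str, Dist]
    debris_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.class_fractions) != set(CELL_CLASSES):
            raise ConfigError(
                f"class_fractions must cover exactly {CELL_CLASSES}"
            )
        fracs = [self.class_fractions[c] for c in CELL_CLASSES]
        if any(f < 0 for f in fracs) or not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ConfigError("class_fractions must be non-negative and sum to 1")
        if not 0 <= self.debris_fraction < 1:
            raise ConfigError("debris_fraction must lie in [0, 1)")
        for attr in _ATTRS:
            table = getattr(self, attr)
            if set(table) != set(CELL_CLASSES):
                raise ConfigError(f"{attr} must define a Dist for each class")
        # deformability orderings hold for every donor: nuclei stiffest,
        # enucleated cells the most deformable (size orderings vary by donor)
        d = {c: self.deformability[c].loc for c in CELL_CLASSES}
        if not (d["nucleus"] < d["nucleated"] < d["enucleated"]):
            raise ConfigError(
                "deformability must order nucleus < nucleated < enucleated"
            )

    def attribute(self, attr: str, cls: str) -> Dist:
        return getattr(self, attr)[cls]

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "class_fractions": dict(self.class_fractions),
            "debris_fraction": self.debris_fraction,
            **{
                attr: {
                    cls: {"loc": d.loc, "scale": d.scale, "family": d.family}
                    for cls, d in getattr(self, attr).items()
                }
                for attr in _ATTRS
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DonorPreset":
        try:
            kwargs = {
                "donor_id": str(doc["donor_id"]),
                "class_fractions": {k: float(v) for k, v in doc["class_fractions"].items()},
                "debris_fraction": float(doc.get("debris_fraction", 0.05)),
            }
            for attr in _ATTRS:
                kwargs[attr] = {
                    c: Dist(float(p["loc"]), float(p["scale"]), p.get("family", "normal"))
                    for c, p in doc[attr].items()
                }
            return cls(**kwargs)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed donor preset: {exc}") from exc


def preset_to_yaml(preset: DonorPreset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(preset.to_dict(), fh, sort_keys=True)


def preset_from_yaml(path) -> DonorPreset:
    with open(path, "r", encoding="utf-8") as fh:
        return DonorPreset.from_dict(yaml.safe_load(fh))


def _fluorescence_defaults() -> dict[str, Mapping[str, Dist]]:
    """Stain panel shared by all donors.

    Enucleated cells are DNA-negative: their DNA channel is the unstained
    background distribution.  Free nuclei express less CD235a than
    nucleated cells.
    """
    return {
        "dna_signal": {
            "enucleated": Dist(5.0, 0.5, "lognormal"),   # background
            "nucleated": Dist(800.0, 0.4, "lognormal"),
            "nucleus": Dist(500.0, 0.4, "lognormal"),
        },
        "cd235a_signal": {
            "enucleated": Dist(300.0, 0.4, "lognormal"),
            "nucleated": Dist(500.0, 0.4, "lognormal"),
            "nucleus": Dist(100.0, 0.5, "lognormal"),
        },
    }


def donor_presets() -> dict[str, DonorPreset]:
    """Presets I–III (donor-like) plus a well-separated control preset.

    Area parameters solve Phi(dmu / sqrt(s1^2 + s2^2)) for the printed
    pairwise overlaps; deformability is on the dimensionless 0–0.1 scale
    of deformability cytometry.
    """
    fluo = _fluorescence_defaults()
    soft = {  # donors I and III: fully deformable product
        "enucleated": Dist(0.08, 0.02),
        "nucleated": Dist(0.03, 0.01),
        "nucleus": Dist(0.01, 0.005),
    }
    stiff = {  # donor II: stiffer enucleated cells
        "enucleated": Dist(0.05, 0.015),
        "nucleated": Dist(0.03, 0.01),
        "nucleus": Dist(0.01, 0.005),
    }
    presets = {
        "I": DonorPreset(
            donor_id="I",
            class_fractions={"enucleated": 0.30, "nucleated": 0.45, "nucleus": 0.25},
            area={
                # enucleated vs nuclei AUC = Phi(5.3/sqrt(8^2+8^2)) = 0.68
                "enucleated": Dist(35.3, 8.0),
                "nucleated": Dist(50.0, 10.0),
                "nucleus": Dist(30.0, 8.0),
            },
            deformability=soft,
            **fluo,
        ),
        "II": DonorPreset(
            donor_id="II",
            class_fractions={"enucleated": 0.10, "nucleated": 0.60, "nucleus": 0.30},
            area={
                "enucleated": Dist(26.0, 7.0),  # smallest subset in this donor
                "nucleated": Dist(50.0, 10.0),
                "nucleus": Dist(30.0, 8.0),
            },
            deformability=stiff,
            **fluo,
        ),
        "III": DonorPreset(
            donor_id="III",
            class_fractions={"enucleated": 0.35, "nucleated": 0.40, "nucleus": 0.25},
            area={
                # vs nuclei: Phi(18.6/11.31) = 0.95; vs nucleated: Phi(1.9/12.81) = 0.56
                "enucleated": Dist(48.6, 8.0),
                "nucleated": Dist(50.5, 10.0),
                "nucleus": Dist(30.0, 8.0),
            },
            deformability=soft,
            **fluo,
        ),
        # not donor-derived: a cleanly separable population for exercising
        # the gating logic at known ground truth
        "separable": DonorPreset(
            donor_id="separable",
            class_fractions={"enucleated": 1 / 3, "nucleated": 1 / 3, "nucleus": 1 / 3},
            area={
                "enucleated": Dist(45.0, 4.0),
                "nucleated": Dist(80.0, 5.0),
                "nucleus": Dist(20.0, 1.5),
            },
            deformability=soft,
            **fluo,
        ),
    }
    return presets


# ------------------------------------------------------------- generation


def _debris_block(n: int, preset: DonorPreset, rng: np.random.Generator) -> pd.DataFrame:
    area = rng.uniform(1.0, 15.0, size=n)
    return pd.DataFrame(
        {
            "true_class": DEBRIS,
            "area_um2": area,
            "deformability": Dist(0.05, 0.02).sample(n, rng),
            "dna_au": preset.dna_signal["enucleated"].sample(n, rng),
            "cd235a_au": Dist(5.0, 0.5, "lognormal").sample(n, rng),
        }
    )


def _class_block(
    cls: str, n: int, preset: DonorPreset, rng: np.random.Generator, unstained: bool
) -> pd.DataFrame:
    dna = preset.dna_signal["enucleated" if unstained else cls]
    return pd.DataFrame(
        {
            "true_class": cls,
            "area_um2": preset.area[cls].sample(n, rng),
            "deformability": preset.deformability[cls].sample(n, rng),
            "dna_au": dna.sample(n, rng),
            "cd235a_au": preset.cd235a_signal[cls].sample(n, rng),
        }
    )


def generate_events(
    preset: DonorPreset, n: int, seed: int, unstained: bool = False
) -> pd.DataFrame:
    """Draw ``n`` events from a donor preset, deterministically per seed.

    Class counts are multinomial over (the three classes scaled by
    1 - debris_fraction, debris_fraction); per-class attributes follow the
    preset distributions and the projected diameter is derived from the
    area (d = sqrt(4 A / pi)).  With ``unstained`` every class draws its
    DNA channel from the background distribution — the stain-control
    sample used to place the DNA gate.
    """
    if n < 0:
        raise InputError("n must be non-negative")
    preset.validate()
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(CELL_CLASSES) + 2)  # classes + debris + shuffle
    rng0 = np.random.default_rng(streams[0])
    fd = preset.debris_fraction
    probs = [preset.class_fractions[c] * (1 - fd) for c in CELL_CLASSES] + [fd]
    counts = rng0.multinomial(n, probs)
    blocks = [
        _class_block(cls, int(k), preset, np.random.default_rng(child), unstained)
        for cls, k, child in zip(CELL_CLASSES, counts[:-1], streams[:3])
        if k
    ]
    if counts[-1]:
        blocks.append(
            _debris_block(int(counts[-1]), preset, np.random.default_rng(streams[3]))
        )
    if blocks:
        table = pd.concat(blocks, ignore_index=True)
        shuffle = np.random.default_rng(streams[4]).permutation(len(table))
        table = table.iloc[shuffle].reset_index(drop=True)
    else:
        table = pd.DataFrame(
            {c: pd.Series(dtype=float) for c in EVENT_COLUMNS if c != "true_class"}
            | {"true_class": pd.Series(dtype=str)}
        )
    table["diameter_um"] = np.sqrt(4.0 * table["area_um2"] / math.pi)
    table["event_id"] = np.arange(len(table), dtype=int)
    table = table[list(EVENT_COLUMNS)]
    table.attrs.update({"seed": seed, "preset": preset.donor_id, "n": n,
                        "unstained": unstained})
    return table


def generate_unstained(preset: DonorPreset, n: int, seed: int) -> pd.DataFrame:
    """Stain-control table: same morphology, DNA channel all background."""
    return generate_events(preset, n, seed, unstained=True)


def sample_lateral_positions(
    model: FocusingModel,
    cell_class: str,
    flow_rate: float,
    n: int,
    seed: int,
    truncate: bool = False,
) -> np.ndarray:
    """Positions (µm from outer wall) for one class at one flow rate.

    Thin convenience wrapper over :meth:`FocusingModel.sample`; raises
    :class:`~spiralsort.errors.MissingModelEntryError` where the model
    has no measurement.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return model.sample(cell_class, flow_rate, n, rng, truncate=truncate)


# -------------------------------------------------------------------- I/O


def write_events(table: pd.DataFrame, path) -> None:
    """Canonical event CSV: UTF-8, '.' decimal, fixed column order."""
    table[list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"event table missing columns: {sorted(missing)}")
    return table[list(EVENT_COLUMNS)]
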