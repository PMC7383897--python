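"""Dimensionless-number design calculations for a spiral microchannel.

The sorting channel is a rectangular-cross-section spiral (default
170 µm x 30 µm, six loops, four balanced outlets).  This module computes
the quantities a designer checks before running cells through it:

* hydraulic diameter  Dh = 2HW / (H + W),
* mean velocity       U  = Q / (W H),
* channel Reynolds    Re = rho U Dh / mu   (inertial / viscous forces),
* Dean number         De = Re * sqrt(Dh / R)  (secondary-flow strength),
* crowding parameter  alpha = 6 W H VF / (pi a^2), the number of particle
  diameters per unit channel length; alpha > 1 signals steric crowding
  that can defeat single-stream focusing,

plus the laminar equal split of flow over the outlets.

Units at the interface are the practitioner's: µm for lengths, ml/min for
flow rates; everything is converted to SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, InputError

_UM = 1e-6                    # µm -> m
_ML_PER_MIN = 1e-6 / 60.0     # ml/min -> m^3/s


@dataclass(frozen=True)
class ChannelGeometry:
    """Spiral channel cross-section and layout (lengths in µm)."""

    width_um: float = 170.0
    height_um: float = 30.0
    loops: int = 6
    curvature_radius_um: float | None = None
    n_outlets: int = 4

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ConfigError("channel width and height must be positive")
        if self.curvature_radius_um is not None and self.curvature_radius_um <= 0:
            raise ConfigError("curvature radius must be positive when set")
        if self.n_outlets < 1:
            raise ConfigError("need at least one outlet")

    @property
    def cross_section_m2(self) -> float:
        return (self.width_um * _UM) * (self.height_um * _UM)


@dataclass(frozen=True)
class Fluid:
    """Carrier medium; defaults are water-like buffer at room temperature."""

    density_kg_m3: float = 1000.0
    viscosity_pa_s: float = 0.001

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise ConfigError("density and viscosity must be positive")


@dataclass(frozen=True)
class CrowdingInput:
    """Particle loading, either as a volume fraction or a concentration.

    When only ``concentration_per_ml`` is given the volume fraction is
    derived assuming spherical particles of diameter ``diameter_um``:
    VF = c * pi a^3 / 6.
    """

    diameter_um: float
    volume_fraction: float | None = None
    concentration_per_ml: float | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ConfigError("particle diameter must be positive")
        if self.volume_fraction is None and self.concentration_per_ml is None:
            raise ConfigError("provide volume_fraction or concentration_per_ml")
        if self.volume_fraction is not None and not (0 <= self.volume_fraction < 1):
            raise ConfigError("volume fraction must lie in [0, 1)")

    def resolved_volume_fraction(self) -> float:
        derived = None
        if self.concentration_per_ml is not None:
            a_cm = self.diameter_um * 1e-4  # µm -> cm, concentration is per ml = cm^3
            derived = self.concentration_per_ml * math.pi * a_cm**3 / 6.0
        if self.volume_fraction is None:
            return derived  # type: ignore[return-value]
        if derived is not None and not math.isclose(
            derived, self.volume_fraction, rel_tol=1e-3, abs_tol=1e-12
        ):
            raise ConfigError(
                "volume_fraction and concentration_per_ml are inconsistent: "
                f"{self.volume_fraction:g} vs derived {derived:g}"
            )
        return self.volume_fraction


def hydraulic_diameter(geom: ChannelGeometry) -> float:
    """Hydraulic diameter of the rectangular duct, in µm."""
    h, w = geom.height_um, geom.width_um
    return 2.0 * h * w / (h + w)


def mean_velocity(flow_rate_ml_min: float, geom: ChannelGeometry) -> float:
    """Mean (superficial) velocity in m/s for a volumetric flow in ml/min."""
    if flow_rate_ml_min < 0:
        raise InputError("flow rate must be non-negative")
    return flow_rate_ml_min * _ML_PER_MIN / geom.cross_section_m2


def reynolds(fluid: Fluid, velocity_m_s: float, dh_um: float) -> float:
    """Channel Reynolds number rho U Dh / mu (Dh given in µm)."""
    if dh_um <= 0:
        raise InputError("hydraulic diameter must be positive")
    return fluid.density_kg_m3 * velocity_m_s * (dh_um * _UM) / fluid.viscosity_pa_s


def dean(re: float, dh_um: float, radius_um: float | None) -> float:
    """Dean number Re * sqrt(Dh / R); requires the curvature radius."""
    if radius_um is None:
        raise ConfigError("curvature radius required to compute the Dean number")
    if radius_um <= 0:
        raise ConfigError("curvature radius must be positive")
    return re * math.sqrt(dh_um / radius_um)


def crowding_alpha(geom: ChannelGeometry, loading: CrowdingInput) -> tuple[float, bool]:
    """Crowding parameter alpha = 6 W H VF / (pi a^2) and a focusing flag.

    Returns ``(alpha, single_stream_ok)`` where the flag is ``alpha <= 1``;
    above one, particles compete for space on the focusing streamline.
    """
    vf = loading.resolved_volume_fraction()
    a = loading.diameter_um
    alpha = 6.0 * geom.width_um * geom.height_um * vf / (math.pi * a**2)
    return alpha, alpha <= 1.0


def outlet_flow_split(flow_rate_ml_min: float, geom: ChannelGeometry) -> list[float]:
    """Equal laminar split of the volumetric flow over the outlets (ml/min)."""
    if flow_rate_ml_min < 0:
        raise InputError("flow rate must be non-negative")
    return [flow_rate_ml_min / geom.n_outlets] * geom.n_outlets


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def operating_table(
    flow_rates_ml_min: list[float],
    geom: ChannelGeometry | None = None,
    fluid: Fluid | None = None,
) -> pd.DataFrame:
    """Operating-condition table: one row per flow rate.

    Velocities are reported both exactly and rounded to two significant
    figures; ``re`` follows from the rounded velocity (the convention of
    the printed design table this reproduces) while ``re_exact`` uses the
    unrounded one.  Dean numbers are included only when the geometry has a
    curvature radius.
    """
    geom = geom or ChannelGeometry()
    fluid = fluid or Fluid()
    dh = hydraulic_diameter(geom)
    rows = []
    for q in flow_rates_ml_min:
        u = mean_velocity(q, geom)
        u2 = round_sig(u, 2)
        row = {
            "flow_rate_ml_min": q,
            "velocity_m_s": u2,
            "velocity_m_s_exact": u,
            "re": round(reynolds(fluid, u2, dh)),
            "re_exact": reynolds(fluid, u, dh),
        }
        if geom.curvature_radius_um is not None:
            row["de"] = dean(row["re"], dh, geom.curvature_radius_um)
            row["de_exact"] = dean(row["re_exact"], dh, geom.curvature_radius_um)
        rows.append(row)
    return pd.DataFrame(rows)
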