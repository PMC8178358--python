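"""Infrared device model: distance-to-spot geometry and radiometry.

An infrared thermometer's distance-to-spot (D:S) ratio fixes the diameter of
its measurement spot (90% encircled energy): spot = distance / D:S.  When the
spot outgrows the target — a forehead is only a few inches across — the
device averages in extraneous background radiance and the reading is invalid;
the manufacturer guidance adopted here is that the target extent should be at
least twice the spot diameter.

Radiometry follows the Stefan–Boltzmann law M = ε·σ·T⁴ (M radiant exitance
in W/m², T absolute temperature in K, ε emissivity; skin ≈ 0.98).  Because
temperature recovery goes as the fourth root, an emissivity mismatch between
the object and the device setting scales the apparent temperature by
(ε_true/ε_assumed)^(1/4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "Length",
    "DeviceSpec",
    "RadiometricModel",
    "SIGMA_SB",
    "SKIN_EMISSIVITY",
    "FLUKE_561",
    "FLUKE_568",
    "EXERGEN_TAT5000",
    "DEVICE_REGISTRY",
    "spot_diameter",
    "spot_adequate",
    "radiant_exitance",
    "temperature_from_exitance",
    "emissivity_mismatch_error",
    "fahrenheit_to_kelvin",
    "kelvin_to_fahrenheit",
    "UnitError",
]

#: Stefan–Boltzmann constant, W·m⁻²·K⁻⁴.
SIGMA_SB = 5.670373e-8

#: Emissivity of human skin (near-perfect emitter).
SKIN_EMISSIVITY = 0.98

#: Default forehead target extent used for spot-adequacy checks.
DEFAULT_FOREHEAD_EXTENT_IN = 3.0

_INCHES_PER = {"in": 1.0, "ft": 12.0, "m": 39.3701}


class UnitError(ValueError):
    """Unknown or mismatched length unit."""


@dataclass(frozen=True)
class Length:
    """A length with an explicit unit tag (ft, in or m)."""

    value: float
    unit: str = "in"

    def __post_init__(self) -> None:
        if self.unit not in _INCHES_PER:
            raise UnitError(f"unknown unit {self.unit!r}; use one of {sorted(_INCHES_PER)}")

    @property
    def inches(self) -> float:
        return self.value * _INCHES_PER[self.unit]

    def to(self, unit: str) -> "Length":
        if unit not in _INCHES_PER:
            raise UnitError(f"unknown unit {unit!r}")
        return Length(self.inches / _INCHES_PER[unit], unit)


@dataclass(frozen=True)
class DeviceSpec:
    """Manufacturer specification envelope for a thermometer."""

    name: str
    ds_ratio: float | None
    emissivity_settings: Mapping[str, float] = field(default_factory=dict)
    accuracy: str = ""
    temp_range_f: tuple[float, float] = (-40.0, 1022.0)
    repeatability: str = ""

    def __post_init__(self) -> None:
        if self.ds_ratio is not None and self.ds_ratio <= 0:
            raise ValueError("ds_ratio must be positive")
        for label, eps in self.emissivity_settings.items():
            if not (0.0 < eps <= 1.0):
                raise ValueError(f"emissivity {label}={eps} outside (0, 1]")


FLUKE_561 = DeviceSpec(
    name="Fluke 561",
    ds_ratio=12.0,
    emissivity_settings={"Lo": 0.3, "Med": 0.7, "Hi": 0.95},
    accuracy="above 32F: max(±1%, ±2F)",
    temp_range_f=(-40.0, 1022.0),
    repeatability="max(±0.5%, ±2F)",
)

FLUKE_568 = DeviceSpec(
    name="Fluke 568",
    ds_ratio=50.0,
    emissivity_settings={"adjustable": 0.95},  # 0.10–1.00 by 0.01
    accuracy="above 32F: max(±1%, ±2F)",
    temp_range_f=(-40.0, 1472.0),
    repeatability="max(±0.5%, ±1F)",
)

EXERGEN_TAT5000 = DeviceSpec(
    name="Exergen TemporalScanner TAT-5000",
    ds_ratio=None,  # contact-scan device; D:S not applicable
    accuracy="±0.2F (ASTM E1112)",
    temp_range_f=(61.0, 110.0),
)

DEVICE_REGISTRY: Mapping[str, DeviceSpec] = {
    "fluke561": FLUKE_561,
    "fluke568": FLUKE_568,
    "tat5000": EXERGEN_TAT5000,
}


@dataclass(frozen=True)
class RadiometricModel:
    epsilon: float = SKIN_EMISSIVITY
    sigma_sb: float = SIGMA_SB

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must be in (0, 1]")


def fahrenheit_to_kelvin(t_f: float) -> float:
    return (t_f - 32.0) * 5.0 / 9.0 + 273.15


def kelvin_to_fahrenheit(t_k: float) -> float:
    return (t_k - 273.15) * 9.0 / 5.0 + 32.0


def spot_diameter(distance: Length, ds_ratio: float) -> Length:
    """Measurement-spot diameter at a distance: distance / D:S, in inches.

    A 12:1 device at 6 ft has a 6 in spot; a 50:1 device at 6 ft, 1.44 in.
    """
    if distance.value <= 0:
        raise ValueError("distance must be positive")
    if ds_ratio <= 0:
        raise ValueError("ds_ratio must be positive")
    return Length(distance.inches / ds_ratio, "in")


def spot_adequate(spot: Length, target_extent: Length) -> tuple[bool, float]:
    """Whether the target is at least twice the spot diameter, plus the margin.

    Returns ``(adequate, target/spot)``; the boundary (margin exactly 2) is
    adequate.
    """
    if spot.inches <= 0 or target_extent.inches <= 0:
        raise ValueError("lengths must be positive")
    margin = target_extent.inches / spot.inches
    return margin >= 2.0, margin


def radiant_exitance(temp_k: float, epsilon: float) -> float:
    """Stefan–Boltzmann radiant exitance ε·σ·T⁴ in W/m²."""
    if temp_k <= 0:
        raise ValueError("absolute temperature must be positive")
    if not (0.0 < epsilon <= 1.0):
        raise ValueError("epsilon must be in (0, 1]")
    return epsilon * SIGMA_SB * temp_k**4


def temperature_from_exitance(m: float, epsilon: float) -> float:
    """Invert the Stefan–Boltzmann law: T = (M / (ε·σ))^(1/4) in K."""
    if m < 0:
        raise ValueError("radiant exitance must be nonnegative")
    if not (0.0 < epsilon <= 1.0):
        raise ValueError("epsilon must be in (0, 1]")
    return (m / (epsilon * SIGMA_SB)) ** 0.25


def emissivity_mismatch_error(t_true_k: float, eps_true: float,
                              eps_assumed: float) -> float:
    """Apparent temperature when the device assumes the wrong emissivity.

    The device recovers T from M assuming ε_assumed while the object emits
    with ε_true, giving apparent T = T_true · (ε_true/ε_assumed)^(1/4).
    """
    if t_true_k <= 0:
        raise ValueError("absolute temperature must be positive")
    for eps in (eps_true, eps_assumed):
        if not (0.0 < eps <= 1.0):
            raise ValueError("emissivities must be in (0, 1]")
    return t_true_k * (eps_true / eps_assumed) ** 0.25
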