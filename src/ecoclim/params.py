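"""Species parameter sets for the ecoclimatic-index model.

A :class:`ParameterSet` holds the full set of growth and stress parameters
that drive the weekly kernels: the temperature trapezoid ``DV0..DV3``, the
soil-moisture trapezoid ``SM0..SM3``, thresholds and weekly accumulation
rates for the four stresses (cold, heat, dry, wet), the annual degree-day
requirement ``PDD``, and the hydrology settings of the soil-moisture bucket
(``soil_capacity``, ``k_et``, ``sm_cap``).

Accumulation rates are stored *signed* exactly as conventionally printed
(cold and dry rates negative); the kernels consume their magnitudes.

Parameter files are flat TOML tables, one species per file.  The bundled
``oil_palm`` preset carries the published parameterisation of
*Elaeis guineensis*.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["ParameterSet", "ParameterError", "load_parameters", "save_parameters", "oil_palm_preset"]

#: Table-style mnemonics that must appear in every parameter file.
REQUIRED_KEYS = (
    "DV0", "DV1", "DV2", "DV3",
    "SM0", "SM1", "SM2", "SM3",
    "TTCS", "THCS", "DTCS", "DHCS",
    "TTHS", "THHS",
    "SMDS", "HDS",
    "SMWS", "HWS",
    "PDD",
)

#: Optional keys with defaults (hydrology settings, not part of the species table).
OPTIONAL_KEYS = ("soil_capacity", "k_et", "sm_cap")


class ParameterError(ValueError):
    """Raised when a parameter file is malformed or violates an invariant."""


@dataclass(frozen=True)
class ParameterSet:
    """Validated species parameters.

    Temperatures in °C, soil moisture as a fraction of soil water-holding
    capacity, rates in week⁻¹, degree-day quantities in °C·days.
    """

    DV0: float  # limiting low temperature (growth stops below)
    DV1: float  # lower optimal temperature
    DV2: float  # upper optimal temperature
    DV3: float  # limiting high temperature
    SM0: float  # limiting low soil moisture
    SM1: float  # lower optimal soil moisture
    SM2: float  # upper optimal soil moisture
    SM3: float  # limiting high soil moisture
    TTCS: float  # cold-stress temperature threshold, °C
    THCS: float  # cold-stress temperature rate, week⁻¹ (negative as printed)
    DTCS: float  # cold-stress degree-day threshold, °C·days per week
    DHCS: float  # degree-day cold-stress rate, week⁻¹ (negative as printed)
    TTHS: float  # heat-stress temperature threshold, °C
    THHS: float  # heat-stress rate, week⁻¹
    SMDS: float  # dry-stress soil-moisture threshold, fraction
    HDS: float  # dry-stress rate, week⁻¹ (negative as printed)
    SMWS: float  # wet-stress soil-moisture threshold, fraction
    HWS: float  # wet-stress rate, week⁻¹
    PDD: float  # minimum annual degree-days above DV0 for establishment
    soil_capacity: float = 100.0  # bucket water-holding capacity, mm
    k_et: float = 1.0  # evapotranspiration coefficient, mm·°C⁻¹·day⁻¹ per unit sm
    sm_cap: float = 2.5  # bucket ceiling as a fraction of soil_capacity

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        p = self
        if not (p.DV0 < p.DV1 <= p.DV2 < p.DV3):
            raise ParameterError(
                f"temperature thresholds must satisfy DV0 < DV1 <= DV2 < DV3, "
                f"got DV0={p.DV0}, DV1={p.DV1}, DV2={p.DV2}, DV3={p.DV3}"
            )
        if not (p.SM0 < p.SM1 <= p.SM2 < p.SM3):
            raise ParameterError(
                f"soil-moisture thresholds must satisfy SM0 < SM1 <= SM2 < SM3, "
                f"got SM0={p.SM0}, SM1={p.SM1}, SM2={p.SM2}, SM3={p.SM3}"
            )
        if p.TTCS > p.DV0:
            raise ParameterError(f"TTCS ({p.TTCS}) must not exceed DV0 ({p.DV0})")
        if p.TTHS < p.DV2:
            raise ParameterError(f"TTHS ({p.TTHS}) must be >= DV2 ({p.DV2})")
        if p.SMDS > p.SM0:
            raise ParameterError(f"SMDS ({p.SMDS}) must not exceed SM0 ({p.SM0})")
        if p.SMWS < p.SM2:
            raise ParameterError(f"SMWS ({p.SMWS}) must be >= SM2 ({p.SM2})")
        if p.PDD < 0:
            raise ParameterError(f"PDD must be non-negative, got {p.PDD}")
        if p.DTCS < 0:
            raise ParameterError(f"DTCS must be non-negative, got {p.DTCS}")
        for key in ("THCS", "DHCS", "HDS"):
            if getattr(p, key) >= 0:
                raise ParameterError(f"{key} is an accumulation rate printed negative; got {getattr(p, key)}")
        for key in ("THHS", "HWS"):
            if getattr(p, key) <= 0:
                raise ParameterError(f"{key} must be a positive rate, got {getattr(p, key)}")
        if p.soil_capacity <= 0:
            raise ParameterError(f"soil_capacity must be positive, got {p.soil_capacity}")
        if p.k_et <= 0:
            raise ParameterError(f"k_et must be positive, got {p.k_et}")
        if p.sm_cap <= p.SM3:
            raise ParameterError(
                f"sm_cap ({p.sm_cap}) must exceed SM3 ({p.SM3}) so wet stress can accumulate"
            )
        for f in dataclasses.fields(p):
            v = getattr(p, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ParameterError(f"{f.name} must be a finite number, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)


def _from_mapping(raw: dict, source: str) -> ParameterSet:
    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if missing:
        raise ParameterError(f"{source}: missing required keys: {', '.join(missing)}")
    unknown = [k for k in raw if k not in REQUIRED_KEYS and k not in OPTIONAL_KEYS]
    if unknown:
        raise ParameterError(f"{source}: unknown keys: {', '.join(sorted(unknown))}")
    kwargs = {k: float(raw[k]) for k in raw}
    return ParameterSet(**kwargs)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a flat TOML parameter file.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ParameterError
        On missing/unknown keys or any ordering/sign invariant violation;
        the message names the offending symbols.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return _from_mapping(raw, str(path))


def save_parameters(p: ParameterSet, path: str | Path) -> None:
    """Write *p* as a flat TOML key=value table (round-trips with load)."""
    lines = [f"{k} = {v!r}" for k, v in p.as_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def oil_palm_preset() -> ParameterSet:
    """The bundled oil-palm (*Elaeis guineensis*) parameter set."""
    ref = resources.files("ecoclim").joinpath("data/oil_palm.toml")
    raw = tomllib.loads(ref.read_text(encoding="utf-8"))
    return _from_mapping(raw, "oil_palm preset")
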