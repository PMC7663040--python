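"""Diffusion-coefficient models for organic contaminants in PET.

Two predictors are provided, both mapping (molecular weight, temperature)
to a diffusion coefficient in cm²/s:

* **Piringer** — the conservative empirical A_P correlation widely used in
  regulatory specific-migration modelling.  For a polymer with parameters
  A_P' and τ it reads::

      D = 1e4 * exp(A_P' - τ/T - 0.1351 * M^(2/3) + 0.003 * M - 10454/T)

  with M in g/mol and T in kelvin.  For PET the pinned upper-bound
  parameters are A_P' = 3.1 and τ = 1577 K.

* **Welle** — a PET-specific correlation yielding more realistic (lower)
  room-temperature diffusivities than the Piringer upper bound.  The
  parameterization shipped here is a log-linear calibration

      ln D = α + β·M      (at 25 °C)

  anchored at two back-calculated room-temperature diffusion coefficients
  for benzene (M 78.1) and carvone (M 150.2); see ``WELLE_ANCHORS_25C``.
  It is valid only at its calibration temperature; querying any other
  temperature raises :class:`UnsupportedTemperatureError`.

Both models are registered under the names ``"piringer"`` and ``"welle"``;
:func:`get_model` resolves a name (with optional parameter overrides) to a
callable ``D(M, T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "DiffusionQuery",
    "PiringerParameters",
    "WelleParameters",
    "DiffusionDomainError",
    "UnsupportedTemperatureError",
    "piringer_D",
    "welle_D",
    "get_model",
    "MODEL_NAMES",
    "WELLE_ANCHORS_25C",
]

#: Admissible molecular-weight range, g/mol.
MW_RANGE = (40.0, 600.0)
#: Admissible temperature range, kelvin.
T_RANGE = (273.0, 473.0)

REFERENCE_TEMPERATURE = 298.15  # 25 °C


class DiffusionDomainError(ValueError):
    """Molecular weight or temperature outside the supported domain."""


class UnsupportedTemperatureError(ValueError):
    """A calibrated model was queried away from its calibration temperature."""


@dataclass(frozen=True)
class DiffusionQuery:
    """A (molecular weight, temperature) point at which to predict D."""

    molecular_weight: float  # g/mol
    temperature: float = REFERENCE_TEMPERATURE  # kelvin

    def __post_init__(self) -> None:
        if not (MW_RANGE[0] < self.molecular_weight < MW_RANGE[1]):
            raise DiffusionDomainError(
                f"molecular weight {self.molecular_weight} g/mol outside {MW_RANGE}"
            )
        if not (T_RANGE[0] < self.temperature < T_RANGE[1]):
            raise DiffusionDomainError(
                f"temperature {self.temperature} K outside {T_RANGE}"
            )


@dataclass(frozen=True)
class PiringerParameters:
    """Polymer constants of the Piringer A_P correlation (PET defaults)."""

    a_p_prime: float = 3.1  # dimensionless upper-bound A_P'
    tau: float = 1577.0  # K, polymer-specific activation contribution
    polymer: str = "PET"


#: Room-temperature (298.15 K) anchor diffusion coefficients for the
#: calibrated Welle parameterization, back-solved through the semi-infinite
#: migration formula from published one-year migration predictions
#: (benzene: 0.000338 µg/L at c_P,0 = 7.5e-4 mg/kg; carvone: 0.001 µg/L at
#: c_P,0 = 0.05 mg/kg; 6 dm²/L, PET density 1.4 g/cm³).
WELLE_ANCHORS_25C: tuple[tuple[float, float], ...] = (
    (78.1, 7.168620272610745e-15),
    (150.2, 1.411837436834685e-17),
)


@dataclass(frozen=True)
class WelleParameters:
    """Parameterization of the Welle PET diffusion correlation.

    ``source="calibrated"`` uses a log-linear fit in molecular weight at a
    single calibration temperature.  A future ``source="reference-constants"``
    would carry the full Arrhenius form (pre-exponential and activation
    energy as functions of M); it is not shipped because no trustworthy
    transcription of those constants is bundled.
    """

    source: str = "calibrated"
    temperature: float = REFERENCE_TEMPERATURE  # K, calibration temperature
    intercept: float = 0.0  # α in ln D = α + β·M
    slope: float = 0.0  # β, 1/(g/mol)

    @classmethod
    def calibrated_pet(cls) -> "WelleParameters":
        """Two-point log-linear calibration through ``WELLE_ANCHORS_25C``."""
        (m1, d1), (m2, d2) = WELLE_ANCHORS_25C
        slope = (math.log(d2) - math.log(d1)) / (m2 - m1)
        intercept = math.log(d1) - slope * m1
        return cls(source="calibrated", temperature=REFERENCE_TEMPERATURE,
                   intercept=intercept, slope=slope)


_WELLE_PET = WelleParameters.calibrated_pet()
_PIRINGER_PET = PiringerParameters()


def piringer_D(q: DiffusionQuery, p: PiringerParameters = _PIRINGER_PET) -> float:
    """Piringer A_P upper-bound diffusion coefficient, cm²/s."""
    M, T = q.molecular_weight, q.temperature
    exponent = p.a_p_prime - p.tau / T - 0.1351 * M ** (2.0 / 3.0) + 0.003 * M - 10454.0 / T
    return 1e4 * math.exp(exponent)


def welle_D(q: DiffusionQuery, p: WelleParameters = _WELLE_PET) -> float:
    """Welle PET diffusion coefficient, cm²/s (calibrated source)."""
    if p.source != "calibrated":
        raise ValueError(f"unsupported Welle parameterization source {p.source!r}")
    if abs(q.temperature - p.temperature) > 0.5:
        raise UnsupportedTemperatureError(
            f"calibrated Welle model is valid at {p.temperature} K only, "
            f"queried at {q.temperature} K"
        )
    return math.exp(p.intercept + p.slope * q.molecular_weight)


MODEL_NAMES = ("piringer", "welle")


def get_model(name: str, **overrides) -> Callable[[float, float], float]:
    """Resolve a model name to a callable ``D(molecular_weight, temperature)``.

    Keyword overrides replace fields of the model's default parameter set
    (e.g. ``get_model("piringer", a_p_prime=2.0)``).
    """
    if name == "piringer":
        params = PiringerParameters(**{**_PIRINGER_PET.__dict__, **overrides})
        return lambda M, T=REFERENCE_TEMPERATURE: piringer_D(DiffusionQuery(M, T), params)
    if name == "welle":
        params = WelleParameters(**{**_WELLE_PET.__dict__, **overrides})
        return lambda M, T=REFERENCE_TEMPERATURE: welle_D(DiffusionQuery(M, T), params)
    raise KeyError(f"unknown diffusion model {name!r}; registered: {MODEL_NAMES}")
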