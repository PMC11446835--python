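"""Model parameters, physical constants, and the uncertainty specification.

The transdermal ethanol model describes one square centimetre of skin as a
stack of four well-mixed compartments — capillary blood, viable epidermis,
stratum corneum, and the supradermal gas space — exchanging ethanol by blood
flow, diffusion, and ventilation.  Eleven physiological parameters carry
literature uncertainty (uniform distributions, given as half-widths about the
average); the remaining quantities are fixed physical constants.

Solubilities ``beta`` use the Ostwald-style convention of
mL ethanol vapour per 100 mL of medium per Torr.  The "per 100 mL" factor is
kept internally for every ``beta``: each flux and capacitance term of the
balance equations carries exactly one solubility, so the convention cancels
and only unit conversion to g/dL needs to handle it explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "BETA_G",
    "L_C",
    "AREA",
    "BODY_TEMP_K",
    "M_ETHANOL",
    "R_GAS",
    "VARIED_PARAMETERS",
    "InvalidParameterError",
    "ModelParameters",
    "ParameterUncertainty",
    "default_parameters",
    "default_uncertainty",
    "mass_transfer_coefficient",
]

# Fixed constants (not sampled in the sensitivity analysis).
BETA_G: float = 0.132      #: solubility of ethanol in gas, mL·(100 mL)^-1·Torr^-1
L_C: float = 0.0007        #: capillary compartment thickness, cm (one blood-cell diameter)
AREA: float = 1.0          #: skin patch / gas compartment surface area, cm^2
BODY_TEMP_K: float = 310.15  #: body temperature, K (37 degC)
M_ETHANOL: float = 46.07   #: ethanol molar mass, g·mol^-1
R_GAS: float = 62_360.0    #: universal gas constant, Torr·cm^3·mol^-1·K^-1

#: The eleven physiological parameters with uncertainty, in canonical order.
VARIED_PARAMETERS: tuple[str, ...] = (
    "beta_b", "beta_e", "beta_s",
    "D_e", "D_s",
    "L_e", "L_s", "L_g",
    "A_c", "Q_dot", "V_dot",
)

_AVERAGES: dict[str, float] = {
    "beta_b": 232.0,
    "beta_e": 232.0,
    "beta_s": 211.0,
    "D_e": 5.0e-6,
    "D_s": 5.0e-10,
    "L_e": 0.02,
    "L_s": 0.0015,
    "L_g": 0.5,
    "A_c": 7.5e-2,
    "Q_dot": 4.0e-4,
    "V_dot": 5.0e-5,
}

_HALF_WIDTH_FRACTIONS: dict[str, float] = {
    "beta_b": 0.10,
    "beta_e": 0.20,
    "beta_s": 0.25,
    "D_e": 0.25,
    "D_s": 0.50,
    "L_e": 0.25,
    "L_s": 0.25,
    "L_g": 0.30,
    "A_c": 0.50,
    "Q_dot": 0.30,
    "V_dot": 0.50,
}


class InvalidParameterError(ValueError):
    """A parameter value violates the model's physical constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """A complete, validated parameter set for the four-compartment model.

    Attributes
    ----------
    beta_b, beta_e, beta_s, beta_g
        Ethanol solubility in blood, epidermis, stratum corneum, and gas,
        mL ethanol·(100 mL medium)^-1·Torr^-1.
    D_e, D_s
        Molecular diffusivity in epidermis and stratum corneum, cm^2·s^-1.
    L_e, L_s, L_g, L_c
        Thickness of epidermis, stratum corneum, gas compartment, and
        capillary layer, cm.
    A, A_c
        Skin/gas surface area and capillary exchange area, cm^2.
    Q_dot, V_dot
        Capillary blood flow and convective gas (ventilation) flow, mL·s^-1.
    T, M_etoh, R_gas
        Temperature (K), ethanol molar mass (g·mol^-1), and the gas constant
        (Torr·cm^3·mol^-1·K^-1).
    """

    beta_b: float
    beta_e: float
    beta_s: float
    D_e: float
    D_s: float
    L_e: float
    L_s: float
    L_g: float
    A_c: float
    Q_dot: float
    V_dot: float
    beta_g: float = BETA_G
    L_c: float = L_C
    A: float = AREA
    T: float = BODY_TEMP_K
    M_etoh: float = M_ETHANOL
    R_gas: float = R_GAS

    def __post_init__(self) -> None:
        for name in (
            "beta_b", "beta_e", "beta_s", "beta_g",
            "D_e", "D_s", "L_e", "L_s", "L_g", "L_c",
            "A", "A_c", "Q_dot", "V_dot", "T", "M_etoh", "R_gas",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise InvalidParameterError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {value}")
        if self.A_c > self.A:
            raise InvalidParameterError(
                f"capillary exchange area A_c={self.A_c} exceeds patch area A={self.A}"
            )

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        """Flat key-value mapping with keys named after the model symbols."""
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**dict(data))

    def replace(self, **changes: float) -> "ModelParameters":
        """A copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def save(self, path: str | Path) -> None:
        """Write the parameter set as YAML (``.yaml``/``.yml``) or JSON."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix.lower() in (".yaml", ".yml") else json.loads(text)
        if not isinstance(data, Mapping):
            raise InvalidParameterError(f"{path}: expected a mapping of parameter keys")
        return cls.from_dict(data)


@dataclass(frozen=True)
class ParameterUncertainty:
    """Uniform uncertainty specification for the eleven varied parameters.

    Each parameter has an average value and a half-width expressed as a
    fraction of the average (0.25 means +/-25%); the distribution over
    ``[avg*(1-f), avg*(1+f)]`` is uniform (rectangular) and parameters are
    independent.
    """

    averages: dict[str, float]
    fractions: dict[str, float]
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if set(self.averages) != set(VARIED_PARAMETERS) or set(self.fractions) != set(VARIED_PARAMETERS):
            raise InvalidParameterError(
                "uncertainty must cover exactly the varied parameters "
                f"{VARIED_PARAMETERS}"
            )
        if self.distribution != "uniform":
            raise InvalidParameterError(f"unsupported distribution {self.distribution!r}")
        for name in VARIED_PARAMETERS:
            avg, frac = self.averages[name], self.fractions[name]
            if avg <= 0:
                raise InvalidParameterError(f"{name}: average must be > 0, got {avg}")
            if not 0.0 < frac < 1.0:
                raise InvalidParameterError(
                    f"{name}: half-width fraction must be in (0, 1), got {frac}"
                )

    def bounds(self, name: str) -> tuple[float, float]:
        """Lower and upper bound of the uniform range for ``name``."""
        avg, frac = self.averages[name], self.fractions[name]
        return avg * (1.0 - frac), avg * (1.0 + frac)


def default_parameters() -> ModelParameters:
    """The literature-average parameter set plus fixed constants."""
    return ModelParameters(**_AVERAGES)


def default_uncertainty() -> ParameterUncertainty:
    """The published uncertainty ranges (as half-width fractions)."""
    return ParameterUncertainty(averages=dict(_AVERAGES), fractions=dict(_HALF_WIDTH_FRACTIONS))


def mass_transfer_coefficient(p: ModelParameters) -> float:
    """Epidermis-stratum-corneum mass transfer coefficient ``k_e,s``.

    Assuming a linear partial-pressure profile between the centres of the two
    layers, the interface conductance is the series combination of two
    half-layer conductances, ``2*D*beta/L`` each::

        k_e,s = [ L_e/(2 D_e beta_e) + L_s/(2 D_s beta_s) ]^-1

    Units: mL ethanol·(100 mL)^-1·cm·s^-1·Torr^-1, consistent with the flux
    terms of the balance equations.  The result is strictly smaller than
    either half-layer conductance (resistances in series add).
    """
    if not isinstance(p, ModelParameters):
        raise InvalidParameterError("p must be a ModelParameters instance")
    r_e = p.L_e / (2.0 * p.D_e * p.beta_e)
    r_s = p.L_s / (2.0 * p.D_s * p.beta_s)
    return 1.0 / (r_e + r_s)
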