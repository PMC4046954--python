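"""Environments, model configuration, and config-file loading.

Units at the user-facing surface follow field reporting conventions:
temperature in °C, photoperiod in hours of daylight, turbulent kinetic
energy dissipation rate ε in W kg⁻¹, and total prey biomass in mg m⁻³.
Internally prey biomass is converted to µg mm⁻³ (1 mg m⁻³ = 10⁻⁶ µg mm⁻³).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigParseError, ValidationError
from .traits import LarvalType, get_builtin

__all__ = [
    "Environment",
    "ModelConfig",
    "calibrated_config",
    "load_config",
    "dump_config",
    "photoperiod_from_date",
    "MG_M3_TO_UG_MM3",
]

#: 1 mg m⁻³ expressed in µg mm⁻³.
MG_M3_TO_UG_MM3 = 1e-6


@dataclass(frozen=True)
class Environment:
    """Exogenous drivers of one 24-h simulation.

    Parameters
    ----------
    T : float
        Water temperature, °C.
    photoperiod : float
        Hours of daylight in the 24-h window, in [0, 24].
    epsilon : float
        Turbulent kinetic energy dissipation rate, W kg⁻¹ (>= 0).
    b_total : float
        Total prey dry biomass over the 0.04–2 mm length range, mg m⁻³.
    s : float
        Normalized biomass size-spectrum slope (biomass density per unit
        body mass as a power law of body mass).  -1.2 is the conventional
        reference value for oligotrophic systems near equilibrium.
    """

    T: float
    photoperiod: float
    epsilon: float = 1e-7
    b_total: float = 10.0
    s: float = -1.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod <= 24.0:
            raise ValidationError("photoperiod must lie in [0, 24] h")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be non-negative")
        if self.b_total < 0:
            raise ValidationError("b_total must be non-negative")

    def replace(self, **changes) -> "Environment":
        return dataclasses.replace(self, **changes)

    @property
    def b_total_ug_mm3(self) -> float:
        """Total prey biomass in internal units, µg mm⁻³."""
        return self.b_total * MG_M3_TO_UG_MM3


@dataclass(frozen=True)
class ModelConfig:
    """Tunable model-level constants (everything that is not a larval trait).

    Attributes
    ----------
    prey_mass_coeff : float
        Coefficient *a* of the prey length–mass law m = a·lᵇ, µg at 1 mm.
        Default 2.5 µg — a typical dry mass for a 1-mm copepod.
    prey_mass_exp : float
        Exponent *b* of the length–mass law.  Default 2.03.
    prey_speed_coeff : float
        Prey swimming speed in body lengths s⁻¹ (v = coeff·l).  Default 3.0.
    kolmogorov_struct_const : float
        Structure-function constant in the inertial-subrange velocity scale
        w² = C·(ε·d)^(2/3).  Default 1.62 ≈ (55/18)·0.53.
    o2_to_drymass : float
        Oxygen-volume to dry-mass conversion, µg µl⁻¹.  Used when deriving
        respiration traits from respirometry; runtime respiration is already
        mass-based, so this constant is documentation only.
    respiration_scale, digestion_scale : float
        Global multipliers on routine respiration and digestive throughput.
        Defaults 1.0; see :func:`calibrated_config` for the shipped
        growth-potential calibration.
    bin_lo, bin_hi, bin_width : float
        Prey length domain, mm: 196 bins of 0.01 mm spanning 0.04–2.00 mm.
    growth_rate_definition : str
        "log" for G = ln(M₂₄/M₀) d⁻¹ (specific growth rate, default) or
        "arithmetic" for (M₂₄−M₀)/M₀.
    solver_log10b_lo, solver_log10b_hi : float
        Bisection bracket for critical prey concentrations, log10 mg m⁻³.
    solver_log10b_tol : float
        Bisection convergence tolerance in log10 b_total.
    satiation_tol : float
        Absolute tolerance on G (d⁻¹) for the satiation-point criterion.
    sensitivity_tol : float
        Convergence tolerance for parameter-perturbation bounds, as a
        fraction of the reference parameter value.
    """

    prey_mass_coeff: float = 2.5
    prey_mass_exp: float = 2.03
    prey_speed_coeff: float = 3.0
    kolmogorov_struct_const: float = 1.62
    o2_to_drymass: float = 0.85
    respiration_scale: float = 1.0
    digestion_scale: float = 1.0
    bin_lo: float = 0.04
    bin_hi: float = 2.00
    bin_width: float = 0.01
    growth_rate_definition: str = "log"
    solver_log10b_lo: float = -3.0
    solver_log10b_hi: float = 4.0
    solver_log10b_tol: float = 1e-4
    satiation_tol: float = 1e-6
    sensitivity_tol: float = 5e-4

    def __post_init__(self) -> None:
        for name in ("prey_mass_coeff", "prey_mass_exp",
                     "kolmogorov_struct_const", "bin_width"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.prey_speed_coeff < 0:
            raise ValidationError("prey_speed_coeff must be non-negative")
        if self.growth_rate_definition not in ("log", "arithmetic"):
            raise ValidationError(
                "growth_rate_definition must be 'log' or 'arithmetic'"
            )
        if self.n_bins < 1:
            raise ValidationError("prey length domain admits no bins")

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    @property
    def n_bins(self) -> int:
        return int(round((self.bin_hi - self.bin_lo) / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        """Strictly increasing bin edges, mm (197 edges / 196 bins by default)."""
        return np.linspace(self.bin_lo, self.bin_hi, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])


#: Respiration scaling that reconciles the printed hourly respiration traits
#: with the daily growth potentials of the four reference larvae (least-squares
#: fit of ad libitum growth at the North Sea reference conditions; see
#: docs/methods.md).  The printed traits alone make positive growth
#: arithmetically impossible in the hourly balance.
CALIBRATED_RESPIRATION_SCALE = 0.133


def calibrated_config(**overrides) -> ModelConfig:
    """A :class:`ModelConfig` with the shipped growth-potential calibration.

    Applies ``respiration_scale = 0.133`` so that ad libitum daily growth of
    the four built-in types at their North Sea reference conditions matches
    the published growth potentials (6.5–17 % d⁻¹).  All critical-prey
    solvers (starvation, satiation, prey requirement) need this calibration
    to return finite values; with the raw traits the hourly energy balance
    is negative everywhere.
    """
    overrides.setdefault("respiration_scale", CALIBRATED_RESPIRATION_SCALE)
    return ModelConfig(**overrides)


# ---------------------------------------------------------------------------
# photoperiod from date and latitude


def photoperiod_from_date(latitude_deg: float, day_of_year: int) -> float:
    """Approximate hours of daylight from latitude and day of year.

    Uses the standard sunrise equation with solar declination
    δ = 23.44°·sin(2π(284+N)/365).  Polar day/night clamp to 24/0 h.
    Accuracy is a few tenths of an hour; atmospheric refraction is ignored.
    """
    decl = math.radians(23.44) * math.sin(2 * math.pi * (284 + day_of_year) / 365)
    lat = math.radians(latitude_deg)
    cos_omega = -math.tan(lat) * math.tan(decl)
    if cos_omega <= -1.0:
        return 24.0
    if cos_omega >= 1.0:
        return 0.0
    return 24.0 * math.acos(cos_omega) / math.pi


# ---------------------------------------------------------------------------
# config-file loading

_SECTIONS = ("larva", "environment", "model")

_LARVA_KEYS = {f.name for f in dataclasses.fields(LarvalType)} - {"name"}
_ENV_KEYS = {f.name for f in dataclasses.fields(Environment)} | {
    "latitude", "day_of_year",
}
_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}

#: traits stored as fractions that users may spell as percentages
_PERCENT_TRAITS = {
    "x_ing", "x_res", "y_dig", "y_dist", "y_eff", "y_swim", "y_turb", "y_vis",
}


def _coerce(key: str, value):
    """Accept '4.11%' for fraction-valued traits; pass numbers through."""
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return float(text[:-1]) / 100.0
        try:
            return float(text)
        except ValueError as exc:
            raise ValidationError(f"field {key!r}: cannot parse {value!r}") from exc
    return value


def load_config(path_or_text, overrides: Optional[dict] = None):
    """Load a YAML config file into a validated (LarvalType, Environment, ModelConfig).

    The file has up to three sections::

        larva:
          type: cod          # built-in to start from, else full trait set
          x_res: 1.8%        # optional overrides; % suffix means fraction
        environment:
          temperature: 5.1
          photoperiod: 11.8  # or latitude: 54.5, day_of_year: 74
          epsilon: 1.0e-7
          b_total: 15        # mg m^-3
          s: -1.2
        model:
          respiration_scale: 0.124

    Parameters
    ----------
    path_or_text : str | pathlib.Path
        Path to a YAML file, or a YAML string.
    overrides : dict, optional
        ``{"section.key": value}`` entries (e.g. from CLI flags) applied on
        top of the file values.

    Returns
    -------
    (LarvalType, Environment, ModelConfig)
    """
    text = path_or_text
    if hasattr(path_or_text, "read_text"):
        text = path_or_text.read_text()
    elif isinstance(path_or_text, str) and "\n" not in path_or_text and (
        path_or_text.endswith((".yml", ".yaml")) or "/" in path_or_text
    ):
        with open(path_or_text) as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigParseError(f"malformed config{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigParseError("config must be a mapping of sections")

    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValidationError(f"unknown config section(s): {', '.join(sorted(unknown))}")

    sections = {name: dict(raw.get(name) or {}) for name in _SECTIONS}
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if section not in _SECTIONS or not key:
            raise ValidationError(f"override {dotted!r} is not 'section.key'")
        sections[section][key] = value

    # larva ---------------------------------------------------------------
    larva_raw = sections["larva"]
    type_name = larva_raw.pop("type", None)
    unknown = set(larva_raw) - _LARVA_KEYS - {"name"}
    if unknown:
        raise ValidationError(f"unknown larva key(s): {', '.join(sorted(unknown))}")
    larva_name = larva_raw.pop("name", None)
    trait_overrides = {k: _coerce(k, v) for k, v in larva_raw.items()}
    if type_name is not None:
        larva = get_builtin(str(type_name))
        if trait_overrides:
            larva = larva.replace(**trait_overrides)
    else:
        missing = {"x_body", "x_ing", "x_len", "x_res", "x_rQ10", "x_tol"} - set(
            trait_overrides
        )
        if missing:
            raise ValidationError(
                "larva section needs 'type' or a full trait set; missing "
                + ", ".join(sorted(missing))
            )
        larva = LarvalType(name=str(larva_name or "custom"), **trait_overrides)

    # environment ---------------------------------------------------------
    env_raw = {k: _coerce(k, v) for k, v in sections["environment"].items()}
    if "temperature" in env_raw:
        env_raw["T"] = env_raw.pop("temperature")
    unknown = set(env_raw) - _ENV_KEYS - {"T"}
    if unknown:
        raise ValidationError(
            f"unknown environment key(s): {', '.join(sorted(unknown))}"
        )
    if "photoperiod" not in env_raw and {"latitude", "day_of_year"} <= set(env_raw):
        env_raw["photoperiod"] = photoperiod_from_date(
            env_raw.pop("latitude"), int(env_raw.pop("day_of_year"))
        )
    env_raw.pop("latitude", None)
    env_raw.pop("day_of_year", None)
    if "T" not in env_raw:
        raise ValidationError("environment section requires 'temperature'")
    if "photoperiod" not in env_raw:
        raise ValidationError(
            "environment section requires 'photoperiod' (or latitude + day_of_year)"
        )
    env = Environment(**env_raw)

    # model ---------------------------------------------------------------
    model_raw = {
        k: v if k == "growth_rate_definition" else _coerce(k, v)
        for k, v in sections["model"].items()
    }
    unknown = set(model_raw) - _MODEL_KEYS
    if unknown:
        raise ValidationError(f"unknown model key(s): {', '.join(sorted(unknown))}")
    cfg = ModelConfig(**model_raw)

    return larva, env, cfg


def dump_config(larva: LarvalType, env: Environment, cfg: ModelConfig) -> str:
    """Serialize a validated bundle back to YAML (inverse of :func:`load_config`)."""
    doc = {
        "larva": {"name": larva.name, **{k: v for k, v in larva.to_dict().items()
                                         if k != "name"}},
        "environment": dataclasses.asdict(env),
        "model": dataclasses.asdict(cfg),
    }
    return yaml.safe_dump(doc, sort_keys=False)
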