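"""Larval trait sets and the four built-in species parameterizations.

A larva is fully described by 16 endogenous traits.  Traits prefixed ``x_``
are species-specific (body shape, mouth gape, initial length, respiration,
thermal tolerance); traits prefixed ``y_`` are generic across the four
built-in types (foraging behaviour and digestion).  Percent-valued traits
are stored as fractions throughout (e.g. a swimming speed of 75 % of body
length per second is ``y_swim = 0.75``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["LarvalType", "builtin_types", "get_builtin", "BUILTIN_NAMES"]


@dataclass(frozen=True)
class LarvalType:
    """One larval parameterization.

    Attributes
    ----------
    name : str
        Label for the type (e.g. ``"cod"``).
    x_body : float
        Body shape, µg mm⁻³ — upper bound on Fulton's condition M/L³.
    x_ing : float
        Maximum ingestible prey length as a fraction of standard length L.
    x_len : float
        Initial standard length, mm.
    x_res : float
        Routine respiration at 10 °C, fraction of dry mass M per hour.
    x_rQ10 : float
        Respiratory Q10.
    x_tol : float
        Upper thermal tolerance, °C.
    y_act : float
        Active (foraging) respiration as a multiple of routine respiration.
    y_det : float
        Prey length detected with 50 % success, mm.
    y_dig : float
        Digestive throughput at 10 °C, fraction of M per hour.
    y_dQ10 : float
        Digestive Q10.
    y_dist : float
        Predator–prey separation at encounter, fraction of L.
    y_eff : float
        Metabolic efficiency (assimilation net of specific dynamic action).
    y_hand : float
        Prey handling time, s.
    y_swim : float
        Effective swimming speed, fraction of L per second.
    y_turb : float
        Maximum corrigible turbulent velocity, fraction of L per second.
    y_vis : float
        Effective visual cylinder radius, fraction of L.
    """

    name: str
    x_body: float
    x_ing: float
    x_len: float
    x_res: float
    x_rQ10: float
    x_tol: float
    y_act: float = 2.0
    y_det: float = 0.07
    y_dig: float = 0.025
    y_dQ10: float = 2.5
    y_dist: float = 0.50
    y_eff: float = 0.675
    y_hand: float = 1.5
    y_swim: float = 0.75
    y_turb: float = 1.00
    y_vis: float = 0.60

    def __post_init__(self) -> None:
        positive = (
            "x_body", "x_ing", "x_len", "x_res", "y_det", "y_dig", "y_dist",
            "y_eff", "y_hand", "y_swim", "y_turb", "y_vis",
        )
        for field in positive:
            if not getattr(self, field) > 0:
                raise ValidationError(f"{field} must be strictly positive")
        if self.y_eff > 1:
            raise ValidationError("y_eff must be a fraction in (0, 1]")
        if not self.x_rQ10 > 1 or not self.y_dQ10 > 1:
            raise ValidationError("Q10 factors must exceed 1")
        if not self.y_act >= 1:
            raise ValidationError("y_act must be >= 1 (multiple of routine respiration)")
        # at least one prey bin (lower domain edge 0.04 mm) must be ingestible
        if not self.x_ing * self.x_len > 0.04:
            raise ValidationError(
                "x_ing * x_len must exceed 0.04 mm (no ingestible prey bin)"
            )

    def replace(self, **changes) -> "LarvalType":
        """Return a copy with the given traits overridden (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def max_ingestible_length(self) -> float:
        """Maximum ingestible prey length x_ing·x_len at the initial size, mm."""
        return self.x_ing * self.x_len

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Species-specific traits; generic traits take the dataclass defaults.
_BUILTINS = {
    "anchovy": dict(x_body=0.226, x_ing=0.0805, x_len=5.5,
                    x_res=0.0411, x_rQ10=1.39, x_tol=25.0),
    "cod": dict(x_body=1.04, x_ing=0.157, x_len=7.0,
                x_res=0.0203, x_rQ10=2.38, x_tol=15.0),
    "herring": dict(x_body=0.168, x_ing=0.0784, x_len=13.0,
                    x_res=0.0240, x_rQ10=1.71, x_tol=20.0),
    # sprat respiration traits estimated by the herring values
    "sprat": dict(x_body=0.0684, x_ing=0.0384, x_len=7.0,
                  x_res=0.0240, x_rQ10=1.71, x_tol=16.0),
}

BUILTIN_NAMES = tuple(_BUILTINS)


def builtin_types() -> list[LarvalType]:
    """Return the four built-in larval types: anchovy, cod, herring, sprat.

    These parameterize young exogenously feeding larvae of European anchovy
    (5.5 mm), Atlantic cod (7 mm), Atlantic herring (13 mm), and European
    sprat (7 mm).
    """
    return [LarvalType(name=name, **traits) for name, traits in _BUILTINS.items()]


def get_builtin(name: str) -> LarvalType:
    """Look up one built-in type by (case-insensitive) name."""
    key = name.lower()
    if key not in _BUILTINS:
        raise ValidationError(
            f"unknown larval type {name!r}; built-ins are {', '.join(_BUILTINS)}"
        )
    return LarvalType(name=key, **_BUILTINS[key])
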