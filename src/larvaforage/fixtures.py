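"""Seeded generator of synthetic trait sets and scenario tables.

These fixtures support testing and exploratory batch runs: random but
plausible larval types are drawn around the built-in parameterizations, and
scenario grids span the environmental envelope over which the model has
been exercised (roughly 3–24 °C and 9–24 h daylight).  The generator is the
only randomised component of the package; everything downstream of a
scenario is deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .config import Environment
from .errors import ValidationError
from .traits import LarvalType, builtin_types

__all__ = ["Scenario", "random_types", "scenario_table", "generate_fixtures"]

#: traits varied by the generator (±50 % of the built-in range)
_VARIED = (
    "x_body", "x_ing", "x_res", "x_rQ10",
    "y_act", "y_det", "y_dig", "y_eff", "y_hand", "y_swim", "y_vis",
)


@dataclass(frozen=True)
class Scenario:
    """One labelled run: a larval type name (or inline traits) plus drivers."""

    label: str
    larva: str | dict
    T: float
    photoperiod: float
    epsilon: float
    b_total: float
    s: float

    def environment(self) -> Environment:
        return Environment(
            T=self.T, photoperiod=self.photoperiod, epsilon=self.epsilon,
            b_total=self.b_total, s=self.s,
        )

    def to_config_yaml(self) -> str:
        larva = {"type": self.larva} if isinstance(self.larva, str) else dict(self.larva)
        doc = {
            "larva": larva,
            "environment": {
                "temperature": self.T,
                "photoperiod": self.photoperiod,
                "epsilon": self.epsilon,
                "b_total": self.b_total,
                "s": self.s,
            },
        }
        return yaml.safe_dump(doc, sort_keys=False)


def random_types(seed: int, n: int) -> list[LarvalType]:
    """Draw ``n`` synthetic trait sets, uniform within ±50 % of the spread
    of the built-in values for each varied trait (re-drawn if invalid)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    builtins = builtin_types()
    out: list[LarvalType] = []
    while len(out) < n:
        base = builtins[rng.integers(len(builtins))]
        changes = {}
        for trait in _VARIED:
            values = [getattr(t, trait) for t in builtins]
            lo, hi = min(values), max(values)
            span = hi - lo if hi > lo else hi * 0.2
            low = max(lo - 0.5 * span, 1e-6)
            high = hi + 0.5 * span
            changes[trait] = float(rng.uniform(low, high))
        changes["y_eff"] = min(changes.get("y_eff", base.y_eff), 1.0)
        changes["y_act"] = max(changes.get("y_act", base.y_act), 1.0)
        for q10 in ("x_rQ10",):
            changes[q10] = max(changes[q10], 1.01)
        try:
            out.append(base.replace(name=f"synthetic-{len(out)}", **changes))
        except ValidationError:
            continue
    return out


def scenario_table(seed: int, n: int) -> list[Scenario]:
    """Draw ``n`` scenarios over the validation envelope.

    Temperature spans 3–24 °C (clipped to each type's thermal tolerance),
    photoperiod 9–24 h, ε log-uniform over 10⁻¹²–10⁻⁴ W kg⁻¹ (plus calm
    water), prey biomass log-uniform over 0.1–100 mg m⁻³, and spectrum
    slope uniform over [−2.5, −0.5].
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    builtins = builtin_types()
    scenarios = []
    for k in range(n):
        larva = builtins[rng.integers(len(builtins))]
        T = float(np.clip(rng.uniform(3.0, 24.0), None, larva.x_tol - 0.1))
        eps = 0.0 if rng.random() < 0.2 else float(10.0 ** rng.uniform(-12, -4))
        scenarios.append(
            Scenario(
                label=f"scenario-{k}",
                larva=larva.name,
                T=round(T, 2),
                photoperiod=round(float(rng.uniform(9.0, 24.0)), 2),
                epsilon=eps,
                b_total=round(float(10.0 ** rng.uniform(-1, 2)), 4),
                s=round(float(rng.uniform(-2.5, -0.5)), 2),
            )
        )
    return scenarios


def generate_fixtures(seed: int, n: int, out_dir=None):
    """Write (or return) a deterministic scenario table and trait sets.

    Returns ``(scenarios, types)``; with ``out_dir`` also writes
    ``scenarios.csv`` and ``types.csv`` there.
    """
    scenarios = scenario_table(seed, n)
    types = random_types(seed + 1, n)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(s) for s in scenarios]).to_csv(
            out / "scenarios.csv", index=False
        )
        pd.DataFrame([t.to_dict() for t in types]).to_csv(
            out / "types.csv", index=False
        )
    return scenarios, types
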