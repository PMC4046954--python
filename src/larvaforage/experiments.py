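"""Model experiments: growth potential, critical prey concentrations,
parameter-perturbation sensitivity, and optimal-foraging analyses.

All critical-concentration solvers bisect on log10 of total prey biomass
(mg m⁻³) over a bracket spanning well beyond observed plankton
concentrations, exploiting that daily growth is monotone non-decreasing in
prey biomass.  Sensitivity ranges follow the individual-parameter
perturbation protocol: for one parameter at a time, find the multiplicative
interval around the reference value within which the chosen output changes
by less than ±10 %.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioenergetics import simulate_day
from .config import Environment, ModelConfig
from .errors import SolverError, ThermalToleranceError, ValidationError
from .foraging import capture_success
from .prey import length_to_mass
from .traits import LarvalType

__all__ = [
    "SensitivityRange",
    "OptimaReport",
    "reference_conditions",
    "growth_potential",
    "starvation_point",
    "satiation_point",
    "prey_requirement",
    "sensitivity_range",
    "optimal_prey_length",
    "optimal_spectrum_slope",
    "turbulence_response",
    "optima_report",
]

#: marker for a perturbation direction in which the output never leaves
#: the ±10 % band (an open bound).
UNBOUNDED = math.inf


@dataclass(frozen=True)
class SensitivityRange:
    """Multiplicative perturbation interval leaving an output within ±10 %.

    ``low_pct``/``high_pct`` are percentages of the reference parameter
    value (100 = unperturbed); 0 and ``inf`` encode open bounds.
    """

    parameter: str
    output_kind: str
    low_pct: float
    high_pct: float
    reference_output: float

    def __post_init__(self) -> None:
        if not (self.low_pct <= 100.0 <= self.high_pct):
            raise ValidationError("sensitivity range must straddle 100 %")


@dataclass(frozen=True)
class OptimaReport:
    """Optimal foraging conditions for one larval type."""

    name: str
    L: float
    max_ingestible_mm: float
    optimal_prey_mm: float
    optimal_ratio: float
    optimal_s: float | None = None
    optimal_epsilon: float | None = None


# ---------------------------------------------------------------------------
# reference conditions

#: North Sea reference conditions for young larvae two weeks after the
#: midpoint of each species' spawning season: (T °C, photoperiod h).
_REFERENCE = {
    "anchovy": (15.0, 15.9),
    "cod": (5.1, 11.8),
    "herring": (14.7, 11.6),
    "sprat": (8.9, 16.0),
}


def reference_conditions(name: str, **overrides) -> Environment:
    """Species-specific reference environment (s = −1.2, ε = 10⁻⁷ W kg⁻¹).

    Temperature and photoperiod represent average central North Sea
    conditions shortly after peak spawning of each species.
    """
    key = name.lower()
    if key not in _REFERENCE:
        raise ValidationError(f"no reference conditions for {name!r}")
    T, photoperiod = _REFERENCE[key]
    env = Environment(T=T, photoperiod=photoperiod, epsilon=1e-7, s=-1.2)
    return env.replace(**overrides) if overrides else env


# ---------------------------------------------------------------------------
# growth potential and critical prey concentrations


def growth_potential(
    larva: LarvalType,
    T: float | None = None,
    photoperiod: float | None = None,
    cfg: ModelConfig | None = None,
    env: Environment | None = None,
) -> float:
    """Daily growth under ad libitum feeding (d⁻¹).

    Every lit hour ingests the full digestive capacity, so the result is
    independent of the prey field and of turbulence by construction.
    """
    cfg = cfg or ModelConfig()
    if env is None:
        if T is None or photoperiod is None:
            raise ValidationError("give either env or both T and photoperiod")
        env = Environment(T=T, photoperiod=photoperiod, epsilon=0.0)
    return simulate_day(larva, env, cfg, ad_libitum=True).G


def _growth_at(b_total: float, larva, env, cfg) -> float:
    return simulate_day(larva, env.replace(b_total=b_total), cfg).G


def _bisect_threshold(larva, env, cfg, target: float, what: str) -> float:
    """Smallest b_total (mg m⁻³) with G(b_total) >= target (G is monotone)."""
    lo, hi = cfg.solver_log10b_lo, cfg.solver_log10b_hi
    if _growth_at(10.0**hi, larva, env, cfg) < target:
        raise SolverError(
            f"{what}: G stays below target even at b_total = 1e{hi:g} mg m^-3 "
            f"(growth potential may be insufficient)"
        )
    if _growth_at(10.0**lo, larva, env, cfg) >= target:
        return 10.0**lo
    while hi - lo > cfg.solver_log10b_tol:
        mid = 0.5 * (lo + hi)
        if _growth_at(10.0**mid, larva, env, cfg) >= target:
            hi = mid
        else:
            lo = mid
    return 10.0**hi


def starvation_point(
    larva: LarvalType, env: Environment, cfg: ModelConfig | None = None
) -> float:
    """Minimum total prey biomass (mg m⁻³) for non-negative daily growth."""
    cfg = cfg or ModelConfig()
    return _bisect_threshold(larva, env, cfg, 0.0, "starvation point")


def satiation_point(
    larva: LarvalType, env: Environment, cfg: ModelConfig | None = None
) -> float:
    """Minimum total prey biomass (mg m⁻³) achieving the full growth potential."""
    cfg = cfg or ModelConfig()
    G_max = growth_potential(larva, env=env.replace(epsilon=0.0), cfg=cfg)
    return _bisect_threshold(
        larva, env, cfg, G_max - cfg.satiation_tol, "satiation point"
    )


def prey_requirement(
    larva: LarvalType,
    env: Environment,
    cfg: ModelConfig | None = None,
    G_target: float = 0.05,
) -> float:
    """Total prey biomass (mg m⁻³) required for growth of exactly ``G_target`` d⁻¹."""
    cfg = cfg or ModelConfig()
    return _bisect_threshold(
        larva, env, cfg, G_target, f"prey requirement (G = {G_target:g}/d)"
    )


# ---------------------------------------------------------------------------
# sensitivity analysis

_ENV_PARAMS = {"temperature": "T", "photoperiod": "photoperiod",
               "epsilon": "epsilon", "s": "s"}
_TRAIT_PARAMS = {
    "x_body", "x_ing", "x_len", "x_res", "x_rQ10", "x_tol",
    "y_act", "y_det", "y_dig", "y_dQ10", "y_dist", "y_eff",
    "y_hand", "y_swim", "y_turb", "y_vis",
}


def _perturbed(larva, env, parameter, r):
    """Scale one parameter by the factor r.

    Temperature and x_tol are perturbed on their °C value (so r multiplies
    the Celsius reading, not an absolute scale).
    """
    if parameter in _ENV_PARAMS:
        field = _ENV_PARAMS[parameter]
        return larva, env.replace(**{field: getattr(env, field) * r})
    if parameter in _TRAIT_PARAMS:
        return larva.replace(**{parameter: getattr(larva, parameter) * r}), env
    raise ValidationError(f"parameter {parameter!r} cannot be perturbed")


def sensitivity_range(
    parameter: str,
    output_kind: str,
    larva: LarvalType,
    env: Environment,
    cfg: ModelConfig | None = None,
    G_target: float = 0.05,
) -> SensitivityRange:
    """Perturbation interval within which the output changes by < ±10 %.

    ``output_kind`` is ``"growth_potential"`` or ``"prey_requirement"``.
    Each bound is located by bisection on the multiplicative factor r; a
    direction is reported open (0 or inf) when even a ten-fold perturbation
    leaves the output inside the band.  An unattainable output under the
    perturbed parameters (e.g. growth below target) counts as a >10 %
    change.
    """
    cfg = cfg or ModelConfig()
    if parameter not in _ENV_PARAMS and parameter not in _TRAIT_PARAMS:
        raise ValidationError(f"parameter {parameter!r} cannot be perturbed")

    def output(larva_p, env_p) -> float:
        if output_kind == "growth_potential":
            return growth_potential(larva_p, env=env_p.replace(epsilon=0.0), cfg=cfg)
        if output_kind == "prey_requirement":
            return prey_requirement(larva_p, env_p, cfg, G_target=G_target)
        raise ValidationError(f"unknown output kind {output_kind!r}")

    def outside(r: float) -> bool:
        try:
            larva_p, env_p = _perturbed(larva, env, parameter, r)
            value = output(larva_p, env_p)
        except (SolverError, ValidationError, ThermalToleranceError):
            # unattainable output (or thermally excluded larva) is a >10% change
            return True
        return abs(value - ref) >= 0.1 * abs(ref)

    ref = output(larva, env)
    if not math.isfinite(ref) or ref == 0:
        raise SolverError(
            f"reference {output_kind} is not finite and nonzero ({ref!r})"
        )

    bounds = {}
    for direction, probe in (("low", 0.1), ("high", 10.0)):
        if not outside(probe):
            bounds[direction] = 0.0 if direction == "low" else UNBOUNDED
            continue
        lo, hi = (probe, 1.0) if direction == "low" else (1.0, probe)
        # invariant: output is inside the band at the end nearer 1
        while hi - lo > cfg.sensitivity_tol:
            mid = 0.5 * (lo + hi)
            if outside(mid):
                if direction == "low":
                    lo = mid
                else:
                    hi = mid
            else:
                if direction == "low":
                    hi = mid
                else:
                    lo = mid
        bounds[direction] = 0.5 * (lo + hi)

    return SensitivityRange(
        parameter=parameter,
        output_kind=output_kind,
        low_pct=bounds["low"] * 100.0,
        high_pct=bounds["high"] * 100.0,
        reference_output=ref,
    )


# ---------------------------------------------------------------------------
# optimal foraging analyses


def optimal_prey_length(
    larva: LarvalType, cfg: ModelConfig | None = None
) -> tuple[float, float]:
    """Prey length maximizing expected ingested mass per encounter.

    Profitability per encounter is e_i/y_hand = P·C_i·m_i/y_hand; with P
    and y_hand constant across bins the argmax reduces to m_i·C_i, the
    trade-off between larger prey mass and falling capture success.

    Returns
    -------
    (l_opt, ratio) : (float, float)
        The optimal bin-centre length (mm) and its ratio to the maximum
        ingestible length x_ing·L.
    """
    cfg = cfg or ModelConfig()
    centers = cfg.bin_centers
    L = larva.x_len
    C = capture_success(centers, L, larva.x_ing)
    m = length_to_mass(centers, cfg)
    benefit = m * C
    if not np.any(benefit > 0):
        raise SolverError(f"{larva.name}: no ingestible prey bin")
    l_opt = float(centers[int(np.argmax(benefit))])
    return l_opt, l_opt / (larva.x_ing * L)


def _golden_min(f, lo: float, hi: float, xtol: float) -> float:
    """Golden-section minimizer (deterministic, derivative-free)."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > xtol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def optimal_spectrum_slope(
    larva: LarvalType,
    env: Environment,
    cfg: ModelConfig | None = None,
    objective: str = "starvation",
    s_lo: float = -4.0,
    s_hi: float = 0.0,
    xtol: float = 0.01,
) -> float:
    """Size-spectrum slope s* minimizing the starvation (or satiation) point.

    The slope fully determines the relative prey-size distribution, so s*
    identifies the most favourable plankton size structure for the larva.
    Golden-section search over [s_lo, s_hi].
    """
    cfg = cfg or ModelConfig()
    solver = {"starvation": starvation_point, "satiation": satiation_point}.get(
        objective
    )
    if solver is None:
        raise ValidationError("objective must be 'starvation' or 'satiation'")

    def f(s: float) -> float:
        try:
            return solver(larva, env.replace(s=s), cfg)
        except SolverError:
            return math.inf

    return _golden_min(f, s_lo, s_hi, xtol)


def turbulence_response(
    larva: LarvalType,
    env: Environment,
    cfg: ModelConfig | None = None,
    epsilon_grid=None,
) -> pd.DataFrame:
    """Starvation and satiation points across turbulence levels.

    Default grid: ε = 0 plus decades 10⁻¹² … 10⁻⁴ W kg⁻¹.  Rows where
    feeding is infeasible (pursuit success zero for every bin) carry
    infinite critical concentrations.
    """
    cfg = cfg or ModelConfig()
    if epsilon_grid is None:
        epsilon_grid = [0.0] + [10.0**k for k in range(-12, -3)]
    epsilon_grid = list(epsilon_grid)
    if not epsilon_grid:
        raise ValidationError("epsilon grid must be nonempty")
    rows = []
    for eps in epsilon_grid:
        env_eps = env.replace(epsilon=eps)
        try:
            starv = starvation_point(larva, env_eps, cfg)
            sat = satiation_point(larva, env_eps, cfg)
        except SolverError:
            starv = sat = math.inf
        rows.append({"epsilon": eps, "starvation": starv, "satiation": sat})
    return pd.DataFrame(rows)


def optima_report(
    larva: LarvalType,
    cfg: ModelConfig | None = None,
    env: Environment | None = None,
    with_slope: bool = False,
) -> OptimaReport:
    """Summarize optimal foraging conditions for one larval type.

    Always reports the maximum ingestible and optimal prey lengths; with
    ``with_slope`` also solves for the optimal spectrum slope (requires a
    calibration under which growth is attainable) and reports the optimal
    turbulence level (ε = 0: the net turbulence effect is negative at the
    parameterized swimming speeds).
    """
    cfg = cfg or ModelConfig()
    l_opt, ratio = optimal_prey_length(larva, cfg)
    s_opt = eps_opt = None
    if with_slope:
        env = env or reference_conditions(larva.name)
        s_opt = optimal_spectrum_slope(larva, env, cfg)
        eps_opt = 0.0
    return OptimaReport(
        name=larva.name,
        L=larva.x_len,
        max_ingestible_mm=larva.max_ingestible_length,
        optimal_prey_mm=l_opt,
        optimal_ratio=ratio,
        optimal_s=s_opt,
        optimal_epsilon=eps_opt,
    )
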