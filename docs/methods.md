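# Methods

This note records the model as implemented, the parameter choices that
matter, and the design decisions taken where the published description of
this class of larval-fish foraging models leaves latitude.

## Model structure

One simulation covers 24 hourly steps: one night followed by one day.
Daylight occupies the final `photoperiod` hours of the window; the dawn
step may be fractional (`λ_t` is the overlap of hour `t` with the daylight
interval, so `Σλ_t = photoperiod` exactly). State is standard length `L`
(mm) and dry mass `M` (µg), initialized at `L₀ = x_len` and
`M₀ = x_body·x_len³`, i.e. at the maximum condition the body-shape trait
allows. All rates are evaluated on start-of-hour state (explicit Euler on
the hourly grid); the update is

```
M′ = M + y_eff·I − A·R,    L′ = max(L, (M′/x_body)^(1/3))
```

so length growth is isometric and mass loss never shortens the larva. If
`M′` would go non-positive the larva is flagged dead and its mass floored
at 10⁻⁹ µg so a (very negative) growth rate can still be reported. The
daily specific growth rate is `G = ln(M₂₄/M₀)` per day; an arithmetic
definition `(M₂₄−M₀)/M₀` is available behind
`ModelConfig.growth_rate_definition` for comparison with studies that
report relative mass change.

Temperatures above the trait `x_tol` raise a `ThermalToleranceError`
rather than extrapolating physiology: thermal limits do not emerge
mechanistically from this model and growth would otherwise increase
unrealistically right up to lethal temperatures.

### Respiration, digestion, ingestion

Routine respiration is a fraction of dry mass per hour at 10 °C
(`x_res`), Q10-corrected (`x_rQ10`), and multiplied during daylight by the
activity factor `A = 1 + (y_act−1)·λ_t` — active metabolism is `y_act`
times routine, interpolating linearly over the fractional dawn hour.
Digestive capacity is `y_dig·M` at 10 °C, Q10-corrected (`y_dQ10`).
Hourly ingestion is the lesser of digestive capacity and what foraging
delivers during the lit fraction: `I = min(D, 3600·λ_t·F)`. Note one
boundary choice: with unbounded foraging, a fractional lit hour still
ingests the full `D` rather than `λ_t·D`; the min-rule above is the
implemented contract.

### The predation sequence

Encounters per second with prey bin `i` are
`E_i = c_i · π(y_vis·L)² · V_i · O_i`: numeric concentration times the
volume of the visually scanned cylinder, discounted by detection.

- Combined velocity `V = √(u² + v² + w²)` with `u = y_swim·L` and
  `v = prey_speed_coeff·l` (default 3 body lengths s⁻¹, typical of
  sub-millimetre zooplankton). The root-sum-of-squares form was chosen
  over the Gerritsen–Strickler ratio form for its symmetry and simplicity;
  at the parameterized speeds the printed clearance rates (below) are
  insensitive to the choice.
- Turbulent velocity from inertial-subrange scaling,
  `w = √(1.62·(ε·d)^(2/3))` at the encounter separation `d = y_dist·L`,
  with ε converted to mm² s⁻³. The constant 1.62 is (55/18) times the
  universal Kolmogorov constant 0.53.
- Detection `O = l/(l + y_det)` (type-2; prey of length `y_det` are
  half-detected), pursuit `P = max(0, 1 − w/(y_turb·L))`, capture
  `C = max(0, 1 − l/(x_ing·L))`.

Intake follows the Holling disk equation over an optimally chosen diet:
`F = Σ_S E_i·e_i / (1 + y_hand·Σ_S E_i)` with per-encounter gain
`e_i = P·C_i·m_i`. The diet S follows the classic zero-one rule — rank
bins by profitability `e_i/y_hand` and include while F still rises —
which attains the global maximum over all subsets (verified against an
exhaustive-subset oracle in the tests). Handling time is charged per
encounter with any diet-included prey, regardless of pursuit/capture
outcome; ties in the profitability ranking break toward the smaller bin.

These choices reproduce the volumetric foraging rates that anchor the
parameterization: searched volumes of 0.5 / 1.0 / 1.0 / 6.7 l h⁻¹ for
anchovy / cod / sprat / herring, and detection-corrected clearances on
0.2-mm prey of 0.38 / 0.78 / 5.0 l h⁻¹ (anchovy / cod / herring).

### Prey fields

196 bins of 0.01 mm span 0.04–2.00 mm (bin centres 0.045 … 1.995 mm).
Individual dry mass follows `m = a·l^b` with defaults `a = 2.5` µg at
1 mm and `b = 2.03`. The published fit behind this law is not available
(only its sample size and r² are), so the defaults are this package's own
calibration: `b` is pinned by the continuous-limit optimal-prey relation
`l*/l_max = b/(b+1) ≈ 67 %`, and `a` is a typical 1-mm copepod dry mass.
The normalized-spectrum assumption — biomass density per unit body mass
∝ `mˢ` — makes bin biomass the analytic integral
`(m_hi^{s+1} − m_lo^{s+1})/(s+1)` (logarithmic for `s = −1`), normalized
to `Σb_i = b_total`. Consequently `a` cancels from the relative size
distribution; only handling-time saturation and count-based diagnostics
depend on it, and the starvation point is insensitive to `a` whenever
`y_hand·ΣE ≪ 1`.

## The respiration calibration

The shipped hourly traits are mutually inconsistent: with routine
respiration at 2–4 % M h⁻¹ (doubled while foraging), digestion at
2.5 % M h⁻¹, and 67.5 % efficiency, the hourly balance
`y_eff·D − y_act·R` is negative for every built-in type at any
temperature, so no prey concentration yields positive growth — yet the
same parameterizations are credited with daily growth potentials of
6.5–17 % d⁻¹. The package keeps the traits exactly as printed and exposes
two global multipliers in `ModelConfig` (`respiration_scale`,
`digestion_scale`, both defaulting to 1.0) as the calibration surface.

`calibrated_config()` applies `respiration_scale = 0.133`, the
least-squares fit that makes ad libitum growth at the four North Sea
reference conditions match the published potentials (fit reproduces
16.8 / 6.6 / 16.3 / 12.3 % d⁻¹ against 16 / 6.5 / 17 / 13). All
critical-concentration solvers need this (or an equivalent user
calibration) to return finite values. Quantities that are ratios of the
foraging side — sensitivity bounds such as the y_vis inverse-square law,
optimal prey lengths, Chesson's α — are invariant to the scaling;
absolute starvation/satiation magnitudes inherit its uncertainty and
should be read as calibrated, not predicted (under the shipped scaling
they come out within ~15 % of the reference-condition values of
7.4 / 7.1 / 2.7 / 1.4 mg m⁻³ for starvation, further off for satiation).

## Reference conditions

Species-specific sensitivity analyses use central North Sea conditions two
weeks after each species' peak spawning: anchovy 15.0 °C / 15.9 h, cod
5.1 °C / 11.8 h, herring 14.7 °C / 11.6 h, sprat 8.9 °C / 16.0 h, all with
`s = −1.2` and `ε = 10⁻⁷ W kg⁻¹` (wind-driven turbulence at depth in storm
conditions, or near-surface in calm ones).

## Solvers and numerical choices

- Critical prey concentrations (starvation, satiation, requirement for a
  target G) bisect on `log10 b_total` over 10⁻³–10⁴ mg m⁻³, tolerance
  10⁻⁴ in log10 (≈ 0.02 % in concentration), exploiting monotonicity of G
  in `b_total`. Satiation uses an absolute band of 10⁻⁶ d⁻¹ below the
  growth potential, well under reporting precision.
- Sensitivity ranges perturb one parameter multiplicatively; each ±10 %
  output boundary is bisected to 0.05 % of the reference parameter.
  Directions in which even a ten-fold perturbation stays inside the band
  are reported open (0 / ∞). Temperature and `x_tol` are perturbed on
  their °C value. An unattainable output (e.g. growth below the 5 %
  target) counts as a >10 % change. The implemented band is symmetric:
  `|Φ(r·θ) − Φ₀| < 0.1·|Φ₀|` in both directions.
- The optimal spectrum slope minimizes the starvation (or satiation)
  point by golden-section search over `s ∈ [−4, 0]`, tolerance 0.01.
- Chesson's α divides per-bin ingestion rate by ambient numeric
  concentration and normalizes to 1 over occupied bins, so it is
  invariant to `b_total`; the reported peak is the argmax bin centre.

## The synthetic-scenario generator

`generate_fixtures(seed, n)` draws larval trait sets uniformly within
±50 % of the spread of the built-in values and scenarios spanning the
envelope over which the model has been exercised: 3–24 °C (clipped below
each type's thermal tolerance), 9–24 h daylight, ε log-uniform over
10⁻¹²–10⁻⁴ W kg⁻¹ plus calm water, prey biomass 0.1–100 mg m⁻³, slopes
−2.5 … −0.5. It emulates the *coverage* of real validation conditions,
not real data: prey fields are ideal power-law spectra, light is binary,
and encounters are deterministic averages. Passing tests on these
fixtures therefore demonstrate internal consistency and numerical
correctness, not field skill.

## Known limitations

- No gut-content state: larvae cannot bank a full gut across steps, and
  stochastic encounter variability is replaced by its mean.
- Light is day/night only; no light-intensity continuum or visual-range
  dependence on irradiance or turbidity.
- Thermal tolerance is a hard exclusion threshold, not a mechanistic
  decline in aerobic scope.
- Traits are fixed within a day and parameterized for a ~2-mm length
  window; multi-day growth trajectories would outgrow them.
- Absolute growth and threshold magnitudes depend on the respiration
  calibration described above.
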