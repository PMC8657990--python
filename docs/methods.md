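# Methods

## The reaction network

The assay measures the second-order rate constant of HNO (azanone) with a
carbon-centred nucleophile by competition against a reference channel of
known rate.  The modelled network is:

| reaction | rate law | default constant |
|---|---|---|
| AS → HNO (+ nitrite co-product) | k_AS [AS] | 8.0 × 10⁻⁴ s⁻¹ |
| HNO + O₂ → ONOO⁻ | k_O2 [O₂][HNO] | 1.8 × 10⁴ M⁻¹s⁻¹ |
| HNO + nucleophile → adduct | k_nuc [nuc][HNO] | the unknown |
| 2 HNO → N₂O + H₂O | k_dim [HNO]² per event | 8 × 10⁶ M⁻¹s⁻¹ |
| ONOO⁻ + FlBA → FlOH + NO₂⁻ | k_FlBA [FlBA][ONOO⁻] | 1 × 10⁶ M⁻¹s⁻¹ |

AS is Angeli's salt (the HNO donor), FlBA the fluorescein boronate probe
and FlOH fluorescein, read out at 490 nm.  Reference conditions: 20 µM
AS, 25 µM FlBA, 225 µM O₂, 600 s observation, 1 cm path, pH 7.4
(metadata only — no acid–base speciation is modelled).

Internal units are SI molar and seconds throughout; rate constants span
ten orders of magnitude, and mixed µM/M arithmetic is the classic source
of silent errors here.  Convenience constructors accept µM.

Stoichiometric choices: one HNO per donor decomposed (unit yield,
configurable in (0, 1]); the donor's nitrite co-product is not tracked
(it touches no modelled channel); probe turnover converts ONOO⁻ to FlOH
and NO₂⁻ one-to-one.  No HNO–probe or HNO–adduct side channels are
included.  ONOO⁻ self-decomposition is excluded by default (the probe
channel dominates at 25 µM probe); a first-order `k_onoo_decay` exists
for sensitivity analysis only, and the closed forms below assume it is
zero.

O₂ is clamped at its initial value by default: it is in ≥10-fold excess
over the donor, so maximal depletion is ≤9%, and the competition law
treats [O₂] as a known constant.  Whether the cuvette re-equilibrates
with air during a run is not knowable from the assay description, so the
clamp is also the assumption most consistent with how the law is used; a
dynamic-O₂ mode (`o2_clamped=False`) is kept for sensitivity checks.

## Integration

`integrate_full_model` uses `scipy.integrate.solve_ivp` (LSODA) with
rtol 1 × 10⁻⁸ and atol 1 × 10⁻¹⁴ M.  The absolute tolerance matters: the
HNO steady state at reference conditions is ≈4 nM and inhibited runs
push it to tens of pM, which a looser atol would flush to noise.  The
returned trajectories are checked in the test suite against a
fixed-step RK4 integrator written independently of the package rhs, and
against two bookkeeping identities that hold exactly in the chemistry:
released nitrogen = HNO + ONOO⁻ + probe-derived NO₂⁻ + adduct + 2 N₂O,
and FlBA + FlOH = FlBA₀.  Tiny negative excursions within solver
tolerance are clipped to zero; substantial negativity aborts.

## Steady state and the competition law

Setting d[HNO]/dt = d[ONOO⁻]/dt = 0 gives

    [HNO]ss = k_AS[AS] / (k_nuc[nuc] + k_O2[O2])
    v0 = k_AS[AS],   vi = v0 · k_O2[O2] / (k_nuc[nuc] + k_O2[O2])
    v0/vi − 1 = (k_nuc/k_O2) · [nuc]/[O2]

The package evaluates these closed forms (`fluorescein_rates`,
`inhibition_prediction`) and verifies, as a property of the
implementation, that the two sides of the last identity agree to 10⁻¹²
relative.  Against the full model the quasi-steady-state rate (evaluated
at instantaneous [AS] and [nuc]) agrees within 5% across
k_nuc ∈ [10, 10⁵] M⁻¹s⁻¹ and [nuc] ∈ [0, 10 mM] from 60 s onward; the
intermediate relaxation times are 1/(k_O2[O₂]) ≈ 0.25 s and
1/(k_FlBA[FlBA]) ≈ 0.04 s, so the QSS is established essentially
instantly on the 600 s observation scale.

`flux_partition` quantifies how much HNO each channel actually consumed
along a trajectory, **counting two HNO per dimerization event**.  At
reference conditions (no scavenger) the dimerization share integrates to
≈1.2% over 600 s — small, and smaller still in inhibited runs, but not
strictly below 1%; with the alternative per-event counting it would be
≈0.6%.  This is the one place where "dimerization is negligible" needs a
stated convention.

## Synthetic traces

`simulate_trace` maps a trajectory through the Beer–Lambert transform
A(t) = baseline + l·(ε_FlOH·[FlOH] + ε_FlBA·[FlBA]) and adds Gaussian
noise.  Defaults and what they represent:

* ε_FlOH(490 nm) = 7.5 × 10⁴ M⁻¹cm⁻¹ — a typical fluorescein-dianion
  magnitude; no assay-specific value is asserted, and every estimator is
  built on rate ratios so ε cancels (verified to machine precision).
* ε_FlBA(490 nm) = 0 — the probe absorbs near 378 nm; a residual term is
  configurable.
* noise_sd = 2 × 10⁻³ AU, additive, i.i.d. — a plain photometric noise
  floor.  Real instruments add drift, mixing transients and lamp
  flicker; none of that is emulated, so passing recovery tests show
  correctness of the analysis chain under the stated noise model, not
  robustness to real-world artefacts.
* Sampling every 5 s over 600 s (121 points per trace).

Seeds: a master `SeedSequence` is expanded and its successive 31-bit
words seed the traces in a fixed order, so series regeneration is
bit-identical.  Noiseless traces are exactly the deterministic
transform.

Concentration grids for a series are placed by inverting the competition
law so that v₀/vᵢ − 1 hits {0.3, 0.75, 1.5, 3.0} — the window where the
slope plot is well conditioned: much lower and the signal drowns in the
v₀ uncertainty, much higher and vᵢ itself becomes poorly measured.

## Estimation

`initial_rate` offers two readouts of a trace:

* **ols** (default) — straight-line least squares on the window
  ([0, 600] s by default; a mixing-lag variant trims to [30, 600] s).
  Over 600 s the donor decays by 38%, so this slope underestimates the
  true initial rate by ≈20% — *deliberately acceptable* for the
  competition statistic, because the decay factor is identical in
  control and inhibited traces and cancels exactly in v₀/vᵢ.
* **exponential** — tangent at t = 0 of a first-order growth fit
  A(t) = A₀ + ΔA(1 − e⁻ᵏᵗ).  This is the readout for absolute rates,
  i.e. donor calibration: on a clean synthetic control it returns
  k_AS within ≈1.5% (the residual offset is the dimerization sink).

`CompetitionModel.fit()` regresses the pooled replicate points through
the origin (the law has no intercept; a free intercept would absorb
noise at small x into bias).  A free-intercept refit is always computed
as a diagnostic and a warning is raised when its intercept exceeds twice
its standard error.  The reported k̂ is slope × k_O₂ exactly.

Uncertainty: the slope SE combines (in quadrature) the residual scatter
of the through-origin fit with the common-mode contribution of the
shared control rate — a relative error δ on v₀ moves every point by
(1 + yⱼ)δ coherently, shifting the slope by δ·Σxⱼ(1 + yⱼ)/Σxⱼ², which
per-point residuals cannot see.  The v₀ SE is the control trace's OLS
slope SE and is dominated by lack-of-fit of the linearity assumption,
which is honest: that *is* the dominant uncertainty of a straight-line
v₀ over 600 s.  Confidence intervals are t-based with n − 1 degrees of
freedom.  Per-replicate through-origin slopes are also reported.  How
replicate scatter enters the uncertainty is a design choice of this
package, not something the assay description fixes.

Known bias: because the generator is the full network, the two-channel
law under-measures k by ≈1.6% (low k) to ≈2.1% (high k, where the
scavenger is also measurably depleted at the low concentrations the grid
assigns it).  This bias cancels in fold *ratios* between compounds
analysed with the same inhibition-target grid, which is why the
fold-relationship checks are exact after rounding, while 95% intervals
— honest about statistical error only — under-cover the generating
value at the default (very clean) noise level.  Debiasing would require
stepping beyond the slope method (e.g. fitting the full model), which
this package intentionally does not do.

`as_concentration_from_absorbance` is the Beer–Lambert helper for donor
stock quantitation at 248 nm (ε = 8.3 × 10³ M⁻¹cm⁻¹).

## Structure–activity regression

`BarrierRegression` fits barrier (kJ/mol) on log₁₀ k by OLS over the
reference compounds that have both values (nine of thirteen; compounds
3, 10, 11 lack a transcribed rate constant and compound 6 a barrier, and
are excluded, never imputed).  Base-10 logs are the default (a natural-
log option rescales the slope by ln 10); the regression direction is
barrier-on-log k, with the inverse direction available and re-expressed
on the same axes.  Changing concentration units shifts only the
intercept.  On the reference set the fit gives a negative slope
(≈ −18 kJ/mol per decade, R² ≈ 0.88); only the sign and rank structure
(Kendall τ < 0) are asserted as properties, since the relationship's
scatter spans roughly an order of magnitude in k, which is also the
honest precision of `predict_rate` for an unseen compound.

## Reproduction runs and problem sizes

`run_reproduction` simulates one series per measured reference compound
(4 concentrations × 3 replicates + control = 13 traces of 121 samples),
recovers each constant, forms the six fold ratios (4/1, 7/1, 2/1, 5/4,
8/4, 9/4, nearest-integer rounded — matching how such fold statements
are conventionally phrased) and refits the barrier regression on the
recovered constants.  Reports are schema-versioned JSON carrying every
seed and a hash of the scientific configuration; runs are byte-identical
for a fixed master seed.  The coverage study in the test suite uses 100
seeded series per ground-truth constant, re-drawing only the noise over
cached deterministic trajectories.  These sizes keep any analysis here
in the seconds-to-minutes range while leaving the statistics (slope SEs
well below the systematic effects discussed above) unchanged by further
enlargement.

## Limitations

* No pH or temperature dependence; pH 7.4 conditions are metadata.
* No ONOO⁻/ONOOH chemistry beyond the probe channel by default.
* No full-spectrum simulation — only the 490 nm band (plus an optional
  residual probe term); the 378 nm probe band is not modelled.
* The slope estimator inherits the small dimerization bias discussed
  above; it is quantified, not corrected.
* Quantum-chemical barriers are input data; nothing is recomputed, and
  no Eyring-type conversion of barriers to absolute rates is attempted.
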