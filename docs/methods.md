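# Methods

## Model

`admtaxa` implements a structured kinetic model of anaerobic digestion
in a continuous stirred tank reactor (CSTR), following the standard
ADM1 benchmark formulation (disintegration, hydrolysis, acidogenesis,
acetogenesis, acetoclastic and hydrogenotrophic methanogenesis,
acid–base speciation, gas transfer) with one structural change: the
single acetoclastic methanogen and the single syntrophic propionate
oxidizer are each replaced by **two competing populations** that share
yield, maximum uptake rate and decay rate but differ in substrate
affinity and free-ammonia sensitivity.

For acetate (population *i* ∈ {1, 2}):

    dX_ac,i/dt = (X_in,ac,i − X_ac,i)/HRT
               + ( Y_ac · k_m,ac · S_ac/(S_ac + K_S,ac,i) · I_ac,i − k_dec ) · X_ac,i

    dS_ac/dt = (S_ac,in − S_ac)/HRT − Σ_i k_m,ac · S_ac/(S_ac + K_S,ac,i) · I_ac,i · X_ac,i
             + Σ_j ν_ac,j · ρ_j                       (acetate-producing uptakes)

with the inhibition products

    I_ac,i  = I_pH,ac · I_IN,lim · I_nh3,i             (acetoclastic)
    I_pro,i = I_pH,aa · I_IN,lim · I_h2,pro · I_nh3,i  (propionate oxidation)
    I_nh3,i = 1 / (1 + S_nh3 / K_I,nh3,i)

Free-ammonia inhibition of propionate oxidation is the second
extension: classical ADM1 inhibits only the acetoclasts with ammonia.
Butyrate/valerate oxidation, LCFA degradation and hydrogenotrophic
methanogenesis keep their classical rate forms.

The competing-population structure is what allows the model to show
*recovery*: an ammonia step washes out the sensitive, high-affinity
populations (*Methanosaeta*-like, *Syntrophobacter*-like), the
corresponding acid accumulates, and the tolerant, low-affinity
populations (*Methanosarcina*-like, an unassigned propionate oxidizer)
grow in and pull the acid back down.  A single-population structure can
only produce no accumulation, a persistent elevated plateau, or
washout/failure; it is retained as a preset for the contrast run.

### Key parameters

| parameter | X_ac,1 | X_ac,2 | X_pro,1 | X_pro,2 | units |
|---|---|---|---|---|---|
| Y (yield) | 0.05 | 0.05 | 0.04 | 0.04 | gCOD_X/gCOD_S |
| k_m | 8 | 8 | 13 | 13 | gCOD_S/gCOD_X/d |
| K_S | 0.34 | 0.15 | 0.34 | 0.10 | gCOD/L |
| K_I,nh3 | 0.3387 | 0.0052 | 0.4887 | 0.0036 | M |
| k_dec | 0.02 | 0.02 | 0.02 | 0.02 | 1/d |

The sensitive populations (index 2) have the higher substrate affinity
(lower K_S) — they dominate at low ammonia — and inhibition constants
roughly two orders of magnitude below the tolerant ones.  All other
stoichiometric, kinetic and physico-chemical constants are the ADM1
benchmark values (packaged in `data/default_params.yaml`).

### Numerical choices

* **pH** is solved algebraically at every right-hand-side evaluation by
  scalar root-finding on the charge balance (Newton warm-started from
  the previous pH, bracketed bisection fallback; residual < 1e-10 M),
  rather than integrating ion-state ODEs.  This is simpler and robust
  under the stiff transients of the pulse days.
* **Temperature**: operation at 310.15 K (37 °C); equilibrium and Henry
  constants are van 't Hoff-corrected from their 298.15 K references.
  A `temperature_correction` switch reverts to the reference values.
* **Elemental closure**: the inorganic-carbon and inorganic-nitrogen
  rows of the Petersen matrix are computed as closure terms, so every
  process column conserves COD, C and N exactly (asserted per column in
  the tests).  In particular, decay (biomass → composite) releases the
  C/N surplus of biomass relative to composite material to the
  inorganic pools instead of leaking it.
* **Gas phase**: headspace of 0.5 L (not reported; configurable) vented
  through a linear overpressure law q = k_p (P − P_atm), clipped at
  zero; k_p = 5·10⁴ L/d/bar keeps the overpressure below 0.1% of
  ambient.  A quadratic orifice law was not used; the choice is
  documented here because the original description does not state it.
* **Integration**: stiff BDF with rtol 1e-6, atol 1e-12, restarted at
  every schedule discontinuity; pulse feedings are applied as
  perfectly-mixed instantaneous state jumps (a 20-minute high-rate
  delivery mode exists behind a flag).  Halving the tolerances moves
  every reported quantity by far less than 1%.
* **Negative-concentration guards**: concentrations are clipped to zero
  inside rate evaluation only; the integrator always sees the raw
  state.
* **Readout convention**: reported day-55/62 values are evaluated
  immediately *before* that day's pulse (the pulse jumps the state
  discontinuously); peaks are read off a fine resampling of the dense
  solver output, not the output grid.

## Scenario

The feed is a synthetic VFA mixture, 37.2 gCOD/L split 45/10/45
(acetic/propionic/butyric on COD basis), in mineral medium with lumped
other cations 78.3 mM and anions 19.8 mM; HRT 5.5 d, working volume
6 L.  Feed inorganic carbon equals feed inorganic nitrogen (ammonium
bicarbonate): 52 mM initially, stepped to 277 mM on day 21 for the
inhibited variants.  The `NH3_HCl` variant adds 100 mM HCl to the feed
anions from day 38 until day 73 (two start days, 36 and 38, are on
record for the HCl addition; day 38 is the default and day 36 is kept
as a named preset).  On days 55, 62 and 69 the inhibited reactors receive one daily
feed volume (V/HRT ≈ 1.09 L) at once, with continuous feeding suspended
for the following 24 h.  Schedules are right-continuous step functions;
every discontinuity is an integrator restart point.

**Initial state.**  The t = 0 condition is the simulated steady state
under the 52 mM feed.  The tolerant populations are competitively
excluded at that steady state (their break-even substrate concentration
is higher), so they are held at exactly zero during spin-up and their
t = 0 concentrations are *free inputs*: X_ac1(0) = 0.06 and
X_pro1(0) = 0.004 gCOD/L by default.  These two numbers are not
directly measurable; the defaults were reconstructed so that the
default run reproduces the reported reference trajectory (in the
reference experiment they were estimated by fitting); they are exposed
in the configuration and are two of the eight calibration targets.

## Degradation-efficiency calculus

For each acid *i* and sampling time *t*, over a look-back window Δt
(default 1 d):

    E_i(t) = [ S_i,in/HRT·Δt − ΔS_i,out(t) + ΔS_i,p(t) − ΔS_i(t) ]
           / [ S_i,in/HRT·Δt + ΔS_i,p(t) ]

where ΔS_i,out uses the arithmetic mean of the endpoint concentrations
(not a trapezoid of the interpolant — the mean is the definition),
ΔS_i is the storage change, and only acetate carries a production
credit ΔS_ac,p from same-window propionate and butyrate oxidation
(1 mol acetate per mol propionate, 2 per mol butyrate, converted to the
declared concentration basis: molar, mass, or COD).  Propionate and
butyrate efficiencies are computed first; acetate does not feed back,
so no iteration is needed.  Concentrations between samples are linearly
interpolated.  E = 1 is complete degradation at steady state; values
exceed 1 when stored acid is drawn down and fall below 0 during strong
accumulation — values are reported unclipped.  The concentration basis
is a required declared input because the definition is basis-invariant
only if the production credit is converted consistently (a property
test asserts this).

## Calibration

Eight parameters are free: X_ac1(0), X_pro1(0), K_S,ac1, K_S,pro1 and
the four K_I,nh3.  Fitting is sequential, as in the source study:
stage 1 fits the propionate-side quartet to the propionate series;
stage 2 fits the acetate-side quartet to the acetate series with the
stage-1 values frozen.  The objective is the unweighted sum of squared
errors between observations and the simulation interpolated to the
observation times (an optional relative-error weighting flag exists,
off by default).  Optimisation is bounded trust-region-reflective least
squares on log10-transformed parameters (positivity for free; default
box start/100 … start×100), optionally multistarted from log-uniform
draws; all randomness flows from one seed, so results are bit-identical
across reruns.  A failed simulation returns a documented penalty
(10⁶ × the SSE of the all-zero model) instead of raising.  The
pre-shock steady state is recomputed when a parameter it depends on
changes, with a quantised cache so that finite-difference probes reuse
their centre point's spin-up.

Because the original reactor measurement series are not available in
numeric form, calibration is validated by **synthetic recovery**: observations are generated from
a known truth, the fit is run from deliberately displaced starts
(sensitive K_I ×2, inocula ×0.5, tolerant K_S ×1.5), and the recovered
sensitive constants are compared with truth.  Noise-free recovery is
accurate to ~1%; across five noisy replicates (CV 7%) the medians stay
within a few percent.

## Synthetic observations

The generator emulates the experiment's measurement process at the
model's resolution: sampling every 2 d over 0–79 d (the experiment
sampled at a few-day cadence; exact days are not tabulated),
multiplicative lognormal concentration noise with CV 0.07 — a typical
VFA-assay spread, not a reported value — parameterised so the *median*
equals truth, a 0.01 g/L detection floor with left-censoring (censored
fraction reported), and Dirichlet-resampled community compositions with
200 effective counts per sample.  What it does **not** emulate:
sequencing reads, OTU clustering, chimeras, copy-number conversion,
T-RF fragment sizes, sample-to-sample correlation of assay error, or
aggregate-related sampling bias.  Passing recovery tests therefore
demonstrate identifiability under the model's own assumptions, not
robustness to real measurement pathologies.

## Problem sizes

Default runs integrate 31 state variables over 79 days with 8–10
segments; one run takes a few seconds.  The recovery study uses one
noise-free fit plus five noisy replicates with an iteration-capped
optimizer (the objective reaches the noise floor within a handful of
trust-region steps); the full study completes in minutes.

## Known limitations

* The tolerant-population inocula are reconstructed, not measured; all
  absolute timing of the recovery phase depends on them.
* The simulated pH after the ammonia step (~7.8–8.0) slightly exceeds
  the 7.7 observed experimentally, because the lumped cation/anion
  totals stand in for the full medium speciation; free ammonia is
  correspondingly somewhat higher.
* Relative-abundance denominators (X_ac1+X_ac2+X_h2 for methanogens;
  the six bacterial guilds for bacteria) are a model-side convention —
  the model resolves no other taxa; both pools are configurable.
* The day-55/62 readouts are defined pre-pulse; the source does not
  state which side of the pulse its values refer to.
* No sulfate reduction, LCFA inhibition, temperature dynamics or
  trace-element limitation; decay biomass recycles through composite
  disintegration, so small fermentative populations persist on decay
  products — accepted, not suppressed.
* Whether the pulse days were included in the original fitted
  simulations is not stated; they are included here by default and can
  be excluded by fitting on a schedule without pulses.
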