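# Methods

## Model and assumptions

`reefnet` integrates, for each reef *i* of a network of N reefs, the coupled
benthic-cover system

    dM_i/dt = a M_i C_i − g_i M_i/(M_i + F_i) + Σ_j γ n_ij F_i M_j
    dC_i/dt = Σ_j r k_ij F_i C_j − a M_i C_i − d_i C_i
    1 = M_i + C_i + F_i

Macroalgae (M) overgrow mature coral at rate `a`, are grazed indiscriminately
together with free space (hence the saturating `M/(M+F)` share of grazing
effort `g_i`), and recruit onto free space from gametes produced across the
network (γ, n_ij). Coral (C) recruits onto free space from larvae produced
across the network (r, k_ij), loses cover to overgrowth and to background
mortality `d_i`. Free space F is eliminated algebraically, so cover closure
holds by construction. The model has no herbivore population dynamics, no
stochastic forcing and no disturbance events; interventions act purely
through `g_i` and `d_i`.

An isolated reef with full self-retention (k=n=1) reproduces the classic
grazing-controlled regimes: a macroalgal-dominated state at low g, bistability
at intermediate g, coral dominance at high g. In the coupled network those
local regimes are modified by dispersal, which is the object of study.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `a` | macroalgal overgrowth of coral | 0.1 | 1/time |
| `r` | coral larval production | 1.0 | 1/time |
| `γ` | macroalgal gamete production | 0.8 | 1/time |
| `d_med` | network median coral mortality | 0.44 | 1/time |
| `g_median` | scenario grazing median | 0.1 / 0.3 / 0.5 | 1/time |
| `t_end` | integration horizon | 20 000 | time |
| healthy threshold | "healthy reef" coral cover | > 0.30 | proportion |

`a = 0.1` and the scenario medians follow the one- and two-reef models this
system descends from. `r`, `γ` and `d_med` are fixed by a calibration
constraint rather than taken from data: `calibrate_globals` grid-searches the
mortality value for which an isolated calibrated reef is macroalgal at
g = 0.1, bistable at g = 0.3 and coral-dominated at g = 0.5. With r = 1.0 and
γ = 0.8 the feasible window is d ≈ (0.34, 0.56); the default 0.44 — the
long-standing baseline mortality of this model family — sits comfortably
inside it and is adopted as `d_med`.

Per-reef rates derive from covariates. Grazing: `g_i = c · density_i` with
the consumption-rate constant c set so that median(g) equals the scenario
median exactly (multiplicative, so zero-density reefs stay at g = 0 and ranks
are preserved). Mortality: a single affine map
`d_i = d_med + k (s_i − median(s))` of the sediment index, with slope k
chosen as the largest value keeping all d inside
`[d_med(1−spread), d_med(1+spread)]` (spread 0.5 by default). A one-slope
map was chosen over a two-segment min/median/max rescale because it pins
median(d) = d_med exactly for even-length inputs as well; the price is that a
skewed sediment distribution fills only one side of the band.

## Synthetic seascape and connectivity

The generator emulates a ~75-site clustered tropical seascape: fishing-ground
centroids scattered over a ~130 × 90 km box, reefs normally scattered (sd
~5.5 km) around them, 21/75 reefs placed in single-reef fishery closures,
herbivore density lognormal (median 100 kg/ha, sdlog 0.75), sediment decaying
exponentially (20 km e-folding) from a southern coast axis with lognormal
noise, and initial covers drawn as Beta variates constrained to M + C ≤ 1.

Connectivity is an isotropic exponential distance-decay kernel,
`p0 · exp(−dist/λ)` with `λ = speed · PLD`, multiplicative lognormal noise
(sd 0.3), pruning below 1e−5 and clipping to [0, 1]. The working coral matrix
is the uniform-weight average of kernels at PLD 10–130 days; macroalgal
gametes use PLD 5 days. Defaults `p0 = 0.65`, `speed = 0.03 km/day` were
fixed once on two structural grounds: (i) the median coral-matrix row sum is
≈ 1, so a network reef experiences recruitment comparable to the calibrated
isolated reef and the grazing-regime calibration remains meaningful; (ii) the
PLD-10 kernel fragments the dispersal graph into many weak components while
PLD 130 and the weighted average form a single connected network. `speed` is
an effective decay scale per PLD day, not an advection speed.

What the generator does **not** emulate: ocean currents (no anisotropy, no
source–sink asymmetry beyond noise), bathymetry or habitat area, correlation
between herbivore density and management history, multi-reef closures, or
empirical marginals of any real survey. Tests passing on these seascapes
therefore demonstrate correctness of the machinery and robustness of the
qualitative orderings (scenario ordering, spillover, intervention ranking) —
not quantitative predictions for any real reef system.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` LSODA, rtol 1e−8, atol 1e−10,
  outputs at unit time spacing by default (`save_every` configurable; the
  orchestrator stores endpoints only). "20 000 time steps" is interpreted as
  integration to t = 20 000 of the continuous system.
* The right-hand side is evaluated on the state projected onto the cover
  simplex, and stored states within 1e−8 of the [0, 1] bounds are snapped to
  the boundary. Without the projection, round-off near the C = 1 corner
  (reachable when d = 0 under a 100% water-quality arm) feeds a
  wrong-signed, diverging grazing term and the solver fails.
* The grazing term `g·M/(M+F)` is defined as 0 when M + F ≤ 1e−12
  (removable singularity at C = 1).
* Equilibrium is declared when the max-abs derivative at t_end is below 1e−8;
  non-equilibrated runs log a warning but are not errors.
* Regime classification integrates coral-heavy (M, C) = (0.05, 0.75) and
  macroalgae-heavy (0.75, 0.05) probes; final |C − M| < 1e−6 is labelled
  "degenerate", otherwise the probe pair maps to coral / macroalgal /
  bistable.
* Healthy counts use a strict inequality with a 1e−9 guard band at the
  threshold. Percentages appear only at the reporting layer; all internal
  state is proportions.
* Closure expansion resolves "~2 km" as an exact ≤ radius test on haversine
  distances (R = 6371 km), boundary ties included. A reef captured by several
  closures takes the unweighted mean of their original grazing rates;
  original closure reefs always count their own closure in that mean. The
  5-km arm ignores fishing-ground boundaries; the 2-km arm requires the
  capturing closure reef to share the captured reef's ground.
* Determinism: every random draw flows from explicit integer seeds;
  orchestrated runs derive per-stage child seeds from the config seed via
  `SeedSequence`. Identical configs reproduce results bitwise.

## Scale of the shipped analyses

The default study grid is 75 reefs × 21 simulations to t = 20 000, which
completes in seconds. Test-suite analyses that iterate (scenario-ordering
statistics across ten seeds, sensitivity bookkeeping) use 12–20-reef
seascapes and shorter horizons; these sizes were chosen as the smallest at
which the network effects of interest (multi-reef closures in range,
connected clusters) are present.

## Design choices on open points

* EVPI across the wider uncertainty grid (a, d_med, PLD, initial conditions)
  is reported both per cell (EVPI over the grazing-scenario axis within each
  cell) and pooled (every cell × scenario combination treated as one
  uncertainty column); neither variant is privileged.
* Initial-condition scenarios use uniform (0.75, 0.05) cover levels for the
  very-high/very-low coral probes; configurable.
* The baseline is re-run for every grazing scenario rather than shared.
* The CLI is a thin binding over the library; all numbers it prints are
  produced by the same functions the tests exercise.

## Known limitations

* The dispersal kernel is a structural stand-in for current-driven transport;
  absolute healthy-reef counts depend strongly on its scale parameters and
  should not be compared to any published survey-based figures.
* Grazing and mortality translations are rank-preserving conveniences, not
  empirical consumption-rate or sediment-dose responses.
* No demographic stochasticity or disturbance: long-run equilibria are the
  only endpoint, and multistable systems are summarized by the basin the
  chosen initial condition falls into.
* Single-reef closures in the generator mean the "average over original
  closure reefs" rule is exercised only through multi-closure capture.
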