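# Methods

`commfba` models the assembly of a small bacterial community under serial
batch passaging in a nutrient-rich medium, and provides the surrounding
analysis: calibration of uptake kinetics against an observed community
composition, inference of interspecies metabolite exchanges, generalized
Lotka–Volterra (gLV) interaction typing, and growth/abundance statistics.
This note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Community dynamic FBA

Each species is a stoichiometric model with one biomass reaction and
exchange reactions under the secretion-positive convention (an exchange
touches one extracellular metabolite with coefficient −1; positive flux
exports). Growth at each instant is the solution of a parsimonious flux
balance problem: maximize biomass flux subject to S·v = 0 and flux bounds,
then minimize Σ|v| with the biomass flux pinned at its optimum (relative
tolerance 1e−9, split into non-negative forward/reverse components). The
parsimonious step both mimics enzyme-cost frugality and makes the reported
flux distribution — hence the inferred exchange network — unique and
deterministic. LPs are solved with HiGHS (`scipy.optimize.linprog`),
feasibility and optimality tolerances 1e−9.

The extracellular environment is a well-mixed set of finite molar pools for
the limiting carbon sources plus an unlimited set (ions, gases, growth
factors). For the R2A-like medium, glucose enters from its mass
concentration (0.5 g/L, MW 180.16), and the summed mass of the peptide
components (peptone, casamino acids, yeast extract; 1.5 g/L total by
default) is split equally over the 20 proteinogenic amino acids and
converted to mmol by molecular weight. Starch, pyruvate and salts are
ignored unless declared limiting or unlimited.

Uptake kinetics default to a hard cap: only a maximum uptake rate is
specified per species, and the bound below prevents overdrawing a pool
within a step, which reproduces batch depletion exactly and is directly
testable. A Monod law is available per species (`monod_km`, mM, applied as
V·c/(Km+c) on finite pools) but off by default, since no half-saturation
constants are part of the study conditions.

Time stepping (default Δt = 0.1 h over 48-h cycles): per species the uptake
bound for a finite pool m is −min(Vmax, pool_m/(X_cons·Δt·1.0001)), where
Vmax is the species' limiting-carbon uptake rate for limiting sources and
its default Vmax (10 mmol/gDW/h) otherwise, and X_cons is the summed biomass
of every species with an uptake route for m. Dividing by the *total*
consumer biomass (rather than each species' own) guarantees the consumers
jointly cannot overdraw the pool in a step; for a single consumer it reduces
to the per-species form. Biomass advances exponentially
(X ← X·exp(µΔt)); pools advance by explicit Euler
(pool ← pool + flux·X·Δt). This first-order pairing overshoots the yield by
a factor ≈ (e^{µΔt}−1)/(µΔt) per step, so the toy generators keep µ·Δt ≲ 0.04
at every rate the calibration visits; the timestep-halving test bounds the
residual discretization error at < 1% on the default community.

Three numerical guards keep the integration exact-cache-friendly and
well-posed (these matter because the per-species LP solution depends only on
its bound vector, so solutions are memoized on it):

* availability-derived caps are quantized *down* to one significant figure —
  pools can never be overdrawn, the bound vector becomes piecewise constant
  in time, and a pool's final depletion is delayed by at most ~2 steps;
* caps below 1e−9 mmol/gDW/h are zeroed (a transporter noise floor aligned
  with the exchange-network edge epsilon), so sub-detectable secretion
  trickles cannot force per-step LP re-solves;
* pools below 1e−11 mmol after a consuming step snap to zero (the 1.0001
  overdraw guard otherwise leaves a geometrically decaying residue).

A pool more negative than −1e−9 mmol raises an integrity error; an
infeasible species LP is treated as zero growth for that step (stationary,
not death). No maintenance ATP drain is modeled. Serial transfer multiplies
every species' biomass by the dilution factor (default 0.1, i.e. 10% vol/vol
into fresh medium at fixed 10 mL volume) and mixes the pools as the convex
combination d·culture + (1−d)·fresh; six passages P0–P5 are simulated by
default, with the initial dry mass 3.9e−7 g per species (3.9e−10 g for a
1,000-fold-diluted inoculum).

## Uptake-rate calibration

The calibration drives the simulated end-of-run composition into a 95%–105%
band around a reference composition by lowering the limiting-carbon uptake
rates of the adjustable species (default: all but the most abundant
reference member, whose rate stays at the 10 mmol/gDW/h start value).
Phase 1 sweeps all adjustable rates down jointly — decrements of 1 to the
floor of 1, then 0.1 — evaluating the full serial-transfer simulation after
each move and stopping at the first undershoot (any adjustable species'
achieved/reference ratio < 0.95). Phase 2 refines species separately with
the 0.01 and then 0.001 decrements, restoring an undershot species to its
last pre-undershoot value before each finer descent.

Two choices here were genuinely open and are this package's own:

* refinement order is *descending* reference fraction. Adjusting a species
  shifts every other fraction through the common denominator by roughly its
  own fraction; placing the largest adjustable species first means later,
  rarer species perturb it the least.
* phase 2 re-checks all species after each placement and makes further
  passes; a species pushed below the band by a later adjustment climbs back
  up on its current grid before descending on the finer one. A pure
  descent-only rule cannot recover from this coupling.

Every rate ever evaluated lies on the grid generated by the decrement
schedule; the search is deterministic, logs every evaluation, and stops at
`max_evaluations` (default 500) with `converged=False` if the band is
unreachable (e.g. narrower than the finest step, or a non-monotone
response).

## Exchange-network inference

Per-step exchange fluxes are integrated over the analysis window (by default
all six passages) into secretion and uptake totals per (species, metabolite),
using start-of-step biomass — the same bookkeeping as the simulator's pool
update, so window additivity and conservation audits are exact. A directed
edge (producer, metabolite, consumer) exists when both integrated secretion
and integrated uptake exceed 1e−9 mmol; its weight is min(secretion, uptake),
a conservative bound, because molecule-level attribution in a well-mixed pool
is ill-posed. Edges whose metabolite has a zero fresh-medium pool and is not
unlimited are flagged `medium_absent` — the *potential interspecies
exchanges*; medium-supplied metabolites still form edges but are not treated
as absolute exchanges. Secretions with no heterospecific consumer are listed
as dangling. A monoculture baseline (each species simulated alone under
identical settings) reports whether each community secretion is constitutive
rather than emergent.

## gLV interaction typing

The gLV model dx_i/dt = x_i(r_i + Σ_j a_ij x_j) is simulated in log space
(LSODA, rtol 1e−9), so trajectories stay strictly positive; divergence past
1e30 raises a blow-up error. Parameters are inferred by gradient matching:
replicates are averaged per time point, central finite differences of ln x_i
at interior points are regressed on [1, x_1 … x_n] by ridge least squares
(default penalty 1e−3 on a root-mean-square-normalized design, intercept
unpenalized — making the fit invariant to abundance units up to the inverse
scaling of A), and the series is segmented per passage so dilution jumps
never enter a difference. Off-diagonal couplings below 1e−6·max|A| count as
sign 0; the negative fraction pools counts across fits. Identifiability
caveat: a single trajectory relaxing to equilibrium leaves A nearly
unidentifiable (collinear design); the recovery tests therefore use several
independently inoculated segments, which is also the shape of the serial
dilution experiment the method targets.

## Growth and abundance statistics

µmax is the least-squares slope of ln(X/X0) versus time over the contiguous
window (≥ 3 points, positive slope) with maximal r²; windows whose r² differ
by less than 0.005 count as tied and the longest (then earliest) wins. The
tie tolerance matters: under multiplicative noise a 3-point window is often
spuriously collinear, and raw argmax-r² selection then returns a badly
biased slope. Fold increase is N(48 h)/N(0 h) on replicate means. Relative
abundances are computed per replicate and averaged with their standard
error. The null-model comparison sets the expected community yield to the
inoculum-fraction-weighted sum of monoculture yields (equal weights
optional) and applies a two-sided Welch t-test across replicates;
observed/expected < 1 flags net negative interaction.

## Synthetic data: what it emulates, and what passing tests show

Toy species are minimal chains — exchange → transport → conversion →
biomass — whose biomass yield per substrate is set directly, plus
growth-coupled byproduct secretion (fixed stoichiometry to biomass, so
secretion survives parsimonious minimization) and uptake-to-biomass routes
for consumed partner byproducts. Byproduct scavenging carries small uptake
caps: cross-feeding is a signal to detect, not a growth driver.

The default three-member community (a dominant fast grower plus two minority
members) plants the qualitative exchange topology of the target system: the
dominant species secretes a polyamine (consumed by both partners) and
xanthine (consumed by one), one partner returns glycerol, the other secretes
an unconsumed byproduct. The dominant member is *anchored* — it exhausts its
amino-acid pools every cycle, so its biomass is pinned at the
pool-conversion level and recovers from any inoculum within a cycle. The
minority members never exhaust their substrates at calibrated rates, so
their end-of-run biomass is exponential in their uptake rate across all six
passages: a steep, smooth, monotone handle for the calibration (about
43 ln-units per unit rate, putting the 95%–105% band roughly 0.002 wide in
rate). A separate fully anchored community, in which every member is
pool-pinned, demonstrates inoculum-ratio invariance no matter *which*
species is 1,000-fold diluted. These two designs are intentionally
different: a composition with a strong attractor is insensitive to the rates
(conservation pins it), and a rate-sensitive composition retains inoculum
memory in the sensitive members — one toy cannot maximize both properties at
once, and the genome-scale system sits between the two regimes.

The randomized planted-rate communities push the rate sensitivity to
55–95 ln-units per unit rate (24-h cycles, six passages), which makes the
acceptance band one-to-two 0.001 decrements wide — wide enough that the
finest grid cannot step across it, narrow enough that recovering the planted
rate requires that grid. Their adjustable members hold ~0.2–2% of community
biomass so the two searches barely couple.

Emulated counts are biomass × 5e11 counts/gDW (a textbook cells-per-gram
figure, a convenience mapping only) divided by the 10 mL volume, sampled at
0/24/48 h of each cycle in triplicate with mean-one lognormal noise
(default CV 0.1) and a detection floor, tagged CFU or qPCR.

What passing tests do *not* show about real data: toy yields and pool sizes
are chosen for identifiability, not realism; there is no lag phase, death,
maintenance cost, pH or volume dynamics; the noise model is purely
multiplicative with no plating or primer biases; and the planted exchange
topology is recovered exactly only because the toys are constructed so that
secretion is obligate and consumption beneficial — on genome-scale models
the same pipeline reports candidate exchanges, not ground truth.

## Problem sizes used

The default simulations are six 48-h passages at Δt = 0.1 h (2,880 steps,
three species); a calibration run evaluates the full simulation 30–100
times. The randomized planted-rate communities use 24-h cycles at
Δt = 0.2 h, and their calibrations start the joint sweep at 0.5 mmol/gDW/h
(the planted rates lie below 0.4 by construction). The gLV recovery suite
uses 20 random three-species systems on three 81-point segments each, and
the µmax noise suite 100 seeds of triplicate 14-point curves.
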