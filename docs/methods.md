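# Methods

This note documents the model implemented by `hepsim`, the defaults it
ships, the numerical choices behind them, and what the synthetic data
generator does and does not emulate.

## Grid and coordinates

All fields live on a regular km-projected lattice (default 20 km cells).
Longitude/latitude appear only at I/O boundaries, mapped by an
equirectangular projection with the meridian-convergence cosine evaluated at
the domain-centre latitude; round trips are exact to < 10⁻⁶ degrees. Cells
are 0-based, row-major, with half-open edges `[edge, edge + Δ)`, so a
coordinate exactly on an edge belongs unambiguously to one cell. Densities
are reported in PDU (humans per 100 km²); for a 20 km cell, PDU = count/4.

## Climate-environment niche (Φ_E)

Seventeen candidate bioclimatic layers are derived from monthly mean
temperature and precipitation (the standard set minus the two
quarter-cross variables Bio8/Bio9). Where the layer names alone do not fix
a formula, the conventional definitions are used: Bio4 = std of monthly
means × 100; Bio15 = coefficient of variation × 100; quarters are circular
3-month windows (Dec–Jan–Feb allowed). Bio2/Bio3 need monthly diurnal
extremes; when a climate carries only monthly means they are produced fully
masked and cannot be selected. A correlation-clustering helper (average
linkage on 1 − |r|, cut at 0.3, representative by point-biserial |r|) is
provided, but the default predictor set is fixed to Bio1, Bio4, Bio16,
Bio15, Bio17.

Training cells are labelled presence (≥ 1 site in the cell — spatial
blocking collapses multiple sites to one record), a-priori absence (any
bioclimatic bound violated), or pseudo-absence. The shipped AMH bounds are
Bio1 ∈ [−2, 16] °C and Bio13 ∈ [30, 250] mm; for populations without
published bounds they are derived as the central 95 % quantiles of the same
variables at that population's presence cells. A presence cell that also
violates the bounds keeps its presence label (the observation outweighs the
prior); the conflict is warned and recorded. Pseudo-absences are handled by
one of three options — excluded; split in thirds (presence/absence/excluded)
per realization; or relabelled presence with the discovery-rate probability
Np/(Np+Npa) (the default, option 3). The realization is redrawn
independently per ensemble member so that label uncertainty propagates into
the ensemble spread.

The fit is an unpenalized maximum-likelihood logistic regression on the 5
linear + 15 unique quadratic terms, repacked into a symmetric quadratic
form (diagonal ½A_ii x², off-diagonals split evenly). Complete separation is
detected either by a convergence failure or by runaway coefficients
(|coef| > 50 on standardized features) and triggers an L2 ridge refit
(default strength 10⁻⁶), flagged on the returned model. Validation is AUC
on the held-out 20 % split; ensemble mean/std fields are accumulated in a
single pass. Training rows are sorted before fitting so a member's fit does
not depend on the order of the random draw.

## Accessibility (Φ_Ac)

Φ_Ac = ⟨Φ_E⟩ · g₁ · g₂ · g₃ · g_x. The modification function descends
linearly from 1.0 below x_l to a 0.8 plateau at x_u (slope 0.2/(x_u−x_l)).
Defaults: AMH g₁ (350, 2000) m elevation and g₂ (70, 400) m roughness; NEA
g₁ (450, 2000) m with roughness disabled (no clear signal at Middle
Paleolithic sites). Water and dense forest zero the field, as does sea. The
MIX population's Φ_Ac is the arithmetic mean of the parental Φ_Ac fields —
the average is taken after the accessibility modifications because the
simulator consumes Φ_Ac; averaging at the Φ_E level would differ only
through the (population-specific) g-factors.

## Demography

ρ_c = C·Φ_Ac. Attractiveness is a normalized Weibull density in
u = (ρ/ρ_c)/ε: f_pa = (u/u*)^(η−1)·exp(u*^η − u^η) with the analytic mode
u* = ((η−1)/η)^(1/η); defaults ε = 0.4, η = 1.6. The published form of the
attractiveness kernel omits the minus sign in the exponential; the Weibull
density reading (with the minus) is used, since only it has the stated
rise-then-fall shape. Φ_Av = f_pa·ρ_c spans [0, C].

The growth rate r_B(ρ) = r_o[(1−η_g)/(1+e^(−x)) + η_g], x = ε_g·ln(ρ/ρ_d),
uses defaults η_g = −0.1, ε_g = 2.5, ρ_d = 0.05 PDU, so r_B(0) = η_g·r_o < 0
(mating-network collapse) and r_B → r_o at high density. The per-step
birth-death module computes the net per-capita rate g = r_B(ρ)(1 − ρ/ρ_c)
per cell and realizes, per agent, a birth with probability g·dt when g ≥ 0
(newborn at the parent's position, random velocity of magnitude σ) or a
death with probability −g·dt otherwise; the expected net change follows the
Verhulst equation. The crowding factor is clamped at −1 everywhere (not
only at ρ_c = 0), capping the per-capita hazard at r_B·dt; this keeps the
stability bound dt·|g| ≤ 0.5 satisfiable when agents stray onto near-zero
HEP, and overcrowded cells still decline strictly. The density used by
demography and attractiveness is optionally smoothed by one pass of a 3×3
uniform kernel (default on) to stabilize gradients at 20 km resolution.

A consequence worth knowing: because events are drawn from the *net* rate,
demographic noise vanishes as a population approaches its local
equilibrium (g → 0 means no events at all, rather than balanced birth and
death streams). Small refugial populations are therefore more stable here
than under a scheme with independent birth and death hazards; desk-scale
runs do not show spontaneous extinction of established refugia, and
extinction-fraction diagnostics require either sub-viable habitat or far
longer horizons than the scaled-down experiments use.

## Mobility

Velocities follow dU = ((α/C)∇Φ_Av − γU)dt + β dW, dX = U dt,
Euler–Maruyama with dt = 1 yr by default. Two readings in the source
formulas are ambiguous and were resolved by dimensional/scaling analysis:

* the drift prefactor is **α/C**, not α·C — only this reading gives a
  steady drift speed of exactly U_s when |∇Φ_Av| = C/G_d (using
  α = U_s·G_d/D_t and τ = D_t) and acceleration units of km/yr²;
* the noise amplitude is **β = σ√(2γ)** so that the stationary per-axis
  velocity std equals σ (15 km/yr by default), the quantity the model sets;
  the literal reading β = σ²γ is dimensionally inconsistent with a Wiener
  forcing but remains switchable (`beta_convention="literal"`).

Defaults U_s = 2.5 km/yr, G_d = 500 km, D_t = 1 yr give α = 1250 km²/yr²;
τ = D_t; noise is isotropic. Stability requires γ·dt ≤ 1 (enforced). With
Euler–Maruyama the discrete stationary velocity std exceeds σ by the factor
√(2/(2−γ·dt)) (+2.6 % at γ·dt = 0.1); the long-run dispersal rate
(mean-squared-displacement slope, 2σ²τ per axis) is exact at any stable
step. The stationary-statistics tests therefore use τ = 10 yr (within the
plausible 1–10 yr response-time range) where the discretization bias is
well inside their tolerance.

Gradients are central finite differences with sea treated as Φ_Av = 0 (so
the coastal gradient points inland) and one-sided differences at domain
edges, bilinearly interpolated to agent positions. Boundaries are
symmetric-reflective: domain edges fold like a billiard; a move ending in a
sea cell is mirrored across the crossed edge(s) of the departure cell with
the normal velocity negated; if the mirror image is also invalid (e.g. a
one-cell channel), the agent reverts to its pre-move position with fully
reversed velocity (counted and reported).

## Admixture

Cells co-occupied by ≥ 1 NEA and ≥ 1 AMH are eligible; each cross pair
independently yields a MIX newborn with probability p·dt (default p = 1 %/yr).
The event unit is configurable (per pair — the default, since encounter
opportunities scale with both local densities — per AMH agent, or per
cell). MIX individuals are placed at the cell centre with a random velocity
of magnitude σ, inherit their own demographic/mobility parameter set
(preset ExpMIX-C), and never admix further (single-generation crossing).

## Engine and ensembles

The per-step order is: (1) bin agents, densities per population; (2)
demography fields (ρ_c, f_pa, Φ_Av) from the period-active Φ_Ac; (3)
motion + reflection; (4) births/deaths; (5) admixture; (6) record. The
order is a fixed convention; at dt = 1 yr the dynamics are insensitive to
swapping (3) and (4). Φ_Ac fields switch discretely at timeline boundaries
(warm/cold snapshots). Initialization draws each centre's N₀ agents
Gaussian in space (std given in degrees, converted to km), resampling
draws that land at sea so the population size is preserved, with random
velocity directions of magnitude σ. The published Neanderthal experiment
centres (four Iberian locations, 1000 agents, std 1°) ship as constants.
The first 300 years are excluded from summaries as spin-up (configurable).

Ensembles multiply every perturbable scalar (C, r_o, η_g, ε_g, ρ_d, α, σ,
D_t, p_adm) by an independent U[1−p, 1+p] draw per member (default
p = 0.1; a Gaussian mode exists). Draws that would violate an invariant are
clipped and logged — in particular D_t (and hence τ) is floored at dt to
keep γ·dt ≤ 1. Members rerun the full scenario, including fresh initial
placement, under per-member seeds spawned from the master seed, so reruns
are bit-identical. Summaries hold member series, mean/std, post-spin-up
minima (for extinction/threshold fractions), and ensemble-mean density
snapshots (for 500-yr rate-of-change maps).

## Synthetic laboratory

The generator emulates the statistical structure of the real inputs, not
their geography or physics: low-pass-filtered random topography with a
coherent coastline and an exact land fraction (quantile thresholding);
monthly temperature with a latitudinal gradient, a 6.5 °C/km lapse rate,
and a seasonal cycle whose amplitude grows inland (continentality);
precipitation with coastal and orographic enhancement and a maritime
winter peak fading inland. The cold (stadial-like) period applies a uniform
ΔT = −5 °C and scales precipitation by 0.6.

Sites are sampled presence-only, proportionally to a frozen "true" niche
surface Φ_E* defined by fixed quadratic-logistic coefficients on the
standardized default predictors — standardized pooling both periods, since
a model trained for two climate states sees both in its training
distribution (warm-only standardization would place the stadial many
standard deviations outside the predictor range and annihilate the niche).
The coefficients were chosen once so the warm period has a moderate mean
accessible HEP (~0.5) with pronounced low-elevation coastal maxima and the
cold period contracts habitability to coastal refugia (~10× lower mean)
— the regime the demographic experiments are meant to probe.

What passing tests on this generator show: that the training pipeline
recovers a known niche surface from presence-only sampling plus the
pseudo-absence machinery; that the coupled simulator orders equilibria by
(C, r_o), collapses populations when the niche contracts, and concentrates
survivors in refugia. What they do not show: fidelity to real paleoclimate
spatial structure (fronts, interannual variability, ice margins), real
coastline geometry, site taphonomy or dating error, or the absolute
population sizes of the published Iberian experiments, which depend on the
real HEP fields.

## Numerical sizes used by the shipped experiments and tests

Desk-scale runs use 24–32 cell square domains (≈350–600 land cells),
300–600 initial agents, 1500-year two-period timelines, and 10–50 member
ensembles; the stochastic-process checks use 2×10³–10⁴ agents over 350–500
years. These sizes put every statistic comfortably inside its tolerance
while keeping a full run in minutes on one core; production-scale
experiments (1000 members, 12,000-year windows) use the same code paths.

## Known limitations

* No age/sex structure; mating networks enter only through r_B(ρ).
* Demographic noise vanishes at local equilibrium (see Demography), so
  rare-event extinction statistics need long horizons or parameter draws
  that render habitat sub-viable.
* The macroscopic transport equation is realized only in Lagrangian form;
  no Eulerian PDE solver is provided (their long-time equivalence is
  checked via the diffusivity property test).
* Discrete period switching; the optional cross-fade is linear.
* Equirectangular geometry; no true cartographic projections, GeoTIFF, or
  shapefile support.
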