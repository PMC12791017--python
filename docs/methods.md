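# Methods

## The model

`pyritize` solves a one-dimensional, steady-state
advection–diffusion–reaction model of the sulfidic anoxic zone of
marine sediments.  Organic carbon (OC) fuels microbial sulfate
reduction (MSR, 1.7 mol OC per mol SO₄²⁻); the sulfide produced
reacts with highly reactive iron (Fe_HR) to form pyrite.  Both solids
decay as reactive continua: their bulk rate coefficients decline with
age, which integrates to power-law depth profiles

    Γ(ζ) = Γ₀ [a / (a + Da* ζ)]^a,   Ψ(ζ) = Ψ₀ [b / (b + χ Da* ζ)]^b.

Working in non-dimensional variables collapses the boundary-condition
space onto three governing numbers: the OC-to-sulfate ratio Γ₀, the
modified Damköhler number Da* = √(D_S·k_G0)/w, and the iron delivery
Ψ₀ (all in sulfate- or sulfide-equivalent units).  Depth is scaled as
ζ = √(k_G0/D_S)·z and solved on ζ ∈ [0, 5].

Porewater sulfate and sulfide are tracked as ³²S and ³⁴S
isotopologues.  MSR partitions its rate between them with a
temperature-dependent equilibrium fractionation factor α³⁴ (sulfide
~65–70‰ lighter than sulfate at seafloor temperatures); pyritization
does not fractionate.  Pyrite isotopologues are accumulated from the
instantaneous sulfide pool:

    dΠ/dζ = −dΨ/dζ · η/(κ_η + η).

The base of the pyrite formation zone, ζmax, is the first depth below
the rate maximum at which dΠ/dζ falls to a threshold β (default
5×10⁻⁴; halving it changes burial outputs by <1% in the representative
scenarios the test suite builds).  The headline isotopic observable is
Δpyrite = δ³⁴S of seawater sulfate minus δ³⁴S of the cumulative pyrite
phase at ζmax.

Model assumptions (no compaction, no bioturbation inside the sulfidic
zone, steady state, Monod kinetics for both reactions, no AOM, no
explicit FeS intermediates, MSR as the only fractionating process) are
inherited from the governing-equation set; none are revisited here.

## Numerics

The four coupled second-order isotopologue ODEs are reduced to a
first-order system of eight and solved with adaptive 4th-order
collocation (`scipy.integrate.solve_bvp`).  The bulk (isotope-summed)
pair is solved first from a heuristic iterate (Rayleigh-style sulfate
drawdown, local-balance sulfide) and seeds the isotopologue solve;
because the partition factors sum to one identically, the
isotopologue sums re-derive the bulk fields, and the residual between
the two independent solves is reported as a diagnostic (≤1e-7 in
practice, asserted ≤1e-6).  Seeded random restarts (≤5) handle
non-convergence.  Boundary conditions: fixed seawater values at ζ = 0,
zero gradient at the cap.  Magnitudes below 1e-10 are treated as zero
inside Monod terms; negative excursions beyond 100× the collocation
tolerance are solver failures, never clipped silently.

Output fields are evaluated on a 400-node grid exponentially refined
toward the surface; pyrite is integrated by cumulative trapezoid from
the analytic right-hand side (not by differencing), and ζmax is
located on that analytic rate.  Whole-column sulfur flux balance
(MSR production + bottom-water sulfide input = sulfide efflux +
sulfide burial + pyrite burial) closes to ≤0.5% across the governing
parameter box (Γ₀ ≤ 50, Da* ≥ 0.05, Ψ₀ ≤ 50, 100 random draws).

Solver verification uses manufactured solutions: a polynomial
sulfate/sulfide pair with exactly compatible boundary data is forced
into the governing operators, a fixed-mesh second-order finite
difference discretization of the same operators converges at its
theoretical order (observed 2.00), and the production collocation
solver recovers the manufactured profile to ~3e-11 in the max norm.

The zero-gradient cap at ζ = 5 is immaterial (<0.2% in formation-zone
outputs) when iron decay completes above it; with slowly decaying iron
the formation zone genuinely extends past the cap and the reported
burial quantities are floor estimates, consistent with the framework's
treatment of deep-sea settings where the sediment column itself ends
(median non-dimensional thickness ~1.8) before the threshold is
crossed.  Dimensional z_max is therefore capped at the column
thickness.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| a | 0.6 | – | OC reactive-continuum shape exponent |
| b | 1.0 | – | Fe_HR shape exponent |
| χ | 1.0 | – | Fe_HR/OC initial reactivity ratio |
| K_S | 1.6 | mM | sulfate Monod half-velocity |
| K_H | 1.0 | mM | sulfide Monod half-velocity |
| ε_eq(T) | −(70.2 − 0.17 T) | ‰ | equilibrium MSR fractionation |
| D(T, φ) | linear in T / (1 − 2 ln φ) | cm² yr⁻¹ | sediment diffusivity |
| k_G_sw(w) | 1.07e-5 · w^0.59 | yr⁻¹ | interface OC reactivity |
| β | 5e-4 | – | formation-zone rate threshold |
| R_VCDT | 0.0441626 | – | ³⁴S/³²S of the VCDT standard |

These are package defaults, all exposed in `RunConfig`.  The kinetic
constants are in the literature-plausible range for marine MSR and
iron-oxide sulfidation and were fixed so that the model reproduces the
published glacial–interglacial worked example (Δpyrite ≈ 21‰ at
Γ₀ = 25.2, Da* = 3.7 and ≈ 66‰ at Γ₀ = 3.9, Da* = 11.4, both with
Ψ₀ = 10); they are not independently fitted to rate data here.  The
fractionation curve is a linearization of published low-temperature
equilibrium estimates; its coefficients can be pinned in config when
an exact α is needed.  The standard parameter set evaluates α at 15 °C
(temperate shelf bottom water, matching the worked example's setting);
site-based workflows recompute α from each site's temperature.

A deliberate reading of the worked example: the published sentence
gives the Γ₀ and Da* endmember ranges without pairing them.  High OC
delivery and high sedimentation rate covary (both rise at a shelf site
during lowstand), and Da* ∝ w^(d/2−1) falls as w rises, so the
physically consistent pairing is (Γ₀ = 25.2, Da* = 3.7) for the
glacial, closed-system endmember and (Γ₀ = 3.9, Da* = 11.4) for the
interglacial, open-system endmember.  Only this pairing reproduces
both published Δpyrite values; it is the one implemented.

## The synthetic grid

`synthesize_grid` emulates gridded global boundary conditions: area
shares 8/7/85% for shelf (0–200 mbsl), slope (200–2000 mbsl) and abyss
(≥2000 mbsl); lognormal sedimentation rates with regime medians
0.05/0.01/0.001 cm yr⁻¹; OC and Fe_HR contents spanning ~0.2–1.4 and
~0.3–3 wt%; porosity 0.6–0.9; seafloor temperature decaying with water
depth; oxygen-penetration depth deepening with depth and shoaling with
sedimentation rate; and an oxic-to-basement mask on the least
productive abyssal cells.  Pixel areas use the spherical lon–lat
formula (R = 6371 km) normalized to the global ocean (3.61e18 cm²).
The generated Γ₀ field spans ~1–40 as in the modern ocean, and
shelf+slope carry the majority of synthetic burial despite minority
area.  The generator does not emulate spatial autocorrelation,
coastal sediment routing, euxinic basins, or the real covariance
between OC and Fe_HR; passing grid tests therefore demonstrates
plumbing and aggregate structure, not geographic fidelity, and global
totals from synthetic grids are order-of-magnitude only.

## Earth-history pipeline

LOESS is the classic tricube-weighted local polynomial regression
(degree 2), cross-checked against R's `loess(..., surface="direct")`
to 1e-5.  Spans: 0.2 for the sulfate record, 0.5 for the pyrite/Δ
record.  Δpyrite is formed at each pyrite timestamp from the smoothed,
linearly interpolated sulfate curve; no extrapolation beyond either
record.  Bootstrap bands resample individual measurements with
replacement (1000 iterations by default, seeded), re-running the full
smooth–interpolate–Δ pipeline per iteration and taking pointwise
5th–95th percentiles.  The band is a sampling-uncertainty band about
the smoothed estimator; it does not absorb smoothing bias, so a
rapidly oscillating truth can fall outside it even when the pipeline
is working correctly.  The inversion marks heat-map cells whose
Δpyrite lies inside an observed range and reports the ∫Π dζ range over
the region as a minimum-content estimate (iron delivery in the past is
unconstrained and was likely higher than modern).

## Known limitations

* Δpyrite can be marginally negative (~−2‰) in the extreme closed
  corner, where cumulative pyrite slightly exceeds seawater sulfate
  δ³⁴S by mass balance against the effluxing light sulfide.
* The Ψ₀-insensitivity of Δpyrite (<5‰ between Ψ₀ = 1 and 10) breaks
  down in the high-Γ₀/low-Da* sequestration corner (up to ~11‰).
* Global totals computed from the synthetic grid are an order of
  magnitude below satellite-constrained modern estimates; real
  boundary-condition grids must be supplied for quantitative upscaling.
* Sites with sulfate below ~3 mM (Precambrian regimes) are outside the
  model's validity; η₀ and S₀ are exposed as inputs but low-sulfate
  kinetics are not modelled.
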