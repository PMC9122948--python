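# Methods

## Model

Two strain-density fields `B1(x, t)`, `B2(x, t)` on a disk Ω of radius
`R` evolve by degenerate-diffusion growth:

    ∂B1/∂t = ∇·( Id (1 − (B1+B2)/k) ∇B1 ) + B1 (1 − (B1+B2)/k) [− B1 B2]
    ∂B2/∂t = ∇·( Id d (1 − (B1+B2)/k) ∇B2 ) + r B2 (1 − (B1+B2)/k) [− c B1 B2]

with no-flux outer boundary.  All quantities are nondimensional (one
time unit ≈ 2.9 h, one space unit ≈ 0.15 mm in the motivating
*B. subtilis* assay; these factors are metadata only).  The mobility
`(1 − (B1+B2)/k)` vanishes at carrying capacity, so established colonies
abut instead of diffusing through one another; the indicator `Id`
(1 where `B1+B2 ≤ k`, else 0) keeps the effective diffusivity
nonnegative.  In the isogenic mode the strains are identical labels
(`r = d = k = 1`, no bilinear terms) and compete for space only.  In the
antagonistic mode the bilinear losses model local (contact-range)
antagonism; `c < 1` makes strain 2 the intrinsically stronger
competitor, and the default `c = 0.2` is a five-fold asymmetry in
competition strength.

The competitive outcome for strain 1 is the relative final mass
`∫B1 / (∫B1 + ∫B2)` at the end time `T = 25`.

## Initial conditions

The inoculum footprint is the concentric disk Ω₀ of radius `R0 = 14`.
Founder microcolonies are mesh nodes inside Ω₀ chosen uniformly at
random without replacement; each carries one strain at carrying capacity
on its nodal (P1 hat) patch, all other nodes start at zero.  An even
founder count `N` is split exactly `N/2` per strain with a uniformly
random label permutation.  The high-density limit is represented by the
piecewise-homogeneous start `B1 = B2 = 0.5` on Ω₀.

The cell-picking sampler models drawing a small inoculum volume from a
large well-mixed culture: total count ~ Poisson(intended total), each
cell independently strain 1 with the culture fraction.  This is the
standard large-culture limit of hypergeometric sampling; the exact
finite-culture law is not identifiable from the available description,
and at the ~10² CFU scale the Poisson-binomial law already reproduces
the qualitative threshold where count and ratio noise become visible
(realised-fraction sd ≈ 0.05 at 100 CFU).

## Discretisation

Method of lines.  Space: mass-lumped linear (P1) finite elements on a
deterministic hexagonal-lattice triangulation of the disk (interior hex
lattice with spacing set by the target element area of 0.36, equally
spaced boundary ring, Delaunay connectivity).  The same triangulation
hosts founder placement and the solve, so no interpolation of initial
data is needed.  Element mobility is the arithmetic mean of the three
nodal mobilities clamped at zero — the clamp realises `Id` and preserves
nonnegativity (the P1 stiffness matrix of a Delaunay triangulation is an
M-matrix, so zero nodes cannot be driven negative beyond round-off).

Time: explicit Heun (RK2) with a fixed step from the lumped-mass
diffusion CFL estimate (`dt = 0.45 · min_i m_i / K_ii / max(1, d)`,
capped at 0.1).  Round-off negatives are clipped to zero; undershoots
beyond 1e-10 abort the run.  Degenerate mobility keeps stiffness mild,
so an explicit scheme is adequate and avoids nonsmooth-Jacobian issues
with the indicator.

Quadrature for masses is the lumped P1 rule (identical to consistent-P1
row sums).  The solver asserts that the colony front (total density
above 0.01·k) stays at least two element spacings away from the outer
boundary; violations raise an error naming the fix (larger `R`).

### Domain size

The linearised leading edge of the model travels at Fisher speed 2 (the
mobility is ≈ 1 ahead of the colony), so a colony seeded in Ω₀ reaches
radius ≈ 64 by `T = 25`.  The default `R = 72` keeps the front assertion
satisfied with margin; smaller domains fail it mid-run.

### Accuracy

Halving the element size (0.36 → 0.09 area would be the next step; we
compare the ensemble mesh, area 1.44, against the default 0.36, i.e. a
halved spacing) moves the outcome of a fixed N=6 layout by ≈ 0.001–0.01.
A single centred colony agrees with an independent 1-D radial
finite-difference solve to ≈ 5% in mass (the residual is dominated by
the unavoidable mismatch between a hexagonal nodal hat and a radial cone
as seed) and stays angularly symmetric to sd < 0.02 behind the front.
Spatially uniform states track the well-mixed ODE to < 1e-4 with a
reduced step (the comparison isolates time-integration error).

## AFS score

A reference circle is drawn around the founders; each circle point is
assigned to the nearest microcolony and AFS₁ is the strain-1 share of
the circumference; AFS₂ = 1 − AFS₁.

The reference circle is taken in the **large-radius limit**: a direction
θ belongs to the microcolony furthest advanced in that direction (the
maximiser of the projection), so ownership is the normal fan of the
convex hull and each hull vertex owns its exterior angle.  This choice
is parameter-free, exactly similarity invariant, and matches the score's
meaning — potential for *radial expansion* into free space, which is a
directional, not metric, notion.  Two observed consequences support it:
the fixed-half N=2 configuration scores exactly 0.5 (hence the unusually
small outcome spread at N=2), and the score spreads at N=6 and N=824
land at σ ≈ 0.166 and σ ≈ 0.109 respectively.  Finite circles (e.g. the
minimal enclosing circle inflated by 5%) remain available through
`enclosing_circle` / `arc_partition`; their σ values are smaller and
grow monotonically toward the limit as the circle inflates (N=6:
0.107 / 0.128 / 0.149 / 0.162 at inflation 1.05 / 1.5 / 3 / 10; N=824:
0.057 / 0.071 / 0.086 / 0.098), which is the sensitivity a user should
expect from the inflation knob.

The spread of AFS₁ across random fixed-half configurations is not
monotone in `N` at the low end: it vanishes at N=2 (two founders always
split the directions evenly), rises to a peak near N=8 (σ ≈ 0.177), and
only then decays with founder density (σ ≈ 0.105 at N=824).  The same
shape appears under finite reference circles, so it is intrinsic to the
arc-partition score, not to the circle choice.  Statements that
variability decreases with founder density hold from roughly N=10
upward.

The finite-circle partition localises owner changes on a fine angular
sample (at least 16 per site, capped at 16384) and then solves each
boundary angle from the two-site equidistance condition in closed form;
owner changes closer than the sample spacing can merge, which the
sampled-oracle agreement tests bound below 1e-3 of the circumference.
Ties are measure-zero and resolved to the lower site index.

## Well-mixed reduction

Removing gradients leaves a planar ODE system.  Isogenic: both strains
share one growth law, the ratio `B1/B2` is conserved, and the outcome
equals the initial ratio (a neutral line of equilibria at capacity).
Antagonistic with `c > 0`: boundary equilibria `(k, 0)`, `(0, k)` and an
interior equilibrium `B1* = rk/(kc+r+c)`, `B2* = kc/(kc+r+c)` are
classified by the Jacobian; the reported winner is decided by the
trajectory from the 1:1 start `B1 = B2 = k/2` (exclusion threshold:
loser below 1e-3·k by t = 1000).  For the default `c = 0.2` both
boundary states are stable and the interior state is a saddle; the 1:1
start lies in the basin of `(0, k)`, so strain 2 wins.  "Bistable" is
reported only when both boundary states are stable and the 1:1
trajectory excludes neither strain (the symmetric case `c = 1`, where
the start sits on the separatrix).

The label-swap transform `r → 1/r, d → 1/d, c → 1/c, k → kc/r`
(time rescaled by `r`, densities by `r/c`) maps the system to itself
with the strain roles exchanged and is used to test classification
equivariance.

## Ensembles and statistics

Realisation `rep` of an ensemble uses seed `base_seed + rep`; every
record (N, seed, AFS₁, outcome, inter-type separation, status) is
reproducible in isolation.  Realisations that fail solver checks are
recorded, counted and excluded — never resampled.  Normal fits are
moment fits (mean, unbiased sd).  The AFS→outcome relation is an
ordinary least-squares line with Pearson correlation.  The inter-type
separation statistic (mean distance from each microcolony to the nearest
microcolony of the other strain) is carried along as the null
comparator; it correlates with outcome far more weakly than AFS does.

Problem sizes: AFS-only ensembles run at the full 1000–5000 replicates
(geometry is cheap).  PDE ensembles default to 100 replicates on a
mesh coarsened four-fold in element area (1.44), a deliberate
scale-down from the 1000–5000 replicate ensembles behind the original
study; the resulting standard error of the mean outcome (≈ 0.014 at
N=6) is small enough to test the distribution centre and the regression
structure.

## What the generator does and does not emulate

The synthetic founder configurations reproduce: random settlement
locations within the footprint, exact or sampled strain splits, and the
one-node-one-microcolony granularity of the mesh (an element is much
larger than a bacterium, so a node stands for an established
microcolony, not a cell).  They do not emulate: cell-scale physics,
demographic noise during growth (segregation here comes entirely from
initial conditions), vertical structure, nutrient gradients, or
image-derived founder positions.  Green tests therefore validate the
model pipeline, not the biology of any particular organism.

## Known limitations

* The pulled (linearised) fronts of this model carry exponential
  low-density tails, so colonies that meet after long free expansion
  interpenetrate at low density before saturating: the co-located mass
  `∫min(B1,B2)` for two colonies seeded 20 apart is ≈ 3.1% of total mass
  at T=25 (mesh- and step-converged; ≈ 2.4% at separation 28, ≈ 8–10% at
  separation 6).  Sub-capacity overlap is a genuine model feature, not a
  numerical artefact; a hard 2% bound is not attainable for
  footprint-scale separations.
* The explicit integrator's step is diffusion-limited; very fine meshes
  scale as `h⁻⁴` in work.  The default geometry solves in seconds; the
  scheme is not intended for high-resolution convergence studies beyond
  the halved-spacing check above.
* The finite-circle arc partition is exact only up to owner changes
  finer than its localisation sample (bounded by the brute-force
  agreement tests).
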