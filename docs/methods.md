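# Methods

## Model structure and assumptions

The system couples one evolving consumer (a constitutive mixotroph, density
`M`, cells cm⁻²) to one prey (bacteria, `B`, cells cm⁻²) in a well-mixed,
depth-integrated water column. Mixotroph per-capita growth is the sum of a
depth-averaged photosynthesis term and a Type-I grazing term minus constant
mortality `l`; bacteria grow logistically (rate `r`, capacity `K_B`) and are
removed by grazing. The key simplifications, inherited deliberately so that
evolutionary nonlinearity can be attributed to ecological feedback alone:

* **Linear thermal scaling.** Both metabolic rates scale linearly in `T`
  with a hard floor at zero: `max(0, m(T−T0))`. Real thermal reaction norms
  are unimodal; over the 13–33 °C analysis window a linear ramp is a
  deliberate approximation that injects no intrinsic nonlinearity. An
  exponential variant (`exp(m(T−13))`, normalized to one at the 13 °C
  reference) is provided as a configuration switch for sensitivity checks;
  it removes the floors and is not separately calibrated.
* **Temperature-independent prey.** `r` and `K_B` do not respond to `T`, so
  every thermal signal in the results flows through the mixotroph.
* **Type-I grazing** (no handling-time saturation) and a **saturating,
  self-shaded light supply**: light decays with depth through the standing
  mixotroph stock, so photosynthetic growth is strictly decreasing in `M` —
  this density dependence is what bounds the phototrophic population.
* **Trade-off curve** `ρ₀(θ) = ρ_max(1−θ^{2^z})^{2^{−z}}`: a single shape
  parameter `z` interpolates between concave (specialist, `z<0`), linear
  (`z=0`) and convex (generalist, `z>0`) constraint sets. The canonical
  analyses use `z ∈ {−1, 0, 1}`.

Default parameters (the standard *Ochromonas*-type set): `ρ_max = 1 /d`,
`α_max = 1.5·10⁻⁹ cm²/d/cell`, `b = 0.15`, `K_B = 10⁸ cells/cm²` (swept to
`3·10⁸`), `r = 0.693 /d`, `h = 250`, `I_in = 100` (swept to 150) µmol quanta
m⁻² s⁻¹, `k = 5·10⁻⁷ cm²/cell`, `l = 0.05 /d`, `m_ρ = 0.1 /°C` with
`T0_ρ = 3 °C`, `m_α = 0.25 /°C` with `T0_α = 9 °C`. Both thermal multipliers
equal exactly 1 at 13 °C, which is also the reference temperature for the
static-lineage comparison. Light units (per m²) and absorbance (per cm²)
are used exactly as printed, without conversion: the set is internally
consistent only at face value, and all densities should be read as
depth-integrated areal abundances.

## Ecological equilibria

At fixed `(θ, T)` the prey nullcline `B(M) = max(0, K_B(1 − αM/r))` is
substituted into the mixotroph per-capita growth, reducing the steady state
to one scalar equation `g(M) = 0`. Both terms of `g` are strictly
decreasing in `M` (self-shading; prey depletion), so an interior root is
unique. The solver scans a 200-point logarithmic grid over
`M ∈ [10³, 10¹⁰]` cells cm⁻² for sign changes and refines each by Brent's
method to relative tolerance `10⁻¹²`; the scan-and-refine harness would
surface multiple roots if a model variant ever produced them, in which case
the largest locally stable root is designated the resident state (the one
reached by forward dynamics from high density). If growth into the empty
environment (`M→0`, `B=K_B`) is non-positive the strategy is non-viable and
the state is clipped to `(0, K_B)` — the clipping rule that produces the
gray PIP regions. The `prey_extinct` boundary (`αM* ≥ r`) is reported with
a warning but lies outside the analyzed coexistence regime at the default
parameters. Local stability is decided by the eigenvalues of a
central-finite-difference Jacobian (relative step `10⁻⁶`) and is
cross-checked in the tests by perturb-and-integrate; equilibria are
independently verified against long LSODA integrations of the full system.

## Adaptive dynamics

Invasion fitness evaluates the mutant's per-capita growth in the resident's
equilibrium environment; for non-viable residents the environment is the
empty state, so λ degenerates to the mutant's empty-environment growth.
Numerical derivatives use steps chosen to sit well above equilibrium-solver
noise: `10⁻⁵` for the selection gradient (central; one-sided at the
boundaries), `10⁻³` for the mutant-direction curvature. Singular points are
located by scanning the gradient of this *extended* fitness on a 201-point
trait grid and bisecting sign changes — the extension matters, because the
concave trade-off's interior repeller can sit inside the non-viable band.
Classification follows the standard second-order conditions: convergence
stability from the gradient decreasing through zero across residents,
evolutionary stability from negative curvature; `|d²λ|` below `10⁻⁶`
(the linear trade-off's flat landscape) is classified `neutral` and treated
as the evolutionary endpoint for continuation purposes, without exploring
the degenerate coexistence it formally permits. In the rasterized PIP a
fitness threshold of `10⁻¹⁰` keeps solver noise on the λ=0 diagonal from
flickering into the invasion category.

Trait-substitution sequences step the resident by `10⁻³` in trait space,
accepting a step only if the stepped mutant invades, with a final local scan
at `10⁻⁴` resolution; on a flat landscape invasion is neutral to numerical
noise, so an exact two-cycle (A→B→A) terminates the sequence. Interior
endpoints are then polished onto the gradient zero by bisection, which is
what makes the flat-landscape identity (`max|λ| < 10⁻⁶` across all mutants
at the linear trade-off's interior point) hold to tolerance. Inside a
non-viable trait region the sequence follows the direction of improving
(still negative) empty-environment growth, so a frozen branch reports the
nearest boundary rather than an arbitrary interior value; its `viable` flag
carries the biology. Temperature continuation warm-starts each grid point
from the previous attractor, preserving branch identity; concave trade-offs
run two branches (from θ=0.05 and θ=0.95) to expose the bistability
created by the interior repeller. Branching points are detected and
classified but dimorphic dynamics after branching are out of scope.

## Experiments

The carbon-cycling comparison contrasts `evolving` records (strategy =
attractor at each `T`) with `static` records (strategy frozen at the 13 °C
attractor), reporting `P·M*` and `G·M*` as carbon-fixation and
remineralization proxies in cell-growth units (no carbon-mass conversion).
At any equilibrium with `M*>0` these components must sum to `l·M*`, which
serves as an internal consistency identity. For the specialist both
boundary branches are emitted for both scenarios. The resource-landscape
sweep crosses `K_B ∈ {1, 3}·10⁸` with `I_in ∈ {100, 150}` and re-runs the
continuation in each cell. The default analysis grid is 13–33 °C in 1 °C
steps; all threshold temperatures quoted anywhere in this package are
defined on that grid and are therefore only resolved to ±1 grid cell.

## Numerical and design choices worth knowing

* The removable `0/0` of the depth-averaged light factor at `M=0` is
  replaced by its analytic limit `I_in/(h+I_in)` when `kM < 10⁻⁸`.
* The trade-off shape `z` has no default anywhere (constructor, config
  files, CLI): every analysis must state its constraint-curvature
  assumption explicitly.
* Prey depletion `B*(θ)` is non-increasing in θ over most of the viable
  range but *recovers* as θ→1, where the loss of photosynthesis collapses
  `M*` and releases grazing pressure — the depletion-monotonicity property
  is therefore only asserted away from full phagotrophy.
* For the specialist trade-off at default resources the interior singularity
  remains a repeller throughout 9–90 °C; a convergence-stable branching
  point (flanked by two repellers) appears only near ~93 °C and above,
  far outside any ecologically meaningful range — the classification
  machinery is exercised there purely as a structural check.
* The linear trade-off's `M*(T)` peak follows a closed form once the
  attractor reaches θ=1: `M* = (r/α)(1 − l/(bαK_B))` is maximized at
  `α = 2l/(bK_B)`, i.e. `T ≈ 26.8 °C` at defaults, so the grid argmax is
  27 °C.
* The entire pipeline is deterministic; CLI and script `--seed` flags are
  recorded in output metadata for provenance but change nothing.

## What the defaults do and do not show

The default scenarios are idealizations: fixed prey thermodynamics, no
co-evolution, no seasonal forcing, monomorphic evolution to an endpoint
(evolution assumed fast relative to environmental change), and proxies
rather than mass-balanced carbon fluxes. Passing tests demonstrate the
internal logic of the eco-evolutionary feedback — warming favors
phagotrophy until prey depletion reverses selection — not a quantitative
forecast for any real mixotroph population.
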