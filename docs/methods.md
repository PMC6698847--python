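# Methods

## The device model

A wrap-around membrane adsorber module is a radial-flow device: liquid
enters through an axial inlet pipe, distributes along an annular gap,
crosses the membrane wrap radially, collects in an inner cylinder and
leaves through an outlet pipe.  `memchrom` resolves the module into five
1-D zones with individual mass balances:

| zone | role | transport |
|------|------|-----------|
| 1 | inlet pipe | convection–dispersion |
| 2 | annular gap | convection–dispersion + flow splitting |
| 3 | membrane | radial convection–dispersion + adsorption |
| 4 | inner cylinder | convection–dispersion + stream merging |
| 5 | outlet pipe | convection–dispersion |

Every zone obeys ∂c/∂t = −u ∂c/∂x + D_ax ∂²c/∂x², with u the interstitial
radial velocity inside the membrane (u_int = u/ε_m).  The annular gap sheds
an equal share of the volumetric flow at every axial cell (V̇ₓ = V̇ₓ₊₁ + V̇ᵣ
under the constant-resistance assumption), so the membrane is discretised
as independent radial columns, one per splitting cell, each discharging
into the matching inner-cylinder cell where streams merge flow-weighted
(V̇ₓ₊₁ c_{x+1} = V̇ₓ c_x + V̇ᵣ c_r — concentrations of merging streams need
not be equal).  The split/merge mapping is bijective, which requires equal
cell counts in zones 2 and 4.

### Adsorption

Equilibria follow an extended competitive Langmuir model with modifier
(salt) dependence,

    q*_i = H_i c_i / (1 + Σ_j (H_j/qmax_j) c_j) + L1 · c_mod · c_i
    qmax_i = a1_i · c_mod + a2_i
    H_i    = b1_i · c_mod^{b2_i},

with q in g per L of membrane bed volume.  The modifier is transported as a
non-binding species and influences binding only through qmax(c_mod) and
H(c_mod); it does not enter the competitive denominator.  The L1 term is
used for hydrophobic-interaction media only (loading keeps growing with
salt beyond Langmuir saturation); for ion exchange L1 = 0.

Mass transfer is lumped into a single linear-driving-force coefficient:

    ∂q_i/∂t = kla (q*_i(c, c_mod) − q_i)
    ∂c_i/∂t = transport − (1/ε_m) ∂q_i/∂t        (membrane zone).

A sink of the form −kla(c_i − q_i) applied directly to the liquid phase is
sometimes written as a shorthand for this exchange; it does not close
dimensionally or conserve mass, so the driving-force form above is the
default and the bare-sink variant is available behind the
`kinetics="literal"` flag for sensitivity checks only (a test documents the
broken closure).

### Numerics

Finite volumes, first-order upwind advection, central second-order
dispersion, Danckwerts closed-vessel conditions at every zone boundary
(advective flux in, zero dispersive gradient out).  The semi-discrete
system is stiff — the outlet zones carry D_ax = 250 cm²/s — and is
integrated with BDF using an analytically constructed Jacobian sparsity
pattern, rtol 1e-6 and atol 1e-9 g/L.  Negative concentrations are clipped
in reporting only, never in the state.  The default reporting grid is 1 s.

Default grid: 12 axial cells in zones 1/2/4/5 and 10 radial membrane cells
(120 radial columns × cells).  On the tracer fixture the outlet curve
changes by < 0.5% of peak height when every count is doubled (the
grid-convergence test), so this resolution is the default; it keeps a full
bind–elute cycle with four species at a few seconds of CPU.  This is
coarser than the upwind scheme could usefully support on finer studies —
users doing front-shape-critical work should double it.

Because the upwind scheme adds numerical dispersion u·Δx/2 that exceeds the
physical 9×10⁻⁴ cm²/s in the plug-flow pipes, the pipe zones are slightly
more dispersive than nominal.  Their variance contribution is ~10⁻³ of the
total (the outlet zones dominate), so tracer moments are unaffected at the
tested tolerances.

## Tracer analysis

Outlet moments are computed by trapezoidal quadrature after subtracting a
baseline (the smaller of the medians of the first and last 5% of points —
robust when the peak reaches into either window).  Voidage follows from
ε = (t̄ − t̄ᵢ)·V̇/V_m with the instrument dead time t̄ᵢ a required input
(for simulated pulses the injection centroid plays that role).  The
closed-vessel variance relation is inverted by bracketed root search on
log₁₀(D_ax/(v·l)) over (10⁻¹², 10⁶), tolerating the six-decade spread of
per-zone dispersion coefficients; the open-vessel relation has a closed
form.  The closed-vessel normalised variance saturates at 1 (perfectly
mixed), so only values in (0, 1) are invertible and anything else raises.

## Isotherm interpretation and fitting

Finite-bath (shake) experiments give the loading two ways: from depletion,
q = (c_feed − c*)·V_total/V_ads, and from the strip, q = c*_elu·V_total/V_ads.
Under multiplicative detector noise these have very different precision —
the binding balance amplifies noise by V_total/V_ads (~137 for a 13 mm
single-layer coupon in 5 mL) except where depletion is strong, while the
elution balance is uniformly ~noise-level.  The fitter therefore combines
both with inverse-variance weights by default (`loading="both"`); either
single balance can be selected.

The joint fit of (a1, a2, b1, b2[, L1]) uses bounded trust-region least
squares seeded from level-wise Scatchard estimates regressed onto the two
salt laws, with a configurable number of perturbed restarts (seeded)
because the Henry power law creates local minima.  b1 is fitted in log
space; a soft penalty keeps qmax positive over the observed salt window,
and the returned parameter set declares the observed window as its
validity range.  Salt-law fitting requires at least two modifier levels and
two concentration levels; fewer raise an informative error.

Identifiability is structurally limited by the protocol itself: with feed
dilutions up to ~5 g/L and a salt window in which the Henry coefficient
must fall steeply enough for gradient elution, loading approaches the
plateau only at the low-salt end, so the qmax-vs-salt slope a1 carries
little Fisher information regardless of the estimator.  The b-parameters
are recovered to a few percent at 5% noise; a1/a2 can be off by large
factors.  This mirrors the practical observation that such "fast-forward"
batch protocols support conceptual process design rather than rigorous
competitive-isotherm determination.

## Synthetic fixtures

No quantitative isotherm, kla or internal-geometry values are published
for the real modules, so all numeric presets here are SYNTHETIC and
labelled as such.  They were chosen once, to emulate the qualitative study
conditions:

* **Geometry** — 3 mL bed, 8 mm radial thickness, total voidage 0.8
  (flow- and tracer-size-independent).  The hold-up split (0.1/0.1/0.5/0.2
  mL for pipe/gap/cylinder/pipe; membrane porosity 0.5) makes the outlet
  zones ~30% of the accessible volume so that the residence-time
  distribution shows the pronounced steep-front/long-tail shape of the
  real device class.  Zone lengths (2/2.5/0.8/2.5/2 cm) are plausible for
  a laboratory module; none of these dimensions are published.
* **Dispersion** — 9×10⁻⁴ cm²/s (zones 1, 2), 5×10⁻³ cm²/s (membrane),
  250 cm²/s (zones 4, 5): plug flow in the pipes (Bodenstein numbers ≫ 5),
  stirred-tank behaviour at the outlet (Bo ≪ 5, critical value 5).
* **IEX isotherm** — product capacity ~50 g/L falling with salt, Henry
  coefficients falling as cmod^−1.7…−2.0; side components with small
  accessible capacities.  The strong binder is 1% of the feed (aggregates
  in a clarified culture) with a high capacity, which keeps its competitive
  term ≪ the product's: a strongly displacing side component would
  contradict the monotone series-loading gains the device class shows.
* **HIC isotherm** — mirrored salt behaviour (binds at 1 M ammonium
  sulfate, elutes toward 0) plus a small linear salting-out term
  (L1 = 0.3).
* **Feed** — product 5 g/L with 1 g/L total side components (case-study
  preset) or 1 + 0.2 g/L (validation preset), split 95/5 between weak and
  strong binder.
* **kla** — 6 min⁻¹, a fast membrane-typical lumped coefficient.

Bath datasets are generated by solving the coupled finite-bath equilibrium
c + q(c)·V_ads/V_total = c_feed exactly (Powell hybrid), so binding and
elution balances agree to machine precision on noise-free data; noise is
multiplicative Gaussian on the measured supernatants, seeded.  What the
fixtures do **not** emulate: non-Langmuirian real-protein behaviour
(aggregation, slow conformational binding), pH effects, membrane fouling
across cycles, and any quantitative agreement with a specific commercial
module — passing tests demonstrate internal consistency and the qualitative
process findings, not predictive accuracy for real hardware.

## Process scheduling

Modules are simulated one at a time and chained through their outlet
chromatograms (interpolated inlet functions).  This is exact for all
reported quantities — masses and durations — because the series-loading
mass balance is preserved by construction; it deliberately does not model
pump-level concurrency.  Gap-free operation (elution protocol no longer
than the loading phase) is checked logically and produces a warning, or an
error in strict mode.

* **Sequential loading** stops when the product concentration at the last
  outlet crosses a threshold (default 1% of feed); the crossing time is
  interpolated and all module states are taken from the dense solver
  output at that instant.  The head module is eluted with the
  3/6/3/3 CV wash/gradient/regenerate/equilibrate protocol and rotated to
  the back.
* **iCCC** couples an IEX and an HIC module.  Elution chromatograms are cut
  at three user-specified CV positions into front/middle/tail fractions
  (before the first cut is waste), routed by configurable maps (defaults:
  IEX front→IEX, middle and tail→HIC; HIC front→HIC, middle→product,
  tail→IEX).  Recycled fractions are stored as volume-weighted pools,
  assumed re-conditioned to the destination module's loading salt, and
  co-loaded before fresh feed in the next cycle; there is no inter-cycle
  degradation and no cut-point optimiser.  A module whose bound product
  reaches 90% of its saturation capacity q*(feed) before loading ends sets
  the `accumulation` flag — q*(feed)·V_m is the asymptote loading can
  actually approach, which is why the flag is referenced to it rather than
  to qmax.  Cyclic steady state is declared when all per-fraction masses
  change by ≤ 3% (configurable) between consecutive cycles.

The iCCC fractionation fixtures elute with a steep 1 CV gradient at
1 CV/min: under those conditions the hold-up tailing is comparable to the
intrinsic peak width, reproducing the regime in which no workable cut
exists for the tailing module (product trapped circulating on the IEX
side) while a column-packed membrane stack with symmetric peaks reaches a
productive cyclic steady state.

## Campaign arithmetic

The batch-vs-sequential case-study engine is closed-form.  Capacity per
run is fermenter_volume·titer/(runs·module_volume); sequential capacity
multiplies by the measured gain factor (default 1.71 for four modules in
series).  Cycle time is loading time (capacity/titer CV at the loading
flow) plus the 15 CV protocol at 5 CV/min, un-overlapped; per-cycle
productivity is capacity·1440/cycle-time (g/L/day); eluent consumption
counts all pumped liquid — feed plus protocol buffer — per gram,
(capacity/titer + 15)/capacity, the only accounting that reproduces the
published 2.45 and 1.52 L/g (a buffer-only variant would give 2.25 L/g for
the batch case).  Sequential sizing divides the batch membrane volume by
the gain factor and rounds to the nearest liter; cycle counts come from
the unrounded volume.  Batch-to-batch productivity is capacity divided by
the harvest interval, default 365/40 ≈ 9.1 days (configurable — the
interval is a plant-scheduling choice, and the sequential:batch ratio is
independent of it).  Sequential total runtime is reported as
n_cycles·n_modules·cycle_time, an un-overlapped upper bound, and is
labelled a modelling choice.  Module backpressure is linear in flow
(0.2 bar per CV/min per module by default), modules in series add, the
instruments contribute a constant 1.1 bar, and the head module must stay
below 4 bar.

## Known limitations

* First-order upwind limits front sharpness at the default grid; numerical
  dispersion dominates the nominal pipe-zone D_ax (harmless for moments,
  visible in front slopes).
* Zone-3 dispersion acts along the radial coordinate only; there is no
  axial communication between radial columns.
* The literal kinetic mode does not conserve mass (by construction) and is
  for sensitivity checks only.
* Recycled iCCC pools are ideal (no hold-time chemistry, instant salt
  re-conditioning).
* The per-zone dispersion set is configuration, not a fit: the machinery to
  re-estimate it from tracer data is provided (moment analysis + both
  Danckwerts inversions), but the original per-zone fitting objective is
  not reconstructable and is left to users.
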