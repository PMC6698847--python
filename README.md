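# memchrom

Process simulation for **radial-flow membrane chromatography modules** and
the semi-continuous capture processes built from them — aimed at
downstream-processing engineers evaluating continuous antibody capture on
membrane adsorbers before committing lab time.

Membrane adsorbers are disposable, convection-dominated and fast, but have
low binding capacity compared to beads; whether concepts like sequential
(counter-current) loading or integrated counter-current chromatography
(iCCC) pay off on a given module is a scheduling-and-fluid-dynamics
question that simulation answers cheaply.  The catch is that a wrap-around
membrane module is not a column: the inlet pipe, flow-splitting annular
gap, radial membrane wrap, stream-merging inner cylinder and outlet pipe
each contribute their own non-ideality, and the outlet hold-up behaves
like a stirred tank (steep front, long tailing).

## The model

`memchrom` resolves the module into five coupled 1-D zones, each with its
own mass balance

    ∂c_i/∂t = −u ∂c_i/∂x + D_ax ∂²c_i/∂x²

with flow splitting along the annular gap (V̇ₓ = V̇ₓ₊₁ + V̇ᵣ, equal radial
shares) and flow-weighted stream merging in the inner cylinder
(V̇ₓ₊₁ c_{x+1} = V̇ₓ c_x + V̇ᵣ c_r).  The membrane zone adds lumped
adsorption kinetics

    ∂q_i/∂t = kla (q*_i − q_i),    q*_i = H_i c_i / (1 + Σ_j H_j c_j / qmax_j) + L1 c_mod c_i

with salt-dependent Langmuir parameters qmax_i = a1_i·c_mod + a2_i and
H_i = b1_i·c_mod^{b2_i}.  Around this core the package provides

* **tracer analysis** — residence-time moments, voidage
  ε = (t̄ − t̄ᵢ)·V̇/V_m, closed- and open-vessel Danckwerts inversion of the
  variance for D_ax, Bodenstein numbers Bo = u·l/D_ax and flow-regime
  classification;
* **batch-adsorption interpretation and fitting** — binding/elution bath
  mass balances and weighted least-squares estimation of the
  salt-dependent competitive Langmuir parameters;
* **process orchestration** — batch cycles, sequential counter-current
  loading with breakthrough-terminated series loading and chain rotation,
  and iCCC cycles with three-way fraction cutting and pool recycling;
* **a campaign case-study engine** — capacity, runtime, productivity,
  eluent consumption and pressure checks for batch vs. sequential
  operation at 20–2000 L fermenter scale;
* **synthetic fixtures** — a fully parameterised reference module
  (geometry, dispersion set, SYNTHETIC isotherms, feeds) so everything is
  testable without any external data.

## Worked example

Compare a batch and a sequential capture campaign for a 2000 L fed-batch
fermenter (5 g/L titer, 5 L modules, 15 CV protocol, four modules in
series at 3 CV/min):

```bash
memchrom case-study --fermenter 2000 --outdir out/
```

prints

```
                                       2000 L batch  2000 L sequential
Total membrane volume (L)                   1500.00             877.00
Module size (L)                                5.00               5.00
Modules per cycle (-)                          1.00               4.00
Runs/cycles (-)                              300.00              44.00
Runtime (h)                                   16.33              11.03
Capacity (g/L)                                 6.67              11.40
Productivity run/cycle (g/L/day)            2939.00            4366.00
Productivity batch-to-batch (g/L/day)          0.73               1.25
Eluent consumption (L/g)                       2.45               1.52
Pressure head module (bar)                     2.10               3.50
{
  "capacity_pct": 71.0,
  "productivity_pct": 48.56382978723401,
  "eluent_pct": -38.13104189044038,
  "runtime_pct": -32.473469387755095
}
```

Reading: loading four modules in series raises the capacity used per cycle
from 6.67 to 11.4 g of antibody per liter of membrane (+71%), which more
than compensates the slower loading flow — per-cycle productivity rises
48.5% and eluent consumption falls 38% — while the module train stays at
3.5 bar, below the 4 bar limit of the head module.

The simulation side in Python:

```python
from memchrom import moments, voidage
from memchrom.fixtures import FixtureSpec, make_tracer_curve

curve = make_tracer_curve(FixtureSpec(), flow=1.0)   # zonal-model pulse
m = moments(curve)
eps = voidage(m.mean_residence_time, t_instrument=0.099 / 2, flow=1.0, vm=3.0)
print(f"voidage = {eps:.3f}")                        # voidage = 0.800
```

Other subcommands: `simulate` (one module, YAML config), `tracer-fit`,
`fit-isotherm`, `run-sequential`, `run-iccc`, `fixtures`.  See
`docs/methods.md` for the model assumptions, numerical choices and the
synthetic-parameter provenance.

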