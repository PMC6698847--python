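"""Five-zone general-rate model of a radial-flow membrane chromatography module.

A wrap-around membrane module is resolved into five 1-D compartments:

1. inlet pipe            axial convection--dispersion
2. annular gap           axial convection--dispersion + flow splitting
3. membrane              radial convection--dispersion + adsorption kinetics
4. inner cylinder        axial convection--dispersion + stream merging
5. outlet pipe           axial convection--dispersion

The annular gap sheds an equal share of the volumetric flow into the
membrane at every axial position (constant-resistance assumption), so the
membrane is discretised as independent radial columns, one per splitting
cell.  Each column discharges into the matching cell of the inner cylinder,
where the streams merge flow-weighted — concentrations of merging streams
need not be equal.  All zones share the transport equation

    dc/dt = -u dc/dx + Dax d2c/dx2

(with u the interstitial radial velocity inside the membrane), and the
membrane adds a lumped linear-driving-force adsorption exchange

    dq/dt = kla (q_eq(c, cmod) - q)
    dc/dt += -(1/eps_m) dq/dt

with q_eq the salt-dependent competitive Langmuir equilibrium and eps_m the
internal membrane porosity.  This formulation conserves mass and reduces to
the Langmuir equilibrium at steady state; a ``kinetics="literal"`` mode with
the bare sink ``-kla (c - q_eq(c))`` is available for sensitivity checks but
does not close the component mass balance.

Everything is discretised by finite volumes with first-order upwind
advection and central dispersion (Danckwerts closed-vessel ends per zone)
and integrated as one stiff ODE system (BDF with an analytic sparsity
pattern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .core import (
    Chromatogram,
    ComponentSystem,
    ConfigError,
    ModuleGeometry,
    OperatingStep,
    ProcessSchedule,
    ZoneFluidParams,
)
from .isotherms import IsothermParams

__all__ = [
    "ZoneGrid",
    "SimulationResult",
    "build_grid",
    "split_flow",
    "merge_streams",
    "MembraneModule",
    "simulate_module",
    "DEFAULT_RESOLUTION",
]

#: default cells per zone (zones 1,2,3-radial,4,5).  Zones 2 and 4 must match
#: so that the split/merge mapping is bijective.
DEFAULT_RESOLUTION = (12, 12, 10, 12, 12)

#: default solver tolerances; absolute tolerance in g/L.
RTOL = 1e-6
ATOL = 1e-9

#: default reporting interval, minutes (1 s).
REPORT_DT = 1.0 / 60.0


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZoneGrid:
    """Finite-volume discretisation of the five zones.

    Cell ordering: zone 1 | zone 2 | zone 3 (column-major: the radial column
    fed by zone-2 cell ``i`` occupies ``i*n3 .. (i+1)*n3``) | zone 4 |
    zone 5.  Column ``i`` discharges into zone-4 cell ``i`` (bijective
    mapping between splitting and merging cells).
    """

    geometry: ModuleGeometry
    n: tuple[int, int, int, int, int]  # cells per zone; n[2] = radial cells

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.n):
            raise ConfigError(f"resolution must be >= 1 per zone, got {self.n}")
        if self.n[1] != self.n[3]:
            raise ConfigError(
                f"zones 2 and 4 need matching cell counts for the split/merge "
                f"mapping, got {self.n[1]} and {self.n[3]}"
            )

    # -- sizes ------------------------------------------------------------
    @property
    def n_columns(self) -> int:
        return self.n[1]

    @property
    def n_cells(self) -> int:
        n1, n2, n3, n4, n5 = self.n
        return n1 + n2 + n2 * n3 + n4 + n5

    def slices(self) -> tuple[slice, slice, slice, slice, slice]:
        n1, n2, n3, n4, n5 = self.n
        o = np.cumsum([0, n1, n2, n2 * n3, n4, n5])
        return tuple(slice(int(o[i]), int(o[i + 1])) for i in range(5))

    # -- volumes / lengths -------------------------------------------------
    @property
    def cell_lengths(self) -> tuple[float, ...]:
        return tuple(l / k for l, k in zip(self.geometry.zone_lengths, self.n))

    @property
    def cell_volumes(self) -> tuple[float, ...]:
        """Geometric cell volume per zone, mL."""
        return tuple(v / k for v, k in zip(self.geometry.zone_volumes, (self.n[0], self.n[1], self.n[1] * self.n[2], self.n[3], self.n[4])))

    @property
    def liquid_cell_volumes(self) -> tuple[float, ...]:
        """Liquid-accessible cell volume per zone, mL (membrane scaled by porosity)."""
        v = list(self.cell_volumes)
        v[2] *= self.geometry.membrane_porosity
        return tuple(v)


def build_grid(geometry: ModuleGeometry, resolution=None) -> ZoneGrid:
    """Build a finite-volume grid; ``resolution`` is an int or 5-tuple."""
    if resolution is None:
        resolution = DEFAULT_RESOLUTION
    if np.isscalar(resolution):
        resolution = (int(resolution),) * 5
    return ZoneGrid(geometry=geometry, n=tuple(int(k) for k in resolution))


# ---------------------------------------------------------------------------
# elementary flow operations
# ---------------------------------------------------------------------------


def split_flow(v_axial_in: float, grid: ZoneGrid, cell_index: int) -> tuple[float, float]:
    """Split the axial flow at annular-gap cell ``cell_index`` (0-based).

    Constant fluid-dynamic resistance along the membrane surface means every
    splitting cell sheds the same radial flow, so the remaining axial flow is
    divided equally among the remaining cells; the axial flow reaches exactly
    zero after the last cell.
    """
    if v_axial_in < 0:
        raise ValueError(f"axial flow must be >= 0, got {v_axial_in}")
    remaining = grid.n_columns - cell_index
    if remaining < 1:
        raise IndexError(f"cell_index {cell_index} outside zone 2 (n={grid.n_columns})")
    v_radial = v_axial_in / remaining
    return v_axial_in - v_radial, v_radial


def merge_streams(
    axial: tuple[float, np.ndarray], radial: tuple[float, np.ndarray]
) -> tuple[float, np.ndarray]:
    """Flow-weighted merge of an axial and a radial stream.

    Each argument is ``(flow mL/min, concentration array)``; returns the
    merged flow and mixing-rule concentrations.
    """
    (qa, ca), (qr, cr) = axial, radial
    if qa < 0 or qr < 0:
        raise ValueError("flows must be >= 0")
    q = qa + qr
    if q == 0:
        raise ValueError("cannot merge two zero-flow streams")
    return q, (qa * np.asarray(ca, float) + qr * np.asarray(cr, float)) / q


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    chromatogram: Chromatogram
    mass_balance: dict[str, dict[str, float]]  # per species: injected/eluted/retained (mg)
    final_state: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def closure_error(self, name: str) -> float:
        """|in + initial - out - final| / max(in + initial, out + final)."""
        mb = self.mass_balance[name]
        lhs = mb["injected"] + mb["retained_initial"]
        rhs = mb["eluted"] + mb["retained_final"]
        denom = max(lhs, rhs, 1e-12)
        return abs(lhs - rhs) / denom


# ---------------------------------------------------------------------------
# the module simulator
# ---------------------------------------------------------------------------


class MembraneModule:
    """A fully parameterised membrane module ready for simulation.

    ``species`` are the transported liquid components; those whose role is
    neither ``modifier`` nor ``tracer`` adsorb according to ``isotherm``
    (one parameter set per binding species, in order).  Without binding
    species the module is a pure fluid-dynamics network (tracer mode).
    """

    def __init__(
        self,
        geometry: ModuleGeometry,
        fluidics: ZoneFluidParams | None = None,
        isotherm: IsothermParams | None = None,
        species: ComponentSystem | None = None,
        resolution=None,
        kinetics: str = "ldf",
        name: str = "module",
    ):
        self.geometry = geometry
        self.fluidics = fluidics if fluidics is not None else ZoneFluidParams()
        self.isotherm = isotherm
        self.name = name
        if kinetics not in ("ldf", "literal"):
            raise ConfigError(f"kinetics must be 'ldf' or 'literal', got {kinetics!r}")
        self.kinetics = kinetics
        self.grid = build_grid(geometry, resolution)

        if species is None:
            from .core import Component

            species = ComponentSystem(
                components=(Component(id=1, name="tracer", role="tracer"),),
                feed_concentrations=(0.0,),
            )
        self.species = species
        self.species_names = list(species.names)
        roles = [c.role for c in species.components]
        self.binding_idx = [i for i, r in enumerate(roles) if r not in ("modifier", "tracer")]
        mod_idx = [i for i, r in enumerate(roles) if r == "modifier"]
        self.modifier_idx = mod_idx[0] if mod_idx else None
        if self.binding_idx:
            if self.isotherm is None:
                raise ConfigError("binding species present but no isotherm parameters given")
            if self.isotherm.n_components != len(self.binding_idx):
                raise ConfigError(
                    f"isotherm has {self.isotherm.n_components} component(s) but the "
                    f"system has {len(self.binding_idx)} binding species"
                )
        self._prepare_static()

    # -- static precomputation --------------------------------------------
    def _prepare_static(self) -> None:
        g = self.grid
        n1, n2, n3, n4, n5 = g.n
        self.ns = len(self.species_names)
        self.nb = len(self.binding_idx)
        self.n_cells = g.n_cells
        self.n_mem = n2 * n3
        self.n_state = self.n_cells * self.ns + self.n_mem * self.nb
        self.sl = g.slices()
        self.Vl = g.liquid_cell_volumes  # liquid volume per cell, per zone
        self.Vmem_cell = g.cell_volumes[2]  # geometric membrane cell volume
        self.eps_m = self.geometry.membrane_porosity
        # dispersion conductances g = D*A/dx (mL/min); Dax cm^2/s -> cm^2/min
        areas = self.geometry.zone_cross_sections
        dx = g.cell_lengths
        dax_min = [d * 60.0 for d in self.fluidics.dax]
        self.g_disp = [dax_min[z] * areas[z] / dx[z] for z in range(5)]
        self.g_disp[2] = dax_min[2] * (areas[2] / n2) / dx[2]  # per radial column
        self._jac_sparsity = None

    # -- state handling ----------------------------------------------------
    def initial_state(self, c0: dict[str, float] | None = None) -> np.ndarray:
        """Uniform initial state (default: everything at zero)."""
        c = np.zeros((self.n_cells, self.ns))
        if c0:
            for name, val in c0.items():
                c[:, self.species_names.index(name)] = val
        q = np.zeros((self.n_mem, self.nb))
        if self.nb and c0:
            cmod = c[0, self.modifier_idx] if self.modifier_idx is not None else 0.0
            from .isotherms import q_equilibrium

            cb = c[0, self.binding_idx]
            if np.any(cb > 0):
                q[:] = q_equilibrium(cb, max(cmod, self.isotherm.modifier_range[0]), self.isotherm)
        return np.concatenate([c.ravel(), q.ravel()])

    def unpack(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = y[: self.n_cells * self.ns].reshape(self.n_cells, self.ns)
        q = y[self.n_cells * self.ns :].reshape(self.n_mem, self.nb)
        return c, q

    def liquid_mass(self, y: np.ndarray) -> np.ndarray:
        """Per-species liquid hold-up mass (mg)."""
        c, _ = self.unpack(y)
        vols = np.empty(self.n_cells)
        for z, sl in enumerate(self.sl):
            vols[sl] = self.Vl[z]
        return vols @ c

    def bound_mass(self, y: np.ndarray) -> np.ndarray:
        """Per-species bound mass (mg); zeros for non-binding species."""
        _, q = self.unpack(y)
        out = np.zeros(self.ns)
        out[self.binding_idx] = q.sum(axis=0) * self.Vmem_cell
        return out

    def bound_loading(self, y: np.ndarray) -> np.ndarray:
        """Average membrane loading per binding species, g per L membrane volume."""
        _, q = self.unpack(y)
        return q.mean(axis=0) if self.nb else np.zeros(0)

    # -- right-hand side ----------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, Q: float, inlet_fn) -> np.ndarray:
        """Semi-discrete residual d(state)/dt at time ``t`` (minutes).

        ``Q`` is the volumetric flow in mL/min, ``inlet_fn(t)`` the inlet
        concentration vector (g/L; modifier slot in mol/L).
        """
        if not np.all(np.isfinite(y)):
            bad = np.flatnonzero(~np.isfinite(y))[0]
            raise FloatingPointError(f"non-finite state at index {bad} (t={t:.4f} min)")
        g = self.grid
        n1, n2, n3, n4, n5 = g.n
        c, q = self.unpack(y)
        dc = np.zeros_like(c)
        s1, s2, s3, s4, s5 = self.sl
        qr = Q / n2  # radial flow per column

        c_in = np.asarray(inlet_fn(t), dtype=float)

        # zone 1: plug-flow pipe
        c1 = c[s1]
        up = np.vstack([c_in, c1[:-1]])
        flux = self.g_disp[0] * np.diff(c1, axis=0)
        # dispersion: d(c)/dt += (flux_above - flux_below)/V with zero-flux ends
        dc1 = np.zeros_like(c1)
        dc1[:-1] += flux / self.Vl[0]
        dc1[1:] -= flux / self.Vl[0]
        dc[s1] = (Q * (up - c1)) / self.Vl[0] + dc1

        # zone 2: annular gap with flow splitting
        c2 = c[s2]
        f_in = Q * (1.0 - np.arange(n2) / n2)  # axial flow entering cell k
        up2 = np.vstack([c1[-1], c2[:-1]])
        flux2 = self.g_disp[1] * np.diff(c2, axis=0)
        dc2 = (f_in[:, None] * up2 - f_in[:, None] * c2) / self.Vl[1]
        dc2[:-1] += flux2 / self.Vl[1]
        dc2[1:] -= flux2 / self.Vl[1]
        dc[s2] = dc2

        # zone 3: membrane columns (radial transport + adsorption)
        c3 = c[s3].reshape(n2, n3, self.ns)
        up3 = np.concatenate([c2[:, None, :], c3[:, :-1, :]], axis=1)
        flux3 = self.g_disp[2] * np.diff(c3, axis=1)
        dc3 = qr * (up3 - c3) / self.Vl[2]
        dc3[:, :-1] += flux3 / self.Vl[2]
        dc3[:, 1:] -= flux3 / self.Vl[2]

        dq = np.zeros_like(q)
        if self.nb:
            iso = self.isotherm
            cb = c3[:, :, self.binding_idx].reshape(self.n_mem, self.nb)
            if self.modifier_idx is not None:
                cmod = c3[:, :, self.modifier_idx].reshape(self.n_mem)
            else:
                cmod = np.full(self.n_mem, iso.modifier_range[0])
            cmod_c = np.clip(cmod, 1e-12, None)
            qmax = np.maximum(cmod_c[:, None] * iso.a1 + iso.a2, 1e-9)
            h = iso.b1 * cmod_c[:, None] ** iso.b2
            cb_pos = np.maximum(cb, 0.0)
            denom = 1.0 + np.sum(h / qmax * cb_pos, axis=1, keepdims=True)
            qstar = h * cb_pos / denom + iso.l1 * cmod_c[:, None] * cb_pos
            if self.kinetics == "ldf":
                dq = iso.kla * (qstar - q)
                sink = dq.reshape(n2, n3, self.nb) / self.eps_m
            else:  # literal printed form: bare sink, q tracks equilibrium
                sink_flat = iso.kla * (cb - qstar)
                dq = iso.kla * (qstar - q)
                sink = sink_flat.reshape(n2, n3, self.nb)
            dc3[:, :, self.binding_idx] -= sink
        dc[s3] = dc3.reshape(self.n_mem, self.ns)

        # zone 4: inner cylinder, merging radial discharges
        c4 = c[s4]
        f_ax = qr * np.arange(n4)  # axial flow entering cell k
        up4 = np.vstack([np.zeros(self.ns), c4[:-1]])
        c3_out = c3[:, -1, :]
        flux4 = self.g_disp[3] * np.diff(c4, axis=0)
        dc4 = (f_ax[:, None] * up4 + qr * c3_out - (f_ax[:, None] + qr) * c4) / self.Vl[3]
        dc4[:-1] += flux4 / self.Vl[3]
        dc4[1:] -= flux4 / self.Vl[3]
        dc[s4] = dc4

        # zone 5: outlet pipe
        c5 = c[s5]
        up5 = np.vstack([c4[-1], c5[:-1]])
        flux5 = self.g_disp[4] * np.diff(c5, axis=0)
        dc5 = (Q * (up5 - c5)) / self.Vl[4]
        dc5[:-1] += flux5 / self.Vl[4]
        dc5[1:] -= flux5 / self.Vl[4]
        dc[s5] = dc5

        return np.concatenate([dc.ravel(), dq.ravel()])

    # -- sparsity -----------------------------------------------------------
    def jac_sparsity(self) -> sparse.csr_matrix:
        """Superset sparsity pattern of the Jacobian (built once per module)."""
        if self._jac_sparsity is not None:
            return self._jac_sparsity
        ns, nb = self.ns, self.nb
        n1, n2, n3, n4, n5 = self.grid.n
        rows: list[int] = []
        cols: list[int] = []

        def cidx(cell: int, spec: int) -> int:
            return cell * ns + spec

        def qidx(mem_cell: int, b: int) -> int:
            return self.n_cells * ns + mem_cell * nb + b

        def couple(i: int, j: int) -> None:
            rows.append(i)
            cols.append(j)

        s1, s2, s3, s4, s5 = self.sl
        mem_start = s3.start

        # axial neighbour chains (zones 1,2,4,5 and inter-zone links)
        chains = [list(range(s1.start, s1.stop)) , list(range(s2.start, s2.stop)),
                  list(range(s4.start, s4.stop)), list(range(s5.start, s5.stop))]
        for chain in chains:
            for a, b_ in zip(chain, chain[1:]):
                for s in range(ns):
                    couple(cidx(a, s), cidx(b_, s))
                    couple(cidx(b_, s), cidx(a, s))
            for a in chain:
                for s in range(ns):
                    couple(cidx(a, s), cidx(a, s))
        # zone1 -> zone2, zone4 -> zone5
        for s in range(ns):
            couple(cidx(s2.start, s), cidx(s1.stop - 1, s))
            couple(cidx(s5.start, s), cidx(s4.stop - 1, s))
        # membrane columns
        for col in range(n2):
            cells = [mem_start + col * n3 + r for r in range(n3)]
            for a, b_ in zip(cells, cells[1:]):
                for s in range(ns):
                    couple(cidx(a, s), cidx(b_, s))
                    couple(cidx(b_, s), cidx(a, s))
            for s in range(ns):
                couple(cidx(cells[0], s), cidx(s2.start + col, s))  # fed by gap cell
                couple(cidx(s4.start + col, s), cidx(cells[-1], s))  # discharges to cylinder
                for a in cells:
                    couple(cidx(a, s), cidx(a, s))
            # Langmuir coupling: all binding species + modifier + q in one cell
            for r in range(n3):
                cell = mem_start + col * n3 + r
                mem_cell = col * n3 + r
                local = [self.binding_idx[i] for i in range(nb)]
                if self.modifier_idx is not None:
                    local = local + [self.modifier_idx]
                for si in local:
                    for sj in local:
                        couple(cidx(cell, si), cidx(cell, sj))
                for bi in range(nb):
                    for sj in local:
                        couple(qidx(mem_cell, bi), cidx(cell, sj))
                        couple(cidx(cell, sj), qidx(mem_cell, bi))
                    couple(qidx(mem_cell, bi), qidx(mem_cell, bi))
                    for s in range(ns):
                        couple(cidx(cell, s), qidx(mem_cell, bi))
        m = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_state, self.n_state)
        ).tocsr()
        self._jac_sparsity = m
        return m

    # -- integration --------------------------------------------------------
    def run_step(
        self,
        y0: np.ndarray,
        duration_min: float,
        flow_ml_min: float,
        inlet_fn,
        t0: float = 0.0,
        report_dt: float = REPORT_DT,
        events=None,
        rtol: float = RTOL,
        atol: float = ATOL,
    ):
        """Integrate one constant-flow interval.

        ``inlet_fn(t)`` must return the inlet concentration vector at
        absolute time ``t``.  Returns ``(t_grid, outlet, y_end, sol)`` where
        ``outlet`` has shape ``(len(t_grid), n_species)``.
        """
        t1 = t0 + duration_min
        n_pts = max(int(math.ceil(duration_min / report_dt)) + 1, 2)
        t_eval = np.linspace(t0, t1, n_pts)
        sol = solve_ivp(
            self.rhs,
            (t0, t1),
            y0,
            method="BDF",
            t_eval=t_eval,
            args=(flow_ml_min, inlet_fn),
            jac_sparsity=self.jac_sparsity(),
            rtol=rtol,
            atol=atol,
            events=events,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed in {self.name!r} at t={sol.t[-1] if len(sol.t) else t0:.4f} min: "
                f"{sol.message}"
            )
        outlet_cells = sol.y[: self.n_cells * self.ns].reshape(self.n_cells, self.ns, -1)
        outlet = outlet_cells[self.sl[4].stop - 1].T  # last cell of zone 5
        y_end = sol.y[:, -1] if sol.status == 0 else sol.sol(sol.t[-1])
        return sol.t, outlet, y_end, sol

    def simulate(
        self,
        schedule: ProcessSchedule,
        y0: np.ndarray | None = None,
        inlet_overrides: dict[str, object] | None = None,
        report_dt: float = REPORT_DT,
        rtol: float = RTOL,
        atol: float = ATOL,
    ) -> SimulationResult:
        """Run a full operating schedule and assemble the chromatogram.

        ``inlet_overrides`` maps a step name to a callable ``f(t) -> array``
        replacing that step's constant inlet composition (used to chain
        modules in series).
        """
        if y0 is None:
            first = schedule.steps[0]
            init = {}
            if self.modifier_idx is not None:
                init[self.species_names[self.modifier_idx]] = first.modifier_start
            y0 = self.initial_state(init)
        y = np.array(y0, dtype=float)
        t_all: list[np.ndarray] = []
        out_all: list[np.ndarray] = []
        mod_all: list[np.ndarray] = []
        flow_all: list[np.ndarray] = []
        injected = np.zeros(self.ns)
        retained0 = self.liquid_mass(y) + self.bound_mass(y)
        t0 = 0.0
        n_steps_solver = 0
        for step in schedule:
            Q = step.flow * self.geometry.membrane_volume
            dur = step.duration_min(self.geometry)
            inlet_fn = self._inlet_for(step, t0, dur, inlet_overrides)
            t, outlet, y, sol = self.run_step(
                y, dur, Q, inlet_fn, t0=t0, report_dt=report_dt, rtol=rtol, atol=atol
            )
            n_steps_solver += sol.t.size
            cin = np.array([inlet_fn(ti) for ti in t])
            injected += np.trapezoid(cin * Q, t, axis=0)
            t_all.append(t)
            out_all.append(outlet)
            if self.modifier_idx is not None:
                mod_all.append(outlet[:, self.modifier_idx])
            flow_all.append(np.full(len(t), Q))
            t0 += dur
        t = np.concatenate([a if i == 0 else a[1:] for i, a in enumerate(t_all)])
        out = np.vstack([a if i == 0 else a[1:] for i, a in enumerate(out_all)])
        flow = np.concatenate([a if i == 0 else a[1:] for i, a in enumerate(flow_all)])
        out_clip = np.clip(out, 0.0, None)  # clipped in reporting only
        conc = {
            name: out_clip[:, i]
            for i, name in enumerate(self.species_names)
            if i != self.modifier_idx
        }
        modifier = out_clip[:, self.modifier_idx] if self.modifier_idx is not None else None
        chrom = Chromatogram(
            time=t, concentrations=conc, modifier=modifier, flow=flow,
            metadata={"module": self.name},
        )
        eluted = np.trapezoid(out * flow[:, None], t, axis=0)
        retained1 = self.liquid_mass(y) + self.bound_mass(y)
        mass_balance = {
            name: {
                "injected": float(injected[i]),
                "eluted": float(eluted[i]),
                "retained_initial": float(retained0[i]),
                "retained_final": float(retained1[i]),
            }
            for i, name in enumerate(self.species_names)
        }
        return SimulationResult(
            chromatogram=chrom,
            mass_balance=mass_balance,
            final_state=y,
            diagnostics={"solver_points": n_steps_solver, "rtol": rtol, "atol": atol},
        )

    def _inlet_for(self, step: OperatingStep, t0: float, dur: float, overrides):
        if overrides and step.name in overrides:
            return overrides[step.name]
        base = np.zeros(self.ns)
        for name, val in step.inlet_composition.items():
            base[self.species_names.index(name)] = val
        mi = self.modifier_idx
        m0, m1 = step.modifier_start, step.modifier_stop

        def inlet(t: float, base=base, t0=t0, dur=dur, m0=m0, m1=m1, mi=mi):
            v = base.copy()
            if mi is not None:
                frac = np.clip((t - t0) / dur, 0.0, 1.0)
                v[mi] = m0 + (m1 - m0) * frac
            return v

        return inlet


def simulate_module(
    geometry: ModuleGeometry,
    fluidics: ZoneFluidParams,
    isotherm: IsothermParams | None,
    schedule: ProcessSchedule,
    feed: ComponentSystem,
    resolution=None,
    **kwargs,
) -> SimulationResult:
    """Convenience wrapper: build a :class:`MembraneModule` and run a schedule."""
    module = MembraneModule(
        geometry, fluidics, isotherm, species=feed, resolution=resolution
    )
    return module.simulate(schedule, **kwargs)
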