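"""Transient axisymmetric heat conduction and moisture diffusion in the bean.

Solves the coupled solid-side problem

    rho(T) Cp(T) dT/dt = div(k(T) grad T)
    dc/dt = div(Deff(T) grad c)

on the two-layer (testa shell + cotyledon core) axisymmetric mesh with
convective/evaporative boundary conditions on the solid-air surface,

    -k dT/dn = h (T - T_air) + q_evap
    -D dc/dn = hm (c - c_inf)

and zero-flux symmetry conditions on the axis.  The film coefficients h and
hm come from the sphere correlations Nu/Sh = 2 + 0.552 Re^0.53 (Pr,Sc)^(1/3);
no external flow field is solved.

The evaporative heat sink q_evap converts the outgoing molar moisture flux
into a latent-heat debit.  Because the nominal initial concentration
co = 10,878 mol/m^3 under-represents the bean's actual water inventory, the
mass carried per model-mole is calibrated by default so the total latent
debit equals the enthalpy of the water mass that actually leaves
(``latent_basis="inventory"``); the literal molar basis (0.018 kg/mol) is
available as ``latent_basis="molar"``.

The raw Robin closure hm (c_solid - c_inf) mixes a solid-phase concentration
with a vapor-side coefficient; taken literally it implies surface moisture
fluxes orders of magnitude beyond what air can carry and collapses the
surface concentration within one time step.  With ``vapor_limited=True``
(default) the surface mass flux is therefore saturated at the vapor-side
carrying capacity hm (c_sat(T_s) - c_inf) (expressed in model moles via the
calibrated mass basis), implemented as a Robin coefficient
hm_eff = min(hm, cap/(c_s - c_inf)) lagged one step.  While the cap binds
the bean dries at the classic constant-rate (wet-bulb) period; once internal
diffusion becomes limiting the condition reverts to the plain Robin flux.
The latent sink is always lambda * m_cal * (actual molar flux), so heat and
mass leave the surface consistently.  See docs/methods.md.

Time integration is implicit (backward Euler by default, Crank-Nicolson
optional) with row-sum lumped mass matrices; material properties and Deff
are lagged and the operators refreshed once the temperature field drifts by
more than ``property_refresh_dT`` since the last assembly, reusing the
sparse LU factorization in between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import properties as props
from .fem import P1Operators
from .geometry import CORE, SHELL, BeanGeometry, Mesh, generate_mesh

__all__ = [
    "TissueMaterial",
    "default_materials",
    "homogenized_material",
    "BoundaryConditions",
    "InitialConditions",
    "SolverConfig",
    "SimulationResult",
    "SimulationInvariantError",
    "TransportProblem",
    "run",
    "moisture_trace_to_mcdb",
    "grid_convergence_study",
    "compare_single_vs_multidomain",
    "average_relative_error",
]

M_WATER = 0.018  # kg/mol


@dataclass(frozen=True)
class TissueMaterial:
    """Temperature-dependent rho/cp/k of one subdomain.

    ``rho`` kg/m^3, ``cp`` kJ/(kg °C), ``k`` W/(m °C); each a vectorized
    callable of T in °C.  ``water_fraction`` (mass) is carried along for the
    latent-heat calibration when known.
    """

    name: str
    rho: object
    cp: object
    k: object
    water_fraction: float | None = None

    @classmethod
    def from_polynomials(cls, name, poly: props.PropertyPolynomials, water_fraction=None):
        return cls(
            name=name,
            rho=lambda T: np.polyval(poly.rho, T),
            cp=lambda T: np.polyval(poly.cp, T),
            k=lambda T: np.polyval(poly.k, T),
            water_fraction=water_fraction,
        )

    @classmethod
    def from_composition(cls, name, comp: props.ProximateComposition):
        def make(idx):
            return lambda T: props._mixture_rck(comp, T)[idx]

        return cls(name=name, rho=make(0), cp=make(1), k=make(2),
                   water_fraction=comp.water)

    @classmethod
    def uniform(cls, name, rho, cp, k, water_fraction=None):
        """Constant-property material (oracle/verification cases)."""
        return cls(
            name=name,
            rho=lambda T: np.full_like(np.asarray(T, float), rho),
            cp=lambda T: np.full_like(np.asarray(T, float), cp),
            k=lambda T: np.full_like(np.asarray(T, float), k),
            water_fraction=water_fraction,
        )


def default_materials(source: str = "published") -> dict:
    """Shell/core materials for the CCN51 bean.

    source="published": the quadratic correlations fitted over 40-70 °C
    (the curves the reference simulation uses); source="composition": the
    Choi-Okos mixture evaluated directly from the proximate compositions.
    """
    if source == "published":
        return {
            "shell": TissueMaterial.from_polynomials(
                "testa", props.SHELL_CORRELATIONS,
                water_fraction=props.TESTA_COMPOSITION.water),
            "core": TissueMaterial.from_polynomials(
                "cotyledon", props.CORE_CORRELATIONS,
                water_fraction=props.COTYLEDON_COMPOSITION.water),
        }
    if source == "composition":
        return {
            "shell": TissueMaterial.from_composition("testa", props.TESTA_COMPOSITION),
            "core": TissueMaterial.from_composition("cotyledon", props.COTYLEDON_COMPOSITION),
        }
    raise ValueError(f"unknown material source {source!r}")


def homogenized_material(materials: dict, weights: dict, name="homogenized") -> TissueMaterial:
    """Volume-weighted blend of the property curves (single-domain model)."""
    wtot = sum(weights.values())
    w = {k: v / wtot for k, v in weights.items()}

    def mix(attr):
        return lambda T: sum(w[key] * getattr(materials[key], attr)(T) for key in w)

    wf = None
    if all(materials[k].water_fraction is not None for k in w):
        wf = sum(w[k] * materials[k].water_fraction for k in w)
    return TissueMaterial(name=name, rho=mix("rho"), cp=mix("cp"), k=mix("k"),
                          water_fraction=wf)


@dataclass(frozen=True)
class InitialConditions:
    """Uniform initial bean temperature (°C) and moisture concentration."""

    To: float = 24.0
    co: float = 10_878.0  # mol/m^3

    def __post_init__(self):
        if self.co <= 0:
            raise ValueError("initial concentration must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Film-side closure of the surface heat and moisture fluxes."""

    air: props.AirState
    h: float  # W/(m^2 °C)
    hm: float  # m/s
    c_inf: float  # mol/m^3
    latent_heat: float = 2.38e6  # J/kg, water near 50 °C
    latent_mass_per_mol: float = M_WATER  # kg per model-mole of moisture
    # saturate the surface mass flux at the vapor-side carrying capacity
    # hm (c_sat(T_s) - c_inf) — the constant-rate drying limit
    vapor_limited: bool = True
    characteristic_length: float | None = None

    def __post_init__(self):
        if self.h <= 0 and self.hm < 0:
            raise ValueError("film coefficients must be positive")
        if self.latent_heat < 0:
            raise ValueError("latent heat must be non-negative")

    @classmethod
    def from_air(
        cls,
        air: props.AirState,
        geometry: BeanGeometry,
        ic: InitialConditions | None = None,
        materials: dict | None = None,
        latent_basis: str = "inventory",
        latent_heat: float = 2.38e6,
        characteristic_length: float | None = None,
        vapor_limited: bool = True,
    ) -> "BoundaryConditions":
        """Build the boundary closure from the air state and geometry.

        latent_basis="inventory" calibrates the evaporated mass per
        model-mole against the composition-based water inventory of the
        bean; "molar" uses 0.018 kg/mol literally.
        """
        L = characteristic_length or geometry.equivalent_sphere_diameter
        h, hm = props.film_coefficients(air, L)
        c_inf = props.far_field_vapor_concentration(air)
        ic = ic or InitialConditions()
        if latent_basis == "molar":
            mass_per_mol = M_WATER
        elif latent_basis == "inventory":
            mats = materials or default_materials()
            mass_per_mol = _calibrated_mass_per_mol(geometry, ic, mats)
        else:
            raise ValueError(f"unknown latent_basis {latent_basis!r}")
        return cls(
            air=air, h=h, hm=hm, c_inf=c_inf, latent_heat=latent_heat,
            latent_mass_per_mol=mass_per_mol, vapor_limited=vapor_limited,
            characteristic_length=L,
        )


def _calibrated_mass_per_mol(geometry: BeanGeometry, ic: InitialConditions,
                             materials: dict) -> float:
    """kg of water per model-mole: (initial water mass) / (co * volume)."""
    V = geometry.volume
    t = geometry.shell_thickness
    inner = BeanGeometry(geometry.length - 2 * t, geometry.width - 2 * t, 0.0)
    v_core, v_shell = inner.volume, V - inner.volume
    water = 0.0
    for key, vol in (("shell", v_shell), ("core", v_core)):
        mat = materials.get(key) or materials.get("core")
        wf = mat.water_fraction
        if wf is None:
            raise ValueError(
                f"material {mat.name!r} has no water fraction; cannot calibrate "
                "the latent basis — pass latent_basis='molar' or set it"
            )
        water += wf * float(np.asarray(mat.rho(ic.To))) * vol
    return water / (ic.co * V)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls of the transient solve."""

    dt: float = 5.0  # s
    t_end: float = 350 * 60.0  # s
    theta: float = 1.0  # 1 = backward Euler, 0.5 = Crank-Nicolson
    property_refresh_dT: float = 0.25  # °C drift triggering reassembly
    picard: bool = False  # iterate properties within the step
    picard_tol: float = 1e-6
    picard_max_iter: int = 25
    trace_cadence: float = 60.0  # s between trace samples
    snapshot_cadence: float = 600.0  # s between stored field snapshots
    store_snapshots: bool = True
    check_invariants: bool = True
    abort_rtol: float = 1e-3  # runtime guard, relative to the data span

    def __post_init__(self):
        if self.dt <= 0 or self.t_end < self.dt:
            raise ValueError("need dt > 0 and t_end >= dt")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0.5, 1]")


class SimulationInvariantError(RuntimeError):
    """A bounds or conservation invariant was violated during the run."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state or {}


@dataclass
class SimulationResult:
    """Traces, extrema and optional snapshots of one drying simulation."""

    times: np.ndarray  # s
    T_core: np.ndarray  # °C at the bean center
    T_surface: np.ndarray  # °C at the equatorial surface node
    T_mean: np.ndarray  # volume-weighted mean temperature, °C
    c_mean: np.ndarray  # volume-weighted mean concentration, mol/m^3
    inventory: np.ndarray  # mol of moisture in the bean
    outflow_rate: np.ndarray  # mol/s across the surface
    cumulative_outflow: np.ndarray  # mol
    heat_in_rate: np.ndarray  # W convective heat into the bean
    evap_rate: np.ndarray  # W latent sink
    T_min: float
    T_max: float
    c_min: float
    c_max: float
    snapshot_times: np.ndarray
    snapshots_T: np.ndarray
    snapshots_c: np.ndarray
    mesh: Mesh
    bc: BoundaryConditions
    ic: InitialConditions
    config: SolverConfig
    meta: dict = field(default_factory=dict)

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0

    def conservation_error(self) -> float:
        """max_t |cumulative outflow - inventory deficit| / initial inventory."""
        inv0 = self.inventory[0]
        return float(np.max(np.abs(self.cumulative_outflow - (inv0 - self.inventory))) / inv0)

    def plateau_temperature(self, t_start_min=60.0, t_end_min=240.0) -> float:
        """Median core temperature over the quasi-steady window (°C)."""
        m = (self.times_min >= t_start_min) & (self.times_min <= t_end_min)
        if not m.any():
            raise ValueError("no trace samples inside the requested window")
        return float(np.median(self.T_core[m]))

    def mr_trace(self, ce: float | None = None) -> np.ndarray:
        """Moisture ratio (c_mean - ce)/(co - ce); ce defaults to c_inf."""
        ce = self.bc.c_inf if ce is None else ce
        return (self.c_mean - ce) / (self.ic.co - ce)

    def mcdb_trace(self, mcdb0: float = 1.82) -> np.ndarray:
        """Dry-basis moisture content; linear map anchored at co -> mcdb0."""
        return moisture_trace_to_mcdb(self, mcdb0)

    def to_frame(self, mcdb0: float = 1.82):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "T_core_C": self.T_core,
                "T_surface_C": self.T_surface,
                "c_mean_mol_m3": self.c_mean,
                "MC_db": self.mcdb_trace(mcdb0),
                "MR": self.mr_trace(),
            }
        )

    def export_vtk_series(self, directory, stem="bean"):
        """Write the stored snapshots as a legacy-VTK time series."""
        import pathlib

        from .geometry import export_vtk

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(self.snapshot_times):
            export_vtk(
                self.mesh,
                directory / f"{stem}_{i:04d}.vtk",
                point_data={
                    "temperature_C": self.snapshots_T[i],
                    "moisture_mol_m3": self.snapshots_c[i],
                },
            )


class TransportProblem:
    """Assembled axisymmetric two-field problem with lagged properties."""

    def __init__(
        self,
        mesh: Mesh,
        materials: dict,
        bc: BoundaryConditions,
        ic: InitialConditions,
        config: SolverConfig | None = None,
        diffusivity: props.ArrheniusDiffusivity | None = None,
    ):
        self.mesh = mesh
        self.bc = bc
        self.ic = ic
        self.config = config or SolverConfig()
        self.diffusivity = diffusivity or props.ArrheniusDiffusivity()

        tags = mesh.element_tags
        self.materials = dict(materials)
        if (tags == SHELL).any() and "shell" not in self.materials:
            raise ValueError("mesh has shell elements but no 'shell' material")
        if "core" not in self.materials:
            raise ValueError("no 'core' material supplied")

        self.ops = P1Operators(mesh.points, mesh.triangles)
        self.w_area = self.ops.boundary_lumped(mesh.exterior_edges, 1.0)
        self.w_h = bc.h * self.w_area
        self.w_hm = bc.hm * self.w_area
        self.boundary_nodes = np.flatnonzero(self.w_area > 0)
        self.Mc = self.ops.lumped_mass(1.0)

        # locate the trace points
        pts = mesh.points
        self.core_node = int(np.argmin(np.hypot(pts[:, 0], pts[:, 1])))
        bn = self.boundary_nodes
        self.surface_node = int(bn[np.argmin(np.abs(pts[bn, 1]))])

        self.T = np.full(mesh.n_points, float(ic.To))
        self.c = np.full(mesh.n_points, float(ic.co))
        self.t = 0.0
        self._T_ref = None
        self._element_tag = tags
        self._refresh_operators(self.T)

    # -- operator assembly -------------------------------------------------

    def _element_property(self, attr, T_elem):
        out = np.empty_like(T_elem)
        tags = self._element_tag
        for tag, key in ((CORE, "core"), (SHELL, "shell")):
            m = tags == tag
            if m.any():
                out[m] = np.asarray(getattr(self.materials[key], attr)(T_elem[m]), float)
        return out

    def _effective_w_hm(self) -> np.ndarray:
        """Nodal Robin weights for moisture, saturated at the vapor limit.

        hm_eff = min(hm, hm * cap / (c_s - c_inf)) with the carrying capacity
        cap = (M_w / m_cal) (c_sat(T_s) - c_inf) expressed in model moles;
        evaluated at the current (lagged) state so the c-solve stays linear.
        """
        bc = self.bc
        if not bc.vapor_limited or bc.hm <= 0:
            return self.w_hm
        csat = props.saturation_vapor_concentration(self.T)
        cap = (M_WATER / bc.latent_mass_per_mol) * np.clip(csat - bc.c_inf, 0.0, None)
        dc = np.maximum(self.c - bc.c_inf, 1e-300)
        return self.w_hm * np.minimum(1.0, cap / dc)

    def _rebuild_c_system(self, w_hm_eff):
        th, dt = self.config.theta, self.config.dt
        A_c = sp.diags(self.Mc / dt + th * w_hm_eff) + th * self.Kc
        self._lu_c = splu(A_c.tocsc())
        self._w_hm_current = w_hm_eff

    def _refresh_operators(self, T_nodal):
        cfg = self.config
        T_elem = T_nodal[self.mesh.triangles].mean(axis=1)
        rho = self._element_property("rho", T_elem)
        cp_J = self._element_property("cp", T_elem) * 1e3
        k = self._element_property("k", T_elem)
        deff = np.asarray(self.diffusivity(T_elem + 273.15), float)
        self.KT = self.ops.stiffness(k)
        self.Kc = self.ops.stiffness(deff)
        self.MT = self.ops.lumped_mass(rho * cp_J)
        th, dt = cfg.theta, cfg.dt
        A_T = sp.diags(self.MT / dt + th * self.w_h) + th * self.KT
        self._lu_T = splu(A_T.tocsc())
        self._rebuild_c_system(self._effective_w_hm())
        self._T_ref = T_nodal.copy()

    # -- time stepping -----------------------------------------------------

    def step(self):
        """Advance one time step; returns (outflow mol/s, conv W, evap W)."""
        cfg, bc = self.config, self.bc
        th, dt = cfg.theta, cfg.dt
        T_iter = self.T
        w_new = self._effective_w_hm()
        if np.max(np.abs(w_new - self._w_hm_current)) > 1e-9 * (np.max(self.w_hm) + 1e-300):
            self._rebuild_c_system(w_new)
        for _ in range(cfg.picard_max_iter if cfg.picard else 1):
            w_hm = self._w_hm_current
            c_rhs = self.Mc / dt * self.c + th * w_hm * bc.c_inf
            if th < 1.0:
                c_rhs -= (1 - th) * (self.Kc @ self.c + w_hm * (self.c - bc.c_inf))
            c_new = self._lu_c.solve(c_rhs)
            c_theta = th * c_new + (1 - th) * self.c

            phi = w_hm * (c_theta - bc.c_inf)  # nodal molar outflow, mol/s
            q = bc.latent_heat * bc.latent_mass_per_mol * np.clip(phi, 0.0, None)

            T_rhs = self.MT / dt * self.T + th * self.w_h * bc.air.temperature - q
            if th < 1.0:
                T_rhs -= (1 - th) * (
                    self.KT @ self.T + self.w_h * (self.T - bc.air.temperature)
                )
            T_new = self._lu_T.solve(T_rhs)
            if not cfg.picard:
                break
            if np.max(np.abs(T_new - T_iter)) < cfg.picard_tol:
                break
            T_iter = T_new
            self._refresh_operators(T_new)

        conv_in = float(np.sum(self.w_h * (bc.air.temperature - th * T_new - (1 - th) * self.T)))
        out_rate = float(phi.sum())
        evap = float(q.sum())
        self.T, self.c = T_new, c_new
        self.t += dt
        if (not cfg.picard) and np.max(np.abs(T_new - self._T_ref)) > cfg.property_refresh_dT:
            self._refresh_operators(T_new)
        return out_rate, conv_in, evap

    # -- full transient ----------------------------------------------------

    def run(self) -> SimulationResult:
        cfg, bc, ic = self.config, self.bc, self.ic
        n_steps = int(round(cfg.t_end / cfg.dt))
        every_trace = max(1, int(round(cfg.trace_cadence / cfg.dt)))
        every_snap = max(1, int(round(cfg.snapshot_cadence / cfg.dt)))

        T_span = (min(ic.To, bc.air.temperature), max(ic.To, bc.air.temperature))
        c_span = (min(ic.co, bc.c_inf), max(ic.co, bc.c_inf))
        guard_T = cfg.abort_rtol * (T_span[1] - T_span[0])
        guard_c = cfg.abort_rtol * (c_span[1] - c_span[0])

        times, Tc, Ts, Tm, cm, inv, rate, cum, conv_tr, evap_tr = ([] for _ in range(10))
        snap_t, snap_T, snap_c = [], [], []
        Vtot = self.Mc.sum()
        cum_out = 0.0
        T_min = T_max = float(ic.To)
        c_min = c_max = float(ic.co)

        def record(out_rate=0.0, conv=0.0, evap=0.0):
            times.append(self.t)
            Tc.append(self.T[self.core_node])
            Ts.append(self.T[self.surface_node])
            Tm.append(float(self.Mc @ self.T) / Vtot)
            cm.append(float(self.Mc @ self.c) / Vtot)
            inv.append(float(self.Mc @ self.c))
            rate.append(out_rate)
            cum.append(cum_out)
            conv_tr.append(conv)
            evap_tr.append(evap)

        record()
        if cfg.store_snapshots:
            snap_t.append(0.0)
            snap_T.append(self.T.copy())
            snap_c.append(self.c.copy())

        for n in range(1, n_steps + 1):
            out_rate, conv, evap = self.step()
            cum_out += out_rate * cfg.dt
            T_min = min(T_min, float(self.T.min()))
            T_max = max(T_max, float(self.T.max()))
            c_min = min(c_min, float(self.c.min()))
            c_max = max(c_max, float(self.c.max()))
            if cfg.check_invariants:
                if (
                    T_min < T_span[0] - guard_T
                    or T_max > T_span[1] + guard_T
                    or c_min < c_span[0] - guard_c
                    or c_max > c_span[1] + guard_c
                ):
                    raise SimulationInvariantError(
                        f"bounds violated at t={self.t:.1f}s: "
                        f"T in [{T_min:.3f}, {T_max:.3f}] °C vs {T_span}, "
                        f"c in [{c_min:.3f}, {c_max:.3f}] vs {c_span}",
                        state={
                            "t": self.t,
                            "T": self.T.copy(),
                            "c": self.c.copy(),
                            "T_span": T_span,
                            "c_span": c_span,
                        },
                    )
            if n % every_trace == 0 or n == n_steps:
                record(out_rate, conv, evap)
            if cfg.store_snapshots and (n % every_snap == 0 or n == n_steps):
                snap_t.append(self.t)
                snap_T.append(self.T.copy())
                snap_c.append(self.c.copy())

        return SimulationResult(
            times=np.asarray(times),
            T_core=np.asarray(Tc),
            T_surface=np.asarray(Ts),
            T_mean=np.asarray(Tm),
            c_mean=np.asarray(cm),
            inventory=np.asarray(inv),
            outflow_rate=np.asarray(rate),
            cumulative_outflow=np.asarray(cum),
            heat_in_rate=np.asarray(conv_tr),
            evap_rate=np.asarray(evap_tr),
            T_min=T_min,
            T_max=T_max,
            c_min=c_min,
            c_max=c_max,
            snapshot_times=np.asarray(snap_t),
            snapshots_T=np.asarray(snap_T) if snap_T else np.empty((0, self.mesh.n_points)),
            snapshots_c=np.asarray(snap_c) if snap_c else np.empty((0, self.mesh.n_points)),
            mesh=self.mesh,
            bc=bc,
            ic=ic,
            config=cfg,
            meta={
                "n_steps": n_steps,
                "n_nodes": self.mesh.n_points,
                "n_elements": self.mesh.n_elements,
                "materials": {k: v.name for k, v in self.materials.items()},
            },
        )


def run(mesh, materials, bc, ic, config=None, diffusivity=None) -> SimulationResult:
    """Assemble and integrate the full transient; deterministic."""
    return TransportProblem(mesh, materials, bc, ic, config, diffusivity).run()


def moisture_trace_to_mcdb(result: SimulationResult, mcdb0: float = 1.82) -> np.ndarray:
    """Map the mean concentration trace to dry-basis moisture content.

    Linear calibration anchored so a uniform field c = co corresponds to the
    initial measured MC_db (g water / g dry matter).
    """
    if mcdb0 <= 0:
        raise ValueError("calibration MC_db must be positive")
    return result.c_mean * (mcdb0 / result.ic.co)


def average_relative_error(t_model, y_model, t_ref, y_ref) -> float:
    """Mean of |model - reference| / |reference| in percent.

    The model trace is interpolated onto the reference times; samples where
    the reference is zero are excluded with a warning.
    """
    t_model = np.asarray(t_model, float)
    y_model = np.asarray(y_model, float)
    t_ref = np.asarray(t_ref, float)
    y_ref = np.asarray(y_ref, float)
    yi = np.interp(t_ref, t_model, y_model)
    ok = y_ref != 0
    if not ok.all():
        warnings.warn(f"excluded {np.sum(~ok)} zero-reference samples")
    if not ok.any():
        raise ValueError("reference trace is identically zero")
    return float(np.mean(np.abs(yi[ok] - y_ref[ok]) / np.abs(y_ref[ok])) * 100.0)


@dataclass
class GridConvergenceReport:
    sizes: list
    n_nodes: list
    times: np.ndarray
    core_traces: np.ndarray  # (n_sizes, n_times)
    max_deviation_finest_pair: float

    def pairwise_max_deviation(self) -> np.ndarray:
        n = len(self.sizes)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                out[i, j] = np.max(np.abs(self.core_traces[i] - self.core_traces[j]))
        return out


def grid_convergence_study(
    geometry: BeanGeometry,
    materials: dict,
    bc: BoundaryConditions,
    ic: InitialConditions,
    sizes,
    config: SolverConfig | None = None,
    shell_layers: int = 3,
) -> GridConvergenceReport:
    """Re-run the transient on successively finer meshes (coarse -> fine)."""
    sizes = sorted(sizes, reverse=True)
    if len(sizes) < 3:
        raise ValueError("grid convergence needs at least 3 mesh sizes")
    traces, nodes, times = [], [], None
    for size in sizes:
        mesh = generate_mesh(geometry, target_size=size, shell_layers=shell_layers)
        res = run(mesh, materials, bc, ic, config)
        traces.append(res.T_core)
        nodes.append(mesh.n_points)
        times = res.times
    traces = np.asarray(traces)
    dev = float(np.max(np.abs(traces[-1] - traces[-2])))
    return GridConvergenceReport(
        sizes=list(sizes),
        n_nodes=nodes,
        times=times,
        core_traces=traces,
        max_deviation_finest_pair=dev,
    )


def compare_single_vs_multidomain(
    mesh: Mesh,
    materials: dict,
    bc: BoundaryConditions,
    ic: InitialConditions,
    config: SolverConfig | None = None,
    diffusivity=None,
) -> dict:
    """Two-material vs volume-weighted homogenized run on the same mesh."""
    multi = run(mesh, materials, bc, ic, config, diffusivity)
    vols = mesh.element_volumes()
    weights = {
        "core": float(vols[mesh.element_tags == CORE].sum()),
        "shell": float(vols[mesh.element_tags == SHELL].sum()) or 0.0,
    }
    if weights["shell"] == 0.0:
        weights.pop("shell")
    homog = homogenized_material(materials, weights)
    single = run(mesh, {"core": homog, "shell": homog}, bc, ic, config, diffusivity)
    return {
        "multidomain": multi,
        "single_domain": single,
        "max_dT_core": float(np.max(np.abs(multi.T_core - single.T_core))),
        "max_dc_mean": float(np.max(np.abs(multi.c_mean - single.c_mean))),
    }
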