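"""Composition-based thermophysical properties of cocoa bean tissues.

The testa (shell) and cotyledon (core) of a fermented CCN51 cocoa bean are
treated as mixtures of six pure food components (water, protein, fat,
carbohydrate, fiber, ash).  Temperature-dependent properties of the pure
components follow the Choi–Okos above-freezing polynomial correlations;
tissue properties are obtained by the standard mixing rules

    rho = 1 / sum(X_i / rho_i)        (mass-fraction harmonic mean)
    Cp  = sum(Cp_i * X_i)             (mass-fraction mean)
    k   = sum(k_i * V_i)              (volume-fraction mean)
    alpha = k / (rho * Cp)

with X_i mass fractions and V_i = (X_i/rho_i) / sum(X_j/rho_j) volume
fractions.  The module also provides quadratic curve fits of the properties
over the drying interval 40–70 °C, the Arrhenius effective moisture
diffusivity, humid-air vapor concentrations, and film-transfer coefficients
from the sphere correlation Sh = 2 + 0.552 Re^0.53 Sc^(1/3) (and its heat
analog with Pr).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "COMPONENTS",
    "ProximateComposition",
    "ThermoProps",
    "PropertyPolynomials",
    "ArrheniusDiffusivity",
    "AirState",
    "TESTA_COMPOSITION",
    "COTYLEDON_COMPOSITION",
    "SHELL_CORRELATIONS",
    "CORE_CORRELATIONS",
    "pure_component_props",
    "mixture_props",
    "fit_property_polynomials",
    "evaluate_polynomials",
    "effective_diffusivity",
    "film_coefficients",
    "sherwood_number",
    "nusselt_number",
    "far_field_vapor_concentration",
    "saturation_vapor_pressure",
    "saturation_vapor_concentration",
    "read_composition_csv",
    "property_table",
]

R_GAS = 8.314  # J/(mol K)

COMPONENTS = ("water", "protein", "fat", "carbohydrate", "fiber", "ash")

# Choi–Okos above-freezing correlations, T in °C.
# Coefficients are (c0, c1, c2) for c0 + c1*T + c2*T**2.
_CHOI_OKOS_RHO = {  # kg/m^3
    "water": (997.18, 3.1439e-3, -3.7574e-3),
    "protein": (1329.9, -0.5184, 0.0),
    "fat": (925.59, -0.41757, 0.0),
    "carbohydrate": (1599.1, -0.31046, 0.0),
    "fiber": (1311.5, -0.36589, 0.0),
    "ash": (2423.8, -0.28063, 0.0),
}
_CHOI_OKOS_CP = {  # kJ/(kg °C)
    "water": (4.1762, -9.0864e-5, 5.4731e-6),
    "protein": (2.0082, 1.2089e-3, -1.3129e-6),
    "fat": (1.9842, 1.4733e-3, -4.8008e-6),
    "carbohydrate": (1.5488, 1.9625e-3, -5.9399e-6),
    "fiber": (1.8459, 1.8306e-3, -4.6509e-6),
    "ash": (1.0926, 1.8896e-3, -3.6817e-6),
}
_CHOI_OKOS_K = {  # W/(m °C)
    "water": (0.57109, 1.7625e-3, -6.7036e-6),
    "protein": (0.17881, 1.1958e-3, -2.7178e-6),
    "fat": (0.18071, -2.7604e-4, -1.7749e-7),
    "carbohydrate": (0.20141, 1.3874e-3, -4.3312e-6),
    "fiber": (0.18331, 1.2497e-3, -3.1683e-6),
    "ash": (0.32962, 1.4011e-3, -2.9069e-6),
}


def _poly(coeffs, T):
    c0, c1, c2 = coeffs
    T = np.asarray(T, dtype=float)
    return c0 + c1 * T + c2 * T * T


@dataclass(frozen=True)
class ProximateComposition:
    """Mass fractions of the six food components of one tissue (sum to 1)."""

    water: float
    protein: float
    fat: float
    carbohydrate: float
    fiber: float = 0.0
    ash: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            x = getattr(self, f.name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"mass fraction {f.name}={x} outside [0, 1]")
        if abs(self.total - 1.0) > 1e-3:
            raise ValueError(
                f"mass fractions sum to {self.total:.5f}, expected 1 within 1e-3"
            )

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COMPONENTS)

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in COMPONENTS}

    @classmethod
    def from_percent(cls, **percent) -> "ProximateComposition":
        return cls(**{k: v / 100.0 for k, v in percent.items()})


# Proximate composition of the fermented Ecuadorian CCN51 bean (mass %).
TESTA_COMPOSITION = ProximateComposition.from_percent(
    protein=8.89, fat=26.0, carbohydrate=27.98, fiber=0.0, ash=2.23, water=34.9
)
COTYLEDON_COMPOSITION = ProximateComposition.from_percent(
    protein=4.8, fat=0.32, carbohydrate=28.0, fiber=0.0, ash=2.28, water=64.6
)


@dataclass(frozen=True)
class ThermoProps:
    """Thermophysical property set at one temperature.

    rho kg/m^3, cp kJ/(kg °C), k W/(m °C), alpha m^2/s.
    """

    rho: float
    cp: float
    k: float
    alpha: float

    def __post_init__(self):
        if min(self.rho, self.cp, self.k, self.alpha) <= 0:
            raise ValueError(f"all properties must be positive: {self}")
        if abs(self.alpha - self.k / (self.rho * self.cp * 1e3)) > 1e-12:
            raise ValueError("alpha inconsistent with k/(rho*cp)")

    @classmethod
    def from_rck(cls, rho, cp, k) -> "ThermoProps":
        return cls(rho=rho, cp=cp, k=k, alpha=k / (rho * cp * 1e3))


def pure_component_props(component: str, T: float) -> ThermoProps:
    """Choi–Okos properties of a pure food component at T (°C, 0–100)."""
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    if not 0.0 <= T <= 100.0:
        raise ValueError(f"T={T} °C outside the supported range [0, 100] °C")
    return ThermoProps.from_rck(
        rho=float(_poly(_CHOI_OKOS_RHO[component], T)),
        cp=float(_poly(_CHOI_OKOS_CP[component], T)),
        k=float(_poly(_CHOI_OKOS_K[component], T)),
    )


def _mixture_rck(comp: ProximateComposition, T):
    """Vectorized (rho, cp, k) of a tissue at temperature(s) T in °C."""
    T = np.asarray(T, dtype=float)
    x = comp.as_dict()
    rho_i = {c: _poly(_CHOI_OKOS_RHO[c], T) for c in COMPONENTS}
    if any(np.any(rho_i[c] == 0) for c in COMPONENTS):
        raise ZeroDivisionError("pure-component density evaluated to zero")
    spec_vol = sum(x[c] / rho_i[c] for c in COMPONENTS)
    rho = 1.0 / spec_vol
    cp = sum(x[c] * _poly(_CHOI_OKOS_CP[c], T) for c in COMPONENTS)
    k = sum((x[c] / rho_i[c]) / spec_vol * _poly(_CHOI_OKOS_K[c], T) for c in COMPONENTS)
    return rho, cp, k


def mixture_props(comp: ProximateComposition, T: float) -> ThermoProps:
    """Tissue properties at T (°C) by the Choi–Okos mixing rules."""
    rho, cp, k = _mixture_rck(comp, T)
    return ThermoProps.from_rck(rho=float(rho), cp=float(cp), k=float(k))


@dataclass(frozen=True)
class PropertyPolynomials:
    """Quadratic correlations (c2, c1, c0) over T in °C for one tissue.

    Valid over ``t_range`` (default 40–70 °C, the drying interval);
    evaluation slightly outside warns but does not fail.
    """

    rho: tuple
    cp: tuple
    k: tuple
    t_range: tuple = (40.0, 70.0)
    residual_rms: dict = field(default_factory=dict)

    def evaluate(self, T) -> ThermoProps:
        lo, hi = self.t_range
        if np.any(np.asarray(T) < lo - 5) or np.any(np.asarray(T) > hi + 5):
            warnings.warn(
                f"T={T} °C well outside the fitted interval {self.t_range}",
                stacklevel=2,
            )
        ev = lambda c: float(np.polyval(c, T))
        return ThermoProps.from_rck(rho=ev(self.rho), cp=ev(self.cp), k=ev(self.k))


# Published quadratic property correlations for the CCN51 bean tissues
# (T in °C, 40–70 °C).  These are the curves the drying simulation uses by
# default; they agree with the composition-based model to <1% for rho and Cp
# of both tissues and for k of the cotyledon.  The published testa k is ~11%
# above the Choi–Okos volume-fraction value — see docs/methods.md.
SHELL_CORRELATIONS = PropertyPolynomials(
    rho=(-0.0017, -0.2415, 1133.9),
    cp=(-1e-6, 0.0011, 2.6096),
    k=(-4e-6, 0.002, 0.3405),
)
CORE_CORRELATIONS = PropertyPolynomials(
    rho=(-0.0032, -0.0633, 1146.9),
    cp=(2e-6, 0.0006, 3.2591),
    k=(-6e-6, 0.0017, 0.4766),
)


def fit_property_polynomials(
    comp: ProximateComposition, T_grid=None
) -> PropertyPolynomials:
    """Least-squares quadratic fit of the mixture properties on a T grid."""
    if T_grid is None:
        T_grid = np.arange(40.0, 70.0 + 1e-9, 5.0)
    T_grid = np.asarray(T_grid, dtype=float)
    if len(np.unique(T_grid)) < 3:
        raise np.linalg.LinAlgError(
            "need at least 3 distinct temperatures for a quadratic fit"
        )
    if len(np.unique(T_grid)) < 4:
        warnings.warn("quadratic fit through only 3 points is exact, not a fit")
    rho, cp, k = _mixture_rck(comp, T_grid)
    out = {}
    rms = {}
    for name, y in (("rho", rho), ("cp", cp), ("k", k)):
        c = np.polyfit(T_grid, y, 2)
        out[name] = tuple(c)
        rms[name] = float(np.sqrt(np.mean((np.polyval(c, T_grid) - y) ** 2)))
    return PropertyPolynomials(
        rho=out["rho"],
        cp=out["cp"],
        k=out["k"],
        t_range=(float(T_grid.min()), float(T_grid.max())),
        residual_rms=rms,
    )


def evaluate_polynomials(poly: PropertyPolynomials, T: float) -> ThermoProps:
    return poly.evaluate(T)


@dataclass(frozen=True)
class ArrheniusDiffusivity:
    """Arrhenius effective moisture diffusivity Deff = Do exp(Ea/(R T)).

    The published pre-exponential/activation pair (Do = 12e-4 m^2/s,
    Ea = -38,000 J/mol) is dimensionally consistent only with the molar gas
    constant R = 8.314 J/(mol K); that combination gives the physically
    plausible Deff ~ 8.6e-10 m^2/s at 323 K and is the default here.  The
    constants are plain fields so alternative conventions can be supplied.
    """

    Do: float = 12e-4  # m^2/s
    Ea: float = -38_000.0  # J/mol (negative sign convention: exponent Ea/(R T))
    R: float = R_GAS

    def __call__(self, T_kelvin):
        T_kelvin = np.asarray(T_kelvin, dtype=float)
        if np.any(T_kelvin <= 0):
            raise ValueError("absolute temperature must be positive")
        deff = self.Do * np.exp(self.Ea / (self.R * T_kelvin))
        if np.any(deff > 1e-6):
            raise ValueError(
                "Deff exceeds 1e-6 m^2/s — Do/Ea/R units are inconsistent. "
                "The exponent must be evaluated with Ea in J/mol and "
                "R = 8.314 J/(mol K); the published R = 8314 J/(mol K) "
                "printed alongside Ea = -38,000 J/mol yields a non-physical "
                "moisture diffusivity."
            )
        return deff if deff.shape else float(deff)


def effective_diffusivity(arr: ArrheniusDiffusivity, T_kelvin: float) -> float:
    """Deff (m^2/s) at absolute temperature T_kelvin."""
    return arr(T_kelvin)


# ---------------------------------------------------------------------------
# Humid air and film-side transport
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(T_celsius) -> float:
    """Magnus saturation pressure of water vapor (Pa), T in °C."""
    T = np.asarray(T_celsius, dtype=float)
    p = 610.94 * np.exp(17.625 * T / (T + 243.04))
    return p if p.shape else float(p)


def saturation_vapor_concentration(T_celsius) -> float:
    """Saturation molar concentration of water vapor (mol/m^3) at T °C."""
    T = np.asarray(T_celsius, dtype=float)
    c = saturation_vapor_pressure(T) / (R_GAS * (T + 273.15))
    return c if c.shape else float(c)


def _air_dynamic_viscosity(TK):
    # Sutherland's law for dry air
    return 1.458e-6 * TK**1.5 / (TK + 110.4)


def _air_density(TK, pressure=101_325.0):
    return pressure / (287.05 * TK)


def _air_thermal_conductivity(TK):
    return 0.0241 * (TK / 273.15) ** 0.9


def _vapor_diffusivity_in_air(TK, pressure=101_325.0):
    # Fuller-type temperature scaling anchored at 2.50e-5 m^2/s (298.15 K, 1 atm)
    return 2.50e-5 * (TK / 298.15) ** 1.75 * (101_325.0 / pressure)


@dataclass(frozen=True)
class AirState:
    """Drying-air state: chamber temperature/speed and the ambient intake air.

    Derived transport properties (nu, Pr, Dair, Sc) are evaluated from dry-air
    correlations at ``film_temperature`` — by default the chamber temperature,
    or the mean of a supplied surface temperature and the free stream.
    """

    temperature: float  # °C, chamber / free stream
    speed: float = 1.0  # m/s
    ambient_temperature: float = 26.0  # °C, intake air before heating
    ambient_rh: float = 0.72  # relative humidity of the intake air, 0–1
    surface_temperature: float | None = None  # °C, optional for film props

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError("air speed must be >= 0")
        if not 0.0 <= self.ambient_rh <= 1.0:
            raise ValueError("relative humidity must be in [0, 1]")

    @property
    def film_temperature(self) -> float:
        if self.surface_temperature is None:
            return self.temperature
        return 0.5 * (self.temperature + self.surface_temperature)

    @property
    def _film_K(self) -> float:
        return self.film_temperature + 273.15

    @property
    def kinematic_viscosity(self) -> float:
        TK = self._film_K
        return _air_dynamic_viscosity(TK) / _air_density(TK)

    @property
    def thermal_conductivity(self) -> float:
        return _air_thermal_conductivity(self._film_K)

    @property
    def prandtl(self) -> float:
        TK = self._film_K
        cp_air = 1007.0
        return _air_dynamic_viscosity(TK) * cp_air / _air_thermal_conductivity(TK)

    @property
    def vapor_diffusivity(self) -> float:
        return _vapor_diffusivity_in_air(self._film_K)

    @property
    def schmidt(self) -> float:
        return self.kinematic_viscosity / self.vapor_diffusivity

    def reynolds(self, L: float) -> float:
        return L * self.speed / self.kinematic_viscosity


def sherwood_number(Re: float, Sc: float) -> float:
    """Sh = 2 + 0.552 Re^0.53 Sc^(1/3) (sphere, stagnant limit Sh=2)."""
    return 2.0 + 0.552 * Re**0.53 * Sc ** (1.0 / 3.0)


def nusselt_number(Re: float, Pr: float) -> float:
    """Heat-transfer analog of the sphere mass-transfer correlation."""
    return 2.0 + 0.552 * Re**0.53 * Pr ** (1.0 / 3.0)


def film_coefficients(air: AirState, L: float) -> tuple:
    """(h, hm): convective heat (W/m^2 °C) and mass (m/s) film coefficients.

    L is the characteristic length of the correlation (volume-equivalent
    sphere diameter of the bean by convention here).
    """
    if L <= 0:
        raise ValueError("characteristic length must be positive")
    Re = air.reynolds(L)
    Sh = sherwood_number(Re, air.schmidt)
    Nu = nusselt_number(Re, air.prandtl)
    hm = Sh * air.vapor_diffusivity / L
    h = Nu * air.thermal_conductivity / L
    return h, hm


def far_field_vapor_concentration(air: AirState) -> float:
    """Water-vapor molar concentration (mol/m^3) of the heated chamber air.

    The intake air at ambient T/RH is heated to the chamber temperature at
    constant pressure; its vapor mole fraction is conserved, so the molar
    concentration is p_v(ambient) / (R * T_chamber).
    """
    pv = air.ambient_rh * saturation_vapor_pressure(air.ambient_temperature)
    c = pv / (R_GAS * (air.temperature + 273.15))
    c_sat = saturation_vapor_concentration(air.temperature)
    if c > c_sat:
        warnings.warn("far-field vapor concentration exceeds chamber saturation")
    return c


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_composition_csv(path) -> dict:
    """Read tissue compositions from a delimited table.

    Expected columns: a sample/tissue label column plus the six component
    columns (case-insensitive, e.g. 'Protein(%)' or 'water').  Values > 1.5
    are interpreted as percentages.
    """
    import pandas as pd

    df = pd.read_csv(path)
    colmap = {}
    for col in df.columns:
        base = col.strip().lower()
        for c in COMPONENTS:
            if base.startswith(c):
                colmap[c] = col
    missing = [c for c in ("water", "protein", "fat", "carbohydrate") if c not in colmap]
    if missing:
        raise ValueError(f"composition table is missing columns: {missing}")
    label_col = [c for c in df.columns if c not in colmap.values()][0]
    out = {}
    for _, row in df.iterrows():
        vals = {c: float(row[col]) for c, col in colmap.items()}
        if max(vals.values()) > 1.5:  # percent table
            vals = {c: v / 100.0 for c, v in vals.items()}
        out[str(row[label_col])] = ProximateComposition(**vals)
    return out


def property_table(comp: ProximateComposition, T_grid=None):
    """DataFrame of (T, rho, cp, k, alpha) for one tissue."""
    import pandas as pd

    if T_grid is None:
        T_grid = np.arange(40.0, 70.0 + 1e-9, 5.0)
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        p = mixture_props(comp, T)
        rows.append({"T_C": T, "rho": p.rho, "cp": p.cp, "k": p.k, "alpha": p.alpha})
    return pd.DataFrame(rows)
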