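"""Thin-layer drying kinetics: the diffusion-approximation model.

The moisture ratio of a drying bean,

    MR(t) = (c(t) - ce) / (co - ce),

is described by the two-exponential diffusion-approximation model

    MR(t) = a exp(-ko t) + (1 - a) exp(-ko b t),     t in minutes,

with kinetic constant ko (1/min) and dimensionless shape constants a, b.
MR(0) = 1 by construction and MR -> 0 as t -> infinity.  The model has the
exact symmetry (a, b, ko) -> (1-a, 1/b, ko*b); fits are reported in the
canonical orientation a <= 0.5 (the slow branch carries the larger weight,
as in the published CCN51 constants).

Fitting is bounded nonlinear least squares started from a small
deterministic grid of initial guesses, so results are reproducible and the
symmetric twin of the optimum cannot be reported by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "REFERENCE_DRYING_CONSTANTS",
    "DryingCurve",
    "DiffusionApproxFit",
    "mc_dry_basis",
    "moisture_ratio",
    "evaluate_diffusion_model",
    "fit_diffusion_model",
    "goodness_of_fit",
    "arrhenius_rate_summary",
]

# Published diffusion-approximation constants for the CCN51 bean,
# temperature °C -> (ko 1/min, a, b).
REFERENCE_DRYING_CONSTANTS = {
    40.0: (0.066, 0.280, 0.103),
    50.0: (0.082, 0.268, 0.127),
    60.0: (0.105, 0.243, 0.149),
    70.0: (0.181, 0.184, 0.128),
}

_BOUNDS_LO = (1e-4, 0.0, 1e-3)
_BOUNDS_HI = (10.0, 1.0, 1e3)


@dataclass
class DryingCurve:
    """A (time, value) drying series: MC dry basis or moisture ratio."""

    times_min: np.ndarray
    values: np.ndarray
    kind: str = "MR"  # "MR" or "MCdb"
    temperature: float | None = None  # drying air temperature, °C

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, float)
        self.values = np.asarray(self.values, float)
        if self.kind not in ("MR", "MCdb"):
            raise ValueError("kind must be 'MR' or 'MCdb'")
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times_min[0] != 0:
            raise ValueError("a drying curve must start at t = 0")
        if self.kind == "MR" and (
            np.any(self.values < -0.05) or np.any(self.values > 1.05)
        ):
            raise ValueError("moisture ratios must lie in [0, 1] up to noise")

    def to_mr(self, mc0: float | None = None, mce: float = 0.0) -> "DryingCurve":
        """Convert an MCdb curve to a moisture-ratio curve."""
        if self.kind == "MR":
            return self
        mc0 = self.values[0] if mc0 is None else mc0
        return DryingCurve(
            self.times_min,
            moisture_ratio(self.values, mc0, mce),
            kind="MR",
            temperature=self.temperature,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "value": self.values,
                "kind": self.kind,
                "temperature_C": self.temperature,
            }
        )

    @classmethod
    def from_csv(cls, path) -> "DryingCurve":
        import pandas as pd

        df = pd.read_csv(path)
        kind = str(df["kind"].iloc[0]) if "kind" in df else "MR"
        temp = float(df["temperature_C"].iloc[0]) if "temperature_C" in df else None
        return cls(df["time_min"].to_numpy(), df["value"].to_numpy(), kind, temp)


@dataclass(frozen=True)
class DiffusionApproxFit:
    """Fitted constants of the diffusion-approximation model."""

    ko: float  # 1/min
    a: float
    b: float
    r2: float = float("nan")
    rmse: float = float("nan")
    temperature: float | None = None
    degenerate: bool = False
    n_obs: int = 0
    residual_norm: float = float("nan")
    starts_tried: int = field(default=0, compare=False)

    def __post_init__(self):
        if self.ko <= 0 or self.b <= 0:
            raise ValueError("ko and b must be positive")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must be in [0, 1]")

    def __call__(self, t_min):
        return evaluate_diffusion_model(self, t_min)


def mc_dry_basis(wet_mass: float, dry_mass: float) -> float:
    """Dry-basis moisture content (wet - dry)/dry, g water per g dry matter."""
    wet = np.asarray(wet_mass, float)
    dry = np.asarray(dry_mass, float)
    if np.any(dry <= 0):
        raise ValueError("dry mass must be positive")
    if np.any(wet < dry):
        raise ValueError("wet mass below dry mass implies negative moisture")
    out = (wet - dry) / dry
    return out if out.shape else float(out)


def moisture_ratio(c, co, ce):
    """MR = (c - ce)/(co - ce): 1 at the start, 0 at equilibrium."""
    if co == ce:
        raise ValueError("co equals ce: moisture-ratio normalization is degenerate")
    c = np.asarray(c, float)
    out = (c - ce) / (co - ce)
    return out if out.shape else float(out)


def evaluate_diffusion_model(fit, t_min):
    """MR(t) = a exp(-ko t) + (1-a) exp(-ko b t), t in minutes."""
    ko, a, b = fit.ko, fit.a, fit.b
    t = np.asarray(t_min, float)
    out = a * np.exp(-ko * t) + (1 - a) * np.exp(-ko * b * t)
    return out if out.shape else float(out)


def _canonical(ko, a, b):
    """Report the orientation with a <= 0.5 (resolves the model symmetry)."""
    if a > 0.5:
        return ko * b, 1 - a, 1 / b
    return ko, a, b


def _start_grid():
    """Deterministic 3x3x3 multi-start grid inside the fit bounds."""
    kos = np.geomspace(1e-3, 1.0, 3)
    aas = np.array([0.15, 0.30, 0.45])
    bs = np.geomspace(1e-2, 10.0, 3)
    return [(ko, a, b) for ko in kos for a in aas for b in bs]


def fit_diffusion_model(
    curve: DryingCurve,
    initial_guess: tuple | None = None,
) -> DiffusionApproxFit:
    """Bounded nonlinear least-squares fit of (ko, a, b) to an MR curve."""
    if curve.kind != "MR":
        raise ValueError("fit expects a moisture-ratio curve; convert with to_mr()")
    t = curve.times_min
    y = curve.values
    if len(t) < 6:
        raise ValueError("need at least 6 samples spanning the decay")

    def resid(p):
        ko, a, b = p
        return a * np.exp(-ko * t) + (1 - a) * np.exp(-ko * b * t) - y

    starts = [initial_guess] if initial_guess is not None else _start_grid()
    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                resid, p0, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf", xtol=1e-14,
                ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        raise RuntimeError("diffusion-approximation fit failed from every start")

    ko, a, b = _canonical(*best.x)
    pred = a * np.exp(-ko * t) + (1 - a) * np.exp(-ko * b * t)
    r2, rmse = goodness_of_fit(y, pred)
    degenerate = min(a, 1 - a) < 5e-3 or abs(b - 1) < 1e-3
    return DiffusionApproxFit(
        ko=float(ko),
        a=float(a),
        b=float(b),
        r2=r2,
        rmse=rmse,
        temperature=curve.temperature,
        degenerate=bool(degenerate),
        n_obs=len(t),
        residual_norm=float(np.sqrt(2 * best.cost)),
        starts_tried=len(starts),
    )


def goodness_of_fit(observed, predicted) -> tuple:
    """(R^2, RMSE): coefficient of determination and root-mean-square error."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length series with at least 3 samples")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ZeroDivisionError("observed series has zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot, float(np.sqrt(ss_res / obs.size))


def arrhenius_rate_summary(fits) -> dict:
    """Arrhenius regression of the kinetic constant: ln ko vs 1/T(K).

    Returns slope (K), activation energy Ea = -R*slope (J/mol), the intercept
    (ln of the pre-exponential, 1/min) and the regression R^2.
    """
    fits = list(fits)
    if len(fits) < 3:
        raise ValueError("need fits at >= 3 temperatures")
    T = np.array([f.temperature for f in fits], float)
    if np.any(~np.isfinite(T)):
        raise ValueError("every fit must carry its drying temperature")
    ko = np.array([f.ko for f in fits], float)
    x = 1.0 / (T + 273.15)
    y = np.log(ko)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    from .properties import R_GAS

    return {
        "slope_K": float(slope),
        "Ea_J_per_mol": float(-R_GAS * slope),
        "ln_pre_exponential": float(intercept),
        "r2": float(r2),
        "n": len(fits),
    }
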