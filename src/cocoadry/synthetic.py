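"""Virtual single-bean drying experiments.

Emulates the laboratory protocol used for the CCN51 drying study: a single
bean (mean initial wet mass 1.973 g) suspended in a forced-convection oven,
weighed every 20 min on a 0.001 g analytical balance, with a core
thermocouple trace.  A generating drying model (fitted kinetic constants or
a transport simulation) provides the clean signals; additive Gaussian
measurement noise and balance quantization produce the virtual measurements.

All randomness is driven by one integer seed through independent
``numpy.random.SeedSequence`` spawns (one stream per measured quantity), so
an experiment is bit-reproducible from its recorded seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .kinetics import (
    DiffusionApproxFit,
    DryingCurve,
    evaluate_diffusion_model,
    fit_diffusion_model,
    moisture_ratio,
)

__all__ = [
    "ExperimentProtocol",
    "SyntheticExperiment",
    "generate_from_kinetics",
    "generate_from_simulation",
    "recover_parameters",
]


@dataclass(frozen=True)
class ExperimentProtocol:
    """Measurement protocol of the virtual oven experiment."""

    weighing_interval_min: float = 20.0
    balance_resolution_g: float = 0.001
    mass_noise_g: float = 0.002  # s.d. of additive mass noise, before rounding
    temp_noise_C: float = 0.2  # s.d. of thermocouple noise
    initial_wet_mass_g: float = 1.973
    dry_matter_g: float = 0.700  # bone-dry mass; 1.973/(1+1.82) by default
    duration_min: float = 350.0
    seed: int = 0

    def __post_init__(self):
        if self.weighing_interval_min <= 0 or self.balance_resolution_g <= 0:
            raise ValueError("interval and balance resolution must be positive")

    @property
    def sample_times_min(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + 1e-9, self.weighing_interval_min)


@dataclass
class SyntheticExperiment:
    """One virtual drying run: measured series plus the generating truth."""

    times_min: np.ndarray
    mass_g: np.ndarray  # noisy, quantized balance readings
    core_temp_C: np.ndarray  # noisy thermocouple trace
    clean_mass_g: np.ndarray  # noiseless signal (non-increasing)
    protocol: ExperimentProtocol
    ground_truth: dict = field(default_factory=dict)

    def to_curve(self) -> DryingCurve:
        """Invert the mass series back to a moisture-ratio curve."""
        gt = self.ground_truth
        mcdb = (self.mass_g - self.protocol.dry_matter_g) / self.protocol.dry_matter_g
        mr = moisture_ratio(mcdb, gt["mc0"], gt["mce"])
        # measurement noise can push samples slightly outside [0, 1]
        return DryingCurve(
            self.times_min, np.clip(mr, 0.0, 1.05), kind="MR",
            temperature=gt.get("temperature"),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "mass_g": self.mass_g,
                "core_temp_C": self.core_temp_C,
            }
        )

    def write(self, csv_path, sidecar_json=None):
        """CSV time series plus a JSON sidecar holding the ground truth."""
        self.to_frame().to_csv(csv_path, index=False)
        if sidecar_json is None:
            sidecar_json = str(csv_path) + ".json"
        payload = {"protocol": asdict(self.protocol), "ground_truth": self.ground_truth}
        with open(sidecar_json, "w") as f:
            json.dump(payload, f, indent=2)


def _streams(seed: int, n: int = 2):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _measure(times, clean_mass, clean_temp, protocol: ExperimentProtocol, truth):
    rng_mass, rng_temp = _streams(protocol.seed)
    mass = clean_mass + rng_mass.normal(0.0, protocol.mass_noise_g, clean_mass.shape)
    res = protocol.balance_resolution_g
    mass = np.round(mass / res) * res
    temp = clean_temp + rng_temp.normal(0.0, protocol.temp_noise_C, clean_temp.shape)
    return SyntheticExperiment(
        times_min=times,
        mass_g=mass,
        core_temp_C=temp,
        clean_mass_g=clean_mass,
        protocol=protocol,
        ground_truth=truth,
    )


def generate_from_kinetics(
    fit: DiffusionApproxFit,
    protocol: ExperimentProtocol | None = None,
    mc0: float = 1.82,
    mce: float = 0.02,
    initial_temp_C: float = 24.0,
    plateau_offset_C: float = 6.0,
    temp_lag_min: float = 15.0,
) -> SyntheticExperiment:
    """Virtual experiment generated by the diffusion-approximation model.

    MR(t) -> MCdb(t) -> mass(t) = dry_matter * (1 + MCdb); the thermocouple
    trace is a first-order lag from ``initial_temp_C`` to a plateau sitting
    ``plateau_offset_C`` below the drying temperature (evaporative cooling).
    """
    if mc0 <= mce or mce < 0:
        raise ValueError("need mc0 > mce >= 0")
    protocol = protocol or ExperimentProtocol()
    times = protocol.sample_times_min
    mr = evaluate_diffusion_model(fit, times)
    mcdb = mce + (mc0 - mce) * mr
    clean_mass = protocol.dry_matter_g * (1.0 + mcdb)
    t_air = fit.temperature if fit.temperature is not None else 50.0
    plateau = t_air - plateau_offset_C
    clean_temp = plateau - (plateau - initial_temp_C) * np.exp(-times / temp_lag_min)
    truth = {
        "ko": fit.ko,
        "a": fit.a,
        "b": fit.b,
        "mc0": mc0,
        "mce": mce,
        "temperature": t_air,
        "seed": protocol.seed,
        "generator": "kinetics",
    }
    return _measure(times, clean_mass, clean_temp, protocol, truth)


def generate_from_simulation(
    result,
    protocol: ExperimentProtocol | None = None,
    mcdb0: float = 1.82,
) -> SyntheticExperiment:
    """Virtual experiment sampled from a transport-solver run."""
    protocol = protocol or ExperimentProtocol()
    times = protocol.sample_times_min
    sim_t = result.times_min
    if sim_t[-1] < protocol.duration_min - 1e-9:
        raise ValueError(
            f"simulation covers {sim_t[-1]:.0f} min but the protocol needs "
            f"{protocol.duration_min:.0f} min"
        )
    mcdb = np.interp(times, sim_t, result.mcdb_trace(mcdb0))
    clean_mass = protocol.dry_matter_g * (1.0 + mcdb)
    clean_temp = np.interp(times, sim_t, result.T_core)
    ce = result.bc.c_inf
    truth = {
        "mc0": mcdb0,
        "mce": mcdb0 * ce / result.ic.co,
        "temperature": result.bc.air.temperature,
        "seed": protocol.seed,
        "generator": "simulation",
    }
    return _measure(times, clean_mass, clean_temp, protocol, truth)


def recover_parameters(experiments, ground_truth: dict | None = None) -> dict:
    """Fit each experiment and summarize bias/spread against the truth.

    Ground truth defaults to the constants recorded in the experiments; all
    experiments must then share one generating parameter set.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("need at least one experiment")
    if ground_truth is None:
        ground_truth = experiments[0].ground_truth
    fits = [fit_diffusion_model(e.to_curve()) for e in experiments]
    report = {"n": len(fits), "fits": fits}
    for name in ("ko", "a", "b"):
        if name not in ground_truth:
            continue
        est = np.array([getattr(f, name) for f in fits])
        truth = ground_truth[name]
        report[name] = {
            "truth": truth,
            "mean": float(est.mean()),
            "bias": float(est.mean() - truth),
            "sd": float(est.std(ddof=1)) if len(est) > 1 else 0.0,
        }
    return report
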