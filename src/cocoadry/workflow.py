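"""End-to-end drying-study workflow: configuration, runs and reports.

One YAML-serializable configuration dictionary drives every stage:
properties -> mesh -> transient simulations at several air temperatures ->
kinetic fitting -> consolidated report.  Each command writes its outputs
plus a config snapshot and a log (package version, seed) into the output
directory; a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import copy
import json
import logging
import pathlib

import numpy as np
import yaml

from . import __version__
from . import properties as props
from . import transport
from .geometry import build_geometry, generate_mesh
from .kinetics import (
    REFERENCE_DRYING_CONSTANTS,
    DiffusionApproxFit,
    DryingCurve,
    arrhenius_rate_summary,
    fit_diffusion_model,
)
from .synthetic import ExperimentProtocol, generate_from_kinetics

__all__ = [
    "default_config",
    "load_config",
    "validate_config",
    "build_setup",
    "simulate_temperature",
    "cmd_properties",
    "cmd_simulate",
    "cmd_fit",
    "cmd_synth",
    "cmd_reproduce",
]

log = logging.getLogger("cocoadry")

REQUIRED_SECTIONS = ("geometry", "materials", "air", "boundary", "initial", "numerics", "outputs")


def default_config() -> dict:
    return {
        "geometry": {"length": 0.022, "width": 0.012, "shell_thickness": 0.00055},
        "materials": {"source": "published"},
        "air": {"speed": 1.0, "ambient_temperature": 26.0, "ambient_rh": 0.72},
        "boundary": {
            "latent_heat": 2.38e6,
            "latent_basis": "inventory",
            "vapor_limited": True,
            "characteristic_length": None,
        },
        "initial": {"To": 24.0, "co": 10878.0},
        "numerics": {
            "target_size": 0.0005,
            "shell_layers": 3,
            "dt": 5.0,
            "t_end_min": 350.0,
            "theta": 1.0,
            "property_refresh_dT": 0.25,
            "trace_cadence": 60.0,
            "snapshot_cadence": 600.0,
            "store_snapshots": False,
        },
        "outputs": {"mcdb0": 1.82, "temperatures": [40.0, 50.0, 60.0, 70.0]},
        "reproduce": {
            "convergence_sizes": [0.0012, 0.0008, 0.0005],
            "convergence_t_end_min": 120.0,
        },
    }


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (extra or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and an override dict."""
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for section in user:
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict):
    missing = [s for s in REQUIRED_SECTIONS if s not in cfg]
    if missing:
        raise ValueError(f"config is missing required sections: {missing}")


def _prepare_outdir(outdir, cfg, seed=None) -> pathlib.Path:
    validate_config(cfg)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config_snapshot.yaml", "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
    with open(outdir / "run.log", "w") as f:
        f.write(f"cocoadry {__version__}\nseed: {seed}\n")
    return outdir


def build_setup(cfg: dict):
    """(geometry, mesh, materials, ic) from the configuration."""
    geom = build_geometry(**cfg["geometry"])
    num = cfg["numerics"]
    mesh = generate_mesh(
        geom, target_size=num["target_size"], shell_layers=num["shell_layers"]
    )
    materials = transport.default_materials(cfg["materials"].get("source", "published"))
    ic = transport.InitialConditions(**cfg["initial"])
    return geom, mesh, materials, ic


def _solver_config(cfg: dict, **overrides) -> transport.SolverConfig:
    num = cfg["numerics"]
    kw = dict(
        dt=num["dt"],
        t_end=num["t_end_min"] * 60.0,
        theta=num["theta"],
        property_refresh_dT=num["property_refresh_dT"],
        trace_cadence=num["trace_cadence"],
        snapshot_cadence=num["snapshot_cadence"],
        store_snapshots=num["store_snapshots"],
    )
    kw.update(overrides)
    return transport.SolverConfig(**kw)


def make_boundary(cfg: dict, geom, ic, materials, temperature: float):
    air = props.AirState(temperature=temperature, **cfg["air"])
    b = cfg["boundary"]
    return transport.BoundaryConditions.from_air(
        air,
        geom,
        ic=ic,
        materials=materials,
        latent_basis=b.get("latent_basis", "inventory"),
        latent_heat=b.get("latent_heat", 2.38e6),
        characteristic_length=b.get("characteristic_length"),
        vapor_limited=b.get("vapor_limited", True),
    )


def simulate_temperature(cfg: dict, temperature: float, setup=None, **solver_overrides):
    """One full transient at the given air temperature (°C)."""
    geom, mesh, materials, ic = setup or build_setup(cfg)
    bc = make_boundary(cfg, geom, ic, materials, temperature)
    solver = _solver_config(cfg, **solver_overrides)
    log.info("simulating T_air=%.0f °C on %d nodes", temperature, mesh.n_points)
    return transport.run(mesh, materials, bc, ic, solver)


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def cmd_properties(cfg: dict, outdir) -> dict:
    """Property tables for both tissues plus the quadratic correlations."""
    outdir = _prepare_outdir(outdir, cfg)
    tissues = {
        "testa": props.TESTA_COMPOSITION,
        "cotyledon": props.COTYLEDON_COMPOSITION,
    }
    grid = np.arange(40.0, 70.0 + 1e-9, 5.0)
    out = {}
    rows_50 = []
    poly_rows = []
    for name, comp in tissues.items():
        table = props.property_table(comp, grid)
        table.to_csv(outdir / f"properties_{name}.csv", index=False)
        p50 = props.mixture_props(comp, 50.0)
        rows_50.append(
            {"sample": name, "rho": p50.rho, "cp": p50.cp, "k": p50.k, "alpha": p50.alpha}
        )
        poly = props.fit_property_polynomials(comp, grid)
        for prop_name in ("rho", "cp", "k"):
            c2, c1, c0 = getattr(poly, prop_name)
            poly_rows.append(
                {
                    "sample": name,
                    "property": prop_name,
                    "c2": c2,
                    "c1": c1,
                    "c0": c0,
                    "residual_rms": poly.residual_rms[prop_name],
                }
            )
        out[name] = {"table": table, "at_50C": p50, "polynomials": poly}
    import pandas as pd

    pd.DataFrame(rows_50).to_csv(outdir / "properties_at_50C.csv", index=False)
    pd.DataFrame(poly_rows).to_csv(outdir / "property_polynomials.csv", index=False)
    out["at_50C"] = pd.DataFrame(rows_50)
    return out


def cmd_simulate(cfg: dict, outdir, temperatures=None, export_fields=False) -> dict:
    """Transient drying runs at each requested air temperature."""
    outdir = _prepare_outdir(outdir, cfg)
    temperatures = temperatures or cfg["outputs"]["temperatures"]
    setup = build_setup(cfg)
    mcdb0 = cfg["outputs"]["mcdb0"]
    results = {}
    for T in temperatures:
        res = simulate_temperature(cfg, T, setup=setup,
                                   store_snapshots=export_fields)
        res.to_frame(mcdb0).to_csv(outdir / f"traces_{T:.0f}C.csv", index=False)
        if export_fields:
            res.export_vtk_series(outdir / f"fields_{T:.0f}C")
        results[float(T)] = res
    return results


def cmd_fit(cfg: dict, curves, outdir) -> dict:
    """Diffusion-approximation fits for a set of drying curves."""
    curves = list(curves)
    if not curves:
        raise ValueError("no drying curves supplied to fit")
    outdir = _prepare_outdir(outdir, cfg)
    fits = []
    for cur in curves:
        if isinstance(cur, (str, pathlib.Path)):
            cur = DryingCurve.from_csv(cur)
        fits.append(fit_diffusion_model(cur.to_mr()))
    import pandas as pd

    table = pd.DataFrame(
        [
            {
                "temperature_C": f.temperature,
                "ko_per_min": f.ko,
                "a": f.a,
                "b": f.b,
                "R2": f.r2,
                "RMSE": f.rmse,
            }
            for f in fits
        ]
    )
    table.to_csv(outdir / "kinetic_constants.csv", index=False)
    payload = table.to_dict(orient="records")
    summary = None
    if len(fits) >= 3 and all(f.temperature is not None for f in fits):
        summary = arrhenius_rate_summary(fits)
    with open(outdir / "kinetic_constants.json", "w") as f:
        json.dump({"fits": payload, "arrhenius": summary}, f, indent=2)
    return {"fits": fits, "table": table, "arrhenius": summary}


def cmd_synth(cfg: dict, outdir, seed: int = 0, temperatures=None, replicates: int = 1) -> list:
    """Virtual oven experiments from the published kinetic constants."""
    outdir = _prepare_outdir(outdir, cfg, seed)
    temperatures = temperatures or cfg["outputs"]["temperatures"]
    experiments = []
    counter = 0
    for T in temperatures:
        ko, a, b = REFERENCE_DRYING_CONSTANTS[float(T)]
        gen = DiffusionApproxFit(ko=ko, a=a, b=b, temperature=float(T))
        for rep in range(replicates):
            protocol = ExperimentProtocol(seed=seed * 10_000 + counter)
            exp = generate_from_kinetics(gen, protocol)
            exp.write(outdir / f"experiment_{T:.0f}C_rep{rep}.csv")
            experiments.append(exp)
            counter += 1
    return experiments


def cmd_reproduce(cfg: dict, outdir, seed: int = 0, make_plots: bool = True) -> dict:
    """The full study: properties, convergence, simulations, kinetics, report."""
    outdir = _prepare_outdir(outdir, cfg, seed)
    report = {}

    prop = cmd_properties(cfg, outdir / "properties")
    report["properties_at_50C"] = prop["at_50C"].to_dict(orient="records")

    geom, mesh, materials, ic = build_setup(cfg)
    bc50 = make_boundary(cfg, geom, ic, materials, 50.0)

    rep_cfg = cfg.get("reproduce", {})
    sizes = rep_cfg.get("convergence_sizes", [0.0012, 0.0008, 0.0005])
    conv = transport.grid_convergence_study(
        geom, materials, bc50, ic, sizes,
        _solver_config(cfg, t_end=rep_cfg.get("convergence_t_end_min", 120.0) * 60.0,
                       store_snapshots=False),
        shell_layers=cfg["numerics"]["shell_layers"],
    )
    report["grid_convergence"] = {
        "sizes_m": conv.sizes,
        "n_nodes": conv.n_nodes,
        "max_deviation_finest_pair_C": conv.max_deviation_finest_pair,
    }

    comparison = transport.compare_single_vs_multidomain(
        mesh, materials, bc50, ic, _solver_config(cfg, store_snapshots=False)
    )
    report["single_vs_multidomain"] = {
        "max_dT_core_C": comparison["max_dT_core"],
        "max_dc_mean_mol_m3": comparison["max_dc_mean"],
    }

    sims = cmd_simulate(cfg, outdir / "simulations")
    mcdb0 = cfg["outputs"]["mcdb0"]
    curves = [
        DryingCurve(res.times_min, res.mr_trace(), kind="MR", temperature=T)
        for T, res in sims.items()
    ]
    fit_out = cmd_fit(cfg, curves, outdir / "kinetics")
    report["kinetics"] = fit_out["table"].to_dict(orient="records")
    report["arrhenius"] = fit_out["arrhenius"]
    report["plateau_T50_C"] = sims[50.0].plateau_temperature() if 50.0 in sims else None

    if make_plots:
        _plot_drying_curves(sims, mcdb0, outdir / "drying_curves.png")

    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=float)
    _write_report_md(report, outdir / "report.md")
    return {"report": report, "simulations": sims, "fits": fit_out["fits"],
            "comparison": comparison, "convergence": conv}


def _plot_drying_curves(sims: dict, mcdb0: float, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for T, res in sorted(sims.items()):
        ax1.plot(res.times_min, res.mcdb_trace(mcdb0), label=f"{T:.0f} °C")
        ax2.plot(res.times_min, res.T_core, label=f"{T:.0f} °C")
    ax1.set_xlabel("time (min)")
    ax1.set_ylabel("MC dry basis (g/g)")
    ax2.set_xlabel("time (min)")
    ax2.set_ylabel("core temperature (°C)")
    ax1.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_report_md(report: dict, path):
    lines = ["# CCN51 bean drying — consolidated report", ""]
    lines += ["## Thermophysical properties at 50 °C", ""]
    for row in report["properties_at_50C"]:
        lines.append(
            f"- {row['sample']}: rho = {row['rho']:.1f} kg/m³, "
            f"cp = {row['cp']:.3f} kJ/(kg·°C), k = {row['k']:.3f} W/(m·°C), "
            f"alpha = {row['alpha']:.3e} m²/s"
        )
    gc = report["grid_convergence"]
    lines += [
        "",
        "## Grid convergence",
        "",
        f"- mesh sizes (m): {gc['sizes_m']} -> nodes {gc['n_nodes']}",
        f"- max core-temperature deviation between the two finest grids: "
        f"{gc['max_deviation_finest_pair_C']:.3f} °C",
        "",
        "## Single vs multidomain (50 °C)",
        "",
        f"- max core-temperature difference: {report['single_vs_multidomain']['max_dT_core_C']:.3f} °C",
        f"- max mean-concentration difference: {report['single_vs_multidomain']['max_dc_mean_mol_m3']:.1f} mol/m³",
        "",
        "## Drying kinetics (diffusion-approximation fits)",
        "",
        "| T (°C) | ko (1/min) | a | b | R² | RMSE |",
        "|---|---|---|---|---|---|",
    ]
    for row in report["kinetics"]:
        lines.append(
            f"| {row['temperature_C']:.0f} | {row['ko_per_min']:.4f} | {row['a']:.3f} "
            f"| {row['b']:.3f} | {row['R2']:.5f} | {row['RMSE']:.5f} |"
        )
    if report.get("arrhenius"):
        arr = report["arrhenius"]
        lines += [
            "",
            f"Arrhenius summary of ko(T): Ea = {arr['Ea_J_per_mol'] / 1e3:.1f} kJ/mol "
            f"(R² = {arr['r2']:.3f})",
        ]
    if report.get("plateau_T50_C") is not None:
        lines += [
            "",
            f"Quasi-steady core temperature at 50 °C / 1 m/s: "
            f"{report['plateau_T50_C']:.1f} °C (60–240 min median)",
        ]
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
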