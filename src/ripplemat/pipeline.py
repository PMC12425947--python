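"""End-to-end pipeline: geometry → flow → scalars → diagnostics → niche map
→ synthetic community table → zonation agreement.

Every artifact is stamped with the config hash and seed; numeric outputs
are a pure function of (config, seed).  Stage failures raise with the
stage name; artifacts written before the failure are left in place.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import diagnostics as diag_mod
from . import lbm_flow, niche_map, scalar_transport, synthetic_data
from .config import RunConfig
from .geometry import RippleGeometry, make_ripple
from .gridio import write_field_csv, write_vtk_structured_points

log = logging.getLogger("ripplemat")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def build_geometry(config: RunConfig):
    g = config.geometry
    geom = RippleGeometry(wavelength_m=g.wavelength_m, height_m=g.height_m,
                          asymmetry=g.asymmetry, bed_depth_m=g.bed_depth_m,
                          n_ripples=g.n_ripples)
    return make_ripple(geom, config.flow.nx, config.flow.ny, g.ns_sediment)


def run_flow(config: RunConfig, porosity) -> lbm_flow.FlowState:
    fc = config.flow
    vent = (fc.vent.x0, fc.vent.x1, fc.vent.w) if fc.vent else None
    bc = lbm_flow.FlowBoundaryConditions(
        u_top=fc.u_top, vent=vent, porous_mode=fc.porous_mode,
        brinkman_drag=fc.brinkman_drag,
    )
    if fc.init == "couette":
        state = lbm_flow.couette_initial_state(fc.ny, fc.nx, fc.u_top)
    else:
        state = lbm_flow.initial_state(fc.ny, fc.nx)
    return lbm_flow.run_to_steady(fc.tau, porosity, bc, state=state,
                                  tol=fc.tol, max_steps=fc.max_steps)


def build_scalars(config: RunConfig, porosity) -> list[scalar_transport.ScalarField]:
    ny, nx = porosity.shape
    out = []
    vent = config.flow.vent
    for sc in config.scalars:
        if not sc.enabled:
            continue
        mask = None
        value = 1.0
        if vent is not None and sc.vent_value is not None:
            mask = np.zeros((ny, nx), dtype=bool)
            mask[0, vent.x0 : vent.x1 + 1] = True
            value = sc.vent_value
        out.append(scalar_transport.ScalarField(
            name=sc.name, C=np.zeros((ny, nx)), D=sc.D,
            bc=scalar_transport.ScalarBC(top_kind=sc.top_kind, top=sc.top,
                                         bottom_kind=sc.bottom_kind,
                                         bottom=sc.bottom),
            source_mask=mask, source_value=value,
        ))
    return out


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; returns the report bundle as a dict and, when
    outdir is given, writes fields, profiles and JSON reports there."""
    t_start = time.perf_counter()
    outdir = Path(outdir if outdir is not None else config.output.directory)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    report: dict = {"stamp": stamp, "stages": {}}
    fmts = config.output.formats

    def _stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start_s": round(time.perf_counter() - t_start, 3)}

    try:
        _stage("geometry")
        porosity = build_geometry(config)
        if "csv" in fmts:
            write_field_csv(outdir / "porosity.csv", porosity.ns,
                            dx_m=porosity.dx_m, name="ns")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("geometry", exc) from exc

    try:
        _stage("convection_check")
        cc = config.convection
        check = scalar_transport.check_no_convection(
            delta_T=cc.delta_T, depth_m=cc.depth_m, alpha=cc.alpha, nu=cc.nu,
            kappa=cc.kappa, permeability_m2=cc.permeability_m2,
            critical_value=cc.critical_value,
        )
        report["convection"] = {"rayleigh_proxy": check.rayleigh_proxy,
                                "critical_value": check.critical_value,
                                "passed": check.passed}
        thermal_blocked = not check.passed and not cc.override
    except StageError:
        raise
    except Exception as exc:
        raise StageError("convection_check", exc) from exc

    try:
        _stage("flow")
        flow = run_flow(config, porosity)
        report["flow"] = {k: flow.meta.get(k) for k in ("converged", "steps", "residual")}
        u = flow.u
        if "csv" in fmts:
            write_field_csv(outdir / "rho.csv", flow.rho, porosity.dx_m, "rho")
            write_field_csv(outdir / "u_x.csv", u[0], porosity.dx_m, "u_x")
            write_field_csv(outdir / "u_y.csv", u[1], porosity.dx_m, "u_y")
            write_field_csv(outdir / "p.csv", flow.p, porosity.dx_m, "p")
        if "vtk" in fmts:
            write_vtk_structured_points(outdir / "flow.vtk",
                                        {"rho": flow.rho, "p": flow.p, "u": u},
                                        dx_m=porosity.dx_m)
        residuals = flow.meta.get("residuals", [])
        (outdir / "flow_residuals.log").write_text(
            "\n".join(f"{(i + 1)} {r:.6e}" for i, r in enumerate(residuals)) + "\n"
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("flow", exc) from exc

    try:
        _stage("scalars")
        scalars = build_scalars(config, porosity)
        if thermal_blocked:
            scalars = [s for s in scalars if s.name != "T"]
            report["stages"]["scalars"]["thermal_blocked"] = True
        scalars = scalar_transport.run_scalars_to_steady(flow, scalars, porosity)
        for s in scalars:
            if "csv" in fmts:
                write_field_csv(outdir / f"scalar_{s.name}.csv", s.C,
                                porosity.dx_m, s.name)
        if "vtk" in fmts and scalars:
            write_vtk_structured_points(outdir / "scalars.vtk",
                                        {s.name: s.C for s in scalars},
                                        dx_m=porosity.dx_m)
        pen = {
            s.name: scalar_transport.penetration_depth(
                s, porosity, config.diagnostics.penetration_threshold)
            for s in scalars
        }
        with open(outdir / "penetration_depth.csv", "w") as fh:
            names = sorted(pen)
            fh.write("x," + ",".join(names) + "\n")
            for x in range(porosity.shape[1]):
                fh.write(f"{x}," + ",".join(f"{pen[n][x]:.1f}" for n in names) + "\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("scalars", exc) from exc

    try:
        _stage("diagnostics")
        dg = diag_mod.diagnose(flow, porosity, scalars,
                               min_eddy_area=config.diagnostics.min_eddy_area,
                               u_ref=config.flow.u_top or None)
        crest, trough = diag_mod.crest_trough_columns(porosity)
        report["diagnostics"] = {
            "separation_points": [[int(x), lab] for x, lab in dg.separation_points],
            "eddies": [
                {"center": list(e.center), "area_cells": e.area_cells,
                 "circulation_sign": e.circulation_sign}
                for e in dg.eddies
            ],
            "crest_col": crest, "trough_col": trough,
            "stoss_mean_pressure": dg.stoss_mean_pressure,
            "lee_mean_pressure": dg.lee_mean_pressure,
            "pressure_min_col": int(np.argmin(dg.surface_pressure)),
        }
        with open(outdir / "surface_pressure.csv", "w") as fh:
            fh.write("x,surface_pressure\n")
            for x, v in enumerate(dg.surface_pressure):
                fh.write(f"{x},{float(v)!r}\n")
        for name, flux in dg.exchange_flux.items():
            with open(outdir / f"flux_{name}.csv", "w") as fh:
                fh.write("x,flux_into_sediment\n")
                for x, v in enumerate(flux):
                    fh.write(f"{x},{float(v)!r}\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("diagnostics", exc) from exc

    try:
        _stage("niche_map")
        thr = None
        nc = config.niche
        if nc.o2_levels is not None and nc.h2s_levels is not None:
            thr = niche_map.NicheThresholds(o2_levels=tuple(nc.o2_levels),
                                            h2s_levels=tuple(nc.h2s_levels))
        profile = niche_map.zonation_profile(
            [s for s in scalars if s.name in ("O2", "H2S", "T")], porosity, thr)
        profile.to_frame().to_csv(outdir / "zonation.csv", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("niche_map", exc) from exc

    try:
        _stage("synthesis_and_agreement")
        spec = synthetic_data.builtin_scenario(
            config.synth.scenario, concentration=config.synth.concentration,
            n_replicates=config.synth.n_replicates, seed=config.seed)
        table = synthetic_data.generate_community_table(spec)
        synthetic_data.write_table_tsv(table, outdir / "community_table.tsv")
        agreement = None
        if table["position"].notna().all():
            agreement = niche_map.zonation_agreement(
                table, {k: v for k, v in nc.indicator_taxa.items()})
        report["agreement"] = {"statistic": agreement,
                               "scenario": config.synth.scenario}
    except StageError:
        raise
    except Exception as exc:
        raise StageError("synthesis_and_agreement", exc) from exc

    report["elapsed_s"] = round(time.perf_counter() - t_start, 3)
    payload = {k: v for k, v in report.items() if k != "elapsed_s"}
    payload["stages"] = sorted(payload["stages"])  # names only: no timings
    (outdir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
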