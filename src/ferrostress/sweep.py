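"""End-to-end case orchestration and the four parametric studies.

One case = one magnet configuration run through the full pipeline in
order: geometry/meshing -> magnetostatics -> vessel hemodynamics ->
tissue blood pressure -> interstitial pressure -> displacement ->
stress post-processing.  The coupling is one-way in that order (steady
state, small strain), so each stage is solved once.

The four studies mirror the study grid of the underlying investigation:

* ``shape``:    HR, VR, SC, BC magnets at 1.5 T, phi_ff = 0.5,
                tangential placement; reports the two headline percent
                changes (HR vs VR, BC vs SC) of the mean dimensionless
                stress along the tumor's horizontal diameter.
* ``flux``:     B_rem in {0.5, 1.5, 2, 2.5, 3} T (HR magnet).
* ``distance``: center-to-center distance in {15, 20, 25, 30, 35} mm
                (HR magnet).
* ``phi``:      ferrofluid volume fraction in {0.1, 0.3, 0.5, 0.7, 0.9}
                (HR magnet).

Everything is deterministic: identical inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import hemodynamics as hemo
from . import magnetostatics as mag
from . import poroelastic as poro
from . import stress as stp
from .fem import write_vtk
from .params import ParamSet, effective_permeability, stress_scale

log = logging.getLogger("ferrostress")

#: study grids
BREM_GRID = (0.5, 1.5, 2.0, 2.5, 3.0)          # T
DISTANCE_GRID = (0.015, 0.020, 0.025, 0.030, 0.035)   # m, center-to-center
PHI_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)

#: mesh resolution presets
RESOLUTIONS = {
    "coarse": dict(h_tissue=4.0e-4, h_tissue_far=1.2e-3,
                   flow_layers=4, flow_arc=3.0e-4, flow_axial=5.0e-4,
                   mag_h=8.0e-4, mag_hmid=2.0e-3),
    "default": dict(h_tissue=2.5e-4, h_tissue_far=1.0e-3,
                    flow_layers=5, flow_arc=1.5e-4, flow_axial=2.5e-4,
                    mag_h=5.0e-4, mag_hmid=1.25e-3),
}


class SweepError(ValueError):
    pass


@dataclass
class CaseSpec:
    """One magnet configuration to simulate."""

    shape_id: str = "HR"
    B_rem: float = 1.5                  # T
    center_distance: float | None = None  # m; None = tangential
    phi_ff: float = 0.5
    resolution: str = "default"
    stokes: bool = True                 # drop convective term
    symmetric_bc: bool = False          # equal feeder pressures (tests)
    magnetize_interstitium: bool = True
    custom: bool = False                # allow off-grid values

    def __post_init__(self):
        if self.shape_id not in geo.SHAPE_IDS:
            raise SweepError(f"unknown magnet shape {self.shape_id!r}")
        if self.resolution not in RESOLUTIONS:
            raise SweepError(f"unknown resolution preset "
                             f"{self.resolution!r}")
        if not self.custom:
            if self.B_rem not in BREM_GRID and self.B_rem != 0.0:
                raise SweepError(
                    f"B_rem {self.B_rem} not on the study grid "
                    f"{BREM_GRID}; pass custom=True to override")
            if (self.center_distance is not None
                    and round(self.center_distance, 6) not in
                    [round(d, 6) for d in DISTANCE_GRID]):
                raise SweepError(
                    f"distance {self.center_distance} not on the study "
                    f"grid {DISTANCE_GRID}; pass custom=True to override")
            if self.phi_ff not in PHI_GRID and self.phi_ff not in (0.0, 0.5):
                raise SweepError(
                    f"phi_ff {self.phi_ff} not on the study grid "
                    f"{PHI_GRID}; pass custom=True to override")

    def case_id(self) -> str:
        d = ("tan" if self.center_distance is None
             else f"{1e3 * self.center_distance:g}mm")
        return f"{self.shape_id}_B{self.B_rem:g}_d{d}_phi{self.phi_ff:g}"


@dataclass
class CaseResult:
    """All stage outputs plus the one-row summary of a case."""

    spec: CaseSpec
    magnet: geo.MagnetSpec
    meshes: geo.MeshSet
    magnetic: mag.MagneticSolution
    flow: hemo.FlowSolution
    poro_solution: poro.PoroSolution
    stress_field: stp.StressField
    profiles: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _build_meshes(p: ParamSet, magnet: geo.MagnetSpec, res: dict):
    tissue = geo.mesh_tissue(p, h_tumor=res["h_tissue"],
                             h_far=res["h_tissue_far"])
    flow = geo.mesh_flow(p, n_layers=res["flow_layers"],
                         h_arc=res["flow_arc"], h_axial=res["flow_axial"])
    magnetic = geo.mesh_magnetics(p, magnet, h_fine=res["mag_h"],
                                  h_mid=res["mag_hmid"])
    return geo.MeshSet(tissue=tissue, flow=flow, magnetic=magnetic)


def run_case(spec: CaseSpec, p: ParamSet | None = None,
             out_dir=None) -> CaseResult:
    """Execute the full pipeline for one case."""
    p = p if p is not None else ParamSet()
    res = RESOLUTIONS[spec.resolution]
    t0 = time.perf_counter()
    stage = "geometry"
    try:
        magnet = geo.place_magnet(spec.shape_id, spec.center_distance, p,
                                  B_rem=spec.B_rem)
        meshes = _build_meshes(p, magnet, res)
        log.info("meshes built: tissue %d / flow %d / magnetic %d nodes",
                 meshes.tissue.n_nodes, meshes.flow.n_nodes,
                 meshes.magnetic.n_nodes)

        stage = "magnetostatics"
        msol = mag.solve_potential(
            meshes.magnetic, magnet, p, phi_ff=spec.phi_ff,
            magnetize_interstitium=spec.magnetize_interstitium)

        stage = "hemodynamics"
        if spec.B_rem != 0.0:
            F_flow = msol.force_at(meshes.flow.centroids)
        else:
            F_flow = None
        kw = {}
        if spec.symmetric_bc:
            pm = 0.5 * (p.P_inlet + p.P_outlet)
            kw = dict(inlet_pressure=pm, outlet_pressure=pm)
        flow = hemo.solve_blood_flow(meshes.flow, F_flow, p,
                                     stokes=spec.stokes, **kw)
        wall = hemo.inner_wall_pressure(flow)

        stage = "poroelastic"
        if spec.B_rem != 0.0:
            F_tis = msol.force_at(meshes.tissue.centroids)
        else:
            F_tis = None
        P_B = poro.solve_tissue_blood_pressure(meshes.tissue, F_tis,
                                               wall, p)
        psol = poro.solve_poroelastic(meshes.tissue, P_B, F_tis, p)

        stage = "stress_post"
        sfield = stp.assemble_stress(psol, p)
        profiles = {
            "sigma_star": {
                pid: stp.sample_stress_profile(sfield, pid, p)
                for pid in stp.PATH_IDS
            },
            "B_mag": mag.sample_B_profiles(
                msol, geo.DomainGeometry(p, magnet, 0.0)),
            "wall_pressure": hemo.wall_pressure_trace(flow, "inner_upper"),
        }
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    Bprof = profiles["B_mag"]["horizontal_diameter"]
    summary = {
        "case_id": spec.case_id(),
        "shape_id": spec.shape_id,
        "B_rem_T": spec.B_rem,
        "center_distance_m": (magnet.center[1]),
        "phi_ff": spec.phi_ff,
        "mu_r_eff": effective_permeability(p, spec.phi_ff),
        "mean_sigma_star_diameter":
            profiles["sigma_star"]["horizontal_diameter"].linear_average,
        "mean_sigma_star_arc":
            profiles["sigma_star"]["upper_semicircle"].linear_average,
        "max_sigma_star":
            float(np.max(profiles["sigma_star"]
                         ["horizontal_diameter"].values)),
        "max_B_tumor_T": float(np.max(Bprof.values)),
        "max_wall_pressure_Pa": float(np.max(flow.P_B_vessel)),
        "picard_iterations": flow.iterations,
        "n_nodes_tissue": meshes.tissue.n_nodes,
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    result = CaseResult(spec=spec, magnet=magnet, meshes=meshes,
                        magnetic=msol, flow=flow, poro_solution=psol,
                        stress_field=sfield, profiles=profiles,
                        summary=summary)
    if out_dir is not None:
        export_case(result, p, out_dir)
    return result


# ----------------------------------------------------------------------
# studies
# ----------------------------------------------------------------------

def run_shape_study(p: ParamSet | None = None, resolution: str = "default",
                    out_dir=None, **case_kw):
    """Run HR, VR, SC, BC at baseline; return (table, percent changes).

    Percent changes are computed on the mean dimensionless von Mises
    stress along the tumor's horizontal diameter, relative to the
    smaller-stress member of each pair (VR for the rectangles, SC for
    the circles).
    """
    p = p if p is not None else ParamSet()
    rows = {}
    for sid in geo.SHAPE_IDS:
        spec = CaseSpec(shape_id=sid, resolution=resolution, **case_kw)
        rows[sid] = run_case(spec, p, out_dir=out_dir).summary
    table = pd.DataFrame([rows[s] for s in geo.SHAPE_IDS])
    mean = {s: rows[s]["mean_sigma_star_diameter"] for s in geo.SHAPE_IDS}
    changes = {
        "HR_vs_VR_percent": stp.percent_change(mean["HR"], mean["VR"]),
        "BC_vs_SC_percent": stp.percent_change(mean["BC"], mean["SC"]),
    }
    if out_dir is not None:
        _write_table(table, Path(out_dir) / "shape_study.csv", p)
        with open(Path(out_dir) / "shape_study_changes.json", "w") as fh:
            json.dump(changes, fh, indent=2)
    return table, changes


def run_sweep(which: str, p: ParamSet | None = None,
              resolution: str = "default", out_dir=None, **case_kw):
    """Run one of the HR-magnet parameter sweeps; returns a tidy table."""
    p = p if p is not None else ParamSet()
    if which == "flux":
        specs = [CaseSpec(shape_id="HR", B_rem=b, resolution=resolution,
                          **case_kw) for b in BREM_GRID]
    elif which == "distance":
        specs = [CaseSpec(shape_id="HR", center_distance=d,
                          resolution=resolution, **case_kw)
                 for d in DISTANCE_GRID]
    elif which == "phi":
        specs = [CaseSpec(shape_id="HR", phi_ff=f, resolution=resolution,
                          **case_kw) for f in PHI_GRID]
    elif which == "shape":
        return run_shape_study(p, resolution, out_dir=out_dir, **case_kw)[0]
    else:
        raise SweepError(f"unknown sweep {which!r} "
                         "(expected shape|flux|distance|phi)")
    table = pd.DataFrame([run_case(s, p, out_dir=out_dir).summary
                          for s in specs])
    if out_dir is not None:
        _write_table(table, Path(out_dir) / f"sweep_{which}.csv", p)
    return table


# ----------------------------------------------------------------------
# output
# ----------------------------------------------------------------------

def _provenance(p: ParamSet) -> str:
    cfg = json.dumps(p.to_config(), sort_keys=True)
    return hashlib.sha256(cfg.encode()).hexdigest()[:12]


def _write_table(table: pd.DataFrame, path: Path, p: ParamSet):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={_provenance(p)}\n")
        table.to_csv(fh, index=False)


def export_case(result: CaseResult, p: ParamSet, out_dir) -> None:
    """Write VTK fields and CSV profiles for one case."""
    out = Path(out_dir) / result.spec.case_id()
    out.mkdir(parents=True, exist_ok=True)
    ms = result.meshes
    sol = result.poro_solution
    write_vtk(out / "tissue.vtk", ms.tissue,
              point_data={"u": sol.u, "P_i": sol.P_i, "P_B": sol.P_B,
                          "sigma_star": result.stress_field.sigma_star},
              cell_data={"e_vol": sol.e_vol_tri,
                         "phi_B": sol.phi_B_tri, "phi_L": sol.phi_L_tri,
                         "V_i": sol.V_i_tri,
                         "sigma_vm": result.stress_field.sigma_vm_tri})
    write_vtk(out / "vessels.vtk", ms.flow,
              point_data={"V_B": result.flow.V_B,
                          "P_B": result.flow.P_B_vessel},
              cell_data={"gamma_dot": result.flow.gamma_dot,
                         "mu_B": result.flow.mu_B_field})
    msol = result.magnetic
    write_vtk(out / "magnetics.vtk", ms.magnetic,
              point_data={"psi": msol.psi, "H": msol.H, "B": msol.B,
                          "M": msol.M},
              cell_data={"F_mag": mag.kelvin_force(msol)})
    rows = []
    for pid, prof in result.profiles["sigma_star"].items():
        for L, v in zip(prof.L_star, prof.values):
            rows.append((result.spec.case_id(), pid, L, v))
    pd.DataFrame(rows, columns=["case_id", "path_id", "L_star",
                                "sigma_star"]).to_csv(
        out / "profiles_sigma_star.csv", index=False)
    wp = result.profiles["wall_pressure"]
    pd.DataFrame({"arc_over_Rt": wp.L_star,
                  "pressure_Pa": wp.values}).to_csv(
        out / "wall_pressure.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump({**result.summary, "config_hash": _provenance(p),
                   "spec": asdict(result.spec)}, fh, indent=2)
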