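"""Named, seeded experiment suites over geometries, models and ensembles.

An :class:`ExperimentConfig` fully determines a batch: geometry, model,
parameter overrides, initial condition, end time, realization count and base
seed.  Per-realization seeds derive deterministically from (base seed, index),
and polarized initial conditions cycle through a configurable set of rotation
angles about the symmetry axis, so a batch is reproducible end to end.

The catalog functions (:func:`experiment_catalog`) mirror the in-silico
studies of the analysis at desk scale: cap drift under polarized initial
conditions across tip shapes, random-initial-condition polarization, the
long-time average of the simplified model, long projections, the sphere-size
series under constant-molecule vs constant-density scaling, the coupled
Cdc42-polarisome model, the frozen-Cdc42 polarisome with and without a
hundred-fold Bni1 recruitment boost, and a high cytoplasmic-diffusion
variant.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    angular_distance_from_tip,
    cap_center,
    count_clusters,
    realization_table,
)
from .engine import compile_system, conservation_check, nsm_run
from .geometry import GeometrySpec, build_geometry, canonical_specs
from .jumps import assemble_jump_matrix
from .models import (
    InitialConditionSpec,
    attach_standard_fields,
    build_initial_state,
    coupled_model,
    load_parameters,
    mechanistic_cdc42_model,
    polarisome_model,
    scale_counts,
    simplified_cdc42_model,
)
from .trajectory import Trajectory, save_trajectory

__all__ = ["ExperimentConfig", "ResultBundle", "run_experiment", "summarize",
           "experiment_catalog"]

MODEL_BUILDERS = {
    "mechanistic": (mechanistic_cdc42_model, "cdc42_mechanistic", "Cdc42Tm"),
    "simplified": (simplified_cdc42_model, "cdc42_simplified", "Cdc42m"),
    "polarisome_frozen": (
        lambda p: polarisome_model(p, cdc42_mode="frozen_field"),
        "polarisome", "Spa2m"),
    "coupled": (lambda p: coupled_model(cdc42_params=None) if p is None
                else coupled_model(), "cdc42_mechanistic", "Cdc42Tm"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    geometry: str = "sphere"              # key of canonical_specs or GeometrySpec
    model: str = "mechanistic"
    param_overrides: dict = field(default_factory=dict)
    ic_mode: str = "polarized"
    t_end: float = 1000.0
    sample_interval: float = 20.0
    n_realizations: int = 20
    base_seed: int = 0
    scale: float = 1.0                    # shrink factor for realizations+counts
    n_rotations: int = 4                  # polarized-IC rotation angles per batch
    target_edge_length: float = 0.5
    count_scaling: str = "constant_molecules"  # vs base sphere
    frozen_cap_radius: float = 1.2        # frozen-Cdc42 field cap (um)
    processes: int = 1                    # per-realization worker processes
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must lie in (0, 1]")


@dataclass
class ResultBundle:
    config: ExperimentConfig
    trajectories: list            # Trajectory (None for failed realizations)
    errors: dict                  # realization index -> traceback string
    table: pd.DataFrame
    mesh: object
    tip_frame: object
    model: object
    tracked_species: str


def _geometry_spec(config: ExperimentConfig) -> GeometrySpec:
    if isinstance(config.geometry, GeometrySpec):
        return config.geometry
    specs = canonical_specs(target_edge_length=config.target_edge_length)
    if config.geometry not in specs:
        raise KeyError(f"unknown geometry {config.geometry!r}; "
                       f"choose from {sorted(specs)}")
    return specs[config.geometry]


def _scaled(value: int, scale: float) -> int:
    return max(1, int(round(value * scale)))


def _build_model(config: ExperimentConfig, mesh, tip_frame):
    builder, param_set, tracked = MODEL_BUILDERS[config.model]
    if config.model == "coupled":
        cp = load_parameters("cdc42_mechanistic",
                             {k: v for k, v in config.param_overrides.items()
                              if not k.startswith("polarisome.")})
        pp = load_parameters("polarisome",
                             {k[len("polarisome."):]: v
                              for k, v in config.param_overrides.items()
                              if k.startswith("polarisome.")})
        from .models import coupled_model as _cm
        model = _cm(cp, pp)
    else:
        params = load_parameters(param_set, config.param_overrides)
        model = builder(params)
    frozen = None
    if config.model == "polarisome_frozen":
        frozen = tip_polarized_field(mesh, tip_frame,
                                     cap_radius=config.frozen_cap_radius,
                                     total=load_parameters(
                                         "cdc42_mechanistic")["n_cdc42"])
    attach_standard_fields(model, mesh, frozen_cdc42=frozen)
    return model, tracked


def tip_polarized_field(mesh, tip_frame, cap_radius: float,
                        total: int) -> np.ndarray:
    """A static active-Cdc42 profile: ``total`` copies spread over the tip cap
    proportional to voxel area (deterministic, not sampled)."""
    from .geometry import surface_geodesic_distances

    dist = surface_geodesic_distances(mesh, tip_frame.tip_vertex)
    in_cap = mesh.on_membrane & (dist <= cap_radius)
    w = np.where(in_cap, mesh.voxel_areas, 0.0)
    if w.sum() == 0:
        raise ValueError("frozen-field cap radius selects no membrane voxel")
    return total * w / w.sum()


def run_experiment(config: ExperimentConfig) -> ResultBundle:
    """Run one experiment batch; deterministic given the config."""
    spec = _geometry_spec(config)
    mesh, tip_frame = build_geometry(spec)
    model, tracked = _build_model(config, mesh, tip_frame)

    from .models import base_totals

    totals = {k: _scaled(v, config.scale)
              for k, v in base_totals(model, config.ic_mode).items()}
    if config.count_scaling != "constant_molecules":
        base_mesh, _ = build_geometry(
            canonical_specs(target_edge_length=config.target_edge_length)["sphere"])
        totals = scale_counts(totals, model, mesh, config.count_scaling, base_mesh)

    jumps = assemble_jump_matrix(mesh, model.species)
    system = compile_system(model, mesh, jumps)
    n_real = _scaled(config.n_realizations, config.scale)
    sample_times = np.arange(0.0, config.t_end + 1e-9, config.sample_interval)
    cap_radius = model.parameters.get("ic_cap_radius", 1.2)

    def _one(idx):
        rotation = (360.0 / config.n_rotations) * (idx % config.n_rotations) \
            if config.ic_mode == "polarized" else 0.0
        ic = InitialConditionSpec(
            mode=config.ic_mode,
            cap_radius=cap_radius,
            rotation_deg=rotation,
            seed=_realization_seed(config.base_seed, idx),
        )
        x0 = build_initial_state(mesh, tip_frame, model, ic, totals=totals)
        return nsm_run(system, x0, config.t_end, sample_times,
                       seed=_realization_seed(config.base_seed, idx))

    trajectories: list = []
    errors: dict = {}
    if config.processes > 1:
        # embarrassingly parallel; per-realization seeds make the result
        # independent of scheduling.  The job is handed to forked workers via
        # a module global (closures do not pickle).
        import multiprocessing as mp

        global _FORK_JOB
        _FORK_JOB = _one
        try:
            with mp.get_context("fork").Pool(config.processes) as pool:
                outcomes = pool.map(_run_guarded, range(n_real))
        finally:
            _FORK_JOB = None
        for idx, (traj, err) in enumerate(outcomes):
            trajectories.append(traj)
            if err is not None:
                errors[idx] = err
    else:
        for idx in range(n_real):
            try:
                trajectories.append(_one(idx))
            except Exception:
                trajectories.append(None)
                errors[idx] = traceback.format_exc()

    ok = [t for t in trajectories if t is not None]
    table = realization_table(ok, tracked, mesh, tip_frame) if ok else pd.DataFrame()
    bundle = ResultBundle(config=config, trajectories=trajectories,
                          errors=errors, table=table, mesh=mesh,
                          tip_frame=tip_frame, model=model,
                          tracked_species=tracked)
    if config.output_dir:
        _persist(bundle)
    return bundle


_FORK_JOB = None


def _run_guarded(idx):
    try:
        return _FORK_JOB(idx), None
    except Exception:
        return None, traceback.format_exc()


def _realization_seed(base_seed: int, idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(idx)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _persist(bundle: ResultBundle) -> None:
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    resolved = {"package_version": __version__,
                **dataclasses.asdict(bundle.config)}
    (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=False))
    if len(bundle.table):
        bundle.table.to_csv(out / "realizations.csv", index=False)
    for idx, traj in enumerate(bundle.trajectories):
        if traj is not None:
            save_trajectory(traj, out / f"trajectory_{idx:04d}.h5")
    (out / "summary.json").write_text(json.dumps(summarize(bundle), indent=2))
    if bundle.errors:
        (out / "errors.txt").write_text(
            "\n\n".join(f"realization {k}:\n{v}" for k, v in bundle.errors.items()))


def _wilson_ci(successes: int, n: int, z: float = 1.96):
    if n == 0:
        return (float("nan"), float("nan"))
    p = successes / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def summarize(bundle: ResultBundle) -> dict:
    """Stability fraction (with binomial CI), distance quantiles, clusters."""
    n_ok = sum(t is not None for t in bundle.trajectories)
    if n_ok == 0:
        return {"experiment": bundle.config.name, "n_realizations": 0,
                "note": "no realizations completed",
                "n_failed": len(bundle.errors)}
    tab = bundle.table
    stable = int(tab["stable"].sum())
    lo, hi = _wilson_ci(stable, len(tab))
    names = bundle.model.species_names
    cluster_counts = [
        count_clusters(t.counts[-1], bundle.tracked_species, names, bundle.mesh)
        for t in bundle.trajectories if t is not None
    ]
    hist = {int(k): int(v) for k, v in
            zip(*np.unique(cluster_counts, return_counts=True))}
    conservation_ok = all(
        all(rep["ok"] for rep in conservation_check(t, bundle.model).values())
        for t in bundle.trajectories if t is not None
    )
    return {
        "experiment": bundle.config.name,
        "geometry": str(bundle.config.geometry),
        "species": bundle.tracked_species,
        "n_realizations": int(n_ok),
        "n_failed": len(bundle.errors),
        "stable_fraction": stable / len(tab),
        "stable_ci95": [lo, hi],
        "distance_um_quantiles": {
            q: float(tab["geodesic_um"].quantile(q)) for q in (0.25, 0.5, 0.75)
        },
        "angle_from_tip_deg_median": float(tab["angle_from_tip_deg"].median()),
        "cluster_count_histogram": hist,
        "moieties_conserved": bool(conservation_ok),
    }


def experiment_catalog(base_seed: int = 0, scale: float = 1.0,
                       out_root: str | None = None) -> dict:
    """Desk-scale configurations mirroring the in-silico studies (E1-E8)."""
    def _out(name):
        return str(Path(out_root) / name) if out_root else None

    cat = {}
    # E1: cap drift, polarized IC, four shapes
    for geom in ("sphere", "slight_deform", "projection1", "projection2"):
        cat[f"E1_drift_{geom}"] = ExperimentConfig(
            name=f"E1_drift_{geom}", geometry=geom, model="mechanistic",
            ic_mode="polarized", t_end=1000.0, n_realizations=40,
            base_seed=base_seed, scale=scale, output_dir=_out(f"E1_{geom}"))
    # E2: random IC
    for geom in ("sphere", "projection2"):
        cat[f"E2_random_{geom}"] = ExperimentConfig(
            name=f"E2_random_{geom}", geometry=geom, model="mechanistic",
            ic_mode="random", t_end=1000.0, n_realizations=40,
            base_seed=base_seed + 1, scale=scale, output_dir=_out(f"E2_{geom}"))
    # E3: simplified model long-run time average
    for geom in ("sphere", "projection2"):
        cat[f"E3_altschuler_{geom}"] = ExperimentConfig(
            name=f"E3_altschuler_{geom}", geometry=geom, model="simplified",
            ic_mode="random", t_end=10000.0, sample_interval=50.0,
            n_realizations=8, base_seed=base_seed + 2, scale=scale,
            output_dir=_out(f"E3_{geom}"))
    # E4: long projection, polarized IC
    cat["E4_long_projection"] = ExperimentConfig(
        name="E4_long_projection", geometry="long_projection",
        model="mechanistic", ic_mode="polarized", t_end=1000.0,
        n_realizations=40, base_seed=base_seed + 3, scale=scale,
        output_dir=_out("E4"))
    # E5: sphere series, constant molecules vs constant density
    for r in (0.5, 1.0, 2.0, 4.0):
        for mode in ("constant_molecules", "constant_density"):
            key = f"E5_sphere_r{r}_{mode}"
            cat[key] = ExperimentConfig(
                name=key,
                geometry=GeometrySpec("sphere", body_radius=r,
                                      target_edge_length=min(0.5, r / 4)),
                model="mechanistic", ic_mode="random", t_end=1000.0,
                n_realizations=10, base_seed=base_seed + 4, scale=scale,
                count_scaling=mode, output_dir=_out(key))
    # E6: coupled Cdc42 + polarisome
    for geom in ("sphere", "projection2"):
        cat[f"E6_coupled_{geom}"] = ExperimentConfig(
            name=f"E6_coupled_{geom}", geometry=geom, model="coupled",
            ic_mode="polarized", t_end=1000.0, n_realizations=20,
            base_seed=base_seed + 5, scale=scale, output_dir=_out(f"E6_{geom}"))
    # E7: frozen-Cdc42 polarisome, base B_on and B_on x100
    base_bon = load_parameters("polarisome")["B_on"]
    for factor in (1, 100):
        key = f"E7_frozen_polarisome_Bon_x{factor}"
        cat[key] = ExperimentConfig(
            name=key, geometry="projection2", model="polarisome_frozen",
            param_overrides={"B_on": base_bon * factor},
            ic_mode="random", t_end=1000.0, n_realizations=20,
            base_seed=base_seed + 6, scale=scale, output_dir=_out(key))
    # E8: high cytoplasmic diffusion variant
    cat["E8_Dc50"] = ExperimentConfig(
        name="E8_Dc50", geometry="projection2", model="mechanistic",
        param_overrides={"D_cyt": 50.0}, ic_mode="polarized", t_end=1000.0,
        n_realizations=10, base_seed=base_seed + 7, scale=scale,
        output_dir=_out("E8"))
    return cat
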