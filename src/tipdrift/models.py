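"""The Cdc42 and polarisome reaction networks, initial conditions and scaling.

Three networks are provided:

* :func:`mechanistic_cdc42_model` — a GTPase-cycle model of Cdc42 polarization
  with a cytosolic GEF complex recruited by active Cdc42 (positive feedback),
  a uniform Gbg (pheromone) drive, and a weak Cla4-mediated negative feedback
  that ejects the GEF.  It forms a single, persistent polarization cap.
* :func:`simplified_cdc42_model` — the minimal positive-feedback model:
  membrane attachment, detachment and recruitment of cytosolic Cdc42 by
  membrane-bound Cdc42.  It clusters only stochastically, with transient
  caps forming and dissolving, and is a density-dependent switch.
* :func:`polarisome_model` — Bni1/Spa2/actin-cable dynamics driven by active
  Cdc42 (rate ``B_on``), optionally with the Cdc42 profile frozen to a static
  per-voxel field.

:func:`coupled_model` joins the mechanistic and polarisome networks, with
active Cdc42 recruiting Bni1 and actin cables delivering Cdc42 back to the
membrane (vesicle-transport positive feedback).

Parameter values ship as YAML files under ``tipdrift/params`` and are
literature-adapted and calibrated on the base sphere (r = 2.0 um); see
docs/methods.md for the provenance and the calibration protocol.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .geometry import Mesh, TipFrame, surface_geodesic_distances
from .model import ReactionModel, ReactionSpec, SpeciesSpec

__all__ = [
    "load_parameters",
    "mechanistic_cdc42_model",
    "simplified_cdc42_model",
    "polarisome_model",
    "coupled_model",
    "attach_standard_fields",
    "InitialConditionSpec",
    "build_initial_state",
    "base_totals",
    "scale_counts",
]

# field names understood by attach_standard_fields
FIELD_ATTACH_CORRECTION = "membrane_volume_correction"
FIELD_FROZEN_CDC42 = "frozen_cdc42_per_area"


def load_parameters(name: str, overrides: dict | None = None) -> dict:
    """Load a named parameter set from the packaged YAML files.

    ``name`` is e.g. 'cdc42_mechanistic', 'cdc42_simplified', 'polarisome'.
    """
    ref = importlib.resources.files("tipdrift") / "params" / f"{name}.yaml"
    params = yaml.safe_load(ref.read_text())
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)} for set {name!r}")
        params = {**params, **overrides}
    return params


def _require(params: dict, keys: list, model: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise KeyError(f"{model}: missing parameters {missing}")


def mechanistic_cdc42_model(params: dict | None = None) -> ReactionModel:
    """GTPase-cycle Cdc42 model with GEF positive feedback and Cla4 brake.

    Species: Cdc42 in cytosolic GDP form (Cdc42Dc), membrane GDP (Cdc42Dm)
    and membrane GTP / active (Cdc42Tm); a cytosolic/membrane GEF complex;
    cytosolic/membrane Cla4.  The uniform Gbg input appears as the basal
    membrane activation rate ``k_act0``.
    """
    if params is None:
        params = load_parameters("cdc42_mechanistic")
    _require(params, ["D_cyt", "D_mem", "k_att", "k_det", "k_act0", "k_act",
                      "k_hyd", "k_gef_on", "k_gg", "k_gef_off", "k_cla_on",
                      "k_cla_off", "k_neg", "n_cdc42", "n_gef", "n_cla4"],
             "mechanistic_cdc42_model")
    Dc, Dm = params["D_cyt"], params["D_mem"]
    species = [
        SpeciesSpec("Cdc42Dc", "cytoplasm", D_cyt=Dc),
        SpeciesSpec("Cdc42Dm", "membrane", D_mem=Dm),
        SpeciesSpec("Cdc42Tm", "membrane", D_mem=Dm),
        SpeciesSpec("GEFc", "cytoplasm", D_cyt=Dc),
        SpeciesSpec("GEFm", "membrane", D_mem=Dm),
        SpeciesSpec("Cla4c", "cytoplasm", D_cyt=Dc),
        SpeciesSpec("Cla4m", "membrane", D_mem=Dm),
    ]
    R = ReactionSpec
    reactions = [
        R("attach", (("Cdc42Dc", 1),), (("Cdc42Dm", 1),), params["k_att"],
          field=FIELD_ATTACH_CORRECTION),
        R("detach", (("Cdc42Dm", 1),), (("Cdc42Dc", 1),), params["k_det"]),
        # uniform Gbg input: basal activation of membrane GDP-Cdc42 (the
        # nucleation path)
        R("gbg_activate", (("Cdc42Dm", 1),), (("Cdc42Tm", 1),), params["k_act0"]),
        # main feedback arm: membrane GEF recruits-and-activates cytosolic
        # GDP-Cdc42 in its voxel; cytosolic Cdc42 is the shared substrate
        # whose depletion enforces a single winning cap
        R("gef_activate", (("GEFm", 1), ("Cdc42Dc", 1)),
          (("GEFm", 1), ("Cdc42Tm", 1)), params["k_act"]),
        R("hydrolyse", (("Cdc42Tm", 1),), (("Cdc42Dm", 1),), params["k_hyd"]),
        R("gef_recruit", (("GEFc", 1), ("Cdc42Tm", 1)),
          (("GEFm", 1), ("Cdc42Tm", 1)), params["k_gef_on"]),
        # cooperative GEF self-recruitment: the quadratic membrane feedback
        # that lets one cap outcompete the others
        R("gef_self_recruit", (("GEFc", 1), ("GEFm", 1)),
          (("GEFm", 2),), params["k_gg"]),
        R("gef_release", (("GEFm", 1),), (("GEFc", 1),), params["k_gef_off"]),
        R("cla4_recruit", (("Cla4c", 1), ("Cdc42Tm", 1)),
          (("Cla4m", 1), ("Cdc42Tm", 1)), params["k_cla_on"]),
        R("cla4_release", (("Cla4m", 1),), (("Cla4c", 1),), params["k_cla_off"]),
        R("cla4_eject_gef", (("Cla4m", 1), ("GEFm", 1)),
          (("Cla4m", 1), ("GEFc", 1)), params["k_neg"]),
    ]
    return ReactionModel(
        name="cdc42_mechanistic",
        species=species,
        reactions=reactions,
        moieties={
            "Cdc42": {"Cdc42Dc", "Cdc42Dm", "Cdc42Tm"},
            "GEF": {"GEFc", "GEFm"},
            "Cla4": {"Cla4c", "Cla4m"},
        },
        parameters=dict(params),
        initial_totals={
            "Cdc42Dc": int(params["n_cdc42"]),
            "GEFc": int(params["n_gef"]),
            "Cla4c": int(params["n_cla4"]),
        },
        initial_totals_polarized=_polarized_split(
            params, [("Cdc42Tm", "Cdc42Dc", "n_cdc42", 0.6),
                     ("GEFm", "GEFc", "n_gef", 0.8),
                     (None, "Cla4c", "n_cla4", 0.0)]),
    )


def _polarized_split(params: dict, plan: list) -> dict:
    """Split totals into a membrane (cap) part and a cytosolic remainder.

    ``plan`` entries are (membrane_species, cytosolic_species, total_key,
    membrane_fraction).
    """
    out = {}
    for mem_name, cyt_name, key, frac in plan:
        total = int(params[key])
        n_mem = int(round(frac * total)) if mem_name else 0
        if mem_name and n_mem:
            out[mem_name] = n_mem
        out[cyt_name] = total - n_mem
    return out


def simplified_cdc42_model(params: dict | None = None) -> ReactionModel:
    """Minimal positive-feedback model: attach, detach, recruit."""
    if params is None:
        params = load_parameters("cdc42_simplified")
    _require(params, ["D_cyt", "D_mem", "k_on", "k_off", "k_fb", "n_total"],
             "simplified_cdc42_model")
    species = [
        SpeciesSpec("Cdc42c", "cytoplasm", D_cyt=params["D_cyt"]),
        SpeciesSpec("Cdc42m", "membrane", D_mem=params["D_mem"]),
    ]
    R = ReactionSpec
    reactions = [
        R("attach", (("Cdc42c", 1),), (("Cdc42m", 1),), params["k_on"],
          field=FIELD_ATTACH_CORRECTION),
        R("detach", (("Cdc42m", 1),), (("Cdc42c", 1),), params["k_off"]),
        R("recruit", (("Cdc42m", 1), ("Cdc42c", 1)), (("Cdc42m", 2),),
          params["k_fb"]),
    ]
    return ReactionModel(
        name="cdc42_simplified",
        species=species,
        reactions=reactions,
        moieties={"Cdc42": {"Cdc42c", "Cdc42m"}},
        parameters=dict(params),
        initial_totals={"Cdc42c": int(params["n_total"])},
        initial_totals_polarized=_polarized_split(
            params, [("Cdc42m", "Cdc42c", "n_total", 0.5)]),
    )


def polarisome_model(params: dict | None = None,
                     cdc42_mode: str = "frozen_field") -> ReactionModel:
    """Bni1/Spa2/actin polarisome module.

    In ``frozen_field`` mode the Bni1 recruitment propensity is driven by a
    static per-voxel active-Cdc42 field (set through
    :func:`attach_standard_fields` or ``model.fields``); in ``dynamic`` mode
    the caller is expected to couple the module to a live Cdc42Tm species via
    :func:`coupled_model`.
    """
    if params is None:
        params = load_parameters("polarisome")
    _require(params, ["D_cyt", "D_mem", "B_on", "B_spont", "B_fb", "B_off",
                      "A_nuc", "A_dec", "S_on", "S_off", "n_bni1", "n_spa2"],
             "polarisome_model")
    if cdc42_mode not in ("frozen_field", "dynamic"):
        raise ValueError(f"unknown cdc42_mode {cdc42_mode!r}")
    Dc, Dm = params["D_cyt"], params["D_mem"]
    species = [
        SpeciesSpec("Bni1c", "cytoplasm", D_cyt=Dc),
        SpeciesSpec("Bni1m", "membrane", D_mem=Dm),
        SpeciesSpec("Spa2c", "cytoplasm", D_cyt=Dc),
        SpeciesSpec("Spa2m", "membrane", D_mem=Dm),
        SpeciesSpec("Actin", "membrane", D_mem=0.0),
    ]
    R = ReactionSpec
    reactions = [
        # weak spontaneous membrane attachment: lets the polarisome nucleate
        # anywhere, not only where the Cdc42 drive acts
        R("bni1_attach_basal", (("Bni1c", 1),), (("Bni1m", 1),),
          params["B_spont"], field=FIELD_ATTACH_CORRECTION),
        R("bni1_release", (("Bni1m", 1),), (("Bni1c", 1),), params["B_off"]),
        R("spa2_recruits_bni1", (("Spa2m", 1), ("Bni1c", 1)),
          (("Spa2m", 1), ("Bni1m", 1)), params["B_fb"]),
        R("actin_nucleate", (("Bni1m", 1),), (("Bni1m", 1), ("Actin", 1)),
          params["A_nuc"]),
        R("actin_decay", (("Actin", 1),), (), params["A_dec"]),
        R("spa2_delivery", (("Actin", 1), ("Spa2c", 1)),
          (("Actin", 1), ("Spa2m", 1)), params["S_on"]),
        R("spa2_release", (("Spa2m", 1),), (("Spa2c", 1),), params["S_off"]),
    ]
    if cdc42_mode == "frozen_field":
        # first-order recruitment whose per-voxel rate is B_on * f_i / A_i,
        # f_i the frozen active-Cdc42 copy number of voxel i
        reactions.insert(0, R("bni1_recruit_frozen", (("Bni1c", 1),),
                              (("Bni1m", 1),), params["B_on"],
                              field=FIELD_FROZEN_CDC42))
    return ReactionModel(
        name=f"polarisome_{cdc42_mode}",
        species=species,
        reactions=reactions,
        moieties={"Bni1": {"Bni1c", "Bni1m"}, "Spa2": {"Spa2c", "Spa2m"}},
        parameters=dict(params),
        initial_totals={"Bni1c": int(params["n_bni1"]),
                        "Spa2c": int(params["n_spa2"])},
        initial_totals_polarized=_polarized_split(
            params, [("Bni1m", "Bni1c", "n_bni1", 0.5),
                     ("Spa2m", "Spa2c", "n_spa2", 0.5)]),
    )


def coupled_model(cdc42_params: dict | None = None,
                  polarisome_params: dict | None = None) -> ReactionModel:
    """Mechanistic Cdc42 network coupled to the polarisome module.

    Active Cdc42 recruits Bni1 at rate ``B_on`` and actin cables deliver
    cytosolic Cdc42-GDP to the membrane at rate ``V_on`` (vesicle transport).
    Species names are distinct by construction; a name collision would be a
    programming error and raises.
    """
    mech = mechanistic_cdc42_model(cdc42_params)
    pol = polarisome_model(polarisome_params, cdc42_mode="dynamic")
    collisions = set(mech.species_names) & set(pol.species_names)
    if collisions:
        raise ValueError(f"species name collision when coupling: {sorted(collisions)}")
    params = {**{f"cdc42.{k}": v for k, v in mech.parameters.items()},
              **{f"polarisome.{k}": v for k, v in pol.parameters.items()}}
    V_on = pol.parameters.get("V_on", 0.0)
    R = ReactionSpec
    coupling = [
        R("bni1_recruit_by_cdc42", (("Cdc42Tm", 1), ("Bni1c", 1)),
          (("Cdc42Tm", 1), ("Bni1m", 1)), pol.parameters["B_on"]),
        R("vesicle_delivery", (("Actin", 1), ("Cdc42Dc", 1)),
          (("Actin", 1), ("Cdc42Dm", 1)), V_on),
    ]
    return ReactionModel(
        name="cdc42_polarisome_coupled",
        species=mech.species + pol.species,
        reactions=mech.reactions + pol.reactions + coupling,
        moieties={**mech.moieties, **pol.moieties},
        parameters=params,
        initial_totals={**mech.initial_totals, **pol.initial_totals},
        initial_totals_polarized={**mech.initial_totals_polarized,
                                  **pol.initial_totals_polarized},
    )


def attach_standard_fields(model: ReactionModel, mesh: Mesh,
                           frozen_cdc42: np.ndarray | None = None) -> None:
    """Fill the per-voxel fields a model declares, for a concrete mesh.

    * ``membrane_volume_correction`` rescales first-order membrane-attachment
      propensities by the inverse volume fraction of membrane voxels, so the
      effective well-mixed attachment rate per cytosolic molecule equals the
      nominal rate constant on any mesh (this keeps the k_on/(k_on+k_off)
      stationary balance geometry-independent).
    * ``frozen_cdc42_per_area`` is the static active-Cdc42 drive divided by
      the voxel membrane area (frozen-field polarisome mode).
    """
    needed = {r.field for r in model.reactions if r.field}
    if FIELD_ATTACH_CORRECTION in needed:
        frac = mesh.voxel_volumes[mesh.on_membrane].sum() / mesh.volume
        model.fields[FIELD_ATTACH_CORRECTION] = np.where(
            mesh.on_membrane, 1.0 / frac, 0.0
        )
    if FIELD_FROZEN_CDC42 in needed:
        if frozen_cdc42 is None:
            raise ValueError(
                "model uses a frozen Cdc42 field; pass frozen_cdc42 (per-voxel "
                "active Cdc42 copy numbers)"
            )
        frozen_cdc42 = np.asarray(frozen_cdc42, dtype=float)
        if frozen_cdc42.shape != (mesh.K,):
            raise ValueError(
                f"frozen Cdc42 field has shape {frozen_cdc42.shape}, "
                f"expected ({mesh.K},)"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            per_area = np.where(mesh.voxel_areas > 0,
                                frozen_cdc42 / np.where(mesh.voxel_areas > 0,
                                                        mesh.voxel_areas, 1.0),
                                0.0)
        model.fields[FIELD_FROZEN_CDC42] = per_area


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitialConditionSpec:
    """How to place the initial molecules.

    mode 'polarized' concentrates every membrane species inside a geodesic cap
    around the tip (cytosolic species are scattered proportional to voxel
    volume); 'random' scatters everything; 'uniform_membrane' scatters
    membrane species over the whole membrane proportional to area.
    """

    mode: str = "polarized"
    cap_radius: float = 1.2       # um, geodesic; see methods note
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("polarized", "random", "uniform_membrane"):
            raise ValueError(f"unknown IC mode {self.mode!r}")
        if not 0.0 <= self.rotation_deg < 360.0:
            raise ValueError("rotation must lie in [0, 360)")


def base_totals(model: ReactionModel, ic_mode: str) -> dict:
    """The species totals an IC mode starts from (polarized split or default)."""
    if ic_mode == "polarized" and model.initial_totals_polarized:
        return dict(model.initial_totals_polarized)
    return dict(model.initial_totals)


def _multinomial_exact(rng, total: int, weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("no admissible voxels for placement")
    return rng.multinomial(int(total), w / w.sum())


def _rotate_counts_about_axis(mesh: Mesh, counts: np.ndarray,
                              angle_deg: float, membrane: bool) -> np.ndarray:
    """Remap a per-voxel count field rotated about the x-axis (nearest vertex)."""
    if angle_deg == 0.0:
        return counts
    ang = np.deg2rad(angle_deg)
    c, s = np.cos(ang), np.sin(ang)
    v = mesh.vertices
    rot = v.copy()
    rot[:, 1] = c * v[:, 1] - s * v[:, 2]
    rot[:, 2] = s * v[:, 1] + c * v[:, 2]
    from scipy.spatial import cKDTree

    if membrane:
        pool = np.flatnonzero(mesh.on_membrane)
    else:
        pool = np.arange(mesh.K)
    tree = cKDTree(v[pool])
    out = np.zeros_like(counts)
    src = np.flatnonzero(counts)
    for i in src:
        _, j = tree.query(rot[i])
        out[pool[j]] += counts[i]
    return out


def build_initial_state(mesh: Mesh, tip_frame: TipFrame, model: ReactionModel,
                        ic: InitialConditionSpec,
                        totals: dict | None = None) -> np.ndarray:
    """Construct a (K, S) integer state realizing the IC specification.

    ``totals`` overrides the model's defaults (species name -> copies); totals
    are placed exactly.  Polarized mode defaults to the model's polarized
    split (membrane species concentrated in the tip cap).
    """
    if totals is None:
        totals = base_totals(model, ic.mode)
    totals = dict(totals)
    rng = np.random.default_rng(np.random.SeedSequence([int(ic.seed), 0x1C5EED]))
    K = mesh.K
    x = np.zeros((K, model.S), dtype=np.int64)
    mem = mesh.on_membrane
    A = mesh.voxel_areas
    V = mesh.voxel_volumes

    cap_weights = None
    if ic.mode == "polarized":
        dist = surface_geodesic_distances(mesh, tip_frame.tip_vertex)
        in_cap = mem & (dist <= ic.cap_radius)
        cap_area = A[in_cap].sum()
        if cap_area > 0.5 * mesh.area:
            raise ValueError(
                f"cap radius {ic.cap_radius} um covers "
                f"{100 * cap_area / mesh.area:.0f}% of the membrane (> 50%)"
            )
        if not np.any(in_cap):
            raise ValueError("cap radius too small: no membrane voxel selected")
        cap_weights = np.where(in_cap, A, 0.0)

    for name, total in totals.items():
        s = model.species_index(name)
        comp = model.species[s].compartment
        if total == 0:
            continue
        if comp == "cytoplasm":
            x[:, s] = _multinomial_exact(rng, total, V)
        elif ic.mode == "polarized":
            placed = _multinomial_exact(rng, total, cap_weights)
            x[:, s] = _rotate_counts_about_axis(mesh, placed, ic.rotation_deg,
                                                membrane=True)
        else:
            x[:, s] = _multinomial_exact(rng, total, np.where(mem, A, 0.0))
    return x


# ---------------------------------------------------------------------------
# Copy-number scaling between geometries
# ---------------------------------------------------------------------------

def scale_counts(base_totals: dict, model: ReactionModel, mesh: Mesh,
                 mode: str, base_mesh: Mesh) -> dict:
    """Scale copy-number totals from a base geometry to another.

    'constant_molecules' keeps totals unchanged; 'constant_density' scales
    cytosolic totals by the volume ratio and membrane totals by the area
    ratio, rounding to the nearest integer.
    """
    if mode == "constant_molecules":
        return {k: int(v) for k, v in base_totals.items()}
    if mode != "constant_density":
        raise ValueError(f"unknown scaling mode {mode!r}")
    v_ratio = mesh.volume / base_mesh.volume
    a_ratio = mesh.area / base_mesh.area
    out = {}
    for name, total in base_totals.items():
        comp = model.spec_of(name).compartment
        ratio = v_ratio if comp == "cytoplasm" else a_ratio
        out[name] = int(np.rint(total * ratio))
    return out
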