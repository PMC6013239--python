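"""Model builders, initial conditions, copy-number scaling, closed forms."""

import numpy as np
import pytest
import scipy.stats as st

from tipdrift.engine import compile_system, conservation_check, nsm_run
from tipdrift.geometry import (GeometrySpec, build_geometry,
                               surface_geodesic_distances)
from tipdrift.jumps import assemble_jump_matrix
from tipdrift.models import (
    FIELD_FROZEN_CDC42,
    InitialConditionSpec,
    attach_standard_fields,
    base_totals,
    build_initial_state,
    coupled_model,
    load_parameters,
    mechanistic_cdc42_model,
    polarisome_model,
    scale_counts,
    simplified_cdc42_model,
)


class TestBuilders:
    def test_mechanistic_structure(self):
        m = mechanistic_cdc42_model()
        assert {"Cdc42Dc", "Cdc42Dm", "Cdc42Tm", "GEFc", "GEFm",
                "Cla4c", "Cla4m"} <= set(m.species_names)
        assert set(m.moieties) == {"Cdc42", "GEF", "Cla4"}
        # every reaction is membrane-restricted
        assert all(r.region == "membrane_only" for r in m.reactions)

    def test_missing_parameter_named(self):
        params = load_parameters("cdc42_mechanistic")
        del params["k_hyd"]
        with pytest.raises(KeyError, match="k_hyd"):
            mechanistic_cdc42_model(params)

    def test_simplified_three_reactions_two_species(self):
        m = simplified_cdc42_model()
        assert m.S == 2
        assert m.M == 3
        assert m.moieties == {"Cdc42": {"Cdc42c", "Cdc42m"}}

    def test_polarisome_frozen_field_modes(self):
        frozen = polarisome_model(cdc42_mode="frozen_field")
        assert any(r.field == FIELD_FROZEN_CDC42 for r in frozen.reactions)
        dynamic = polarisome_model(cdc42_mode="dynamic")
        assert not any(r.field == FIELD_FROZEN_CDC42 for r in dynamic.reactions)
        with pytest.raises(ValueError):
            polarisome_model(cdc42_mode="fixed")

    def test_coupled_union_preserves_moieties(self):
        m = coupled_model()
        assert {"Cdc42", "GEF", "Cla4", "Bni1", "Spa2"} == set(m.moieties)
        names = [r.name for r in m.reactions]
        assert "bni1_recruit_by_cdc42" in names
        assert "vesicle_delivery" in names

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError, match="bogus"):
            load_parameters("cdc42_simplified", {"bogus": 1.0})


class TestFrozenField:
    def test_zero_field_silences_recruitment(self, projection_mesh):
        """With B_spont = 0, a zero Cdc42 field drives no Bni1 recruitment."""
        mesh, frame = projection_mesh
        model = polarisome_model(load_parameters("polarisome",
                                                 {"B_spont": 0.0}),
                                 cdc42_mode="frozen_field")
        attach_standard_fields(model, mesh, frozen_cdc42=np.zeros(mesh.K))
        jm = assemble_jump_matrix(mesh, model.species)
        system = compile_system(model, mesh, jm)
        ic = InitialConditionSpec(mode="random", seed=3)
        x0 = build_initial_state(mesh, frame, model, ic)
        # only Bni1c/Spa2c start occupied; no drive, no Spa2m-mediated path
        x0[:, model.species_index("Spa2m")] = 0
        x0[:, model.species_index("Bni1m")] = 0
        tr = nsm_run(system, x0, 50.0, np.linspace(0, 50, 11), seed=1)
        assert tr.totals("Bni1m").sum() == 0

    def test_field_shape_mismatch(self, projection_mesh):
        mesh, _ = projection_mesh
        model = polarisome_model(cdc42_mode="frozen_field")
        with pytest.raises(ValueError, match="shape"):
            attach_standard_fields(model, mesh, frozen_cdc42=np.zeros(3))


class TestInitialConditions:
    def test_polarized_cap_at_tip(self, projection_mesh):
        mesh, frame = projection_mesh
        model = mechanistic_cdc42_model()
        ic = InitialConditionSpec(mode="polarized", cap_radius=1.2, seed=0)
        x = build_initial_state(mesh, frame, model, ic)
        s = model.species_index("Cdc42Tm")
        dist = surface_geodesic_distances(mesh, frame.tip_vertex)
        occupied = np.flatnonzero(x[:, s])
        assert np.all(dist[occupied] <= 1.2 + 1e-9)
        from tipdrift.analysis import cap_center
        cap = cap_center(x, "Cdc42Tm", model.species_names, mesh, frame)
        assert cap.theta_deg == pytest.approx(90.0, abs=8.0)
        assert cap.phi_deg == pytest.approx(180.0, abs=8.0)

    def test_totals_exact(self, sphere_mesh):
        mesh, frame = sphere_mesh
        model = mechanistic_cdc42_model()
        for mode in ("polarized", "random", "uniform_membrane"):
            ic = InitialConditionSpec(mode=mode, seed=5)
            x = build_initial_state(mesh, frame, model, ic)
            want = base_totals(model, mode)
            for name, total in want.items():
                assert x[:, model.species_index(name)].sum() == total

    def test_seed_reproducibility(self, sphere_mesh):
        mesh, frame = sphere_mesh
        model = simplified_cdc42_model()
        ic = InitialConditionSpec(mode="random", seed=11)
        x1 = build_initial_state(mesh, frame, model, ic)
        x2 = build_initial_state(mesh, frame, model, ic)
        assert np.array_equal(x1, x2)

    def test_oversized_cap_rejected(self, sphere_mesh):
        mesh, frame = sphere_mesh
        model = simplified_cdc42_model()
        ic = InitialConditionSpec(mode="polarized", cap_radius=5.0, seed=0)
        with pytest.raises(ValueError, match="50%"):
            build_initial_state(mesh, frame, model, ic)

    def test_membrane_species_only_on_membrane(self, projection_mesh):
        mesh, frame = projection_mesh
        model = mechanistic_cdc42_model()
        ic = InitialConditionSpec(mode="uniform_membrane", seed=2)
        x = build_initial_state(mesh, frame, model, ic)
        for sp in model.species:
            if sp.compartment == "membrane":
                s = model.species_index(sp.name)
                assert x[~mesh.on_membrane, s].sum() == 0


class TestScaleCounts:
    def test_same_mesh_identity(self, sphere_mesh):
        mesh, _ = sphere_mesh
        model = mechanistic_cdc42_model()
        base = {"Cdc42Dc": 250, "GEFc": 60}
        for mode in ("constant_molecules", "constant_density"):
            out = scale_counts(base, model, mesh, mode, mesh)
            assert out == base

    def test_volume_and_area_ratios(self):
        model = mechanistic_cdc42_model()
        base_mesh, _ = build_geometry(GeometrySpec("sphere", 2.0,
                                                   target_edge_length=0.5))
        big_mesh, _ = build_geometry(GeometrySpec("sphere", 4.0,
                                                  target_edge_length=1.0))
        base = {"Cdc42Dc": 1000, "Cdc42Tm": 400}
        out = scale_counts(base, model, big_mesh, "constant_density", base_mesh)
        v_ratio = big_mesh.volume / base_mesh.volume
        a_ratio = big_mesh.area / base_mesh.area
        # discretized spheres: ratios approximate the analytic 8x and 4x
        assert out["Cdc42Dc"] == int(np.rint(1000 * v_ratio))
        assert out["Cdc42Tm"] == int(np.rint(400 * a_ratio))
        assert v_ratio == pytest.approx(8.0, rel=0.05)
        assert a_ratio == pytest.approx(4.0, rel=0.05)
        unchanged = scale_counts(base, model, big_mesh, "constant_molecules",
                                 base_mesh)
        assert unchanged == base


class TestSimplifiedClosedForm:
    def test_membrane_fraction_without_feedback(self, projection_mesh):
        """k_fb = 0: stationary membrane fraction is k_on/(k_on+k_off),
        independent of the geometry (linear two-state balance)."""
        mesh, frame = projection_mesh
        params = load_parameters("cdc42_simplified",
                                 {"k_fb": 0.0, "n_total": 400})
        model = simplified_cdc42_model(params)
        attach_standard_fields(model, mesh)
        jm = assemble_jump_matrix(mesh, model.species)
        system = compile_system(model, mesh, jm)
        ic = InitialConditionSpec(mode="random", seed=1)
        x0 = build_initial_state(mesh, frame, model, ic)
        k_on, k_off = params["k_on"], params["k_off"]
        p = k_on / (k_on + k_off)
        # sample well past the relaxation time 1/(k_on+k_off)
        times = np.linspace(60.0, 400.0, 35)
        fracs = []
        for seed in (0, 1, 2):
            tr = nsm_run(system, x0, times[-1], times, seed=seed)
            fracs.append(tr.totals("Cdc42m").mean() / 400.0)
        mean_frac = np.mean(fracs)
        # 3 sigma of a binomial with the effective number of sampled molecules
        n_eff = 400 * 3 * len(times) / 8.0  # correlated samples, conservative
        sigma = np.sqrt(p * (1 - p) / n_eff)
        assert abs(mean_frac - p) < 3 * sigma

    def test_conservation_in_simulation(self, sphere_mesh):
        mesh, frame = sphere_mesh
        model = simplified_cdc42_model()
        attach_standard_fields(model, mesh)
        jm = assemble_jump_matrix(mesh, model.species)
        system = compile_system(model, mesh, jm)
        x0 = build_initial_state(mesh, frame, model,
                                 InitialConditionSpec(mode="random", seed=0))
        tr = nsm_run(system, x0, 50.0, np.linspace(0, 50, 26), seed=3)
        rep = conservation_check(tr, model)
        assert rep["Cdc42"]["ok"]


class TestMeanFieldLimit:
    def test_totals_track_deterministic_ode(self):
        """At high copy numbers the well-mixed stochastic model's species
        means follow the mass-action ODE (the sampler adds no bias)."""
        from scipy.integrate import solve_ivp
        from tipdrift.engine import single_voxel_system

        params = load_parameters("cdc42_mechanistic")
        scale = 20
        params = {**params, "n_cdc42": params["n_cdc42"] * scale,
                  "n_gef": params["n_gef"] * scale,
                  "n_cla4": params["n_cla4"] * scale}
        model = mechanistic_cdc42_model(params)
        volume, area = 33.5, 50.3  # r = 2 sphere
        # the attachment correction field is 1 in a well-mixed single voxel
        model.fields["membrane_volume_correction"] = np.ones(1)
        system = single_voxel_system(model, volume, area)

        def rhs(_, y):
            dy = np.zeros_like(y)
            for r in range(system.r_rate.shape[0]):
                k = system.r_rate[r] * system.r_scale[r, 0]
                if system.r_order[r] == 0:
                    a = k
                elif system.r_order[r] == 1:
                    a = k * y[system.r_s1[r]]
                else:
                    s1, s2 = system.r_s1[r], system.r_s2[r]
                    a = k * (y[s1] * (y[s1] - 1) if s1 == s2 else y[s1] * y[s2])
                for l in range(system.st_n[r]):
                    dy[system.st_species[r, l]] += a * system.st_delta[r, l]
            return dy

        x0 = np.zeros((1, model.S), dtype=np.int64)
        for name, n in model.initial_totals.items():
            x0[0, model.species_index(name)] = n
        sol = solve_ivp(rhs, (0.0, 150.0), x0[0].astype(float),
                        t_eval=[150.0], rtol=1e-8, atol=1e-8)
        ode_final = sol.y[:, -1]
        means = np.zeros(model.S)
        n_rep = 4
        for seed in range(n_rep):
            tr = nsm_run(system, x0, 150.0, np.array([150.0]), seed=seed)
            means += tr.counts[0, 0] / n_rep
        for s in range(model.S):
            if ode_final[s] > 50:  # relative comparison meaningful
                assert abs(means[s] - ode_final[s]) / ode_final[s] < 0.05
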