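"""Sampler exactness: master-equation, SSA cross-validation, stationarity."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats as st
from scipy.sparse.linalg import expm_multiply

from tipdrift.engine import (
    SimulationError,
    compile_system,
    conservation_check,
    direct_ssa_run,
    manual_system,
    nsm_run,
    single_voxel_system,
)
from tipdrift.jumps import assemble_jump_matrix
from tipdrift.model import ReactionModel, ReactionSpec, SpeciesSpec
from tipdrift.trajectory import Trajectory


def _chain_master_equation_dist(volumes, d, birth, death, t, cap=8):
    """Joint distribution of (x1, x2, x3) at time t from the empty state,
    by direct matrix exponential of the truncated generator."""
    K = len(volumes)
    states = [(i, j, k) for i in range(cap) for j in range(cap)
              for k in range(cap)]
    index = {s: n for n, s in enumerate(states)}
    rows, cols, vals = [], [], []

    def add(frm, to, rate):
        if rate <= 0:
            return
        rows.append(index[to])
        cols.append(index[frm])
        vals.append(rate)
        rows.append(index[frm])
        cols.append(index[frm])
        vals.append(-rate)

    for s in states:
        for i in range(K):
            if s[i] + 1 < cap:
                to = list(s)
                to[i] += 1
                add(s, tuple(to), birth * volumes[i])
            if s[i] > 0:
                to = list(s)
                to[i] -= 1
                add(s, tuple(to), death * s[i])
                for j in range(K):
                    if d[i, j] > 0 and s[j] + 1 < cap:
                        to = list(s)
                        to[i] -= 1
                        to[j] += 1
                        add(s, tuple(to), d[i, j] * s[i])
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(len(states), len(states)))
    p0 = np.zeros(len(states))
    p0[index[(0, 0, 0)]] = 1.0
    p = expm_multiply(Q * t, p0)
    return states, np.maximum(p, 0.0)


class TestMasterEquationOracle:
    def test_nsm_matches_matrix_exponential(self, decay_diffusion_chain):
        """Joint state distribution at t = 8 s vs the exact master equation."""
        model, volumes, mats = decay_diffusion_chain
        system = manual_system(model, volumes, [0, 0, 0],
                               [True, True, True], mats)
        d = mats["X"].toarray()
        states, p = _chain_master_equation_dist(volumes, d, birth=0.05,
                                                death=0.3, t=8.0)
        n_real = 10_000
        counts = {}
        x0 = np.zeros((3, 1), dtype=np.int64)
        for seed in range(n_real):
            tr = nsm_run(system, x0, 8.0, np.array([8.0]), seed=seed)
            s = tuple(int(v) for v in tr.counts[0, :, 0])
            counts[s] = counts.get(s, 0) + 1
        # chi^2 with expected >= 5, tail lumped
        expected, observed = [], []
        tail_e = tail_o = 0.0
        for sidx, state in enumerate(states):
            e = p[sidx] * n_real
            o = counts.get(state, 0)
            if e >= 5:
                expected.append(e)
                observed.append(o)
            else:
                tail_e += e
                tail_o += o
        expected.append(tail_e)
        observed.append(tail_o)
        expected = np.array(expected) * (n_real / np.sum(expected))
        chi2, pval = st.chisquare(observed, expected)
        assert pval > 0.01

    def test_direct_ssa_agrees_with_nsm(self, decay_diffusion_chain):
        """Two-sample comparison of the total-count marginal at t = 6 s."""
        model, volumes, mats = decay_diffusion_chain
        system = manual_system(model, volumes, [0, 0, 0],
                               [True, True, True], mats)
        x0 = np.zeros((3, 1), dtype=np.int64)
        totals_nsm = []
        totals_dssa = []
        for seed in range(1500):
            tr = nsm_run(system, x0, 6.0, np.array([6.0]), seed=seed)
            totals_nsm.append(int(tr.counts[0].sum()))
        for seed in range(1500):
            tr = direct_ssa_run(system, x0, 6.0, np.array([6.0]), seed=seed + 7)
            totals_dssa.append(int(tr.counts[0].sum()))
        pval = st.ks_2samp(totals_nsm, totals_dssa).pvalue
        assert pval > 0.01


class TestElementaryBehaviour:
    def test_frozen_state_without_dynamics(self, single_tet_mesh):
        model = ReactionModel(name="inert",
                              species=[SpeciesSpec("X", "cytoplasm")],
                              reactions=[])
        jm = assemble_jump_matrix(single_tet_mesh, model.species)
        system = compile_system(model, single_tet_mesh, jm)
        x0 = np.array([[3], [1], [0], [2]])
        tr = nsm_run(system, x0, 50.0, np.linspace(1, 50, 20), seed=0)
        assert np.all(tr.counts == x0[None, :, :])

    def test_zero_propensity_direct_ssa_returns(self, single_tet_mesh):
        model = ReactionModel(name="inert",
                              species=[SpeciesSpec("X", "cytoplasm")],
                              reactions=[])
        jm = assemble_jump_matrix(single_tet_mesh, model.species)
        system = compile_system(model, single_tet_mesh, jm)
        tr = direct_ssa_run(system, np.zeros((4, 1), dtype=int), 5.0, seed=1)
        assert tr.event_count == 0
        assert tr.times[-1] == 5.0

    def test_two_voxel_occupancy_proportional_to_volume(self):
        model = ReactionModel(name="d",
                              species=[SpeciesSpec("X", "cytoplasm", D_cyt=1.0)],
                              reactions=[])
        d = sp.csr_matrix(np.array([[0.0, 3.0], [1.0, 0.0]]))
        system = manual_system(model, [1.0, 3.0], [0, 0], [True, True],
                               {"X": d})
        times = np.linspace(1.0, 10_000.0, 10_000)
        tr = nsm_run(system, np.array([[1], [0]]), times[-1], times, seed=4)
        occ = tr.counts[:, 0, 0].mean()
        p = 0.25
        sigma = np.sqrt(p * (1 - p) / len(times))
        # samples are correlated; allow 3 sigma on an effective n of ~1/10
        assert abs(occ - p) < 3 * sigma * np.sqrt(10)

    def test_exponential_waiting_time(self):
        model = ReactionModel(
            name="decay",
            species=[SpeciesSpec("A", "cytoplasm"), SpeciesSpec("B", "cytoplasm")],
            reactions=[ReactionSpec("dec", (("A", 1),), (("B", 1),), 0.5,
                                    region="everywhere")],
        )
        system = manual_system(model, [1.0], [0.0], [True])
        grid = np.arange(0.005, 30.0, 0.005)
        waits = []
        for seed in range(1500):
            tr = nsm_run(system, np.array([[1, 0]]), 30.0, grid, seed=seed)
            dead = tr.counts[:, 0, 0] == 0
            waits.append(grid[np.argmax(dead)] - 0.0025 if dead.any() else 30.0)
        assert st.kstest(waits, "expon", args=(0, 2.0)).pvalue > 0.01

    def test_single_voxel_nsm_matches_well_mixed_ssa(self,
                                                     membrane_exchange_model):
        system = single_voxel_system(membrane_exchange_model, volume=2.0,
                                     area=1.5)
        x0 = np.array([[40, 0]])
        mem_nsm, mem_ssa = [], []
        for seed in range(300):
            tr = nsm_run(system, x0, 40.0, np.array([40.0]), seed=seed)
            mem_nsm.append(tr.counts[0, 0, 1])
            tr = direct_ssa_run(system, x0, 40.0, np.array([40.0]), seed=seed)
            mem_ssa.append(tr.counts[0, 0, 1])
        m1, m2 = np.mean(mem_nsm), np.mean(mem_ssa)
        se = np.sqrt(np.var(mem_nsm) / 300 + np.var(mem_ssa) / 300)
        assert abs(m1 - m2) < 3 * se
        # closed form: fraction on membrane = k_on/(k_on+k_off) = 2/3
        se1 = np.std(mem_nsm) / np.sqrt(300)
        assert abs(m1 - 40 * 2 / 3) < 3 * se1

    def test_determinism_bitwise(self, membrane_exchange_model, sphere_mesh):
        mesh, _ = sphere_mesh
        jm = assemble_jump_matrix(mesh, membrane_exchange_model.species)
        system = compile_system(membrane_exchange_model, mesh, jm)
        rng = np.random.default_rng(0)
        x0 = np.zeros((mesh.K, 2), dtype=np.int64)
        idx = rng.choice(mesh.K, 50, p=mesh.voxel_volumes / mesh.volume)
        np.add.at(x0[:, 0], idx, 1)
        t1 = nsm_run(system, x0, 5.0, np.linspace(0, 5, 11), seed=123)
        t2 = nsm_run(system, x0, 5.0, np.linspace(0, 5, 11), seed=123)
        assert np.array_equal(t1.counts, t2.counts)
        t3 = nsm_run(system, x0, 5.0, np.linspace(0, 5, 11), seed=124)
        assert not np.array_equal(t1.counts, t3.counts)

    def test_membrane_species_in_interior_rejected(self, sphere_mesh,
                                                   membrane_exchange_model):
        mesh, _ = sphere_mesh
        jm = assemble_jump_matrix(mesh, membrane_exchange_model.species)
        system = compile_system(membrane_exchange_model, mesh, jm)
        x0 = np.zeros((mesh.K, 2), dtype=np.int64)
        interior = np.flatnonzero(~mesh.on_membrane)[0]
        x0[interior, 1] = 1
        with pytest.raises(ValueError, match="membrane"):
            nsm_run(system, x0, 1.0, seed=0)


class TestDiffusionPhysics:
    def test_stationary_occupancy_proportional_to_volume(self, sphere_mesh):
        """Pure cytosolic diffusion: time-averaged occupancy tracks V_i."""
        mesh, _ = sphere_mesh
        model = ReactionModel(name="d",
                              species=[SpeciesSpec("X", "cytoplasm", D_cyt=10.0)],
                              reactions=[])
        jm = assemble_jump_matrix(mesh, model.species)
        system = compile_system(mesh=mesh, model=model, jumps=jm)
        rng = np.random.default_rng(1)
        x0 = np.zeros((mesh.K, 1), dtype=np.int64)
        idx = rng.choice(mesh.K, 200, p=mesh.voxel_volumes / mesh.volume)
        np.add.at(x0[:, 0], idx, 1)
        times = np.linspace(1.0, 100.0, 200)
        tr = nsm_run(system, x0, times[-1], times, seed=2)
        observed = tr.counts[:, :, 0].sum(axis=0).astype(float)
        expected = observed.sum() * mesh.voxel_volumes / mesh.volume
        # coarse chi-square on aggregated bins (sorted by volume, 20 bins)
        order = np.argsort(mesh.voxel_volumes)
        bins = np.array_split(order, 20)
        obs_b = np.array([observed[b].sum() for b in bins])
        exp_b = np.array([expected[b].sum() for b in bins])
        exp_b *= obs_b.sum() / exp_b.sum()
        # correlated samples: rescale to an effective number of sojourns
        scale = obs_b.sum() / 5000.0
        chi2, p = st.chisquare(obs_b / scale, exp_b / scale)
        assert p > 0.01

    def test_membrane_diffusion_stationary_on_area(self, sphere_mesh):
        mesh, _ = sphere_mesh
        model = ReactionModel(name="m",
                              species=[SpeciesSpec("Mm", "membrane", D_mem=0.5)],
                              reactions=[])
        jm = assemble_jump_matrix(mesh, model.species)
        system = compile_system(model, mesh, jm)
        rng = np.random.default_rng(3)
        mem = np.flatnonzero(mesh.on_membrane)
        x0 = np.zeros((mesh.K, 1), dtype=np.int64)
        w = mesh.voxel_areas[mem] / mesh.area
        np.add.at(x0[:, 0], rng.choice(mem, 200, p=w), 1)
        times = np.linspace(1.0, 400.0, 200)
        tr = nsm_run(system, x0, times[-1], times, seed=5)
        observed = tr.counts[:, mem, 0].sum(axis=0).astype(float)
        expected = observed.sum() * mesh.voxel_areas[mem] / mesh.area
        order = np.argsort(mesh.voxel_areas[mem])
        bins = np.array_split(order, 15)
        obs_b = np.array([observed[b].sum() for b in bins])
        exp_b = np.array([expected[b].sum() for b in bins])
        exp_b *= obs_b.sum() / exp_b.sum()
        scale = obs_b.sum() / 5000.0
        chi2, p = st.chisquare(obs_b / scale, exp_b / scale)
        assert p > 0.01

    def test_tracer_msd_short_time(self, sphere_mesh):
        """Mean squared displacement of a central tracer approximates 6 D t."""
        mesh, _ = sphere_mesh
        D = 1.0
        model = ReactionModel(name="tracer",
                              species=[SpeciesSpec("X", "cytoplasm", D_cyt=D)],
                              reactions=[])
        jm = assemble_jump_matrix(mesh, model.species)
        system = compile_system(model, mesh, jm)
        center = int(np.argmin(np.linalg.norm(mesh.vertices, axis=1)))
        x0 = np.zeros((mesh.K, 1), dtype=np.int64)
        x0[center, 0] = 1
        t_obs = 0.15
        sq = []
        for seed in range(2000):
            tr = nsm_run(system, x0, t_obs, np.array([t_obs]), seed=seed)
            pos = mesh.vertices[np.argmax(tr.counts[0, :, 0])]
            sq.append(np.sum((pos - mesh.vertices[center]) ** 2))
        msd = float(np.mean(sq))
        assert msd == pytest.approx(6 * D * t_obs, rel=0.10)


class TestConservation:
    def test_moieties_constant(self, membrane_exchange_model, sphere_mesh):
        mesh, _ = sphere_mesh
        jm = assemble_jump_matrix(mesh, membrane_exchange_model.species)
        system = compile_system(membrane_exchange_model, mesh, jm)
        rng = np.random.default_rng(0)
        x0 = np.zeros((mesh.K, 2), dtype=np.int64)
        idx = rng.choice(mesh.K, 100, p=mesh.voxel_volumes / mesh.volume)
        np.add.at(x0[:, 0], idx, 1)
        tr = nsm_run(system, x0, 20.0, np.linspace(0, 20, 40), seed=9)
        report = conservation_check(tr, membrane_exchange_model)
        assert report["total"]["ok"]
        assert report["total"]["total"] == 100

    def test_corrupted_snapshot_flagged(self, membrane_exchange_model):
        traj = Trajectory(
            times=np.array([0.0, 1.0, 2.0]),
            counts=np.array([[[5, 5]], [[5, 5]], [[4, 5]]]),
            species=["C", "Mm"],
        )
        report = conservation_check(traj, membrane_exchange_model)
        assert not report["total"]["ok"]
        assert report["total"]["first_violation"] == 2
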