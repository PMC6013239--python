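"""Exact spatial stochastic samplers for the reaction-diffusion master equation.

Two samplers draw statistically exact realizations of the RDME Markov process:

* :func:`nsm_run` — the Next Subvolume Method.  Each voxel keeps the time of
  its next event (reaction or outgoing diffusion jump) in an indexed binary
  min-heap; after a reaction only the host voxel's clock is rebuilt, after a
  jump both endpoint voxels'.  The hot loop is compiled with numba.
* :func:`direct_ssa_run` — a deliberately naive Direct-Method SSA that
  recomputes every propensity after every event.  It exists purely as an
  oracle for cross-validating the NSM on small fixtures.

Propensity conventions (per voxel i with dual volume V_i / membrane area A_i):
zeroth order k*V_i (k*A_i for membrane-only reactions); unimolecular k*x;
heterodimeric k*x1*x2/Omega; homodimeric k*x*(x-1)/Omega, where Omega is V_i
for cytosol-cytosol pairs and A_i for membrane-membrane or mixed pairs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import Mesh
from .jumps import JumpMatrix
from .model import ReactionModel
from .trajectory import Trajectory

__all__ = [
    "CompiledSystem",
    "compile_system",
    "single_voxel_system",
    "reaction_propensity",
    "nsm_run",
    "direct_ssa_run",
    "conservation_check",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class CompiledSystem:
    """Flat-array form of (model, mesh, jump matrix) for the samplers."""

    model: ReactionModel
    K: int
    S: int
    mem_mask: np.ndarray      # (K,) bool
    volumes: np.ndarray       # (K,)
    areas: np.ndarray         # (K,)
    # reactions
    r_rate: np.ndarray        # (M,)
    r_order: np.ndarray       # (M,) 0|1|2
    r_s1: np.ndarray          # (M,) first reactant species (-1 none)
    r_s2: np.ndarray          # (M,) second reactant (-1 none; == r_s1 homodimer)
    r_scale: np.ndarray       # (M, K) per-voxel propensity multiplier
    st_species: np.ndarray    # (M, L) species changed
    st_delta: np.ndarray      # (M, L)
    st_n: np.ndarray          # (M,)
    # diffusion, CSR per species with global offsets
    d_indptr: np.ndarray      # (S, K+1)
    d_cols: np.ndarray        # (nnz,)
    d_rates: np.ndarray       # (nnz,)
    out_rate: np.ndarray      # (S, K)
    dep_indptr: np.ndarray = None  # (S+1,) species -> dependent reactions
    dep_r: np.ndarray = None
    mesh_hash: str = ""

    def model_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.r_rate.tobytes())
        h.update(self.st_species.tobytes())
        h.update(self.st_delta.tobytes())
        h.update(self.r_scale.tobytes())
        return h.hexdigest()[:16]

    def validate_state(self, x: np.ndarray) -> None:
        x = np.asarray(x)
        if x.shape != (self.K, self.S):
            raise ValueError(f"state must have shape {(self.K, self.S)}")
        if np.any(x < 0):
            raise ValueError("negative molecule counts")
        names = self.model.species_names
        for s, sp in enumerate(self.model.species):
            if sp.compartment == "membrane" and np.any(x[~self.mem_mask, s] > 0):
                raise ValueError(
                    f"membrane species {names[s]} present in non-membrane voxels"
                )


def compile_system(model: ReactionModel, mesh: Mesh,
                   jumps: JumpMatrix) -> CompiledSystem:
    """Flatten a reaction model on a mesh into sampler-ready arrays."""
    K = mesh.K
    S = model.S
    names = model.species_names
    mem = mesh.on_membrane.astype(bool)
    V, A = mesh.voxel_volumes, mesh.voxel_areas

    M = model.M
    L = max((len(r.net_change()) for r in model.reactions), default=1) or 1
    r_rate = np.zeros(M)
    r_order = np.zeros(M, dtype=np.int64)
    r_s1 = -np.ones(M, dtype=np.int64)
    r_s2 = -np.ones(M, dtype=np.int64)
    r_scale = np.zeros((M, K))
    st_species = np.zeros((M, L), dtype=np.int64)
    st_delta = np.zeros((M, L), dtype=np.int64)
    st_n = np.zeros(M, dtype=np.int64)

    compartment = {s.name: s.compartment for s in model.species}
    for r_idx, rx in enumerate(model.reactions):
        r_rate[r_idx] = rx.rate
        r_order[r_idx] = rx.order
        mask = mem if rx.region == "membrane_only" else np.ones(K, dtype=bool)
        for s, _ in rx.products:
            if compartment[s] == "membrane" and rx.region != "membrane_only":
                raise ValueError(
                    f"reaction {rx.name} can produce membrane species {s} in "
                    "non-membrane voxels; declare it membrane_only"
                )
        if rx.order == 0:
            measure = A if rx.region == "membrane_only" else V
            scale = np.where(mask, measure, 0.0)
        elif rx.order == 1:
            (s1, _), = rx.reactants
            r_s1[r_idx] = names.index(s1)
            scale = mask.astype(float)
        else:
            if len(rx.reactants) == 1:  # homodimer
                (s1, _), = rx.reactants
                r_s1[r_idx] = r_s2[r_idx] = names.index(s1)
                comps = [compartment[s1], compartment[s1]]
            else:
                (s1, _), (s2, _) = rx.reactants
                r_s1[r_idx] = names.index(s1)
                r_s2[r_idx] = names.index(s2)
                comps = [compartment[s1], compartment[s2]]
            if all(c == "cytoplasm" for c in comps):
                omega = V
            else:
                omega = np.where(A > 0, A, np.inf)
            with np.errstate(divide="ignore"):
                scale = np.where(mask & (omega > 0), 1.0 / omega, 0.0)
        if rx.field is not None:
            fld = np.asarray(model.fields[rx.field], dtype=float)
            if fld.shape != (K,):
                raise ValueError(
                    f"field {rx.field!r} has shape {fld.shape}, expected ({K},)"
                )
            scale = scale * fld
        r_scale[r_idx] = scale
        net = rx.net_change()
        st_n[r_idx] = len(net)
        for j, (s, d) in enumerate(net.items()):
            st_species[r_idx, j] = names.index(s)
            st_delta[r_idx, j] = d

    # diffusion CSR, concatenated over species
    indptr = np.zeros((S, K + 1), dtype=np.int64)
    cols_parts = []
    rates_parts = []
    out_rate = np.zeros((S, K))
    offset = 0
    for s, sp in enumerate(model.species):
        mat = jumps.matrices[sp.name].tocsr()
        indptr[s] = mat.indptr + offset
        cols_parts.append(mat.indices.astype(np.int64))
        rates_parts.append(mat.data.astype(float))
        out_rate[s] = np.asarray(mat.sum(axis=1)).ravel()
        offset += mat.nnz
    d_cols = np.concatenate(cols_parts) if cols_parts else np.zeros(0, np.int64)
    d_rates = np.concatenate(rates_parts) if rates_parts else np.zeros(0)

    # species -> reactions whose propensity depends on that species
    dep_lists = [[] for _ in range(S)]
    for r_idx in range(M):
        for s in (r_s1[r_idx], r_s2[r_idx]):
            if s >= 0 and r_idx not in dep_lists[s]:
                dep_lists[s].append(r_idx)
    dep_indptr = np.zeros(S + 1, dtype=np.int64)
    for s in range(S):
        dep_indptr[s + 1] = dep_indptr[s] + len(dep_lists[s])
    dep_r = np.array([r for lst in dep_lists for r in lst] or [0], dtype=np.int64)

    return CompiledSystem(
        model=model, K=K, S=S, mem_mask=mem, volumes=V, areas=A,
        r_rate=r_rate, r_order=r_order, r_s1=r_s1, r_s2=r_s2, r_scale=r_scale,
        st_species=st_species, st_delta=st_delta, st_n=st_n,
        d_indptr=indptr, d_cols=d_cols, d_rates=d_rates, out_rate=out_rate,
        dep_indptr=dep_indptr, dep_r=dep_r,
        mesh_hash=mesh.content_hash(),
    )


def reaction_propensity(state_row, reaction, species: list, volume: float,
                        area: float, on_membrane: bool = True) -> float:
    """Propensity (1/s) of one reaction in one voxel.

    ``state_row`` maps species name to count (or is a sequence ordered like
    ``species``).  Zeroth-order reactions scale with the voxel measure
    (area for membrane-only, volume otherwise); bimolecular reactions divide
    by the volume for cytosol-cytosol pairs and by the area when a membrane
    species is involved.  A membrane-only reaction in a non-membrane voxel
    has propensity exactly zero.
    """
    if reaction.region == "membrane_only" and not on_membrane:
        return 0.0
    if isinstance(state_row, dict):
        count = state_row.__getitem__
    else:
        names = [s.name for s in species]
        count = lambda n: state_row[names.index(n)]
    comp = {s.name: s.compartment for s in species}
    k = reaction.rate
    if reaction.order == 0:
        return k * (area if reaction.region == "membrane_only" else volume)
    if reaction.order == 1:
        (s1, _), = reaction.reactants
        return k * count(s1)
    if len(reaction.reactants) == 1:  # homodimer
        (s1, _), = reaction.reactants
        omega = volume if comp[s1] == "cytoplasm" else area
        x = count(s1)
        return k * x * (x - 1) / omega
    (s1, _), (s2, _) = reaction.reactants
    both_cyt = comp[s1] == "cytoplasm" and comp[s2] == "cytoplasm"
    omega = volume if both_cyt else area
    return k * count(s1) * count(s2) / omega


def manual_system(model: ReactionModel, volumes, areas, mem_mask,
                  matrices: dict | None = None) -> CompiledSystem:
    """Compile a model on hand-specified voxels (fixtures and oracles).

    ``matrices`` maps species name to a (K, K) sparse matrix of jump
    coefficients d_sij; species not listed do not diffuse.
    """
    from scipy.sparse import csr_matrix

    volumes = np.asarray(volumes, dtype=float)
    K = len(volumes)

    class _Stub:
        pass

    stub = _Stub()
    stub.K = K
    stub.voxel_volumes = volumes
    stub.voxel_areas = np.asarray(areas, dtype=float)
    stub.on_membrane = np.asarray(mem_mask, dtype=bool)
    stub.content_hash = lambda: f"manual-{K}"
    mats = {s.name: csr_matrix((K, K)) for s in model.species}
    if matrices:
        for name, m in matrices.items():
            mats[name] = csr_matrix(m)
    jm = JumpMatrix(matrices=mats,
                    clipped_fraction={s.name: 0.0 for s in model.species})
    return compile_system(model, stub, jm)


def single_voxel_system(model: ReactionModel, volume: float,
                        area: float) -> CompiledSystem:
    """A well-mixed (K = 1) system, for oracle comparisons with the SSA."""
    return manual_system(model, [volume], [area], [True])


# ---------------------------------------------------------------------------
# numba NSM core
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sift_up(pos_in_heap, heap, keys, i):
    # plain < comparisons: exact key ties occur with probability zero for
    # continuous clocks, and determinism is fixed by the RNG stream anyway
    while i > 0:
        parent = (i - 1) >> 1
        if keys[heap[i]] < keys[heap[parent]]:
            tmp = heap[i]
            heap[i] = heap[parent]
            heap[parent] = tmp
            pos_in_heap[heap[i]] = i
            pos_in_heap[heap[parent]] = parent
            i = parent
        else:
            break


@njit(cache=True, inline="always")
def _sift_down(pos_in_heap, heap, keys, i, n):
    while True:
        left = 2 * i + 1
        right = left + 1
        smallest = i
        if left < n and keys[heap[left]] < keys[heap[smallest]]:
            smallest = left
        if right < n and keys[heap[right]] < keys[heap[smallest]]:
            smallest = right
        if smallest == i:
            break
        tmp = heap[i]
        heap[i] = heap[smallest]
        heap[smallest] = tmp
        pos_in_heap[heap[i]] = i
        pos_in_heap[heap[smallest]] = smallest
        i = smallest


@njit(cache=True, inline="always")
def _heap_update(pos_in_heap, heap, keys, voxel, n):
    i = pos_in_heap[voxel]
    _sift_up(pos_in_heap, heap, keys, i)
    _sift_down(pos_in_heap, heap, keys, pos_in_heap[voxel], n)


@njit(cache=True, inline="always")
def _voxel_propensity(x, i, r_rate, r_order, r_s1, r_s2, r_scale, out_rate):
    a = 0.0
    M = r_rate.shape[0]
    for r in range(M):
        sc = r_scale[i, r]
        if sc == 0.0:
            continue
        k = r_rate[r]
        if k == 0.0:
            continue
        if r_order[r] == 0:
            a += k * sc
        elif r_order[r] == 1:
            a += k * sc * x[i, r_s1[r]]
        else:
            s1 = r_s1[r]
            s2 = r_s2[r]
            if s1 == s2:
                a += k * sc * x[i, s1] * (x[i, s1] - 1)
            else:
                a += k * sc * x[i, s1] * x[i, s2]
    S = out_rate.shape[0]
    for s in range(S):
        if x[i, s] > 0 and out_rate[i, s] > 0.0:
            a += out_rate[i, s] * x[i, s]
    return a


@njit(cache=True, inline="always")
def _reaction_prop(x, i, r, r_rate, r_order, r_s1, r_s2, r_scale):
    sc = r_scale[i, r]
    if sc == 0.0:
        return 0.0
    k = r_rate[r]
    if k == 0.0:
        return 0.0
    if r_order[r] == 0:
        return k * sc
    if r_order[r] == 1:
        return k * sc * x[i, r_s1[r]]
    s1 = r_s1[r]
    s2 = r_s2[r]
    if s1 == s2:
        return k * sc * x[i, s1] * (x[i, s1] - 1)
    return k * sc * x[i, s1] * x[i, s2]


@njit(cache=True, inline="always")
def _refresh_voxel(x, i, changed_s1, changed_s2, rp, react_prop, diff_prop,
                   r_rate, r_order, r_s1, r_s2, r_scale, out_rate,
                   dep_indptr, dep_r, delta1, delta2):
    """Incrementally update cached propensities of voxel i after species
    changed_s1 (by delta1) and optionally changed_s2 (by delta2) changed."""
    if changed_s1 >= 0:
        diff_prop[i] += out_rate[i, changed_s1] * delta1
        for idx in range(dep_indptr[changed_s1], dep_indptr[changed_s1 + 1]):
            r = dep_r[idx]
            new = _reaction_prop(x, i, r, r_rate, r_order, r_s1, r_s2, r_scale)
            react_prop[i] += new - rp[i, r]
            rp[i, r] = new
    if changed_s2 >= 0 and changed_s2 != changed_s1:
        diff_prop[i] += out_rate[i, changed_s2] * delta2
        for idx in range(dep_indptr[changed_s2], dep_indptr[changed_s2 + 1]):
            r = dep_r[idx]
            new = _reaction_prop(x, i, r, r_rate, r_order, r_s1, r_s2, r_scale)
            react_prop[i] += new - rp[i, r]
            rp[i, r] = new


@njit(cache=True)
def _nsm_core(x, t0, sample_times, out_counts,
              r_rate, r_order, r_s1, r_s2, r_scale,
              st_species, st_delta, st_n,
              d_indptr, d_cols, d_rates, out_rate,
              dep_indptr, dep_r, seed):
    np.random.seed(seed)
    K, S = x.shape
    T = sample_times.shape[0]
    M = r_rate.shape[0]

    rp = np.zeros((K, M))            # cached per-reaction propensities
    react_prop = np.zeros(K)
    diff_prop = np.zeros(K)
    keys = np.empty(K)
    heap = np.empty(K, dtype=np.int64)
    pos_in_heap = np.empty(K, dtype=np.int64)
    for i in range(K):
        tot = 0.0
        for r in range(M):
            p = _reaction_prop(x, i, r, r_rate, r_order, r_s1, r_s2, r_scale)
            rp[i, r] = p
            tot += p
        react_prop[i] = tot
        dsum = 0.0
        for s in range(S):
            if x[i, s] > 0:
                dsum += out_rate[i, s] * x[i, s]
        diff_prop[i] = dsum
        a_i = tot + dsum
        if not np.isfinite(a_i) or a_i < 0.0:
            return -1, i, 0
        keys[i] = t0 + np.random.exponential(1.0 / a_i) if a_i > 0 else 1.0e300
        heap[i] = i
        pos_in_heap[i] = i
    for i in range(K // 2 - 1, -1, -1):
        _sift_down(pos_in_heap, heap, keys, i, K)

    snap = 0
    n_events = 0
    recal = 5_000_000  # periodic full recompute bounds float drift
    while snap < T:
        if n_events >= recal:
            recal += 5_000_000
            for i in range(K):
                tot = 0.0
                for r in range(M):
                    p = _reaction_prop(x, i, r, r_rate, r_order, r_s1, r_s2, r_scale)
                    rp[i, r] = p
                    tot += p
                react_prop[i] = tot
                dsum = 0.0
                for s in range(S):
                    if x[i, s] > 0:
                        dsum += out_rate[i, s] * x[i, s]
                diff_prop[i] = dsum
        top = heap[0]
        t_next = keys[top]
        while snap < T and sample_times[snap] <= t_next:
            for i in range(K):
                for s in range(S):
                    out_counts[snap, i, s] = x[i, s]
            snap += 1
        if snap >= T:
            break
        i = top
        a_i = react_prop[i] + diff_prop[i]
        u = np.random.random() * a_i
        fired = -1
        j_changed = -1
        cs1 = -1
        cs2 = -1
        d1 = 0
        d2 = 0
        if u < react_prop[i]:
            acc = 0.0
            fired = M - 1
            for r in range(M):
                acc += rp[i, r]
                if u < acc:
                    fired = r
                    break
            for l in range(st_n[fired]):
                s = st_species[fired, l]
                x[i, s] += st_delta[fired, l]
                if x[i, s] < 0:
                    return -2, i, fired
                if l == 0:
                    cs1 = s
                    d1 = st_delta[fired, l]
                elif l == 1:
                    cs2 = s
                    d2 = st_delta[fired, l]
                else:
                    # rare >2-species reactions: full refresh below
                    cs1 = -9
            if cs1 == -9:
                tot = 0.0
                for r in range(M):
                    p = _reaction_prop(x, i, r, r_rate, r_order, r_s1, r_s2, r_scale)
                    rp[i, r] = p
                    tot += p
                react_prop[i] = tot
                dsum = 0.0
                for s in range(S):
                    if x[i, s] > 0:
                        dsum += out_rate[i, s] * x[i, s]
                diff_prop[i] = dsum
            else:
                _refresh_voxel(x, i, cs1, cs2, rp, react_prop, diff_prop,
                               r_rate, r_order, r_s1, r_s2, r_scale, out_rate,
                               dep_indptr, dep_r, d1, d2)
        else:
            u -= react_prop[i]
            s_pick = -1
            acc = 0.0
            for s in range(S):
                if x[i, s] > 0:
                    acc += out_rate[i, s] * x[i, s]
                    if u < acc:
                        s_pick = s
                        break
            if s_pick < 0:
                # numerical residue between cached and true totals: redraw
                keys[i] = t_next + (np.random.exponential(1.0 / a_i)
                                    if a_i > 0 else 1.0e300)
                _heap_update(pos_in_heap, heap, keys, i, K)
                continue
            row_lo = d_indptr[s_pick, i]
            row_hi = d_indptr[s_pick, i + 1]
            u2 = np.random.random() * out_rate[i, s_pick]
            acc2 = 0.0
            j_changed = d_cols[row_hi - 1]
            for idx in range(row_lo, row_hi):
                acc2 += d_rates[idx]
                if u2 < acc2:
                    j_changed = d_cols[idx]
                    break
            x[i, s_pick] -= 1
            if x[i, s_pick] < 0:
                return -2, i, -1
            x[j_changed, s_pick] += 1
            _refresh_voxel(x, i, s_pick, -1, rp, react_prop, diff_prop,
                           r_rate, r_order, r_s1, r_s2, r_scale, out_rate,
                           dep_indptr, dep_r, -1, 0)
            if j_changed != i:
                _refresh_voxel(x, j_changed, s_pick, -1, rp, react_prop,
                               diff_prop, r_rate, r_order, r_s1, r_s2, r_scale,
                               out_rate, dep_indptr, dep_r, 1, 0)
        n_events += 1
        a_i = react_prop[i] + diff_prop[i]
        if not np.isfinite(a_i):
            return -1, i, fired
        keys[i] = t_next + (np.random.exponential(1.0 / a_i) if a_i > 0 else 1.0e300)
        _heap_update(pos_in_heap, heap, keys, i, K)
        if j_changed >= 0 and j_changed != i:
            j = j_changed
            a_j = react_prop[j] + diff_prop[j]
            if not np.isfinite(a_j):
                return -1, j, -1
            keys[j] = t_next + (np.random.exponential(1.0 / a_j) if a_j > 0 else 1.0e300)
            _heap_update(pos_in_heap, heap, keys, j, K)
    return 0, 0, n_events


def _seed_for(base_seed: int, realization: int = 0) -> int:
    """Derive an independent 31-bit stream seed from (base seed, index)."""
    ss = np.random.SeedSequence([int(base_seed), int(realization)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def nsm_run(system: CompiledSystem, init: np.ndarray, t_end: float,
            sample_times: np.ndarray | None = None, seed: int = 0,
            t_start: float = 0.0) -> Trajectory:
    """One exact NSM realization, sampled on a fixed time grid.

    Identical (system, init, seed) inputs give bitwise-identical trajectories.
    """
    system.validate_state(init)
    if sample_times is None:
        sample_times = np.linspace(t_start, t_end, 51)
    sample_times = np.asarray(sample_times, dtype=float)
    x = np.array(init, dtype=np.int64, copy=True)
    out = np.zeros((len(sample_times), system.K, system.S), dtype=np.int32)
    # voxel-major copies of the hot per-voxel tables (cache locality)
    r_scale_T = np.ascontiguousarray(system.r_scale.T)
    out_rate_T = np.ascontiguousarray(system.out_rate.T)
    status, where, n_events = _nsm_core(
        x, float(t_start), sample_times, out,
        system.r_rate, system.r_order, system.r_s1, system.r_s2, r_scale_T,
        system.st_species, system.st_delta, system.st_n,
        system.d_indptr, system.d_cols, system.d_rates, out_rate_T,
        system.dep_indptr, system.dep_r,
        _seed_for(seed),
    )
    if status == -1:
        raise SimulationError(f"non-finite propensity in voxel {where}")
    if status == -2:
        raise SimulationError(f"negative count produced in voxel {where}")
    return Trajectory(
        times=sample_times, counts=out, species=system.model.species_names,
        seed=seed, model_name=system.model.name,
        model_hash=system.model_hash(), mesh_hash=system.mesh_hash,
        event_count=int(n_events),
    )


def direct_ssa_run(system: CompiledSystem, init: np.ndarray, t_end: float,
                   sample_times: np.ndarray | None = None, seed: int = 0,
                   max_events: int = 50_000_000) -> Trajectory:
    """Naive Direct-Method SSA (full propensity recompute every event).

    Exists as an independent oracle for the NSM; use on small fixtures only.
    """
    system.validate_state(init)
    if sample_times is None:
        sample_times = np.linspace(0.0, t_end, 51)
    sample_times = np.asarray(sample_times, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD15EA5E]))
    x = np.array(init, dtype=np.int64, copy=True)
    K, S = x.shape
    out = np.zeros((len(sample_times), K, S), dtype=np.int32)
    t = 0.0
    snap = 0
    n_events = 0
    while snap < len(sample_times):
        # full recompute of every (voxel, channel) propensity
        props = []   # (rate, kind, i, payload)
        for i in range(K):
            for r, rx in enumerate(system.model.reactions):
                sc = system.r_scale[r, i]
                k = system.r_rate[r]
                if sc == 0.0 or k == 0.0:
                    continue
                if system.r_order[r] == 0:
                    a = k * sc
                elif system.r_order[r] == 1:
                    a = k * sc * x[i, system.r_s1[r]]
                else:
                    s1, s2 = system.r_s1[r], system.r_s2[r]
                    a = k * sc * (
                        x[i, s1] * (x[i, s1] - 1) if s1 == s2 else x[i, s1] * x[i, s2]
                    )
                if a > 0:
                    props.append((a, 0, i, r))
            for s in range(S):
                if x[i, s] > 0:
                    lo, hi = system.d_indptr[s, i], system.d_indptr[s, i + 1]
                    for idx in range(lo, hi):
                        a = system.d_rates[idx] * x[i, s]
                        if a > 0:
                            props.append((a, 1, i, (s, system.d_cols[idx])))
        a0 = sum(p[0] for p in props)
        if a0 <= 0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / a0)
        while snap < len(sample_times) and sample_times[snap] <= t_next:
            out[snap] = x
            snap += 1
        if snap >= len(sample_times):
            break
        t = t_next
        u = rng.random() * a0
        acc = 0.0
        chosen = props[-1]
        for p in props:
            acc += p[0]
            if u < acc:
                chosen = p
                break
        _, kind, i, payload = chosen
        if kind == 0:
            r = payload
            for l in range(system.st_n[r]):
                x[i, system.st_species[r, l]] += system.st_delta[r, l]
        else:
            s, j = payload
            x[i, s] -= 1
            x[j, s] += 1
        if np.any(x < 0):
            raise SimulationError(f"negative count after event at t={t}")
        n_events += 1
        if n_events > max_events:
            raise SimulationError("direct SSA exceeded max_events")
    return Trajectory(
        times=sample_times, counts=out, species=system.model.species_names,
        seed=seed, model_name=system.model.name,
        model_hash=system.model_hash(), mesh_hash=system.mesh_hash,
        event_count=n_events,
    )


def conservation_check(traj: Trajectory, model: ReactionModel) -> dict:
    """Verify that every declared moiety total is constant over the trajectory.

    Returns a report dict: {moiety: {"ok": bool, "total": int,
    "first_violation": time index or None}}.
    """
    mat = model.moiety_matrix()
    totals = traj.counts.sum(axis=1)  # (T, S)
    report = {}
    for k, name in enumerate(model.moieties):
        series = totals @ mat[k]
        ok = bool(np.all(series == series[0]))
        first = None if ok else int(np.argmax(series != series[0]))
        report[name] = {"ok": ok, "total": int(series[0]), "first_violation": first}
    return report
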