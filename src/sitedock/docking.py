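"""Flexible-ligand docking by conformational space annealing (CSA).

The protein is held rigid; the ligand pose is parameterized by a rigid
translation, an orientation quaternion, and one dihedral offset per
rotatable torsion, all applied to a reference conformation taken from the
template poses.  A pool of 100 conformations seeded from the template
ligand poses is evolved by crossover/mutation trials, each locally
minimized, with a distance cutoff d_cut annealed from half the initial
pool diameter down to 1 A so the search focuses on progressively narrower
low-energy regions while preserving pool diversity.  The final answer is
the lowest-energy pose of the largest cluster, not the global minimum:
a basin populated by many pool members is better evidence of a binding
mode than a single deep outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .structio import LigandTopology
from .superpose import kabsch

__all__ = [
    "LigandPose",
    "CsaState",
    "PoseCluster",
    "CountingEnergy",
    "init_pool",
    "local_minimize",
    "pose_distance",
    "csa_run",
    "select_representative",
    "CsaConfig",
]

POOL_SIZE = 100
CLUSTER_RADIUS = 2.0  # A, single-linkage pose clustering


@dataclass
class CsaConfig:
    """Tunable CSA knobs; defaults are desk-scale and deliberately modest."""

    pool_size: int = POOL_SIZE
    sigma_translation: float = 1.0          # A
    sigma_rotation: float = np.deg2rad(15)  # rad
    sigma_torsion: float = np.deg2rad(30)   # rad
    minimize_evals: int = 60                # energy calls per local search
    trials_per_round: int = 8
    d_cut_final: float = 1.0                # A
    stall_rounds: int = 5
    cluster_radius: float = CLUSTER_RADIUS


@dataclass
class LigandPose:
    """A ligand conformation: rigid placement + torsion offsets.

    Cartesian coordinates are regenerated deterministically from the
    internal variables and the shared reference conformation: torsion
    offsets are applied to the reference, the result re-centered, rotated
    by the quaternion and moved to ``translation`` (the pose centroid).
    """

    topology: LigandTopology
    ref_coords: np.ndarray
    translation: np.ndarray
    quaternion: np.ndarray  # (x, y, z, w), scipy convention, unit norm
    torsions: np.ndarray
    energy: float | None = None
    _cartesian: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        q = np.asarray(self.quaternion, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            q = q / n
        self.quaternion = q
        self.torsions = np.atleast_1d(np.asarray(self.torsions, dtype=float))

    @property
    def cartesian(self) -> np.ndarray:
        if self._cartesian is None:
            self._cartesian = self._build_cartesian()
        return self._cartesian

    def _build_cartesian(self) -> np.ndarray:
        coords = apply_torsions(self.ref_coords, self.topology, self.torsions)
        coords = coords - coords.mean(axis=0)
        R = Rotation.from_quat(self.quaternion).as_matrix()
        return coords @ R.T + self.translation

    def with_params(self, translation=None, quaternion=None, torsions=None):
        return replace(
            self,
            translation=self.translation if translation is None else translation,
            quaternion=self.quaternion if quaternion is None else quaternion,
            torsions=self.torsions if torsions is None else torsions,
            energy=None, _cartesian=None)


def _moving_sets(topology: LigandTopology):
    """For each rotatable torsion (a,i,j,b): the set of atoms rigidly
    attached to j once bond (i,j) is cut.  Cached on the topology object."""
    cached = getattr(topology, "_moving_sets", None)
    if cached is not None:
        return cached
    import networkx as nx
    g = topology.graph
    sets = []
    for (a, i, j, b) in topology.rotatable_torsions:
        h = g.copy()
        h.remove_edge(i, j)
        comp = nx.node_connected_component(h, j)
        sets.append((i, j, np.array(sorted(comp), dtype=int)))
    topology._moving_sets = sets
    return sets


def apply_torsions(ref_coords: np.ndarray, topology: LigandTopology,
                   torsions) -> np.ndarray:
    """Rotate each torsion's distal atom set about its bond axis."""
    coords = np.array(ref_coords, dtype=float)
    torsions = np.atleast_1d(torsions)
    if len(torsions) != len(topology.rotatable_torsions):
        raise ValueError("torsion vector length mismatch")
    for angle, (i, j, movers) in zip(torsions, _moving_sets(topology)):
        if abs(angle) < 1e-12:
            continue
        axis = coords[j] - coords[i]
        n = np.linalg.norm(axis)
        if n < 1e-9:
            continue
        R = Rotation.from_rotvec(axis / n * angle).as_matrix()
        coords[movers] = (coords[movers] - coords[i]) @ R.T + coords[i]
    return coords


class CountingEnergy:
    """Wraps an energy callable, counting evaluations for the CSA budget."""

    def __init__(self, fn):
        self.fn = fn
        self.n_evals = 0

    def __call__(self, coords) -> float:
        self.n_evals += 1
        return float(self.fn(coords))


@dataclass
class CsaState:
    """Pool of poses plus annealing bookkeeping."""

    pool: list[LigandPose]
    d_cut: float
    n_evals: int
    rng_seed: int
    rng: np.random.Generator = field(repr=False, default=None)
    d_cut_initial: float = 0.0

    @property
    def best(self) -> LigandPose:
        return min(self.pool, key=lambda p: p.energy)


@dataclass
class PoseCluster:
    member_poses: list[LigandPose]

    @property
    def representative(self) -> LigandPose:
        return min(self.member_poses, key=lambda p: p.energy)


def pose_distance(a: LigandPose, b: LigandPose) -> float:
    """Heavy-atom RMSD between two poses in the shared protein frame.

    No re-superposition (binding poses live in a fixed frame); minimized
    over the ligand graph's element-preserving automorphisms so chemically
    indistinguishable atom relabelings (e.g. an aromatic ring flip) count
    as the same pose.
    """
    if a.topology is not b.topology and \
            len(a.topology.atoms) != len(b.topology.atoms):
        raise ValueError("pose topologies do not match")
    heavy = a.topology.heavy_idx
    xa = a.cartesian[heavy]
    autos = _cached_automorphisms(a.topology)
    best = np.inf
    for perm in autos:
        xb = b.cartesian[perm][heavy]
        rmsd = np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1)))
        if rmsd < best:
            best = float(rmsd)
    return best


def _cached_automorphisms(topology):
    cached = getattr(topology, "_automorphisms", None)
    if cached is None:
        cached = topology.automorphisms()
        topology._automorphisms = cached
    return cached


def _perturb(pose: LigandPose, rng, cfg: CsaConfig) -> LigandPose:
    t = pose.translation + rng.normal(0.0, cfg.sigma_translation, 3)
    if cfg.sigma_rotation > 0:
        rv = rng.normal(0.0, cfg.sigma_rotation, 3)
        q = (Rotation.from_rotvec(rv)
             * Rotation.from_quat(pose.quaternion)).as_quat()
    else:
        q = pose.quaternion
    tor = pose.torsions + (rng.normal(0.0, cfg.sigma_torsion,
                                      len(pose.torsions))
                           if len(pose.torsions) else 0.0)
    return pose.with_params(translation=t, quaternion=q, torsions=tor)


def local_minimize(pose: LigandPose, energy_fn, max_iter: int = 200
                   ) -> LigandPose:
    """Derivative-free local minimization over translation, rotation
    vector, and torsions (Nelder-Mead).  Never returns a pose worse than
    the input."""
    n_tor = len(pose.torsions)
    x0 = np.concatenate([pose.translation, np.zeros(3), pose.torsions])
    q0 = Rotation.from_quat(pose.quaternion)

    def unpack(x):
        t = x[:3]
        q = (Rotation.from_rotvec(x[3:6]) * q0).as_quat()
        tor = x[6:6 + n_tor]
        return pose.with_params(translation=t, quaternion=q, torsions=tor)

    def objective(x):
        return energy_fn(unpack(x).cartesian)

    e0 = energy_fn(pose.cartesian)
    # explicit simplex scales: 0.3 A translation, ~0.2 rad rotation/torsion
    # (the default simplex barely perturbs zero-initialized coordinates)
    scales = np.concatenate([np.full(3, 0.3), np.full(3, 0.2),
                             np.full(n_tor, 0.3)])
    simplex = np.vstack([x0, x0 + np.diag(scales)])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxfev": max_iter, "fatol": 1e-4,
                            "xatol": 1e-4, "adaptive": False,
                            "initial_simplex": simplex})
    if res.fun < e0:
        out = unpack(res.x)
        out.energy = float(res.fun)
        return out
    out = pose.with_params()
    out.energy = float(e0)
    return out


def poses_from_templates(template_coords_list, topology: LigandTopology
                         ) -> list[LigandPose]:
    """Express each template ligand pose (target-frame coordinates) in the
    internal pose parameterization of a shared reference conformation (the
    first template pose, centered)."""
    if not template_coords_list:
        raise ValueError("no-initial-pose")
    ref = np.asarray(template_coords_list[0], dtype=float)
    ref = ref - ref.mean(axis=0)
    n_tor = len(topology.rotatable_torsions)
    poses = []
    for coords in template_coords_list:
        coords = np.asarray(coords, dtype=float)
        centroid = coords.mean(axis=0)
        if len(ref) >= 3:
            R, _, _ = kabsch(coords - centroid, ref)
            q = Rotation.from_matrix(R).as_quat()
        else:
            q = np.array([0.0, 0.0, 0.0, 1.0])
        poses.append(LigandPose(topology=topology, ref_coords=ref,
                                translation=centroid, quaternion=q,
                                torsions=np.zeros(n_tor)))
    return poses


def init_pool(template_poses, topology: LigandTopology, energy_fn,
              seed: int, cfg: CsaConfig | None = None) -> CsaState:
    """Build the initial CSA pool by perturbing template-derived poses.

    Template poses are cycled round-robin; each copy gets Gaussian noise
    on translation, orientation and torsions and a short local
    minimization.  Deterministic for a fixed seed.
    """
    cfg = cfg or CsaConfig()
    if isinstance(template_poses[0] if template_poses else None, LigandPose):
        base = list(template_poses)
    else:
        base = poses_from_templates(template_poses, topology)
    if not base:
        raise ValueError("no-initial-pose")
    rng = np.random.default_rng(seed)
    pool = []
    for k in range(cfg.pool_size):
        p = _perturb(base[k % len(base)], rng, cfg)
        p = local_minimize(p, energy_fn, max_iter=cfg.minimize_evals)
        pool.append(p)
    d0 = _pool_diameter(pool)
    state = CsaState(pool=pool, d_cut=max(cfg.d_cut_final, d0 / 2.0),
                     n_evals=getattr(energy_fn, "n_evals", 0),
                     rng_seed=seed, rng=rng)
    state.d_cut_initial = state.d_cut
    return state


def _pool_diameter(pool) -> float:
    n = len(pool)
    best = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pose_distance(pool[i], pool[j])
            if d > best:
                best = d
    return best


def csa_run(state: CsaState, energy_fn, budget: int,
            cfg: CsaConfig | None = None) -> CsaState:
    """Evolve the pool until the energy-evaluation budget is spent.

    Each round generates trial poses by crossover (torsion-subset swap plus
    translation/orientation interpolation between two pool members) and
    mutation (fresh Gaussian perturbation), locally minimizes them, and
    applies the CSA replacement rule: a trial replaces the worst member of
    its d_cut neighborhood if it improves on it, otherwise the global worst
    if it improves on that, otherwise it is discarded.  d_cut anneals
    geometrically from half the initial pool diameter to ``d_cut_final``
    across the budget.  Stops early after ``stall_rounds`` rounds with no
    replacement.
    """
    cfg = cfg or CsaConfig()
    if budget <= 0:
        return state
    rng = state.rng if state.rng is not None else \
        np.random.default_rng(state.rng_seed)
    counter = energy_fn if isinstance(energy_fn, CountingEnergy) \
        else CountingEnergy(energy_fn)
    start_evals = counter.n_evals
    d0 = state.d_cut_initial or state.d_cut
    stall = 0
    while counter.n_evals - start_evals < budget and stall < cfg.stall_rounds:
        replaced_any = False
        for _ in range(cfg.trials_per_round):
            if counter.n_evals - start_evals >= budget:
                break
            trial = _make_trial(state.pool, rng, cfg)
            trial = local_minimize(trial, counter,
                                   max_iter=cfg.minimize_evals)
            replaced_any |= _csa_replace(state, trial, cfg)
        frac = min(1.0, (counter.n_evals - start_evals) / budget)
        if d0 > cfg.d_cut_final:
            state.d_cut = d0 * (cfg.d_cut_final / d0) ** frac
        else:
            state.d_cut = cfg.d_cut_final
        stall = 0 if replaced_any else stall + 1
    state.n_evals = counter.n_evals
    return state


def _make_trial(pool, rng, cfg: CsaConfig) -> LigandPose:
    if rng.random() < 0.5 and len(pool) >= 2:
        i, j = rng.choice(len(pool), size=2, replace=False)
        p, q = pool[i], pool[j]
        u = rng.random()
        t = u * p.translation + (1 - u) * q.translation
        rots = Rotation.from_quat(np.stack([p.quaternion, q.quaternion]))
        from scipy.spatial.transform import Slerp
        quat = Slerp([0.0, 1.0], rots)([1 - u]).as_quat()[0]
        if len(p.torsions):
            mask = rng.random(len(p.torsions)) < 0.5
            tor = np.where(mask, p.torsions, q.torsions)
        else:
            tor = p.torsions
        child = p.with_params(translation=t, quaternion=quat, torsions=tor)
        return child
    k = int(rng.integers(len(pool)))
    return _perturb(pool[k], rng, cfg)


def _csa_replace(state: CsaState, trial: LigandPose, cfg: CsaConfig) -> bool:
    dists = np.array([pose_distance(trial, p) for p in state.pool])
    close = np.where(dists < state.d_cut)[0]
    if len(close):
        worst_close = max(close, key=lambda k: state.pool[k].energy)
        if trial.energy < state.pool[worst_close].energy:
            state.pool[worst_close] = trial
            return True
        return False
    worst = int(np.argmax([p.energy for p in state.pool]))
    if trial.energy < state.pool[worst].energy:
        state.pool[worst] = trial
        return True
    return False


def select_representative(state: CsaState,
                          cluster_radius: float = CLUSTER_RADIUS):
    """Cluster the final pool (single linkage at ``cluster_radius`` A) and
    return ``(clusters, representative)``: the representative is the
    lowest-energy member of the largest cluster (ties between equally
    large clusters go to the one holding the lower-energy pose)."""
    pool = state.pool
    n = len(pool)
    if n == 1:
        c = PoseCluster(member_poses=list(pool))
        return [c], c.representative
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(pose_distance(pool[i], pool[j]))
    labels = fcluster(linkage(np.array(condensed), method="single"),
                      t=cluster_radius, criterion="distance")
    clusters: dict[int, list[LigandPose]] = {}
    for lab, pose in zip(labels, pool):
        clusters.setdefault(int(lab), []).append(pose)
    out = [PoseCluster(member_poses=m) for m in clusters.values()]
    out.sort(key=lambda c: (-len(c.member_poses),
                            min(p.energy for p in c.member_poses)))
    return out, out[0].representative
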