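"""Hybrid docking energy: capped physical pair potential + template restraints.

The docking energy is

    E = E_phys + w * E_restraint,        w = 1.1 by default,

where E_phys is an AutoDock3-style sum of pairwise van der Waals (12-6),
directional hydrogen-bond (12-10), screened electrostatic and desolvation
terms -- with the one modification that each interacting atom pair
contributes at most +1.0 kcal/mol, so that steric clashes caused by
imperfect model structures are tolerated rather than fatal -- and
E_restraint is a negative log of weighted Gaussians centered on the
ligand-protein distances observed in superposed template complexes:

    E_restraint = - sum_i ln[ sum_j sum_k  w_ijk exp(-(r_ij - r_ij^(k))^2 / d_jk^2) ]

with per-restraint weight

    w_ijk = TM_k * ResidueScore_jk * E_phys,ij(r_ij^(k)) / E_phys,ij(r_min).

TM_k is the template's TM-score; the residue score gates on amino-acid
identity, CA deviation d_jk <= 2 A, and side-chain orientation agreement;
the energy ratio measures how close the template contact distance is to
the pair's own energy optimum (clashing template distances give a
negative ratio and are clamped to weight 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

from .structio import ProteinStructure, Residue

__all__ = [
    "PairPotentialTable",
    "Restraint",
    "RestraintSet",
    "residue_score",
    "build_restraints",
    "restraint_energy",
    "total_energy",
    "HybridEnergy",
    "RESTRAINT_WEIGHT",
]

RESTRAINT_WEIGHT = 1.1          # relative weight of the restraint term
PAIR_ENERGY_CAP = 1.0           # kcal/mol, per interacting atom pair
NONBONDED_CUTOFF = 12.0         # A
RESTRAINT_CONTACT_CUTOFF = 5.0  # A, template protein atom near template ligand
D_FLOOR = 0.5                   # A, floor on d_jk (Gaussian width)
RESIDUE_DEV_CUTOFF = 2.0        # A, d_jk above which the residue score is 0
INNER_SUM_FLOOR = 1e-12         # floor inside the log of the restraint sum

_ELEC_K = 332.06  # kcal mol^-1 A e^-2

# Mehler-Solmajer sigmoidal distance-dependent dielectric constants
_MS_A = -8.5525
_MS_B = 78.4 - _MS_A
_MS_K = 7.7839
_MS_LAM = 0.003627


def _dielectric(r):
    return _MS_A + _MS_B / (1.0 + _MS_K * np.exp(-_MS_LAM * _MS_B * r))


class PairPotentialTable:
    """Pairwise potential parameters loaded from a versioned text table.

    Evaluates the capped per-pair energy and caches the location and depth
    of each type pair's uncapped minimum (needed by the restraint weights).
    """

    def __init__(self, vdw, hbond, solv, coeffs):
        self.vdw = vdw          # type -> (Rii, eps_ii)
        self.hbond = hbond      # frozenset{ti,tj} -> (Rij, eps_ij)
        self.solv = solv        # type -> (S, V)
        self.coeffs = coeffs
        self.cap = coeffs.get("cap", PAIR_ENERGY_CAP)
        self.types = sorted(vdw)
        self._tidx = {t: i for i, t in enumerate(self.types)}
        n = len(self.types)
        self._R = np.zeros((n, n))
        self._eps = np.zeros((n, n))
        self._hbR = np.zeros((n, n))
        self._hbeps = np.zeros((n, n))
        self._is_hb = np.zeros((n, n), dtype=bool)
        self._S = np.array([solv.get(t, (0.0, 0.0))[0] for t in self.types])
        self._V = np.array([solv.get(t, (0.0, 0.0))[1] for t in self.types])
        for i, ti in enumerate(self.types):
            for j, tj in enumerate(self.types):
                Ri, ei = vdw[ti]
                Rj, ej = vdw[tj]
                self._R[i, j] = 0.5 * (Ri + Rj)
                self._eps[i, j] = np.sqrt(ei * ej)
                key = frozenset((ti, tj))
                if key in hbond:
                    self._is_hb[i, j] = True
                    self._hbR[i, j], self._hbeps[i, j] = hbond[key]
        self._rmin_cache: dict = {}

    @classmethod
    def default(cls) -> "PairPotentialTable":
        text = (resources.files("sitedock") / "data" / "ad3_params.txt"
                ).read_text()
        return cls.from_text(text)

    @classmethod
    def from_text(cls, text: str) -> "PairPotentialTable":
        vdw, hbond, solv, coeffs = {}, {}, {}, {}
        for raw in text.splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "coeff":
                coeffs[tok[1]] = float(tok[2])
            elif tok[0] == "vdw":
                vdw[tok[1]] = (float(tok[2]), float(tok[3]))
            elif tok[0] == "hbond":
                hbond[frozenset((tok[1], tok[2]))] = (float(tok[3]),
                                                      float(tok[4]))
            elif tok[0] == "solv":
                solv[tok[1]] = (float(tok[2]), float(tok[3]))
        return cls(vdw, hbond, solv, coeffs)

    def type_index(self, t: str) -> int:
        if t not in self._tidx:
            raise KeyError(f"no parameters for atom type {t!r}")
        return self._tidx[t]

    def pair_energy_raw(self, ti_idx, tj_idx, qq, r):
        """Uncapped pair energy, vectorized over broadcastable arrays."""
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("pair distance must be positive")
        R = self._R[ti_idx, tj_idx]
        eps = self._eps[ti_idx, tj_idx]
        is_hb = self._is_hb[ti_idx, tj_idx]
        x = R / r
        e_vdw = self.coeffs["vdw"] * eps * (x ** 12 - 2.0 * x ** 6)
        if np.any(is_hb):
            xh = self._hbR[ti_idx, tj_idx] / r
            e_hb = self.coeffs["hbond"] * self._hbeps[ti_idx, tj_idx] \
                * (5.0 * xh ** 12 - 6.0 * xh ** 10)
            e_vdw = np.where(is_hb, e_hb, e_vdw)
        e_el = self.coeffs["estat"] * _ELEC_K * qq / (_dielectric(r) * r)
        Si, Vi = self._S[ti_idx], self._V[ti_idx]
        Sj, Vj = self._S[tj_idx], self._V[tj_idx]
        e_sol = self.coeffs["desolv"] * (Si * Vj + Sj * Vi) \
            * np.exp(-(r * r) / (2.0 * 3.5 ** 2))
        return e_vdw + e_el + e_sol

    def pair_energy(self, type_i: str, type_j: str, q_i: float, q_j: float,
                    r, capped: bool = True):
        """Per-pair energy (kcal/mol), capped at ``self.cap`` by default."""
        ti, tj = self.type_index(type_i), self.type_index(type_j)
        e = self.pair_energy_raw(ti, tj, q_i * q_j, r)
        return np.minimum(e, self.cap) if capped else e

    def pair_minimum(self, type_i: str, type_j: str,
                     q_i: float = 0.0, q_j: float = 0.0):
        """(r_min, E(r_min)) of the uncapped pair potential on r in (0, 12]."""
        key = (type_i, type_j, round(q_i * q_j, 6))
        if key in self._rmin_cache:
            return self._rmin_cache[key]
        ti, tj = self.type_index(type_i), self.type_index(type_j)
        qq = q_i * q_j
        grid = np.linspace(0.6, NONBONDED_CUTOFF, 400)
        e = self.pair_energy_raw(ti, tj, qq, grid)
        k = int(np.argmin(e))
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]
        res = minimize_scalar(
            lambda r: float(self.pair_energy_raw(ti, tj, qq, r)),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8})
        out = (float(res.x), float(res.fun))
        self._rmin_cache[key] = out
        return out


def residue_score(target_res: Residue, template_res: Residue,
                  d_jk: float, rotation=None) -> float:
    """Similarity of a target residue to its aligned template residue.

    0 on amino-acid mismatch or CA deviation d_jk > 2 A; otherwise the dot
    product of the normalized CA -> side-chain-centroid vectors, clamped to
    [0, 1].  ``rotation`` (the template-onto-target superposition rotation)
    brings the template vector into the target frame; pass None when both
    residues are already in a common frame.  Glycine (no side chain,
    zero-length vector) scores 1 on an amino-acid match within the
    deviation cutoff.
    """
    if target_res.aa_type != template_res.aa_type:
        return 0.0
    if d_jk > RESIDUE_DEV_CUTOFF:
        return 0.0
    u = target_res.sidechain_centroid - target_res.ca_coords
    v = template_res.sidechain_centroid - template_res.ca_coords
    if rotation is not None:
        v = np.asarray(rotation) @ v
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        return 1.0
    return float(np.clip(np.dot(u / nu, v / nv), 0.0, 1.0))


@dataclass(frozen=True)
class Restraint:
    """One template-derived distance restraint on a ligand atom."""

    ligand_atom_i: int
    protein_atom_j: int
    template_k: int
    r_ref: float
    d: float
    weight: float


@dataclass
class RestraintSet:
    """Restraints grouped by ligand atom, with flat arrays for evaluation.

    ``protein_coords`` snapshots the target heavy-atom coordinates the
    ``protein_atom_j`` indices refer to (the protein is rigid during
    docking, so distances can be precomputed against it).
    """

    restraints: list[Restraint]
    protein_coords: np.ndarray
    _groups: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        groups: dict[int, list[Restraint]] = {}
        for r in self.restraints:
            if r.weight > 0:
                groups.setdefault(r.ligand_atom_i, []).append(r)
        self._groups = {
            i: (np.array([r.protein_atom_j for r in rs], dtype=int),
                np.array([r.r_ref for r in rs]),
                np.array([r.d for r in rs]),
                np.array([r.weight for r in rs]))
            for i, rs in groups.items()
        }

    def __len__(self):
        return len(self.restraints)

    @property
    def restrained_atoms(self):
        return sorted(self._groups)

    @property
    def total_weight_per_atom(self) -> dict[int, float]:
        return {i: float(g[3].sum()) for i, g in self._groups.items()}

    def atom_group(self, i):
        return self._groups[i]


def build_restraints(candidate, target: ProteinStructure,
                     table: PairPotentialTable,
                     contact_cutoff: float = RESTRAINT_CONTACT_CUTOFF,
                     d_floor: float = D_FLOOR,
                     min_weight: float = 1e-6) -> RestraintSet:
    """Derive distance restraints for a ligand from its supporting templates.

    For every supporting template k, every template protein heavy atom
    within ``contact_cutoff`` of the template ligand whose residue is
    aligned to a target residue contributes, for each ligand atom i, a
    restraint at the template distance r_ij^(k), with width d_jk (floored
    at ``d_floor``) and weight TM_k * ResidueScore * energy-ratio, clamped
    to [0, 1].  Restraints with weight below ``min_weight`` (including all
    clamped clashing-template ones) are dropped; pure-repulsive type pairs
    (no negative minimum) are dropped because the ratio is undefined.
    """
    p_coords, p_types, p_charges, p_res = target.heavy_atom_table()
    # target atom lookup: (residue ordinal, atom name) -> flat heavy index
    name_of = {}
    flat = 0
    for ri, res in enumerate(target.residues):
        for a in res.heavy_atoms:
            name_of[(ri, a.name)] = flat
            flat += 1
    res_ordinal = {(r.index, r.icode): ri
                   for ri, r in enumerate(target.residues)}
    restraints: list[Restraint] = []
    k_index = 0
    for tpl in candidate.supporting_templates:
        sup = tpl.superposition
        tm = sup.tm_score
        aligned = {p.template_res_idx: p.target_res_idx for p in tpl.alignment}
        for topo, lig_coords in tpl.ligands:
            if topo.ligand_code != candidate.ligand_code:
                continue
            lig_types = [a.autodock_type for a in topo.atoms]
            lig_charges = [a.partial_charge for a in topo.atoms]
            heavy = topo.heavy_idx
            for tpl_res in tpl.structure.residues:
                if tpl_res.index not in aligned:
                    continue
                tgt_idx = aligned[tpl_res.index]
                if (tgt_idx, "") not in res_ordinal:
                    continue
                ri = res_ordinal[(tgt_idx, "")]
                tgt_res = target.residues[ri]
                d_jk = sup.per_residue_dev.get(tgt_idx)
                if d_jk is None:
                    continue  # unaligned residue: no restraint information
                rscore = residue_score(tgt_res, tpl_res, d_jk,
                                       rotation=sup.rotation)
                if rscore <= 0:
                    continue
                d_eff = max(d_jk, d_floor)
                for atom in tpl_res.heavy_atoms:
                    j = name_of.get((ri, atom.name))
                    if j is None:
                        continue  # no matching atom in the target residue
                    dists = np.linalg.norm(lig_coords[heavy] - atom.coords,
                                           axis=1)
                    if dists.min() > contact_cutoff:
                        continue
                    tj = p_types[j]
                    qj = p_charges[j]
                    for ii, i in enumerate(heavy):
                        r_ref = float(dists[ii])
                        _, e_min = table.pair_minimum(lig_types[i], tj,
                                                      lig_charges[i], qj)
                        if e_min >= -1e-9:
                            continue  # pure-repulsive pair: ratio undefined
                        e_ref = float(table.pair_energy(
                            lig_types[i], tj, lig_charges[i], qj, r_ref))
                        ratio = np.clip(e_ref / e_min, 0.0, 1.0)
                        w = tm * rscore * float(ratio)
                        if w >= min_weight:
                            restraints.append(Restraint(
                                ligand_atom_i=int(i), protein_atom_j=int(j),
                                template_k=k_index, r_ref=r_ref,
                                d=float(d_eff), weight=float(w)))
            k_index += 1
    return RestraintSet(restraints=restraints, protein_coords=p_coords)


def restraint_energy(lig_coords, rs: RestraintSet) -> float:
    """Template-restraint energy of a ligand conformation (kcal/mol).

    Ligand atoms with no positive-weight restraint are excluded from the
    outer sum; the inner weighted Gaussian sum is floored at 1e-12 before
    the log so the energy stays finite for any finite pose.
    """
    lig_coords = np.asarray(lig_coords)
    e = 0.0
    for i in rs.restrained_atoms:
        j_idx, r_ref, d, w = rs.atom_group(i)
        r = np.linalg.norm(rs.protein_coords[j_idx] - lig_coords[i], axis=1)
        s = np.sum(w * np.exp(-((r - r_ref) ** 2) / (d * d)))
        e -= np.log(max(s, INNER_SUM_FLOOR))
    return float(e)


class HybridEnergy:
    """Evaluator of the total docking energy for one ligand against a
    rigid target protein.

    Precomputes flat protein arrays, ligand atom types/charges, and the
    ligand internal nonbonded pair list (heavy-atom pairs three or more
    bonds apart that span at least one rotatable bond).  Hydrogens are
    excluded (united-atom model).
    """

    def __init__(self, target: ProteinStructure, topology,
                 restraint_set: RestraintSet | None,
                 table: PairPotentialTable | None = None,
                 weight: float = RESTRAINT_WEIGHT,
                 cutoff: float = NONBONDED_CUTOFF):
        self.table = table or PairPotentialTable.default()
        self.weight = weight
        self.cutoff = cutoff
        self.topology = topology
        self.restraint_set = restraint_set
        coords, types, charges, _ = target.heavy_atom_table()
        self.p_coords = coords
        self.p_tidx = np.array([self.table.type_index(t) for t in types])
        self.p_charges = charges
        heavy = topology.heavy_idx
        self.l_heavy = heavy
        self.l_tidx = np.array([self.table.type_index(
            topology.atoms[i].autodock_type) for i in heavy])
        self.l_charges = np.array([topology.atoms[i].partial_charge
                                   for i in heavy])
        self._internal_pairs = self._internal_pair_list(topology)
        if len(self._internal_pairs):
            pos = {int(x): k for k, x in enumerate(heavy)}
            a = self._internal_pairs[:, 0]
            b = self._internal_pairs[:, 1]
            self._ip_ta = np.array([self.l_tidx[pos[int(x)]] for x in a])
            self._ip_tb = np.array([self.l_tidx[pos[int(x)]] for x in b])
            self._ip_qq = np.array(
                [topology.atoms[int(x)].partial_charge for x in a]) * \
                np.array([topology.atoms[int(x)].partial_charge for x in b])

    @staticmethod
    def _internal_pair_list(topology):
        import networkx as nx
        g = topology.graph
        heavy = set(int(i) for i in topology.heavy_idx)
        rot_edges = [frozenset((t[1], t[2]))
                     for t in topology.rotatable_torsions]
        moving = []
        for e in rot_edges:
            h = g.copy()
            h.remove_edge(*tuple(e))
            comp = nx.node_connected_component(h, tuple(e)[0])
            moving.append(comp)
        dist = dict(nx.all_pairs_shortest_path_length(g))
        pairs = []
        nodes = sorted(heavy)
        for ai in range(len(nodes)):
            for bi in range(ai + 1, len(nodes)):
                a, b = nodes[ai], nodes[bi]
                if dist[a].get(b, 99) < 3:
                    continue
                # pair must move relative to each other under some torsion
                if any((a in comp) != (b in comp) for comp in moving):
                    pairs.append((a, b))
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def autodock_energy(self, lig_coords) -> float:
        """Capped physical energy: intermolecular + ligand internal."""
        lig = np.asarray(lig_coords)[self.l_heavy]
        r = cdist(lig, self.p_coords)
        r = np.maximum(r, 1e-6)
        e = self.table.pair_energy_raw(
            self.l_tidx[:, None], self.p_tidx[None, :],
            self.l_charges[:, None] * self.p_charges[None, :], r)
        e = np.minimum(e, self.table.cap)
        e_inter = float(np.sum(e[r <= self.cutoff]))
        e_intra = 0.0
        if len(self._internal_pairs):
            a = self._internal_pairs[:, 0]
            b = self._internal_pairs[:, 1]
            coords = np.asarray(lig_coords)
            rr = np.linalg.norm(coords[a] - coords[b], axis=1)
            rr = np.maximum(rr, 1e-6)
            ei = self.table.pair_energy_raw(self._ip_ta, self._ip_tb,
                                            self._ip_qq, rr)
            e_intra = float(np.sum(np.minimum(ei, self.table.cap)))
        return e_inter + e_intra

    def restraint_energy(self, lig_coords) -> float:
        if self.restraint_set is None or len(self.restraint_set) == 0:
            return 0.0
        return restraint_energy(lig_coords, self.restraint_set)

    def __call__(self, lig_coords) -> float:
        return self.autodock_energy(lig_coords) \
            + self.weight * self.restraint_energy(lig_coords)


def total_energy(lig_coords, energy: HybridEnergy) -> float:
    """Total hybrid energy of a conformation; equals
    ``autodock_energy + weight * restraint_energy`` by construction."""
    return energy(lig_coords)
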