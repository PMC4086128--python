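"""Structure I/O and chemical perception.

Reads protein structures and bound ligands from PDB files, assigns
united-atom AutoDock-style atom types and Gasteiger partial charges, and
perceives ligand bond graphs and rotatable torsions.  All downstream
modules (superposition, restraints, docking) consume the containers
defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "LigandTopology",
    "read_protein",
    "extract_ligands",
    "write_complex",
]

# Residue names treated as solvent, never as candidate ligands.
WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# Covalent radii (A) for distance-based bond perception.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84, "SE": 1.20,
}
_BOND_TOLERANCE = 0.45  # A added to the radius sum

# Elements that are single-atom ions / metals when alone in a HET group.
_METALS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "PB", "PT", "AU", "AG", "MO",
    "W", "V", "CR",
}

# Approximate united-atom partial charges for protein atoms by PDB name.
# Side-chain pseudo-atoms and apolar carbons are neutral; the docking
# energy is dominated by the vdW/H-bond terms and the restraints.
_PROTEIN_CHARGES = {"N": -0.35, "CA": 0.10, "C": 0.55, "O": -0.55}


@dataclass
class Atom:
    """One atom with coordinates, charge and a scoring atom type.

    ``autodock_type`` is one of C, A (aromatic carbon), N, O, S, H, P or a
    halogen element symbol; metals get type ``M`` and are excluded from
    scoring.
    """

    name: str
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    autodock_type: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.autodock_type:
            self.autodock_type = assign_autodock_type(self.element)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


def assign_autodock_type(element: str, aromatic: bool = False) -> str:
    el = element.upper()
    if el == "C":
        return "A" if aromatic else "C"
    if el in {"N", "O", "S", "H", "P"}:
        return el
    if el in {"F", "CL", "BR", "I"}:
        return el.capitalize()
    if el in _METALS:
        return "M"
    return "C"  # unknown heavy atoms scored as generic carbon


@dataclass
class Residue:
    """A protein residue: index as authored in the file, type, atoms.

    ``sidechain_centroid`` is the mean of side-chain heavy atoms and falls
    back to the CA position for glycine (no side chain).
    """

    index: int
    aa_type: str
    atoms: list[Atom]
    icode: str = ""

    @property
    def ca_coords(self) -> np.ndarray:
        for a in self.atoms:
            if a.name == "CA":
                return a.coords
        raise ValueError(f"residue {self.index} has no CA atom")

    @property
    def has_ca(self) -> bool:
        return any(a.name == "CA" for a in self.atoms)

    @property
    def sidechain_centroid(self) -> np.ndarray:
        side = [a.coords for a in self.atoms
                if a.name not in BACKBONE_NAMES and not a.is_hydrogen]
        if not side:
            return self.ca_coords
        return np.mean(side, axis=0)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class ProteinStructure:
    """Ordered residues of a single chain (or concatenated chains)."""

    residues: list[Residue]
    chain_id: str = "A"

    def __post_init__(self):
        self._by_index = {(r.index, r.icode): r for r in self.residues}

    def residue(self, index: int, icode: str = "") -> Residue:
        return self._by_index[(index, icode)]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_matrix(self) -> np.ndarray:
        return np.array([r.ca_coords for r in self.residues])

    def heavy_atom_table(self):
        """Flat arrays over all heavy atoms: coords, types, charges and the
        residue each atom belongs to.  Used by the energy module."""
        coords, types, charges, res_ids = [], [], [], []
        for ri, r in enumerate(self.residues):
            for a in r.heavy_atoms:
                coords.append(a.coords)
                types.append(a.autodock_type)
                charges.append(a.partial_charge)
                res_ids.append(ri)
        return (np.array(coords), types, np.array(charges),
                np.array(res_ids, dtype=int))


@dataclass
class LigandTopology:
    """Chemical graph of a ligand with rotatable torsions.

    ``bonds`` are (i, j, order) with order 1/2/3 (1.5 for aromatic).
    ``rotatable_torsions`` are 4-tuples (a, i, j, b) about acyclic,
    non-terminal single bonds.  ``center_atom_idx`` is the atom nearest
    the geometric center (ties broken by lowest index); it anchors the
    positional-variation filter on candidate ligands.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, int | float]]
    ligand_code: str = "LIG"
    rotatable_torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    center_atom_idx: int = -1

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("ligand with zero atoms")
        g = self.graph
        if len(self.atoms) > 1 and not nx.is_connected(g):
            raise ValueError("ligand bond graph is disconnected")
        if not self.rotatable_torsions:
            self.rotatable_torsions = perceive_torsions(self.atoms, self.bonds)
        if self.center_atom_idx < 0:
            self.center_atom_idx = _center_atom(self.coords)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element.upper())
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def heavy_idx(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms)
                         if not a.is_hydrogen], dtype=int)

    def automorphisms(self, max_count: int = 720) -> list[np.ndarray]:
        """Element-preserving graph self-isomorphisms, as index maps."""
        g = self.graph
        matcher = nx.algorithms.isomorphism.GraphMatcher(
            g, g, node_match=lambda a, b: a["element"] == b["element"])
        maps = []
        for iso in matcher.isomorphisms_iter():
            maps.append(np.array([iso[i] for i in range(len(self.atoms))]))
            if len(maps) >= max_count:
                break
        return maps


def _center_atom(coords: np.ndarray) -> int:
    center = coords.mean(axis=0)
    # round so numerically-equal distances tie, then lowest index wins
    d = np.round(np.linalg.norm(coords - center, axis=1), 6)
    return int(np.argmin(d))


def perceive_bonds(atoms: list[Atom]) -> list[tuple[int, int, int]]:
    """Distance-based bond perception from covalent radii (single bonds)."""
    coords = np.array([a.coords for a in atoms])
    radii = np.array([_COVALENT_RADII.get(a.element.upper(), 0.77)
                      for a in atoms])
    bonds = []
    n = len(atoms)
    if n < 2:
        return bonds
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + _BOND_TOLERANCE
    for i in range(n):
        for j in range(i + 1, n):
            if 0.4 < d[i, j] < cut[i, j]:
                bonds.append((i, j, 1))
    return bonds


def perceive_torsions(atoms, bonds) -> list[tuple[int, int, int, int]]:
    """Rotatable torsions: single, acyclic, non-terminal heavy-atom bonds.

    For each such bond (i, j) one torsion (a, i, j, b) is emitted with a/b
    the lowest-index heavy neighbors; the set is invariant to atom input
    order up to tuple reversal.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    for i, j, order in bonds:
        g.add_edge(i, j, order=order)
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for k in range(len(cycle)):
            e = frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))
            ring_edges.add(e)
    torsions = []
    for i, j, order in bonds:
        if order != 1 or frozenset((i, j)) in ring_edges:
            continue
        ni = [n for n in g.neighbors(i) if n != j and not atoms[n].is_hydrogen]
        nj = [n for n in g.neighbors(j) if n != i and not atoms[n].is_hydrogen]
        if not ni or not nj:
            continue  # terminal bond: rotation changes nothing heavy
        a, b = min(ni), min(nj)
        lo, hi = (i, j) if i < j else (j, i)
        if (lo, hi) == (i, j):
            torsions.append((a, i, j, b))
        else:
            torsions.append((b, j, i, a))
    torsions.sort(key=lambda t: (t[1], t[2]))
    return torsions


def _mark_aromatic(atoms, bonds):
    """Type ring carbons as 'A' (aromatic-like) for the pair potentials."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from([(i, j) for i, j, _ in bonds])
    in_ring = set()
    for cycle in nx.cycle_basis(g):
        if len(cycle) in (5, 6):
            in_ring.update(cycle)
    for i in in_ring:
        if atoms[i].element.upper() == "C":
            atoms[i].autodock_type = "A"


def gasteiger_charges(atoms, bonds) -> np.ndarray:
    """Gasteiger partial charges via RDKit; zeros if perception fails."""
    try:
        from rdkit import Chem
        from rdkit.Chem import rdPartialCharges

        mol = Chem.RWMol()
        for a in atoms:
            ra = Chem.Atom(a.element.capitalize())
            ra.SetNoImplicit(True)
            mol.AddAtom(ra)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
        for i, j, order in bonds:
            mol.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE))
        m = mol.GetMol()
        Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                         | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION)
        rdPartialCharges.ComputeGasteigerCharges(m, throwOnParamFailure=False)
        q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()])
        q[~np.isfinite(q)] = 0.0
        return q
    except Exception as exc:  # pragma: no cover - rdkit corner cases
        warnings.warn(f"Gasteiger charge computation failed ({exc}); "
                      "using zero charges")
        return np.zeros(len(atoms))


def _resolve_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken toward 'A'."""
    groups: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        groups.setdefault(a.name, []).append(a)
    out = []
    for name, alts in groups.items():
        alts.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        out.append(alts[0])
    return out


def read_protein(path, dialect: str = "pdb") -> ProteinStructure:
    """Read the polymer chains of a PDB file into a ProteinStructure.

    HETATM groups are ignored here (see :func:`extract_ligands`); alternate
    locations are resolved to the highest-occupancy conformer; insertion
    codes are preserved in residue identity.  Raises if more than 10% of
    residues lack a CA atom ("backbone-incomplete") or no residues parse.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    residues: list[Residue] = []
    chain_id = "A"
    model = st[0]
    for chain in model:
        for gres in chain:
            if gres.het_flag != "A" or gres.name in WATER_NAMES:
                continue
            atoms = []
            for ga in _resolve_altloc(gres):
                el = ga.element.name.upper() if ga.element else "C"
                atoms.append(Atom(
                    name=ga.name, element=el,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    partial_charge=_PROTEIN_CHARGES.get(ga.name, 0.0),
                ))
            if atoms:
                chain_id = chain.name
                residues.append(Residue(index=gres.seqid.num,
                                        aa_type=gres.name,
                                        atoms=atoms,
                                        icode=gres.seqid.icode.strip()))
    if not residues:
        raise ValueError(f"no protein residues in {path}")
    n_no_ca = sum(1 for r in residues if not r.has_ca)
    if n_no_ca > 0.1 * len(residues):
        raise ValueError(f"backbone-incomplete: {n_no_ca}/{len(residues)} "
                         "residues lack CA atoms")
    return ProteinStructure(residues=residues, chain_id=chain_id)


def extract_ligands(path, sdf_path=None) -> list[tuple[LigandTopology, np.ndarray]]:
    """Extract non-metal HETATM ligands with coordinates in the file frame.

    Water and single-atom ion groups are skipped (solvent and metals are
    out of scope).  Bond orders come from an SDF sidecar when supplied;
    otherwise bonds are perceived from interatomic distances.  Disconnected
    HETATM groups with no perceivable bonds are skipped with a warning.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    sdf_bonds = _read_sdf_bonds(sdf_path) if sdf_path else None
    out = []
    for chain in st[0]:
        for gres in chain:
            if gres.het_flag != "H" or gres.name in WATER_NAMES:
                continue
            gatoms = _resolve_altloc(gres)
            if len(gatoms) <= 1:
                continue  # single-atom ion/metal: not a candidate ligand
            atoms = []
            for ga in gatoms:
                el = ga.element.name.upper() if ga.element else "C"
                atoms.append(Atom(name=ga.name, element=el,
                                  coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
            bonds = None
            if sdf_bonds and gres.name in sdf_bonds \
                    and sdf_bonds[gres.name][0] == len(atoms):
                bonds = sdf_bonds[gres.name][1]
            if bonds is None:
                bonds = perceive_bonds(atoms)
            g = nx.Graph()
            g.add_nodes_from(range(len(atoms)))
            g.add_edges_from([(i, j) for i, j, _ in bonds])
            if len(atoms) > 1 and not nx.is_connected(g):
                warnings.warn(f"skipping HETATM group {gres.name}: "
                              "disconnected bond graph")
                continue
            _mark_aromatic(atoms, bonds)
            charges = gasteiger_charges(atoms, bonds)
            for a, q in zip(atoms, charges):
                a.partial_charge = float(q)
            topo = LigandTopology(atoms=atoms, bonds=bonds,
                                  ligand_code=gres.name)
            out.append((topo, topo.coords))
    return out


def _read_sdf_bonds(sdf_path):
    """Map ligand code -> (n_atoms, bond list) from a V2000 SDF sidecar."""
    from rdkit import Chem
    table = {}
    supplier = Chem.SDMolSupplier(str(sdf_path), sanitize=False, removeHs=False)
    for mol in supplier:
        if mol is None:
            continue
        name = (mol.GetProp("_Name") or "LIG").strip()[:3].upper() or "LIG"
        bonds = []
        for b in mol.GetBonds():
            order = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                     Chem.BondType.TRIPLE: 3,
                     Chem.BondType.AROMATIC: 1.5}.get(b.GetBondType(), 1)
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        table[name] = (mol.GetNumAtoms(), bonds)
    return table


def write_complex(protein: ProteinStructure, ligand: LigandTopology | None,
                  ligand_coords, path) -> None:
    """Write a protein(-ligand) complex as a PDB file.

    Protein residues go out as ATOM records and the ligand (if any) as a
    HETATM group named after its component code.  Coordinates round-trip
    through :func:`read_protein` / :func:`extract_ligands` to PDB precision
    (3 decimals).
    """
    if ligand is not None:
        ligand_coords = np.asarray(ligand_coords, dtype=float)
        if len(ligand.atoms) == 0:
            raise ValueError("ligand with zero atoms")
        if ligand_coords.shape != (len(ligand.atoms), 3):
            raise ValueError("ligand coordinate shape mismatch")
        if not np.all(np.isfinite(ligand_coords)):
            raise ValueError("non-finite ligand coordinates")
    st = gemmi.Structure()
    model = gemmi.Model(1)
    chain = gemmi.Chain(protein.chain_id or "A")
    for r in protein.residues:
        gres = gemmi.Residue()
        gres.name = r.aa_type
        gres.seqid = gemmi.SeqId(r.index, r.icode or " ")
        gres.het_flag = "A"
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = 1.0
            gres.add_atom(ga)
        chain.add_residue(gres)
    model.add_chain(chain)
    if ligand is not None:
        lchain = gemmi.Chain("L")
        gres = gemmi.Residue()
        gres.name = ligand.ligand_code
        gres.seqid = gemmi.SeqId(1, " ")
        gres.het_flag = "H"
        for a, xyz in zip(ligand.atoms, ligand_coords):
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*xyz)
            ga.occ = 1.0
            gres.add_atom(ga)
        lchain.add_residue(gres)
        model.add_chain(lchain)
    st.add_model(model)
    st.write_pdb(str(path))
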