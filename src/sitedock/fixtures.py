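"""Deterministic synthetic target/template systems for testing and demos.

Generates a helix-like target protein (ideal backbone trace with
side-chain pseudo-atoms), template complexes that are noisy copies of the
target carrying a planted ligand, alignment and score tables, and a truth
record (planted pose, true binding residues, applied transforms).  The
generator controls exactly the quantities the method depends on: the
CA jitter (hence TM-score and d_jk), the planted ligand placement, and
the inter-template center-atom spread exercised by the
positional-variation filter.

These systems emulate the geometry of template-based docking inputs, not
protein chemistry: sequences are a fixed rotation of ten residue types,
backbone geometry is approximate, and ligands are small generic
molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import (Atom, LigandTopology, ProteinStructure, Residue,
                       perceive_bonds, write_complex)

__all__ = ["FixtureSpec", "make_system", "build_target", "build_ligand"]

_AA_CYCLE = ["ALA", "LEU", "SER", "VAL", "LYS",
             "PHE", "ASP", "THR", "ILE", "GLU"]

_HELIX_RADIUS = 2.3      # A
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RISE = 1.5        # A per residue


@dataclass
class FixtureSpec:
    """Parameters of a synthetic docking system.

    ``template_noise`` is the per-coordinate sigma (A) of the Gaussian
    jitter applied rigidly to each template residue; it controls both the
    measured TM-score and the per-residue deviations d_jk.
    ``center_spread`` is the exact maximum pairwise distance realized
    between planted ligand center atoms across templates (0 plants the
    identical pose everywhere).
    """

    n_residues: int = 24
    n_templates: int = 3
    template_noise: float = 0.3
    ligand_kind: str = "rigid_triatomic"
    n_torsions: int = 2          # flexible_chain only
    center_spread: float = 0.0
    pocket_offset: float = 7.0   # A, half the helix-axis separation
    seed: int = 0


def helix_ca(n: int, spec: FixtureSpec | None = None) -> np.ndarray:
    """CA trace of a two-helix bundle: an up helix at the origin and a
    down helix offset along +x, forming a binding groove between them."""
    sep = 2.0 * (spec.pocket_offset if spec else 7.5)
    half = n // 2
    out = np.zeros((n, 3))
    for i in range(n):
        if i < half:
            ang = _HELIX_TWIST * i
            out[i] = [_HELIX_RADIUS * np.cos(ang),
                      _HELIX_RADIUS * np.sin(ang),
                      _HELIX_RISE * i]
        else:
            j = i - half
            ang = np.pi + _HELIX_TWIST * j  # inward-facing start
            out[i] = [sep + _HELIX_RADIUS * np.cos(ang),
                      _HELIX_RADIUS * np.sin(ang),
                      _HELIX_RISE * (half - 1 - j)]
    return out


def build_target(spec: FixtureSpec) -> ProteinStructure:
    """Two-helix-bundle CA trace with approximate N/C/O backbone positions
    and a radially outward CB pseudo-atom standing in for the side chain.
    Residues facing the inter-helix groove form the binding pocket."""
    n = spec.n_residues
    half = n // 2
    ca = helix_ca(n, spec)
    axis_x = np.array([0.0, 0.0]), np.array([2.0 * spec.pocket_offset, 0.0])
    residues = []
    for i in range(n):
        aa = _AA_CYCLE[i % len(_AA_CYCLE)]
        prev_dir = _unit(ca[i - 1] - ca[i]) if i > 0 else \
            _unit(ca[0] - ca[1])
        next_dir = _unit(ca[i + 1] - ca[i]) if i < n - 1 \
            else _unit(ca[-1] - ca[-2])
        ax = axis_x[0] if i < half else axis_x[1]
        radial = _unit(np.array([ca[i, 0] - ax[0], ca[i, 1] - ax[1], 0.0]))
        atoms = [
            Atom("N", "N", ca[i] + 1.46 * prev_dir, partial_charge=-0.35),
            Atom("CA", "C", ca[i], partial_charge=0.10),
            Atom("C", "C", ca[i] + 1.52 * next_dir, partial_charge=0.55),
            Atom("O", "O", ca[i] + 1.52 * next_dir + 1.23 * radial,
                 partial_charge=-0.55),
        ]
        if aa != "GLY":
            atoms.append(Atom("CB", "C", ca[i] + 1.8 * radial
                              + np.array([0.0, 0.0, 0.3])))
        residues.append(Residue(index=i + 1, aa_type=aa, atoms=atoms))
    return ProteinStructure(residues=residues, chain_id="A")


def build_ligand(kind: str, n_torsions: int = 2) -> LigandTopology:
    """Small generic ligands in a local centered frame.

    ``rigid_triatomic``: a bent C-O-C ether (no rotatable torsions);
    ``benzene_like``: a six-carbon aromatic ring; ``flexible_chain``: a
    carbon zigzag with ``n_torsions`` rotatable bonds.
    """
    if kind == "rigid_triatomic":
        coords = np.array([[-1.16, -0.30, 0.0],
                           [0.00, 0.45, 0.0],
                           [1.16, -0.30, 0.0]])
        elements = ["C", "O", "C"]
        code = "LGA"
    elif kind == "benzene_like":
        ang = np.deg2rad(60.0) * np.arange(6)
        coords = np.stack([1.39 * np.cos(ang), 1.39 * np.sin(ang),
                           np.zeros(6)], axis=1)
        elements = ["C"] * 6
        code = "LGB"
    elif kind == "flexible_chain":
        n_atoms = n_torsions + 3
        coords = []
        bond, theta = 1.53, np.deg2rad(111.0)
        for i in range(n_atoms):
            coords.append([bond * np.sin(theta / 2) * i,
                           bond * np.cos(theta / 2) * (i % 2), 0.0])
        coords = np.array(coords)
        elements = ["C"] * n_atoms
        code = "LGC"
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")
    coords = coords - coords.mean(axis=0)
    atoms = [Atom(f"{el}{i + 1}", el, xyz)
             for i, (el, xyz) in enumerate(zip(elements, coords))]
    bonds = perceive_bonds(atoms)
    if kind == "benzene_like":
        for a in atoms:
            a.autodock_type = "A"
    return LigandTopology(atoms=atoms, bonds=bonds, ligand_code=code)


def planted_ligand_coords(spec: FixtureSpec, topology: LigandTopology
                          ) -> np.ndarray:
    """Place the ligand at the center of the inter-helix groove, with a
    fixed seed-derived orientation."""
    z_mid = _HELIX_RISE * (spec.n_residues // 2 - 1) / 2.0
    center = np.array([spec.pocket_offset, 0.0, z_mid])
    rng = np.random.default_rng(spec.seed + 12345)
    R = Rotation.random(rng=rng).as_matrix()
    local = topology.coords - topology.coords.mean(axis=0)
    return local @ R.T + center


def make_system(spec: FixtureSpec, out_dir) -> dict:
    """Write a full synthetic system and return its truth record.

    Produces ``target.pdb``, ``templates/template_XX.pdb`` (noisy target copies with
    the planted ligand, each in its own random rigid frame),
    ``alignments/template_XX.tsv`` (identity alignments),
    ``scores.tsv`` (descending template scores) and ``truth.json``.
    """
    out_dir = Path(out_dir)
    (out_dir / "alignments").mkdir(parents=True, exist_ok=True)
    (out_dir / "templates").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    target = build_target(spec)
    topo = build_ligand(spec.ligand_kind, spec.n_torsions)
    planted = planted_ligand_coords(spec, topo)
    write_complex(target, None, None, out_dir / "target.pdb")

    # center displacements realizing exactly `center_spread` (max pairwise)
    nt = spec.n_templates
    if nt > 1 and spec.center_spread > 0:
        # two extremes separated by center_spread; others at midpoints
        along = _unit(np.array([0.37, -0.62, 0.69]))
        offsets = [(-0.5 + (t / (nt - 1))) * spec.center_spread * along
                   for t in range(nt)]
    else:
        offsets = [np.zeros(3)] * nt

    from .siteeval import extract_site
    true_site = extract_site(target, planted)

    names, scores = [], []
    transforms = []
    for t in range(nt):
        name = f"template_{t:02d}"
        names.append(name)
        scores.append(round(10.0 - t, 3))
        # noisy copy of the target: rigid per-residue jitter
        residues = []
        for res in target.residues:
            jitter = rng.normal(0.0, spec.template_noise, 3) \
                if spec.template_noise > 0 else np.zeros(3)
            atoms = [Atom(a.name, a.element, a.coords + jitter,
                          partial_charge=a.partial_charge)
                     for a in res.atoms]
            residues.append(Residue(index=res.index, aa_type=res.aa_type,
                                    atoms=atoms))
        tpl_protein = ProteinStructure(residues=residues, chain_id="A")
        lig_coords = planted + offsets[t]
        # express the whole template in its own random rigid frame
        R = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-20.0, 20.0, 3)
        for res in tpl_protein.residues:
            for a in res.atoms:
                a.coords = a.coords @ R.T + shift
        lig_coords = lig_coords @ R.T + shift
        write_complex(tpl_protein, topo, lig_coords,
                      out_dir / "templates" / f"{name}.pdb")
        transforms.append({"rotation": R.tolist(), "shift": shift.tolist()})
        with open(out_dir / "alignments" / f"{name}.tsv", "w") as fh:
            for res in target.residues:
                fh.write(f"{res.index}\t{res.index}\n")

    with open(out_dir / "scores.tsv", "w") as fh:
        for name, sc in zip(names, scores):
            fh.write(f"{name}\t{sc}\n")

    truth = {
        "spec": asdict(spec),
        "ligand_code": topo.ligand_code,
        "planted_coords": planted.tolist(),
        "binding_residues": sorted(f"{c}:{r}"
                                   for c, r in true_site.residue_ids),
        "template_names": names,
        "template_scores": scores,
        "template_transforms": transforms,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
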