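"""Binding-site extraction from a docked pose and MCC evaluation.

A residue is a binding-site residue when any of its heavy atoms lies
within a contact cutoff (default 4.5 A) of any ligand heavy atom.
Predictions are scored against a reference site with the Matthews
correlation coefficient over the residue-level binding/non-binding
confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structio import ProteinStructure

__all__ = [
    "BindingSite",
    "SiteComparison",
    "extract_site",
    "mcc",
    "read_site",
    "write_site",
    "VDW_RADII",
]

CONTACT_CUTOFF = 4.5  # A, heavy-atom contact distance

# vdW radii for the alternative "vdW-sum + margin" contact mode.
VDW_RADII = {"C": 1.70, "A": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "H": 1.20, "F": 1.47, "Cl": 1.75, "Br": 1.85,
             "I": 1.98}


@dataclass
class BindingSite:
    """Set of (chain, residue index) ids in contact with a ligand pose."""

    residue_ids: set[tuple[str, int]]
    cutoff_used: float = CONTACT_CUTOFF

    def __len__(self):
        return len(self.residue_ids)


@dataclass
class SiteComparison:
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float


def extract_site(protein: ProteinStructure, lig_coords,
                 lig_types=None, cutoff: float = CONTACT_CUTOFF,
                 mode: str = "fixed") -> BindingSite:
    """Residues with any heavy atom within ``cutoff`` of any ligand atom.

    ``mode="fixed"`` uses the flat distance cutoff; ``mode="vdw"`` uses
    per-pair vdW-radius sums plus ``cutoff`` as a margin (pass e.g. 0.5).
    """
    lig_coords = np.asarray(lig_coords, dtype=float)
    ids = set()
    for res in protein.residues:
        atoms = res.heavy_atoms
        if not atoms:
            continue
        coords = np.array([a.coords for a in atoms])
        d = cdist(coords, lig_coords)
        if mode == "vdw":
            if lig_types is None:
                raise ValueError("vdw mode needs ligand atom types")
            rp = np.array([VDW_RADII.get(a.autodock_type, 1.7)
                           for a in atoms])
            rl = np.array([VDW_RADII.get(t, 1.7) for t in lig_types])
            thresh = rp[:, None] + rl[None, :] + cutoff
        else:
            thresh = cutoff
        if np.any(d <= thresh):
            ids.add((protein.chain_id, res.index))
    return BindingSite(residue_ids=ids, cutoff_used=cutoff)


def mcc(predicted: BindingSite, reference: BindingSite,
        n_residues: int) -> SiteComparison:
    """Matthews correlation coefficient over the residue universe.

    Degenerate marginals (e.g. an empty prediction or an all-residue
    reference) give MCC 0 by convention so batch medians stay defined.
    """
    p = predicted.residue_ids
    r = reference.residue_ids
    if n_residues < len(p | r):
        raise ValueError("n_residues smaller than the union of sites")
    tp = len(p & r)
    fp = len(p - r)
    fn = len(r - p)
    tn = n_residues - tp - fp - fn
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    value = 0.0 if den == 0 else num / np.sqrt(den)
    return SiteComparison(tp=tp, fp=fp, fn=fn, tn=tn, mcc=float(value))


def read_site(path) -> BindingSite:
    """Read a site list: one ``chain:resid`` per line."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chain, resid = line.split(":")
            ids.add((chain, int(resid)))
    return BindingSite(residue_ids=ids)


def write_site(site: BindingSite, path) -> None:
    with open(path, "w") as fh:
        for chain, resid in sorted(site.residue_ids):
            fh.write(f"{chain}:{resid}\n")
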