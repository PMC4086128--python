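"""Candidate-ligand selection from filtered template complexes.

Ligands observed in the retained templates are pooled by chemical
component code, crystallization additives are removed, ligands whose
binding position is inconsistent across templates (center atoms more than
10 A apart after superposition onto the target) are removed, and the
survivors are ranked by the summed similarity score of their supporting
templates.  Up to three top-ranked ligands proceed to docking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structio import LigandTopology, ProteinStructure
from .superpose import SuperpositionResult

__all__ = [
    "TemplateComplex",
    "LigandCandidate",
    "load_blocklist",
    "collect_candidates",
    "filter_nonbiological",
    "filter_positional_variation",
    "rank_and_take",
]

POSITIONAL_VARIATION_CUTOFF = 10.0  # A
MAX_LIGANDS = 3


@dataclass
class TemplateComplex:
    """A template protein-ligand complex with its map onto the target."""

    name: str
    structure: ProteinStructure
    ligands: list[tuple[LigandTopology, np.ndarray]]
    alignment: list
    template_score: float
    superposition: SuperpositionResult | None = None

    @property
    def tm_score(self) -> float:
        if self.superposition is None:
            raise ValueError(f"template {self.name} not superposed")
        return self.superposition.tm_score


@dataclass
class LigandCandidate:
    """A ligand type pooled across the templates that contain it.

    ``rank_score`` is the sum of template scores over supporting templates;
    ``center_variation`` is the maximum pairwise distance between the
    ligands' center atoms after superposition into the target frame
    (0 for a single supporting template).
    """

    ligand_code: str
    rank_score: float
    supporting_templates: list[TemplateComplex] = field(default_factory=list)
    center_variation: float = 0.0
    poses: list[tuple[LigandTopology, np.ndarray]] = field(default_factory=list)


def load_blocklist(path=None) -> set[str]:
    """Non-biological ligand codes, one per line; '#' starts a comment."""
    if path is None:
        text = (resources.files("sitedock") / "data" / "nonbio_ligands.txt"
                ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    codes = set()
    for line in text.splitlines():
        line = line.split("#")[0].strip().upper()
        if line:
            codes.add(line)
    return codes


def collect_candidates(templates: list[TemplateComplex]) -> list[LigandCandidate]:
    """Pool ligands of the (already filtered) templates by component code.

    Each supporting template contributes one pose, mapped into the target
    frame through that template's superposition.
    """
    by_code: dict[str, LigandCandidate] = {}
    for tpl in templates:
        if tpl.superposition is None:
            raise ValueError(f"template {tpl.name} not superposed")
        seen_codes = set()
        for topo, coords in tpl.ligands:
            code = topo.ligand_code
            cand = by_code.setdefault(
                code, LigandCandidate(ligand_code=code, rank_score=0.0))
            if code not in seen_codes:
                cand.rank_score += tpl.template_score
                cand.supporting_templates.append(tpl)
                seen_codes.add(code)
            cand.poses.append((topo, tpl.superposition.transform(coords)))
    out = list(by_code.values())
    for cand in out:
        cand.center_variation = _center_variation(cand)
    out.sort(key=lambda c: c.ligand_code)
    return out


def _center_variation(cand: LigandCandidate) -> float:
    centers = np.array([coords[topo.center_atom_idx]
                        for topo, coords in cand.poses])
    if len(centers) < 2:
        return 0.0
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    return float(d.max())


def filter_nonbiological(candidates, blocklist=None):
    """Remove crystallization additives (sulphate, glycerol, PEG, ...)."""
    if blocklist is None:
        blocklist = load_blocklist()
    blocklist = {c.upper() for c in blocklist}
    return [c for c in candidates if c.ligand_code.upper() not in blocklist]


def filter_positional_variation(candidates,
                                cutoff: float = POSITIONAL_VARIATION_CUTOFF):
    """Remove ligands whose center atoms vary by more than ``cutoff`` A
    across the superposed templates that contain them.  A ligand seen in a
    single template has variation 0 and always passes."""
    return [c for c in candidates if c.center_variation <= cutoff]


def rank_and_take(candidates, max_n: int = MAX_LIGANDS):
    """Return the ``max_n`` best candidates by summed template score.

    Ties broken by more supporting templates, then by component code.
    """
    ranked = sorted(candidates,
                    key=lambda c: (-c.rank_score,
                                   -len(c.supporting_templates),
                                   c.ligand_code))
    return ranked[:max_n]


def select_ligands(templates, blocklist=None, max_n: int = MAX_LIGANDS,
                   variation_cutoff: float = POSITIONAL_VARIATION_CUTOFF):
    """Full selection pipeline: pool, filter additives, filter positional
    variation, rank, truncate.  Returns possibly empty list ("no ligand
    predicted" is a valid outcome)."""
    cands = collect_candidates(templates)
    cands = filter_nonbiological(cands, blocklist)
    cands = filter_positional_variation(cands, variation_cutoff)
    return rank_and_take(cands, max_n)
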