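"""Rigid superposition, TM-score, and template filtering.

The TM-score drives two things downstream: the restraint weights carry the
template's TM-score as a factor, and candidate templates are filtered by
TM-score cutoffs that tighten as the best available template improves.
The per-residue CA deviations d_jk measured after the TM-score-optimal
superposition set the widths of the restraint Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import ProteinStructure

__all__ = [
    "AlignmentPair",
    "SuperpositionResult",
    "kabsch",
    "tm_score",
    "filter_templates",
    "tm_d0",
    "read_alignment",
]


@dataclass(frozen=True)
class AlignmentPair:
    """One aligned residue pair (author residue numbers, 1-based)."""

    target_res_idx: int
    template_res_idx: int


@dataclass
class SuperpositionResult:
    """Optimal rigid map of template onto target and derived similarity.

    ``rotation``/``translation`` map template coordinates into the target
    frame as ``x @ rotation.T + translation``.  ``per_residue_dev`` maps
    target residue index -> CA deviation d (A) under that map.
    """

    rotation: np.ndarray
    translation: np.ndarray
    tm_score: float
    per_residue_dev: dict[int, float]

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(fixed, moving):
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (reflections are corrected by flipping the smallest singular vector).
    Requires >= 3 non-collinear points.
    """
    P = np.asarray(fixed, dtype=float)
    Q = np.asarray(moving, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching Nx3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9:
        raise ValueError("degenerate (collinear) point geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - qc @ R.T
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return R, t, rmsd


def tm_d0(n_aligned_target: int) -> float:
    """Length-normalization distance d0, floored at 0.5 A for short chains."""
    L = n_aligned_target
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_transform(R, t, P, Q, d0):
    dev = np.linalg.norm(Q @ R.T + t - P, axis=1)
    return float(np.mean(1.0 / (1.0 + (dev / d0) ** 2))), dev


def tm_score(alignment, target: ProteinStructure,
             template: ProteinStructure,
             min_seed: int = 4, max_iter: int = 30) -> SuperpositionResult:
    """TM-score of a template against the target over a fixed alignment.

    The score is normalized by the target length and maximized over rigid
    superpositions by iterative refinement seeded from every contiguous
    aligned fragment of length >= ``min_seed``: each seed is superposed by
    least squares, the aligned pairs closer than an inclusion cutoff are
    re-superposed, and the cutoff grows until the included set stabilizes.
    The best transform over all seeds is kept.  Per-residue CA deviations
    are measured under that final transform.
    """
    pairs = list(alignment)
    if len(pairs) < 3:
        raise ValueError("need at least 3 aligned pairs")
    P = np.array([target.residue(p.target_res_idx).ca_coords for p in pairs])
    Q = np.array([template.residue(p.template_res_idx).ca_coords for p in pairs])
    L_norm = len(target)
    d0 = tm_d0(L_norm)
    n = len(pairs)

    best = (-1.0, None, None)
    seeds = [(s, e) for s in range(n) for e in range(s + min_seed, n + 1)]
    if (0, n) not in seeds:
        seeds.append((0, n))
    for s, e in seeds:
        idx = np.arange(s, e)
        if len(idx) < 3:
            continue
        try:
            R, t, _ = kabsch(P[idx], Q[idx])
        except ValueError:
            continue
        for cutoff in (d0 + 0.5, d0 + 1.0, d0 + 1.5, d0 + 2.0):
            prev = None
            for _ in range(max_iter):
                tm, dev = _tm_from_transform(R, t, P, Q, d0)
                if tm > best[0]:
                    best = (tm, R, t)
                sel = np.where(dev < cutoff)[0]
                if len(sel) < 3:
                    break
                if prev is not None and len(sel) == len(prev) \
                        and np.all(sel == prev):
                    break
                prev = sel
                try:
                    R, t, _ = kabsch(P[sel], Q[sel])
                except ValueError:
                    break
    tm_best, R, t = best
    if R is None:
        raise ValueError("superposition failed for all seeds")
    # TM-score is a mean over aligned pairs of terms <= 1, normalized by
    # target length: scale if the alignment does not cover the target.
    tm_norm = tm_best * n / L_norm
    _, dev = _tm_from_transform(R, t, P, Q, d0)
    per_res = {p.target_res_idx: float(d) for p, d in zip(pairs, dev)}
    return SuperpositionResult(rotation=R, translation=t,
                               tm_score=min(1.0, tm_norm),
                               per_residue_dev=per_res)


def filter_cutoff(best_tm: float) -> float:
    """TM-score cutoff given the closest template's TM-score.

    Stricter when a very close template exists: 0.5 if the best template
    scores > 0.8, 0.4 if > 0.6, else 0.3.
    """
    if best_tm > 0.8:
        return 0.5
    if best_tm > 0.6:
        return 0.4
    return 0.3


def filter_templates(candidates):
    """Drop structurally dissimilar templates, preserving input order.

    Each candidate must expose ``.tm_score`` (TemplateComplex does, via its
    superposition).  Candidates strictly below the cutoff chosen by
    :func:`filter_cutoff` are removed; the boundary value is kept.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no-templates")
    best = max(_tm_of(c) for c in cands)
    cut = filter_cutoff(best)
    return [c for c in cands if _tm_of(c) >= cut]


def _tm_of(c) -> float:
    if hasattr(c, "tm_score"):
        v = c.tm_score
        return float(v() if callable(v) else v)
    return float(c.superposition.tm_score)


def read_alignment(path) -> list[AlignmentPair]:
    """Read a 2-column TSV of 1-based residue numbers (target, template)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            pairs.append(AlignmentPair(int(a), int(b)))
    return pairs
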