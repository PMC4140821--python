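"""Least-squares (Kabsch) and iterative structural superposition.

The iterative variant seeds a residue correspondence from a global sequence
alignment, superposes on the current Cα pairs, prunes pairs whose Cα
distance exceeds a cutoff, and repeats until the matched-pair set is stable.
Pruned pairs are re-admitted whenever a later superposition brings them back
under the cutoff, so the procedure converges to a self-consistent core of
equivalent residues — the quantity reported is the RMSD over that core
together with the sequence identity of the matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentFailureError, DegenerateGeometryError
from .structure_io import Residue, Structure


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    matched_pairs: list[tuple[Residue, Residue]] = field(default_factory=list)
    seq_identity: float = 0.0  # percent over matched pairs

    def apply(self, s: Structure) -> Structure:
        return s.transformed(self.rotation, self.translation)


def kabsch(fixed: np.ndarray, moving: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping `moving` onto `fixed`.

    Minimizes RMSD over paired points; reflections are excluded by the
    determinant correction, so the result is always a physical rotation.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {fixed.shape} vs {moving.shape}")
    n = fixed.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    X = moving - cm
    Y = fixed - cf
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line undetermined
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise DegenerateGeometryError("point set is collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    diff = (moving @ R.T + t) - fixed
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(R, t, rmsd, n)


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _align_chains(seq_a: str, seq_b: str, gap_open: float = 8.0, gap_extend: float = 1.0):
    """Global BLOSUM62 alignment; returns index pairs (i in a, j in b)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    sa = seq_a.replace("X", "A")  # X is outside BLOSUM62's alphabet handling here
    sb = seq_b.replace("X", "A")
    aln = aligner.align(sa, sb)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs, aln.score


def iterative_superpose(
    a: Structure,
    b: Structure,
    chain_a: str | None = None,
    chain_b: str | None = None,
    init: list[tuple[int, int]] | None = None,
    prune_cutoff: float = 3.5,
    max_iter: int = 20,
    min_alignment_score: float = 0.0,
) -> SuperpositionResult:
    """Iteratively superpose chain of `b` onto chain of `a` with pair pruning.

    Parameters
    ----------
    init : optional precomputed residue-index pairs (positions within each
        chain); when omitted the correspondence is seeded from a global
        BLOSUM62 sequence alignment (gap open 8, extend 1).
    prune_cutoff : Å; pairs farther than this after superposition drop out
        of the next round (and may re-enter later).
    """
    chain_a = chain_a or a.chain_ids[0]
    chain_b = chain_b or b.chain_ids[0]
    res_a = [r for r in a.chains[chain_a] if r.ca is not None]
    res_b = [r for r in b.chains[chain_b] if r.ca is not None]
    if init is None:
        seq_a = "".join(r.one_letter() for r in res_a)
        seq_b = "".join(r.one_letter() for r in res_b)
        all_pairs, score = _align_chains(seq_a, seq_b)
        if not all_pairs or score < min_alignment_score:
            raise AlignmentFailureError(
                f"no usable alignment between {chain_a} and {chain_b} (score {score})"
            )
    else:
        all_pairs = list(init)
        if not all_pairs:
            raise AlignmentFailureError("empty precomputed pair list")

    ca_a = np.vstack([res_a[i].ca.coord for i, _ in all_pairs])
    ca_b = np.vstack([res_b[j].ca.coord for _, j in all_pairs])

    active = np.ones(len(all_pairs), dtype=bool)
    result = None
    for _ in range(max_iter):
        if active.sum() < 3:
            raise DegenerateGeometryError("fewer than 3 pairs remain during pruning")
        result = kabsch(ca_a[active], ca_b[active])
        moved = ca_b @ result.rotation.T + result.translation
        d = np.linalg.norm(moved - ca_a, axis=1)
        new_active = d <= prune_cutoff
        if not new_active.any():
            # cutoff excludes everything: keep previous set, stop
            break
        if np.array_equal(new_active, active):
            active = new_active
            break
        active = new_active
    # final superposition on the converged set
    result = kabsch(ca_a[active], ca_b[active])
    matched = [
        (res_a[i], res_b[j]) for (i, j), keep in zip(all_pairs, active) if keep
    ]
    ident = sum(1 for ra, rb in matched if ra.res_name == rb.res_name)
    result.matched_pairs = matched
    result.n_pairs = len(matched)
    result.seq_identity = 100.0 * ident / len(matched) if matched else 0.0
    return result
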