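"""Per-position sequence conservation from a multiple alignment.

Each alignment column is scored by averaging, over all unordered pairs of
non-gap residues, a BLOSUM62-derived pairwise similarity

    s(x, y) = clamp[0,1] (B(x,y) − Bmin) / ((B(x,x) + B(y,y))/2 − Bmin)

where Bmin is the minimum of the 20×20 standard-residue block. The column
score is 100·mean(s), so a column of identical residues (no gaps) scores
exactly 100. Pairs involving a gap or 'X' are skipped; columns with fewer
than two usable residues are flagged undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, MappingError, UndefinedStatisticError
from .structure_io import Structure, extract_sequence

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_B62 = substitution_matrices.load("BLOSUM62")
BLOSUM62_MIN = float(min(_B62[x][y] for x in AMINO_ACIDS for y in AMINO_ACIDS))


def pair_similarity(x: str, y: str) -> float:
    """Normalized BLOSUM62 similarity of two residues, in [0, 1]."""
    b = float(_B62[x][y])
    denom = (float(_B62[x][x]) + float(_B62[y][y])) / 2.0 - BLOSUM62_MIN
    return float(np.clip((b - BLOSUM62_MIN) / denom, 0.0, 1.0))


@dataclass
class Alignment:
    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise FormatError("alignment needs >= 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def get(self, seq_id: str) -> str:
        for i, s in zip(self.ids, self.sequences):
            if i == seq_id:
                return s
        raise KeyError(f"sequence id {seq_id!r} not in alignment")


@dataclass
class ConservationProfile:
    scores: np.ndarray    # per column, [0, 100]; NaN where undefined
    coverage: np.ndarray  # per column fraction of non-gap sequences


def read_alignment(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq).upper() for r in records])


def write_alignment(a: Alignment, path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.sequences)]
    SeqIO.write(records, str(path), "fasta")


def conservation_profile(a: Alignment) -> ConservationProfile:
    ncol = a.length
    scores = np.full(ncol, np.nan)
    coverage = np.zeros(ncol)
    for c in range(ncol):
        column = [s[c] for s in a.sequences]
        usable = [x for x in column if x in AMINO_ACIDS]
        coverage[c] = sum(1 for x in column if x != "-") / a.n_sequences
        if len(usable) < 2:
            continue
        sims = [
            pair_similarity(usable[i], usable[j])
            for i in range(len(usable))
            for j in range(i + 1, len(usable))
        ]
        scores[c] = 100.0 * float(np.mean(sims))
    return ConservationProfile(scores, coverage)


def map_profile(
    p: ConservationProfile,
    a: Alignment,
    ref_id: str,
    s: Structure,
    chain_id: str,
    min_identity: float = 0.95,
) -> dict[int, float]:
    """Map column scores onto chain residues via the reference sequence.

    The de-gapped reference must match the chain sequence at >= min_identity
    positional identity (same length). Returns {author seq_id: score}; NaN
    columns are omitted.
    """
    ref = a.get(ref_id)
    chain_seq, seq_ids = extract_sequence(s, chain_id)
    degapped_cols = [c for c, x in enumerate(ref) if x != "-"]
    degapped = "".join(ref[c] for c in degapped_cols)
    if len(degapped) != len(chain_seq):
        raise MappingError(
            f"reference {ref_id!r} has {len(degapped)} residues but chain "
            f"{chain_id!r} has {len(chain_seq)}"
        )
    matches = sum(1 for x, y in zip(degapped, chain_seq) if x == y or "X" in (x, y))
    identity = matches / len(chain_seq)
    if identity < min_identity:
        first = next(i for i, (x, y) in enumerate(zip(degapped, chain_seq)) if x != y)
        raise MappingError(
            f"reference/structure identity {identity:.2f} < {min_identity}; "
            f"first conflict at position {first}: {degapped[first]} vs {chain_seq[first]}"
        )
    out: dict[int, float] = {}
    for pos, col in enumerate(degapped_cols):
        if np.isfinite(p.scores[col]):
            out[seq_ids[pos]] = float(p.scores[col])
    return out


def interface_conservation(
    scores: dict[int, float],
    iface: set[int],
    surface: set[int],
) -> dict[str, float]:
    """Mean conservation of interface vs (non-interface) surface residues.

    enrichment = iface_mean − surface_mean; positive values indicate the
    interface is more conserved than the rest of the exposed surface.
    """
    iface_scores = [scores[r] for r in iface if r in scores]
    surf_scores = [scores[r] for r in surface if r in scores]
    if not iface_scores or not surf_scores:
        raise UndefinedStatisticError("empty interface or surface residue set")
    im = float(np.mean(iface_scores))
    sm = float(np.mean(surf_scores))
    return {"iface_mean": im, "surface_mean": sm, "enrichment": im - sm}
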