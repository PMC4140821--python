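"""Chemical cross-link tables: parsing, score filtering, model auditing and
flat-bottom distance restraints.

Cross-links (lysine-reactive DSS by default) are treated as Cα–Cα distance
observations between subunit residues. Auditing a model classifies each
mapped link as satisfied (d < satisfied_cutoff), outlier (d > outlier_cutoff)
or violated-non-outlier, and reports mean distances with and without the
outliers. The restraint energy is a flat-bottom harmonic: zero below the
upper bound, k·(d − d_upper)² beyond it, with an analytic gradient on the
Cα positions for use in refinement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AuditError, FormatError, ParameterError
from .structure_io import Structure

REQUIRED_COLUMNS = ["protein1", "res1", "protein2", "res2", "type", "ld_score", "delta_score"]

#: post-search identification thresholds
LD_MIN = 25.0
DELTA_MAX = 0.95

SATISFIED_CUTOFF = 40.0
OUTLIER_CUTOFF = 60.0


@dataclass
class CrossLink:
    protein1: str
    res1: int
    protein2: str
    res2: int
    link_type: str = "inter"        # {inter, intra}
    ld_score: float | None = None
    delta_score: float | None = None
    linker: str = "DSS"
    residue_letter1: str | None = None
    residue_letter2: str | None = None

    def __post_init__(self) -> None:
        if self.res1 <= 0 or self.res2 <= 0:
            raise FormatError(f"non-positive residue index in link {self}")


def _parse_residue(token) -> tuple[int, str | None]:
    """'180' or 'K180' → (180, optional residue letter)."""
    text = str(token).strip()
    m = re.fullmatch(r"([A-Za-z]?)(\d+)", text)
    if not m:
        raise FormatError(f"unparsable residue field {token!r}")
    letter = m.group(1).upper() or None
    return int(m.group(2)), letter


def read_links(path) -> list[CrossLink]:
    """Read a TSV cross-link table (columns: protein1, res1, protein2, res2,
    type, ld_score, delta_score). Residue fields may carry a one-letter
    residue prefix (K180); row order is preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    links: list[CrossLink] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            r1, l1 = _parse_residue(row.res1)
            r2, l2 = _parse_residue(row.res2)
            ld = float(row.ld_score) if pd.notna(row.ld_score) and row.ld_score != "" else None
            ds = float(row.delta_score) if pd.notna(row.delta_score) and row.delta_score != "" else None
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
        links.append(
            CrossLink(
                str(row.protein1), r1, str(row.protein2), r2,
                link_type=str(row.type), ld_score=ld, delta_score=ds,
                residue_letter1=l1, residue_letter2=l2,
            )
        )
    return links


def write_links(links: list[CrossLink], path) -> None:
    rows = [
        {
            "protein1": l.protein1, "res1": l.res1,
            "protein2": l.protein2, "res2": l.res2,
            "type": l.link_type, "ld_score": l.ld_score, "delta_score": l.delta_score,
        }
        for l in links
    ]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_links(
    links: list[CrossLink],
    ld_min: float = LD_MIN,
    delta_max: float = DELTA_MAX,
) -> list[CrossLink]:
    """Keep links with ld_score > ld_min AND delta_score < delta_max.

    Links missing either score are kept (tables exported after upstream
    filtering typically omit them) with a warning.
    """
    kept = []
    for l in links:
        if l.ld_score is None or l.delta_score is None:
            import warnings

            warnings.warn(f"link {l.protein1}:{l.res1}-{l.protein2}:{l.res2} has no scores; kept", stacklevel=2)
            kept.append(l)
        elif l.ld_score > ld_min and l.delta_score < delta_max:
            kept.append(l)
    return kept


@dataclass
class LinkRecord:
    link: CrossLink
    distance: float | None          # Å, None if unmapped
    satisfied: bool = False
    outlier: bool = False
    ambiguous: bool = False
    duplicate: bool = False


@dataclass
class LinkAudit:
    records: list[LinkRecord]
    mean_all: float
    mean_excl_outliers: float
    n_mapped: int = 0
    n_satisfied: int = 0
    n_violated: int = 0             # cutoff ≤ d ≤ outlier_cutoff
    n_outliers: int = 0
    n_unmapped: int = 0
    satisfied_cutoff: float = SATISFIED_CUTOFF
    outlier_cutoff: float = OUTLIER_CUTOFF

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            l = r.link
            rows.append(
                {
                    "protein1": l.protein1, "res1": l.res1,
                    "protein2": l.protein2, "res2": l.res2,
                    "type": l.link_type, "distance": r.distance,
                    "satisfied": r.satisfied, "outlier": r.outlier,
                    "ambiguous": r.ambiguous, "duplicate": r.duplicate,
                }
            )
        return pd.DataFrame(rows)


def _ca_positions(model: Structure, chain_id: str, seq_id: int) -> list[np.ndarray]:
    out = []
    for res in model.chains.get(chain_id, []):
        if res.seq_id == seq_id and res.ca is not None:
            out.append(res.ca.coord)
    return out


def audit_links(
    model: Structure,
    links: list[CrossLink],
    chain_map: dict[str, str] | None = None,
    satisfied_cutoff: float = SATISFIED_CUTOFF,
    outlier_cutoff: float = OUTLIER_CUTOFF,
) -> LinkAudit:
    """Measure Cα–Cα distances of each link on `model` and classify them.

    chain_map maps protein names in the table to chain ids (identity when
    omitted). Residues present in several copies use the minimum distance
    over copies (flagged ambiguous); links to residues absent from the
    model are counted unmapped and excluded from the means.
    """
    chain_map = chain_map or {}
    records: list[LinkRecord] = []
    seen: set[tuple] = set()
    for l in links:
        c1 = chain_map.get(l.protein1, l.protein1)
        c2 = chain_map.get(l.protein2, l.protein2)
        p1 = _ca_positions(model, c1, l.res1)
        p2 = _ca_positions(model, c2, l.res2)
        key = (c1, l.res1, c2, l.res2)
        dup = key in seen or (key[2:] + key[:2]) in seen
        seen.add(key)
        if not p1 or not p2:
            records.append(LinkRecord(l, None, duplicate=dup))
            continue
        d = min(
            float(np.linalg.norm(a - b)) for a in p1 for b in p2
        )
        rec = LinkRecord(
            l,
            d,
            satisfied=d < satisfied_cutoff,
            outlier=d > outlier_cutoff,
            ambiguous=len(p1) > 1 or len(p2) > 1,
            duplicate=dup,
        )
        records.append(rec)
    mapped = [r.distance for r in records if r.distance is not None]
    if not mapped:
        raise AuditError("no link could be mapped onto the model")
    non_outlier = [
        r.distance for r in records if r.distance is not None and not r.outlier
    ]
    return LinkAudit(
        records=records,
        mean_all=float(np.mean(mapped)),
        mean_excl_outliers=float(np.mean(non_outlier)) if non_outlier else float("nan"),
        n_mapped=len(mapped),
        n_satisfied=sum(r.satisfied for r in records),
        n_violated=sum(
            1
            for r in records
            if r.distance is not None and not r.satisfied and not r.outlier
        ),
        n_outliers=sum(r.outlier for r in records),
        n_unmapped=sum(1 for r in records if r.distance is None),
        satisfied_cutoff=satisfied_cutoff,
        outlier_cutoff=outlier_cutoff,
    )


def restraint_energy(
    model: Structure,
    links: list[CrossLink],
    chain_map: dict[str, str] | None = None,
    d_upper: float = SATISFIED_CUTOFF,
    k: float = 1.0,
) -> tuple[float, dict[tuple[str, int], np.ndarray]]:
    """Flat-bottom harmonic restraint energy E = Σ k·max(0, d − d_upper)².

    Returns (E, gradient) where gradient maps (chain_id, seq_id) of each
    restrained Cα to dE/dx (Å⁻¹ energy units). Unmapped links contribute
    nothing; ambiguous links act on the closest copy.
    """
    if k <= 0:
        raise ParameterError(f"force constant k must be > 0, got {k}")
    chain_map = chain_map or {}
    energy = 0.0
    grad: dict[tuple[str, int], np.ndarray] = {}
    for l in links:
        c1 = chain_map.get(l.protein1, l.protein1)
        c2 = chain_map.get(l.protein2, l.protein2)
        p1 = _ca_positions(model, c1, l.res1)
        p2 = _ca_positions(model, c2, l.res2)
        if not p1 or not p2:
            continue
        best = min(
            ((a, b) for a in p1 for b in p2),
            key=lambda ab: float(np.linalg.norm(ab[0] - ab[1])),
        )
        a, b = best
        d = float(np.linalg.norm(a - b))
        if d <= d_upper or d == 0.0:
            continue
        excess = d - d_upper
        energy += k * excess**2
        g = 2.0 * k * excess * (a - b) / d
        k1, k2 = (c1, l.res1), (c2, l.res2)
        grad[k1] = grad.get(k1, np.zeros(3)) + g
        grad[k2] = grad.get(k2, np.zeros(3)) - g
    return energy, grad
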