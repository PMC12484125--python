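"""PLP-binding-motif analysis: the conserved catalytic lysine and its
tetrad signature.

PLP-dependent decarboxylases anchor the cofactor through a Schiff base to
a strictly conserved active-site lysine.  The residues immediately
N-terminal of that lysine modulate substrate specificity, so the
four-residue window ending in the lysine (the *tetrad*, e.g. ``SGHK`` in
glutamate decarboxylases) acts as a family signature.  This module locates
the conserved lysine column in a family alignment, extracts each member's
tetrad from its ungapped sequence, derives the family consensus pattern in
bracket notation (minority variants lowercased, e.g. ``S-[Fy]-[Sa]-K``),
classifies tetrads against known consensus sets, and predicts cofactor
type (PLP vs pyruvoyl).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import enum

from .align import MultipleAlignment, OutlierReport
from .catalog import ProteinRecord
from .families import AADCFamily, CofactorClass, MOTIF_GROUP_NAME

TETRAD_LENGTH = 4


class MotifError(Exception):
    pass


@dataclass
class TetradMotif:
    """One sequence's PLP-binding tetrad: the conserved K plus the three
    residues immediately N-terminal, with the K's 1-based ungapped position."""

    record_id: str
    tetrad: str
    lysine_position: int

    def __post_init__(self) -> None:
        if len(self.tetrad) != TETRAD_LENGTH or not self.tetrad.endswith("K"):
            raise MotifError(f"malformed tetrad {self.tetrad!r}")
        if self.lysine_position < TETRAD_LENGTH:
            raise MotifError("lysine position leaves no room for the tetrad")


@dataclass
class ConsensusMotif:
    """Family-level tetrad consensus with per-position residue counts."""

    family_name: str
    position_frequencies: list[Counter]
    primary_motif: str
    secondary_motifs: list[str]
    pattern: str
    n_tetrads: int = 0

    def matches(self, tetrad: str) -> bool:
        """True when every tetrad residue was observed at its position."""
        if len(tetrad) != TETRAD_LENGTH:
            return False
        return all(
            tetrad[i] in self.position_frequencies[i] for i in range(TETRAD_LENGTH)
        )


class CofactorBasis(enum.Enum):
    FAMILY_RULE = "FAMILY_RULE"          # HisDC / A1DC: always pyruvoyl
    MOTIF_ABSENT_SHORT = "MOTIF_ABSENT_SHORT"  # no tetrad + short sequence
    MOTIF_PRESENT = "MOTIF_PRESENT"


@dataclass
class CofactorCall:
    record_id: str
    call: CofactorClass
    basis: CofactorBasis


# ---------------------------------------------------------------------------
# Conserved lysine and tetrad extraction
# ---------------------------------------------------------------------------

def find_conserved_lysine_column(
    msa: MultipleAlignment, min_conservation: float = 0.7
) -> int | None:
    """Column index of the conserved catalytic lysine, or None.

    Picks the column with the highest fraction of rows carrying K (gaps
    count against conservation) provided that fraction reaches
    ``min_conservation``.  Columns tying on K fraction are ranked by how
    conserved the tetrad extracted around them is (the catalytic lysine
    sits in a conserved context, a lone conserved K does not); any
    remaining tie goes to the leftmost column.
    """
    if len(msa.rows) < 2:
        raise MotifError("need an alignment of >= 2 rows")
    n_rows = len(msa.rows)
    best: tuple[float, float, int] | None = None  # (k_frac, support, -col)
    for j in range(msa.n_columns):
        col = msa.column(j)
        k_frac = col.count("K") / n_rows
        if k_frac == 0:
            continue
        key = (k_frac, _tetrad_support(msa, j), -j)
        if best is None or key > best:
            best = key
    if best is None or best[0] < min_conservation:
        return None
    return -best[2]


def _tetrad_support(msa: MultipleAlignment, k_column: int) -> float:
    """Fraction of rows sharing the modal tetrad at ``k_column``."""
    tetrads = Counter()
    for rid, row in zip(msa.ids, msa.rows):
        t = _tetrad_at(row, k_column)
        if t is not None:
            tetrads[t] += 1
    if not tetrads:
        return 0.0
    return tetrads.most_common(1)[0][1] / len(msa.rows)


def _tetrad_at(row: str, k_column: int) -> str | None:
    if row[k_column] != "K":
        return None
    ungapped = row.replace("-", "")
    k_pos = len(row[: k_column + 1].replace("-", ""))  # 1-based ungapped
    if k_pos < TETRAD_LENGTH:
        return None
    return ungapped[k_pos - TETRAD_LENGTH : k_pos]


def extract_tetrad(
    record_id: str, msa: MultipleAlignment, k_column: int
) -> TetradMotif | None:
    """Tetrad for one row: the K at ``k_column`` plus its three N-terminal
    neighbors in the *ungapped* sequence (insertions in other rows cannot
    corrupt a row's motif).  None if the row lacks K there or the K sits
    within the first three residues.
    """
    if not 0 <= k_column < msa.n_columns:
        raise MotifError(f"k_column {k_column} out of range")
    row = msa.row(record_id)
    tetrad = _tetrad_at(row, k_column)
    if tetrad is None:
        return None
    k_pos = len(row[: k_column + 1].replace("-", ""))
    return TetradMotif(record_id=record_id, tetrad=tetrad, lysine_position=k_pos)


def extract_family_tetrads(
    msa: MultipleAlignment, min_conservation: float = 0.7
) -> dict[str, TetradMotif]:
    """Convenience: locate the conserved K column and extract every row's
    tetrad; empty dict when no conserved lysine column exists."""
    k_col = find_conserved_lysine_column(msa, min_conservation)
    if k_col is None:
        return {}
    out = {}
    for rid in msa.ids:
        t = extract_tetrad(rid, msa, k_col)
        if t is not None:
            out[rid] = t
    return out


# ---------------------------------------------------------------------------
# Consensus derivation
# ---------------------------------------------------------------------------

def consensus_motif(
    tetrads: list[TetradMotif],
    minority_fraction: float = 0.10,
    family_name: str = "",
) -> ConsensusMotif:
    """Family consensus pattern from observed tetrads.

    The primary motif is the modal full tetrad (ties: lexicographically
    smallest); secondaries are every other observed tetrad in descending
    frequency.  The pattern renders invariant positions as the residue and
    variable positions as a bracket list ordered by descending frequency,
    lowercasing residues seen in under ``minority_fraction`` of tetrads.
    """
    if not tetrads:
        raise MotifError("consensus_motif: no tetrads")
    n = len(tetrads)
    full = Counter(t.tetrad for t in tetrads)
    top = max(full.values())
    primary = min(t for t, c in full.items() if c == top)
    secondaries = sorted(
        (t for t in full if t != primary), key=lambda t: (-full[t], t)
    )
    pos_freq = [Counter(t.tetrad[i] for t in tetrads) for i in range(TETRAD_LENGTH)]
    pattern = _render_pattern(pos_freq, n, minority_fraction)
    return ConsensusMotif(
        family_name=family_name,
        position_frequencies=pos_freq,
        primary_motif=primary,
        secondary_motifs=secondaries,
        pattern=pattern,
        n_tetrads=n,
    )


def _render_pattern(
    pos_freq: list[Counter], n: int, minority_fraction: float
) -> str:
    segments: list[str] = []
    run = ""  # run of single-residue positions
    for freq in pos_freq:
        if len(freq) == 1:
            run += next(iter(freq))
            continue
        if run:
            segments.append(run)
            run = ""
        residues = sorted(freq, key=lambda r: (-freq[r], r))
        rendered = "".join(
            r.lower() if freq[r] / n < minority_fraction else r for r in residues
        )
        segments.append(f"[{rendered}]")
    if run:
        segments.append(run)
    return "-".join(segments)


# ---------------------------------------------------------------------------
# Classification, reassignment, cofactor prediction
# ---------------------------------------------------------------------------

def classify_by_tetrad(
    tetrad: str, known_consensus: list[ConsensusMotif]
) -> list[ConsensusMotif]:
    """Candidate families for a tetrad, best first: exact primary-motif
    matches, then secondary-motif matches, then pattern-only matches."""
    if len(tetrad) != TETRAD_LENGTH or not tetrad.endswith("K"):
        raise MotifError(f"malformed tetrad {tetrad!r}")
    if not known_consensus:
        raise MotifError("classify_by_tetrad: empty consensus set")
    primary = [c for c in known_consensus if c.primary_motif == tetrad]
    secondary = [
        c
        for c in known_consensus
        if tetrad in c.secondary_motifs and c not in primary
    ]
    pattern_only = [
        c
        for c in known_consensus
        if c.matches(tetrad) and c not in primary and c not in secondary
    ]
    return primary + secondary + pattern_only


def scan_tetrads(sequence: str, known_consensus: list[ConsensusMotif]) -> list[TetradMotif]:
    """Scan an ungapped sequence for 4-mers ending in K that match any known
    family consensus pattern.  Used for sequences that do not align to their
    group's conserved-lysine column (e.g. flagged outliers)."""
    hits = []
    for i in range(TETRAD_LENGTH - 1, len(sequence)):
        if sequence[i] != "K":
            continue
        window = sequence[i - TETRAD_LENGTH + 1 : i + 1]
        if any(c.matches(window) for c in known_consensus):
            hits.append(TetradMotif("", tetrad=window, lysine_position=i + 1))
    return hits


def reassign_outliers(
    outliers: list[OutlierReport],
    tetrads: dict[str, TetradMotif],
    known_consensus: list[ConsensusMotif],
    own_family_name: str,
    sequences: dict[str, str] | None = None,
) -> list[OutlierReport]:
    """Propose a source family for flagged outliers whose tetrad is the
    primary motif of a *different* family.

    A flagged outlier usually fails to align at the group's conserved-K
    column, so when it has no aligned tetrad and ``sequences`` is given,
    its sequence is scanned for a tetrad matching any known consensus.
    """
    own_group = MOTIF_GROUP_NAME.get(own_family_name, own_family_name)
    for rep in outliers:
        if not rep.flagged:
            continue
        tet = tetrads.get(rep.record_id)
        candidates: list[str] = []
        if tet is not None:
            candidates = [tet.tetrad]
        elif sequences and rep.record_id in sequences:
            candidates = [
                t.tetrad for t in scan_tetrads(sequences[rep.record_id], known_consensus)
            ]
        for tetrad in candidates:
            primaries = [c for c in known_consensus if c.primary_motif == tetrad]
            if any(c.family_name == own_group for c in primaries):
                continue  # motif is its own family's: nothing to propose
            foreign = [c for c in primaries if c.family_name != own_group]
            if foreign:
                rep.candidate_family = foreign[0].family_name
                break
    return outliers


def predict_cofactor(
    record: ProteinRecord,
    tetrad_found: bool,
    short_length_cutoff: int = 200,
) -> CofactorCall:
    """Cofactor call for one record.

    Histidine and aspartate-1 decarboxylases are pyruvoyl-dependent as a
    family; otherwise a sequence with no PLP tetrad and a length under
    ``short_length_cutoff`` residues (the hallmark of pyruvoyl-dependent
    arginine decarboxylases) is called pyruvoyl, and everything else PLP.
    """
    fam = record.family
    if fam is None:
        raise MotifError(f"record {record.record_id} has no family annotation")
    if fam.cofactor_class is CofactorClass.PYRUVOYL:
        return CofactorCall(record.record_id, CofactorClass.PYRUVOYL,
                            CofactorBasis.FAMILY_RULE)
    if not tetrad_found and record.length < short_length_cutoff:
        return CofactorCall(record.record_id, CofactorClass.PYRUVOYL,
                            CofactorBasis.MOTIF_ABSENT_SHORT)
    return CofactorCall(record.record_id, CofactorClass.PLP,
                        CofactorBasis.MOTIF_PRESENT)
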