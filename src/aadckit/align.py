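"""Pairwise and multiple alignment, percent-identity matrices, group
summaries and low-identity outlier detection.

Percent identity here follows the common percent-identity-matrix (PIM)
convention: identical residue columns divided by columns where *both*
rows carry a residue (gap-containing columns are excluded from the
denominator).  ``X`` is treated as an unknown residue and never matches
anything, including another ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .families import AADCFamily


class AlignmentError(Exception):
    pass


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences as equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned strings differ in length")


_DEFAULT_MATRIX = substitution_matrices.load("BLOSUM62")


def _make_aligner(substitution_table, gap_open: float, gap_extend: float):
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        _DEFAULT_MATRIX if substitution_table is None else substitution_table
    )
    # A gap run of length L scores -(gap_open + (L-1) * gap_extend).
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    substitution_table=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties.

    Defaults are the classic protein settings: BLOSUM62 with gap open 10
    and extend 1.  Among co-optimal alignments the first one enumerated by
    the traceback is returned, so results are deterministic.
    """
    if not a or not b:
        raise AlignmentError("global_align: empty sequence")
    aligner = _make_aligner(substitution_table, gap_open, gap_extend)
    best = aligner.align(a, b)[0]
    return PairwiseAlignment(best[0], best[1], float(best.score))


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity of two rows of an alignment.

    100 x identical residue columns over columns where both rows have a
    residue; ``X`` matches nothing; an alignment with no shared residue
    columns scores 0.
    """
    if len(aligned_a) != len(aligned_b):
        raise AlignmentError("percent_identity: length mismatch")
    both = 0
    same = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        both += 1
        if x == y and x != "X":
            same += 1
    if both == 0:
        return 0.0
    return 100.0 * same / both


# ---------------------------------------------------------------------------
# Multiple alignment (center star) and external alignment readers
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """A gapped multiple alignment: parallel id and row lists."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, record_id: str) -> str:
        return self.rows[self.ids.index(record_id)]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _center_index(seqs: Sequence[str]) -> int:
    """Index of the most central sequence: minimal summed edit distance.

    Edit distance (via edlib) is a fast, exact stand-in for summed pairwise
    identity when picking the star center; the actual alignment is still
    done with the affine-gap aligner.
    """
    n = len(seqs)
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")[
                "editDistance"
            ]
            total[i] += d
            total[j] += d
    return int(np.argmin(total))


def _merge_into_star(
    master_center: str, merged_rows: list[str], pair: PairwiseAlignment
) -> tuple[str, list[str], str]:
    """Merge one center-vs-sequence alignment into the growing MSA.

    Standard "once a gap, always a gap": walk the master center row and the
    new pairwise center row together, inserting gap columns on whichever
    side lacks one.
    """
    old_c, new_c, new_row = master_center, pair.aligned_a, pair.aligned_b
    out_old_cols: list[int | None] = []  # None = gap column inserted into old
    out_new_cols: list[int | None] = []
    i = j = 0
    while i < len(old_c) or j < len(new_c):
        ci = old_c[i] if i < len(old_c) else None
        cj = new_c[j] if j < len(new_c) else None
        if ci is not None and cj is not None and (ci == cj or (ci != "-" and cj != "-")):
            out_old_cols.append(i)
            out_new_cols.append(j)
            i += 1
            j += 1
        elif ci == "-" and (cj is None or cj != "-"):
            out_old_cols.append(i)
            out_new_cols.append(None)
            i += 1
        elif cj == "-" or ci is None:
            out_old_cols.append(None)
            out_new_cols.append(j)
            j += 1
        else:  # cj is None
            out_old_cols.append(i)
            out_new_cols.append(None)
            i += 1

    def expand(row: str, cols: list[int | None]) -> str:
        return "".join("-" if c is None else row[c] for c in cols)

    new_center = expand(old_c, out_old_cols)
    new_merged = [expand(r, out_old_cols) for r in merged_rows]
    new_last = expand(new_row, out_new_cols)
    return new_center, new_merged, new_last


def build_msa(
    seqs: Sequence[tuple[str, str]],
    substitution_table=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Center-star multiple alignment of ``(record_id, sequence)`` pairs.

    The center is the sequence closest to all others; every other sequence
    is globally aligned to it and the pairwise alignments are merged with
    "once a gap, always a gap".  Row order follows the input order.
    """
    if len(seqs) < 2:
        raise AlignmentError("build_msa needs at least two sequences")
    ids = [rid for rid, _ in seqs]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate record ids in MSA input")
    raw = [s for _, s in seqs]
    c = _center_index(raw)
    master = raw[c]
    merged: list[str] = []
    order: list[int] = []
    for i, s in enumerate(raw):
        if i == c:
            continue
        pair = global_align(raw[c], s, substitution_table, gap_open, gap_extend)
        master, merged, new_row = _merge_into_star(master, merged, pair)
        merged.append(new_row)
        order.append(i)
    rows_by_index: dict[int, str] = {c: master}
    for idx, row in zip(order, merged):
        rows_by_index[idx] = row
    return MultipleAlignment(ids=ids, rows=[rows_by_index[i] for i in range(len(raw))])


def read_external_alignment(path: str | Path, fmt: str = "fasta") -> MultipleAlignment:
    """Read an externally produced alignment (aligned FASTA or Clustal).

    Downstream behavior is identical to a ``build_msa`` result, so Clustal
    Omega output can be dropped in directly.
    """
    if fmt not in {"fasta", "clustal"}:
        raise AlignmentError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    return MultipleAlignment(
        ids=[r.id for r in aln], rows=[str(r.seq).upper() for r in aln]
    )


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# Percent identity matrix and summaries
# ---------------------------------------------------------------------------

@dataclass
class PercentIdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal 100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise AlignmentError("PIM shape does not match id count")

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def off_diagonal(self) -> np.ndarray:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pim_from_msa(msa: MultipleAlignment) -> PercentIdentityMatrix:
    """Pairwise percent identity over every row pair of an alignment."""
    n = len(msa.ids)
    if n < 2:
        raise AlignmentError("pim_from_msa needs >= 2 rows")
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(msa.rows[i], msa.rows[j])
            values[i, j] = values[j, i] = pid
    return PercentIdentityMatrix(ids=list(msa.ids), values=values)


def write_pim(pim: PercentIdentityMatrix, path: str | Path) -> None:
    pim.to_frame().to_csv(path, sep="\t")


def read_pim(path: str | Path) -> PercentIdentityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PercentIdentityMatrix(ids=[str(i) for i in df.index], values=df.values)


@dataclass
class GroupIdentitySummary:
    """Average and minimum off-diagonal identity for one family group.

    ``average_identity`` / ``minimum_identity`` are None when the group has
    fewer than two members (reported as N/A, as for families where no
    single comparable group exists).
    """

    family: AADCFamily | None
    average_identity: float | None
    minimum_identity: float | None

    @property
    def applicable(self) -> bool:
        return self.average_identity is not None


def summarize_group(
    pim: PercentIdentityMatrix | None, family: AADCFamily | None = None
) -> GroupIdentitySummary:
    if pim is None or len(pim.ids) < 2:
        return GroupIdentitySummary(family, None, None)
    off = pim.off_diagonal()
    return GroupIdentitySummary(family, float(off.mean()), float(off.min()))


# ---------------------------------------------------------------------------
# Outliers and phylum block structure
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    record_id: str
    max_identity_to_group: float
    mean_identity_to_group: float
    flagged: bool
    lowest_in_group: bool = False
    candidate_family: str | None = None  # filled by the motif module


def detect_outliers(
    pim: PercentIdentityMatrix, threshold: float = 30.0
) -> list[OutlierReport]:
    """Flag members whose best identity to any other member is below
    ``threshold`` percent; the group's lowest-identity member is always
    reported, flagged or not.
    """
    n = len(pim.ids)
    if n < 3:
        raise AlignmentError("detect_outliers needs a group of >= 3")
    mask = ~np.eye(n, dtype=bool)
    reports = []
    maxima = []
    for i, rid in enumerate(pim.ids):
        others = pim.values[i][mask[i]]
        mx = float(others.max())
        maxima.append(mx)
        reports.append(
            OutlierReport(
                record_id=rid,
                max_identity_to_group=mx,
                mean_identity_to_group=float(others.mean()),
                flagged=mx < threshold,
            )
        )
    lowest = int(np.argmin(maxima))
    reports[lowest].lowest_in_group = True
    return [r for r in reports if r.flagged or r.lowest_in_group]


def phylum_block_summary(
    pim: PercentIdentityMatrix, phylum_labels: dict[str, str]
) -> dict[tuple[str, str], float | None]:
    """Mean identity within each phylum and between each phylum pair.

    Keys are sorted ``(phylum_a, phylum_b)`` tuples; a within-phylum entry
    with fewer than two members is None.
    """
    missing = set(pim.ids) - set(phylum_labels)
    if missing:
        raise AlignmentError(f"unlabelled ids: {sorted(missing)[:5]}")
    phyla = sorted({phylum_labels[i] for i in pim.ids})
    out: dict[tuple[str, str], float | None] = {}
    idx = {p: [k for k, i in enumerate(pim.ids) if phylum_labels[i] == p] for p in phyla}
    for a_i, pa in enumerate(phyla):
        for pb in phyla[a_i:]:
            if pa == pb:
                members = idx[pa]
                if len(members) < 2:
                    out[(pa, pb)] = None
                    continue
                sub = pim.values[np.ix_(members, members)]
                iu = np.triu_indices(len(members), k=1)
                out[(pa, pb)] = float(sub[iu].mean())
            else:
                sub = pim.values[np.ix_(idx[pa], idx[pb])]
                out[(pa, pb)] = float(sub.mean())
    return out
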