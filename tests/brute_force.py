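"""Independent brute-force oracle for global alignment with affine gaps.

Enumerates every global alignment of two sequences (no gap-gap columns)
and scores each one directly from its column list, so the optimum is
found without any dynamic-programming shortcut shared with the package.
"""

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_alignments(a: str, b: str):
    """Yield every alignment as a list of (char_a, char_b) columns."""
    if not a and not b:
        yield []
        return
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest


def affine_score(columns, matrix=BLOSUM62, gap_open=10.0, gap_extend=1.0):
    """Score one alignment: substitution scores on residue columns, and
    open + (L-1)*extend charged per maximal gap run of length L."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in columns:
        if x == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += matrix[x, y]
            in_gap_a = in_gap_b = False
    return score


def best_score(a: str, b: str, matrix=BLOSUM62, gap_open=10.0, gap_extend=1.0):
    return max(
        affine_score(cols, matrix, gap_open, gap_extend)
        for cols in enumerate_alignments(a, b)
    )
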