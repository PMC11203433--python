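"""Independent reference computations used to cross-check the package.

Nothing here imports alignment code from the package or from biopython:
the exhaustive enumerator generates every gapped pairing of two sequences,
and the Gotoh recursion is a hand-written three-state affine DP.  Both
score a gap run of length L as ``gap_open + (L - 1) * gap_extend`` per
sequence, with end gaps treated like internal ones (global alignment).
"""

from __future__ import annotations

NEG_INF = float("-inf")


def score_alignment_rows(row_a: str, row_b: str, scheme) -> float:
    """Score a finished alignment by direct column/run inspection."""
    total = 0.0
    for a, b in zip(row_a, row_b):
        if a != "-" and b != "-":
            total += scheme.substitution_score(a, b)
    for row in (row_a, row_b):
        in_gap = False
        for ch in row:
            if ch == "-":
                total += scheme.gap_extend if in_gap else scheme.gap_open
                in_gap = True
            else:
                in_gap = False
    return total


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment (pair of gapped rows) of a and b."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def brute_force_score(a: str, b: str, scheme) -> float:
    """Maximum score over the literally enumerated alignment space."""
    return max(
        score_alignment_rows(ra, rb, scheme)
        for ra, rb in enumerate_alignments(a, b)
    )


def gotoh_score(a: str, b: str, scheme) -> float:
    """Affine-gap global alignment score via a three-state recursion.

    Optimizes over the same space as :func:`brute_force_score` (checked
    against it in the unit suite) but is feasible for the full sweep of
    short sequence pairs.
    """
    m, n = len(a), len(b)
    open_, ext = scheme.gap_open, scheme.gap_extend

    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # last col: residue pair
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # last col: gap in b
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # last col: gap in a
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, n + 1):
        Y[0][j] = open_ + (j - 1) * ext

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = scheme.substitution_score(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + open_,
                X[i - 1][j] + ext,
                Y[i - 1][j] + open_,
            )
            Y[i][j] = max(
                M[i][j - 1] + open_,
                Y[i][j - 1] + ext,
                X[i][j - 1] + open_,
            )
    return max(M[m][n], X[m][n], Y[m][n])


def apply_called_variants(ref: str, variants, exon_start: int = 1) -> str:
    """Re-apply called variants to the reference (3'-to-5') independently
    of the package's own apply routine."""
    seq = ref
    for v in sorted(variants, key=lambda v: -v.cdna_start):
        s = v.cdna_start - exon_start + 1
        if v.kind == "substitution":
            seq = seq[: s - 1] + v.alt_allele + seq[s:]
        elif v.kind == "deletion":
            e = v.cdna_end - exon_start + 1
            seq = seq[: s - 1] + seq[e:]
        else:
            seq = seq[:s] + v.alt_allele + seq[s:]
    return seq
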