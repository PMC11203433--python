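"""Global pairwise alignment of a sample exon against the reference exon.

The aligner is Biopython's ``PairwiseAligner`` in global mode with affine gap
penalties: a gap of length L costs ``gap_open + (L - 1) * gap_extend``.  The
identity score is the fraction of alignment columns in which both rows carry
the same unambiguous residue; gap columns count toward the denominator, so
the score penalizes indels as well as substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align as _bio_align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "Alignment",
    "AlignmentError",
    "DEFAULT_SCHEME",
    "global_align",
    "identity_score",
    "format_alignment",
    "alignment_columns",
]

_ALPHABET = "ACGTN"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap parameters.

    ``match`` must exceed ``mismatch``; gap penalties are non-positive with
    ``gap_open <= gap_extend`` (opening a gap never costs less than extending
    one).  'N' scores as a mismatch against every base, including 'N'.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise AlignmentError("match score must exceed mismatch score")
        if not self.gap_open <= self.gap_extend <= 0:
            raise AlignmentError("require gap_open <= gap_extend <= 0")

    def substitution_score(self, a: str, b: str) -> float:
        if a == "N" or b == "N":
            return self.mismatch
        return self.match if a == b else self.mismatch


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class Alignment:
    """A global alignment: two equal-length gapped rows plus its score."""

    ref_row: str
    sample_row: str
    scheme: ScoringScheme
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.sample_row):
            raise AlignmentError("alignment rows must have equal length")
        if len(self.ref_row) == 0:
            raise AlignmentError("empty alignment")
        for i, (a, b) in enumerate(zip(self.ref_row, self.sample_row)):
            if a == "-" and b == "-":
                raise AlignmentError(f"all-gap column at {i}")

    @property
    def ref_seq(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def sample_seq(self) -> str:
        return self.sample_row.replace("-", "")


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise AlignmentError(f"{label} sequence is empty")
    seq = seq.upper()
    for i, b in enumerate(seq):
        if b not in _ALPHABET:
            raise AlignmentError(
                f"{label} sequence has illegal character {b!r} at position {i + 1}"
            )
    return seq


@lru_cache(maxsize=8)
def _matrix(scheme: ScoringScheme) -> substitution_matrices.Array:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = scheme.substitution_score(a, b)
    return m


def global_align(
    ref: str, sample: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> Alignment:
    """Optimal global alignment of ``sample`` against ``ref``.

    Returns one optimal alignment (ties resolved deterministically by the
    aligner); indel placement among co-optimal alignments is irrelevant
    downstream because variant calling re-normalizes indels 3'-wards.
    """
    ref = _check_sequence(ref, "reference")
    sample = _check_sequence(sample, "sample")

    aligner = _bio_align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(scheme)
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend

    result = aligner.align(ref, sample)
    best = result[0]
    return Alignment(
        ref_row=str(best[0]),
        sample_row=str(best[1]),
        scheme=scheme,
        score=float(result.score),
    )


def identity_score(aln: Alignment) -> float:
    """Identical-residue columns divided by total aligned columns, in [0, 1].

    Equals 1.0 iff the two rows are identical and gap-free.  'N' is never
    counted as identical (it is a no-call, not a residue match).
    """
    n = len(aln.ref_row)
    if n == 0:
        raise AlignmentError("zero-length alignment has no identity score")
    identical = sum(
        1
        for a, b in zip(aln.ref_row, aln.sample_row)
        if a == b and a != "-" and a != "N"
    )
    return identical / n


def alignment_columns(aln: Alignment) -> list[tuple[int, str, str, str]]:
    """Per-column classification: (column 1-based, ref, sample, class).

    Class is one of match / mismatch / deletion (gap in sample) /
    insertion (gap in reference) / nocall (an 'N' in either row).
    """
    rows = []
    for i, (a, b) in enumerate(zip(aln.ref_row, aln.sample_row), start=1):
        if b == "-":
            cls = "deletion"
        elif a == "-":
            cls = "insertion"
        elif a == "N" or b == "N":
            cls = "nocall"
        elif a == b:
            cls = "match"
        else:
            cls = "mismatch"
        rows.append((i, a, b, cls))
    return rows


def format_alignment(aln: Alignment, width: int = 60) -> str:
    """Human-readable juxtaposition of the two rows, wrapped at ``width``.

    The middle line marks identical columns with '|'.
    """
    out = []
    for start in range(0, len(aln.ref_row), width):
        r = aln.ref_row[start : start + width]
        s = aln.sample_row[start : start + width]
        marks = "".join(
            "|" if a == b and a not in "-N" else " " for a, b in zip(r, s)
        )
        out.append(f"ref     {r}")
        out.append(f"        {marks}")
        out.append(f"sample  {s}")
        out.append("")
    return "\n".join(out).rstrip() + "\n"
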